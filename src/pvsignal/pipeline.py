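"""End-to-end orchestration: config, ETL, screen, characteristics, outputs.

``run_pipeline`` chains the stages — parse quarterly files, clean cases,
build drug-event pairs, screen the configured targets against the
configured events — and writes TSV artifacts plus a line-oriented log.
Identical inputs and config always produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort
from .cleaning import CleanReportSet, clean_quarter, load_deletion_list
from .io import parse_quarter
from .stats import format_screen, run_screen

__all__ = ["StudyConfig", "run_pipeline", "summarize_characteristics"]

# Outcome-code precedence for mutually exclusive seriousness categories:
# a report with several outcomes is counted once under the most severe.
SERIOUSNESS_PRECEDENCE = (("DE", "Fatal"), ("LT", "Life-threatening"), ("HO", "Hospitalization"))

OCCUPATION_GROUPS = {
    "MD": "Health professional",
    "PH": "Health professional",
    "OT": "Health professional",
    "HP": "Health professional",
    "CN": "Consumer",
    "LW": "Other",
}


@dataclass
class StudyConfig:
    """Study definition for one pipeline run (YAML-loadable)."""

    input_dir: str
    output_dir: str
    target_drugs: list[str] = field(default_factory=lambda: ["piperacillin\\tazobactam"])
    events: list[str] | None = None  # None -> all packaged electrolyte disorders
    comparator: str | list[str] = "all_other_drugs"
    dialect: str = "auto"
    quarters: list[str] | None = None  # None -> whatever single quarter is present
    deletion_list: str | None = None
    seed: int = 0
    display_digits: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.quarters is not None and len(self.quarters) == 0:
            raise ValueError("quarter list must not be empty")
        if isinstance(self.comparator, list):
            missing = [d for d in self.target_drugs if d not in self.comparator]
            if missing:
                raise ValueError(f"comparator drug list must include the target(s): {missing}")


def summarize_characteristics(clean: CleanReportSet, target_reports: set[str] | None = None) -> pd.DataFrame:
    """Characteristics table (n, % of reports to 1 dp) for a report set.

    Sections: age group, sex, seriousness (serious iff any outcome code;
    serious subdivided by the fatal > life-threatening > hospitalization >
    other precedence), report source, top-4 reporter countries.
    """
    demo = clean.demo
    if target_reports is not None:
        demo = demo[demo["report_id"].isin(target_reports)]
    n = len(demo)
    rows: list[tuple[str, str, int]] = []

    def section(name: str, counts: dict[str, int]) -> None:
        for level, k in counts.items():
            rows.append((name, level, k))

    ages = demo["age_group"].value_counts()
    section("age", {g: int(ages.get(g, 0)) for g in ("<=18", "19-64", ">=65", "unknown")})

    sex = demo["sex"].map({"M": "male", "F": "female"}).fillna("unknown").replace("", "unknown")
    sc = sex.value_counts()
    section("sex", {g: int(sc.get(g, 0)) for g in ("male", "female", "unknown")})

    outc = clean.outc[clean.outc["report_id"].isin(set(demo["report_id"]))]
    codes_by_report = outc.groupby("report_id")["outc_cod"].agg(set)
    serious_ids = set(codes_by_report.index)
    cat_counts = {"Serious": len(serious_ids & set(demo["report_id"]))}
    remaining = codes_by_report.copy()
    for code, label in SERIOUSNESS_PRECEDENCE:
        hit = remaining.map(lambda s: code in s)
        cat_counts[label] = int(hit.sum())
        remaining = remaining[~hit]
    cat_counts["Other serious"] = len(remaining)
    cat_counts["Non-serious"] = n - cat_counts["Serious"]
    section("seriousness", cat_counts)

    occ = demo["occupation"].map(OCCUPATION_GROUPS).fillna("Unknown")
    oc = occ.value_counts()
    section("report_source", {g: int(oc.get(g, 0)) for g in ("Health professional", "Consumer", "Other", "Unknown")})

    country = demo["country"].astype(str).str.strip()
    known = country[country != ""]
    top = list(known.value_counts().head(4).index)
    cc = {c: int((known == c).sum()) for c in top}
    cc["Other"] = int(len(known) - sum(cc.values()))
    cc["Unknown"] = int((country == "").sum())
    section("reporter_country", cc)

    out = pd.DataFrame(rows, columns=["section", "level", "n"])
    out["pct"] = (100.0 * out["n"] / n).round(1) if n else 0.0
    return out


def run_pipeline(config: StudyConfig) -> dict[str, Path]:
    """Run ETL -> cleaning -> pairs -> screen; write TSV artifacts + log.

    Returns the artifact paths.  Any stage failure propagates with a
    stage-tagged message (the CLI maps it to a non-zero exit code).
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def stage(name: str):
        log_lines.append(f"stage={name}")
        return name

    try:
        stage("parse")
        quarters = config.quarters or [None]
        parsed = [parse_quarter(config.input_dir, quarter=q, dialect=config.dialect) for q in quarters]
        qd = parsed[0]
        if len(parsed) > 1:
            qd.demo = pd.concat([p.demo for p in parsed], ignore_index=True)
            qd.drug = pd.concat([p.drug for p in parsed], ignore_index=True)
            qd.reac = pd.concat([p.reac for p in parsed], ignore_index=True)
            qd.outc = pd.concat([p.outc for p in parsed], ignore_index=True)
            qd.rejects = pd.concat([p.rejects for p in parsed], ignore_index=True)
        log_lines.append(f"parsed demo={len(qd.demo)} drug={len(qd.drug)} reac={len(qd.reac)} rejects={len(qd.rejects)}")
    except Exception as err:
        raise RuntimeError(f"[parse] {err}") from err

    try:
        stage("clean")
        deletion = load_deletion_list(config.deletion_list)
        clean, tally = clean_quarter(qd, deletion)
        log_lines.append(
            f"cleaned retained={tally.retained} superseded={tally.superseded_version} "
            f"concomitant_rows={tally.concomitant_rows_removed}"
        )
    except Exception as err:
        raise RuntimeError(f"[clean] {err}") from err

    try:
        stage("pairs")
        dictionary = cohort.load_drug_dictionary()
        pairs = cohort.build_pairs(clean, dictionary)
        log_lines.append(f"pairs n={len(pairs)}")
    except Exception as err:
        raise RuntimeError(f"[pairs] {err}") from err

    try:
        stage("screen")
        queries = cohort.load_event_queries()
        if config.events is not None:
            queries = {k: queries[k] for k in config.events}
        table = run_screen(pairs, config.target_drugs, queries, comparator=config.comparator)
        log_lines.append(f"screen rows={len(table)} signals={int(table['signal_any'].sum())}")
    except Exception as err:
        raise RuntimeError(f"[screen] {err}") from err

    artifacts: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        artifacts[name] = path

    emit("signals", format_screen(table, config.display_digits))
    emit("signals_full_precision", table)
    target_ids = set(pairs.loc[pairs["drug"].isin(config.target_drugs), "report_id"])
    emit("characteristics", summarize_characteristics(clean, target_ids))
    tally.to_tsv(outdir / "exclusions.tsv")
    artifacts["exclusions"] = outdir / "exclusions.tsv"
    emit("rejects", qd.rejects)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    artifacts["log"] = outdir / "run.log"
    return artifacts
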
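"""Synthetic FAERS-dialect quarterly files with planted association structure.

The generator emulates the hazards of real spontaneous-report extracts —
multi-version cases, concomitant drug roles, heterogeneous age units,
missing demographics — around a configurable drug-by-event relative
reporting-rate matrix ``lambda``.  With ``lambda = 1`` everywhere, events
are reported independently of drugs; a pair with ``lambda(d, e) = 3``
is reported three times more often (in odds-of-selection terms) on reports
carrying drug ``d``.

Sampling model, per report: drugs are drawn first (without replacement,
by the catalog's marginal probabilities), then each event is drawn with
probability proportional to ``baseline(e) * max over the report's drugs of
lambda(d, e)``.  This deliberately simple mechanism makes the planted
relative reporting rate directly recoverable from clean pair counts.

``PlantedTruth`` records what was actually realized — clean pair counts
(latest case version, non-concomitant drug rows only) and the record
tallies — so every downstream stage can be tested against exact ground
truth without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AGE_UNIT_YEARS

__all__ = ["SynthConfig", "PlantedTruth", "ParameterError", "simulate_reports", "generate_quarter", "planted_ror"]


class ParameterError(ValueError):
    """Invalid generator configuration."""


DEFAULT_DRUGS = {
    "piperacillin\\tazobactam": 0.06,
    "amoxicillin\\clavulanic acid": 0.06,
    "nafcillin": 0.02,
    "flucloxacillin": 0.02,
    "vancomycin": 0.08,
    "furosemide": 0.10,
    "metformin": 0.16,
    "atorvastatin": 0.16,
    "omeprazole": 0.17,
    "paracetamol": 0.17,
}

DEFAULT_EVENTS = {
    "hypokalaemia": 0.02,
    "blood potassium decreased": 0.01,
    "hyponatraemia": 0.02,
    "hypernatraemia": 0.01,
    "nausea": 0.22,
    "diarrhoea": 0.16,
    "rash": 0.16,
    "headache": 0.14,
    "pyrexia": 0.13,
    "dizziness": 0.13,
}


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults give a mid-sized quarter with the
    reporting hazards of real extracts at plausible rates (a few percent of
    cases re-versioned, moderate concomitant coding, ~10% missing age)."""

    n_reports: int = 5000
    drug_catalog: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DRUGS))
    event_catalog: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EVENTS))
    lambda_matrix: dict[tuple[str, str], float] = field(default_factory=dict)
    drugs_per_report_dist: dict[int, float] = field(default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1})
    events_per_report_dist: dict[int, float] = field(default_factory=lambda: {1: 0.5, 2: 0.35, 3: 0.15})
    p_duplicate_version: float = 0.05
    p_concomitant: float = 0.15
    p_missing_age: float = 0.10
    p_missing_sex: float = 0.05
    age_unit_mix: dict[str, float] = field(
        default_factory=lambda: {"YR": 0.85, "DEC": 0.03, "MON": 0.05, "WK": 0.02, "DY": 0.05}
    )
    dialect: str = "current"
    quarter: str = "18Q1"
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ParameterError("n_reports must be positive")
        if not self.drug_catalog or not self.event_catalog:
            raise ParameterError("drug and event catalogs must be non-empty")
        for name, probs in (
            ("drug_catalog", self.drug_catalog.values()),
            ("event_catalog", self.event_catalog.values()),
            ("age_unit_mix", self.age_unit_mix.values()),
            ("drugs_per_report_dist", self.drugs_per_report_dist.values()),
            ("events_per_report_dist", self.events_per_report_dist.values()),
        ):
            if any(p < 0 for p in probs):
                raise ParameterError(f"{name} has a negative probability")
        for p_name in ("p_duplicate_version", "p_concomitant", "p_missing_age", "p_missing_sex"):
            p = getattr(self, p_name)
            if not 0 <= p <= 1:
                raise ParameterError(f"{p_name} must be in [0, 1], got {p}")
        if any(lam < 0 for lam in self.lambda_matrix.values()):
            raise ParameterError("lambda values must be non-negative")
        for d, e in self.lambda_matrix:
            if d not in self.drug_catalog or e not in self.event_catalog:
                raise ParameterError(f"lambda entry ({d!r}, {e!r}) not in the catalogs")
        if any(k < 1 for k in self.drugs_per_report_dist):
            raise ParameterError("drugs per report must be >= 1")
        if any(k < 1 for k in self.events_per_report_dist):
            raise ParameterError("events per report must be >= 1")
        if max(self.drugs_per_report_dist) > len(self.drug_catalog):
            raise ParameterError("more drugs per report than catalog entries")
        if max(self.events_per_report_dist) > len(self.event_catalog):
            raise ParameterError("more events per report than catalog entries")
        if self.dialect not in ("legacy", "current"):
            raise ParameterError(f"dialect must be legacy or current, got {self.dialect!r}")


@dataclass
class PlantedTruth:
    """Exact realized ground truth of one generated quarter.

    ``pair_counts`` holds clean drug-event pair counts (drugs indexing rows,
    events columns): pairs from the latest version of each case with
    concomitant drug rows excluded — exactly what a correct cleaning +
    pairing pipeline must recover.
    """

    lambda_matrix: dict[tuple[str, str], float]
    pair_counts: pd.DataFrame
    n_cases: int
    n_demo_records: int
    n_superseded: int
    n_concomitant_rows: int
    n_drug_rows: int
    n_reac_rows: int

    def to_tsv(self, path: str | Path) -> None:
        long = self.pair_counts.stack().rename("count").reset_index()
        long.columns = ["drug", "event", "count"]
        long["lambda"] = [
            self.lambda_matrix.get((d, e), 1.0) for d, e in zip(long["drug"], long["event"])
        ]
        long.to_csv(path, sep="\t", index=False)


def _draw_counts(rng: np.random.Generator, dist: dict[int, float], n: int) -> np.ndarray:
    ks = np.array(sorted(dist))
    ps = np.array([dist[k] for k in ks], dtype=float)
    ps = ps / ps.sum()
    return rng.choice(ks, size=n, p=ps)


def simulate_reports(config: SynthConfig) -> tuple[dict[str, pd.DataFrame], PlantedTruth]:
    """Draw one quarter of reports in memory; returns harmonized-ish raw
    tables (pre-dialect) and the realized ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    drugs = list(config.drug_catalog)
    drug_p = np.array([config.drug_catalog[d] for d in drugs], dtype=float)
    drug_p = drug_p / drug_p.sum()
    events = list(config.event_catalog)
    base_p = np.array([config.event_catalog[e] for e in events], dtype=float)

    lam = np.ones((len(drugs), len(events)))
    for (d, e), v in config.lambda_matrix.items():
        lam[drugs.index(d), events.index(e)] = v

    n = config.n_reports
    n_drugs_per = _draw_counts(rng, config.drugs_per_report_dist, n)
    n_events_per = _draw_counts(rng, config.events_per_report_dist, n)

    demo_rows: list[dict] = []
    drug_rows: list[dict] = []
    reac_rows: list[dict] = []
    outc_rows: list[dict] = []
    pair_counts = np.zeros((len(drugs), len(events)), dtype=np.int64)
    n_superseded = 0
    n_concomitant = 0

    units = list(config.age_unit_mix)
    unit_p = np.array([config.age_unit_mix[u] for u in units], dtype=float)
    unit_p = unit_p / unit_p.sum()
    outc_codes = np.array(["HO", "DE", "LT", "DS", "OT", "RI", "CA"])
    outc_p = np.array([0.45, 0.10, 0.06, 0.08, 0.23, 0.05, 0.03])

    next_id = 10_000_001
    for i in range(n):
        case_id = str(1_000_001 + i)
        di = rng.choice(len(drugs), size=n_drugs_per[i], replace=False, p=drug_p)
        w = base_p * lam[di].max(axis=0)
        ei = rng.choice(len(events), size=n_events_per[i], replace=False, p=w / w.sum())

        roles = np.where(
            rng.random(len(di)) < config.p_concomitant,
            "C",
            rng.choice(["PS", "SS", "I"], size=len(di), p=[0.6, 0.3, 0.1]),
        )
        n_concomitant += int((roles == "C").sum())

        age_years = float(np.clip(rng.gamma(9.0, 6.5), 0.0, 105.0))
        unit = str(rng.choice(units, p=unit_p))
        if rng.random() < config.p_missing_age:
            age_val, unit = "", ""
        else:
            age_val = str(int(round(age_years / AGE_UNIT_YEARS[unit])))
        sex = "" if rng.random() < config.p_missing_sex else ("F" if rng.random() < 0.5 else "M")
        occupation = str(rng.choice(["MD", "PH", "OT", "CN"], p=[0.4, 0.2, 0.25, 0.15]))
        country = str(rng.choice(["US", "FR", "JP", "GB", "DE"], p=[0.4, 0.2, 0.15, 0.15, 0.1]))
        n_outc = int(rng.choice([0, 1, 2], p=[0.2, 0.65, 0.15]))
        codes = rng.choice(outc_codes, size=n_outc, replace=False, p=outc_p)

        versions = [next_id]
        next_id += 1
        if rng.random() < config.p_duplicate_version:
            versions.append(next_id)  # later id = follow-up version
            next_id += 1
            n_superseded += 1

        for v_idx, rid in enumerate(versions):
            rid_s = str(rid)
            latest = v_idx == len(versions) - 1
            # earlier versions may carry stale demographics; the content that
            # counts (and the truth tallies) comes from the latest version.
            v_age = age_val if latest or rng.random() < 0.7 else ""
            demo_rows.append(
                {
                    "report_id": rid_s,
                    "case_id": case_id,
                    "age_value": v_age,
                    "age_unit": unit if v_age else "",
                    "sex": sex,
                    "occupation": occupation,
                    "country": country,
                    "receipt_date": "20180215",
                }
            )
            for j, role in zip(di, roles):
                drug_rows.append({"report_id": rid_s, "drugname": drugs[j], "role_cod": role})
            for k in ei:
                reac_rows.append({"report_id": rid_s, "pt": events[k]})
            for code in codes:
                outc_rows.append({"report_id": rid_s, "outc_cod": str(code)})

        for j, role in zip(di, roles):
            if role != "C":
                for k in ei:
                    pair_counts[j, k] += 1

    truth = PlantedTruth(
        lambda_matrix=dict(config.lambda_matrix),
        pair_counts=pd.DataFrame(pair_counts, index=drugs, columns=events),
        n_cases=n,
        n_demo_records=len(demo_rows),
        n_superseded=n_superseded,
        n_concomitant_rows=n_concomitant,
        n_drug_rows=len(drug_rows),
        n_reac_rows=len(reac_rows),
    )
    tables = {
        "demo": pd.DataFrame(demo_rows),
        "drug": pd.DataFrame(drug_rows),
        "reac": pd.DataFrame(reac_rows),
        "outc": pd.DataFrame(outc_rows, columns=["report_id", "outc_cod"]),
    }
    return tables, truth


_DEMO_HEADERS = {
    "legacy": ["ISR", "CASE", "AGE", "AGE_COD", "GNDR_COD", "OCCP_COD", "REPORTER_COUNTRY", "FDA_DT"],
    "current": ["primaryid", "caseid", "age", "age_cod", "sex", "occp_cod", "reporter_country", "fda_dt"],
}
_DEMO_SOURCE = ["report_id", "case_id", "age_value", "age_unit", "sex", "occupation", "country", "receipt_date"]


def generate_quarter(config: SynthConfig, outdir: str | Path) -> tuple[list[Path], PlantedTruth]:
    """Write one synthetic quarter in the selected dialect to ``outdir``.

    Emits DEMO/DRUG/REAC/OUTC plus header-only THER/RPSR/INDI stubs and a
    ``planted_truth.tsv`` sidecar.  Same config (including seed) twice gives
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables, truth = simulate_reports(config)
    q = config.quarter
    legacy = config.dialect == "legacy"
    key = "ISR" if legacy else "primaryid"

    paths = []

    def write(name: str, df: pd.DataFrame, headers: list[str], source: list[str]) -> None:
        path = outdir / f"{name}{q}.txt"
        with open(path, "w", newline="\n") as fh:
            fh.write("$".join(headers) + "\n")
            if len(df):
                for row in df[source].itertuples(index=False):
                    fh.write("$".join(map(str, row)) + "\n")
        paths.append(path)

    write("DEMO", tables["demo"], _DEMO_HEADERS[config.dialect], _DEMO_SOURCE)
    write(
        "DRUG",
        tables["drug"],
        [key, "ROLE_COD" if legacy else "role_cod", "DRUGNAME" if legacy else "drugname"],
        ["report_id", "role_cod", "drugname"],
    )
    write("REAC", tables["reac"], [key, "PT" if legacy else "pt"], ["report_id", "pt"])
    write("OUTC", tables["outc"], [key, "OUTC_COD" if legacy else "outc_cod"], ["report_id", "outc_cod"])
    for stub in ("THER", "RPSR", "INDI"):
        path = outdir / f"{stub}{q}.txt"
        path.write_text(key + "\n")
        paths.append(path)
    truth.to_tsv(outdir / "planted_truth.tsv")
    return paths, truth


def planted_ror(truth: PlantedTruth, drug: str, event: str) -> float:
    """ROR of a (drug, event) pair computed directly from realized clean counts.

    Returns nan (not an exception) when a zero cell makes the ratio
    undefined; raises ``KeyError`` for names outside the catalogs.
    """
    counts = truth.pair_counts
    if drug not in counts.index:
        raise KeyError(f"unknown drug {drug!r}")
    if event not in counts.columns:
        raise KeyError(f"unknown event {event!r}")
    a = int(counts.loc[drug, event])
    b = int(counts.loc[drug].sum()) - a
    c = int(counts[event].sum()) - a
    d = int(counts.values.sum()) - a - b - c
    if min(a, b, c, d) == 0:
        return float("nan")
    return (a / b) / (c / d)
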
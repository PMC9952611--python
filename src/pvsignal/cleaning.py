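"""Report-level exclusion cascade for spontaneous-report data.

A FAERS case can appear as several report versions (an initial submission
plus follow-ups); only the latest version carries the current information.
Cleaning therefore (1) keeps the latest version of each case, (2) drops
cases the regulator has flagged as erroneous (an optional deletion list),
(3) drops reports missing mandatory content (identification key, any
usable drug name, any reaction term), and (4) removes drug rows coded as
concomitant medication — suspect and interacting drugs are kept, since
only suspected drugs should drive disproportionality counts.

Every input report ends up either retained or tallied under exactly one
exclusion reason, and cleaning an already-clean set is a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io import QuarterData, standardize_age_series, age_group

__all__ = ["ExclusionTally", "CleanReportSet", "select_latest_version", "apply_exclusions", "clean_quarter", "load_deletion_list"]


@dataclass
class ExclusionTally:
    """Per-reason counts of excluded reports (plus dropped drug rows)."""

    input_reports: int = 0
    retained: int = 0
    superseded_version: int = 0
    deletion_listed: int = 0
    missing_key: int = 0
    missing_drug_name: int = 0
    missing_reaction: int = 0
    concomitant_only: int = 0
    concomitant_rows_removed: int = 0
    implausible_age: int = 0

    REASONS = (
        "superseded_version",
        "deletion_listed",
        "missing_key",
        "missing_drug_name",
        "missing_reaction",
        "concomitant_only",
    )

    @property
    def excluded(self) -> int:
        return sum(getattr(self, r) for r in self.REASONS)

    def check_conservation(self) -> None:
        if self.input_reports != self.retained + self.excluded:
            raise AssertionError(
                f"tally does not reconcile: {self.input_reports} in, "
                f"{self.retained} retained + {self.excluded} excluded"
            )

    def to_tsv(self, path: str | Path) -> None:
        rows = [("input_reports", self.input_reports), ("retained", self.retained)]
        rows += [(r, getattr(self, r)) for r in self.REASONS]
        rows += [
            ("concomitant_rows_removed", self.concomitant_rows_removed),
            ("implausible_age", self.implausible_age),
        ]
        pd.DataFrame(rows, columns=["reason", "count"]).to_csv(path, sep="\t", index=False)


@dataclass
class CleanReportSet:
    """One row per retained case in ``demo`` (standardized demographics),
    with its suspect/interacting drug rows, reaction rows and outcome codes
    keyed by ``report_id``."""

    demo: pd.DataFrame
    drugs: pd.DataFrame
    reacs: pd.DataFrame
    outc: pd.DataFrame

    @property
    def n_reports(self) -> int:
        return len(self.demo)


def select_latest_version(demo: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep, per case, the report with the greatest (quarter, numeric id).

    FAERS report ids increase over time, so within a quarter the larger id
    is the later version.  Returns the retained DEMO rows and the count of
    superseded versions.
    """
    if demo.empty:
        return demo.copy(), 0
    df = demo.copy()
    df["_rid_num"] = pd.to_numeric(df["report_id"], errors="coerce").fillna(-1)
    df = df.sort_values(["case_id", "quarter", "_rid_num"], kind="mergesort")
    latest = df.drop_duplicates("case_id", keep="last").drop(columns="_rid_num")
    return latest.sort_index(), len(demo) - len(latest)


def load_deletion_list(path: str | Path | None) -> set[str]:
    """Read a plain-text deletion list (one case id per line); None -> empty."""
    if path is None:
        return set()
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


def apply_exclusions(
    demo_latest: pd.DataFrame,
    drug: pd.DataFrame,
    reac: pd.DataFrame,
    outc: pd.DataFrame,
    deletion_list: set[str] | None = None,
    tally: ExclusionTally | None = None,
) -> tuple[CleanReportSet, ExclusionTally]:
    """Apply the content exclusions to latest-version reports.

    Reports are dropped (and tallied once each, in this order of precedence)
    when their case id is deletion-listed, their case id is blank, they have
    no non-blank drug name, every usable drug row is concomitant, or no
    non-blank reaction term remains.  Concomitant drug rows are then removed
    from the surviving reports.
    """
    tally = tally or ExclusionTally(input_reports=len(demo_latest))
    deletion_list = deletion_list or set()

    demo = demo_latest.copy()
    keep = pd.Series(True, index=demo.index)

    listed = demo["case_id"].isin(deletion_list)
    tally.deletion_listed += int(listed.sum())
    keep &= ~listed

    blank_key = demo["case_id"].astype(str).str.strip() == ""
    blank_key &= keep
    tally.missing_key += int(blank_key.sum())
    keep &= ~blank_key

    drug = drug.copy()
    drug["drugname"] = drug["drugname"].astype(str).str.strip()
    usable_drug = drug[drug["drugname"] != ""]
    named_ids = set(usable_drug["report_id"])
    non_conc_ids = set(usable_drug.loc[usable_drug["role_cod"] != "C", "report_id"])
    reac = reac[reac["pt"].astype(str).str.strip() != ""]
    reac_ids = set(reac["report_id"])

    no_drug = ~demo["report_id"].isin(named_ids) & keep
    tally.missing_drug_name += int(no_drug.sum())
    keep &= ~no_drug

    conc_only = ~demo["report_id"].isin(non_conc_ids) & keep
    tally.concomitant_only += int(conc_only.sum())
    keep &= ~conc_only

    no_reac = ~demo["report_id"].isin(reac_ids) & keep
    tally.missing_reaction += int(no_reac.sum())
    keep &= ~no_reac

    demo = demo[keep].copy()
    tally.retained = len(demo)

    if "age_years" not in demo.columns:
        ages, n_bad = standardize_age_series(demo)
        demo["age_years"] = ages
        demo["age_group"] = ages.map(age_group)
        tally.implausible_age += n_bad

    retained_ids = set(demo["report_id"])
    drugs_kept = usable_drug[
        usable_drug["report_id"].isin(retained_ids) & (usable_drug["role_cod"] != "C")
    ].reset_index(drop=True)
    tally.concomitant_rows_removed += int(
        (usable_drug["report_id"].isin(retained_ids) & (usable_drug["role_cod"] == "C")).sum()
    )
    reacs_kept = reac[reac["report_id"].isin(retained_ids)].reset_index(drop=True)
    outc_kept = outc[outc["report_id"].isin(retained_ids)].reset_index(drop=True)

    tally.check_conservation()
    return CleanReportSet(demo.reset_index(drop=True), drugs_kept, reacs_kept, outc_kept), tally


def clean_quarter(
    qd: QuarterData, deletion_list: set[str] | None = None
) -> tuple[CleanReportSet, ExclusionTally]:
    """Full cascade on one parsed quarter: latest version, then exclusions."""
    tally = ExclusionTally(input_reports=len(qd.demo))
    latest, n_super = select_latest_version(qd.demo)
    tally.superseded_version = n_super
    return apply_exclusions(latest, qd.drug, qd.reac, qd.outc, deletion_list, tally)
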
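"""Published reference fixtures for the piperacillin/tazobactam screen.

A published FAERS disproportionality study of electrolyte disorders under
piperacillin/tazobactam printed its full 2x2 contingency tables, which
makes the screening arithmetic desk-checkable without any report-level
data.  The packaged TSVs carry, per row, the four cells, the printed
statistics (2 dp), which statistics were flagged as signals (``starred``),
and which printed values are *not* internally consistent with their own
cells under the standard formulas (``inconsistent`` — presumed misprints;
they are excluded from exact-reproduction checks but their signal pattern
still holds).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import ContingencyTable

__all__ = ["REFERENCE_SCREENS", "load_reference_screen", "load_risk_marginals", "reference_tables"]

# screen name -> (file, comparator description)
REFERENCE_SCREENS = {
    "tzp_ed_vs_all_drugs": "ten electrolyte disorders for piperacillin/tazobactam vs all other drugs",
    "pcn_hypokalemia_within_class": "hypokalemia for twelve penicillins vs the other penicillins",
    "pcn_hypokalemia_vs_all_drugs": "hypokalemia for twelve penicillins vs all other drugs",
}


def _tokens(cell: str) -> frozenset[str]:
    cell = str(cell).strip()
    return frozenset() if cell in ("", "-") else frozenset(cell.split(","))


def load_reference_screen(name: str) -> pd.DataFrame:
    """One reference screen with cells, printed statistics and flags.

    ``starred`` and ``inconsistent`` columns hold frozensets of tokens
    (``prr``, ``ror``, ``ic`` for stars; statistic column names for
    inconsistencies).
    """
    if name not in REFERENCE_SCREENS:
        raise KeyError(f"unknown reference screen {name!r}; have {sorted(REFERENCE_SCREENS)}")
    path = resources.files("pvsignal").joinpath("data", "reference_tables", f"{name}.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", dtype={"label": str, "starred": str, "inconsistent": str})
    df["starred"] = df["starred"].map(_tokens)
    df["inconsistent"] = df["inconsistent"].map(_tokens)
    return df


def reference_tables(name: str) -> list[tuple[str, ContingencyTable]]:
    """The (label, ContingencyTable) rows of one reference screen."""
    df = load_reference_screen(name)
    return [
        (row.label, ContingencyTable(int(row.a), int(row.b), int(row.c), int(row.d)))
        for row in df.itertuples()
    ]


def load_risk_marginals() -> pd.DataFrame:
    """Printed sex/age marginal counts of the hypokalemia risk-factor table."""
    path = resources.files("pvsignal").joinpath(
        "data", "reference_tables", "tzp_hypokalemia_risk_marginals.tsv"
    )
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype={"variable": str, "level": str})
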
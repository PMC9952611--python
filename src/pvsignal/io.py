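"""Reading FAERS/LAERS quarterly ASCII extracts.

The FDA publishes spontaneous-report extracts as "$"-delimited ASCII tables,
one set per quarter: DEMO (demographics/administrative), DRUG, REAC
(MedDRA-coded reactions) and OUTC (outcomes), plus THER/RPSR/INDI which this
pipeline does not use.  Two schema dialects exist: the legacy system
(pre-2012Q3, key fields ``ISR``/``CASE``) and the current one
(``primaryid``/``caseid``).  Parsing harmonizes both into a single field
vocabulary so downstream stages never see the dialect.

Parsing is total: malformed data rows are routed to a rejects frame, never
silently dropped and never raised.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "QuarterData",
    "parse_quarter",
    "detect_dialect",
    "standardize_age",
    "standardize_age_series",
    "age_group",
    "AGE_UNIT_YEARS",
    "normalize_pt",
]

# Calendar conversion factors: years per one unit.
AGE_UNIT_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

MAX_PLAUSIBLE_AGE = 150.0

ROLE_CODES = {"PS", "SS", "I", "C"}
OUTCOME_CODES = {"DE", "LT", "HO", "DS", "CA", "RI", "OT"}

# Harmonized column name <- per-dialect source column (lower-cased headers).
_DEMO_MAP = {
    "legacy": {
        "isr": "report_id",
        "case": "case_id",
        "age": "age_value",
        "age_cod": "age_unit",
        "gndr_cod": "sex",
        "occp_cod": "occupation",
        "reporter_country": "country",
        "fda_dt": "receipt_date",
    },
    "current": {
        "primaryid": "report_id",
        "caseid": "case_id",
        "age": "age_value",
        "age_cod": "age_unit",
        "sex": "sex",
        "occp_cod": "occupation",
        "reporter_country": "country",
        "fda_dt": "receipt_date",
    },
}

_TABLES = ("demo", "drug", "reac", "outc")


@dataclass
class QuarterData:
    """Harmonized records of one quarter plus the rejects log."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    rejects: pd.DataFrame
    dialect: str
    quarter: str


def detect_dialect(header: str) -> str:
    cols = {c.strip().lower() for c in header.rstrip("\n").split("$")}
    if "primaryid" in cols:
        return "current"
    if "isr" in cols:
        return "legacy"
    raise ValueError(f"header matches neither FAERS dialect: {header!r}")


def normalize_pt(pt: str) -> str:
    """MedDRA preferred-term normalization: lowercase, trim, collapse whitespace."""
    return re.sub(r"\s+", " ", str(pt).strip().lower())


def _find_table_file(directory: Path, table: str, quarter: str | None) -> Path:
    quarter_re = re.escape(quarter) if quarter else r"\d\dQ\d"
    pattern = re.compile(rf"^{table}{quarter_re}\.txt$", re.IGNORECASE)
    hits = sorted(p for p in directory.iterdir() if pattern.match(p.name))
    if not hits:
        raise FileNotFoundError(f"no {table.upper()} file for quarter {quarter or '*'} in {directory}")
    if len(hits) > 1:
        raise ValueError(f"multiple quarters present for {table.upper()}; pass quarter explicitly")
    return hits[0]


def _read_dollar(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def parse_quarter(
    directory: str | Path, quarter: str | None = None, dialect: str = "auto"
) -> QuarterData:
    """Parse one quarter's DEMO/DRUG/REAC/OUTC files from ``directory``.

    ``dialect`` may be ``legacy``, ``current`` or ``auto`` (detected from the
    DEMO header).  Rows whose mandatory key (report id; case id in DEMO) is
    blank are appended to the rejects frame with the table name and reason.
    Blank drug names or reaction terms are *not* rejected here — they flow
    through so the cleaning stage can tally them as exclusions.
    """
    directory = Path(directory)
    paths = {t: _find_table_file(directory, t, quarter) for t in _TABLES}
    if quarter is None:
        m = re.match(r"^demo(\d\dQ\d)\.txt$", paths["demo"].name, re.IGNORECASE)
        quarter = m.group(1).upper() if m else ""

    with open(paths["demo"]) as fh:
        header = fh.readline()
    detected = detect_dialect(header)
    if dialect == "auto":
        dialect = detected
    elif dialect not in ("legacy", "current"):
        raise ValueError(f"unknown dialect {dialect!r}")
    elif dialect != detected:
        raise ValueError(f"requested dialect {dialect!r} but header looks like {detected!r}")

    rejects: list[dict] = []
    key = "isr" if dialect == "legacy" else "primaryid"

    def split_valid(df: pd.DataFrame, table: str, required: list[str]) -> pd.DataFrame:
        missing_cols = [c for c in required if c not in df.columns]
        if missing_cols:
            raise ValueError(f"{table.upper()} file lacks mandatory column(s) {missing_cols}")
        bad = pd.Series(False, index=df.index)
        for c in required:
            bad |= df[c].str.strip() == ""
        for _, row in df[bad].iterrows():
            rejects.append({"table": table, "reason": "missing key", "row": "$".join(row)})
        return df[~bad].copy()

    demo = split_valid(_read_dollar(paths["demo"]), "demo", [key])
    drug = split_valid(_read_dollar(paths["drug"]), "drug", [key])
    reac = split_valid(_read_dollar(paths["reac"]), "reac", [key])
    outc = split_valid(_read_dollar(paths["outc"]), "outc", [key])

    demo = demo.rename(columns=_DEMO_MAP[dialect])
    for col in _DEMO_MAP[dialect].values():
        if col not in demo.columns:
            demo[col] = ""
    demo = demo[list(dict.fromkeys(_DEMO_MAP[dialect].values()))]
    demo["quarter"] = quarter
    demo["sex"] = demo["sex"].str.strip().str.upper().where(lambda s: s.isin(["M", "F"]), "")
    demo["age_unit"] = demo["age_unit"].str.strip().str.upper()

    def ensure(df: pd.DataFrame, col: str) -> pd.Series:
        if col not in df.columns:
            df[col] = ""
        return df[col].astype(str)

    drug = drug.rename(columns={key: "report_id"})
    drug["drugname"] = ensure(drug, "drugname")
    drug["role_cod"] = ensure(drug, "role_cod").str.strip().str.upper()
    drug = drug[["report_id", "drugname", "role_cod"]]

    reac = reac.rename(columns={key: "report_id"})
    reac["pt"] = ensure(reac, "pt").map(normalize_pt)
    reac = reac[["report_id", "pt"]]

    outc = outc.rename(columns={key: "report_id"})
    outc["outc_cod"] = ensure(outc, "outc_cod").str.strip().str.upper()
    outc = outc[["report_id", "outc_cod"]]

    return QuarterData(
        demo=demo.reset_index(drop=True),
        drug=drug.reset_index(drop=True),
        reac=reac.reset_index(drop=True),
        outc=outc.reset_index(drop=True),
        rejects=pd.DataFrame(rejects, columns=["table", "reason", "row"]),
        dialect=dialect,
        quarter=quarter or "",
    )


def standardize_age(age_value: float | str | None, age_unit: str | None) -> float:
    """Convert a reported age to years; anomalies become nan, never an error.

    A present value with a blank/missing unit is read as years (the dominant
    FAERS convention).  Negative results or results above 150 years are
    implausible and become nan.
    """
    if age_value is None:
        return float("nan")
    s = str(age_value).strip()
    if s == "":
        return float("nan")
    try:
        v = float(s)
    except ValueError:
        return float("nan")
    unit = (age_unit or "").strip().upper()
    factor = AGE_UNIT_YEARS.get(unit, 1.0 if unit == "" else None)
    if factor is None:
        return float("nan")
    years = v * factor
    if years < 0 or years > MAX_PLAUSIBLE_AGE:
        return float("nan")
    return years


def standardize_age_series(demo: pd.DataFrame) -> tuple[pd.Series, int]:
    """Vectorized :func:`standardize_age` over a harmonized DEMO frame.

    Returns the age-in-years series and the count of present-but-implausible
    values that were coerced to missing.
    """
    years = pd.Series(
        [standardize_age(v, u) for v, u in zip(demo["age_value"], demo["age_unit"])],
        index=demo.index,
        dtype=float,
    )
    present = demo["age_value"].astype(str).str.strip() != ""
    n_anomalous = int((present & years.isna()).sum())
    return years, n_anomalous


AGE_GROUPS = ("<=18", "19-64", ">=65", "unknown")


def age_group(age_years: float | None) -> str:
    """Bin an age in years into <=18 / 19-64 / >=65 / unknown.

    Fractional ages are floored before comparison, so 18.9 falls in <=18.
    """
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        return "unknown"
    whole = int(np.floor(age_years))
    if whole <= 18:
        return "<=18"
    if whole <= 64:
        return "19-64"
    return ">=65"
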
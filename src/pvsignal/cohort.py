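"""Drug name standardization, event queries and contingency-table building.

The analysis unit of a disproportionality screen is the drug-event *pair*:
one (drug, MedDRA preferred term) combination from one report.  A report
listing two suspect drugs and three reactions contributes six pairs.  The
2x2 table for a (target drug, event set) then counts pairs, not reports:

    a = target drug & query event      b = target drug & other events
    c = comparator drugs & query event d = comparators & other events

where the comparator universe is either every other drug in the database or
a configured drug list (e.g. the penicillin class).

Verbatim drug names are mapped to standardized study drugs through an
editable synonym dictionary (exact match after normalization; trailing
dosage tokens such as "4.5 g" are stripped, but no fuzzy matching is
attempted).  Unmatched names keep their normalized verbatim form and are
tagged unmatched, so pair counts in the "all other drugs" universe are
preserved drug by drug.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .cleaning import CleanReportSet
from .io import normalize_pt
from .stats import ContingencyTable

__all__ = [
    "DrugDictionary",
    "load_drug_dictionary",
    "load_event_queries",
    "normalize_drug_name",
    "match_drug",
    "build_pairs",
    "build_contingency",
    "OTHER",
]

OTHER = "other"

# bare units / numeral+unit fragments allowed to trail a drug name
_DOSE_TOKEN = re.compile(r"^(\d+(\.\d+)?|\d+(\.\d+)?(mg|g|mcg|ml|l|iu)|mg|g|mcg|ml|iu|%)$")


def normalize_drug_name(name: str) -> str:
    """Lowercase, trim, collapse whitespace, strip trailing dosage tokens."""
    s = re.sub(r"\s+", " ", str(name).strip().lower())
    tokens = s.split(" ")
    while len(tokens) > 1 and _DOSE_TOKEN.match(tokens[-1]):
        tokens.pop()
    return " ".join(tokens)


@dataclass
class DrugDictionary:
    """Standardized drug -> synonym set, with an ATC-class tag per drug."""

    synonyms: dict[str, set[str]]
    atc_class: dict[str, str]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for drug, syns in self.synonyms.items():
            for s in syns:
                if s in seen and seen[s] != drug:
                    raise ValueError(f"synonym {s!r} claimed by both {seen[s]!r} and {drug!r}")
                seen[s] = drug
        self._reverse = seen

    @property
    def drugs(self) -> list[str]:
        return list(self.synonyms)

    def lookup(self, normalized: str) -> str | None:
        return self._reverse.get(normalized)


def _data_path(name: str):
    return resources.files("pvsignal").joinpath("data", name)


def load_drug_dictionary(path: str | Path | None = None) -> DrugDictionary:
    """Load the packaged penicillin dictionary, or a user-supplied YAML.

    Format: ``{drug: {atc_class: str, synonyms: [str, ...]}}``.  The
    standardized name itself is always a synonym.
    """
    if path is None:
        raw = yaml.safe_load(_data_path("drug_dictionary.yaml").read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    synonyms = {}
    atc = {}
    for drug, entry in raw.items():
        syns = {normalize_drug_name(s) for s in entry.get("synonyms", [])}
        syns.add(normalize_drug_name(drug))
        synonyms[drug] = syns
        atc[drug] = entry.get("atc_class", "")
    return DrugDictionary(synonyms=synonyms, atc_class=atc)


def load_event_queries(path: str | Path | None = None) -> dict[str, set[str]]:
    """Electrolyte-disorder name -> set of MedDRA preferred terms.

    The packaged resource carries the ten disorders screened here, each
    expanded to its clinical PT plus the corresponding laboratory PT
    (e.g. hypokalemia -> {"hypokalaemia", "blood potassium decreased"}).
    """
    if path is None:
        raw = yaml.safe_load(_data_path("event_queries.yaml").read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    return {name: {normalize_pt(pt) for pt in pts} for name, pts in raw.items()}


def match_drug(verbatim_name: str, dictionary: DrugDictionary) -> str:
    """Standardized drug for a verbatim name, or ``"other"`` when unmatched."""
    return dictionary.lookup(normalize_drug_name(verbatim_name)) or OTHER


def build_pairs(clean: CleanReportSet, dictionary: DrugDictionary) -> pd.DataFrame:
    """Drug-event pairs of a clean report set, deduplicated within report.

    Returns columns ``report_id``, ``drug`` (standardized name for
    dictionary hits, else the normalized verbatim name), ``matched`` (bool)
    and ``pt``.  The cartesian product of each report's distinct drugs and
    distinct reaction terms is taken; identical (drug, pt) repeats within a
    report collapse to one pair.
    """
    drugs = clean.drugs.copy()
    norm = drugs["drugname"].map(normalize_drug_name)
    std = norm.map(lambda s: dictionary.lookup(s))
    drugs["drug"] = std.fillna(norm)
    drugs["matched"] = std.notna()
    drugs = drugs[["report_id", "drug", "matched"]].drop_duplicates(["report_id", "drug"])
    pairs = drugs.merge(clean.reacs.drop_duplicates(["report_id", "pt"]), on="report_id")
    return pairs[["report_id", "drug", "matched", "pt"]].reset_index(drop=True)


def build_contingency(
    pairs: pd.DataFrame,
    target_drug: str,
    event_query: set[str] | frozenset[str],
    comparator: str | list[str] | tuple[str, ...] = "all_other_drugs",
) -> ContingencyTable:
    """Count the 2x2 pair table for one target drug and one event query.

    ``comparator`` is either ``"all_other_drugs"`` (the whole pair universe)
    or an explicit drug list defining a restricted universe; the target must
    belong to it.  Restricting first and building second commutes with
    building on pre-restricted pairs.
    """
    if isinstance(comparator, str):
        if comparator != "all_other_drugs":
            raise ValueError(f"unknown comparator mode {comparator!r}")
        universe = pairs
    else:
        if target_drug not in comparator:
            raise ValueError("target drug must be part of the comparator drug list")
        universe = pairs[pairs["drug"].isin(set(comparator))]
    if len(universe) == 0:
        raise ValueError("empty pair universe")
    if target_drug not in set(universe["drug"]):
        raise ValueError(f"target drug {target_drug!r} absent from the pair universe")

    is_target_drug = universe["drug"] == target_drug
    is_event = universe["pt"].isin(event_query)
    a = int((is_target_drug & is_event).sum())
    b = int((is_target_drug & ~is_event).sum())
    c = int((~is_target_drug & is_event).sum())
    d = int((~is_target_drug & ~is_event).sum())
    return ContingencyTable(a, b, c, d)
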
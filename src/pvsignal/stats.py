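"""Disproportionality statistics for 2x2 drug-event contingency tables.

Implements the three classical pharmacovigilance screening indices on a
report-pair contingency table

    =============  ============  ============
                   target event  other events
    target drug         a             b
    comparators         c             d
    =============  ============  ============

* the proportional reporting ratio PRR = [a/(a+b)] / [c/(c+d)],
* the reporting odds ratio ROR = (a/b)/(c/d) with a Wald interval on the
  log scale, and
* the BCPNN information component IC = log2 of the shrunk
  observed-to-expected joint reporting probability, with a closed-form
  posterior expectation and variance.

Signal rules follow the common frequentist thresholds (observed count >= 3,
ratio >= 2, Yates chi-square >= 4, ROR 95% lower bound > 1) and, for the
Bayesian index, IC 95% lower credibility bound > 0.

Statistics that are undefined for a table (zero cells or margins) are
returned as ``nan`` rather than raised; their signal flags are False.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable",
    "DisproResult",
    "prr",
    "ror_with_ci",
    "yates_chi2",
    "ic_bcpnn",
    "evaluate_signals",
    "compute_dispro",
    "screen_tables",
    "run_screen",
    "round_display",
]

Z95 = 1.96  # two-sided 95% normal quantile, as used for every interval here

LN2 = math.log(2.0)


def round_display(x: float, ndigits: int = 2) -> float:
    """Round half away from zero for display (3.485 -> 3.49, -0.005 -> -0.01).

    Internal arithmetic is always full precision; this is applied only when
    statistics are printed or compared against published 2-dp values.
    """
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of a 2x2 exposure-by-event table of drug-event pairs.

    ``a`` target drug & target event, ``b`` target drug & other events,
    ``c`` comparator drugs & target event, ``d`` comparators & other events.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_target(self) -> int:
        """Pairs involving the target drug (a+b); the BCPNN margin c_x."""
        return self.a + self.b

    @property
    def col_target(self) -> int:
        """Pairs involving the target event (a+c); the BCPNN margin c_y."""
        return self.a + self.c


def prr(t: ContingencyTable) -> float:
    """Proportional reporting ratio [a/(a+b)] / [c/(c+d)].

    Undefined (nan) when the target drug has no pairs, the comparator
    universe is empty, or the event was never reported for comparators.
    """
    if t.a + t.b == 0 or t.c + t.d == 0 or t.c == 0:
        return float("nan")
    return (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))


def ror_with_ci(t: ContingencyTable, z: float = Z95) -> tuple[float, float, float]:
    """Reporting odds ratio (a/b)/(c/d) with a Wald 95% CI on the log scale.

    SE(ln ROR) = sqrt(1/a + 1/b + 1/c + 1/d); the interval is
    exp(ln ROR +/- z*SE), multiplicatively symmetric about the estimate.
    Any zero cell makes all three values nan.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        nan = float("nan")
        return nan, nan, nan
    est = (t.a / t.b) / (t.c / t.d)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return est, est * math.exp(-z * se), est * math.exp(z * se)


def yates_chi2(t: ContingencyTable) -> float:
    """Continuity-corrected chi-square N*(|ad-bc| - N/2)^2 / product of margins.

    The correction is clamped: when |ad - bc| <= N/2 the statistic is 0.
    Undefined (nan) when any margin is zero.
    """
    n = t.n
    margins = (t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d)
    if min(margins) == 0:
        return float("nan")
    corrected = max(0.0, abs(t.a * t.d - t.b * t.c) - n / 2.0)
    return n * corrected * corrected / math.prod(margins)


def ic_bcpnn(t: ContingencyTable, z: float = Z95) -> tuple[float, float, float]:
    """BCPNN information component: posterior E(IC), V(IC) and the 95% lower bound.

    Closed-form posterior moments with Beta(1, 1) marginal priors and the
    joint prior balanced so that E(IC) = 0 under independence
    (gamma11 = 1, gamma = (N+2)^2 / ((c_x+1)(c_y+1))):

        E(IC)  = log2[ (a+1)(N+2)^2 / ((N+gamma)(c_x+1)(c_y+1)) ]
        V(IC)  = (1/ln 2)^2 * [ (N-a+gamma-1)/((a+1)(1+N+gamma))
                              + (N-c_x+1)/((c_x+1)(3+N))
                              + (N-c_y+1)/((c_y+1)(3+N)) ]
        IC025  = E(IC) - z*sqrt(V(IC))

    Defined for a = 0 (the priors regularize every cell); nan only for an
    empty table.
    """
    n = t.n
    if n == 0:
        nan = float("nan")
        return nan, nan, nan
    cx = t.row_target
    cy = t.col_target
    gamma = (n + 2) ** 2 / ((cx + 1) * (cy + 1))
    e_ic = math.log2((t.a + 1) * (n + 2) ** 2 / ((n + gamma) * (cx + 1) * (cy + 1)))
    v_ic = (1.0 / LN2) ** 2 * (
        (n - t.a + gamma - 1) / ((t.a + 1) * (1 + n + gamma))
        + (n - cx + 1) / ((cx + 1) * (3 + n))
        + (n - cy + 1) / ((cy + 1) * (3 + n))
    )
    return e_ic, v_ic, e_ic - z * math.sqrt(v_ic)


def evaluate_signals(
    a: int,
    prr_value: float,
    chi2_value: float,
    ror_value: float,
    ror_low: float,
    ic025: float,
) -> tuple[bool, bool, bool, bool]:
    """Apply the three signal rules; an undefined (nan) statistic never signals.

    signal_prr: a >= 3 and PRR >= 2 and chi2 >= 4
    signal_ror: a >= 3 and ROR >= 2 and chi2 >= 4 and ROR 95% lower bound > 1
    signal_ic:  IC025 > 0
    """

    def ok(x: float) -> bool:
        return x is not None and not math.isnan(x)

    s_prr = bool(a >= 3 and ok(prr_value) and prr_value >= 2 and ok(chi2_value) and chi2_value >= 4)
    s_ror = bool(
        a >= 3
        and ok(ror_value)
        and ror_value >= 2
        and ok(chi2_value)
        and chi2_value >= 4
        and ok(ror_low)
        and ror_low > 1
    )
    s_ic = bool(ok(ic025) and ic025 > 0)
    return s_prr, s_ror, s_ic, s_prr or s_ror or s_ic


@dataclass(frozen=True)
class DisproResult:
    """All disproportionality statistics and signal flags for one table."""

    table: ContingencyTable
    prr: float
    ror: float
    ror_low: float
    ror_high: float
    chi2_yates: float
    ic: float
    ic_var: float
    ic025: float
    gamma: float
    signal_prr: bool = field(default=False)
    signal_ror: bool = field(default=False)
    signal_ic: bool = field(default=False)
    signal_any: bool = field(default=False)


def compute_dispro(t: ContingencyTable, z: float = Z95) -> DisproResult:
    """Compute PRR, ROR + CI, Yates chi-square, IC and the signal flags."""
    p = prr(t)
    r, lo, hi = ror_with_ci(t, z=z)
    x2 = yates_chi2(t)
    e_ic, v_ic, ic025 = ic_bcpnn(t, z=z)
    gamma = (t.n + 2) ** 2 / ((t.row_target + 1) * (t.col_target + 1)) if t.n else float("nan")
    s_prr, s_ror, s_ic, s_any = evaluate_signals(t.a, p, x2, r, lo, ic025)
    return DisproResult(
        table=t,
        prr=p,
        ror=r,
        ror_low=lo,
        ror_high=hi,
        chi2_yates=x2,
        ic=e_ic,
        ic_var=v_ic,
        ic025=ic025,
        gamma=gamma,
        signal_prr=s_prr,
        signal_ror=s_ror,
        signal_ic=s_ic,
        signal_any=s_any,
    )


_SCREEN_COLUMNS = [
    "drug",
    "event",
    "a",
    "b",
    "c",
    "d",
    "prr",
    "ror",
    "ror_low",
    "ror_high",
    "ic025",
    "chi2_yates",
    "signal_prr",
    "signal_ror",
    "signal_ic",
    "signal_any",
]


def screen_tables(
    labelled_tables: Iterable[tuple[str, str, ContingencyTable]], z: float = Z95
) -> pd.DataFrame:
    """Compute the full statistics row for each (drug, event, table) triple.

    Rows keep the input order; statistics are full precision (round with
    :func:`round_display` at report time).
    """
    rows = []
    for drug, event, t in labelled_tables:
        r = compute_dispro(t, z=z)
        rows.append(
            {
                "drug": drug,
                "event": event,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "prr": r.prr,
                "ror": r.ror,
                "ror_low": r.ror_low,
                "ror_high": r.ror_high,
                "ic025": r.ic025,
                "chi2_yates": r.chi2_yates,
                "signal_prr": r.signal_prr,
                "signal_ror": r.signal_ror,
                "signal_ic": r.signal_ic,
                "signal_any": r.signal_any,
            }
        )
    return pd.DataFrame(rows, columns=_SCREEN_COLUMNS)


def run_screen(
    pairs: pd.DataFrame,
    targets: Sequence[str],
    events: Mapping[str, set[str]] | Sequence[tuple[str, set[str]]],
    comparator: str | Sequence[str] = "all_other_drugs",
    z: float = Z95,
) -> pd.DataFrame:
    """Screen every (target drug, event query) combination into a signal table.

    ``pairs`` is the drug-event pair frame from :func:`pvsignal.cohort.build_pairs`;
    ``events`` maps a disorder name to its preferred-term query set. Rows are
    ordered by the configured drug order, then event order.
    """
    from .cohort import build_contingency  # local import to avoid a cycle

    if isinstance(events, Mapping):
        event_items = list(events.items())
    else:
        event_items = list(events)
    labelled = []
    for drug in targets:
        for name, pt_set in event_items:
            t = build_contingency(pairs, drug, pt_set, comparator=comparator)
            labelled.append((drug, name, t))
    return screen_tables(labelled, z=z)


def format_screen(table: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Display-rounded copy of a screen table (half away from zero)."""
    out = table.copy()
    for col in ("prr", "ror", "ror_low", "ror_high", "ic025", "chi2_yates"):
        out[col] = out[col].map(lambda x: round_display(x, ndigits))
    return out
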
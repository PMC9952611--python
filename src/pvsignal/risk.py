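"""Risk-factor analysis for a detected signal.

Given the reports of the target drug, the question is whether demographics
(sex, age group) predict the signalled event among those reports.  The
tools are the classical case-control ones: the 2x2 odds ratio with a Wald
interval, binary logistic regression fitted by iteratively reweighted
least squares (all terms entered simultaneously — no stepwise selection),
and the Hosmer-Lemeshow decile goodness-of-fit test.

For a single binary covariate the logistic odds ratio exp(beta) equals the
closed-form 2x2 odds ratio exactly (identical Wald standard errors); the
test suite uses that identity as a cross-module oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .cleaning import CleanReportSet

__all__ = [
    "SeparationError",
    "LogisticFit",
    "HLTestResult",
    "odds_ratio_2x2",
    "fit_logistic",
    "hosmer_lemeshow",
    "build_case_control",
    "risk_factor_table",
]

Z95 = 1.96


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


def odds_ratio_2x2(
    n11: int, n10: int, n01: int, n00: int, z: float = Z95
) -> tuple[float, float, float]:
    """Odds ratio (n11*n00)/(n10*n01) with a Wald 95% CI on the log scale.

    ``n11`` exposed cases, ``n10`` unexposed cases, ``n01`` exposed
    controls, ``n00`` unexposed controls.  Any zero cell -> nan triple.
    """
    if min(n11, n10, n01, n00) <= 0:
        nan = float("nan")
        return nan, nan, nan
    est = (n11 * n00) / (n10 * n01)
    se = np.sqrt(1 / n11 + 1 / n10 + 1 / n01 + 1 / n00)
    return est, est * np.exp(-z * se), est * np.exp(z * se)


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit: coefficients, Wald inference and
    convergence metadata.  ``params`` is indexed 'intercept' then the term
    names; ``odds_ratios``/CIs are exp of the coefficients/limits."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    n_iter: int
    converged: bool
    max_score: float
    n_obs: int
    fitted: np.ndarray

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self, z: float = Z95) -> pd.DataFrame:
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        return pd.DataFrame({"or_low": lo, "or_high": hi})


def fit_logistic(
    rows: pd.DataFrame,
    terms: list[str],
    outcome: str = "outcome",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Fit P(outcome=1) = logit^-1(b0 + X b) by Newton/IRLS.

    ``terms`` name numeric (0/1 dummy or continuous) columns of ``rows``;
    an intercept is always included.  Convergence is declared when the
    maximum absolute score (gradient of the log-likelihood) falls below
    ``tol``; failure to converge with diverging coefficients is reported
    as :class:`SeparationError` rather than returned silently.
    """
    y = np.asarray(rows[outcome], dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one event and one non-event")
    X = np.column_stack([np.ones(len(rows))] + [np.asarray(rows[t], dtype=float) for t in terms])
    names = ["intercept"] + list(terms)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant or collinear terms)")

    beta = np.zeros(X.shape[1])
    max_score = np.inf
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        score = X.T @ (y - p)
        max_score = float(np.abs(score).max())
        if max_score < tol:
            break
        w = np.clip(p * (1 - p), 1e-12, None)
        hessian = (X * w[:, None]).T @ X
        try:
            beta = beta + np.linalg.solve(hessian, score)
        except np.linalg.LinAlgError as err:
            raise SeparationError(f"singular information matrix at iteration {it}") from err
    converged = max_score < tol
    p = expit(X @ beta)
    # under separation the score also vanishes as the coefficients diverge,
    # so convergence alone is no guarantee the MLE exists: flag fits whose
    # probabilities have all been pushed to the 0/1 boundary, and
    # non-converged fits with a diverging linear predictor
    boundary = (p < 1e-6) | (p > 1 - 1e-6)
    if boundary.all() or (not converged and np.abs(X @ beta).max() > 30):
        raise SeparationError(
            "complete or quasi-complete separation detected: the maximum-"
            "likelihood estimate does not exist for this design"
        )
    w = np.clip(p * (1 - p), 1e-12, None)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    bse = np.sqrt(np.diag(cov))
    zvals = beta / bse
    llf = float(np.sum(y * np.log(np.clip(p, 1e-300, None)) + (1 - y) * np.log(np.clip(1 - p, 1e-300, None))))
    return LogisticFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        pvalues=pd.Series(2 * norm.sf(np.abs(zvals)), index=names),
        llf=llf,
        n_iter=it,
        converged=converged,
        max_score=max_score,
        n_obs=len(y),
        fitted=p,
    )


@dataclass
class HLTestResult:
    """Hosmer-Lemeshow decile test: group table, statistic, df, p-value."""

    groups: pd.DataFrame
    statistic: float
    df: int
    pvalue: float


def hosmer_lemeshow(fitted: np.ndarray, y: np.ndarray, g: int = 10) -> HLTestResult:
    """Goodness of fit by deciles of fitted risk.

    Group edges are fitted-probability quantiles; observations tied at an
    edge go to the lower group, and duplicate edges are merged so ties stay
    in one group.  The statistic is sum over groups of
    (O - E)^2 / (n_k * pbar_k * (1 - pbar_k)), referred to chi-square with
    (number of groups - 2) degrees of freedom.
    """
    fitted = np.asarray(fitted, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(fitted) < g:
        raise ValueError(f"need at least g={g} observations")
    edges = np.unique(np.quantile(fitted, np.linspace(0, 1, g + 1)[1:-1]))
    group = np.searchsorted(edges, fitted, side="left")
    labels = np.unique(group)
    if len(labels) < 3:
        raise ValueError("fewer than 3 distinct fitted-risk groups; test not applicable")
    rows = []
    stat = 0.0
    for k in labels:
        mask = group == k
        n_k = int(mask.sum())
        obs = float(y[mask].sum())
        exp = float(fitted[mask].sum())
        pbar = exp / n_k
        denom = n_k * pbar * (1 - pbar)
        contrib = (obs - exp) ** 2 / denom if denom > 0 else 0.0
        stat += contrib
        rows.append({"group": int(k), "n": n_k, "observed": obs, "expected": exp, "mean_p": pbar})
    df = len(labels) - 2
    return HLTestResult(
        groups=pd.DataFrame(rows),
        statistic=stat,
        df=df,
        pvalue=float(chi2_dist.sf(stat, df)),
    )


def build_case_control(
    clean: CleanReportSet,
    pairs: pd.DataFrame,
    target_drug: str,
    event_query: set[str],
) -> pd.DataFrame:
    """Case-control rows for the target drug's reports with known sex and age.

    ``outcome`` is 1 when the report carries any query event with the target
    drug, ``female`` / ``age_19_64`` / ``age_65_plus`` are 0/1 indicators
    (reference: male, age <= 18).  Reports missing sex or age are dropped,
    mirroring how such analyses restrict to complete demographics.
    """
    target_ids = set(pairs.loc[pairs["drug"] == target_drug, "report_id"])
    case_ids = set(
        pairs.loc[(pairs["drug"] == target_drug) & pairs["pt"].isin(event_query), "report_id"]
    )
    demo = clean.demo[clean.demo["report_id"].isin(target_ids)].copy()
    demo = demo[(demo["sex"].isin(["M", "F"])) & (demo["age_group"] != "unknown")]
    return pd.DataFrame(
        {
            "report_id": demo["report_id"],
            "outcome": demo["report_id"].isin(case_ids).astype(int),
            "female": (demo["sex"] == "F").astype(int),
            "age_19_64": (demo["age_group"] == "19-64").astype(int),
            "age_65_plus": (demo["age_group"] == ">=65").astype(int),
        }
    ).reset_index(drop=True)


def risk_factor_table(rows: pd.DataFrame, g: int = 10) -> tuple[pd.DataFrame, HLTestResult]:
    """Univariate + multivariate logistic summary over sex and age group.

    Returns a frame with one row per term (odds ratios, CIs, p-values from
    the univariate fit of that variable's terms and from the joint fit of
    all terms) and the Hosmer-Lemeshow result for the joint model.
    """
    variable_terms = {"sex": ["female"], "age": ["age_19_64", "age_65_plus"]}
    all_terms = [t for ts in variable_terms.values() for t in ts]
    multi = fit_logistic(rows, all_terms)
    multi_ci = multi.conf_int()
    out = []
    for _, terms in variable_terms.items():
        uni = fit_logistic(rows, terms)
        uni_ci = uni.conf_int()
        for t in terms:
            out.append(
                {
                    "term": t,
                    "uni_or": float(np.exp(uni.params[t])),
                    "uni_or_low": float(uni_ci.loc[t, "or_low"]),
                    "uni_or_high": float(uni_ci.loc[t, "or_high"]),
                    "uni_p": float(uni.pvalues[t]),
                    "multi_or": float(np.exp(multi.params[t])),
                    "multi_or_low": float(multi_ci.loc[t, "or_low"]),
                    "multi_or_high": float(multi_ci.loc[t, "or_high"]),
                    "multi_p": float(multi.pvalues[t]),
                }
            )
    hl = hosmer_lemeshow(multi.fitted, np.asarray(rows["outcome"], dtype=float), g=g)
    return pd.DataFrame(out), hl
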
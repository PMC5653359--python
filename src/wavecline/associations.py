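"""Residual-correlation and group-comparison statistics.

After the clinal trend along the transect is removed from each trait and
from squared flow resistance, any remaining association between a trait's
residuals and the resistance residuals points at that trait contributing to
grip beyond what the shared geography explains.  The correlation method is
chosen per trait by a Shapiro–Wilk normality gate: Pearson's r when the
trait residuals look Gaussian, Spearman's rank rho otherwise.  The family of
trait-vs-resistance p-values is corrected by the Benjamini–Hochberg step-up.

For common-garden snails (lab-raised offspring of crab and wave ecotype
mothers, so differences are inherited rather than induced) the ecotypes are
compared by a Kruskal–Wallis rank-sum test — the discrete velocity ladder
makes the data heavily tied, which the test's tie correction handles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "KWResult",
    "normality_gate",
    "correlate",
    "bh_adjust",
    "residual_correlation_table",
    "pairwise_residual_correlations",
    "kruskal_wallis",
]


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" or "spearman"
    coefficient: float
    p_value: float
    n: int


@dataclass(frozen=True)
class KWResult:
    """Kruskal–Wallis H (chi-square approximation), df = groups - 1, p."""

    statistic: float
    df: int
    p_value: float


def _clean_vector(x, name: str = "x") -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def normality_gate(x, alpha: float = 0.05) -> str:
    """Pick the correlation method for a residual vector.

    Shapiro–Wilk p < alpha → "spearman" (normality rejected), else "pearson".
    """
    x = _clean_vector(x)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk gate needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: normality undefined")
    p = stats.shapiro(x).pvalue
    return "spearman" if p < alpha else "pearson"


def correlate(x, y, method: str) -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided t-approximation p."""
    x, y = _clean_vector(x, "x"), _clean_vector(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method=method, coefficient=float(r),
                             p_value=float(p), n=len(x))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, each >= raw)."""
    p = _clean_vector(pvalues, "pvalues")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def residual_correlation_table(residuals: pd.DataFrame, response: str = "SFR",
                               alpha: float = 0.05) -> pd.DataFrame:
    """Each trait's residuals vs the response residuals, gated and BH-corrected.

    ``residuals`` holds one column per trait plus the response column; rows
    with NaN in a given trait (e.g. missing foot area) are dropped pairwise.
    """
    traits = [c for c in residuals.columns if c != response]
    if response not in residuals.columns:
        raise ValueError(f"response column {response!r} missing")
    rows = []
    for trait in traits:
        pair = residuals[[trait, response]].dropna()
        method = normality_gate(pair[trait], alpha=alpha)
        res = correlate(pair[trait], pair[response], method)
        rows.append({"trait": trait, "method": res.method,
                     "coefficient": res.coefficient, "p_value": res.p_value,
                     "n": res.n})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    return table


def pairwise_residual_correlations(residuals: pd.DataFrame, alpha: float = 0.05
                                   ) -> dict[str, pd.DataFrame]:
    """Symmetric trait-by-trait residual correlations.

    Returns {"coefficient", "p_value", "method"} DataFrames indexed by trait;
    the coefficient matrix has a unit diagonal.  Each cell's method comes
    from gating the pairwise-complete residuals of both traits (Spearman as
    soon as either deviates from normality).
    """
    traits = list(residuals.columns)
    if len(traits) < 2:
        raise ValueError("need at least 2 traits")
    coef = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    pval = pd.DataFrame(np.zeros((len(traits), len(traits))), index=traits, columns=traits)
    meth = pd.DataFrame("", index=traits, columns=traits)
    np.fill_diagonal(pval.values, np.nan)
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            pair = residuals[[a, b]].dropna()
            gates = {normality_gate(pair[a], alpha), normality_gate(pair[b], alpha)}
            method = "spearman" if "spearman" in gates else "pearson"
            res = correlate(pair[a], pair[b], method)
            coef.loc[a, b] = coef.loc[b, a] = res.coefficient
            pval.loc[a, b] = pval.loc[b, a] = res.p_value
            meth.loc[a, b] = meth.loc[b, a] = method
    return {"coefficient": coef, "p_value": pval, "method": meth}


def kruskal_wallis(groups) -> KWResult:
    """Kruskal–Wallis rank-sum test with mid-ranks and tie correction."""
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("total n must be at least 3")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # every rank tied: H is exactly 0
        return KWResult(statistic=0.0, df=len(groups) - 1, p_value=1.0)
    stat, p = stats.kruskal(*groups)
    return KWResult(statistic=float(stat), df=len(groups) - 1, p_value=float(p))
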
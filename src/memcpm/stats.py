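"""Model evaluation and significance machinery.

Performance is summarized by Spearman's rank correlation between predicted
and observed scores and by the root mean square error

    RMSE = sqrt( (1/n) * sum_i (actual_i - predicted_i)^2 ).

Model significance is permutation-based: scores are shuffled relative to
(connectome, covariates), the full cross-validated procedure is re-run per
permutation, and

    p = #{ rho_null >= rho_median } / n_permutations,

where rho_median is the unpermuted ensemble's median performance.  Families
of such p-values (21 models per subject group: 7 scans x 3 scores) are
corrected by the Benjamini-Hochberg step-up procedure.  Sex differences in
performance distributions are compared with two-sided Wilcoxon rank-sum
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def spearman_rho(x, y, warn: bool = True) -> float:
    """Spearman rank correlation (Pearson on mid-ranks; average ranks on ties).

    Returns NaN with a warning when either vector is constant, where rank
    correlation is undefined.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        if warn:
            warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


def rmse(predicted, observed) -> float:
    """Root mean square error between predictions and observations."""
    p = np.asarray(predicted, float)
    o = np.asarray(observed, float)
    if p.shape != o.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("predicted and observed must be equal-length vectors")
    return float(np.sqrt(np.mean((o - p) ** 2)))


def bh_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1, for the
    ascending order statistics p_(1) <= ... <= p_(m).
    """
    p = np.asarray(pvalues, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p-values must be a non-empty 1-D vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    m = n if m is None else int(m)
    if m < n:
        raise ValueError("family size m cannot be smaller than the number of tests")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(n)
    out[order] = adj
    return out


@dataclass
class PermutationResult:
    """Permutation-null performance distribution and non-parametric p."""

    rho_null: np.ndarray
    rho_median: float
    n_permutations: int

    @property
    def p(self) -> float:
        finite = self.rho_null[np.isfinite(self.rho_null)]
        return float(np.sum(finite >= self.rho_median) / self.n_permutations)

    @property
    def p_display(self) -> str:
        """Zero p reported as a bound (< 1/n_perm) in human-readable output."""
        p = self.p
        return f"< {1.0 / self.n_permutations:g}" if p == 0.0 else f"{p:g}"


def permutation_test(X: np.ndarray, y: np.ndarray, covariates: dict | None,
                     config, rho_median: float, n_permutations: int = 1000,
                     seed: int | None = None) -> PermutationResult:
    """Permutation-null significance for a completed CPM ensemble.

    Each permutation shuffles the score vector relative to the connectomes
    and covariates (outcome shuffling preserves the confound structure of the
    null) and re-runs the full cross-validated procedure once; the fraction of
    null performances at or above the unpermuted median is the p-value.
    """
    from .cpm import config_with_seed, run_cpm  # local import: avoid cycle

    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if not np.isfinite(rho_median):
        raise ValueError("rho_median must be finite")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    y = np.asarray(y, float)
    rho_null = np.empty(n_permutations)
    for b in range(n_permutations):
        y_perm = y[rng.permutation(y.size)]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = run_cpm(X, y_perm, covariates,
                      config_with_seed(_single_iteration(config), sub_seed))
        rho_null[b] = res[0].rho
    return PermutationResult(rho_null=rho_null, rho_median=float(rho_median),
                             n_permutations=n_permutations)


def _single_iteration(config):
    from dataclasses import replace
    return replace(config, n_iterations=1)


def compare_group_performance(rho_f, rho_m) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of per-iteration performances.

    Exact enumeration for combined n <= 20 without ties; otherwise the
    tie-corrected normal approximation.  Returns (U statistic for the first
    group, two-sided p).
    """
    a = np.asarray(rho_f, float)
    b = np.asarray(rho_m, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def performance_table(rows: list[dict]) -> pd.DataFrame:
    """Flat results table (group, scan, score, rho_median, rmse_median, p_raw)
    with BH-adjusted p added within each group family."""
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["p_bh"] = np.nan
    for group, idx in df.groupby("group").groups.items():
        fam = df.loc[idx, "p_raw"].to_numpy(float)
        df.loc[idx, "p_bh"] = bh_adjust(fam)
    return df
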
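"""Cohort-level statistics.

Nonparametric group comparisons (Mann-Whitney, Kruskal-Wallis), Spearman
correlation with a permutation p-value at small n, Benjamini-Hochberg FDR,
z-scaled group-median heatmap tables, Euclidean nearest-neighbour cohort
matching with hard sex/T2D strata, and the linear-regression validation of
model-derived against tracer-measured fluxes (with a Bland-Altman-style
agreement table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "MatchResult",
    "StatsError",
    "mann_whitney",
    "kruskal_wallis",
    "spearman",
    "bh_fdr",
    "group_median_zscale",
    "match_cohorts",
    "linear_validation",
]

#: per-group size at or below which the Mann-Whitney p is computed exactly
EXACT_MW_MAX_N = 8
#: sample size at or below which the Spearman p uses permutations
PERMUTATION_SPEARMAN_MAX_N = 10


class StatsError(ValueError):
    pass


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    n_per_group: list[int]
    groups: list[str] | None = None
    q_value: float | None = None


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # columns id_a, id_b, distance
    features: list[str]
    standardization: dict = field(default_factory=dict)
    unmatched_a: list = field(default_factory=list)
    unmatched_b: list = field(default_factory=list)

    @property
    def total_distance(self) -> float:
        return float(self.pairs["distance"].sum())


def mann_whitney(a, b) -> GroupComparison:
    """Two-sided Mann-Whitney U test; exact null distribution when both
    groups have <= 8 observations and no ties, tie-corrected normal
    approximation otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise StatsError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if len(a) <= EXACT_MW_MAX_N and len(b) <= EXACT_MW_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        test="mann-whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=[len(a), len(b)],
    )


def kruskal_wallis(groups: list, labels: list[str] | None = None) -> GroupComparison:
    """Kruskal-Wallis H test with tie correction, chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise StatsError("need at least 2 non-empty groups")
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        # identical samples: H = 0, no evidence against the null
        return GroupComparison("kruskal-wallis", 0.0, 1.0,
                               [len(g) for g in groups], labels)
    res = sps.kruskal(*groups)
    return GroupComparison(
        test="kruskal-wallis",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=[len(g) for g in groups],
        groups=labels,
    )


def spearman(x, y, seed: int = 0) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties).

    The p-value uses a permutation test for n <= 10 and the t
    approximation otherwise.  Constant input is an error (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsError("need paired samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatsError("constant input: Spearman rho undefined")
    if len(x) <= PERMUTATION_SPEARMAN_MAX_N:
        def stat(xp):
            return sps.spearmanr(xp, y).statistic

        res = sps.permutation_test(
            (x,), stat, permutation_type="pairings",
            n_resamples=20000, rng=np.random.default_rng(seed),
        )
        return float(sps.spearmanr(x, y).statistic), float(res.pvalue)
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def group_median_zscale(
    table: pd.DataFrame,
    groups: pd.Series,
    group_order: list[str] | None = None,
) -> pd.DataFrame:
    """Heatmap table: z-scale each variable across all subjects (zero mean,
    unit variance), then take the median within each group.

    Zero-variance variables are dropped with a warning.  Rows are groups,
    columns variables.
    """
    groups = pd.Series(groups).reset_index(drop=True)
    table = table.reset_index(drop=True)
    if len(table) != len(groups):
        raise StatsError("table and groups must align")
    sd = table.std(ddof=1)
    dead = sd.index[(sd == 0) | sd.isna()].tolist()
    if dead:
        warnings.warn(f"dropping zero-variance variables: {dead}", stacklevel=2)
        table = table.drop(columns=dead)
        sd = sd.drop(dead)
    z = (table - table.mean()) / sd
    med = z.groupby(groups).median()
    if group_order is not None:
        med = med.reindex(group_order)
    return med


def _standardize_pooled(a: pd.DataFrame, b: pd.DataFrame, cols: list[str]):
    pooled = pd.concat([a[cols], b[cols]], axis=0)
    mean, sd = pooled.mean(), pooled.std(ddof=1).replace(0, 1.0)
    return (a[cols] - mean) / sd, (b[cols] - mean) / sd, {
        "mean": mean.to_dict(), "sd": sd.to_dict()}


def match_cohorts(
    a: pd.DataFrame,
    b: pd.DataFrame,
    features: list[str],
    strata: list[str] = ("sex", "t2d"),
    id_col: str = "id",
    standardize: bool = True,
    method: str = "greedy",
) -> MatchResult:
    """1:1 cross-cohort matching minimizing Euclidean distance.

    Continuous features are z-standardized on the pooled data; categorical
    strata (sex, T2D) are matched exactly -- pairs across levels are
    forbidden.  ``method='greedy'`` pairs in order of ascending best
    distance without replacement; ``method='optimal'`` solves the
    assignment problem per stratum.  Subjects left without an admissible
    partner are reported unmatched.
    """
    strata = [s for s in strata if s in a.columns and s in b.columns]
    missing = [f for f in features if f not in a.columns or f not in b.columns]
    if missing:
        raise StatsError(f"features missing from a cohort table: {missing}")
    if standardize:
        fa, fb, std = _standardize_pooled(a, b, list(features))
    else:
        fa, fb, std = a[list(features)], b[list(features)], {}
    key_a = a[strata].astype(str).agg("|".join, axis=1) if strata else pd.Series("", index=a.index)
    key_b = b[strata].astype(str).agg("|".join, axis=1) if strata else pd.Series("", index=b.index)

    pairs = []
    unmatched_a: list = []
    unmatched_b: list = []
    for level in sorted(set(key_a) | set(key_b)):
        ia = a.index[key_a == level]
        ib = b.index[key_b == level]
        if len(ia) == 0 or len(ib) == 0:
            unmatched_a += a.loc[ia, id_col].tolist()
            unmatched_b += b.loc[ib, id_col].tolist()
            continue
        D = np.linalg.norm(
            fa.loc[ia].to_numpy()[:, None, :] - fb.loc[ib].to_numpy()[None, :, :],
            axis=2,
        )
        if method == "optimal":
            # pad to square so the assignment drops the surplus side
            ra, cb = linear_sum_assignment(D)
            taken_a = set(ra)
            taken_b = set(cb)
            for i, j in zip(ra, cb):
                pairs.append((a.loc[ia[i], id_col], b.loc[ib[j], id_col],
                              float(D[i, j])))
        elif method == "greedy":
            Dw = D.copy()
            taken_a, taken_b = set(), set()
            n_pairs = min(len(ia), len(ib))
            for _ in range(n_pairs):
                i, j = np.unravel_index(np.argmin(Dw), Dw.shape)
                pairs.append((a.loc[ia[i], id_col], b.loc[ib[j], id_col],
                              float(D[i, j])))
                taken_a.add(i)
                taken_b.add(j)
                Dw[i, :] = np.inf
                Dw[:, j] = np.inf
        else:
            raise StatsError(f"unknown matching method {method!r}")
        unmatched_a += [a.loc[ia[i], id_col] for i in range(len(ia))
                        if i not in taken_a]
        unmatched_b += [b.loc[ib[j], id_col] for j in range(len(ib))
                        if j not in taken_b]
    pairs_df = pd.DataFrame(pairs, columns=["id_a", "id_b", "distance"])
    return MatchResult(
        pairs=pairs_df,
        features=list(features),
        standardization=std,
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
    )


def linear_validation(x, y) -> dict:
    """Ordinary least squares of model-derived (y) on measured (x) fluxes.

    Returns slope, intercept, Pearson r and its p-value, plus a
    Bland-Altman-style agreement summary (bias = mean difference and 95%
    limits of agreement).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsError("need paired samples with n >= 3")
    if np.all(x == x[0]):
        raise StatsError("zero variance in x: regression undefined")
    res = sps.linregress(x, y)
    diff = y - x
    agreement = pd.DataFrame({
        "mean": (x + y) / 2.0,
        "difference": diff,
    })
    bias = float(diff.mean())
    loa = 1.96 * float(diff.std(ddof=1))
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "p": float(res.pvalue),
        "n": int(len(x)),
        "bias": bias,
        "loa_low": bias - loa,
        "loa_high": bias + loa,
        "agreement": agreement,
    }
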
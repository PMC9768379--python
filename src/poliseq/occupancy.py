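"""Replicate- and strain-level occupancy statistics.

Given normalized occupancy profiles for replicate NET-Seq libraries of two
strains, this module provides the comparisons used to characterize polymerase
repositioning: per-position medians and Welch t tests with an
increased/decreased/no-change classification, two-sample Kolmogorov-Smirnov
comparisons of positional distributions within a region (spacers, typically),
moving-average and ECDF summaries, replicate Spearman correlation matrices,
and a PCA of the libraries-by-positions matrix.

Statistical choices (all parameterized):

* Welch (unequal-variance) two-sided t test per position, no multiple-testing
  correction by default — each position is colored at its own p < alpha, with
  an optional Benjamini-Hochberg flag.
* Positions where both strains have zero variance and equal means get p = 1
  (no-change) instead of NaN.
* The KS p-value uses the asymptotic Kolmogorov distribution with Stephens'
  finite-sample correction; the effective sample size is the region-mapped
  read count per strain, capped (default 10,000) so read-level n does not
  drive every p to zero.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .rdna import Region
from .reads import OccupancyProfile

INCREASED = "increased"
DECREASED = "decreased"
NO_CHANGE = "no_change"


def _stack(profiles: Sequence[OccupancyProfile]) -> np.ndarray:
    mats = []
    for p in profiles:
        if p.normalized is None:
            raise ValueError(f"profile {p.library_id} is not normalized")
        mats.append(p.normalized)
    lengths = {len(m) for m in mats}
    if len(lengths) != 1:
        raise ValueError("profiles have mismatched template lengths")
    return np.vstack(mats)


def median_occupancy(profiles: Sequence[OccupancyProfile]) -> np.ndarray:
    """Elementwise median of normalized occupancy across replicates."""
    if not profiles:
        raise ValueError("need at least one profile")
    return np.median(_stack(profiles), axis=0)


def positionwise_ttest(
    reps_a: Sequence[OccupancyProfile],
    reps_b: Sequence[OccupancyProfile],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-position Welch t test of strain B vs strain A normalized occupancy.

    Returns a table with 1-based ``position``, ``median_a``, ``median_b``,
    ``p_value`` and ``cls`` (increased/decreased in B vs A at p < alpha, by
    median direction; equal medians or p >= alpha -> no_change).
    """
    if len(reps_a) < 2 or len(reps_b) < 2:
        raise ValueError("need >= 2 replicates per strain")
    a = _stack(reps_a)
    b = _stack(reps_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("strains have mismatched template lengths")
    med_a = np.median(a, axis=0)
    med_b = np.median(b, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        _t, p = stats.ttest_ind(b, a, axis=0, equal_var=False)
    p = np.asarray(p, dtype=float)
    zero_var = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    equal_mean = a.mean(axis=0) == b.mean(axis=0)
    p[zero_var & equal_mean] = 1.0
    p[zero_var & ~equal_mean] = 0.0
    p[np.isnan(p)] = 1.0
    p_eval = _bh_adjust(p) if bh_correct else p
    cls = np.full(len(p), NO_CHANGE, dtype=object)
    sig = (p_eval < alpha) & (med_a != med_b)
    cls[sig & (med_b > med_a)] = INCREASED
    cls[sig & (med_b < med_a)] = DECREASED
    return pd.DataFrame(
        {
            "position": np.arange(1, a.shape[1] + 1),
            "median_a": med_a,
            "median_b": med_b,
            "p_value": p_eval,
            "cls": cls,
        }
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def region_ks_test(
    profile_a: OccupancyProfile,
    profile_b: OccupancyProfile,
    region: Region,
    cap: int = 10_000,
) -> tuple[float, float]:
    """Two-sample KS comparison of positional occupancy within one region.

    Each strain's positional distribution is its normalized counts inside the
    region rescaled to sum 1; D is the maximum ECDF difference over positions.
    The p-value uses the asymptotic Kolmogorov tail at effective sample sizes
    equal to region-mapped read counts capped at ``cap`` per strain.
    """
    sl = slice(region.start, region.end)
    wa = np.asarray(profile_a.normalized[sl], dtype=float)
    wb = np.asarray(profile_b.normalized[sl], dtype=float)
    if wa.sum() == 0 or wb.sum() == 0:
        raise ValueError(f"no occupancy in region {region.name} for one strain")
    Fa = np.cumsum(wa) / wa.sum()
    Fb = np.cumsum(wb) / wb.sum()
    D = float(np.max(np.abs(Fa - Fb)))
    na = min(cap, int(profile_a.counts[sl].sum()))
    nb = min(cap, int(profile_b.counts[sl].sum()))
    en = np.sqrt(na * nb / (na + nb))
    p = float(special.kolmogorov((en + 0.12 + 0.11 / en) * D))
    return D, min(max(p, 0.0), 1.0)


def moving_average(values: Sequence[float], window: int) -> np.ndarray:
    """Centered moving average; edge windows are truncated, not padded."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    x = np.asarray(values, dtype=float)
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    norms = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / norms


def ecdf(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF: sorted unique values and the right-continuous step
    heights (terminal value 1)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    xs, counts = np.unique(x, return_counts=True)
    return xs, np.cumsum(counts) / x.size


def spearman_matrix(profiles: Sequence[OccupancyProfile]) -> pd.DataFrame:
    """Pairwise Spearman rank correlations of normalized profiles.

    Ties get average ranks; a constant profile yields NaN against everything
    (rank correlation undefined) but 1.0 on the diagonal.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    import warnings

    X = _stack(profiles)
    n = X.shape[0]
    rho = np.ones((n, n))
    with warnings.catch_warnings():
        # constant profiles are deliberately reported as NaN
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        for i in range(n):
            for j in range(i + 1, n):
                r = stats.spearmanr(X[i], X[j]).statistic
                rho[i, j] = rho[j, i] = r
    labels = [p.library_id for p in profiles]
    return pd.DataFrame(rho, index=labels, columns=labels)


def pca_variance(
    profiles: Sequence[OccupancyProfile],
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the libraries x positions matrix of normalized counts.

    Columns (positions) are mean-centered; components come from the SVD.
    Returns ``(variance_fractions, scores)`` with fractions non-increasing and
    summing to 1, and scores of shape (n_libraries, n_components).
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    X = _stack(profiles)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValueError("profiles are identical; PCA variance undefined")
    fractions = var / total
    scores = U * s
    return fractions, scores


def ttest_table_summary(table: pd.DataFrame) -> dict[str, int]:
    """Counts of increased / decreased / no_change classifications."""
    return table["cls"].value_counts().reindex(
        [INCREASED, DECREASED, NO_CHANGE], fill_value=0
    ).to_dict()
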
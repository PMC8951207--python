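"""Group comparison of network metrics and connectivity matrices.

Covers the study's statistical chain: pooled-variance independent-samples
t tests per band x metric x sparsity with Benjamini-Hochberg FDR control
(family = all sparsity levels within one band x metric, configurable),
Cohen's d effect sizes, averaging of metrics over the significant sparsity
range, a rank-sum utility for demographics, and a permutation-based
network-difference test in the style of the network-based statistic (NBS):
edge-wise t statistics, suprathreshold connected components, and a
max-component-size permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .connectivity import PLIMatrix
from .network import METRICS, TopologyCurve

__all__ = [
    "ttest_ind", "cohens_d_from_t", "cohens_d_pooled", "fdr_bh",
    "wilcoxon_rank_sum", "compare_topology", "average_significant",
    "AveragedComparison", "nbs_test", "NbsResult",
]


def ttest_ind(values_a, values_b) -> tuple[float, int, float]:
    """Two-sided pooled-variance t test; returns (t, df, p) with df = n1+n2-2."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in t-test input")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, a.size + b.size - 2, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = sst.ttest_ind(a, b, equal_var=True)
    return float(t), int(a.size + b.size - 2), float(p)


def cohens_d_from_t(t: float, df: int) -> float:
    """Equal-n conversion d = 2|t| / sqrt(df)."""
    if df <= 0:
        raise ValueError("df must be positive")
    return 2.0 * abs(float(t)) / np.sqrt(df)


def cohens_d_pooled(values_a, values_b) -> float:
    """Signed Cohen's d from raw samples with the pooled standard deviation."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two observations")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0.0:
        raise ValueError("zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank_sum(values_a, values_b) -> tuple[float, float]:
    """Two-sided rank-sum (Mann-Whitney U) test for demographics.

    Exact null for group sizes up to 25, normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    method = "exact" if max(a.size, b.size) <= 25 else "asymptotic"
    try:
        res = sst.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:  # exact method refuses ties
        res = sst.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


# ----------------------------------------------------------------------------
# Topology-curve comparisons
# ----------------------------------------------------------------------------

def _curve_matrix(curves: Sequence[TopologyCurve], metric: str) -> np.ndarray:
    grids = {tuple(np.round(c.sparsity, 10)) for c in curves}
    if len(grids) != 1:
        raise ValueError("all curves must share the same sparsity grid")
    return np.stack([c.metric(metric) for c in curves])


def compare_topology(
    curves_a: Sequence[TopologyCurve],
    curves_b: Sequence[TopologyCurve],
    *,
    metrics: Iterable[str] = METRICS,
    fdr_family: str = "band_metric",
) -> pd.DataFrame:
    """Per-sparsity group comparison of each metric.

    Returns one row per (band, metric, sparsity) with t, df, p, BH-adjusted p
    (family controlled by `fdr_family`: "band_metric" adjusts across the
    sparsity grid within each metric, "all" across every row), Cohen's d
    (2t/sqrt(df) conversion, signed like t), and group means/SDs.
    """
    if fdr_family not in ("band_metric", "all"):
        raise ValueError("fdr_family must be 'band_metric' or 'all'")
    band = curves_a[0].band
    grid = curves_a[0].sparsity
    frames = []
    for metric in metrics:
        ma = _curve_matrix(list(curves_a) + list(curves_b), metric)
        va, vb = ma[: len(curves_a)], ma[len(curves_a):]
        rows = []
        for k, s in enumerate(grid):
            t, df, p = ttest_ind(va[:, k], vb[:, k])
            d = float(np.sign(t)) * cohens_d_from_t(t, df)
            rows.append(
                (band, metric, float(s), t, df, p, d,
                 va[:, k].mean(), vb[:, k].mean(),
                 va[:, k].std(ddof=1), vb[:, k].std(ddof=1))
            )
        frame = pd.DataFrame(
            rows,
            columns=["band", "metric", "sparsity", "t", "df", "p", "cohens_d",
                     "mean_a", "mean_b", "sd_a", "sd_b"],
        )
        if fdr_family == "band_metric":
            frame["p_fdr"] = fdr_bh(frame["p"].to_numpy())
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    if fdr_family == "all":
        out["p_fdr"] = fdr_bh(out["p"].to_numpy())
    return out


@dataclass(frozen=True)
class AveragedComparison:
    """Comparison of a metric averaged over its FDR-significant sparsity levels."""

    band: str | None
    metric: str
    significant_sparsities: np.ndarray
    values_a: np.ndarray
    values_b: np.ndarray
    t: float
    df: int
    p: float
    cohens_d: float

    @property
    def empty(self) -> bool:
        return self.significant_sparsities.size == 0


def average_significant(
    curves_a: Sequence[TopologyCurve],
    curves_b: Sequence[TopologyCurve],
    metric: str,
    *,
    alpha: float = 0.05,
    comparison: pd.DataFrame | None = None,
) -> AveragedComparison | None:
    """Average each subject's metric over the FDR-significant sparsity levels.

    Identifies grid values where the BH-adjusted comparison is significant,
    averages each subject's metric over that (not necessarily contiguous) set,
    and re-runs the t test and effect size on the averaged values.  Returns
    ``None`` when no sparsity level is significant.
    """
    if comparison is None:
        comparison = compare_topology(curves_a, curves_b, metrics=(metric,))
    sub = comparison[comparison["metric"] == metric]
    sig = sub.loc[sub["p_fdr"] < alpha, "sparsity"].to_numpy()
    if sig.size == 0:
        return None
    grid = curves_a[0].sparsity
    mask = np.isin(np.round(grid, 10), np.round(sig, 10))
    va = _curve_matrix(curves_a, metric)[:, mask].mean(axis=1)
    vb = _curve_matrix(curves_b, metric)[:, mask].mean(axis=1)
    t, df, p = ttest_ind(va, vb)
    d = float(np.sign(t)) * cohens_d_from_t(t, df)
    return AveragedComparison(curves_a[0].band, metric, sig, va, vb, t, df, p, d)


# ----------------------------------------------------------------------------
# Network-based permutation statistics
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class NbsResult:
    """Suprathreshold components and their permutation p-values."""

    primary_threshold: float
    components: tuple[tuple[tuple[int, int], ...], ...]
    component_p: np.ndarray
    component_sizes: np.ndarray
    n_permutations: int
    seed: int
    max_null_sizes: np.ndarray = field(repr=False, default=None)


def _edge_tstats(stack: np.ndarray, n_a: int, iu, ju) -> np.ndarray:
    """Pooled-variance t statistics for every upper-triangular edge."""
    ea = stack[:n_a, iu, ju]
    eb = stack[n_a:, iu, ju]
    na, nb = ea.shape[0], eb.shape[0]
    va = ea.var(axis=0, ddof=1)
    vb = eb.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ea.mean(axis=0) - eb.mean(axis=0)) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return t


def _components(edge_mask: np.ndarray, iu, ju, n: int):
    """Connected components (as edge lists) of the suprathreshold graph."""
    keep = np.flatnonzero(edge_mask)
    if keep.size == 0:
        return []
    rows = iu[keep]
    cols = ju[keep]
    data = np.ones(keep.size)
    adj = csr_matrix((data, (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    comps: dict[int, list[tuple[int, int]]] = {}
    for r, c in zip(rows, cols):
        comps.setdefault(labels[r], []).append((int(r), int(c)))
    return sorted((tuple(v) for v in comps.values()), key=len, reverse=True)


def nbs_test(
    matrices_a: Sequence[PLIMatrix | np.ndarray],
    matrices_b: Sequence[PLIMatrix | np.ndarray],
    *,
    primary_t: float = 2.0,
    n_perm: int = 1000,
    seed: int = 0,
    tail: str = "both",
) -> NbsResult:
    """Permutation network-difference test on connectivity matrices.

    Edge-wise pooled t statistics are thresholded at `primary_t` (on |t| for
    ``tail="both"``, on t for ``tail="greater"``); connected components of the
    suprathreshold graph are scored by edge count against the permutation null
    of the maximum component size.  ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if tail not in ("both", "greater"):
        raise ValueError("tail must be 'both' or 'greater'")
    arrs_a = [m.values if isinstance(m, PLIMatrix) else np.asarray(m, float) for m in matrices_a]
    arrs_b = [m.values if isinstance(m, PLIMatrix) else np.asarray(m, float) for m in matrices_b]
    if len(arrs_a) < 2 or len(arrs_b) < 2:
        raise ValueError("each group needs at least two subjects")
    stack = np.stack(arrs_a + arrs_b)
    n_a = len(arrs_a)
    n = stack.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    span = stack[:, iu, ju]
    if np.any(span.max(axis=0) == span.min(axis=0)):
        raise ValueError("degenerate (constant) edge across all subjects")

    def supra(t):
        return (np.abs(t) if tail == "both" else t) > primary_t

    t_obs = _edge_tstats(stack, n_a, iu, ju)
    comps = _components(supra(t_obs), iu, ju, n)
    sizes = np.array([len(c) for c in comps], dtype=int)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm, dtype=int)
    n_tot = stack.shape[0]
    for k in range(n_perm):
        perm = rng.permutation(n_tot)
        t_null = _edge_tstats(stack[perm], n_a, iu, ju)
        mask = supra(t_null)
        if mask.any():
            null_comps = _components(mask, iu, ju, n)
            null_max[k] = len(null_comps[0])
    pvals = np.array([(1 + int((null_max >= s).sum())) / (1 + n_perm) for s in sizes])
    return NbsResult(primary_t, tuple(comps), pvals, sizes, n_perm, seed, null_max)
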
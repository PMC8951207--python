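"""Rank correlation of metabolites and depression scores with network topology.

Spearman correlations are evaluated at every sparsity level of each subject's
topology curve, producing a (feature x band x metric x sparsity) map and, per
slice, the sparsity of maximum absolute correlation.  Because the scan spans
36 correlated thresholds, a max-statistic permutation family-wise p-value is
available alongside the per-threshold p-values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

from .network import METRICS, TopologyCurve

__all__ = [
    "spearman", "CorrelationMap", "metabolite_topology_scan",
    "score_metabolite_correlation", "scan_max_statistic_p", "pathway_score",
]


def spearman(x, y, *, exact_limit: int = 8) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties get average ranks.  For n <= `exact_limit` the p-value comes from
    exact enumeration of all n! pairings (permutation null); otherwise from
    the t approximation.  The default limit of 8 keeps the exact path below
    ~50k enumerated pairings; raise it (to at most ~10) if an exact p at
    slightly larger n is worth seconds of compute.  Constant inputs raise.
    """
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("constant input vector: rank correlation undefined")
    if n <= exact_limit:
        rx = sst.rankdata(xa) - (n + 1) / 2.0
        ry = sst.rankdata(ya) - (n + 1) / 2.0
        den = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
        rho = float(rx @ ry / den)
        count = total = 0
        chunk: list = []
        for perm in itertools.permutations(range(n)):
            chunk.append(perm)
            if len(chunk) == 50_000:
                r = (ry[np.array(chunk)] @ rx) / den
                count += int((np.abs(r) >= abs(rho) - 1e-12).sum())
                total += len(chunk)
                chunk.clear()
        if chunk:
            r = (ry[np.array(chunk)] @ rx) / den
            count += int((np.abs(r) >= abs(rho) - 1e-12).sum())
            total += len(chunk)
        return rho, count / total
    rho, p = sst.spearmanr(xa, ya)
    return float(rho), float(p)


def _spearman_grid(feat: np.ndarray, curves_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """rho and t-approximation p of one feature against each grid column."""
    n, k = curves_mat.shape
    rf = sst.rankdata(feat)
    rc = sst.rankdata(curves_mat, axis=0)
    rf = rf - rf.mean()
    rc = rc - rc.mean(axis=0)
    denom = np.sqrt((rf ** 2).sum() * (rc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rf @ rc) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * sst.t.sf(np.abs(t), n - 2)
    p[np.isnan(p)] = 0.0  # |rho| == 1
    return rho, p


@dataclass(frozen=True)
class CorrelationMap:
    """Tidy correlation results over the sparsity grid.

    ``frame`` has one row per (feature, band, metric, sparsity) with rho, p
    and n; ``argmax`` one row per (feature, band, metric) with the sparsity of
    maximum |rho| and the correlation there (plus the family-wise permutation
    p when requested).
    """

    frame: pd.DataFrame
    argmax: pd.DataFrame


def _curves_by_subject(curves: Sequence[TopologyCurve]) -> tuple[list[str], np.ndarray, dict]:
    subjects = [c.subject for c in curves]
    if any(s is None for s in subjects):
        raise ValueError("every topology curve needs a subject ID")
    grids = {tuple(np.round(c.sparsity, 10)) for c in curves}
    if len(grids) != 1:
        raise ValueError("curves must share one sparsity grid")
    return subjects, curves[0].sparsity, {c.subject: c for c in curves}


def metabolite_topology_scan(
    features: pd.DataFrame,
    curves: Sequence[TopologyCurve],
    *,
    metrics: Sequence[str] = METRICS,
    n_perm: int | None = None,
    seed: int = 0,
) -> CorrelationMap:
    """Spearman scan of each feature against each metric across the grid.

    `features` is a samples x features DataFrame (typically the selected
    metabolites); subjects are matched to curves by ID, and a mismatch (empty
    intersection) raises.  With `n_perm` set, a max-|rho| permutation
    family-wise p-value over the grid is added per (feature, band, metric).
    """
    subjects, grid, by_subj = _curves_by_subject(curves)
    common = [s for s in features.index if s in by_subj]
    if not common:
        raise ValueError("subject IDs of features and topology curves do not overlap")
    if features.shape[1] == 0:
        raise ValueError("no features to correlate")
    band = curves[0].band
    n = len(common)
    feat_mat = features.loc[common].to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    arg_rows = []
    for metric in metrics:
        cm = np.stack([by_subj[s].metric(metric) for s in common])
        for j, fname in enumerate(features.columns):
            rho, p = _spearman_grid(feat_mat[:, j], cm)
            for k, s in enumerate(grid):
                rows.append((fname, band, metric, float(s), rho[k], p[k], n))
            kmax = int(np.argmax(np.abs(rho)))
            fw_p = np.nan
            if n_perm:
                obs = np.abs(rho[kmax])
                exceed = 0
                for _ in range(n_perm):
                    pr, _ = _spearman_grid(rng.permutation(feat_mat[:, j]), cm)
                    if np.abs(pr).max() >= obs:
                        exceed += 1
                fw_p = (1 + exceed) / (1 + n_perm)
            arg_rows.append((fname, band, metric, float(grid[kmax]), rho[kmax], p[kmax], fw_p))
    frame = pd.DataFrame(rows, columns=["feature", "band", "metric", "sparsity", "rho", "p", "n"])
    argmax = pd.DataFrame(
        arg_rows,
        columns=["feature", "band", "metric", "argmax_sparsity", "rho", "p", "p_fw_perm"],
    )
    return CorrelationMap(frame, argmax)


def scan_max_statistic_p(
    feature: np.ndarray,
    curves_mat: np.ndarray,
    *,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Family-wise p for the maximum |rho| over a grid, by permutation."""
    rng = np.random.default_rng(seed)
    rho, _ = _spearman_grid(np.asarray(feature, float), curves_mat)
    obs = np.abs(rho).max()
    exceed = 0
    for _ in range(n_perm):
        pr, _ = _spearman_grid(rng.permutation(feature), curves_mat)
        if np.abs(pr).max() >= obs:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def score_metabolite_correlation(
    scores: pd.Series | Mapping[str, float],
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman rho and p of each feature against the depression score."""
    scores = pd.Series(scores)
    common = [s for s in features.index if s in scores.index]
    if len(common) < 3:
        raise ValueError("fewer than 3 subjects with both score and metabolite data")
    sv = scores.loc[common].to_numpy(dtype=np.float64)
    if np.ptp(sv) == 0:
        raise ValueError("constant score vector")
    rows = []
    for fname in features.columns:
        rho, p = spearman(sv, features.loc[common, fname].to_numpy())
        rows.append((fname, rho, p, len(common)))
    return pd.DataFrame(rows, columns=["feature", "rho", "p", "n"]).set_index("feature")


def pathway_score(features: pd.DataFrame, members: Sequence[str]) -> pd.Series:
    """First principal-component score of a pathway's member features.

    Interpretation of 'pathway-level' correlation: member intensities are
    log10-transformed, z-scored, and projected on their first principal
    component (sign fixed so the mean loading is non-negative).
    """
    missing = [m for m in members if m not in features.columns]
    if missing:
        raise KeyError(f"pathway members absent from table: {missing}")
    x = np.log10(features.loc[:, list(members)].to_numpy())
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    x /= sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    v = vt[0]
    if v.mean() < 0:
        v = -v
    return pd.Series(x @ v, index=features.index, name="pathway_pc1")
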
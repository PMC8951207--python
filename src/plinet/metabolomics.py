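"""Differential-metabolite screening: PLS-DA, VIP, and univariate tests.

The multivariate stage fits a partial-least-squares discriminant model
(PLS-DA, NIPALS deflation on a centred class dummy) and ranks features by
their variable importance in projection:

    VIP_j = sqrt( p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a )

where ``p`` is the feature count and ``SSY_a`` the class-variance explained by
component ``a``.  By construction ``mean_j VIP_j^2 = 1``.  The univariate
stage runs per-feature two-sample t tests (on log intensities by default) with
Benjamini-Hochberg adjustment and raw-scale fold changes; a metabolite is
selected when ``VIP > 1`` and ``p < 0.05``.

An optional orthogonal-signal-correction prefilter (removal of the dominant
class-orthogonal component) approximates an OPLS-style predictive/orthogonal
split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

from .groupstats import fdr_bh, ttest_ind

__all__ = [
    "MetaboliteTable", "PLSDAModel", "ScreenResult",
    "preprocess_intensities", "pls_da", "vip", "univariate_screen",
]


@dataclass(frozen=True)
class MetaboliteTable:
    """Samples x features intensity matrix with binary group labels.

    ``intensities`` is a DataFrame indexed by sample ID with feature-name
    columns; all values strictly positive.  ``group_order`` fixes which label
    is the case (numerator of fold changes); it defaults to the first label
    encountered in `groups`.
    """

    intensities: pd.DataFrame
    groups: pd.Series
    group_order: tuple[str, str] | None = None

    def __post_init__(self):
        x = self.intensities
        if not isinstance(x, pd.DataFrame):
            x = pd.DataFrame(x)
        x = x.astype(np.float64)
        if (x.to_numpy() <= 0).any() or not np.isfinite(x.to_numpy()).all():
            raise ValueError("intensities must be strictly positive and finite")
        if x.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        g = pd.Series(self.groups)
        g = g.reindex(x.index)
        if g.isna().any():
            raise ValueError("every sample needs a group label")
        uniq = list(dict.fromkeys(g))
        if len(uniq) != 2:
            raise ValueError(f"group labels must be binary, got {uniq}")
        order = self.group_order or (uniq[0], uniq[1])
        if set(order) != set(uniq):
            raise ValueError("group_order does not match the labels present")
        object.__setattr__(self, "intensities", x)
        object.__setattr__(self, "groups", g)
        object.__setattr__(self, "group_order", tuple(order))

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def feature_names(self) -> pd.Index:
        return self.intensities.columns

    def group_mask(self) -> np.ndarray:
        """Boolean mask of case-group samples (first label of group_order)."""
        return (self.groups == self.group_order[0]).to_numpy()


def preprocess_intensities(
    table: MetaboliteTable,
    *,
    log_transform: bool = True,
    scale: str = "unit-variance",
) -> pd.DataFrame:
    """Log-transform (base 10), centre, and scale intensities.

    Returns the processed samples x features matrix (no longer positive, so a
    plain DataFrame rather than a MetaboliteTable).  Constant features scale
    to zero and are flagged with a warning attribute ``attrs['constant']``.
    """
    if scale not in ("unit-variance", "pareto", "none"):
        raise ValueError("scale must be 'unit-variance', 'pareto' or 'none'")
    x = table.intensities.to_numpy(copy=True)
    if log_transform:
        x = np.log10(x)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    constant = sd == 0.0
    if scale != "none":
        denom = np.where(constant, 1.0, sd if scale == "unit-variance" else np.sqrt(sd))
        x = x / denom
    out = pd.DataFrame(x, index=table.sample_ids, columns=table.feature_names)
    out.attrs["constant"] = list(table.feature_names[constant])
    return out


@dataclass(frozen=True)
class PLSDAModel:
    """Fitted PLS-DA latent-variable model (NIPALS, X-deflation).

    ``weights``/``loadings`` are (features x components); ``scores`` is
    (samples x components); ``y_loadings`` the per-component class loadings;
    ``ssy`` the class-variance explained per component.
    """

    weights: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    y_loadings: np.ndarray
    ssy: np.ndarray
    explained_y_variance: float
    feature_names: tuple[str, ...]


def _osc_filter(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Remove the dominant class-orthogonal component from X."""
    w = x.T @ y
    nw = np.linalg.norm(w)
    if nw == 0:
        return x
    w /= nw
    # principal component of X after projecting out the predictive direction
    xo = x - np.outer(x @ w, w)
    u, s, vt = np.linalg.svd(xo, full_matrices=False)
    if s[0] == 0:
        return x
    w_o = vt[0]
    t_o = x @ w_o
    p_o = x.T @ t_o / (t_o @ t_o)
    return x - np.outer(t_o, p_o)


def pls_da(
    data: MetaboliteTable | pd.DataFrame,
    n_components: int = 2,
    *,
    y: Sequence[float] | None = None,
    orthogonal_correction: bool = False,
    log_transform: bool = True,
    scale: str = "unit-variance",
) -> PLSDAModel:
    """Fit a PLS-DA model of the (centred) class dummy on the feature matrix.

    With a single response the NIPALS weight direction is closed-form
    (``w_a = X'y / ||X'y||``), so the fit is deterministic.  Raises when no
    covariance with the class remains (degenerate component).
    """
    if isinstance(data, MetaboliteTable):
        x_df = preprocess_intensities(data, log_transform=log_transform, scale=scale)
        if y is None:
            y = np.where(data.group_mask(), 1.0, -1.0)
    else:
        x_df = data
        if y is None:
            raise ValueError("y labels required when passing a plain matrix")
    x = x_df.to_numpy(copy=True)
    yv = np.asarray(y, dtype=np.float64)
    if yv.ndim != 1 or yv.size != x.shape[0]:
        raise ValueError("y must be one value per sample")
    classes = np.unique(yv)
    if classes.size == 2:
        if min((yv == c).sum() for c in classes) < 3:
            raise ValueError("need at least 3 samples per group")
    yv = yv - yv.mean()
    if n_components >= min(x.shape):
        raise ValueError("n_components must be < min(n_samples, n_features)")
    if orthogonal_correction:
        x = _osc_filter(x, yv)

    n, p = x.shape
    ssy_total = float(yv @ yv)
    weights = np.zeros((p, n_components))
    loadings = np.zeros((p, n_components))
    scores = np.zeros((n, n_components))
    y_load = np.zeros(n_components)
    ssy = np.zeros(n_components)
    y_res = yv.copy()
    for a in range(n_components):
        w = x.T @ y_res
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * max(1.0, np.linalg.norm(x)):
            # no covariance with the class left: stop early, remaining
            # components stay zero and explain no class variance
            break
        w /= nw
        t = x @ w
        tt = float(t @ t)
        if tt == 0:
            break
        pl = x.T @ t / tt
        q = float(y_res @ t) / tt
        x = x - np.outer(t, pl)
        y_res = y_res - q * t
        weights[:, a] = w
        loadings[:, a] = pl
        scores[:, a] = t
        y_load[a] = q
        ssy[a] = q * q * tt
    explained = float(ssy.sum() / ssy_total) if ssy_total > 0 else 0.0
    return PLSDAModel(weights, loadings, scores, y_load, ssy,
                      explained, tuple(map(str, x_df.columns)))


def vip(model: PLSDAModel) -> pd.Series:
    """Variable importance in projection; ``mean(VIP^2) = 1`` by construction."""
    total = model.ssy.sum()
    if total <= 0:
        raise ValueError("model explains no class variance; VIP undefined")
    p = model.weights.shape[0]
    wnorm2 = (model.weights ** 2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    contrib = (model.weights ** 2) / wnorm2
    v = np.sqrt(p * (contrib @ model.ssy) / total)
    return pd.Series(v, index=list(model.feature_names), name="vip")


@dataclass(frozen=True)
class ScreenResult:
    """Per-feature screening table plus the underlying PLS-DA model.

    ``frame`` columns: vip, t, p, p_fdr, fold_change (case mean / control mean
    on raw intensities), selected (VIP > 1 and raw p < 0.05).
    """

    frame: pd.DataFrame
    model: PLSDAModel
    table: MetaboliteTable = field(repr=False, default=None)

    @property
    def selected(self) -> pd.Index:
        return self.frame.index[self.frame["selected"]]


def univariate_screen(
    table: MetaboliteTable,
    *,
    n_components: int = 2,
    log_transform: bool = True,
    scale: str = "unit-variance",
    vip_threshold: float = 1.0,
    p_threshold: float = 0.05,
    orthogonal_correction: bool = False,
) -> ScreenResult:
    """VIP > 1 & p < 0.05 differential-metabolite screen.

    t tests run on (log) intensities; fold changes on raw group means with the
    case group (first of ``table.group_order``) in the numerator; BH-adjusted
    p-values are reported alongside the raw-p selection rule.
    """
    model = pls_da(table, n_components, log_transform=log_transform, scale=scale,
                   orthogonal_correction=orthogonal_correction)
    vips = vip(model)
    mask = table.group_mask()
    raw = table.intensities.to_numpy()
    xs = np.log10(raw) if log_transform else raw
    tvals = np.empty(raw.shape[1])
    pvals = np.empty(raw.shape[1])
    for j in range(raw.shape[1]):
        col = xs[:, j]
        if col[mask].var(ddof=1) == 0.0 and col[~mask].var(ddof=1) == 0.0 and \
                col[mask].mean() != col[~mask].mean():
            raise ValueError(f"degenerate zero-variance feature: {table.feature_names[j]!r}")
        tvals[j], _, pvals[j] = ttest_ind(col[mask], col[~mask])
    fc = raw[mask].mean(axis=0) / raw[~mask].mean(axis=0)
    frame = pd.DataFrame(
        {
            "vip": vips.to_numpy(),
            "t": tvals,
            "p": pvals,
            "p_fdr": fdr_bh(pvals),
            "fold_change": fc,
            "selected": (vips.to_numpy() > vip_threshold) & (pvals < p_threshold),
        },
        index=table.feature_names,
    )
    return ScreenResult(frame, model, table)
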
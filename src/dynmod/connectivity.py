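"""Weighted functional connectivity from annotated ROI time series.

Block-design task data mix conditions every ~30 s, and the hemodynamic
response delays and smears the neural signal relative to the block
boundaries. Connectivity is therefore estimated with a *weighted* Pearson
correlation: the task boxcar is convolved with a canonical HRF, negative
lobes are clipped, and the resulting nonnegative time course weights each
retained volume's contribution to the correlation. Correlations are
Fisher-z transformed (arctanh) and negative edges are set to zero, giving
symmetric nonnegative matrices with zero diagonal — the graphs on which
modularity is optimized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TimeSeriesPanel",
    "HRFKernel",
    "BlockStack",
    "canonical_hrf",
    "hrf_weights",
    "weighted_pearson",
    "condition_connectivity",
    "block_connectivity",
]

# correlations are clipped just inside (-1, 1) before arctanh so perfectly
# collinear ROIs yield a large finite z rather than inf
_R_CLIP = 1.0 - 1e-15


@dataclass
class TimeSeriesPanel:
    """ROI x volume signal matrix with per-volume block/condition labels."""

    signal: np.ndarray
    tr_seconds: float
    annotations: pd.DataFrame  # columns: volume, block, condition
    roi_ids: list

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be ROI x volume")
        if self.tr_seconds <= 0:
            raise ValueError("TR must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if len(self.annotations) != self.n_volumes:
            raise ValueError("annotation length must equal number of volumes")
        if len(self.roi_ids) != self.n_rois:
            raise ValueError("roi_ids must align with signal rows")

    @property
    def n_rois(self) -> int:
        return self.signal.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[1]

    @property
    def blocks(self) -> np.ndarray:
        return np.unique(self.annotations["block"])

    @property
    def conditions(self) -> list:
        seen = []
        for c in self.annotations["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def block_condition(self, block) -> str:
        conds = self.annotations.loc[self.annotations["block"] == block,
                                     "condition"].unique()
        if len(conds) != 1:
            raise ValueError(f"block {block} has mixed condition labels")
        return conds[0]

    @classmethod
    def from_files(cls, signal_path, annotations_path,
                   tr_seconds: float) -> "TimeSeriesPanel":
        sig = pd.read_csv(signal_path, sep="\t", header=None, index_col=0)
        ann = pd.read_csv(annotations_path, sep="\t")
        return cls(signal=sig.to_numpy(float), tr_seconds=tr_seconds,
                   annotations=ann, roi_ids=list(sig.index))


@dataclass(frozen=True)
class HRFKernel:
    """Canonical HRF sampled at the panel's TR."""

    values: np.ndarray
    tr_seconds: float
    peak_s: float
    undershoot_s: float
    ratio: float
    length_s: float

    def __post_init__(self):
        if float(np.sum(self.values)) <= 0:
            raise ValueError("HRF kernel must integrate to a positive value")


def canonical_hrf(tr_seconds: float, peak_s: float = 6.0,
                  undershoot_s: float = 16.0, ratio: float = 6.0,
                  length_s: float = 32.0) -> HRFKernel:
    """Double-gamma HRF: a peak gamma minus a scaled undershoot gamma.

    Shape parameters ``peak_s``/``undershoot_s`` (unit scale) place the
    response and undershoot; ``ratio`` is the peak-to-undershoot amplitude
    ratio; support is truncated at ``length_s``. Values are normalized to a
    unit-maximum kernel.
    """
    if tr_seconds <= 0:
        raise ValueError("TR must be positive")
    t = np.arange(0, length_s + tr_seconds / 2, tr_seconds)
    h = (stats.gamma.pdf(t, a=peak_s, scale=1.0)
         - stats.gamma.pdf(t, a=undershoot_s, scale=1.0) / ratio)
    h = h / np.max(h)
    return HRFKernel(values=h, tr_seconds=tr_seconds, peak_s=peak_s,
                     undershoot_s=undershoot_s, ratio=ratio,
                     length_s=length_s)


def hrf_weights(block_regressor: np.ndarray, hrf: HRFKernel) -> np.ndarray:
    """Convolve a 0/1 block regressor with the HRF and clip negatives.

    The result, truncated to the regressor's length, is the nonnegative
    per-volume weight vector used by the weighted correlation.
    """
    reg = np.asarray(block_regressor, dtype=float)
    if reg.ndim != 1:
        raise ValueError("regressor must be a vector")
    w = np.convolve(reg, hrf.values)[: reg.size]
    return np.clip(w, 0.0, None)


def _weighted_moments(X: np.ndarray, w: np.ndarray):
    wn = w / w.sum()
    mean = X @ wn
    Xc = X - mean[:, None]
    cov = (Xc * wn) @ Xc.T
    return cov


def weighted_pearson(x, y, w) -> float:
    """Weighted Pearson correlation with weighted means and moments.

    Invariant to positive rescaling of ``w``; reduces to the ordinary
    Pearson correlation under uniform weights.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if not (x.shape == y.shape == w.shape) or x.ndim != 1:
        raise ValueError("x, y, w must be equal-length vectors")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if w.sum() <= 0:
        raise ValueError("zero total weight")
    cov = _weighted_moments(np.vstack([x, y]), w)
    vx, vy = cov[0, 0], cov[1, 1]
    if vx <= 0 or vy <= 0:
        raise ValueError("zero weighted variance")
    return float(np.clip(cov[0, 1] / np.sqrt(vx * vy), -1.0, 1.0))


def _weighted_corr_matrix(X: np.ndarray, w: np.ndarray,
                          roi_ids=None) -> np.ndarray:
    cov = _weighted_moments(X, w)
    var = np.diag(cov).copy()
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        names = [roi_ids[i] for i in bad] if roi_ids is not None else list(bad)
        raise ValueError(f"zero weighted variance for ROIs: {names}")
    d = np.sqrt(var)
    R = cov / np.outer(d, d)
    return np.clip(R, -1.0, 1.0)


def _finalize(R: np.ndarray, rectify: bool) -> np.ndarray:
    Z = np.arctanh(np.clip(R, -_R_CLIP, _R_CLIP))
    if rectify:
        Z = np.clip(Z, 0.0, None)
    np.fill_diagonal(Z, 0.0)
    return (Z + Z.T) / 2.0


def _condition_regressor(panel: TimeSeriesPanel, condition) -> np.ndarray:
    if condition is None:
        # any labelled task volume; instruction/rest volumes carry no label
        mask = panel.annotations["condition"].notna().to_numpy()
    else:
        mask = (panel.annotations["condition"] == condition).to_numpy()
    return mask.astype(float)


def condition_connectivity(panel: TimeSeriesPanel, condition=None,
                           hrf: HRFKernel | None = None,
                           rectify: bool = True) -> np.ndarray:
    """Connectivity matrix for one task condition (or all task volumes).

    The condition's boxcar is HRF-convolved and rectified; volumes of the
    condition with positive weight are retained, and every ROI pair is
    correlated with those weights, Fisher-transformed, and (by default)
    rectified to nonnegative edges. Returns an N x N symmetric matrix with
    zero diagonal.
    """
    if condition is not None and condition not in panel.conditions:
        raise ValueError(f"condition {condition!r} absent from panel")
    if hrf is None:
        hrf = canonical_hrf(panel.tr_seconds)
    reg = _condition_regressor(panel, condition)
    w = hrf_weights(reg, hrf)
    mask = (reg > 0) & (w > 0)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 usable volumes for the condition")
    R = _weighted_corr_matrix(panel.signal[:, mask], w[mask], panel.roi_ids)
    return _finalize(R, rectify)


@dataclass
class BlockStack:
    """Ordered per-block connectivity matrices (layers of the multilayer
    network) with each layer's condition label."""

    weights: np.ndarray  # T x N x N
    conditions: list
    blocks: list

    @property
    def n_layers(self) -> int:
        return self.weights.shape[0]


def block_connectivity(panel: TimeSeriesPanel,
                       hrf: HRFKernel | None = None,
                       rectify: bool = True) -> BlockStack:
    """One weighted connectivity matrix per task block.

    HRF weights are recomputed from each block's own boxcar, so every
    layer's weighting reflects the response to that block alone.
    """
    if hrf is None:
        hrf = canonical_hrf(panel.tr_seconds)
    mats, conds, blocks = [], [], []
    for b in panel.blocks:
        in_block = (panel.annotations["block"] == b).to_numpy()
        w = hrf_weights(in_block.astype(float), hrf)
        mask = in_block & (w > 0)
        if mask.sum() < 3:
            raise ValueError(f"block {b}: fewer than 3 usable volumes")
        R = _weighted_corr_matrix(panel.signal[:, mask], w[mask],
                                  panel.roi_ids)
        mats.append(_finalize(R, rectify))
        conds.append(panel.block_condition(b))
        blocks.append(b)
    return BlockStack(weights=np.stack(mats), conditions=conds, blocks=blocks)


def write_matrix(A: np.ndarray, path) -> None:
    np.savetxt(path, A, delimiter="\t")


def read_matrix(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")
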
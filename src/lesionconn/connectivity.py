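"""Fisher-z functional connectivity matrices and scalar FC summaries.

Three scalars summarise a subject's matrix:

* ``tu_el`` — mean Fisher-z correlation between the tumor node and every
  retained extralesional atlas ROI (patients, preoperative only);
* ``el``    — mean z over all unordered pairs of retained atlas ROIs;
* ``con_el`` — ``el`` restricted to pairs within the hemisphere contralateral
  to the lesion.  For controls the analogue is the mean of the within-left
  and within-right values (:func:`control_hemispheric_baseline`).

Negative correlations enter all means as-is: the statistics are signed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.signal

from .parcellation import TUMOR_NODE, RoiTimeseriesSet, ZERO_VARIANCE_TOL

#: default clip applied to r before atanh, keeping z finite
DEFAULT_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N Fisher-z matrix; the diagonal is NaN (self-pairs excluded)."""

    z: np.ndarray
    node_ids: list

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.ndim != 2 or self.z.shape != (n, n) or n < 2:
            raise ValueError("z must be square with N >= 2")
        if len(self.node_ids) != n:
            raise ValueError("node_ids length must match matrix size")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(self.z, self.z.T, equal_nan=True):
            raise ValueError("z must be symmetric")
        if not np.isfinite(self.z[off]).all():
            raise ValueError("off-diagonal entries must be finite")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]

    @property
    def has_tumor_node(self) -> bool:
        return TUMOR_NODE in self.node_ids

    @property
    def atlas_index(self) -> np.ndarray:
        """Positions of non-tumor nodes."""
        return np.array([i for i, n in enumerate(self.node_ids) if n != TUMOR_NODE])


def fc_matrix(ts: RoiTimeseriesSet, clip: float = DEFAULT_CLIP) -> ConnectivityMatrix:
    """Pairwise Pearson correlation over frames, Fisher z-transformed.

    r is clipped to [-clip, +clip] before atanh so degenerate (perfectly
    correlated) pairs stay finite.  Columns must have positive variance;
    flat columns should have been dropped at extraction.
    """
    x = ts.series
    if x.shape[0] < 3:
        raise ValueError("need at least 3 frames for a correlation matrix")
    if x.shape[1] < 2:
        raise ValueError("need at least 2 nodes")
    variances = x.var(axis=0)
    flat = np.nonzero(variances < ZERO_VARIANCE_TOL)[0]
    if flat.size:
        names = [ts.node_ids[i] for i in flat]
        raise ValueError(f"zero-variance series for node(s) {names}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -clip, clip)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(z=z, node_ids=list(ts.node_ids))


def _pair_mean(z: np.ndarray, idx: np.ndarray) -> float:
    """Mean z over unordered pairs within the index set (upper triangle)."""
    if idx.size < 2:
        raise ValueError("need at least 2 nodes for a pair mean")
    sub = z[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].mean())


def summary_tu_el(m: ConnectivityMatrix) -> float:
    """Tumor-to-extralesional coupling: mean z of the tumor row."""
    if not m.has_tumor_node:
        raise ValueError("matrix has no tumor node")
    t = m.node_ids.index(TUMOR_NODE)
    others = m.atlas_index
    return float(m.z[t, others].mean())


def summary_el(m: ConnectivityMatrix) -> float:
    """Extralesional FC: mean z over all unordered atlas-ROI pairs.

    The tumor row/column, when present, is excluded; the result for a
    patient matrix therefore equals that of the same matrix with the tumor
    node deleted.
    """
    idx = m.atlas_index
    if idx.size < 3:
        raise ValueError("need at least 3 atlas nodes")
    return _pair_mean(m.z, idx)


def _hemi_index(
    m: ConnectivityMatrix, hemispheres: Mapping[int, str], hemisphere: str
) -> np.ndarray:
    return np.array(
        [
            i
            for i, n in enumerate(m.node_ids)
            if n != TUMOR_NODE and hemispheres.get(int(n)) == hemisphere
        ],
        dtype=int,
    )


def summary_conel(
    m: ConnectivityMatrix, hemispheres: Mapping[int, str], lesion_side: str
) -> float:
    """Contralesional FC: mean z over pairs with both nodes opposite the lesion."""
    if lesion_side not in ("left", "right"):
        raise ValueError(f"lesion_side must be left/right, got {lesion_side!r}")
    contra = "right" if lesion_side == "left" else "left"
    idx = _hemi_index(m, hemispheres, contra)
    if idx.size < 2:
        raise ValueError(f"fewer than 2 retained nodes in {contra} hemisphere")
    return _pair_mean(m.z, idx)


def control_hemispheric_baseline(
    m: ConnectivityMatrix, hemispheres: Mapping[int, str]
) -> float:
    """Controls' conEL analogue: mean of within-left and within-right pair means."""
    if m.has_tumor_node:
        raise ValueError("baseline is defined for control matrices only")
    means = []
    for hemi in ("left", "right"):
        idx = _hemi_index(m, hemispheres, hemi)
        if idx.size < 2:
            raise ValueError(f"fewer than 2 nodes in {hemi} hemisphere")
        means.append(_pair_mean(m.z, idx))
    return float(np.mean(means))


def highpass_filter(
    ts: RoiTimeseriesSet, tr_s: float, cutoff_hz: float = 0.01, order: int = 4
) -> RoiTimeseriesSet:
    """Optional zero-phase Butterworth high-pass (> cutoff_hz) plus demeaning.

    Attenuates slow drifts below the cutoff; passband amplitudes are
    preserved (the filter is applied forward and backward).  Frame count is
    unchanged.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    nyquist = 0.5 / tr_s
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist:.4f} Hz")
    x = ts.series - ts.series.mean(axis=0, keepdims=True)
    sos = scipy.signal.butter(order, cutoff_hz / nyquist, btype="highpass", output="sos")
    y = scipy.signal.sosfiltfilt(sos, x, axis=0)
    y = y - y.mean(axis=0, keepdims=True)
    return RoiTimeseriesSet(
        series=y, node_ids=list(ts.node_ids), excluded_ids=set(ts.excluded_ids),
        tr_s=tr_s,
    )
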
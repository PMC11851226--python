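"""Lesion masks, ROI exclusion and mean time-series extraction.

The combined (tumor ∪ resection) mask drives both voxel masking and ROI
exclusion at both timepoints, so that pre- and postoperative connectivity are
computed over an identical extralesional node set.  The tumor node's signal is
taken from the *unmasked* preoperative BOLD — masking first would delete the
very signal the tumor-coupling statistic is about.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .imaging_io import AtlasParcellation, Volume, check_grid_compatibility

logger = logging.getLogger(__name__)

#: sentinel node id for the tumor column in time-series and FC matrices
TUMOR_NODE = "tumor"

#: series with variance below this are treated as flat and dropped
ZERO_VARIANCE_TOL = 1e-12


@dataclass
class LesionMask:
    """Binary lesion volume: tumor, resection cavity, or their union."""

    mask: Volume
    kind: str  # 'tumor' | 'resection' | 'combined'
    side: str  # 'left' | 'right'

    def __post_init__(self) -> None:
        if self.kind not in ("tumor", "resection", "combined"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown lesion side {self.side!r}")
        if not self.mask.is_binary():
            raise ValueError("lesion mask must be binary {0,1}")
        if self.kind == "tumor" and self.n_voxels == 0:
            raise ValueError("tumor mask has no voxels")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask.data))

    @property
    def indicator(self) -> np.ndarray:
        return self.mask.data.astype(bool)


@dataclass
class RoiTimeseriesSet:
    """T x N matrix of mean BOLD per retained node.

    ``node_ids`` is the ordered list of retained roi_ids (ascending), with the
    sentinel :data:`TUMOR_NODE` appended last when a tumor node is present.
    ``excluded_ids`` are the atlas ROIs removed by lesion overlap or because
    they had no usable signal.
    """

    series: np.ndarray
    node_ids: list
    excluded_ids: set = field(default_factory=set)
    tr_s: float | None = None

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValueError("series must be a T x N matrix")
        if self.series.shape[1] != len(self.node_ids):
            raise ValueError("node_ids length must match number of columns")
        if len(set(map(str, self.node_ids))) != len(self.node_ids):
            raise ValueError("duplicate node ids")
        overlap = set(self.excluded_ids) & set(
            i for i in self.node_ids if i != TUMOR_NODE
        )
        if overlap:
            raise ValueError(f"excluded ids present in node_ids: {overlap}")

    @property
    def n_frames(self) -> int:
        return self.series.shape[0]

    @property
    def has_tumor_node(self) -> bool:
        return bool(self.node_ids) and self.node_ids[-1] == TUMOR_NODE

    @property
    def atlas_node_ids(self) -> list[int]:
        return [i for i in self.node_ids if i != TUMOR_NODE]


def combine_lesion_masks(tumor: LesionMask, resection: LesionMask) -> LesionMask:
    """Voxelwise union of the pre- and postoperative lesions.

    Both masks must live on one grid and one side; the result has
    ``kind='combined'``.
    """
    if tumor.side != resection.side:
        raise ValueError(
            f"lesion sides differ: {tumor.side} vs {resection.side}"
        )
    check_grid_compatibility([tumor.mask, resection.mask])
    union = (tumor.indicator | resection.indicator).astype(np.int16)
    return LesionMask(
        mask=Volume(union, tumor.mask.affine), kind="combined", side=tumor.side
    )


def lesioned_roi_ids(
    atlas: AtlasParcellation,
    lesion: LesionMask,
    min_overlap_voxels: int = 1,
) -> set[int]:
    """Atlas ROIs whose overlap with the lesion reaches the voxel threshold.

    The default threshold of 1 voxel is the strictest reading of "covers
    lesion tissue"; raise it to tolerate marginal touches.
    """
    check_grid_compatibility([atlas.labels, lesion.mask])
    if min_overlap_voxels < 1:
        raise ValueError("min_overlap_voxels must be >= 1")
    labels = atlas.labels.data.astype(int)
    under = labels[lesion.indicator]
    counts = np.bincount(under[under > 0], minlength=1)
    return {
        int(i) for i in np.nonzero(counts >= min_overlap_voxels)[0] if i > 0
    }


def apply_lesion_mask(bold: Volume, lesion: LesionMask) -> Volume:
    """Blank all lesion voxels at every frame (NaN sentinel); others untouched."""
    if bold.data.ndim != 4:
        raise ValueError("expected a 4D BOLD volume")
    check_grid_compatibility([bold, lesion.mask])
    out = bold.data.astype(float, copy=True)
    out[lesion.indicator, :] = np.nan
    return Volume(out, bold.affine)


def extract_roi_timeseries(
    bold: Volume,
    atlas: AtlasParcellation,
    excluded: set[int] = frozenset(),
    tumor: LesionMask | None = None,
    tumor_bold: Volume | None = None,
    tr_s: float | None = None,
) -> RoiTimeseriesSet:
    """Mean BOLD time series per retained atlas ROI, plus an optional tumor node.

    Parameters
    ----------
    bold
        4D series, typically already lesion-masked (NaN sentinel inside the
        combined lesion).
    excluded
        ROI ids removed by lesion overlap; must be a subset of the atlas ids.
    tumor
        When given, one extra column is appended: the mean over the tumor
        voxels of ``tumor_bold`` (defaults to ``bold``) — pass the unmasked
        preoperative series here.

    ROIs left with zero usable voxels, or with flat (variance below
    ``ZERO_VARIANCE_TOL``) mean series, are dropped with a warning and added
    to ``excluded_ids``.
    """
    if bold.data.ndim != 4:
        raise ValueError("expected a 4D BOLD volume")
    check_grid_compatibility([bold, atlas.labels])
    excluded = set(excluded)
    if not excluded <= set(atlas.roi_ids):
        raise ValueError("excluded ids not in atlas")

    data = bold.data.reshape(-1, bold.data.shape[3]).astype(float)
    labels = atlas.labels.data.reshape(-1).astype(int)
    usable_voxel = ~np.isnan(data).any(axis=1)

    columns: list[np.ndarray] = []
    node_ids: list = []
    excluded_out = set(excluded)
    for roi in atlas.roi_ids:
        if roi in excluded:
            continue
        sel = (labels == roi) & usable_voxel
        if not sel.any():
            logger.warning("ROI %d has no usable voxels; excluded", roi)
            excluded_out.add(roi)
            continue
        col = data[sel].mean(axis=0)
        if np.var(col) < ZERO_VARIANCE_TOL:
            logger.warning("ROI %d has a flat mean series; excluded", roi)
            excluded_out.add(roi)
            continue
        columns.append(col)
        node_ids.append(int(roi))

    if tumor is not None:
        if tumor.n_voxels == 0:
            raise ValueError("tumor mask has zero voxels")
        src = tumor_bold if tumor_bold is not None else bold
        check_grid_compatibility([src, tumor.mask])
        tdata = src.data.reshape(-1, src.data.shape[3]).astype(float)
        tcol = tdata[tumor.indicator.reshape(-1)].mean(axis=0)
        if np.isnan(tcol).any():
            raise ValueError(
                "tumor time series contains masked voxels; pass the unmasked "
                "BOLD as tumor_bold"
            )
        columns.append(tcol)
        node_ids.append(TUMOR_NODE)

    series = np.column_stack(columns) if columns else np.empty((bold.data.shape[3], 0))
    return RoiTimeseriesSet(
        series=series, node_ids=node_ids, excluded_ids=excluded_out, tr_s=tr_s
    )


def tumor_volume_cm3(tumor: LesionMask) -> float:
    """Lesion volume: voxel count x voxel volume, mm^3 converted to cm^3."""
    return tumor.n_voxels * tumor.mask.voxel_volume_mm3 / 1000.0
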
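"""Volumetric image and cohort-table I/O.

All images of one subject (BOLD, atlas, lesion masks) must live on a single
voxel grid; no resampling is performed here — spatially normalised inputs are
assumed.  Volumes are NIfTI-1/NIfTI-2, tables are UTF-8 CSV with a header row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the five cognitive measures carried per timepoint
MEASURES = ("learning", "consolidation", "recognition", "alertness", "flexibility")

#: polarity flag: True means a higher score indicates *worse* performance
#: (forgotten words, attention quotient, reaction-time difference)
HIGHER_IS_WORSE = {
    "learning": False,
    "consolidation": True,
    "recognition": False,
    "alertness": True,
    "flexibility": True,
}

TIMEPOINTS = ("initial", "followup")


class GridError(ValueError):
    """Raised when volumes of one subject do not share a voxel grid."""


class FormatError(ValueError):
    """Raised for images that are not 3D or 4D."""


class CohortValidationError(ValueError):
    """Raised for cohort-table rows that violate the record invariants."""


@dataclass
class Volume:
    """A 3D volume or 4D time series on a voxel grid.

    Parameters
    ----------
    data
        Array of shape (X, Y, Z) or (X, Y, Z, T).
    affine
        4x4 voxel-to-world map (mm).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim not in (3, 4):
            raise FormatError(
                f"expected a 3D or 4D image, got {self.data.ndim} dimensions"
            )
        if any(s < 1 for s in self.data.shape[:3]):
            raise FormatError(f"degenerate spatial shape {self.data.shape[:3]}")
        if self.data.ndim == 4 and self.data.shape[3] < 2:
            raise FormatError("4D image must have at least 2 frames")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def n_frames(self) -> int | None:
        """Number of time frames, or None for a 3D volume."""
        return self.data.shape[3] if self.data.ndim == 4 else None

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm per spatial axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def is_binary(self) -> bool:
        return bool(np.isin(np.unique(self.data), (0, 1)).all())

    def is_label(self) -> bool:
        vals = np.unique(self.data)
        return bool(np.all(vals == np.round(vals)) and vals.min() >= 0)


def load_volume(path: str | Path) -> Volume:
    """Read a NIfTI file into a :class:`Volume`, values untouched."""
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several error types
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise FormatError(f"{path}: expected 3D/4D image, got {data.ndim}D")
    return Volume(data=data, affine=img.affine)


def save_volume(vol: Volume, path: str | Path) -> Path:
    """Write a :class:`Volume` as NIfTI-1; returns the path written."""
    path = Path(path)
    data = vol.data
    # keep integer/binary data bit-exact on round trip
    if data.dtype.kind in "ui" or (data.dtype.kind == "b"):
        data = data.astype(np.int32)
    img = nib.Nifti1Image(data, vol.affine)
    nib.save(img, path)
    return path


def check_grid_compatibility(
    volumes: Sequence[Volume], tol_mm: float = 1e-3
) -> None:
    """Verify that all volumes share spatial shape and voxel size.

    Raises :class:`GridError` naming the offending pair; returns silently on
    success.  Voxel sizes are compared within ``tol_mm`` millimetres.
    """
    if not volumes:
        raise ValueError("empty volume list")
    ref = volumes[0]
    for other in volumes[1:]:
        if other.spatial_shape != ref.spatial_shape:
            raise GridError(
                f"spatial shape mismatch: {ref.spatial_shape} vs {other.spatial_shape}"
            )
        if not np.allclose(other.voxel_size, ref.voxel_size, atol=tol_mm):
            raise GridError(
                f"voxel size mismatch: {ref.voxel_size} vs {other.voxel_size} mm"
            )


@dataclass
class AtlasParcellation:
    """Integer label volume plus the ROI lookup table.

    ``roi_table`` columns: roi_id (positive int), name, hemisphere
    ({'left', 'right'}).  Background label is 0.  The canonical atlas has 246
    regions, but any parcellation with >= 2 regions is accepted.
    """

    labels: Volume
    roi_table: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.labels.is_label():
            raise FormatError("atlas volume must contain non-negative integers")
        tab = self.roi_table
        required = {"roi_id", "name", "hemisphere"}
        if not required.issubset(tab.columns):
            raise CohortValidationError(
                f"ROI table must have columns {sorted(required)}"
            )
        if tab["roi_id"].duplicated().any():
            raise CohortValidationError("duplicate roi_id in ROI table")
        if (tab["roi_id"] <= 0).any():
            raise CohortValidationError("roi_id must be positive")
        bad_hemi = set(tab["hemisphere"]) - {"left", "right"}
        if bad_hemi:
            raise CohortValidationError(f"unknown hemisphere labels {bad_hemi}")
        present = set(np.unique(self.labels.data)) - {0}
        known = set(tab["roi_id"].astype(int))
        if not present <= known:
            raise CohortValidationError(
                f"labels {sorted(present - known)[:5]}... missing from ROI table"
            )
        if len(tab) < 2:
            raise CohortValidationError("parcellation needs at least 2 regions")

    @property
    def roi_ids(self) -> list[int]:
        return sorted(int(i) for i in self.roi_table["roi_id"])

    @property
    def hemispheres(self) -> dict[int, str]:
        """Mapping roi_id -> 'left' | 'right'."""
        return dict(
            zip(self.roi_table["roi_id"].astype(int), self.roi_table["hemisphere"])
        )


def load_roi_table(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path)
    tab["roi_id"] = tab["roi_id"].astype(int)
    return tab


def load_atlas(labels_path: str | Path, table_path: str | Path) -> AtlasParcellation:
    return AtlasParcellation(load_volume(labels_path), load_roi_table(table_path))


@dataclass
class CohortRecord:
    """One subject: metadata, covariates and ten score cells.

    ``scores`` maps (measure, timepoint) to a float or None for an explicitly
    missing cell.  Controls carry ``lesion_side='none'`` and no tumor volume.
    """

    subject_id: str
    group: str  # 'patient' | 'control'
    age: float
    lesion_side: str = "none"  # 'left' | 'right' | 'none'
    tumor_volume_cm3: float | None = None
    scores: dict[tuple[str, str], float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise CohortValidationError(
                f"{self.subject_id}: unknown group {self.group!r}"
            )
        if self.lesion_side not in ("left", "right", "none"):
            raise CohortValidationError(
                f"{self.subject_id}: unknown lesion_side {self.lesion_side!r}"
            )
        if self.group == "control":
            if self.lesion_side != "none":
                raise CohortValidationError(
                    f"{self.subject_id}: control with lesion_side={self.lesion_side}"
                )
            if self.tumor_volume_cm3 is not None:
                raise CohortValidationError(
                    f"{self.subject_id}: control with a tumor_volume"
                )
        for key, val in self.scores.items():
            if val is not None and not np.isfinite(val):
                raise CohortValidationError(
                    f"{self.subject_id}: non-finite score for {key}"
                )

    def score(self, measure: str, timepoint: str) -> float | None:
        return self.scores.get((measure, timepoint))


def _score_columns() -> list[str]:
    return [f"{m}_{t}" for m in MEASURES for t in TIMEPOINTS]


def load_cohort_table(path: str | Path) -> list[CohortRecord]:
    """Read the cohort CSV into typed records.

    Missing score cells become explicit ``None`` values (logged), never 0.
    Rows violating the record invariants raise
    :class:`CohortValidationError`.
    """
    df = pd.read_csv(path)
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise CohortValidationError(f"duplicate subject_id: {dups}")
    records = []
    for _, row in df.iterrows():
        scores: dict[tuple[str, str], float | None] = {}
        for m in MEASURES:
            for t in TIMEPOINTS:
                col = f"{m}_{t}"
                if col not in df.columns or pd.isna(row[col]):
                    scores[(m, t)] = None
                    logger.info("subject %s: missing %s", row["subject_id"], col)
                else:
                    scores[(m, t)] = float(row[col])
        tv = row.get("tumor_volume_cm3")
        records.append(
            CohortRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                lesion_side=str(row.get("lesion_side", "none")),
                tumor_volume_cm3=None if pd.isna(tv) else float(tv),
                scores=scores,
            )
        )
    return records


def cohort_to_frame(records: Iterable[CohortRecord]) -> pd.DataFrame:
    """Tidy one-row-per-subject DataFrame (inverse of :func:`load_cohort_table`)."""
    rows = []
    for rec in records:
        row = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "age": rec.age,
            "lesion_side": rec.lesion_side,
            "tumor_volume_cm3": rec.tumor_volume_cm3,
        }
        for m in MEASURES:
            for t in TIMEPOINTS:
                row[f"{m}_{t}"] = rec.score(m, t)
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "group", "age", "lesion_side",
                                       "tumor_volume_cm3"] + _score_columns())
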
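"""Synthetic cohorts with known ground truth.

The generator emulates the measured structure of a resting-state glioma
cohort, not the physics of BOLD: extralesional parcels share one common
latent signal (equicorrelation at ``base_within_corr``), the tumor signal
mixes a fraction ``rho`` of that latent with independent noise, and an
attention-like score depends linearly on the subject's true tumor coupling
(higher = worse).  Everything is driven by one integer seed; the same config
and seed reproduce every array bit-for-bit.

Per-parcel signals can optionally be given AR(1) temporal autocorrelation;
the default is white noise, under which Pearson-r standard errors follow the
textbook 1/sqrt(T-3) law used by the recovery tolerances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage
import yaml

from .imaging_io import (
    MEASURES,
    AtlasParcellation,
    Volume,
    cohort_to_frame,
    CohortRecord,
    save_volume,
)
from .parcellation import LesionMask, RoiTimeseriesSet, TUMOR_NODE, tumor_volume_cm3


@dataclass
class SyntheticConfig:
    """Conditions for one simulated cohort.

    Defaults mirror the acquisition being emulated: 300 frames at TR 2.2 s
    over a 246-region parcellation, 18 patients and 18 controls, and a
    left-sided contiguous lesion overlapping 12 regions.
    """

    seed: int  # mandatory: no implicit randomness
    n_rois: int = 246
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 3.1
    T: int = 300
    tr_s: float = 2.2
    base_within_corr: float = 0.3
    rho_range: tuple[float, float] = (0.2, 0.8)  # per-patient tumor coupling
    voxel_noise_sd: float = 0.5
    ar1_coef: float = 0.0  # temporal autocorrelation of parcel signals
    lesion_side: str = "left"
    n_lesioned_rois: int = 12
    resection_dilation: int = 1  # voxels the cavity extends beyond the tumor
    behavior_slope: float = 4.0  # alertness units per unit true coupling
    behavior_noise_sd: float = 0.5
    followup_slope_factor: float = 0.6  # attenuated coupling effect at follow-up
    age_range: tuple[float, float] = (30.0, 62.0)
    n_patients: int = 18
    n_controls: int = 18

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.grid_shape = tuple(self.grid_shape)
        self.rho_range = tuple(self.rho_range)
        self.age_range = tuple(self.age_range)
        if not 0 <= self.base_within_corr < 1:
            raise ValueError("base_within_corr must be in [0, 1)")
        lo, hi = self.rho_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("rho_range must satisfy 0 <= lo <= hi < 1")
        if self.n_lesioned_rois >= self.n_rois / 2:
            raise ValueError("n_lesioned_rois must be < n_rois / 2")
        if self.voxel_noise_sd <= 0 or self.behavior_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted quantities, stored next to the generated data for recovery tests."""

    lesioned_roi_ids: list[int]
    behavior_slope: float
    rho_by_subject: dict[str, float] = field(default_factory=dict)
    tumor_volume_cm3_by_subject: dict[str, float] = field(default_factory=dict)
    tumor_size_frac_by_subject: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# parcel-level simulation


def _noise(rng: np.random.Generator, shape, ar1: float) -> np.ndarray:
    """Unit-variance noise, white or AR(1)."""
    e = rng.standard_normal(shape)
    if ar1 == 0.0:
        return e
    out = np.empty_like(e)
    out[0] = e[0]
    scale = np.sqrt(1.0 - ar1**2)
    for t in range(1, e.shape[0]):
        out[t] = ar1 * out[t - 1] + scale * e[t]
    return out


def simulate_parcel_timeseries(
    cfg: SyntheticConfig, subject_rng: np.random.Generator, rho: float
) -> np.ndarray:
    """T x (n_rois + 1) matrix: extralesional parcels then the tumor column.

    Parcel i = sqrt(b) * g + sqrt(1-b) * e_i with one shared latent g, so the
    expected pairwise parcel correlation is b = ``base_within_corr``.  The
    tumor column = rho * g + sqrt(1-rho^2) * noise, giving an expected
    tumor-parcel correlation of rho * sqrt(b).  All columns have unit
    variance in expectation.
    """
    b = cfg.base_within_corr
    g = _noise(subject_rng, cfg.T, cfg.ar1_coef)
    eps = _noise(subject_rng, (cfg.T, cfg.n_rois), cfg.ar1_coef)
    parcels = np.sqrt(b) * g[:, None] + np.sqrt(1.0 - b) * eps
    tumor = rho * g + np.sqrt(1.0 - rho**2) * _noise(subject_rng, cfg.T, cfg.ar1_coef)
    return np.column_stack([parcels, tumor])


def expected_tumor_parcel_r(cfg: SyntheticConfig, rho: float) -> float:
    """Closed-form expected correlation between tumor and any parcel."""
    return rho * np.sqrt(cfg.base_within_corr)


# ---------------------------------------------------------------------------
# atlas / lesion geometry


def build_atlas(cfg: SyntheticConfig) -> AtlasParcellation:
    """Partition the grid into contiguous parcels with a left/right split.

    The left hemisphere is the low-x half; ids 1..n/2 are left,
    n/2+1..n right, each hemisphere split into equal contiguous runs of
    raster-ordered voxels.
    """
    nx, ny, nz = cfg.grid_shape
    half = nx // 2
    labels = np.zeros(cfg.grid_shape, dtype=np.int32)
    n_left = cfg.n_rois // 2
    n_right = cfg.n_rois - n_left
    for hemi, (sl, n_h, id0) in {
        "left": (np.s_[:half], n_left, 1),
        "right": (np.s_[half:], n_right, n_left + 1),
    }.items():
        idx = np.argwhere(np.ones((nx, ny, nz), dtype=bool)[sl])
        idx[:, 0] += 0 if hemi == "left" else half
        chunks = np.array_split(np.arange(len(idx)), n_h)
        if min(len(c) for c in chunks) == 0:
            raise ValueError("grid too small for n_rois")
        for j, chunk in enumerate(chunks):
            vox = idx[chunk]
            labels[vox[:, 0], vox[:, 1], vox[:, 2]] = id0 + j
    affine = np.diag([cfg.voxel_size_mm] * 3 + [1.0])
    table = pd.DataFrame(
        {
            "roi_id": np.arange(1, cfg.n_rois + 1),
            "name": [f"parcel_{i:03d}" for i in range(1, cfg.n_rois + 1)],
            "hemisphere": ["left"] * n_left + ["right"] * n_right,
        }
    )
    return AtlasParcellation(Volume(labels, affine), table)


def planted_lesioned_ids(cfg: SyntheticConfig) -> list[int]:
    """The k consecutive lesion-side roi_ids covered by the tumor."""
    n_left = cfg.n_rois // 2
    k = cfg.n_lesioned_rois
    if cfg.lesion_side == "left":
        start = max(1, n_left // 3)
    else:
        start = n_left + max(1, (cfg.n_rois - n_left) // 3)
    return list(range(start, start + k))


def build_tumor_mask(
    cfg: SyntheticConfig, atlas: AtlasParcellation, size_frac: float = 1.0
) -> LesionMask:
    """Contiguous tumor mask covering exactly the planted lesioned ROIs.

    ``size_frac`` in (0, 1] shrinks the mask within the *last* lesioned ROI
    (at least one voxel always remains) so tumor volumes vary across
    patients while the overlapped ROI set stays fixed.
    """
    if not 0 < size_frac <= 1:
        raise ValueError("size_frac must be in (0, 1]")
    ids = planted_lesioned_ids(cfg)
    ind = np.isin(atlas.labels.data, ids[:-1])
    last_vox = np.argwhere(atlas.labels.data == ids[-1])  # raster order
    n_keep = max(1, int(np.ceil(size_frac * len(last_vox))))
    keep = last_vox[:n_keep]
    ind[keep[:, 0], keep[:, 1], keep[:, 2]] = True
    return LesionMask(
        Volume(ind.astype(np.int16), atlas.labels.affine),
        kind="tumor",
        side=cfg.lesion_side,
    )


def build_resection_mask(
    cfg: SyntheticConfig, atlas: AtlasParcellation, tumor: LesionMask
) -> LesionMask:
    """Resection cavity: the tumor dilated by ``resection_dilation`` voxels,
    restricted to the lesion-side half so the cavity stays unilateral."""
    ind = tumor.indicator
    if cfg.resection_dilation > 0:
        ind = scipy.ndimage.binary_dilation(ind, iterations=cfg.resection_dilation)
    nx = cfg.grid_shape[0]
    half = nx // 2
    keep = np.zeros_like(ind)
    if cfg.lesion_side == "left":
        keep[:half] = True
    else:
        keep[half:] = True
    ind = ind & keep
    return LesionMask(
        Volume(ind.astype(np.int16), atlas.labels.affine),
        kind="resection",
        side=cfg.lesion_side,
    )


# ---------------------------------------------------------------------------
# in-memory cohort (fast path: no voxel rendering)


def parcel_series_to_timeseries_set(
    cfg: SyntheticConfig,
    series: np.ndarray,
    include_tumor: bool,
    lesioned_ids: list[int] | None = None,
) -> RoiTimeseriesSet:
    """Wrap a simulated T x (n_rois+1) matrix as the extraction output.

    Lesioned parcels are dropped (they are what the tumor overwrote); the
    tumor column is appended last for patients.
    """
    lesioned = set(lesioned_ids if lesioned_ids is not None else
                   (planted_lesioned_ids(cfg) if include_tumor else []))
    keep = [i for i in range(1, cfg.n_rois + 1) if i not in lesioned]
    cols = [series[:, i - 1] for i in keep]
    node_ids: list = list(keep)
    if include_tumor:
        cols.append(series[:, -1])
        node_ids.append(TUMOR_NODE)
    return RoiTimeseriesSet(
        series=np.column_stack(cols),
        node_ids=node_ids,
        excluded_ids=lesioned,
        tr_s=cfg.tr_s,
    )


def _behavior_row(
    rng: np.random.Generator, cfg: SyntheticConfig, group: str, age: float, rho: float
) -> dict[str, float]:
    """Ten score cells for one subject; patients are worse on every measure.

    Only the alertness quotient carries the planted coupling effect
    (``behavior_slope`` per unit rho preoperatively, attenuated at follow-up);
    higher alertness/consolidation/flexibility = worse, per the instruments'
    polarities.
    """
    pat = group == "patient"
    sd = cfg.behavior_noise_sd
    base = {
        "learning": (55.0 - 6.0 * pat - 0.15 * age, 6.0 * sd),
        "consolidation": (1.5 + 1.5 * pat + 0.02 * age, 1.5 * sd),
        "recognition": (13.0 - 1.8 * pat - 0.03 * age, 2.0 * sd),
        "flexibility": (40.0 + 18.0 * pat + 0.5 * age, 15.0 * sd),
    }
    row: dict[str, float] = {}
    for m, (mu, s) in base.items():
        for t, drift in (("initial", 0.0), ("followup", 0.05 * mu)):
            row[f"{m}_{t}"] = mu + drift * pat + s * rng.standard_normal()
    alert_mu = 5.0 + 0.02 * age + 0.5 * pat
    coupling = cfg.behavior_slope * rho if pat else 0.0
    row["alertness_initial"] = alert_mu + coupling + sd * rng.standard_normal()
    row["alertness_followup"] = (
        alert_mu + cfg.followup_slope_factor * coupling + sd * rng.standard_normal()
    )
    return row


def simulate_cohort_records(
    cfg: SyntheticConfig,
) -> tuple[list[CohortRecord], dict[str, np.ndarray], GroundTruth]:
    """In-memory cohort: records, per-subject parcel series, ground truth.

    Returns ``(records, series_by_subject, truth)`` where each series is the
    preoperative T x (n_rois + 1) matrix (tumor column last; for controls the
    tumor column is generated but unused downstream).
    """
    root = np.random.SeedSequence(cfg.seed)
    lesioned = planted_lesioned_ids(cfg)
    vox_per_roi = int(np.prod(cfg.grid_shape)) / cfg.n_rois

    records: list[CohortRecord] = []
    series: dict[str, np.ndarray] = {}
    truth = GroundTruth(lesioned_roi_ids=lesioned, behavior_slope=cfg.behavior_slope)
    subjects = [("patient", i) for i in range(cfg.n_patients)] + [
        ("control", i) for i in range(cfg.n_controls)
    ]
    for child, (group, i) in zip(root.spawn(len(subjects)), subjects):
        rng = np.random.default_rng(child)
        sid = f"sub-{'p' if group == 'patient' else 'c'}{i + 1:03d}"
        age = rng.uniform(*cfg.age_range)
        rho = rng.uniform(*cfg.rho_range) if group == "patient" else 0.0
        # tumor extent varies per patient within the fixed lesioned-ROI set
        size_frac = rng.uniform(0.5, 1.0) if group == "patient" else 1.0
        vol_cm3 = (
            (len(lesioned) - 1 + size_frac)
            * vox_per_roi
            * cfg.voxel_size_mm**3
            / 1000.0
        )
        series[sid] = simulate_parcel_timeseries(cfg, rng, rho)
        scores_flat = _behavior_row(rng, cfg, group, age, rho)
        scores = {
            (m, t): scores_flat[f"{m}_{t}"]
            for m in MEASURES
            for t in ("initial", "followup")
        }
        if group == "patient":
            truth.rho_by_subject[sid] = rho
            truth.tumor_volume_cm3_by_subject[sid] = vol_cm3
            truth.tumor_size_frac_by_subject[sid] = size_frac
        records.append(
            CohortRecord(
                subject_id=sid,
                group=group,
                age=age,
                lesion_side=cfg.lesion_side if group == "patient" else "none",
                tumor_volume_cm3=vol_cm3 if group == "patient" else None,
                scores=scores,
            )
        )
    return records, series, truth


def hemisphere_map(cfg: SyntheticConfig) -> dict[int, str]:
    """roi_id -> hemisphere for the generated parcellation (low ids left)."""
    n_left = cfg.n_rois // 2
    return {
        i: ("left" if i <= n_left else "right") for i in range(1, cfg.n_rois + 1)
    }


def cohort_fc_table(cfg: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a cohort in memory and run the FC summaries on it.

    Returns one row per subject with group, age, tumor volume, the true
    coupling rho, the estimated Tu-EL / EL / conEL summaries (controls get
    the hemispheric baseline in ``con_el``), and the ten score cells.  The
    estimation path is the package's own (``fc_matrix`` + summaries); only
    the voxel-rendering step is bypassed.
    """
    from .connectivity import (
        control_hemispheric_baseline,
        fc_matrix,
        summary_conel,
        summary_el,
        summary_tu_el,
    )

    records, series, truth = simulate_cohort_records(cfg)
    hemis = hemisphere_map(cfg)
    rows = []
    for rec in records:
        patient = rec.group == "patient"
        ts = parcel_series_to_timeseries_set(
            cfg, series[rec.subject_id], include_tumor=patient
        )
        m = fc_matrix(ts)
        row = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "age": rec.age,
            "tumor_volume_cm3": rec.tumor_volume_cm3,
            "rho_true": truth.rho_by_subject.get(rec.subject_id, np.nan),
            "n_nodes": m.n_nodes,
            "tu_el": summary_tu_el(m) if patient else np.nan,
            "el": summary_el(m),
            "con_el": (
                summary_conel(m, hemis, rec.lesion_side)
                if patient
                else control_hemispheric_baseline(m, hemis)
            ),
        }
        for (meas, tp), val in rec.scores.items():
            row[f"{meas}_{tp}"] = val
        rows.append(row)
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# rendered cohort (files on disk)


def _render_bold(
    cfg: SyntheticConfig,
    atlas: AtlasParcellation,
    parcel_series: np.ndarray,
    rng: np.random.Generator,
    tumor: LesionMask | None,
    resected: bool = False,
) -> Volume:
    """Voxel field: each voxel carries its parcel's series plus i.i.d. noise.

    Tumor voxels carry the tumor column instead (the lesion overwrote the
    underlying parcels); in a resected follow-up they carry pure noise.
    """
    labels = atlas.labels.data
    T = cfg.T
    vol = np.empty(cfg.grid_shape + (T,), dtype=np.float32)
    flat_labels = labels.reshape(-1)
    flat = vol.reshape(-1, T)
    # background voxels (label 0), if any, get noise only
    flat[:] = 0.0
    for roi in range(1, cfg.n_rois + 1):
        sel = flat_labels == roi
        flat[sel] = parcel_series[:, roi - 1]
    if tumor is not None:
        tsel = tumor.indicator.reshape(-1)
        flat[tsel] = 0.0 if resected else parcel_series[:, -1]
    flat += cfg.voxel_noise_sd * rng.standard_normal(flat.shape).astype(np.float32)
    return Volume(vol, atlas.labels.affine)


def make_followup(
    cfg: SyntheticConfig,
    atlas: AtlasParcellation,
    tumor: LesionMask,
    rng: np.random.Generator,
) -> tuple[Volume, LesionMask]:
    """Follow-up BOLD (same extralesional structure, cavity silenced) and
    the resection mask covering at least the tumor core."""
    resection = build_resection_mask(cfg, atlas, tumor)
    series = simulate_parcel_timeseries(cfg, rng, rho=0.0)
    bold = _render_bold(cfg, atlas, series, rng, tumor=tumor, resected=True)
    return bold, resection


def render_cohort(cfg: SyntheticConfig, out_dir: str | Path) -> dict:
    """Write a complete cohort to disk; returns a manifest dict (also saved
    as ``manifest.yaml``) consumable by the pipeline.

    Files: atlas + lookup table, per-subject pre/post BOLD NIfTIs, patient
    tumor and resection masks, cohort CSV, ground-truth JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = build_atlas(cfg)
    save_volume(atlas.labels, out / "atlas.nii.gz")
    atlas.roi_table.to_csv(out / "lut.csv", index=False)

    records, series, truth = simulate_cohort_records(cfg)

    render_root = np.random.SeedSequence([cfg.seed, 7])
    manifest: dict = {
        "atlas": str(out / "atlas.nii.gz"),
        "lut": str(out / "lut.csv"),
        "cohort": str(out / "cohort.csv"),
        "tr_s": cfg.tr_s,
        "subjects": {},
    }
    for child, rec in zip(render_root.spawn(len(records)), records):
        rng = np.random.default_rng(child)
        sid = rec.subject_id
        sdir = out / sid
        sdir.mkdir(exist_ok=True)
        is_patient = rec.group == "patient"
        tumor = (
            build_tumor_mask(cfg, atlas, truth.tumor_size_frac_by_subject[sid])
            if is_patient
            else None
        )
        pre = _render_bold(cfg, atlas, series[sid], rng, tumor)
        save_volume(pre, sdir / "bold_initial.nii.gz")
        entry = {"initial_bold": str(sdir / "bold_initial.nii.gz")}
        if is_patient:
            save_volume(tumor.mask, sdir / "tumor.nii.gz")
            entry["tumor"] = str(sdir / "tumor.nii.gz")
            # realized mask volume replaces the voxel-count estimate
            vol_cm3 = tumor_volume_cm3(tumor)
            truth.tumor_volume_cm3_by_subject[sid] = vol_cm3
            rec.tumor_volume_cm3 = vol_cm3
            post, resection = make_followup(cfg, atlas, tumor, rng)
            save_volume(resection.mask, sdir / "resection.nii.gz")
            entry["resection"] = str(sdir / "resection.nii.gz")
        else:
            post_series = simulate_parcel_timeseries(cfg, rng, rho=0.0)
            post = _render_bold(cfg, atlas, post_series, rng, tumor=None)
        save_volume(post, sdir / "bold_followup.nii.gz")
        entry["followup_bold"] = str(sdir / "bold_followup.nii.gz")
        manifest["subjects"][sid] = entry

    cohort_to_frame(records).to_csv(out / "cohort.csv", index=False)
    truth.to_json(out / "ground_truth.json")
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
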
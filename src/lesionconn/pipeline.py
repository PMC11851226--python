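"""End-to-end orchestration: extract -> connectivity -> statistics.

One YAML config (or the manifest written by the synthetic generator, plus a
``params`` block) drives the whole cohort.  Every stage writes plain CSV/JSON
so each step can be re-run from its on-disk inputs; re-running with the same
config yields byte-identical tables.

Per patient, the combined (tumor ∪ resection) mask fixes one extralesional
node set used at both timepoints; the tumor node is computed from the
unmasked preoperative BOLD only.  Controls get the full atlas node set and
the hemispheric-mean baseline in the ``con_el`` column.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imaging_io import (
    HIGHER_IS_WORSE,
    MEASURES,
    TIMEPOINTS,
    cohort_to_frame,
    load_atlas,
    load_cohort_table,
    load_volume,
)
from .connectivity import (
    DEFAULT_CLIP,
    control_hemispheric_baseline,
    fc_matrix,
    highpass_filter,
    summary_conel,
    summary_el,
    summary_tu_el,
)
from .parcellation import (
    LesionMask,
    apply_lesion_mask,
    combine_lesion_masks,
    extract_roi_timeseries,
    lesioned_roi_ids,
    tumor_volume_cm3,
)
from .stats import (
    adjust_p,
    multivariate_group_test,
    partial_correlation,
    rm_ancova,
    winsorize_group,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

#: FC summary columns analysed longitudinally
FC_VARS = ("el", "con_el")


@dataclass
class PipelineConfig:
    """Validated run configuration.

    ``subjects`` maps subject_id to a dict with keys ``initial_bold``,
    ``followup_bold`` and, for patients, ``tumor`` and optionally
    ``resection`` (all NIfTI paths).
    """

    cohort: Path
    atlas: Path
    lut: Path
    subjects: dict
    out_dir: Path
    tr_s: float = 2.2
    seed: int = 0
    min_overlap_voxels: int = 1
    clip: float = DEFAULT_CLIP
    alpha: float = 0.05
    m_patients: int | None = None  # Bonferroni family sizes; None = tests run
    m_controls: int | None = None
    winsorize: bool = True
    highpass: bool = False
    highpass_cutoff_hz: float = 0.01
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for attr in ("cohort", "atlas", "lut"):
            p = Path(getattr(self, attr))
            setattr(self, attr, p)
            if not p.exists():
                raise FileNotFoundError(f"{attr} path does not exist: {p}")
        self.out_dir = Path(self.out_dir)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_overlap_voxels < 1:
            raise ValueError("min_overlap_voxels must be >= 1")
        for sid, entry in self.subjects.items():
            for key, path in entry.items():
                if not Path(path).exists():
                    raise FileNotFoundError(f"{sid}/{key}: missing file {path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        params = raw.pop("params", {})
        raw.update(params)
        raw.update(overrides)
        raw.setdefault("out_dir", Path(path).parent / "results")
        return cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})


def _subject_summaries(cfg: PipelineConfig, atlas, record, entry) -> list[dict]:
    """FC summary rows (one per timepoint) for one subject."""
    hemis = atlas.hemispheres
    rows = []
    is_patient = record.group == "patient"
    tumor = resection = combined = None
    excluded: set[int] = set()
    if is_patient:
        tumor = LesionMask(
            load_volume(entry["tumor"]), kind="tumor", side=record.lesion_side
        )
        if "resection" in entry:
            resection = LesionMask(
                load_volume(entry["resection"]),
                kind="resection",
                side=record.lesion_side,
            )
            combined = combine_lesion_masks(tumor, resection)
        else:
            combined = LesionMask(tumor.mask, kind="combined", side=tumor.side)
        excluded = lesioned_roi_ids(atlas, combined, cfg.min_overlap_voxels)

    for timepoint in TIMEPOINTS:
        bold = load_volume(entry[f"{timepoint}_bold"])
        if is_patient:
            masked = apply_lesion_mask(bold, combined)
            ts = extract_roi_timeseries(
                masked,
                atlas,
                excluded=excluded,
                tumor=tumor if timepoint == "initial" else None,
                tumor_bold=bold,
                tr_s=cfg.tr_s,
            )
        else:
            ts = extract_roi_timeseries(bold, atlas, tr_s=cfg.tr_s)
        if cfg.highpass:
            ts = highpass_filter(ts, tr_s=cfg.tr_s, cutoff_hz=cfg.highpass_cutoff_hz)
        m = fc_matrix(ts, clip=cfg.clip)
        row = {
            "subject_id": record.subject_id,
            "group": record.group,
            "timepoint": timepoint,
            "n_nodes": m.n_nodes,
            "n_excluded": len(ts.excluded_ids),
            "node_ids": ",".join(str(i) for i in ts.node_ids),
            "el": summary_el(m),
            "tu_el": summary_tu_el(m) if m.has_tumor_node else np.nan,
        }
        if is_patient:
            row["con_el"] = summary_conel(m, hemis, record.lesion_side)
            row["tumor_volume_cm3"] = tumor_volume_cm3(tumor)
        else:
            row["con_el"] = control_hemispheric_baseline(m, hemis)
            row["tumor_volume_cm3"] = np.nan
        rows.append(row)
    return rows


def _winsorize_frame(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Group-bound winsorization per variable, skipping missing cells."""
    out = df.copy()
    for group, idx in df.groupby("group").groups.items():
        for col in columns:
            finite = out.loc[idx, col].dropna()
            if len(finite) >= 3:
                out.loc[finite.index, col] = winsorize_group(finite.to_list())
    return out


def _wide_table(cohort: pd.DataFrame, summaries: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: scores plus FC summaries per timepoint."""
    wide = cohort.copy()
    for timepoint in TIMEPOINTS:
        sub = summaries[summaries["timepoint"] == timepoint]
        for var in FC_VARS:
            col = sub.set_index("subject_id")[var]
            wide[f"{var}_{timepoint}"] = wide["subject_id"].map(col)
    pre = summaries[summaries["timepoint"] == "initial"]
    wide["tu_el"] = wide["subject_id"].map(pre.set_index("subject_id")["tu_el"])
    tv = pre.set_index("subject_id")["tumor_volume_cm3"]
    measured = wide["subject_id"].map(tv).astype(float)
    wide["tumor_volume_cm3"] = wide["tumor_volume_cm3"].astype(float).fillna(measured)
    return wide


def _ancova_table(wide: pd.DataFrame) -> pd.DataFrame:
    """Repeated-measures ANCOVAs (age covariate) per measure and FC summary,
    plus the multivariate group test over the five measures jointly."""
    rows = []
    for var in list(MEASURES) + list(FC_VARS):
        cols = [f"{var}_initial", f"{var}_followup", "group", "age"]
        data = wide[cols].dropna()
        try:
            effects = rm_ancova(
                data,
                value_cols=(f"{var}_initial", f"{var}_followup"),
                covariate_cols=("age",),
            )
        except ValueError as exc:
            logger.warning("rm_ancova skipped for %s: %s", var, exc)
            continue
        for eff in effects:
            rows.append(
                {
                    "analysis": var,
                    "effect": eff.name,
                    "F": eff.F,
                    "df_num": eff.df_num,
                    "df_den": eff.df_den,
                    "p": eff.p,
                    "n": len(data),
                }
            )
    # multivariate group effect on the five measures (subject means over time)
    mcols = {m: [f"{m}_initial", f"{m}_followup"] for m in MEASURES}
    needed = [c for cols in mcols.values() for c in cols] + ["group", "age"]
    complete = wide[needed].dropna()
    if len(complete) > len(MEASURES) + 3:
        y = np.column_stack(
            [complete[cols].mean(axis=1).to_numpy() for cols in mcols.values()]
        )
        eff = multivariate_group_test(
            y, complete["group"].to_numpy(), complete["age"].to_numpy()
        )
        rows.append(
            {
                "analysis": "all_measures",
                "effect": eff.name,
                "F": eff.F,
                "df_num": eff.df_num,
                "df_den": eff.df_den,
                "p": eff.p,
                "n": len(complete),
            }
        )
    return pd.DataFrame(rows)


def _correlation_table(cfg: PipelineConfig, wide: pd.DataFrame) -> pd.DataFrame:
    """Partial correlations between FC measures and scores, per group.

    Patients: covariates age + tumor volume; tested FC variables include the
    preoperative tumor coupling.  Controls: covariate age.  Each family is
    Bonferroni-adjusted with its configured m (default: tests actually run).
    """
    score_cols = [f"{m}_{t}" for m in MEASURES for t in TIMEPOINTS]
    fam_rows: list[dict] = []
    for group, covs, fc_cols, m_cfg in (
        (
            "patient",
            ["age", "tumor_volume_cm3"],
            ["tu_el"] + [f"{v}_{t}" for v in FC_VARS for t in TIMEPOINTS],
            cfg.m_patients,
        ),
        (
            "control",
            ["age"],
            [f"{v}_{t}" for v in FC_VARS for t in TIMEPOINTS],
            cfg.m_controls,
        ),
    ):
        sub = wide[wide["group"] == group]
        rows: list[dict] = []
        for fc_col in fc_cols:
            for score_col in score_cols:
                cols = [fc_col, score_col] + covs
                data = sub[cols].dropna()
                if len(data) < len(covs) + 3:
                    logger.info("skipping %s/%s~%s: too few complete cases",
                                group, fc_col, score_col)
                    continue
                try:
                    res = partial_correlation(
                        data[fc_col],
                        data[score_col],
                        data[covs].to_numpy(),
                        covariate_names=tuple(covs),
                    )
                except ValueError as exc:
                    logger.warning("%s/%s~%s failed: %s", group, fc_col, score_col, exc)
                    continue
                rows.append(
                    {
                        "group": group,
                        "fc_measure": fc_col,
                        "score": score_col,
                        "higher_is_worse": HIGHER_IS_WORSE[score_col.rsplit("_", 1)[0]],
                        "r": res.r,
                        "df": res.df,
                        "t": res.t_stat,
                        "p": res.p,
                        "n": res.n,
                    }
                )
        m = m_cfg if m_cfg is not None else max(len(rows), 1)
        padj = adjust_p([r["p"] for r in rows], m)
        alpha_adj = cfg.alpha / m
        for row, pa in zip(rows, padj):
            row["p_adjusted"] = pa
            row["m"] = m
            row["alpha_adjusted"] = alpha_adj
        fam_rows.extend(rows)
    return pd.DataFrame(fam_rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full battery; returns DataFrames and writes the result bundle.

    Outputs under ``cfg.out_dir``: ``summaries.csv`` (per subject/timepoint
    FC), ``analysis_table.csv`` (wide per-subject table after optional
    winsorization), ``ancova.csv``, ``correlations.csv``, ``run_log.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = load_atlas(cfg.atlas, cfg.lut)
    records = load_cohort_table(cfg.cohort)
    by_id = {r.subject_id: r for r in records}

    rows = []
    for sid in sorted(cfg.subjects):
        if sid not in by_id:
            raise KeyError(f"subject {sid} in manifest but not in cohort table")
        try:
            rows.extend(_subject_summaries(cfg, atlas, by_id[sid], cfg.subjects[sid]))
        except Exception as exc:
            raise RuntimeError(f"stage 'extract/fc' failed for {sid}: {exc}") from exc
    summaries = pd.DataFrame(rows)

    cohort = cohort_to_frame(records)
    wide = _wide_table(cohort, summaries)
    if cfg.winsorize:
        score_cols = [f"{m}_{t}" for m in MEASURES for t in TIMEPOINTS]
        fc_cols = ["tu_el"] + [f"{v}_{t}" for v in FC_VARS for t in TIMEPOINTS]
        wide = _winsorize_frame(wide, score_cols + fc_cols)

    ancova = _ancova_table(wide)
    correlations = _correlation_table(cfg, wide)

    summaries.to_csv(out / "summaries.csv", index=False, float_format=_FLOAT_FMT)
    wide.to_csv(out / "analysis_table.csv", index=False, float_format=_FLOAT_FMT)
    ancova.to_csv(out / "ancova.csv", index=False, float_format=_FLOAT_FMT)
    correlations.to_csv(out / "correlations.csv", index=False, float_format=_FLOAT_FMT)
    log = {
        "lesionconn_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "parameters": {
            "min_overlap_voxels": cfg.min_overlap_voxels,
            "clip": cfg.clip,
            "alpha": cfg.alpha,
            "m_patients": cfg.m_patients,
            "m_controls": cfg.m_controls,
            "winsorize": cfg.winsorize,
            "highpass": cfg.highpass,
            "highpass_cutoff_hz": cfg.highpass_cutoff_hz,
            "tr_s": cfg.tr_s,
        },
        "n_subjects": len(cfg.subjects),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return {
        "summaries": summaries,
        "analysis_table": wide,
        "ancova": ancova,
        "correlations": correlations,
        "out_dir": out,
    }


def render_report(results: dict, out_dir: str | Path | None = None) -> list[Path]:
    """Descriptive figures: behavior and FC by group x timepoint, the tumor
    coupling vs attention scatter, and grade-stratified coupling means when a
    ``grade`` column is present.  Best-effort: failures never gate the run."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir if out_dir is not None else results["out_dir"]) / "figures"
    out.mkdir(parents=True, exist_ok=True)
    wide = results["analysis_table"]
    written: list[Path] = []

    def _grouped_box(columns: list[str], title: str, fname: str) -> None:
        fig, axes = plt.subplots(1, len(columns), figsize=(3 * len(columns), 3.2),
                                 squeeze=False)
        plot_data = []
        for ax, var in zip(axes[0], columns):
            data, labels = [], []
            for group in ("control", "patient"):
                for timepoint in TIMEPOINTS:
                    vals = wide.loc[wide["group"] == group, f"{var}_{timepoint}"].dropna()
                    if len(vals):
                        data.append(vals.to_numpy())
                        labels.append(f"{group[0].upper()}-{timepoint[:4]}")
                        for v in vals:
                            plot_data.append({"variable": var, "group": group,
                                              "timepoint": timepoint, "value": v})
            if data:
                ax.boxplot(data, tick_labels=labels)
            ax.set_title(var, fontsize=9)
            ax.tick_params(axis="x", rotation=45, labelsize=7)
        fig.suptitle(title)
        fig.tight_layout()
        fig.savefig(out / fname, dpi=120)
        plt.close(fig)
        pd.DataFrame(plot_data).to_csv(
            out / fname.replace(".png", ".csv"), index=False, float_format=_FLOAT_FMT
        )
        written.append(out / fname)

    try:
        _grouped_box(list(MEASURES), "Cognitive scores by group and timepoint",
                     "behavior.png")
        _grouped_box(list(FC_VARS), "FC summaries by group and timepoint", "fc.png")
    except Exception as exc:  # pragma: no cover - plotting is best-effort
        logger.warning("behavior/FC figures failed: %s", exc)

    patients = wide[(wide["group"] == "patient") & wide["tu_el"].notna()]
    if len(patients) >= 3:
        try:
            corr = results["correlations"]
            sel = corr[(corr["fc_measure"] == "tu_el") & (corr["score"] == "alertness_initial")]
            fig, ax = plt.subplots(figsize=(4, 3.5))
            ax.scatter(patients["tu_el"], patients["alertness_initial"], c="k")
            ax.set_xlabel("Tu-EL FC (mean z)")
            ax.set_ylabel("alertness (higher = worse)")
            if len(sel):
                ax.set_title(
                    f"partial r={sel['r'].iloc[0]:.3f}, p={sel['p'].iloc[0]:.3g}",
                    fontsize=9,
                )
            fig.tight_layout()
            fig.savefig(out / "tu_el_alertness.png", dpi=120)
            plt.close(fig)
            patients[["subject_id", "tu_el", "alertness_initial"]].to_csv(
                out / "tu_el_alertness.csv", index=False, float_format=_FLOAT_FMT
            )
            written.append(out / "tu_el_alertness.png")
        except Exception as exc:  # pragma: no cover
            logger.warning("scatter figure failed: %s", exc)

    if "grade" in wide.columns and len(patients) >= 2:
        try:
            means = patients.groupby("grade")["tu_el"].mean()
            fig, ax = plt.subplots(figsize=(4, 3.5))
            ax.bar([str(i) for i in means.index], means.to_numpy())
            ax.set_xlabel("tumor grade")
            ax.set_ylabel("mean Tu-EL FC (z)")
            fig.tight_layout()
            fig.savefig(out / "tu_el_by_grade.png", dpi=120)
            plt.close(fig)
            means.to_csv(out / "tu_el_by_grade.csv", float_format=_FLOAT_FMT)
            written.append(out / "tu_el_by_grade.png")
        except Exception as exc:  # pragma: no cover
            logger.warning("grade figure failed: %s", exc)
    return written
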
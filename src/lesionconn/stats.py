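"""Statistical battery: outlier winsorization, partial correlation,
Bonferroni correction, and the two-group repeated-measures ANCOVA.

Conventions
-----------
* All p-values are two-sided.
* Winsorization bounds use the group mean +/- 1.5 sample standard deviations
  (n-1 denominator), computed once on the original data; values beyond a
  bound are replaced by it.
* The repeated-measures design has exactly two groups and two timepoints.
  With two timepoints the mixed model decomposes exactly into a between part
  (per-subject mean across timepoints) and a within part (follow-up minus
  initial difference); covariates enter both parts as between-subject
  regressors, centred, with the group factor effect-coded, so each F is a
  Type III-style full-vs-reduced model comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)

_TINY_P = np.finfo(float).tiny


@dataclass
class PartialCorrResult:
    """Pearson partial correlation of x and y given k covariates."""

    r: float
    df: int  # n - 2 - k
    t_stat: float
    p: float
    n: int
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"|r| must be <= 1, got {self.r}")
        if self.df < 1:
            raise ValueError("df must be >= 1")


@dataclass
class AncovaEffect:
    """One F test from the repeated-measures battery."""

    name: str  # 'group' | 'time' | 'group_x_time' | 'multivariate_group'
    F: float
    df_num: int
    df_den: int
    p: float

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be non-negative")
        if self.df_num < 1 or self.df_den < 1:
            raise ValueError("degrees of freedom must be >= 1")


def winsorize_group(values: Sequence[float]) -> list[float]:
    """Replace outliers by the group mean +/- 1.5 sample SD bound.

    Bounds are computed once from the input; order and length are preserved.
    A zero-SD group is returned unchanged with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    sd = x.std(ddof=1)
    if sd == 0:
        logger.warning("zero standard deviation; returning input unchanged")
        return list(x)
    lo, hi = x.mean() - 1.5 * sd, x.mean() + 1.5 * sd
    clipped = np.clip(x, lo, hi)
    n_repl = int(np.count_nonzero(clipped != x))
    if n_repl:
        logger.info("winsorized %d of %d values to [%.4g, %.4g]", n_repl, x.size, lo, hi)
    return list(clipped)


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | None = None,
    covariate_names: tuple[str, ...] = (),
) -> PartialCorrResult:
    """Pearson correlation of x and y after regressing out the covariates.

    ``r`` is the plain Pearson correlation of the two residual vectors from
    least-squares regression on [1, covariates]; with no covariates this is
    the ordinary Pearson correlation.  ``t = r * sqrt(df / (1 - r^2))`` with
    ``df = n - 2 - k``, tested two-sided against Student's t.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match n")
    k = cov.shape[1]
    if n < k + 3:
        raise ValueError(f"need n >= k + 3 (n={n}, k={k})")
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(cov).all()):
        raise ValueError("inputs must be finite")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    if rx.std() <= 1e-10 * max(x.std(), 1e-30) or ry.std() <= 1e-10 * max(
        y.std(), 1e-30
    ):
        raise ValueError("a variable is fully explained by the covariates")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
        p = _TINY_P
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * scipy.stats.t.sf(abs(t), df))
        p = max(p, _TINY_P)
    return PartialCorrResult(
        r=r, df=df, t_stat=float(t), p=p, n=n, covariate_names=tuple(covariate_names)
    )


def bonferroni(alpha: float, m: int) -> float:
    """Per-test significance level alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def adjust_p(p_list: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni-adjusted p-values: min(1, p * m); m defaults to len(p_list)."""
    p = np.asarray(p_list, dtype=float)
    m = len(p) if m is None else m
    if m < 1:
        raise ValueError("m must be >= 1")
    return list(np.minimum(1.0, p * m))


def _f_test(
    y: np.ndarray, x_full: np.ndarray, drop: Sequence[int]
) -> tuple[float, int, int, float]:
    """F for dropping columns ``drop`` from the full design (full vs reduced SSE)."""
    n, p_full = x_full.shape
    keep = [j for j in range(p_full) if j not in set(drop)]
    sse_full = float(np.sum(_residualize(y, x_full) ** 2))
    x_red = x_full[:, keep] if keep else np.empty((n, 0))
    if x_red.shape[1]:
        sse_red = float(np.sum(_residualize(y, x_red) ** 2))
    else:
        sse_red = float(np.sum(y**2))
    df_num = len(drop)
    df_den = n - p_full
    ss_eff = max(sse_red - sse_full, 0.0)
    if sse_full <= 1e-12 * max(sse_red, 1.0):
        if ss_eff <= 1e-12:
            return 0.0, df_num, df_den, 1.0
        return np.inf, df_num, df_den, _TINY_P
    F = (ss_eff / df_num) / (sse_full / df_den)
    p = max(float(scipy.stats.f.sf(F, df_num, df_den)), _TINY_P)
    return F, df_num, df_den, p


def rm_ancova(
    table: pd.DataFrame,
    value_cols: tuple[str, str] = ("initial", "followup"),
    group_col: str = "group",
    covariate_cols: Sequence[str] = ("age",),
) -> list[AncovaEffect]:
    """Two-group x two-timepoint repeated-measures ANCOVA.

    Parameters
    ----------
    table
        One row per subject with the measure at both timepoints, a two-level
        group column, and covariate columns.  Incomplete rows are dropped
        listwise (logged).

    Returns the ``group``, ``time`` and ``group_x_time`` effects.  The group
    effect is tested on the per-subject mean across timepoints, the time and
    interaction effects on the follow-up minus initial difference, each via
    full-vs-reduced least-squares model comparison with the covariates as
    centred between-subject regressors and group effect-coded (+/- 1/2).
    """
    cols = list(value_cols) + [group_col] + list(covariate_cols)
    data = table[cols].copy()
    complete = data.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("rm_ancova: dropped %d incomplete case(s)", n_dropped)
    data = data[complete]
    groups = sorted(data[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    counts = data[group_col].value_counts()
    if counts.min() < 3:
        raise ValueError(f"a group has fewer than 3 complete cases: {dict(counts)}")

    y1 = data[value_cols[0]].to_numpy(dtype=float)
    y2 = data[value_cols[1]].to_numpy(dtype=float)
    g = np.where(data[group_col].to_numpy() == groups[1], 0.5, -0.5)
    cov = data[list(covariate_cols)].to_numpy(dtype=float)
    cov = cov - cov.mean(axis=0, keepdims=True)
    n = len(data)
    design = np.column_stack([np.ones(n), g, cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (constant covariate or group)")

    avg = (y1 + y2) / 2.0  # between-subject part
    diff = y2 - y1  # within-subject part

    effects = []
    F, dn, dd, p = _f_test(avg, design, drop=[1])
    effects.append(AncovaEffect("group", F, dn, dd, p))
    F, dn, dd, p = _f_test(diff, design, drop=[0])
    effects.append(AncovaEffect("time", F, dn, dd, p))
    F, dn, dd, p = _f_test(diff, design, drop=[1])
    effects.append(AncovaEffect("group_x_time", F, dn, dd, p))
    return effects


def multivariate_group_test(
    measures: np.ndarray,
    group: Sequence,
    covariates: np.ndarray | None = None,
) -> AncovaEffect:
    """Wilks' lambda test of the two-group effect on several measures jointly.

    After adjusting for the covariates, the hypothesis and error SSCP
    matrices are built by full-vs-reduced residual cross-products; with one
    hypothesis degree of freedom (two groups) Wilks' lambda converts to an
    exact F with ``df_num = p`` measures and ``df_den = n - k - p - 1``.
    """
    y = np.asarray(measures, dtype=float)
    if y.ndim != 2:
        raise ValueError("measures must be an n x p matrix")
    n, p = y.shape
    glabels = np.asarray(group)
    levels = sorted(pd.unique(glabels))
    if len(levels) != 2:
        raise ValueError("need exactly 2 groups")
    g = np.where(glabels == levels[1], 0.5, -0.5)
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    k = cov.shape[1]
    if n <= p + k + 2:
        raise ValueError(f"need n > p + k + 2 (n={n}, p={p}, k={k})")
    cov = cov - cov.mean(axis=0, keepdims=True) if k else cov
    x_full = np.column_stack([np.ones(n), cov, g])
    x_red = np.column_stack([np.ones(n), cov])
    r_full = _residualize(y, x_full)
    r_red = _residualize(y, x_red)
    E = r_full.T @ r_full
    H = r_red.T @ r_red - E
    df_den = n - k - p - 1
    try:
        lam = float(np.linalg.det(E) / np.linalg.det(E + H))
    except FloatingPointError:
        lam = np.nan
    if not np.isfinite(lam) or np.linalg.det(E) <= 0:
        raise ValueError(
            "singular within-group covariance; reduce the number of measures"
        )
    lam = min(max(lam, 0.0), 1.0)
    if lam == 0.0:
        F = np.inf
        pval = _TINY_P
    else:
        F = (1.0 - lam) / lam * df_den / p
        pval = max(float(scipy.stats.f.sf(F, p, df_den)), _TINY_P)
    return AncovaEffect("multivariate_group", float(F), p, df_den, pval)
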
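"""Control-normalized scoring of a promoter-reporter screen.

For every compound well the pipeline computes, against the mean of the nine
vehicle (DMSO) control wells of the same plate at each time point:

* the **GFP score** -- area under the curve of the GFP fold-change series
  over 72 h.  By default the AUC is divided by the total duration
  (time-normalized), so a well indistinguishable from the controls scores
  1 and the published hit threshold of 5 reads as "an average five-fold
  induction"; a raw trapezoid-in-hours mode is retained.
* the **confluency score** -- arithmetic mean of the confluence fold-change
  series over all acquired time points (a no-effect well scores 1; the
  published threshold 0.65 marks growth suppression).

Compounds whose GFP fold change is already high at the start of the
observation window are flagged as intrinsically fluorescent and excluded:
reporter-driven fluorescence cannot rise before transcription, translation
and fluorophore maturation have had time to act, so an early jump marks an
artifact rather than induction.

Hit classes combine the two thresholds; category-level association between
growth suppression and reporter induction is measured with Spearman's rank
correlation (average ranks for ties; two-sided p from the t approximation
for n >= 10 and from exact permutation below that).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScoringConfig",
    "ScoreRow",
    "control_mean_series",
    "fold_change_series",
    "gfp_score",
    "confluency_score",
    "autofluorescence_qc",
    "classify",
    "spearman",
    "category_correlation",
    "score_screen",
    "correlation_table",
]

HIT_CLASSES = ("arrested_induced", "arrested_only", "induced_only",
               "inactive", "excluded")


@dataclass(frozen=True)
class ScoringConfig:
    gfp_score_threshold: float = 5.0
    confluency_score_threshold: float = 0.65
    control_floor_gcu: float = 0.05
    control_floor_confluence_pct: float = 1.0
    auc_mode: str = "time_normalized"  # or raw_hours, baseline_subtracted
    qc_early_window_h: float = 2.0
    qc_early_fc_cutoff: float = 2.0

    def __post_init__(self) -> None:
        for name in ("gfp_score_threshold", "confluency_score_threshold",
                     "control_floor_gcu", "control_floor_confluence_pct",
                     "qc_early_fc_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScoringConfig.{name} must be > 0")
        if self.qc_early_window_h < 0:
            raise ValueError("qc_early_window_h must be >= 0")
        if self.auc_mode not in ("time_normalized", "raw_hours", "baseline_subtracted"):
            raise ValueError(f"unknown auc_mode {self.auc_mode!r}")


@dataclass(frozen=True)
class ScoreRow:
    compound_id: str
    category: str
    gfp_score: float
    confluency_score: float
    qc_autofluorescent: bool
    hit_class: str


# ---------------------------------------------------------------------------
# series operations

def control_mean_series(plate_table: pd.DataFrame, role: str,
                        metric: str) -> pd.Series:
    """Per-time-point mean of a metric over one plate's wells of a role.

    Control means are always per plate -- never pooled across plates -- so
    that plate-to-plate variation normalizes out.
    """
    plate_ids = plate_table["plate"].unique()
    if len(plate_ids) != 1:
        raise ValueError("control_mean_series expects a single plate's table")
    ctrl = plate_table[plate_table["role"] == role]
    if ctrl.empty:
        raise ValueError(f"plate {plate_ids[0]!r} has no {role!r} wells")
    return ctrl.groupby("time_h")[metric].mean()


def fold_change_series(well_series: pd.Series, control_series: pd.Series,
                       floor: float) -> pd.Series:
    """FC(t) = well(t) / max(control(t), floor) on a shared time grid."""
    if len(well_series) != len(control_series) or \
            not np.allclose(np.asarray(well_series.index, dtype=float),
                            np.asarray(control_series.index, dtype=float)):
        raise ValueError("well and control series are on different time grids")
    denom = np.maximum(control_series.to_numpy(dtype=float), floor)
    return pd.Series(well_series.to_numpy(dtype=float) / denom,
                     index=well_series.index)


def gfp_score(fc_series: pd.Series, config: ScoringConfig | None = None) -> float:
    """AUC of the GFP fold-change curve (trapezoid; see module docstring)."""
    config = config or ScoringConfig()
    if len(fc_series) < 2:
        raise ValueError("gfp_score needs at least two time points")
    t = np.asarray(fc_series.index, dtype=float)
    y = fc_series.to_numpy(dtype=float)
    if config.auc_mode == "baseline_subtracted":
        y = y - y[0]
    auc = float(np.trapezoid(y, t))
    if config.auc_mode == "raw_hours":
        return auc
    return auc / (t[-1] - t[0])


def confluency_score(fc_series: pd.Series) -> float:
    """Arithmetic mean of the confluence fold change over all time points."""
    if len(fc_series) == 0:
        raise ValueError("confluency_score needs at least one time point")
    return float(fc_series.mean())


def autofluorescence_qc(gfp_fc_series: pd.Series,
                        config: ScoringConfig | None = None) -> bool:
    """True when the GFP fold change is implausibly high in the early window."""
    config = config or ScoringConfig()
    t = np.asarray(gfp_fc_series.index, dtype=float)
    if t.min() > config.qc_early_window_h:
        raise ValueError("series does not cover the early QC window")
    early = gfp_fc_series.to_numpy(dtype=float)[t <= config.qc_early_window_h]
    return bool(np.any(early > config.qc_early_fc_cutoff))


def classify(gfp: float, confluency: float, excluded: bool = False,
             config: ScoringConfig | None = None) -> str:
    """Quadrant hit class from the two scores (exclusion overrides)."""
    config = config or ScoringConfig()
    if excluded:
        return "excluded"
    induced = gfp > config.gfp_score_threshold
    arrested = confluency < config.confluency_score_threshold
    if induced and arrested:
        return "arrested_induced"
    if arrested:
        return "arrested_only"
    if induced:
        return "induced_only"
    return "inactive"


# ---------------------------------------------------------------------------
# rank correlation

def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def spearman(x, y) -> tuple[float, float, int]:
    """Spearman rank correlation with a reproducible two-sided p value.

    Ties receive average ranks.  For n >= 10 the p value uses the
    t = rho*sqrt((n-2)/(1-rho^2)) approximation with n-2 df; for n < 10 it
    is exact, by enumerating all n! permutations of one rank vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 4:
        raise ValueError("spearman needs at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation is undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_rho(rx, ry)
    if n < 10:
        perms = np.array(list(itertools.permutations(range(n))))
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt((rx_c @ rx_c) * (ry_c @ ry_c))
        rhos = (rx_c[perms] @ ry_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p, n


def category_correlation(score_table: pd.DataFrame, category: str,
                         min_n: int = 4) -> tuple[float, float, int]:
    """Spearman correlation of confluency vs GFP score within one category.

    Only QC-passing (non-excluded) compounds enter.
    """
    sub = score_table[(score_table["category"] == category)
                      & (~score_table["qc_autofluorescent"])]
    if len(sub) < min_n:
        raise ValueError(
            f"category {category!r} has only {len(sub)} QC-passing compounds "
            f"(need at least {min_n})")
    return spearman(sub["confluency_score"].to_numpy(),
                    sub["gfp_score"].to_numpy())


# ---------------------------------------------------------------------------
# pipeline

def _well_series(df: pd.DataFrame, metric: str) -> pd.Series:
    s = df.set_index("time_h")[metric].sort_index()
    return s


def score_screen(timeseries: pd.DataFrame, platemap: pd.DataFrame,
                 library: pd.DataFrame,
                 config: ScoringConfig | None = None) -> pd.DataFrame:
    """Score every compound well of a screen against its plate's controls.

    Parameters are the long-format well time series (plate, well, time_h,
    confluence_pct, gfp_mean_gcu), the plate map (plate, well, role,
    compound_id) and the library table (compound_id, category).  Returns one
    row per compound with both scores, the QC flag and the hit class.
    """
    config = config or ScoringConfig()
    merged = timeseries.merge(platemap, on=["plate", "well"], how="left")
    if merged["role"].isna().any():
        bad = merged[merged["role"].isna()][["plate", "well"]].iloc[0]
        raise ValueError(f"well {bad['plate']}/{bad['well']} missing from plate map")
    categories = library.set_index("compound_id")["category"]

    rows = []
    for plate, plate_df in merged.groupby("plate", sort=True):
        ctrl_gfp = control_mean_series(plate_df, "dmso_control", "gfp_mean_gcu")
        ctrl_conf = control_mean_series(plate_df, "dmso_control", "confluence_pct")
        cmp_df = plate_df[plate_df["role"] == "compound"]
        for (well, cid), well_df in cmp_df.groupby(["well", "compound_id"], sort=True):
            gfp_fc = fold_change_series(_well_series(well_df, "gfp_mean_gcu"),
                                        ctrl_gfp, config.control_floor_gcu)
            conf_fc = fold_change_series(_well_series(well_df, "confluence_pct"),
                                         ctrl_conf,
                                         config.control_floor_confluence_pct)
            excluded = autofluorescence_qc(gfp_fc, config)
            g = gfp_score(gfp_fc, config)
            c = confluency_score(conf_fc)
            rows.append((cid, categories.get(cid, "unknown"), plate, well,
                         g, c, excluded,
                         classify(g, c, excluded, config)))
    return pd.DataFrame(rows, columns=[
        "compound_id", "category", "plate", "well", "gfp_score",
        "confluency_score", "qc_autofluorescent", "hit_class",
    ]).sort_values("compound_id", ignore_index=True)


def correlation_table(score_table: pd.DataFrame, min_n: int = 4) -> pd.DataFrame:
    """Per-category Spearman(confluency, GFP) for all scorable categories."""
    rows = []
    for cat in sorted(score_table["category"].unique()):
        try:
            rho, p, n = category_correlation(score_table, cat, min_n=min_n)
        except ValueError:
            continue
        rows.append((cat, rho, p, n))
    return pd.DataFrame(rows, columns=["category", "rho", "p", "n"])
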
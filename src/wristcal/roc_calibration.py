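"""Cut-point derivation: ROC analysis of sedentary vs light-intensity counts.

A cut-point is the count threshold separating sedentary from
light-or-above epochs.  Following the calibration design, the ROC contrasts
walking (the light-intensity positive class) against the single seated
activity producing the highest counts — any threshold that separates the
most active seated behavior from walking necessarily classifies the quieter
seated behaviors as sedentary.  Children are split once into calibration
and validation sets; within the calibration children a k-fold (default 10)
procedure derives a Youden-optimal threshold on the training folds and
evaluates it on the held-out fold, and the per-fold thresholds and metrics
are averaged.  All splitting happens at the child level, never the epoch
level, to respect within-child clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .epoch_io import add_vector_magnitude

__all__ = [
    "PUBLISHED_CUTPOINTS",
    "SIGNALS",
    "CalibrationConfig",
    "FoldResult",
    "CutpointResult",
    "select_reference_activity",
    "youden_cutpoint",
    "roc_auc",
    "calibrate",
    "calibrate_all",
]

SIGNALS = ("axis1", "axis2", "axis3", "vm")

#: published wrist cut-points (counts/5 s) for 5-11-year-old children,
#: keyed by (signal, wrist); usable directly by the sedentary summary
PUBLISHED_CUTPOINTS: dict[tuple[str, str], float] = {
    ("axis1", "non_dominant"): 203,
    ("axis1", "dominant"): 229,
    ("axis2", "non_dominant"): 200,
    ("axis2", "dominant"): 220,
    ("axis3", "non_dominant"): 201,
    ("axis3", "dominant"): 219,
    ("vm", "non_dominant"): 397,
    ("vm", "dominant"): 428,
}


@dataclass(frozen=True)
class CalibrationConfig:
    """Settings for the calibration / cross-validation procedure.

    ``calibration_fraction`` defaults to 100/167, the published split of
    children between the calibration and held-out validation samples.
    ``mode`` selects k-fold cross-validation ("cv", default) or k
    independent Monte Carlo repeats ("repeats"); ``fold_eval`` selects
    whether per-fold metrics are measured on the held-out fold
    ("held_out", default) or reported as returned by the threshold search
    on the training folds ("train").
    """

    k: int = 10
    calibration_fraction: float = 100 / 167
    seed: int = 0
    signals: tuple[str, ...] = SIGNALS
    mode: str = "cv"
    fold_eval: str = "held_out"
    pooled_sedentary: bool = False
    validation_bootstrap_B: int = 200

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0.0 < self.calibration_fraction < 1.0:
            raise ValueError("calibration_fraction must be in (0, 1)")
        if self.mode not in ("cv", "repeats"):
            raise ValueError("mode must be 'cv' or 'repeats'")
        if self.fold_eval not in ("held_out", "train"):
            raise ValueError("fold_eval must be 'held_out' or 'train'")
        if any(s not in SIGNALS for s in self.signals):
            raise ValueError(f"signals must be a subset of {SIGNALS}")


@dataclass(frozen=True)
class FoldResult:
    fold_id: int
    cutpoint: float
    sensitivity: float
    specificity: float
    auc: float


@dataclass(frozen=True)
class CutpointResult:
    signal: str
    wrist: str
    reference_activity: str
    cutpoint: float
    cutpoint_int: int
    sensitivity: float
    specificity: float
    auc_calibration: float
    auc_calibration_ci: tuple[float, float]
    auc_validation: float
    auc_validation_ci: tuple[float, float]
    sensitivity_validation: float
    specificity_validation: float
    folds: tuple[FoldResult, ...] = field(default_factory=tuple)


def _ensure_signal(epochs: pd.DataFrame, signal: str) -> pd.DataFrame:
    if signal == "vm" and "vm" not in epochs.columns:
        return add_vector_magnitude(epochs)
    return epochs


def select_reference_activity(
    epochs: pd.DataFrame, signal: str, wrist: str
) -> str:
    """Seated activity with the highest median of ``signal`` on ``wrist``.

    Ties are broken by the higher 75th percentile, then lexicographically.
    """
    epochs = _ensure_signal(epochs, signal)
    sub = epochs[(epochs["posture"] == "seated") & (epochs["wrist"] == wrist)]
    if sub.empty:
        raise ValueError("no seated activities present")
    stats = (
        sub.groupby("activity")[signal]
        .agg(median="median", q75=lambda v: v.quantile(0.75))
        .reset_index()
    )
    stats = stats.sort_values(
        ["median", "q75", "activity"], ascending=[False, False, True]
    )
    return str(stats["activity"].iloc[0])


def youden_cutpoint(
    sedentary_counts, light_counts
) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity (the Youden criterion).

    Classification rule: count >= threshold -> light, count < threshold ->
    sedentary.  Sensitivity is the percentage of light epochs at or above
    the threshold; specificity the percentage of sedentary epochs below it.
    Candidates are all distinct observed values plus one past the maximum;
    ties go to the smallest threshold.

    Returns (threshold, sensitivity %, specificity %).
    """
    sed = np.sort(np.asarray(sedentary_counts, dtype=float))
    light = np.sort(np.asarray(light_counts, dtype=float))
    if sed.size == 0 or light.size == 0:
        raise ValueError("both classes must be non-empty")
    cand = np.unique(np.concatenate([sed, light]))
    cand = np.append(cand, cand[-1] + 1.0)
    n_light_ge = light.size - np.searchsorted(light, cand, side="left")
    n_sed_lt = np.searchsorted(sed, cand, side="left")
    # exact integer score proportional to sensitivity + specificity, so ties
    # are broken deterministically (argmax -> first max -> smallest threshold)
    score = n_light_ge * sed.size + n_sed_lt * light.size
    best = int(np.argmax(score))
    sens = 100.0 * n_light_ge[best] / light.size
    spec = 100.0 * n_sed_lt[best] / sed.size
    return float(cand[best]), float(sens), float(spec)


def roc_auc(sedentary_counts, light_counts) -> float:
    """Probability a random light epoch outranks a random sedentary epoch,
    ties counted half — the rank-statistic (Mann-Whitney) form of the area
    under the empirical ROC curve."""
    sed = np.asarray(sedentary_counts, dtype=float)
    light = np.asarray(light_counts, dtype=float)
    if sed.size == 0 or light.size == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(np.concatenate([light, sed]))
    r_light = ranks[: light.size].sum()
    return float(
        (r_light - light.size * (light.size + 1) / 2.0) / (light.size * sed.size)
    )


def _sens_spec_at(threshold: float, sed: np.ndarray, light: np.ndarray
                  ) -> tuple[float, float]:
    sens = 100.0 * float(np.mean(light >= threshold))
    spec = 100.0 * float(np.mean(sed < threshold))
    return sens, spec


def _concat(blocks: dict[str, np.ndarray], children) -> np.ndarray:
    parts = [blocks[c] for c in children if blocks[c].size]
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


def _fold_partitions(
    cal_children: np.ndarray, cfg: CalibrationConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    if cfg.mode == "cv":
        return [f for f in np.array_split(cal_children, cfg.k)]
    m = max(1, int(np.ceil(len(cal_children) / cfg.k)))
    return [
        rng.choice(cal_children, size=m, replace=False) for _ in range(cfg.k)
    ]


def calibrate(
    epochs: pd.DataFrame,
    cfg: CalibrationConfig,
    wrist: str,
    signal: str,
) -> CutpointResult:
    """Derive the cut-point for one signal x wrist with k-fold calibration
    and held-out validation.

    Children are split once into calibration and validation sets (seeded,
    at the child level).  In ``mode="cv"`` the calibration children are
    partitioned into k folds; each iteration derives the Youden threshold
    on the other folds and evaluates sensitivity, specificity and AUC on
    the held-out fold; thresholds and metrics are averaged across folds.
    The validation AUC is computed on the untouched validation children,
    with a child-level bootstrap CI, and the averaged threshold's
    sensitivity/specificity are reported there as well.
    """
    epochs = _ensure_signal(epochs, signal)
    sub = epochs[epochs["wrist"] == wrist]
    if cfg.pooled_sedentary:
        reference = "all seated"
        sed_df = sub[sub["posture"] == "seated"]
    else:
        reference = select_reference_activity(epochs, signal, wrist)
        sed_df = sub[sub["activity"] == reference]
    light_df = sub[sub["posture"] == "walking"]
    if sed_df.empty or light_df.empty:
        raise ValueError("need non-empty sedentary and light classes")

    children = np.array(
        sorted(set(sed_df["child_id"]) | set(light_df["child_id"]))
    )
    sed_blocks = {
        c: sed_df.loc[sed_df["child_id"] == c, signal].to_numpy(dtype=float)
        for c in children
    }
    light_blocks = {
        c: light_df.loc[light_df["child_id"] == c, signal].to_numpy(dtype=float)
        for c in children
    }

    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(children)
    n_cal = int(round(cfg.calibration_fraction * len(children)))
    n_cal = min(max(n_cal, 2), len(children) - 1)
    cal_children, val_children = perm[:n_cal], perm[n_cal:]

    folds: list[FoldResult] = []
    for i, held_out in enumerate(_fold_partitions(cal_children, cfg, rng)):
        train = np.setdiff1d(cal_children, held_out)
        sed_tr, light_tr = _concat(sed_blocks, train), _concat(light_blocks, train)
        sed_ho, light_ho = _concat(sed_blocks, held_out), _concat(light_blocks, held_out)
        if min(sed_tr.size, light_tr.size) == 0 or (
            cfg.fold_eval == "held_out" and min(sed_ho.size, light_ho.size) == 0
        ):
            warnings.warn(f"fold {i}: a class is empty; fold skipped", stacklevel=2)
            continue
        thr, sens_tr, spec_tr = youden_cutpoint(sed_tr, light_tr)
        if cfg.fold_eval == "held_out":
            sens, spec = _sens_spec_at(thr, sed_ho, light_ho)
            auc = roc_auc(sed_ho, light_ho)
        else:
            sens, spec = sens_tr, spec_tr
            auc = roc_auc(sed_tr, light_tr)
        folds.append(FoldResult(i, thr, sens, spec, auc))
    if not folds:
        raise ValueError("every fold was skipped: a class is missing throughout")

    cut = float(np.mean([f.cutpoint for f in folds]))
    sens = float(np.mean([f.sensitivity for f in folds]))
    spec = float(np.mean([f.specificity for f in folds]))
    aucs = np.array([f.auc for f in folds])
    auc_cal = float(aucs.mean())
    if len(aucs) > 1:
        half = 1.96 * aucs.std(ddof=1) / np.sqrt(len(aucs))
    else:
        half = 0.0
    auc_cal_ci = (auc_cal - half, auc_cal + half)

    sed_val = _concat(sed_blocks, val_children)
    light_val = _concat(light_blocks, val_children)
    if min(sed_val.size, light_val.size) == 0:
        raise ValueError("validation set lacks one of the classes")
    auc_val = roc_auc(sed_val, light_val)
    sens_val, spec_val = _sens_spec_at(cut, sed_val, light_val)
    boot = np.empty(cfg.validation_bootstrap_B)
    for b in range(cfg.validation_bootstrap_B):
        idx = rng.integers(0, len(val_children), size=len(val_children))
        draw = val_children[idx]
        s, l = _concat(sed_blocks, draw), _concat(light_blocks, draw)
        boot[b] = roc_auc(s, l) if min(s.size, l.size) else np.nan
    boot = boot[~np.isnan(boot)]
    auc_val_ci = tuple(float(x) for x in np.percentile(boot, [2.5, 97.5]))

    return CutpointResult(
        signal=signal,
        wrist=wrist,
        reference_activity=reference,
        cutpoint=cut,
        cutpoint_int=int(round(cut)),
        sensitivity=sens,
        specificity=spec,
        auc_calibration=auc_cal,
        auc_calibration_ci=auc_cal_ci,
        auc_validation=auc_val,
        auc_validation_ci=auc_val_ci,
        sensitivity_validation=sens_val,
        specificity_validation=spec_val,
        folds=tuple(folds),
    )


def calibrate_all(
    epochs: pd.DataFrame,
    cfg: CalibrationConfig,
    wrists: tuple[str, ...] = ("non_dominant", "dominant"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cut-points for every wrist x signal; returns (summary, per-fold) tables."""
    epochs = _ensure_signal(epochs, "vm")
    rows, fold_rows = [], []
    for wrist in wrists:
        for signal in cfg.signals:
            res = calibrate(epochs, cfg, wrist, signal)
            rows.append(
                {
                    "wrist": wrist,
                    "signal": signal,
                    "reference_activity": res.reference_activity,
                    "cutpoint": res.cutpoint,
                    "cutpoint_int": res.cutpoint_int,
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                    "auc_calibration": res.auc_calibration,
                    "auc_calibration_ci_low": res.auc_calibration_ci[0],
                    "auc_calibration_ci_high": res.auc_calibration_ci[1],
                    "auc_validation": res.auc_validation,
                    "auc_validation_ci_low": res.auc_validation_ci[0],
                    "auc_validation_ci_high": res.auc_validation_ci[1],
                    "sensitivity_validation": res.sensitivity_validation,
                    "specificity_validation": res.specificity_validation,
                }
            )
            for f in res.folds:
                fold_rows.append(
                    {
                        "wrist": wrist,
                        "signal": signal,
                        "fold_id": f.fold_id,
                        "cutpoint": f.cutpoint,
                        "sensitivity": f.sensitivity,
                        "specificity": f.specificity,
                        "auc": f.auc,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(fold_rows)
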
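"""Apply a cut-point to an epoch stream and summarize sedentary time.

Every epoch is classified: counts below the cut-point are sedentary,
counts at or above it are light-or-above (the boundary convention matches
the threshold search, where the threshold is the smallest count classified
as light).  Minutes follow from the 5-s epoch length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IntensitySummary", "classify_epochs", "summarize"]

SEDENTARY = "sedentary"
LIGHT_PLUS = "light_plus"


@dataclass(frozen=True)
class IntensitySummary:
    minutes_sedentary: float
    minutes_light_plus: float
    total_minutes: float
    epochs_classified: int


def classify_epochs(series, cutpoint: float) -> np.ndarray:
    """Label each epoch sedentary (< cutpoint) or light_plus (>= cutpoint)."""
    if cutpoint <= 0:
        raise ValueError("cutpoint must be > 0")
    arr = np.asarray(series, dtype=float)
    return np.where(arr >= cutpoint, LIGHT_PLUS, SEDENTARY)


def summarize(labels, epoch_seconds: float = 5.0) -> IntensitySummary:
    """Minutes in each intensity class; sedentary + light always sums to total."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("no classified epochs to summarize")
    n_sed = int(np.sum(labels == SEDENTARY))
    factor = epoch_seconds / 60.0
    total = labels.size * factor
    sed_min = n_sed * factor
    # light minutes derived by subtraction so conservation is exact in
    # floating point, not just up to rounding of two independent products
    return IntensitySummary(
        minutes_sedentary=sed_min,
        minutes_light_plus=total - sed_min,
        total_minutes=total,
        epochs_classified=int(labels.size),
    )
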
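"""Reference activity profiles for the 5-11-year-old calibration cohort.

The quantile targets are the published per-activity descriptive statistics
(median and interquartile range of axis-1 counts per 5-s epoch, by wrist)
from the wrist-placement calibration study this package re-implements:
eight seated sedentary activities plus researcher-paced slow walking as the
light-intensity contrast.  The copula correlation is 0.95 for walking (both
wrists swing together) and 0.5 for seated activities, where hands move much
more independently.
"""

from __future__ import annotations

from .synthetic_data import SEATED, WALKING, ActivityProfile, WristQuantiles

__all__ = ["reference_profiles", "WALKING_ACTIVITY"]

WALKING_ACTIVITY = "Walking"

# (name, posture, dominant (q25, q50, q75), non-dominant (q25, q50, q75))
_ROWS = [
    ("TV", SEATED, (0, 0, 2), (0, 0, 0)),
    ("Tablets", SEATED, (0, 14, 66), (0, 0, 40)),
    ("Writing", SEATED, (0, 7, 65), (0, 0, 42)),
    ("Snack", SEATED, (0, 20, 93), (0, 12, 80)),
    ("Reading Books", SEATED, (0, 36, 142), (0, 35, 137)),
    ("Board Games", SEATED, (29, 129, 246), (0, 83, 210)),
    ("Cards", SEATED, (22, 106, 219), (8, 74, 176)),
    ("Cut/paste", SEATED, (21, 85, 171), (8, 68, 158)),
    (WALKING_ACTIVITY, WALKING, (193, 357, 607), (195, 357, 602)),
]


def reference_profiles() -> tuple[ActivityProfile, ...]:
    """The nine study activities with published quantile targets."""
    return tuple(
        ActivityProfile(
            name=name,
            posture=posture,
            dominant=WristQuantiles(*dom),
            non_dominant=WristQuantiles(*nd),
            rho=0.95 if posture == WALKING else 0.5,
        )
        for name, posture, dom, nd in _ROWS
    )
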
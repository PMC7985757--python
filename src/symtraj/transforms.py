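"""Box-Cox transform of the total symptom distress score (TSDS).

The raw TSDS (sum of the nine ESAS item scores, 0-90) is strongly
right-skewed; the analysis models a shifted one-parameter Box-Cox
transform with lambda = 0.25,

    f(x) = ((x + 1)**0.25 - 1) / 0.25,

where the +1 shift keeps the argument positive at x = 0.  The transform
is strictly increasing, maps 0 -> 0, 15 -> 4, 80 -> 8, and maps the
full 0-90 range onto [0, ~8.355].
"""

from __future__ import annotations

import numpy as np

LAMBDA = 0.25
SHIFT = 1.0

__all__ = [
    "LAMBDA",
    "SHIFT",
    "TSDS_MAX",
    "TRANSFORMED_MAX",
    "boxcox_transform",
    "boxcox_inverse",
]

TSDS_MAX = 90.0


def boxcox_transform(x):
    """Transform raw TSDS values (0-90) to the modeling scale.

    Accepts scalars or arrays.  Raises ``ValueError`` on negative input;
    NaN passes through (missing stays missing).
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("TSDS must be non-negative")
    out = ((arr + SHIFT) ** LAMBDA - 1.0) / LAMBDA
    return out if arr.ndim else float(out)


def boxcox_inverse(y):
    """Inverse of :func:`boxcox_transform` (transformed scale -> raw TSDS)."""
    arr = np.asarray(y, dtype=float)
    out = (LAMBDA * arr + 1.0) ** (1.0 / LAMBDA) - SHIFT
    return out if arr.ndim else float(out)


TRANSFORMED_MAX = boxcox_transform(TSDS_MAX)
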
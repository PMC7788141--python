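"""Routine count-rate distributions.

Singles rates sampled every 500 ms during patient exams are pooled per
(tracer, camera) group and summarised as box-plot statistics.  The upper and
lower limits of a group are the extrema after removing outliers; the
published outlier phrasing is ambiguous, so both readings are available:

* ``"tukey"`` (default): the conventional box-plot fences
  Q1 - 1.5*IQR and Q3 + 1.5*IQR;
* ``"quartile_scaled"``: literal 1.5-fold quartile thresholds,
  Q1 / 1.5 and Q3 * 1.5.

Rate limits are converted to NEMA-phantom-equivalent activity concentrations
through a camera's inverse rate model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError
from .presets import CameraPreset
from .ratemodel import predict


@dataclass
class RateDistribution:
    labels: dict = field(default_factory=dict)   # e.g. {"tracer": ..., "camera": ...}
    samples_mcps: np.ndarray | None = None
    median: float = float("nan")
    q1: float = float("nan")
    q3: float = float("nan")
    lower_limit: float = float("nan")            # min after outlier removal
    upper_limit: float = float("nan")            # max after outlier removal
    n_samples: int = 0
    n_outliers: int = 0


def summarize_rates(
    samples: Sequence[float],
    labels: dict | None = None,
    fence: str = "tukey",
) -> RateDistribution:
    """Box-plot summary of a pooled singles-rate sample.

    Quartiles use the standard linear-interpolation definition; the limits
    are the extrema of the samples surviving the outlier fences.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 4:
        raise DomainError("need at least 4 samples for a box-plot summary")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    if fence == "tukey":
        iqr = q3 - q1
        lo_f, hi_f = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    elif fence == "quartile_scaled":
        lo_f, hi_f = q1 / 1.5, q3 * 1.5
    else:
        raise DomainError(f"unknown fence rule {fence!r}")
    keep = (x >= lo_f) & (x <= hi_f)
    kept = x[keep]
    return RateDistribution(
        labels=dict(labels or {}),
        samples_mcps=x,
        median=float(med), q1=float(q1), q3=float(q3),
        lower_limit=float(kept.min()), upper_limit=float(kept.max()),
        n_samples=int(x.size), n_outliers=int(x.size - kept.size),
    )


def limits_to_activity(
    dist: RateDistribution, preset: CameraPreset
) -> tuple[float, float]:
    """Phantom-equivalent activity concentrations (kBq/mL) of the rate limits."""
    lo = float(predict(preset.inverse_rate_model, dist.lower_limit))
    hi = float(predict(preset.inverse_rate_model, dist.upper_limit))
    return lo, hi
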
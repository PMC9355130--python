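"""Piecewise-constant age-scale hazard model.

The breast-cancer onset model is a piecewise-exponential distribution on the
age scale: within each age band the hazard is constant, and a carrier group's
hazard is the non-carrier baseline multiplied by a proportional hazard ratio.
The published calibration anchors are cumulative incidences, not hazards, so
the baseline is specified as decade-band *weights* and rescaled once so that
the non-carrier cumulative incidence at a target age matches the configured
anchor (default 4.3% by age 70).
"""

from __future__ import annotations

import math

import numpy as np

#: Relative per-year hazard by decade band, reflecting the age profile of
#: female breast-cancer incidence (near zero before 30, rising to a plateau).
DEFAULT_BAND_WEIGHTS: tuple[tuple[float, float, float], ...] = (
    (0.0, 30.0, 0.02),
    (30.0, 40.0, 0.5),
    (40.0, 50.0, 1.0),
    (50.0, 60.0, 1.3),
    (60.0, 70.0, 1.5),
    (70.0, 80.0, 1.6),
    (80.0, 100.0, 1.6),
)


def validate_bands(bands) -> np.ndarray:
    """Check bands are contiguous from 0 to >=100 with non-negative rates."""
    arr = np.asarray(bands, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("bands must be (lo, hi, rate) triples")
    if arr[0, 0] != 0.0:
        raise ValueError("hazard bands must start at age 0")
    if not np.all(arr[1:, 0] == arr[:-1, 1]):
        raise ValueError("hazard bands must be contiguous")
    if arr[-1, 1] < 100.0:
        raise ValueError("hazard bands must cover ages 0-100")
    if np.any(arr[:, 2] < 0):
        raise ValueError("hazard rates must be non-negative")
    return arr


def cumulative_hazard(bands, ages) -> np.ndarray:
    """Integrated baseline hazard H(a) for each age."""
    arr = validate_bands(bands)
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    widths = arr[:, 1] - arr[:, 0]
    cum = np.concatenate([[0.0], np.cumsum(widths * arr[:, 2])])
    k = np.clip(np.searchsorted(arr[:, 1], ages, side="left"), 0, len(arr) - 1)
    return cum[k] + np.clip(ages - arr[k, 0], 0.0, None) * arr[k, 2]


def inverse_cumulative_hazard(bands, h) -> np.ndarray:
    """Smallest age a with H(a) >= h; +inf when h exceeds the total mass."""
    arr = validate_bands(bands)
    h = np.atleast_1d(np.asarray(h, dtype=float))
    widths = arr[:, 1] - arr[:, 0]
    cum = np.concatenate([[0.0], np.cumsum(widths * arr[:, 2])])
    k = np.clip(np.searchsorted(cum[1:], h, side="left"), 0, len(arr) - 1)
    rate = arr[k, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ages = arr[k, 0] + (h - cum[k]) / rate
    # zero-rate stretch: the mass resumes at the end of the flat band
    flat = rate == 0
    ages[flat] = np.where(h[flat] > cum[k[flat]], arr[k[flat], 1], arr[k[flat], 0])
    ages[h > cum[-1]] = np.inf
    return ages


def closed_form_incidence(bands, hr: float, age: float) -> float:
    """Exact cumulative incidence 1 - exp(-hr * H(age)) of the model."""
    return float(1.0 - math.exp(-hr * cumulative_hazard(bands, [age])[0]))


def calibrate_baseline(
    target_incidence: float = 0.043,
    target_age: float = 70.0,
    weights=DEFAULT_BAND_WEIGHTS,
) -> tuple[tuple[float, float, float], ...]:
    """Rescale band weights so baseline incidence at ``target_age`` hits the anchor."""
    arr = validate_bands(weights)
    h_at_target = cumulative_hazard(arr, [target_age])[0]
    if h_at_target <= 0:
        raise ValueError("weights carry no hazard mass before the target age")
    scale = -math.log(1.0 - target_incidence) / h_at_target
    return tuple((float(lo), float(hi), float(r * scale)) for lo, hi, r in arr)


def sample_event_ages(bands, hr: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw event ages by inversion from S(t) = exp(-hr * H(t)).

    Ages beyond the band coverage come back as +inf (no event in lifetime).
    """
    if hr < 0:
        raise ValueError("hazard ratio must be non-negative")
    u = rng.uniform(size=n)
    if hr == 0:
        return np.full(n, np.inf)
    return inverse_cumulative_hazard(bands, -np.log(u) / hr)
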
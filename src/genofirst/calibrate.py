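"""One-time calibration of the synthetic-cohort family-history severity.

The generator's two severity scales are set so that, among synthetic
carriers, the base family-history testing criteria detect about one third
of carriers and the adjusted criteria slightly more than half — the
operating point the screening analysis targets:

* ``fh_breast_scale`` multiplies relatives' breast/ovarian cancer hazards
  and drives the base-criteria detection rate;
* ``fh_adjacent_scale`` multiplies relatives' prostate/pancreatic rates and
  drives the adjusted-criteria increment.

``scripts/calibrate_fh.py`` runs this and prints the scales frozen into
``CohortConfig`` defaults.
"""

from __future__ import annotations

import dataclasses

from .config import CohortConfig
from .reporting import fh_detection_rates


def _rates(config: CohortConfig, n_probands: int, seed: int) -> tuple[float, float]:
    det = fh_detection_rates(seed, n_probands=n_probands, config=config)
    return det["base"]["rate"], det["adjusted"]["rate"]


def _bisect(f, lo: float, hi: float, target: float, iters: int = 12) -> float:
    """Find x with f(x) ~ target for monotone-increasing f, by bisection."""
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_fh_severity(
    target_base: float = 0.33,
    target_adjusted: float = 0.53,
    n_probands: int = 4000,
    seed: int = 20180,
    config: CohortConfig | None = None,
) -> dict:
    """Return calibrated (fh_breast_scale, fh_adjacent_scale) and the rates.

    The breast/ovarian scale is solved first against the base criteria
    (which prostate/pancreatic events cannot fire), then the adjacent-cancer
    scale is solved against the adjusted criteria with the first scale held
    fixed.
    """
    base_cfg = config or CohortConfig()

    def with_scales(breast: float, adjacent: float) -> CohortConfig:
        return dataclasses.replace(
            base_cfg, fh_breast_scale=breast, fh_adjacent_scale=adjacent
        )

    breast = _bisect(
        lambda s: _rates(with_scales(s, 0.0), n_probands, seed)[0],
        0.05, 3.0, target_base,
    )
    adjacent = _bisect(
        lambda s: _rates(with_scales(breast, s), n_probands, seed)[1],
        0.0, 4.0, target_adjusted,
    )
    base_rate, adj_rate = _rates(with_scales(breast, adjacent), n_probands, seed)
    return {
        "fh_breast_scale": round(breast, 3),
        "fh_adjacent_scale": round(adjacent, 3),
        "base_rate": base_rate,
        "adjusted_rate": adj_rate,
    }
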
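"""Flask-incubation N₂O production rates and denitrification partitioning.

Soils are incubated under three headspaces: oxic (ambient air), anoxic
(N₂-flushed) and anoxic with 10 vol-% acetylene. Acetylene blocks N₂O
reductase, making N₂O the terminal denitrification product, so the
acetylene treatment measures total denitrification and the difference to
the plain anoxic treatment estimates the N₂ fraction.

Rate conventions follow the incubation design with sampling at days
0, 1, 2, 3 and 6:

* oxic: OLS slope over the first four sampling points (production is
  constant early; the day-6 point may saturate);
* anoxic (± acetylene): the maximum production rate between two
  consecutive sampling points, because net N₂O consumption or steady
  state often follows the initial production phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "IncubationSeries",
    "ProductionRates",
    "oxic_rate",
    "anoxic_max_rate",
    "denit_partition",
    "fold_change",
]

DEFAULT_SAMPLING_DAYS = (0.0, 1.0, 2.0, 3.0, 6.0)


@dataclass
class IncubationSeries:
    """Headspace N₂O amount (μg N per flask) over time for one flask."""

    times: np.ndarray  # days
    headspace_n2o: np.ndarray  # μg N per flask
    soil_dw: float  # kg dry soil in the flask
    treatment: str = "oxic"  # oxic | anoxic | anoxic_c2h2
    amendment: str = "none"  # control | C | C_NO3 | none
    flask_id: str = ""
    surface_class: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.headspace_n2o = np.asarray(self.headspace_n2o, dtype=float)
        if self.times.size != self.headspace_n2o.size:
            raise ValueError("times and headspace_n2o must have equal length")
        if self.times.size < 3:
            raise ValueError("need at least 3 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.soil_dw <= 0:
            raise ValueError("soil_dw must be positive")


@dataclass
class ProductionRates:
    """Per-soil summary across the three headspace treatments."""

    oxic_rate: float  # μg N kg-1 DW d-1
    anoxic_max_rate: float
    denit_total: float  # rate under acetylene = total denitrification
    n2_rate: float  # denit_total - anoxic_max_rate, floored at 0
    n2o_to_total_ratio: float  # anoxic / total, in [0, 1] when total > 0


def oxic_rate(series: IncubationSeries, n_points: int = 4) -> float:
    """Constant production rate: OLS slope over the first ``n_points`` samples,
    normalized by dry soil mass (μg N kg⁻¹ DW d⁻¹)."""
    if series.times.size < n_points:
        raise ValueError(f"need at least {n_points} points for the linear fit")
    t = series.times[:n_points]
    y = series.headspace_n2o[:n_points]
    slope = np.polyfit(t, y, 1)[0]
    return float(slope) / series.soil_dw


def anoxic_max_rate(series: IncubationSeries) -> tuple[float, bool]:
    """Maximum N₂O production rate between two consecutive sampling points.

    Returns ``(rate, declining)``: the rate is negative (and ``declining``
    True) when the series falls over every interval, i.e. net N₂O
    consumption dominated throughout. Negative rates are reported, not
    zeroed — they carry information about N₂O reduction to N₂.
    """
    if series.times.size < 2:
        raise ValueError("need at least 2 points")
    rates = np.diff(series.headspace_n2o) / np.diff(series.times) / series.soil_dw
    best = float(rates.max())
    return best, best < 0


def denit_partition(anoxic: float, with_c2h2: float) -> tuple[float, Optional[float]]:
    """Partition denitrification products from the acetylene-block contrast.

    ``with_c2h2`` is total denitrification (N₂O + N₂); ``anoxic`` is the
    N₂O fraction. Returns ``(n2_rate, ratio)`` where n2_rate =
    max(0, with_c2h2 − anoxic) and ratio = with_c2h2/anoxic, or None when
    the anoxic rate is non-positive (ratio undefined).
    """
    n2 = max(0.0, with_c2h2 - anoxic)
    ratio = with_c2h2 / anoxic if anoxic > 0 else None
    return n2, ratio


def fold_change(treated: float, control: float) -> Optional[float]:
    """Amendment response as a ratio; None (undefined) when control ≤ 0."""
    if control <= 0:
        return None
    return treated / control


def production_rates(
    oxic: IncubationSeries,
    anoxic: IncubationSeries,
    c2h2: IncubationSeries,
) -> ProductionRates:
    """Full per-soil rate summary from the three matched treatment flasks."""
    ox = oxic_rate(oxic)
    an, _ = anoxic_max_rate(anoxic)
    total, _ = anoxic_max_rate(c2h2)
    n2, _ = denit_partition(an, total)
    ratio = an / total if total > 0 else float("nan")
    return ProductionRates(
        oxic_rate=ox,
        anoxic_max_rate=an,
        denit_total=total,
        n2_rate=n2,
        n2o_to_total_ratio=ratio,
    )
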
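"""The four lodging-resistance statistics of the wind-machine framework.

* ``reduction_index`` — RI_s = 1 - u1/u0, the fractional reduction of wind
  speed behind the canopy relative to the machine outlet;
* ``failure_wind_speed`` — FWS, the weighted L1 median of the lodging
  distribution: argmin over s in (0, S_m] of sum_v p(v) |v - s|;
* ``lodging_resistance`` — LR(s) = 1 / (1 + integral_0^s p(v) dv), a
  piecewise-constant, non-increasing curve bounded in [0.5, 1];
* ``cumulative_lodging_index`` — CLI = integral_0^{S_m} LR(s) ds / S_m,
  the normalised area under the resistance curve (1 = fully resistant up to
  the machine maximum, 0.5 = everything lodges immediately).

The lodging distribution is discrete (mass only at generated levels), so the
integral in LR is the cumulative mass at speeds <= s, and the CLI integral of
the resulting step function is evaluated in closed form. Plants that never
lodged (the censored mass) represent survival beyond S_m: they never enter
LR or CLI, and they enter the FWS objective at a pseudo-speed one schedule
step above S_m so that a majority-censored cultivar is reported as censored
("> S_m") rather than assigned an unobservable speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .trial_data import (
    CANOPY_LAYERS,
    AnemometerRecord,
    FWSResult,
    Layer,
    LodgingDistribution,
    ValidationError,
    WindSchedule,
)

__all__ = [
    "ReductionIndexResult",
    "LodgingResistanceCurve",
    "reduction_index",
    "aggregate_reduction_index",
    "cumulative_lodged_fraction",
    "lodging_resistance",
    "lodging_resistance_curve",
    "failure_wind_speed",
    "cumulative_lodging_index",
]

#: Pseudo-speed offset for the censored mass in the FWS objective, m s^-1.
#: One fine schedule step above the machine maximum.
CENSOR_SPEED_OFFSET = 2.0

#: Default spacing of the FWS candidate grid, m s^-1.
DEFAULT_FWS_RESOLUTION = 1.0


@dataclass(frozen=True)
class ReductionIndexResult:
    """RI at one generated level and layer.

    ``negative_flagged`` marks the physically surprising case of the mean
    downstream speed exceeding the outlet speed (gusts can do this
    transiently); the negative value is reported, not clamped.
    """

    generated_speed: float
    layer: Layer
    ri: float

    @property
    def negative_flagged(self) -> bool:
        return self.ri < 0


def reduction_index(u0_mean: float, u1_mean: float) -> float:
    """RI = 1 - u1/u0 for mean outlet speed u0 and mean downstream speed u1."""
    if u0_mean <= 0:
        raise ValidationError(f"outlet mean speed must be > 0, got {u0_mean}")
    if u1_mean < 0:
        raise ValidationError(f"downstream mean speed must be >= 0, got {u1_mean}")
    return 1.0 - u1_mean / u0_mean


def aggregate_reduction_index(
    outlet: Iterable[AnemometerRecord],
    downstream: Iterable[AnemometerRecord],
    layer: Layer,
    schedule: WindSchedule,
) -> list[ReductionIndexResult]:
    """Per-level RI from raw anemometer logs.

    For each schedule level, u0 is the time mean of outlet samples within the
    level's hold window and u1 the time-and-station mean of downstream samples
    at ``layer`` in the same window. An empty window is an error naming the
    level.
    """
    if layer not in CANOPY_LAYERS:
        raise ValidationError(f"layer must be a canopy layer, got {layer}")
    outlet = [r for r in outlet if r.layer is Layer.OUTLET]
    down = [r for r in downstream if r.layer is layer]
    results = []
    for start, end, level in schedule.hold_windows():
        u0 = [r.speed for r in outlet if start <= r.time < end]
        u1 = [r.speed for r in down if start <= r.time < end]
        if not u0:
            raise ValidationError(
                f"no outlet records in hold window of level {level.speed} m/s"
            )
        if not u1:
            raise ValidationError(
                f"no downstream {layer.value} records in hold window of "
                f"level {level.speed} m/s"
            )
        ri = reduction_index(math.fsum(u0) / len(u0), math.fsum(u1) / len(u1))
        results.append(
            ReductionIndexResult(generated_speed=level.speed, layer=layer, ri=ri)
        )
    return results


def cumulative_lodged_fraction(dist: LodgingDistribution, s: float) -> float:
    """Cumulative lodged fraction at speeds <= s; censored mass never counts."""
    if s < 0 or s > dist.s_max:
        raise ValidationError(f"s must lie in [0, s_max={dist.s_max}], got {s}")
    return math.fsum(p for v, p in dist.bins if v <= s)


def lodging_resistance(dist: LodgingDistribution, s: float) -> float:
    """LR(s) = 1 / (1 + cumulative lodged fraction at s); in [0.5, 1]."""
    return 1.0 / (1.0 + cumulative_lodged_fraction(dist, s))


@dataclass(frozen=True)
class LodgingResistanceCurve:
    """Piecewise-constant, right-continuous LR over (0, s_max].

    ``breakpoints`` are the bin speeds with positive mass; ``values`` has one
    more entry than ``breakpoints``: values[k] applies on
    [breakpoints[k-1], breakpoints[k]) (the first segment starts at 0).
    """

    breakpoints: tuple[float, ...]
    values: tuple[float, ...]
    s_max: float

    def __post_init__(self) -> None:
        if len(self.values) != len(self.breakpoints) + 1:
            raise ValidationError("curve needs len(values) == len(breakpoints) + 1")
        if any(b > a + 1e-12 for a, b in zip(self.values, self.values[1:])):
            raise ValidationError("LR values must be non-increasing")

    def __call__(self, s: float) -> float:
        if s < 0 or s > self.s_max:
            raise ValidationError(f"s must lie in [0, {self.s_max}], got {s}")
        idx = 0
        for bp in self.breakpoints:
            if s >= bp:
                idx += 1
            else:
                break
        return self.values[idx]


def lodging_resistance_curve(dist: LodgingDistribution) -> LodgingResistanceCurve:
    """The full LR step curve; mass at v lowers LR for every s >= v."""
    breakpoints = tuple(v for v, _ in dist.bins)
    values = [1.0]
    cum = 0.0
    for _, p in dist.bins:
        cum += p
        values.append(1.0 / (1.0 + cum))
    return LodgingResistanceCurve(
        breakpoints=breakpoints, values=tuple(values), s_max=dist.s_max
    )


def _fws_candidates(dist: LodgingDistribution, resolution: float) -> np.ndarray:
    if resolution <= 0:
        raise ValidationError(f"candidate resolution must be > 0, got {resolution}")
    n = int(math.floor(dist.s_max / resolution + 1e-9))
    grid = resolution * np.arange(1, n + 1)
    cands = np.unique(
        np.concatenate([grid, [dist.s_max], [v for v, _ in dist.bins]])
    )
    return cands[(cands > 0) & (cands <= dist.s_max)]


def failure_wind_speed(
    dist: LodgingDistribution,
    candidate_resolution: float = DEFAULT_FWS_RESOLUTION,
    censor_offset: float = CENSOR_SPEED_OFFSET,
) -> FWSResult:
    """Weighted L1 median of the lodging distribution.

    Minimises sum_v p(v)|v - s| over candidate speeds s in (0, s_max] on a
    grid of ``candidate_resolution`` spacing augmented with the bin speeds;
    ties go to the smallest minimiser. The censored mass participates at
    pseudo-speed s_max + ``censor_offset``; if the minimising set reaches
    s_max and the censored mass outweighs all observed lodging, the result is
    censored ("> s_max").
    """
    total = dist.bin_mass + dist.censored_mass
    if total <= 0:
        raise ValidationError("distribution has zero total mass")

    speeds = np.array([v for v, _ in dist.bins] + [dist.s_max + censor_offset])
    masses = np.array([p for _, p in dist.bins] + [dist.censored_mass])
    cands = _fws_candidates(dist, candidate_resolution)

    obj = np.abs(cands[:, None] - speeds[None, :]) @ masses
    best = obj.min()
    minimisers = cands[obj <= best + 1e-12]

    at_boundary = bool(np.any(np.isclose(minimisers, dist.s_max)))
    if at_boundary and dist.censored_mass > dist.bin_mass:
        return FWSResult(value=None, s_max=dist.s_max, censored=True)
    return FWSResult(value=float(minimisers[0]), s_max=dist.s_max)


def cumulative_lodging_index(dist: LodgingDistribution) -> float:
    """CLI = closed-form integral of the LR step curve over [0, s_max] / s_max."""
    curve = lodging_resistance_curve(dist)
    edges = (0.0,) + curve.breakpoints + (dist.s_max,)
    area = math.fsum(
        (b - a) * lr for a, b, lr in zip(edges, edges[1:], curve.values)
    )
    return area / dist.s_max
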
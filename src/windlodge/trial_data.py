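"""Domain types, validation and CSV round-trip I/O for wind-machine lodging trials.

Three tables move through the toolkit:

* lodging counts — per cultivar/year, how many plants lodged at each generated
  wind-speed level, plus a right-censored count of plants still standing at the
  machine maximum (written as the literal token ``>Smax``);
* anemometer logs — timestamped wind speed at the machine outlet and at
  stations behind the canopy (three heights);
* cultivar traits — per-cultivar means and standard errors of stalk mechanical
  properties and plant morphology.

Lodging *masses* are stored as fractions in [0, 1] throughout, never 0-100:
the lodging-resistance function LR(s) = 1/(1 + cumulative fraction) is only
bounded in [0.5, 1] under the fraction reading, which is the range the
cumulative lodging index lives in.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

__all__ = [
    "CENSORED",
    "Censored",
    "Layer",
    "WindLevel",
    "WindSchedule",
    "LodgingObservation",
    "LodgingDistribution",
    "AnemometerRecord",
    "TraitRecord",
    "FWSResult",
    "ValidationError",
    "TRAIT_NAMES",
    "TRAIT_CODES",
    "build_distribution",
    "read_lodging_csv",
    "write_lodging_csv",
    "read_anemometer_csv",
    "write_anemometer_csv",
    "read_traits_csv",
    "write_traits_csv",
]

#: Literal token used in lodging CSVs for plants that never lodged.
CENSORED_TOKEN = ">Smax"


class Censored:
    """Singleton marker for a right-censored observation (plant outlasted S_max)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return CENSORED_TOKEN


CENSORED = Censored()

SpeedOrCensored = Union[float, Censored]


class ValidationError(ValueError):
    """Raised when an input table or domain value violates an invariant."""


class Layer(str, enum.Enum):
    """Anemometer station height class; heights are metres above ground."""

    OUTLET = "outlet"
    BOTTOM = "bottom"  # 0.2 m
    MIDDLE = "middle"  # 1.2 m
    TOP = "top"        # 2.2 m

    @property
    def height_m(self) -> float | None:
        return {"bottom": 0.2, "middle": 1.2, "top": 2.2}.get(self.value)


CANOPY_LAYERS = (Layer.BOTTOM, Layer.MIDDLE, Layer.TOP)


@dataclass(frozen=True)
class WindLevel:
    """One step of the generated wind schedule.

    Parameters
    ----------
    speed : float
        Generated wind speed at the machine outlet, m s^-1. Must be > 0.
    hold_duration : float
        Seconds the level is maintained. Must be > 0.
    """

    speed: float
    hold_duration: float

    def __post_init__(self) -> None:
        if not self.speed > 0:
            raise ValidationError(f"wind level speed must be > 0, got {self.speed}")
        if not self.hold_duration > 0:
            raise ValidationError(
                f"hold duration must be > 0, got {self.hold_duration}"
            )


@dataclass(frozen=True)
class WindSchedule:
    """Ordered, strictly increasing sequence of generated wind-speed levels.

    The final level's speed is the machine maximum S_m, the upper bound of
    every index integral. The default machine safety cap is 30 m s^-1.
    """

    levels: tuple[WindLevel, ...]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValidationError("schedule must contain at least one level")
        speeds = [lv.speed for lv in self.levels]
        if any(b <= a for a, b in zip(speeds, speeds[1:])):
            raise ValidationError(f"schedule speeds must be strictly increasing: {speeds}")

    @property
    def max_speed(self) -> float:
        """S_m, the maximum generated speed (m s^-1)."""
        return self.levels[-1].speed

    @property
    def speeds(self) -> tuple[float, ...]:
        return tuple(lv.speed for lv in self.levels)

    def hold_windows(self) -> list[tuple[float, float, WindLevel]]:
        """Consecutive [start, end) time windows (s since forcing start) per level."""
        windows = []
        t = 0.0
        for lv in self.levels:
            windows.append((t, t + lv.hold_duration, lv))
            t += lv.hold_duration
        return windows

    @property
    def total_duration(self) -> float:
        return sum(lv.hold_duration for lv in self.levels)


@dataclass(frozen=True)
class LodgingObservation:
    """Count of plants that lodged at one generated level (or never lodged)."""

    cultivar: str
    year: int
    level_speed: SpeedOrCensored
    lodged_count: int

    def __post_init__(self) -> None:
        if self.lodged_count < 0:
            raise ValidationError(
                f"lodged_count must be >= 0, got {self.lodged_count} "
                f"({self.cultivar}, {self.year})"
            )
        if not isinstance(self.level_speed, Censored) and not self.level_speed > 0:
            raise ValidationError(
                f"level_speed must be > 0 or censored, got {self.level_speed}"
            )

    @property
    def is_censored(self) -> bool:
        return isinstance(self.level_speed, Censored)


@dataclass(frozen=True)
class LodgingDistribution:
    """Discrete lodging-fraction distribution over generated wind-speed levels.

    ``bins`` maps each speed v (m s^-1, strictly increasing, all <= s_max) to
    the fraction p(v) of plants that lodged when level v was generated.
    ``censored_mass`` is the fraction still standing at s_max; together with
    the bin masses it sums to 1.
    """

    cultivar: str
    year: int
    bins: tuple[tuple[float, float], ...]
    censored_mass: float
    s_max: float

    def __post_init__(self) -> None:
        if not self.s_max > 0:
            raise ValidationError(f"s_max must be > 0, got {self.s_max}")
        speeds = [v for v, _ in self.bins]
        if any(b <= a for a, b in zip(speeds, speeds[1:])):
            raise ValidationError(f"bin speeds must be strictly increasing: {speeds}")
        if any(v <= 0 or v > self.s_max for v in speeds):
            raise ValidationError(
                f"bin speeds must lie in (0, s_max={self.s_max}]: {speeds}"
            )
        masses = [p for _, p in self.bins] + [self.censored_mass]
        if any(p < 0 for p in masses):
            raise ValidationError(f"masses must be >= 0: {masses}")
        total = math.fsum(masses)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"masses must sum to 1 within 1e-9, got {total!r}")

    @property
    def bin_mass(self) -> float:
        """Total observed (non-censored) lodged fraction."""
        return math.fsum(p for _, p in self.bins)


@dataclass(frozen=True)
class AnemometerRecord:
    """One 1 Hz wind-speed sample at a station.

    ``distance`` is metres from the machine outlet; it is ``None`` for the
    outlet station itself (written as ``NA`` in CSV).
    """

    time: float
    layer: Layer
    distance: float | None
    speed: float

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValidationError(f"anemometer speed must be >= 0, got {self.speed}")
        if self.layer is not Layer.OUTLET and self.distance is None:
            raise ValidationError("canopy stations require a distance")


#: Canonical trait names (CSV column stems) in trait-table order.
TRAIT_NAMES = (
    "youngs_modulus",
    "max_bending_load",
    "max_transverse_displacement",
    "plant_height",
    "plant_azimuthal_deviation",
    "leaf_number",
    "leaf_inclination_angle",
    "ear_number",
    "ear_height",
    "ear_length",
)

#: Short labels used in correlation matrices, matching field convention.
TRAIT_CODES = {
    "youngs_modulus": "YM",
    "max_bending_load": "MBL",
    "max_transverse_displacement": "MTD",
    "plant_height": "PH",
    "plant_azimuthal_deviation": "PAD",
    "leaf_number": "LN",
    "leaf_inclination_angle": "LIA",
    "ear_number": "EN",
    "ear_height": "EH",
    "ear_length": "EL",
}


@dataclass(frozen=True)
class TraitRecord:
    """Per-cultivar trait means and standard errors.

    Mechanical properties come from three-point bending of the rank-3
    internode (Young's modulus in 10^3 MPa, maximum bending load in N,
    maximum transverse displacement in mm); the rest are plant morphology.
    """

    cultivar: str
    means: dict[str, float]
    ses: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.means.items():
            if name not in TRAIT_NAMES:
                raise ValidationError(f"unknown trait {name!r}")
            if value < 0:
                raise ValidationError(f"trait mean {name} must be >= 0, got {value}")
        for name, value in self.ses.items():
            if name not in TRAIT_NAMES:
                raise ValidationError(f"unknown trait {name!r}")
            if value < 0:
                raise ValidationError(f"trait se {name} must be >= 0, got {value}")


@dataclass(frozen=True)
class FWSResult:
    """A failure wind speed: either a value in (0, s_max] or censored '> s_max'."""

    value: float | None
    s_max: float
    censored: bool = False

    def __post_init__(self) -> None:
        if self.censored:
            if self.value is not None:
                raise ValidationError("censored FWS carries no value")
        else:
            if self.value is None or not 0 < self.value <= self.s_max:
                raise ValidationError(
                    f"FWS value must be in (0, {self.s_max}], got {self.value}"
                )

    def as_number(self) -> float:
        """Numeric stand-in: censored results map to s_max (biases RMSE low)."""
        return self.s_max if self.censored else float(self.value)  # type: ignore[arg-type]

    def __str__(self) -> str:
        return f">{self.s_max:g}" if self.censored else f"{self.value:g}"


# ---------------------------------------------------------------------------
# distribution construction


def build_distribution(
    observations: Iterable[LodgingObservation], s_max: float
) -> LodgingDistribution:
    """Normalise lodging counts for one cultivar/year into a LodgingDistribution.

    Counts at duplicated levels are summed before normalisation. Raises
    :class:`ValidationError` on mixed cultivar/year input or a zero total.
    """
    obs = list(observations)
    if not obs:
        raise ValidationError("no observations supplied")
    keys = {(o.cultivar, o.year) for o in obs}
    if len(keys) > 1:
        raise ValidationError(f"observations mix cultivar/year groups: {sorted(keys)}")
    (cultivar, year), = keys

    counts: dict[float, int] = {}
    censored_count = 0
    for o in obs:
        if o.is_censored:
            censored_count += o.lodged_count
        else:
            counts[float(o.level_speed)] = counts.get(float(o.level_speed), 0) + o.lodged_count
    total = sum(counts.values()) + censored_count
    if total == 0:
        raise ValidationError(f"zero total plant count for {cultivar}/{year}")

    bins = tuple((v, counts[v] / total) for v in sorted(counts) if counts[v] > 0)
    return LodgingDistribution(
        cultivar=cultivar,
        year=year,
        bins=bins,
        censored_mass=censored_count / total,
        s_max=s_max,
    )


# ---------------------------------------------------------------------------
# CSV I/O — comma-separated, UTF-8, header required, "NA" for not-applicable

LODGING_COLUMNS = ["cultivar", "year", "level_speed", "lodged_count"]
ANEMOMETER_COLUMNS = ["time_s", "layer", "distance_m", "speed_ms"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def read_lodging_csv(path) -> list[LodgingObservation]:
    """Read lodging counts; ``level_speed`` is numeric or the token ``>Smax``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, LODGING_COLUMNS, path)
    out: list[LodgingObservation] = []
    for i, row in df.iterrows():
        token = row["level_speed"].strip()
        speed: SpeedOrCensored
        if token == CENSORED_TOKEN:
            speed = CENSORED
        else:
            try:
                speed = float(token)
            except ValueError:
                raise ValidationError(
                    f"{path} row {i + 2}: unparseable level_speed {token!r}"
                ) from None
        try:
            count = int(row["lodged_count"])
            out.append(
                LodgingObservation(
                    cultivar=row["cultivar"],
                    year=int(row["year"]),
                    level_speed=speed,
                    lodged_count=count,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} row {i + 2}: {exc}") from None
    return out


def write_lodging_csv(path, observations: Iterable[LodgingObservation]) -> None:
    rows = [
        {
            "cultivar": o.cultivar,
            "year": o.year,
            "level_speed": CENSORED_TOKEN if o.is_censored else repr(float(o.level_speed)),
            "lodged_count": o.lodged_count,
        }
        for o in observations
    ]
    pd.DataFrame(rows, columns=LODGING_COLUMNS).to_csv(path, index=False)


def read_anemometer_csv(path) -> list[AnemometerRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ANEMOMETER_COLUMNS, path)
    out: list[AnemometerRecord] = []
    for i, row in df.iterrows():
        try:
            layer = Layer(row["layer"].strip())
        except ValueError:
            raise ValidationError(
                f"{path} row {i + 2}: unknown layer {row['layer']!r}"
            ) from None
        distance_token = row["distance_m"].strip()
        distance = None if distance_token == "NA" else float(distance_token)
        try:
            out.append(
                AnemometerRecord(
                    time=float(row["time_s"]),
                    layer=layer,
                    distance=distance,
                    speed=float(row["speed_ms"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} row {i + 2}: {exc}") from None
    return out


def write_anemometer_csv(path, records: Iterable[AnemometerRecord]) -> None:
    rows = [
        {
            "time_s": repr(float(r.time)),
            "layer": r.layer.value,
            "distance_m": "NA" if r.distance is None else repr(float(r.distance)),
            "speed_ms": repr(float(r.speed)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ANEMOMETER_COLUMNS).to_csv(path, index=False)


def read_traits_csv(path) -> list[TraitRecord]:
    """Read the cultivar trait table (columns ``<trait>_mean`` / ``<trait>_se``)."""
    df = pd.read_csv(path)
    _require_columns(df, ["cultivar"], path)
    out: list[TraitRecord] = []
    for i, row in df.iterrows():
        means = {
            t: float(row[f"{t}_mean"])
            for t in TRAIT_NAMES
            if f"{t}_mean" in df.columns and pd.notna(row[f"{t}_mean"])
        }
        ses = {
            t: float(row[f"{t}_se"])
            for t in TRAIT_NAMES
            if f"{t}_se" in df.columns and pd.notna(row[f"{t}_se"])
        }
        try:
            out.append(TraitRecord(cultivar=str(row["cultivar"]), means=means, ses=ses))
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i + 2}: {exc}") from None
    return out


def write_traits_csv(path, records: Iterable[TraitRecord]) -> None:
    records = list(records)
    traits = [t for t in TRAIT_NAMES if any(t in r.means for r in records)]
    rows = []
    for r in records:
        row: dict[str, object] = {"cultivar": r.cultivar}
        for t in traits:
            row[f"{t}_mean"] = repr(float(r.means[t])) if t in r.means else "NA"
            row[f"{t}_se"] = repr(float(r.ses[t])) if t in r.ses else "NA"
        rows.append(row)
    columns = ["cultivar"] + [f"{t}_{k}" for t in traits for k in ("mean", "se")]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
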
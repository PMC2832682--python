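"""Stimulus designs and projective geometry for the size/distance-change task.

A ball of physical diameter ``s`` at egocentric distance ``d`` subtends a
visual angle ``2·arctan(s/2d)``.  When the ball simultaneously changes size
(rate ``ṡ``, mm/s, negative = deflating) and moves in depth (rate ``ḋ``,
mm/s, negative = approaching), the monocular image-size cue alone cannot
separate the two: any (ḋ, ṡ) pair on the line ``ṡ = (s₀/d₀)·ḋ`` leaves the
image size unchanged over the trial.

This module enumerates the two experimental designs used to probe that
ambiguity:

* **Experiment 1** — a 33-point (distance-rate × size-rate) grid built from
  3 pedestal distance rates × 11 satellite offsets, each satellite paired
  with one size rate, replicated per cue condition (haptic and/or binocular
  distance cues present or absent), with a binary inflating/deflating
  judgment per trial.
* **Experiment 2** — a two-interval forced-choice (2IFC) speed
  discrimination: 2 standard distance rates × 7 comparison offsets, fixed
  ball size, one single-cue condition per session.

Grids are plain :class:`pandas.DataFrame` tables wrapped in
:class:`DesignGrid`; single trials round-trip through :class:`TrialSpec`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "BALL_DIAMETER_MM",
    "INITIAL_DISTANCE_RANGE_MM",
    "NORMALIZATION_DISTANCE_MM",
    "TRIAL_DURATION_S",
    "OSCILLATION_AMPLITUDE_RANGE_MM",
    "OSCILLATION_FREQUENCY_RANGE_HZ",
    "EXP1_PEDESTALS_MM_S",
    "EXP1_SATELLITES_MM_S",
    "EXP1_SIZE_RATES_MM_S",
    "EXP2_STANDARDS_MM_S",
    "EXP2_OFFSETS_MM_S",
    "CueCondition",
    "DirectionGroup",
    "TrialSpec",
    "DesignGrid",
    "build_exp1_grid",
    "build_exp2_design",
    "visual_angle",
    "trajectory",
    "image_boundary_slope",
]

# Stimulus geometry (mm, s) --------------------------------------------------

BALL_DIAMETER_MM = 35.0
INITIAL_DISTANCE_RANGE_MM = (443.0, 455.0)
#: mid-point of the initial-distance range; default geometry for normalizing
#: discrimination-boundary slopes into confusion ratios.
NORMALIZATION_DISTANCE_MM = 449.0
TRIAL_DURATION_S = 1.0
OSCILLATION_AMPLITUDE_RANGE_MM = (5.0, 15.0)
OSCILLATION_FREQUENCY_RANGE_HZ = (0.35, 0.5)

# Experiment 1 rate sets (mm/s) ----------------------------------------------

EXP1_PEDESTALS_MM_S = (-71.5, 0.0, 71.5)
EXP1_SATELLITES_MM_S = (
    -32.5, -26.0, -19.5, -13.0, -6.5, 0.0, 6.5, 13.0, 19.5, 26.0, 32.5,
)
EXP1_SIZE_RATES_MM_S = (
    -11.0, -8.8, -6.6, -4.4, -2.2, 0.0, 2.2, 4.4, 6.6, 8.8, 11.0,
)

# Experiment 2 rate sets (mm/s) ----------------------------------------------

EXP2_STANDARDS_MM_S = (-55.0, 55.0)
EXP2_OFFSETS_MM_S = (-54.0, -36.0, -18.0, 0.0, 18.0, 36.0, 54.0)


class DirectionGroup(str, Enum):
    """Distance-direction stratum of an Experiment-1 trial (by pedestal)."""

    APPROACHING = "approaching"
    INTERMEDIATE = "intermediate"
    RECEDING = "receding"

    @classmethod
    def from_pedestal(cls, pedestal: float) -> "DirectionGroup":
        if pedestal < 0:
            return cls.APPROACHING
        if pedestal > 0:
            return cls.RECEDING
        return cls.INTERMEDIATE


@dataclass(frozen=True, order=True)
class CueCondition:
    """Presence/absence of the haptic (H) and binocular (B) distance cues.

    Exactly four distinct conditions exist: H-/B-, H+/B-, H-/B+, H+/B+.
    """

    haptic: bool
    binocular: bool

    @property
    def label(self) -> str:
        return f"H{'+' if self.haptic else '-'}/B{'+' if self.binocular else '-'}"

    @property
    def is_single_cue(self) -> bool:
        return self.haptic != self.binocular

    @classmethod
    def parse(cls, label: str) -> "CueCondition":
        text = label.strip().replace("−", "-")
        valid = {c.label: c for c in cls.all_conditions()}
        if text not in valid:
            raise ValueError(
                f"unknown cue condition {label!r}; expected one of {sorted(valid)}"
            )
        return valid[text]

    @classmethod
    def all_conditions(cls) -> tuple["CueCondition", ...]:
        return (
            cls(haptic=False, binocular=False),
            cls(haptic=True, binocular=False),
            cls(haptic=False, binocular=True),
            cls(haptic=True, binocular=True),
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class TrialSpec:
    """One stimulus presentation.

    Rates follow the plotting convention of the task: negative ``distance_rate``
    means the ball approaches the observer, negative ``size_rate`` means it
    deflates.
    """

    size_rate: float
    distance_rate: float
    initial_diameter: float = BALL_DIAMETER_MM
    initial_distance: float = NORMALIZATION_DISTANCE_MM
    duration: float = TRIAL_DURATION_S
    condition: CueCondition = CueCondition(haptic=False, binocular=False)
    direction_group: DirectionGroup | None = None
    oscillation_amplitude: float = 0.0
    oscillation_frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("trial duration must be positive")
        if self.initial_diameter <= 0:
            raise ValueError("initial diameter must be positive")
        if self.initial_distance <= 0:
            raise ValueError("initial distance must be positive")
        if self.initial_distance + self.distance_rate * self.duration <= 0:
            raise ValueError("trajectory reaches nonpositive distance")
        if self.initial_diameter + self.size_rate * self.duration < 0:
            raise ValueError("trajectory reaches negative diameter")
        if self.oscillation_amplitude < 0 or self.oscillation_frequency < 0:
            raise ValueError("oscillation parameters must be nonnegative")

    @property
    def k_img(self) -> float:
        """Zero-image-change slope s0/d0 for this trial's start geometry."""
        return self.initial_diameter / self.initial_distance

    @classmethod
    def from_row(cls, row) -> "TrialSpec":
        """Build a TrialSpec from one record/design table row."""
        group = row.get("direction_group") if hasattr(row, "get") else None
        return cls(
            size_rate=float(row["size_rate_mm_s"]),
            distance_rate=float(row["distance_rate_mm_s"]),
            initial_diameter=float(row["initial_diameter_mm"]),
            initial_distance=float(row["initial_distance_mm"]),
            duration=float(row["duration_s"]),
            condition=CueCondition.parse(row["condition"]),
            direction_group=DirectionGroup(group) if group else None,
            oscillation_amplitude=float(row.get("osc_amplitude_mm", 0.0)),
            oscillation_frequency=float(row.get("osc_freq_hz", 0.0)),
        )


@dataclass
class DesignGrid:
    """An enumerated design: one row per trial plus the generating sets."""

    trials: pd.DataFrame
    experiment: int
    repeats: int
    pedestals: tuple = ()
    satellites: tuple = ()
    size_rates: tuple = ()
    standards: tuple = ()
    offsets: tuple = ()
    conditions: tuple = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_unique_rate_pairs(self) -> int:
        """Number of distinct (distance-rate, size-rate) stimulus pairs."""
        cols = ["distance_rate_mm_s", "size_rate_mm_s"]
        return len(self.trials[cols].drop_duplicates())


def visual_angle(diameter, distance):
    """Visual angle (degrees) subtended by ``diameter`` at ``distance``.

    Exact projective geometry: ``2·arctan(diameter / (2·distance))``.
    Broadcasts over array inputs.
    """
    diameter = np.asarray(diameter, dtype=float)
    distance = np.asarray(distance, dtype=float)
    if np.any(distance <= 0):
        raise ValueError("distance must be positive")
    if np.any(diameter < 0):
        raise ValueError("diameter must be nonnegative")
    angle = np.degrees(2.0 * np.arctan2(diameter, 2.0 * distance))
    return float(angle) if angle.ndim == 0 else angle


def trajectory(trial: TrialSpec, t):
    """Instantaneous (diameter, eye distance, visual angle) at time ``t``.

    Diameter and axial depth change linearly; a sinusoidal fronto-parallel
    oscillation (lateral displacement ``A·sin(2π f t)``) adds to the
    line-of-sight distance geometrically.  ``t`` may be a scalar or array in
    ``[0, duration]``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > trial.duration):
        raise ValueError("time outside [0, duration]")
    diameter = trial.initial_diameter + trial.size_rate * t
    axial = trial.initial_distance + trial.distance_rate * t
    lateral = trial.oscillation_amplitude * np.sin(
        2.0 * math.pi * trial.oscillation_frequency * t
    )
    distance = np.hypot(axial, lateral)
    angle = visual_angle(diameter, distance)
    if t.ndim == 0:
        return float(diameter), float(distance), float(angle)
    return diameter, distance, angle


def image_boundary_slope(s0: float, d0: float) -> float:
    """Slope ``dṡ/dḋ`` of the zero-image-change line for start geometry (s0, d0).

    Under small-angle projection the image size is unchanged at the end of the
    trial exactly when ``s(T)/d(T) = s0/d0``, i.e. along ``ṡ = (s0/d0)·ḋ``.
    """
    if s0 <= 0 or d0 <= 0:
        raise ValueError("s0 and d0 must be positive")
    return s0 / d0


def _pair_satellites(satellites, size_rates, pairing):
    if len(satellites) != len(size_rates):
        raise ValueError("satellites and size_rates must have equal length")
    if pairing not in ("monotone", "antimonotone"):
        raise ValueError("pairing must be 'monotone' or 'antimonotone'")
    sats = sorted(satellites)
    sizes = sorted(size_rates, reverse=(pairing == "antimonotone"))
    return list(zip(sats, sizes))


def build_exp1_grid(
    repeats: int = 10,
    conditions=None,
    pairing: str = "monotone",
    seed: int = 0,
    *,
    pedestals=EXP1_PEDESTALS_MM_S,
    satellites=EXP1_SATELLITES_MM_S,
    size_rates=EXP1_SIZE_RATES_MM_S,
    initial_diameter: float = BALL_DIAMETER_MM,
    duration: float = TRIAL_DURATION_S,
) -> DesignGrid:
    """Enumerate the Experiment-1 design grid.

    Every pedestal + satellite distance rate is paired one-to-one with a size
    rate (``pairing='monotone'`` pairs sorted satellites with sorted size
    rates; ``'antimonotone'`` reverses the size rates) and replicated
    ``repeats`` times per cue condition.  Initial distance, oscillation
    amplitude/frequency are drawn uniformly from the design ranges under
    ``seed``.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if conditions is None:
        conditions = CueCondition.all_conditions()
    conditions = tuple(conditions)
    if not conditions:
        raise ValueError("condition list must not be empty")
    pairs = _pair_satellites(satellites, size_rates, pairing)

    rng = np.random.default_rng(seed)
    rows = []
    trial_id = 0
    for condition in conditions:
        for pedestal in pedestals:
            group = DirectionGroup.from_pedestal(pedestal)
            for satellite, size_rate in pairs:
                for _ in range(repeats):
                    d0 = rng.uniform(*INITIAL_DISTANCE_RANGE_MM)
                    amp = rng.uniform(*OSCILLATION_AMPLITUDE_RANGE_MM)
                    freq = rng.uniform(*OSCILLATION_FREQUENCY_RANGE_HZ)
                    rows.append(
                        {
                            "trial_id": trial_id,
                            "experiment": 1,
                            "condition": condition.label,
                            "pedestal_mm_s": pedestal,
                            "satellite_mm_s": satellite,
                            "distance_rate_mm_s": pedestal + satellite,
                            "size_rate_mm_s": size_rate,
                            "initial_diameter_mm": initial_diameter,
                            "initial_distance_mm": d0,
                            "duration_s": duration,
                            "direction_group": group.value,
                            "osc_amplitude_mm": amp,
                            "osc_freq_hz": freq,
                            "seed": seed,
                        }
                    )
                    trial_id += 1
    return DesignGrid(
        trials=pd.DataFrame(rows),
        experiment=1,
        repeats=repeats,
        pedestals=tuple(pedestals),
        satellites=tuple(sorted(satellites)),
        size_rates=tuple(size_rates),
        conditions=conditions,
    )


def build_exp2_design(
    repeats: int = 14,
    condition: CueCondition = CueCondition(haptic=False, binocular=True),
    seed: int = 0,
    *,
    standards=EXP2_STANDARDS_MM_S,
    offsets=EXP2_OFFSETS_MM_S,
    initial_diameter: float = BALL_DIAMETER_MM,
    duration: float = TRIAL_DURATION_S,
) -> DesignGrid:
    """Enumerate the Experiment-2 2IFC speed-discrimination design.

    Each (standard, comparison-offset) cell appears ``repeats`` times for the
    given single-cue condition; the interval order (standard first or second)
    is balanced within each cell and shuffled under ``seed``.  The ball never
    changes size (size rate fixed at 0).
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if not condition.is_single_cue:
        raise ValueError(
            "Experiment 2 runs single-cue conditions only (H+/B- or H-/B+), "
            f"got {condition.label}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    trial_id = 0
    for standard in standards:
        for offset in offsets:
            # balance interval order: counts per cell differ by at most 1
            first = np.array([True] * ((repeats + 1) // 2) + [False] * (repeats // 2))
            rng.shuffle(first)
            for rep in range(repeats):
                d0 = rng.uniform(*INITIAL_DISTANCE_RANGE_MM)
                amp = rng.uniform(*OSCILLATION_AMPLITUDE_RANGE_MM)
                freq = rng.uniform(*OSCILLATION_FREQUENCY_RANGE_HZ)
                rows.append(
                    {
                        "trial_id": trial_id,
                        "experiment": 2,
                        "condition": condition.label,
                        "standard_mm_s": standard,
                        "offset_mm_s": offset,
                        "comparison_mm_s": standard + offset,
                        "size_rate_mm_s": 0.0,
                        "standard_first": bool(first[rep]),
                        "initial_diameter_mm": initial_diameter,
                        "initial_distance_mm": d0,
                        "duration_s": duration,
                        "osc_amplitude_mm": amp,
                        "osc_freq_hz": freq,
                        "seed": seed,
                    }
                )
                trial_id += 1
    return DesignGrid(
        trials=pd.DataFrame(rows),
        experiment=2,
        repeats=repeats,
        standards=tuple(standards),
        offsets=tuple(offsets),
        conditions=(condition,),
    )
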
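"""Light/dark-box behavioral metrics from tracked head coordinates.

The arena is a 100 × 50 cm box (40 cm tall) split along its length into
a darkened and a lit half connected by a doorway.  A circular
transition zone of radius 1.25 × doorway width, centered at the doorway
base, is carved out of both halves; every in-box point belongs to
exactly one of {dark, light, transition}, with the transition zone
taking precedence.

From a (t, x, y) track the module computes zone occupancy times,
compartment-switch counts (crossings of the dividing line, regardless
of transition-zone membership), and entry hesitation — the dwell time
in the transition zone before a crossing, split by crossing direction,
with approaches that retreat without crossing reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BoxGeometry",
    "ZoneMetrics",
    "HesitationResult",
    "assign_zone",
    "occupancy",
    "entry_hesitation",
    "normalize_behavior",
]


@dataclass(frozen=True)
class BoxGeometry:
    """Arena geometry in cm.  The divider runs at x = length/2.

    The doorway sits on the divider at ``doorway_y`` (along the width).
    Its width has no published default and must be supplied; the
    transition radius defaults to 1.25 × doorway_width.
    """

    doorway_width: float
    length: float = 100.0
    width: float = 50.0
    height: float = 40.0  # informational
    dark_side: str = "left"  # which half along x is darkened
    doorway_y: float | None = None
    transition_radius: float | None = None

    def __post_init__(self) -> None:
        if self.doorway_width <= 0:
            raise ValueError("doorway_width must be positive")
        if self.length <= 0 or self.width <= 0:
            raise ValueError("box dimensions must be positive")
        if self.dark_side not in ("left", "right"):
            raise ValueError("dark_side must be 'left' or 'right'")
        if self.doorway_y is None:
            object.__setattr__(self, "doorway_y", self.width / 2)
        if not (0 <= self.doorway_y <= self.width):
            raise ValueError("doorway_y must lie on the dividing wall")
        if self.transition_radius is None:
            object.__setattr__(self, "transition_radius", 1.25 * self.doorway_width)
        if self.transition_radius <= 0:
            raise ValueError("transition_radius must be positive")

    @property
    def divider_x(self) -> float:
        return self.length / 2

    @property
    def doorway_center(self) -> tuple[float, float]:
        return (self.divider_x, self.doorway_y)

    def compartment(self, x: float) -> str:
        """dark/light by side of the divider (divider itself → dark side)."""
        left = x <= self.divider_x
        if self.dark_side == "left":
            return "dark" if left else "light"
        return "light" if left else "dark"

    def area_fraction(self, zone: str) -> float:
        """Fraction of the box area occupied by a zone.

        The transition circle straddles the divider symmetrically in x,
        but may be clipped by the side walls in y.
        """
        total = self.length * self.width
        r, cy = self.transition_radius, self.doorway_y
        # area of the circle clipped to the y-range [0, width] (full
        # x-range assumed available near the divider)
        y_lo, y_hi = max(-cy, -r), min(self.width - cy, r)
        circ = _circle_strip_area(r, y_lo, y_hi)
        if zone == "transition":
            return circ / total
        half = total / 2 - circ / 2
        if zone in ("dark", "light"):
            return half / total
        raise ValueError(f"unknown zone {zone!r}")


def _circle_strip_area(r: float, y_lo: float, y_hi: float) -> float:
    """Area of x²+y² <= r² between horizontal lines y_lo and y_hi."""

    def f(y):
        y = min(max(y, -r), r)
        return y * math.sqrt(max(r * r - y * y, 0.0)) + r * r * math.asin(min(max(y / r, -1), 1))

    return f(y_hi) - f(y_lo)


def assign_zone(x: float, y: float, g: BoxGeometry, *, atol: float = 1e-9) -> str:
    """Zone of a point: transition takes precedence over dark/light."""
    if not (-atol <= x <= g.length + atol and -atol <= y <= g.width + atol):
        raise ValueError(f"point ({x}, {y}) outside the {g.length}x{g.width} cm box")
    cx, cy = g.doorway_center
    if math.hypot(x - cx, y - cy) <= g.transition_radius:
        return "transition"
    return g.compartment(x)


@dataclass
class ZoneMetrics:
    """Occupancy and transition statistics for one session."""

    t_dark: float = 0.0
    t_light: float = 0.0
    t_transition: float = 0.0
    n_switches: int = 0
    tracked_duration: float = 0.0
    excluded_duration: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def fractions(self) -> dict[str, float]:
        tot = self.tracked_duration
        if tot <= 0:
            return {"dark": np.nan, "light": np.nan, "transition": np.nan}
        return {"dark": self.t_dark / tot, "light": self.t_light / tot,
                "transition": self.t_transition / tot}


def _validated_track(t, x, y):
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (t.shape == x.shape == y.shape) or t.ndim != 1 or t.size < 2:
        raise ValueError("track needs matching 1-D t, x, y with >= 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    return t, x, y


def occupancy(t, x, y, g: BoxGeometry, *, max_gap_factor: float = 5.0) -> ZoneMetrics:
    """Zone occupancy and compartment switches for one tracked session.

    Each inter-sample interval is attributed to the zone of its starting
    sample.  Detector dropouts — gaps longer than ``max_gap_factor`` ×
    the median frame interval — are excluded from the occupancy times
    (but still counted in ``excluded_duration``).  Switches count
    crossings of the dividing line between consecutive samples,
    independent of transition-zone membership.
    """
    t, x, y = _validated_track(t, x, y)
    zones = [assign_zone(xi, yi, g) for xi, yi in zip(x, y)]
    comp = [g.compartment(xi) for xi in x]
    dt = np.diff(t)
    gap_limit = max_gap_factor * float(np.median(dt))
    m = ZoneMetrics()
    for i, d in enumerate(dt):
        if d > gap_limit:
            m.excluded_duration += float(d)
        else:
            m.tracked_duration += float(d)
            if zones[i] == "dark":
                m.t_dark += float(d)
            elif zones[i] == "light":
                m.t_light += float(d)
            else:
                m.t_transition += float(d)
        if comp[i + 1] != comp[i]:
            m.n_switches += 1
    return m


@dataclass
class HesitationResult:
    """Transition-zone dwell times preceding crossings, by direction.

    ``latencies_to_light``/``latencies_to_dark`` hold one dwell time per
    completed crossing; aborted approaches (transition-zone visits that
    retreat without crossing) are counted per starting compartment.
    """

    latencies_to_light: list[float] = field(default_factory=list)
    latencies_to_dark: list[float] = field(default_factory=list)
    aborted_from_dark: int = 0
    aborted_from_light: int = 0

    def mean_latency(self, direction: str) -> float:
        lat = self.latencies_to_light if direction == "light" else self.latencies_to_dark
        return float(np.mean(lat)) if lat else np.nan


def entry_hesitation(t, x, y, g: BoxGeometry) -> HesitationResult:
    """Per-direction doorway hesitation from one tracked session.

    A visit starts when the track enters the transition zone from a
    compartment; if the dividing line is crossed before the zone is
    left, the dwell from zone entry to the crossing is recorded as a
    latency for the entered compartment.  Visits that leave the zone on
    the starting side are aborted approaches.
    """
    t, x, y = _validated_track(t, x, y)
    zones = [assign_zone(xi, yi, g) for xi, yi in zip(x, y)]
    comp = [g.compartment(xi) for xi in x]
    res = HesitationResult()
    entry_time: float | None = None
    entry_comp: str | None = None
    crossed = False
    for i in range(len(t)):
        in_zone = zones[i] == "transition"
        if entry_time is None:
            if in_zone:
                entry_time, entry_comp, crossed = float(t[i]), comp[i], False
            continue
        if not crossed and comp[i] != entry_comp:
            # first sample on the far side: completed crossing
            lat = float(t[i]) - entry_time
            (res.latencies_to_light if comp[i] == "light" else res.latencies_to_dark).append(lat)
            crossed = True
        if not in_zone:
            if not crossed:
                if entry_comp == "dark":
                    res.aborted_from_dark += 1
                else:
                    res.aborted_from_light += 1
            entry_time, entry_comp, crossed = None, None, False
    return res


def normalize_behavior(metrics: pd.DataFrame,
                       value_cols,
                       reference_genotype: str = "+/+") -> pd.DataFrame:
    """Normalize each parameter to the pooled wildtype mean.

    The wildtype mean pools all measurements (every timepoint) per
    parameter, so the wildtype pooled entry maps to 1.0.  Zero or
    missing references are errors.
    """
    ref_rows = metrics[metrics["genotype"] == reference_genotype]
    if ref_rows.empty:
        raise ValueError(f"no rows for reference genotype {reference_genotype!r}")
    out = metrics.copy()
    for c in value_cols:
        ref = float(ref_rows[c].mean())
        if not np.isfinite(ref) or ref == 0:
            raise ValueError(f"pooled wildtype mean for {c!r} is zero or undefined")
        out[f"{c}_norm"] = metrics[c] / ref
    return out
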
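"""Synthetic phenotype-data generators.

Every analysis stage in this package has a matching generator whose
ground truth is known, so the extraction chains can be validated end to
end without recordings:

* ERG traces: Gaussian-bump a- and b-wave components with a windowed
  sinusoid for the oscillatory potentials (default 120 Hz, inside the
  30–235 Hz band the filters are designed around), additive Gaussian
  noise, and a Naka–Rushton intensity–response V(I) = Vmax·Iⁿ/(Iⁿ+Kⁿ).
  These are modeling conveniences for validation, not biophysics.
* OCT cohorts: knockout total thickness follows
  T(t) = A + (T0 − A)·exp(−t/τ) with the loss taken from the outer
  nuclear layer; wildtype and heterozygous retinas stay flat.
* Light/dark-box tracks: a reflected 2-D random walk that can cross the
  divider only through the doorway, lingers in the transition zone for
  an exponential dwell, and weights crossing direction by a
  dark-preference factor (1.0 = no preference, as in a blind animal).

All generators are seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import BoxGeometry
from .erg import (DEFAULT_DURATION_S, DEFAULT_N_SAMPLES,
                  DEFAULT_STIMULUS_ONSET_S, ErgTrace)

__all__ = [
    "ErgSimParams",
    "OctSimParams",
    "TrackSimParams",
    "simulate_erg_trace",
    "simulate_flicker_trace",
    "simulate_erg",
    "simulate_oct",
    "simulate_track",
]

GENOTYPES = ("+/+", "+/-", "-/-")


def _bump(t: np.ndarray, mu_s: float, sigma_s: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu_s) / sigma_s) ** 2)


@dataclass(frozen=True)
class ErgSimParams:
    """Waveform and cohort parameters for the ERG generator.

    Latencies/widths are in ms post-stimulus, amplitudes in µV.  The
    default b-wave of ~450 µV trough-to-peak at the brightest flash and
    a knockout scale of 0.08 emulate a severe rod-pathway loss.
    """

    a_amp: float = 150.0
    a_latency: float = 30.0
    a_width: float = 8.0
    b_amp: float = 300.0
    b_latency: float = 70.0
    b_width: float = 12.0
    op_amp: float = 40.0
    op_freq: float = 120.0  # Hz, within the 30–235 Hz OP band
    op_center: float | None = None  # ms; default: midway up the b-wave's rise
    op_width: float | None = None  # ms; default: a quarter of the a→b interval
    noise_sd: float = 5.0
    intensities: tuple[float, ...] = (0.3, 30.0)
    vmax: float = 1.0
    semisaturation: float = 1.0  # cd·s/m²
    hill_n: float = 0.7
    genotype_scale: dict = field(default_factory=lambda: {"+/+": 1.0, "+/-": 1.0, "-/-": 0.08})
    flicker_hz: float = 9.0
    flicker_p_amp: float = 80.0
    flicker_p_latency: float = 40.0
    flicker_p_width: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("a_width", "b_width", "flicker_p_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 30.0 < self.op_freq < 235.0:
            raise ValueError("op_freq must lie inside the (30, 235) Hz OP band")

    def intensity_gain(self, intensity: float) -> float:
        """Naka–Rushton response fraction at a flash intensity."""
        i_n = intensity ** self.hill_n
        return self.vmax * i_n / (i_n + self.semisaturation ** self.hill_n)

    def effective_amplitudes(self, intensity: float, genotype: str = "+/+") -> dict[str, float]:
        """Ground-truth component amplitudes after intensity and genotype scaling."""
        s = self.intensity_gain(intensity) * self.genotype_scale[genotype]
        return {"a_amp": self.a_amp * s, "b_amp": self.b_amp * s,
                "op_amp": self.op_amp * s, "b_absolute": (self.a_amp + self.b_amp) * s}


def simulate_erg_trace(params: ErgSimParams,
                       intensity: float = 30.0,
                       genotype: str = "+/+",
                       rng: np.random.Generator | None = None,
                       **trace_meta) -> ErgTrace:
    """One synthetic single-flash trace on the 512-sample/350-ms grid."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    dt = DEFAULT_DURATION_S / DEFAULT_N_SAMPLES
    t = np.arange(DEFAULT_N_SAMPLES) * dt
    onset = DEFAULT_STIMULUS_ONSET_S
    ta = onset + params.a_latency * 1e-3
    tb = onset + params.b_latency * 1e-3
    if not (onset <= ta < DEFAULT_DURATION_S and onset <= tb < DEFAULT_DURATION_S):
        raise ValueError("component latencies fall outside the trace")
    amp = params.effective_amplitudes(intensity, genotype)
    # OPs ride on the b-wave's rising limb, between the a-trough and the
    # b-peak, so the unfiltered read-out at either extremum stays clean
    op_mu = params.op_center if params.op_center is not None \
        else (params.a_latency + params.b_latency) / 2
    op_sig = params.op_width if params.op_width is not None \
        else (params.b_latency - params.a_latency) / 4
    y = (-amp["a_amp"] * _bump(t, ta, params.a_width * 1e-3)
         + amp["b_amp"] * _bump(t, tb, params.b_width * 1e-3)
         + amp["op_amp"] * np.sin(2 * np.pi * params.op_freq * (t - onset))
         * _bump(t, onset + op_mu * 1e-3, op_sig * 1e-3))
    y += rng.normal(0.0, params.noise_sd, size=y.size)
    return ErgTrace(samples=y, dt=dt, stimulus_onset=onset, intensity=intensity,
                    genotype=genotype, **trace_meta)


def simulate_flicker_trace(params: ErgSimParams,
                           intensity: float = 30.0,
                           genotype: str = "+/+",
                           rng: np.random.Generator | None = None,
                           **trace_meta) -> ErgTrace:
    """A flicker response: superposed per-flash bumps at the train rate."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    dt = DEFAULT_DURATION_S / DEFAULT_N_SAMPLES
    t = np.arange(DEFAULT_N_SAMPLES) * dt
    onset = DEFAULT_STIMULUS_ONSET_S
    s = params.intensity_gain(intensity) * params.genotype_scale[genotype]
    y = np.zeros_like(t)
    period = 1.0 / params.flicker_hz
    flash = onset
    while flash < DEFAULT_DURATION_S:
        y += s * params.flicker_p_amp * _bump(t, flash + params.flicker_p_latency * 1e-3,
                                              params.flicker_p_width * 1e-3)
        flash += period
    y += rng.normal(0.0, params.noise_sd, size=y.size)
    return ErgTrace(samples=y, dt=dt, stimulus_onset=onset, intensity=intensity,
                    mode="flicker", flicker_hz=params.flicker_hz, genotype=genotype,
                    **trace_meta)


def simulate_erg(params: ErgSimParams,
                 genotypes=GENOTYPES,
                 n_animals: int = 6,
                 include_flicker: bool = False) -> list[ErgTrace]:
    """A full seeded cohort: every genotype × animal × intensity."""
    rng = np.random.default_rng(params.seed)
    traces = []
    for genotype in genotypes:
        for k in range(n_animals):
            animal = f"{genotype}-{k + 1}"
            for intensity in params.intensities:
                traces.append(simulate_erg_trace(
                    params, intensity, genotype, rng,
                    animal_id=animal, eye="OD"))
            if include_flicker:
                traces.append(simulate_flicker_trace(
                    params, max(params.intensities), genotype, rng,
                    animal_id=animal, eye="OD"))
    return traces


@dataclass(frozen=True)
class OctSimParams:
    """Cohort parameters for the OCT thinning generator.

    Layer baselines (µm) sum to the total retinal thickness; the
    knockout's total relaxes to ``asymptote_frac`` × baseline with time
    constant ``tau_weeks``, the loss drawn entirely from the ONL.
    """

    layers: dict = field(default_factory=lambda: {"IPL": 50.0, "INL": 25.0,
                                                  "ONL": 60.0, "other": 95.0})
    asymptote_frac: float = 0.78
    tau_weeks: float = 4.0
    noise_sd: float = 5.0
    n_animals: int = 6
    ages: tuple[float, ...] = (2, 3, 4, 6, 8, 12, 16)
    extent_mm: float = 3.0
    points_per_scan: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.asymptote_frac <= 1:
            raise ValueError("asymptote_frac must be in (0, 1]")
        if self.tau_weeks <= 0:
            raise ValueError("tau_weeks must be positive")

    @property
    def total_baseline(self) -> float:
        return float(sum(self.layers.values()))

    def total_at(self, age_weeks: float, genotype: str) -> float:
        """Noise-free total thickness from the decay model."""
        t0 = self.total_baseline
        if genotype != "-/-":
            return t0
        a = self.asymptote_frac * t0
        return a + (t0 - a) * np.exp(-age_weeks / self.tau_weeks)


def simulate_oct(params: OctSimParams, genotypes=GENOTYPES) -> pd.DataFrame:
    """Long-format thickness-profile table for a longitudinal cohort.

    Columns: animal, genotype, age_weeks, eye, scan_offset, position_mm,
    layer, thickness_um.  Layers are IPL/INL/ONL/total; per-point
    measurement noise is shared between the layer rows and the total so
    the layer sum stays consistent.
    """
    from .oct_thickness import SCAN_OFFSETS

    rng = np.random.default_rng(params.seed)
    positions = np.linspace(-params.extent_mm, params.extent_mm, params.points_per_scan)
    rows = []
    for genotype in genotypes:
        for k in range(params.n_animals):
            animal = f"{genotype}-{k + 1}"
            for age in params.ages:
                onl_loss = params.total_baseline - params.total_at(age, genotype)
                layer_means = dict(params.layers)
                layer_means["ONL"] = max(layer_means["ONL"] - onl_loss, 1.0)
                for eye in ("OD", "OS"):
                    for off in SCAN_OFFSETS:
                        noise = {lay: rng.normal(0, params.noise_sd, positions.size)
                                 for lay in layer_means}
                        total = np.zeros(positions.size)
                        for lay, mu in layer_means.items():
                            vals = np.maximum(mu + noise[lay], 0.5)
                            total += vals
                            if lay != "other":
                                for p, v in zip(positions, vals):
                                    rows.append((animal, genotype, age, eye, off, p, lay, v))
                        for p, v in zip(positions, total):
                            rows.append((animal, genotype, age, eye, off, p, "total", v))
    return pd.DataFrame(rows, columns=["animal", "genotype", "age_weeks", "eye",
                                       "scan_offset", "position_mm", "layer",
                                       "thickness_um"])


@dataclass(frozen=True)
class TrackSimParams:
    """Random-walk parameters for the light/dark-box agent.

    ``dark_preference`` weights doorway crossings: 1.0 is indifferent
    (blind-like), values above 1 bias crossings toward the dark side
    and make the agent reluctant to leave it (sighted-like).
    ``doorway_dwell_mean_s`` is the mean exponential pause on reaching
    the doorway before a crossing can complete; the base (no-
    preference) agent hesitates only briefly — prolonged doorway
    hesitation is the sighted phenotype and is modeled by raising this
    together with ``dark_preference``.
    """

    step_sd: float = 2.0  # cm per frame
    frame_rate: float = 15.0  # Hz
    session_s: float = 1200.0  # twenty minutes
    doorway_dwell_mean_s: float = 1.0
    dark_preference: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_sd <= 0:
            raise ValueError("step_sd must be positive")
        if self.dark_preference <= 0:
            raise ValueError("dark_preference must be positive")


def _reflect(v: float, lo: float, hi: float) -> float:
    span = hi - lo
    while not (lo <= v <= hi):
        if v < lo:
            v = 2 * lo - v
        else:
            v = 2 * hi - v
        if span <= 0:  # pragma: no cover
            return min(max(v, lo), hi)
    return v


def simulate_track(params: TrackSimParams, g: BoxGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one session; returns (t, x, y) in s and cm.

    The agent starts at the center of the light half (animals are
    placed in the lit compartment), diffuses with Gaussian steps, and
    reflects off the outer walls.  The divider is a solid wall with a
    physical opening of ``doorway_width``: a step changes compartments
    only when its path crosses the divider inside the opening, the
    hesitation dwell (timed from entering the transition zone) has
    elapsed, and the direction is accepted under ``dark_preference``.
    Blocked crossings reflect off the divider like a wall.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.session_s * params.frame_rate)) + 1
    dt = 1.0 / params.frame_rate
    cx, cy = g.doorway_center
    r = g.transition_radius
    light_x = (3 * g.length / 4) if g.dark_side == "left" else (g.length / 4)
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = light_x, g.width / 2
    w = params.dark_preference
    p_into = {"dark": min(1.0, w), "light": min(1.0, 1.0 / w)}
    in_zone = (x[0] - cx) ** 2 + (y[0] - cy) ** 2 <= r * r
    dwell_until = -np.inf
    steps = rng.normal(0.0, params.step_sd, size=(n - 1, 2))
    unif = rng.random(n - 1)
    dwells = rng.exponential(params.doorway_dwell_mean_s, size=n - 1)
    for i in range(1, n):
        t_now = i * dt
        nx = _reflect(x[i - 1] + steps[i - 1, 0], 0.0, g.length)
        ny = _reflect(y[i - 1] + steps[i - 1, 1], 0.0, g.width)
        crossing = (x[i - 1] - cx) * (nx - cx) < 0
        if crossing:
            # y-coordinate where the step's path meets the divider
            frac = (cx - x[i - 1]) / (nx - x[i - 1])
            yc = y[i - 1] + frac * (ny - y[i - 1])
            through_gap = abs(yc - cy) <= g.doorway_width / 2
            target = g.compartment(nx)
            allowed = (through_gap and t_now >= dwell_until
                       and unif[i - 1] < p_into[target])
            if not allowed:
                nx = _reflect(2 * cx - nx, 0.0, g.length)
        x[i], y[i] = nx, ny
        now_zone = (nx - cx) ** 2 + (ny - cy) ** 2 <= r * r
        if now_zone and not in_zone:
            dwell_until = t_now + dwells[i - 1]
        in_zone = now_zone
    t = np.arange(n) * dt
    return t, x, y
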
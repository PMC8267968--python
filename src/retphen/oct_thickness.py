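"""OCT retinal-thickness quantification.

Thickness profiles (µm vs position along a B-scan, in mm relative to
the optic nerve) are sampled on a fixed grid — every ``interval`` mm,
keeping a minimum ``exclusion`` distance from the optic nerve — then
pooled per eye, per animal, and per genotype × age group.  Group means
are normalized to the wildtype thickness at 2 weeks of age, and the
knockout trajectory can be summarized by a single-exponential
degeneration fit T(t) = A + (T0 − A)·exp(−t/τ).

Scan offsets (−20, −10, 0, +10, +20) are treated as labels for the five
analyzed B-scans around the optic-nerve crossing, not as physical
angles.  Layer segmentation is an input: this module consumes thickness
profiles, it does not segment images.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ThicknessProfile",
    "DegenerationFit",
    "SCAN_OFFSETS",
    "sample_grid",
    "grid_positions",
    "eye_mean",
    "summarize_cohort",
    "normalize_series",
    "fit_degeneration",
]

logger = logging.getLogger(__name__)

SCAN_OFFSETS = (-20, -10, 0, 10, 20)
DEFAULT_INTERVAL_MM = 1.0
DEFAULT_EXCLUSION_MM = 0.5


@dataclass
class ThicknessProfile:
    """One B-scan's thickness vs position (mm from the optic nerve)."""

    positions: np.ndarray
    thickness: np.ndarray
    scan_offset: int = 0
    layer: str = "total"
    eye: str = "OD"
    animal_id: str = ""
    genotype: str = "+/+"
    age_weeks: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.thickness = np.asarray(self.thickness, dtype=float)
        if self.positions.shape != self.thickness.shape or self.positions.ndim != 1:
            raise ValueError("positions and thickness must be matching 1-D arrays")
        if self.positions.size < 2:
            raise ValueError("a profile needs at least 2 points")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.thickness <= 0):
            raise ValueError("thickness values must be positive")
        if self.scan_offset not in SCAN_OFFSETS:
            raise ValueError(f"scan_offset must be one of {SCAN_OFFSETS}")


def grid_positions(extent: tuple[float, float],
                   interval: float = DEFAULT_INTERVAL_MM,
                   exclusion: float = DEFAULT_EXCLUSION_MM) -> np.ndarray:
    """Sampling positions ±(exclusion + k·interval) within ``extent``.

    Anchored at the exclusion boundary on both sides of the optic nerve
    so every admissible point as close to the nerve as allowed is used.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    if exclusion < 0:
        raise ValueError("exclusion must be >= 0")
    lo, hi = extent
    ks = np.arange(0, max(0.0, (max(abs(lo), hi) - exclusion)) // interval + 1)
    pos = exclusion + ks * interval
    grid = np.concatenate([-pos[::-1], pos])
    return grid[(grid >= lo) & (grid <= hi)]


def sample_grid(profile: ThicknessProfile,
                interval: float = DEFAULT_INTERVAL_MM,
                exclusion: float = DEFAULT_EXCLUSION_MM) -> tuple[np.ndarray, np.ndarray]:
    """Thickness at the grid positions, by linear interpolation.

    Returns ``(positions, values)``; errors if no grid point falls
    within the profile's extent.
    """
    grid = grid_positions((profile.positions[0], profile.positions[-1]), interval, exclusion)
    if grid.size == 0:
        raise ValueError(
            f"no sampling point within profile extent "
            f"[{profile.positions[0]}, {profile.positions[-1]}] mm "
            f"(animal {profile.animal_id!r}, scan {profile.scan_offset:+d})")
    return grid, np.interp(grid, profile.positions, profile.thickness)


def eye_mean(profiles: list[ThicknessProfile],
             interval: float = DEFAULT_INTERVAL_MM,
             exclusion: float = DEFAULT_EXCLUSION_MM) -> float:
    """Unweighted mean over all sampled points of all scans of one eye.

    Up to five scans are expected; fewer are tolerated (down to one,
    with a warning), zero is an error.
    """
    if not profiles:
        raise ValueError("eye_mean needs at least one scan")
    if len(profiles) < 5:
        logger.warning("only %d of 5 scans present for animal %r eye %r",
                       len(profiles), profiles[0].animal_id, profiles[0].eye)
    vals = np.concatenate([sample_grid(p, interval, exclusion)[1] for p in profiles])
    return float(vals.mean())


def _profiles_from_table(df: pd.DataFrame) -> list[ThicknessProfile]:
    keys = ["animal", "genotype", "age_weeks", "eye", "scan_offset", "layer"]
    out = []
    for vals, g in df.groupby(keys, dropna=False):
        g = g.sort_values("position_mm")
        out.append(ThicknessProfile(
            positions=g["position_mm"].to_numpy(),
            thickness=g["thickness_um"].to_numpy(),
            scan_offset=int(vals[4]), layer=str(vals[5]), eye=str(vals[3]),
            animal_id=str(vals[0]), genotype=str(vals[1]), age_weeks=float(vals[2]),
        ))
    return out


def summarize_cohort(df: pd.DataFrame,
                     layer: str = "total",
                     interval: float = DEFAULT_INTERVAL_MM,
                     exclusion: float = DEFAULT_EXCLUSION_MM) -> pd.DataFrame:
    """Group thickness summary from a long profile table.

    Expects columns (animal, genotype, age_weeks, eye, scan_offset,
    position_mm, layer, thickness_um).  Averaging is hierarchical:
    sampled points → per-eye mean → per-animal mean → group mean ± SE
    by genotype × age.
    """
    sub = df[df["layer"] == layer]
    if sub.empty:
        raise ValueError(f"no rows for layer {layer!r}")
    profiles = _profiles_from_table(sub)
    rows = []
    by_eye: dict[tuple, list[ThicknessProfile]] = {}
    for p in profiles:
        by_eye.setdefault((p.animal_id, p.genotype, p.age_weeks, p.eye), []).append(p)
    for (animal, genotype, age, eye), ps in by_eye.items():
        rows.append({"animal": animal, "genotype": genotype, "age_weeks": age,
                     "eye": eye, "eye_mean_um": eye_mean(ps, interval, exclusion)})
    per_eye = pd.DataFrame(rows)
    per_animal = (per_eye.groupby(["animal", "genotype", "age_weeks"])["eye_mean_um"]
                  .mean().reset_index())
    g = per_animal.groupby(["genotype", "age_weeks"])["eye_mean_um"]
    summary = g.agg(mean_um="mean", se_um="sem", n="count").reset_index()
    summary["se_um"] = summary["se_um"].fillna(0.0)
    return summary


def normalize_series(summary: pd.DataFrame,
                     baseline_genotype: str = "+/+",
                     baseline_age: float = 2.0) -> pd.DataFrame:
    """Divide group means by the wildtype thickness at the baseline age.

    The baseline entry itself maps to exactly 1.0; a missing baseline
    group is an error.
    """
    ref = summary[(summary["genotype"] == baseline_genotype)
                  & np.isclose(summary["age_weeks"].astype(float), baseline_age)]
    if ref.empty:
        raise ValueError(
            f"baseline group ({baseline_genotype!r} at {baseline_age} weeks) missing")
    baseline = float(ref.iloc[0]["mean_um"])
    if baseline <= 0:
        raise ValueError("baseline thickness must be positive")
    out = summary.copy()
    out["mean_norm"] = out["mean_um"] / baseline
    out["se_norm"] = out["se_um"] / baseline
    return out


@dataclass(frozen=True)
class DegenerationFit:
    """Exponential-decay summary of a normalized thinning trajectory."""

    t0: float
    asymptote: float
    tau_weeks: float
    residual_norm: float
    converged: bool
    tau_identifiable: bool


def fit_degeneration(age_weeks: np.ndarray, values: np.ndarray) -> DegenerationFit:
    """Least-squares fit of T(t) = A + (T0 − A)·exp(−t/τ).

    Needs at least 4 time points.  A flat series leaves τ
    unidentifiable; that (and non-convergence) is flagged rather than
    raised, with the best-effort estimates returned.
    """
    t = np.asarray(age_weeks, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size or t.size < 4:
        raise ValueError("need >= 4 (age, value) pairs")

    def model(tt, t0, a, tau):
        return a + (t0 - a) * np.exp(-tt / tau)

    span = max(t.max() - t.min(), 1.0)
    p0 = (y[np.argmin(t)], y[np.argmax(t)], span / 3)
    if np.ptp(y) < 1e-12:  # flat: amplitude zero, tau meaningless
        return DegenerationFit(t0=float(y[0]), asymptote=float(y[0]), tau_weeks=np.nan,
                               residual_norm=0.0, converged=True, tau_identifiable=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(model, t, y, p0=p0,
                                   bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
                                   maxfev=20_000)
        converged = np.all(np.isfinite(popt))
    except RuntimeError:
        return DegenerationFit(*p0, residual_norm=np.inf, converged=False,
                               tau_identifiable=False)
    resid = float(np.linalg.norm(y - model(t, *popt)))
    # tau is unidentifiable when the fitted amplitude is negligible or
    # its variance estimate exploded
    amp = abs(popt[0] - popt[1])
    tau_var = pcov[2, 2] if np.all(np.isfinite(pcov)) else np.inf
    identifiable = bool(amp > 1e-6 * max(1.0, abs(popt[0])) and np.isfinite(tau_var)
                        and np.sqrt(tau_var) < 100 * span)
    return DegenerationFit(t0=float(popt[0]), asymptote=float(popt[1]),
                           tau_weeks=float(popt[2]), residual_norm=resid,
                           converged=bool(converged), tau_identifiable=identifiable)
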
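"""Synthetic background-matching experiments with known ground truth.

Generates repeated-measures colour-change experiments with the structure the
analysis assumes — populations differing in how fast they approach their
test background, fish-level random intercepts, sex and length covariates,
and measurement noise — plus flat synthetic photographs with embedded grey
standards so the calibration stage is testable without real imagery.

The trajectory model is this generator's own assumption (the study design
does not parameterise dynamics): each colour metric relaxes exponentially
from its acclimated starting value toward the background's nominal value,

    m(t) = target + (m0 - target) * (gap + (1 - gap) * exp(-k t))
           + b_fish + eps(t)

where ``k`` (per minute) sets the speed — large ``k`` gives the rapid
first-minute change of strong colour changers, small ``k`` a steady drift —
and ``gap`` is the fraction of the initial mismatch never closed. ``b_fish``
is a fish-level random intercept drawn once per fish and ``eps`` is i.i.d.
measurement noise; with both SDs zero the closed form holds exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import Region

__all__ = [
    "METRICS",
    "BackgroundSpec",
    "ExperimentDesign",
    "PopulationProfile",
    "FishCovariates",
    "CameraModel",
    "DEFAULT_BACKGROUNDS",
    "DEFAULT_PROFILES",
    "null_profiles",
    "generate_fish_cohort",
    "simulate_colour_trajectory",
    "generate_cone_catch_table",
    "catches_from_metrics",
    "min_saturation_for_hue",
    "render_synthetic_image",
]

METRICS = ("luminance", "hue", "saturation")

#: Floor applied to simulated catches; log contrasts need strict positivity.
CATCH_FLOOR = 1e-6


def _per_metric(value: float | Mapping[str, float]) -> dict[str, float]:
    """Broadcast a scalar parameter to all metrics, or validate a mapping."""
    if isinstance(value, Mapping):
        missing = set(METRICS) - set(value)
        if missing:
            raise ValueError(f"per-metric mapping missing {sorted(missing)}")
        return {m: float(value[m]) for m in METRICS}
    return {m: float(value) for m in METRICS}


@dataclass(frozen=True)
class BackgroundSpec:
    """One printed test background: nominal colour targets on metric scales.

    ``reflectance`` doubles as the background's nominal luminance on the
    double-cone catch scale (reflectance units). ``saturation`` defaults to
    the least-saturated colour-space point consistent with the nominal hue.
    ``instant_shift`` models any instantaneous (reflective, minute-0) colour
    response to the background as an additive shift of the starting values.
    """

    label: str
    reflectance: float
    hue: float = 0.0
    saturation: float | None = None
    instant_shift: float | Mapping[str, float] = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.reflectance < 1:
            raise ValueError(f"reflectance must be in (0, 1); got {self.reflectance}")
        if not -0.5 < self.hue < 1.0:
            raise ValueError(f"hue must lie in (-0.5, 1); got {self.hue}")

    def targets(self) -> dict[str, float]:
        sat = self.saturation
        if sat is None:
            sat = min_saturation_for_hue(self.hue)
        return {"luminance": self.reflectance, "hue": self.hue, "saturation": sat}


#: The five test backgrounds of the study design. Black/white reflectances
#: are the measured paper values (5.9% and 85.5%); the chromatic backgrounds
#: use their measured average hues (beige 0.005, brown 0.015, green 0.075)
#: with plausible substrate reflectances, as the printed papers' reflectances
#: are design choices of this generator.
DEFAULT_BACKGROUNDS = (
    BackgroundSpec("black", reflectance=0.059),
    BackgroundSpec("white", reflectance=0.855),
    BackgroundSpec("beige", reflectance=0.40, hue=0.005),
    BackgroundSpec("brown", reflectance=0.25, hue=0.015),
    BackgroundSpec("green", reflectance=0.18, hue=0.075),
)


@dataclass(frozen=True)
class ExperimentDesign:
    """Dimensions and sampling plan of one synthetic experiment.

    Defaults mirror the study: 4 populations × 5 backgrounds × 20 fish per
    population-background cell, photographed at minutes 0, 1, 8 and 15, with
    fish length ~ Normal(3.5, 0.67²) cm truncated at zero.
    """

    populations: tuple[str, ...] = ("FW1", "FW2", "MW1", "MW2")
    backgrounds: tuple[BackgroundSpec, ...] = DEFAULT_BACKGROUNDS
    fish_per_cell: int = 20
    time_points_min: tuple[float, ...] = (0.0, 1.0, 8.0, 15.0)
    seed: int = 0
    length_mean_cm: float = 3.5
    length_sd_cm: float = 0.67
    background_measurement_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.fish_per_cell < 2:
            raise ValueError(f"fish_per_cell must be >= 2; got {self.fish_per_cell}")
        times = tuple(self.time_points_min)
        if len(times) < 1 or any(t < 0 for t in times):
            raise ValueError("time points must be non-empty and non-negative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"time points must be strictly increasing; got {times}")
        labels = [b.label for b in self.backgrounds]
        if len(set(labels)) != len(labels):
            raise ValueError("background labels must be unique")
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("population labels must be unique")
        if not self.length_mean_cm > 0 or not self.length_sd_cm >= 0:
            raise ValueError("length distribution parameters invalid")

    @property
    def n_fish(self) -> int:
        return len(self.populations) * len(self.backgrounds) * self.fish_per_cell


@dataclass(frozen=True)
class PopulationProfile:
    """Ground-truth colour-change dynamics of one population.

    ``baseline_*`` are the acclimated (midpoint-grey) starting values;
    ``rate_k`` (per minute) and ``asymptote_gap`` shape the approach to the
    background; ``fish_sd``/``resid_sd`` are the random-intercept and
    residual noise SDs; ``sex_effect`` (added for males) and
    ``length_effect`` (per cm of length, centred at the cohort mean) inject
    recoverable covariate effects, both zero by default. Scalar values are
    broadcast across metrics; pass a mapping for per-metric control.
    """

    baseline_luminance: float = 0.457
    baseline_hue: float = 0.0
    baseline_saturation: float = 0.01
    rate_k: float | Mapping[str, float] = 1.5
    asymptote_gap: float | Mapping[str, float] = 0.3
    fish_sd: float | Mapping[str, float] = field(
        default_factory=lambda: {"luminance": 0.04, "hue": 0.004, "saturation": 0.008})
    resid_sd: float | Mapping[str, float] = field(
        default_factory=lambda: {"luminance": 0.04, "hue": 0.004, "saturation": 0.008})
    sex_effect: float | Mapping[str, float] = 0.0
    length_effect: float | Mapping[str, float] = 0.0

    def __post_init__(self) -> None:
        for name in ("rate_k", "asymptote_gap", "fish_sd", "resid_sd"):
            vals = _per_metric(getattr(self, name))
            if any(v < 0 for v in vals.values()):
                raise ValueError(f"{name} must be >= 0; got {vals}")
        gaps = _per_metric(self.asymptote_gap)
        if any(not 0 <= g <= 1 for g in gaps.values()):
            raise ValueError(f"asymptote_gap must lie in [0, 1]; got {gaps}")

    def baselines(self) -> dict[str, float]:
        return {"luminance": self.baseline_luminance, "hue": self.baseline_hue,
                "saturation": self.baseline_saturation}


#: Default population profiles: three fast changers with slightly different
#: rates and one steady (slow, incomplete) changer, expressing both dynamic
#: regimes the trajectory model supports.
DEFAULT_PROFILES: dict[str, PopulationProfile] = {
    "FW1": PopulationProfile(rate_k=1.8, asymptote_gap=0.30),
    "FW2": PopulationProfile(rate_k=1.2, asymptote_gap=0.35),
    "MW1": PopulationProfile(rate_k=1.5, asymptote_gap=0.25),
    "MW2": PopulationProfile(rate_k=0.25, asymptote_gap=0.45),
}


def null_profiles(design: ExperimentDesign,
                  base: PopulationProfile | None = None) -> dict[str, PopulationProfile]:
    """Profiles in which every population shares one dynamic (no interaction)."""
    base = base if base is not None else PopulationProfile()
    return {pop: base for pop in design.populations}


@dataclass(frozen=True)
class FishCovariates:
    """Identity and covariates of one experimental fish."""

    fish_id: str
    population: str
    background: str
    sex: str
    length_cm: float

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F'; got {self.sex!r}")
        if not self.length_cm > 0:
            raise ValueError(f"length must be > 0; got {self.length_cm}")


def _truncated_normal_lengths(rng: np.random.Generator, n: int,
                              mean: float, sd: float) -> np.ndarray:
    """Normal draws truncated at zero by resampling."""
    lengths = rng.normal(mean, sd, size=n)
    while (lengths <= 0).any():
        bad = lengths <= 0
        lengths[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return lengths


def generate_fish_cohort(
    design: ExperimentDesign,
    profiles: Mapping[str, PopulationProfile],
) -> list[FishCovariates]:
    """Draw the full fish cohort: ids, population/background assignment, covariates.

    Each population contributes ``fish_per_cell`` fish to every background.
    Sexes are balanced within each cell up to rounding (order shuffled);
    lengths are truncated-normal draws. Deterministic given ``design.seed``.
    """
    missing = set(design.populations) - set(profiles)
    if missing:
        raise ValueError(f"no profile for populations: {sorted(missing)}")
    rng = np.random.default_rng(design.seed)
    cohort: list[FishCovariates] = []
    counter = 0
    for pop in design.populations:
        for bg in design.backgrounds:
            n = design.fish_per_cell
            sexes = np.array(["M", "F"] * (n // 2) + ["M"] * (n % 2))
            rng.shuffle(sexes)
            lengths = _truncated_normal_lengths(
                rng, n, design.length_mean_cm, design.length_sd_cm)
            for i in range(n):
                counter += 1
                cohort.append(FishCovariates(
                    fish_id=f"F{counter:04d}",
                    population=pop,
                    background=bg.label,
                    sex=str(sexes[i]),
                    length_cm=float(lengths[i]),
                ))
    return cohort


def simulate_colour_trajectory(
    fish: FishCovariates,
    profile: PopulationProfile,
    background_targets: Mapping[str, float],
    times: Sequence[float],
    rng: np.random.Generator | None = None,
    start_values: Mapping[str, float] | None = None,
    length_centre_cm: float = 3.5,
) -> dict[str, np.ndarray]:
    """Simulate one fish's per-metric colour trajectory at the given times.

    Returns ``{metric: values}`` following the exponential-approach model in
    the module docstring, with the fish's random intercept, covariate
    effects and residual noise added. With both noise SDs zero the closed
    form is exact. ``start_values`` overrides the profile baselines (used
    for instantaneous minute-0 shifts).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if (times < 0).any():
        raise ValueError(f"negative time points: {times[times < 0]}")
    rng = rng if rng is not None else np.random.default_rng(0)

    rate = _per_metric(profile.rate_k)
    gap = _per_metric(profile.asymptote_gap)
    fish_sd = _per_metric(profile.fish_sd)
    resid_sd = _per_metric(profile.resid_sd)
    sex_eff = _per_metric(profile.sex_effect)
    len_eff = _per_metric(profile.length_effect)
    starts = dict(profile.baselines())
    if start_values:
        starts.update({m: float(v) for m, v in start_values.items()})

    out: dict[str, np.ndarray] = {}
    for m in METRICS:
        target = float(background_targets[m])
        m0 = starts[m]
        decay = gap[m] + (1.0 - gap[m]) * np.exp(-rate[m] * times)
        mean = target + (m0 - target) * decay
        shift = 0.0
        if fish.sex == "M":
            shift += sex_eff[m]
        shift += len_eff[m] * (fish.length_cm - length_centre_cm)
        b_fish = rng.normal(0.0, fish_sd[m]) if fish_sd[m] > 0 else 0.0
        eps = rng.normal(0.0, resid_sd[m], size=times.size) if resid_sd[m] > 0 else 0.0
        out[m] = mean + shift + b_fish + eps
    return out


def min_saturation_for_hue(hue: float) -> float:
    """Saturation of the least-saturated colour-space point with a given hue.

    Hue pins the standardised MW catch (``s_MW = (hue + 0.5) / 1.5``); along
    the remaining LW-versus-SW freedom the distance from the achromatic
    centre is minimised in closed form.
    """
    s_mw = (hue + 0.5) / 1.5
    if not 0 <= s_mw <= 1:
        raise ValueError(f"hue {hue} outside representable range")
    c = 1.0 - 1.5 * s_mw
    u = (s_mw + 2.0 * c) / 4.0  # argmin of the squared distance in s_LW
    u = min(max(u, 0.0), 1.0 - s_mw)
    x = math.sqrt(0.5) * (u - s_mw)
    y = math.sqrt(2.0 / 3.0) * (1.0 - 1.5 * s_mw - 1.5 * u)
    return math.hypot(x, y)


def catches_from_metrics(luminance: float, hue: float, saturation: float
                         ) -> tuple[float, float, float, float]:
    """Invert (luminance, hue, saturation) to catches ``(q_SW, q_MW, q_LW, q_dbl)``.

    The standardised triple is reconstructed from hue (which fixes
    ``s_MW``) and saturation (a quadratic in ``s_LW``; the longer-wavelength
    root is taken, matching fish-like warm colours); single-cone catches are
    scaled so their sum is ``3 * luminance``. Requested saturations below the
    hue's geometric minimum (or values driven out of range by noise) are
    clamped, and all catches are floored at a small positive value.
    """
    lum = max(float(luminance), CATCH_FLOOR)
    h = min(max(float(hue), -0.499), 0.999)
    s_mw = (h + 0.5) / 1.5
    c = 1.0 - 1.5 * s_mw

    sat = max(float(saturation), min_saturation_for_hue(h))
    # (u - s_mw)^2 / 2 + (2/3) (c - 1.5 u)^2 = sat^2, u = s_LW
    a2 = 2.0
    a1 = -(s_mw + 2.0 * c)
    a0 = 0.5 * s_mw ** 2 + (2.0 / 3.0) * c ** 2 - sat ** 2
    disc = a1 ** 2 - 4.0 * a2 * a0
    if disc < 0:  # numerically just below the minimum-saturation circle
        disc = 0.0
    u = (-a1 + math.sqrt(disc)) / (2.0 * a2)
    u = min(max(u, 0.0), 1.0 - s_mw)
    s_lw, s_sw = u, 1.0 - s_mw - u

    total = 3.0 * lum
    q_sw = max(s_sw * total, CATCH_FLOOR)
    q_mw = max(s_mw * total, CATCH_FLOOR)
    q_lw = max(s_lw * total, CATCH_FLOOR)
    return (q_sw, q_mw, q_lw, lum)


TABLE_COLUMNS = [
    "fish_id", "population", "background", "sex", "length_cm", "time_min",
    "role", "q_SW", "q_MW", "q_LW", "q_dbl",
]


def generate_cone_catch_table(
    design: ExperimentDesign,
    profiles: Mapping[str, PopulationProfile],
) -> pd.DataFrame:
    """Generate the long-format cone-catch table for a whole experiment.

    One row per fish × time point (``role == "fish"``) plus one background
    ROI row per fish at minute 0 (``role == "background"``), mirroring the
    per-image background measurement. All catches strictly positive;
    bitwise-deterministic given ``design.seed``.
    """
    cohort = generate_fish_cohort(design, profiles)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    bg_by_label = {b.label: b for b in design.backgrounds}
    times = np.asarray(design.time_points_min, dtype=float)

    rows = []
    for fish in cohort:
        bg = bg_by_label[fish.background]
        targets = bg.targets()
        shift = _per_metric(bg.instant_shift)
        profile = profiles[fish.population]
        starts = {m: profile.baselines()[m] + shift[m] for m in METRICS}
        traj = simulate_colour_trajectory(
            fish, profile, targets, times, rng=rng, start_values=starts,
            length_centre_cm=design.length_mean_cm)
        for j, t in enumerate(times):
            q_sw, q_mw, q_lw, q_dbl = catches_from_metrics(
                traj["luminance"][j], traj["hue"][j], traj["saturation"][j])
            rows.append((fish.fish_id, fish.population, fish.background,
                         fish.sex, fish.length_cm, float(t), "fish",
                         q_sw, q_mw, q_lw, q_dbl))
        bsd = design.background_measurement_sd
        noise = rng.normal(0.0, bsd, size=3) if bsd > 0 else np.zeros(3)
        q_sw, q_mw, q_lw, q_dbl = catches_from_metrics(
            targets["luminance"] + noise[0], targets["hue"] + noise[1],
            targets["saturation"] + noise[2])
        rows.append((fish.fish_id, fish.population, fish.background,
                     fish.sex, fish.length_cm, 0.0, "background",
                     q_sw, q_mw, q_lw, q_dbl))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


@dataclass(frozen=True)
class CameraModel:
    """Monotone camera response ``pixel = offset + gain * R**(1/gamma)``.

    ``gamma == 1`` gives a linear camera; ``gamma == 2.2`` emulates typical
    display-referred encoding. The response is applied identically to every
    channel.
    """

    gain: float = 1.0
    offset: float = 0.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.gamma <= 0:
            raise ValueError("gain and gamma must be > 0")

    def response(self, reflectance: np.ndarray | float) -> np.ndarray | float:
        r = np.clip(np.asarray(reflectance, dtype=float), 0.0, None)
        out = self.offset + self.gain * np.power(r, 1.0 / self.gamma)
        return out if out.ndim else float(out)


def render_synthetic_image(
    fish_reflectance: float | Sequence[float],
    background_reflectance: float | Sequence[float],
    standards: Sequence[float],
    camera: CameraModel | None = None,
    shape: tuple[int, int] = (96, 128),
    n_channels: int = 3,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict[str, Region]]:
    """Render a flat synthetic photograph with labelled regions.

    The background fills the frame; a central rectangle is the fish and the
    grey standards sit in the top corners. Pixel values are
    ``camera.response(reflectance)`` plus optional Gaussian noise. Returns
    the float image (H×W×C) and a label→:class:`~camoquant.calibration.Region`
    mapping for the calibration stage.
    """
    stds = [float(s) for s in standards]
    if len(stds) < 2:
        raise ValueError("need at least 2 reflectance standards")
    if len(set(stds)) != len(stds):
        raise ValueError("duplicate standard reflectances leave the "
                         "linearisation underdetermined")
    if any(not 0 < s <= 1 for s in stds):
        raise ValueError(f"standards must lie in (0, 1]; got {stds}")
    camera = camera if camera is not None else CameraModel()
    rng = rng if rng is not None else np.random.default_rng(0)

    h, w = shape
    if h < 32 or w < 32:
        raise ValueError("image must be at least 32x32")

    def _chan(x) -> np.ndarray:
        arr = np.asarray(x, dtype=float).ravel()
        if arr.size == 1:
            arr = np.repeat(arr, n_channels)
        if arr.size != n_channels:
            raise ValueError(f"expected 1 or {n_channels} reflectances, got {arr.size}")
        return arr

    image = np.empty((h, w, n_channels), dtype=float)
    image[:] = camera.response(_chan(background_reflectance))

    regions: dict[str, Region] = {}
    fh, fw = h // 4, w // 3
    fish_reg = Region(top=h // 2 - fh // 2, left=w // 2 - fw // 2,
                      bottom=h // 2 - fh // 2 + fh, right=w // 2 - fw // 2 + fw)
    image[fish_reg.slices()] = camera.response(_chan(fish_reflectance))
    regions["fish"] = fish_reg
    # background ROI: a clear patch away from fish and standards
    regions["background"] = Region(top=3 * h // 4, left=2, bottom=h - 2, right=w // 3)

    ps = min(h, w) // 6
    for i, s in enumerate(stds):
        left = 2 + i * (ps + 4)
        reg = Region(top=2, left=left, bottom=2 + ps, right=left + ps)
        if reg.right > w:
            raise ValueError("too many standards for the image width")
        image[reg.slices()] = camera.response(s)
        regions[f"standard_{i}"] = reg

    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    return image, regions
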
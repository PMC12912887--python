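"""Avian cone-catch visual modelling and colour-space metrics.

Maps calibrated per-channel reflectances into the quantum catches of a
trichromatic avian receiver (single cones SW, MW, LW plus the double cone,
``dbl``, assumed to mediate achromatic vision) and derives the colour metrics
used throughout the pipeline:

* **luminance** — the double-cone catch, taken directly;
* **standardised catches** — each single-cone catch divided by the sum of the
  three, removing overall intensity;
* **colour-space coordinates** — the standardised triple projected into a
  trichromatic (Maxwell-triangle) space with Cartesian coordinates
  ``x = sqrt(1/2) * (s_LW - s_MW)`` and
  ``y = sqrt(2/3) * (s_SW - (s_LW + s_MW) / 2)``;
* **saturation** — Euclidean distance from the achromatic centre (the origin);
* **hue** — the signed contrast of the standardised middle-wave catch against
  the mean of the long- and short-wave catches,
  ``h = s_MW - (s_LW + s_SW) / 2``; 0 means achromatic (equal catches).

Receptor noise for the chromatic channels is propagated from the reference
(most abundant) cone's Weber fraction through the relative cone densities:
``e_i = sqrt(eta_ref / eta_i) * e_ref``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VisualSystemSpec",
    "ConeCatch",
    "StandardisedCatch",
    "ColourMetrics",
    "PEAFOWL",
    "BACKGROUND_HUE_REFERENCES",
    "receptor_noise",
    "printed_receptor_noise",
    "luminance",
    "standardise_catches",
    "colour_space_xy",
    "saturation",
    "hue",
    "map_camera_to_cones",
    "identity_transform",
    "metrics_from_catch",
    "add_metric_columns",
]

SINGLE_CONES = ("SW", "MW", "LW")

#: Measured average hues of the printed chromatic backgrounds. These are
#: observed values shipped for labelling plots and sanity checks only; they
#: are not recomputable from first principles.
BACKGROUND_HUE_REFERENCES = {"beige": 0.005, "brown": 0.015, "green": 0.075}


@dataclass(frozen=True)
class VisualSystemSpec:
    """A receiver's receptor set and noise model.

    Parameters
    ----------
    densities
        Relative cone densities for the single cones, e.g. peafowl
        ``{"SW": 1.9, "MW": 2.2, "LW": 2.1}``. Only ratios matter.
    weber_reference
        Weber fraction of the reference cone (the most abundant class).
    weber_achromatic
        Weber fraction of the double-cone (achromatic) channel.
    reference
        Label of the reference cone; must appear in ``densities``.
    """

    densities: Mapping[str, float]
    weber_reference: float = 0.06
    weber_achromatic: float = 0.2
    reference: str = "MW"

    def __post_init__(self) -> None:
        for cone in SINGLE_CONES:
            if cone not in self.densities:
                raise ValueError(f"densities must include {cone!r}")
            if not self.densities[cone] > 0:
                raise ValueError(f"density for {cone!r} must be > 0")
        if self.reference not in self.densities:
            raise ValueError(f"reference cone {self.reference!r} not in densities")
        for name, w in (("weber_reference", self.weber_reference),
                        ("weber_achromatic", self.weber_achromatic)):
            if not 0 < w < 1:
                raise ValueError(f"{name} must lie in (0, 1); got {w}")


#: The peafowl (Pavo cristatus) trichromatic model used as the avian
#: predator receiver: cone abundances SW 1.9 : MW 2.2 : LW 2.1, MW Weber
#: fraction 0.06, double-cone Weber fraction 0.2.
PEAFOWL = VisualSystemSpec(densities={"SW": 1.9, "MW": 2.2, "LW": 2.1})


@dataclass(frozen=True)
class ConeCatch:
    """Quantum catches of one stimulus on an arbitrary common scale.

    Single-cone catches must be strictly positive (log contrasts are taken
    downstream). ``dbl`` may be ``None`` for purely chromatic records.
    """

    sw: float
    mw: float
    lw: float
    dbl: float | None = None

    def __post_init__(self) -> None:
        for name, q in (("sw", self.sw), ("mw", self.mw), ("lw", self.lw)):
            if not q > 0:
                raise ValueError(f"cone catch {name} must be > 0; got {q}")
        if self.dbl is not None and not self.dbl > 0:
            raise ValueError(f"double-cone catch must be > 0; got {self.dbl}")

    def chromatic_triple(self) -> tuple[float, float, float]:
        """Catches ordered (SW, MW, LW)."""
        return (self.sw, self.mw, self.lw)


@dataclass(frozen=True)
class StandardisedCatch:
    """Single-cone catches normalised to sum to one."""

    s_sw: float
    s_mw: float
    s_lw: float

    def __post_init__(self) -> None:
        total = self.s_sw + self.s_mw + self.s_lw
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"standardised catches must sum to 1; got {total}")
        if min(self.s_sw, self.s_mw, self.s_lw) < -1e-12:
            raise ValueError("standardised catches must be non-negative")


@dataclass(frozen=True)
class ColourMetrics:
    """The per-record colour metrics analysed by the statistics layer."""

    luminance: float | None
    x: float
    y: float
    saturation: float
    hue: float


def receptor_noise(spec: VisualSystemSpec) -> dict[str, float]:
    """Propagate the reference Weber fraction to every single cone.

    ``e_i = sqrt(eta_ref / eta_i) * e_ref`` — less abundant cone classes are
    noisier. The reference cone's own noise is returned unchanged. Values are
    carried at full precision; see :func:`printed_receptor_noise` for the
    conventional 4-decimal display form.
    """
    eta_ref = spec.densities[spec.reference]
    noises = {}
    for cone in SINGLE_CONES:
        eta = spec.densities[cone]
        if not eta > 0:
            raise ValueError(f"density for {cone!r} must be > 0")
        noises[cone] = math.sqrt(eta_ref / eta) * spec.weber_reference
    return noises


def printed_receptor_noise(spec: VisualSystemSpec, decimals: int = 4) -> dict[str, float]:
    """Receptor noises truncated (not rounded) to ``decimals`` places.

    Display convention for reporting Weber fractions: the trailing digits are
    dropped, e.g. 0.0645636 -> 0.0645 at 4 dp. Computation elsewhere always
    uses the full-precision values from :func:`receptor_noise`.
    """
    scale = 10 ** decimals
    return {c: math.floor(e * scale) / scale for c, e in receptor_noise(spec).items()}


def luminance(catch: ConeCatch) -> float:
    """Achromatic signal: the double-cone catch, unchanged."""
    if catch.dbl is None:
        raise ValueError("catch has no double-cone (dbl) value; luminance undefined")
    return catch.dbl


def standardise_catches(catch: ConeCatch) -> StandardisedCatch:
    """Divide each single-cone catch by the sum of the three."""
    total = catch.sw + catch.mw + catch.lw
    if not total > 0:
        raise ValueError("sum of single-cone catches must be > 0")
    return StandardisedCatch(s_sw=catch.sw / total, s_mw=catch.mw / total,
                             s_lw=catch.lw / total)


_X_COEF = math.sqrt(0.5)
_Y_COEF = math.sqrt(2.0 / 3.0)


def colour_space_xy(s: StandardisedCatch) -> tuple[float, float]:
    """Cartesian coordinates in the trichromatic colour space.

    The achromatic point (1/3, 1/3, 1/3) maps to the origin; each pure-catch
    vertex lies at distance sqrt(2/3) from it.
    """
    x = _X_COEF * (s.s_lw - s.s_mw)
    y = _Y_COEF * (s.s_sw - (s.s_lw + s.s_mw) / 2.0)
    return (x, y)


def saturation(x: float, y: float) -> float:
    """Distance from the achromatic centre of the colour space."""
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError("coordinates must be finite")
    return math.hypot(x, y)


def hue(s: StandardisedCatch) -> float:
    """Signed middle-versus-ends contrast: ``s_MW - (s_LW + s_SW) / 2``.

    Zero for an achromatic stimulus (equal catches); positive when the
    middle-wave channel dominates. Under the sum-to-one constraint this
    equals ``1.5 * s_MW - 0.5`` and lies in [-1/2, 1].
    """
    return s.s_mw - (s.s_lw + s.s_sw) / 2.0


def identity_transform(channels: Sequence[str] = ("R", "G", "B")) -> pd.DataFrame:
    """Camera→cone matrix mapping three channels directly onto LW/MW/SW.

    The long-wave-most channel drives LW and so on; the double cone is the
    mean of the three. A stand-in for a fitted camera mapping so the
    downstream maths can run on synthetic imagery without claiming any real
    camera's coefficients.
    """
    if len(channels) != 3:
        raise ValueError("identity transform needs exactly 3 channels")
    rows = {
        "LW": [1.0, 0.0, 0.0],
        "MW": [0.0, 1.0, 0.0],
        "SW": [0.0, 0.0, 1.0],
        "dbl": [1 / 3, 1 / 3, 1 / 3],
    }
    return pd.DataFrame(rows, index=list(channels)).T


def map_camera_to_cones(
    reflectances: Mapping[str, float] | pd.Series,
    transform: pd.DataFrame,
    record_id: str | None = None,
) -> ConeCatch:
    """Linear camera-to-receiver mapping: ``catch_r = sum_c T[r, c] * refl[c]``.

    Parameters
    ----------
    reflectances
        Calibrated per-channel reflectances keyed by channel name.
    transform
        Coefficient matrix with receptor rows (must cover SW, MW, LW, dbl)
        and channel columns matching ``reflectances``.
    record_id
        Optional identifier included in error messages.
    """
    required = set(SINGLE_CONES) | {"dbl"}
    missing = required - set(transform.index)
    if missing:
        raise ValueError(f"transform missing receptor rows: {sorted(missing)}")
    refl = pd.Series(reflectances, dtype=float)
    missing_ch = set(transform.columns) - set(refl.index)
    if missing_ch:
        raise ValueError(f"reflectances missing channels: {sorted(missing_ch)}")
    catches = transform @ refl[transform.columns]
    bad = catches[catches <= 0]
    if len(bad):
        who = f" for record {record_id!r}" if record_id else ""
        raise ValueError(
            f"non-positive cone catch{who}: {bad.to_dict()} "
            "(check calibration and transform)"
        )
    return ConeCatch(sw=float(catches["SW"]), mw=float(catches["MW"]),
                     lw=float(catches["LW"]), dbl=float(catches["dbl"]))


def metrics_from_catch(catch: ConeCatch) -> ColourMetrics:
    """Compute all colour metrics for one catch record."""
    s = standardise_catches(catch)
    x, y = colour_space_xy(s)
    return ColourMetrics(
        luminance=catch.dbl,
        x=x,
        y=y,
        saturation=saturation(x, y),
        hue=hue(s),
    )


def add_metric_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Append standardised catches, colour-space coordinates and metrics.

    Expects columns ``q_SW, q_MW, q_LW, q_dbl`` (strictly positive). Returns
    a copy with ``s_SW, s_MW, s_LW, x, y, luminance, hue, saturation`` added.
    """
    for col in ("q_SW", "q_MW", "q_LW", "q_dbl"):
        if col not in table.columns:
            raise ValueError(f"table missing required column {col!r}")
        if not (table[col] > 0).all():
            bad = table.index[table[col] <= 0].tolist()[:5]
            raise ValueError(f"non-positive {col} at rows {bad}")
    out = table.copy()
    total = out["q_SW"] + out["q_MW"] + out["q_LW"]
    out["s_SW"] = out["q_SW"] / total
    out["s_MW"] = out["q_MW"] / total
    out["s_LW"] = out["q_LW"] / total
    out["x"] = _X_COEF * (out["s_LW"] - out["s_MW"])
    out["y"] = _Y_COEF * (out["s_SW"] - (out["s_LW"] + out["s_MW"]) / 2.0)
    out["luminance"] = out["q_dbl"]
    out["hue"] = out["s_MW"] - (out["s_LW"] + out["s_SW"]) / 2.0
    out["saturation"] = np.hypot(out["x"], out["y"])
    return out
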
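"""Receptor-noise-limited (RNL) discrimination distances in JND units.

Perceptual distances between a fish and its test background as seen by the
modelled avian receiver, following the log-linear receptor-contrast form of
the RNL model (the Vorobyev–Osorio model with logarithmic quantum-catch
contrasts, as modified by Siddiqi and colleagues):

* achromatic:  ``dL = |ln(q_dbl_a / q_dbl_b)| / e_dbl``
* chromatic (trichromat), with ``df_i = ln(q_i_a / q_i_b)``::

      dS^2 = [ e_SW^2 (df_LW - df_MW)^2
             + e_MW^2 (df_LW - df_SW)^2
             + e_LW^2 (df_SW - df_MW)^2 ]
             / [ (e_SW e_MW)^2 + (e_SW e_LW)^2 + (e_MW e_LW)^2 ]

Both are expressed in just-noticeable differences (JNDs): below 1 the two
stimuli are indistinguishable to the receiver, between 1 and 3 they may be
detectable under good viewing conditions, and above 3 they become
increasingly distinguishable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .visual_model import ConeCatch, VisualSystemSpec, receptor_noise

__all__ = [
    "JNDResult",
    "achromatic_jnd",
    "chromatic_jnd",
    "classify_detectability",
    "compare_stimuli",
    "add_jnd_columns",
]

#: Detectability bands in JND units. Values exactly at a boundary fall in the
#: "conditional" band (the 1–3 range is read inclusively).
INDISTINGUISHABLE_BELOW = 1.0
DISTINGUISHABLE_ABOVE = 3.0


@dataclass(frozen=True)
class JNDResult:
    """Achromatic and chromatic RNL distances for one fish–background pair."""

    achromatic_jnd: float
    chromatic_jnd: float
    achromatic_category: str
    chromatic_category: str


def achromatic_jnd(q_dbl_a: float, q_dbl_b: float, weber: float = 0.2) -> float:
    """Luminance (double-cone) contrast in JNDs.

    ``|ln(q_a / q_b)| / e`` with the achromatic Weber fraction ``e``
    (default 0.2). Symmetric in its arguments and zero iff the catches are
    equal.
    """
    if not (q_dbl_a > 0 and q_dbl_b > 0):
        raise ValueError(f"catches must be > 0; got {q_dbl_a}, {q_dbl_b}")
    if not weber > 0:
        raise ValueError(f"Weber fraction must be > 0; got {weber}")
    return abs(math.log(q_dbl_a / q_dbl_b)) / weber


def chromatic_jnd(
    catch_a: ConeCatch | Sequence[float],
    catch_b: ConeCatch | Sequence[float],
    noises: Sequence[float] | dict[str, float],
) -> float:
    """Trichromatic RNL colour distance in JNDs.

    Parameters
    ----------
    catch_a, catch_b
        Cone catches of the two stimuli, either :class:`ConeCatch` objects
        or (SW, MW, LW) triples. Strictly positive.
    noises
        Receptor Weber fractions, either a ``{"SW": .., "MW": .., "LW": ..}``
        mapping (e.g. from :func:`~camoquant.visual_model.receptor_noise`)
        or an (e_SW, e_MW, e_LW) triple.

    The distance is invariant to a common positive rescaling of either
    stimulus's three catches: only log-catch *differences* between receptor
    channels enter.
    """
    a = catch_a.chromatic_triple() if isinstance(catch_a, ConeCatch) else tuple(catch_a)
    b = catch_b.chromatic_triple() if isinstance(catch_b, ConeCatch) else tuple(catch_b)
    if isinstance(noises, dict):
        e = (noises["SW"], noises["MW"], noises["LW"])
    else:
        e = tuple(noises)
    if len(a) != 3 or len(b) != 3 or len(e) != 3:
        raise ValueError("catches and noises must each have 3 entries (SW, MW, LW)")
    if min(a) <= 0 or min(b) <= 0:
        raise ValueError(f"cone catches must be > 0; got {a}, {b}")
    if min(e) <= 0:
        raise ValueError(f"receptor noises must be > 0; got {e}")

    e_sw, e_mw, e_lw = e
    df_sw = math.log(a[0] / b[0])
    df_mw = math.log(a[1] / b[1])
    df_lw = math.log(a[2] / b[2])
    num = (
        e_sw ** 2 * (df_lw - df_mw) ** 2
        + e_mw ** 2 * (df_lw - df_sw) ** 2
        + e_lw ** 2 * (df_sw - df_mw) ** 2
    )
    den = (e_sw * e_mw) ** 2 + (e_sw * e_lw) ** 2 + (e_mw * e_lw) ** 2
    return math.sqrt(num / den)


def classify_detectability(jnd: float) -> str:
    """Map a JND to its detectability band.

    <1 → ``indistinguishable``; 1–3 (inclusive) → ``conditional`` (possibly
    detectable under good viewing conditions); >3 → ``distinguishable``.
    """
    if jnd < 0 or not math.isfinite(jnd):
        raise ValueError(f"JND must be finite and >= 0; got {jnd}")
    if jnd < INDISTINGUISHABLE_BELOW:
        return "indistinguishable"
    if jnd <= DISTINGUISHABLE_ABOVE:
        return "conditional"
    return "distinguishable"


def compare_stimuli(
    catch_a: ConeCatch, catch_b: ConeCatch, spec: VisualSystemSpec
) -> JNDResult:
    """Full achromatic + chromatic comparison of two stimuli under a receiver."""
    dl = achromatic_jnd(catch_a.dbl, catch_b.dbl, weber=spec.weber_achromatic)
    ds = chromatic_jnd(catch_a, catch_b, receptor_noise(spec))
    return JNDResult(
        achromatic_jnd=dl,
        chromatic_jnd=ds,
        achromatic_category=classify_detectability(dl),
        chromatic_category=classify_detectability(ds),
    )


def add_jnd_columns(table: pd.DataFrame, spec: VisualSystemSpec) -> pd.DataFrame:
    """Append per-row fish-versus-background JND columns to a long table.

    Each fish row is compared against the background ROI of its own image,
    measured once at minute 0 (rows with ``role == "background"``) and reused
    for the later time points. Adds ``luminance_jnd``, ``colour_jnd``,
    ``luminance_jnd_category`` and ``colour_jnd_category`` to the fish rows;
    background rows are dropped from the output.
    """
    for col in ("fish_id", "role", "q_SW", "q_MW", "q_LW", "q_dbl"):
        if col not in table.columns:
            raise ValueError(f"table missing required column {col!r}")
    bg = table[table["role"] == "background"]
    if bg.empty:
        raise ValueError("table has no background rows (role == 'background')")
    dup = bg["fish_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"multiple background rows for fish {bg.loc[dup, 'fish_id'].tolist()[:5]}"
        )
    fish = table[table["role"] == "fish"].copy()
    missing = set(fish["fish_id"]) - set(bg["fish_id"])
    if missing:
        raise ValueError(f"no background row for fish {sorted(missing)[:5]}")

    bg_idx = bg.set_index("fish_id")
    noises = receptor_noise(spec)
    e = (noises["SW"], noises["MW"], noises["LW"])

    b = bg_idx.loc[fish["fish_id"], ["q_SW", "q_MW", "q_LW", "q_dbl"]].to_numpy(float)
    f = fish[["q_SW", "q_MW", "q_LW", "q_dbl"]].to_numpy(float)
    if (f <= 0).any() or (b <= 0).any():
        raise ValueError("all cone catches must be > 0 for JND computation")

    dl = np.abs(np.log(f[:, 3] / b[:, 3])) / spec.weber_achromatic
    dfq = np.log(f[:, :3] / b[:, :3])  # columns: SW, MW, LW
    e_sw, e_mw, e_lw = e
    num = (
        e_sw ** 2 * (dfq[:, 2] - dfq[:, 1]) ** 2
        + e_mw ** 2 * (dfq[:, 2] - dfq[:, 0]) ** 2
        + e_lw ** 2 * (dfq[:, 0] - dfq[:, 1]) ** 2
    )
    den = (e_sw * e_mw) ** 2 + (e_sw * e_lw) ** 2 + (e_mw * e_lw) ** 2
    ds = np.sqrt(num / den)

    fish["luminance_jnd"] = dl
    fish["colour_jnd"] = ds
    fish["luminance_jnd_category"] = [classify_detectability(v) for v in dl]
    fish["colour_jnd_category"] = [classify_detectability(v) for v in ds]
    return fish.reset_index(drop=True)
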
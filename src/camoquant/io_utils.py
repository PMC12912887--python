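"""Table, image and configuration plumbing for pipeline runs.

CSV is the interchange format between stages. Every table written by the
pipeline carries ``#``-prefixed header comment lines recording the package
version and a hash of the resolved run configuration, so outputs are
traceable to the exact run that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import Region
from .synthetic_data import (
    BackgroundSpec,
    DEFAULT_BACKGROUNDS,
    ExperimentDesign,
    PopulationProfile,
)
from .visual_model import VisualSystemSpec

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "write_table",
    "load_long_table",
    "read_table",
    "write_regions",
    "read_regions",
    "REQUIRED_CATCH_COLUMNS",
]

REQUIRED_CATCH_COLUMNS = [
    "fish_id", "population", "background", "sex", "length_cm", "time_min",
    "role", "q_SW", "q_MW", "q_LW", "q_dbl",
]

_CONFIG_KEYS = {
    "seed", "design", "profiles", "visual_system", "transform_overrides",
    "tukey_family", "outdir", "column_map",
}
_DESIGN_KEYS = {
    "populations", "backgrounds", "fish_per_cell", "time_points_min",
    "length_mean_cm", "length_sd_cm", "background_measurement_sd",
}
_PROFILE_KEYS = {
    "baseline_luminance", "baseline_hue", "baseline_saturation", "rate_k",
    "asymptote_gap", "fish_sd", "resid_sd", "sex_effect", "length_effect",
}
_VISUAL_KEYS = {"densities", "weber_reference", "weber_achromatic", "reference"}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    profiles: dict[str, PopulationProfile] | None = None
    visual_system: VisualSystemSpec | None = None
    transform_overrides: dict[str, str] = field(default_factory=dict)
    tukey_family: str = "within"
    outdir: str = "camoquant_out"
    column_map: dict[str, str] = field(default_factory=dict)

    def resolved(self) -> dict[str, Any]:
        """Plain-dict form of the full configuration (written next to outputs)."""
        from .synthetic_data import DEFAULT_PROFILES
        from .visual_model import PEAFOWL

        profiles = self.profiles or {
            p: DEFAULT_PROFILES.get(p, PopulationProfile())
            for p in self.design.populations
        }
        vs = self.visual_system or PEAFOWL
        return {
            "seed": self.seed,
            "design": {
                "populations": list(self.design.populations),
                "backgrounds": [asdict(b) for b in self.design.backgrounds],
                "fish_per_cell": self.design.fish_per_cell,
                "time_points_min": list(self.design.time_points_min),
                "seed": self.design.seed,
                "length_mean_cm": self.design.length_mean_cm,
                "length_sd_cm": self.design.length_sd_cm,
                "background_measurement_sd": self.design.background_measurement_sd,
            },
            "profiles": {k: asdict(v) for k, v in profiles.items()},
            "visual_system": {
                "densities": dict(vs.densities),
                "weber_reference": vs.weber_reference,
                "weber_achromatic": vs.weber_achromatic,
                "reference": vs.reference,
            },
            "transform_overrides": dict(self.transform_overrides),
            "tukey_family": self.tukey_family,
            "outdir": self.outdir,
            "column_map": dict(self.column_map),
        }


def _reject_unknown(mapping: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected at every level so typos fail loudly before
    any compute starts.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    _reject_unknown(raw, _CONFIG_KEYS, "config")

    seed = int(raw.get("seed", 0))
    design_raw = dict(raw.get("design", {}))
    _reject_unknown(design_raw, _DESIGN_KEYS, "design")
    backgrounds = design_raw.pop("backgrounds", None)
    if backgrounds is not None:
        backgrounds = tuple(BackgroundSpec(**b) for b in backgrounds)
    else:
        backgrounds = DEFAULT_BACKGROUNDS
    if "populations" in design_raw:
        design_raw["populations"] = tuple(design_raw["populations"])
    if "time_points_min" in design_raw:
        design_raw["time_points_min"] = tuple(design_raw["time_points_min"])
    design = ExperimentDesign(backgrounds=backgrounds, seed=seed, **design_raw)

    profiles = None
    if "profiles" in raw:
        profiles = {}
        for pop, p in dict(raw["profiles"]).items():
            _reject_unknown(p, _PROFILE_KEYS, f"profiles.{pop}")
            profiles[pop] = PopulationProfile(**p)

    visual = None
    if "visual_system" in raw:
        v = dict(raw["visual_system"])
        _reject_unknown(v, _VISUAL_KEYS, "visual_system")
        if "densities" not in v:
            raise ValueError("visual_system requires 'densities' "
                             "(relative cone densities for SW, MW, LW)")
        visual = VisualSystemSpec(**v)

    overrides = dict(raw.get("transform_overrides", {}))
    for metric, transform in overrides.items():
        if transform not in ("identity", "log", "sqrt"):
            raise ValueError(f"unknown transform {transform!r} for {metric!r}")
    tukey_family = raw.get("tukey_family", "within")
    if tukey_family not in ("within", "all"):
        raise ValueError(f"tukey_family must be 'within' or 'all'; got {tukey_family!r}")

    return RunConfig(seed=seed, design=design, profiles=profiles,
                     visual_system=visual, transform_overrides=overrides,
                     tukey_family=tukey_family,
                     outdir=str(raw.get("outdir", "camoquant_out")),
                     column_map=dict(raw.get("column_map", {})))


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the resolved scientific configuration.

    The output location is excluded so identical runs written to different
    directories produce identical tables.
    """
    resolved = config.resolved()
    resolved.pop("outdir", None)
    blob = json.dumps(resolved, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path,
                config: RunConfig | None = None) -> Path:
    """Write a CSV with provenance header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# camoquant {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash {config_hash(config)}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (comment lines skipped)."""
    return pd.read_csv(path, comment="#")


def load_long_table(
    path: str | Path,
    required: list[str] | None = None,
    column_map: Mapping[str, str] | None = None,
    on_bad_rows: str = "error",
) -> pd.DataFrame:
    """Load and validate a long-format cone-catch table.

    Parameters
    ----------
    path
        Delimited text file (comma-separated; ``#`` comments allowed).
    required
        Columns that must be present after renaming (defaults to the
        pipeline's cone-catch schema).
    column_map
        Optional ``{file column -> canonical column}`` renaming, for
        externally deposited tables whose headers differ.
    on_bad_rows
        ``"error"`` (default) raises on rows with non-numeric or
        non-positive catches; ``"skip"`` drops and logs them.
    """
    if on_bad_rows not in ("error", "skip"):
        raise ValueError(f"on_bad_rows must be 'error' or 'skip'; got {on_bad_rows!r}")
    required = required if required is not None else REQUIRED_CATCH_COLUMNS
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"{path}: file is empty or has no data rows")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    numeric = [c for c in ("length_cm", "time_min", "q_SW", "q_MW", "q_LW", "q_dbl")
               if c in required]
    bad_mask = np.zeros(len(df), dtype=bool)
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_mask |= vals.isna().to_numpy()
        df[col] = vals
    for col in ("q_SW", "q_MW", "q_LW", "q_dbl"):
        if col in df.columns:
            bad_mask |= ~(df[col] > 0).to_numpy()
    if bad_mask.any():
        bad_rows = df.index[bad_mask].tolist()
        if on_bad_rows == "error":
            raise ValueError(
                f"{path}: {bad_mask.sum()} rows with non-numeric or "
                f"non-positive values (first few: {bad_rows[:5]}); "
                "pass on_bad_rows='skip' to drop them"
            )
        logger.warning("%s: dropping %d flagged rows", path, int(bad_mask.sum()))
        df = df[~bad_mask]
        if df.empty:
            raise ValueError(f"{path}: no valid rows remain after filtering")
    return df.reset_index(drop=True)


def write_regions(regions: Mapping[str, Region], path: str | Path) -> Path:
    """Write a region-annotation sidecar (JSON) for a rendered image.

    Boxes are 0-based with half-open pixel intervals, keyed by label.
    """
    path = Path(path)
    payload = {
        label: {"top": r.top, "left": r.left, "bottom": r.bottom, "right": r.right}
        for label, r in regions.items()
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def read_regions(path: str | Path) -> dict[str, Region]:
    """Read a region-annotation sidecar written by :func:`write_regions`."""
    payload = json.loads(Path(path).read_text())
    return {label: Region(**box) for label, box in payload.items()}
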
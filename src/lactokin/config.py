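"""Parameter-file IO, regimen presets, and run metadata."""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import yaml

from .model_core import DosingRegimen, FeedingPattern, ParameterSet

__all__ = ["load_parameters", "save_parameters", "default_parameters",
           "REGIMENS", "get_regimen", "run_metadata"]

#: maternal dosing presets
REGIMENS = {
    "standard": DosingRegimen(0.5, 24.0, 14, "standard"),
    "high-od": DosingRegimen(1.0, 24.0, 7, "high-od"),
    "high-bid": DosingRegimen(0.5, 12.0, 14, "high-bid"),
    "sld": DosingRegimen(0.25, 24.0, 1, "sld"),
    "weekly8": DosingRegimen(0.75, 168.0, 8, "weekly8"),
}


def get_regimen(label: str) -> DosingRegimen:
    try:
        return REGIMENS[label]
    except KeyError:
        raise KeyError(f"unknown regimen {label!r}; choose from "
                       f"{sorted(REGIMENS)}") from None


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Load a validated :class:`ParameterSet` from YAML (the bundled final
    model estimates when ``path`` is None).  Unknown keys are rejected."""
    if path is None:
        text = (resources.files("lactokin") / "data/final_model_params.yaml"
                ).read_text()
    else:
        text = Path(path).read_text()
    d = yaml.safe_load(text)
    if not isinstance(d, dict):
        raise ValueError("parameter file must be a mapping")
    return ParameterSet.from_dict(d)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def default_parameters() -> ParameterSet:
    return load_parameters(None)


def run_metadata(seed: int | None, config: dict | None = None) -> dict:
    """Seed / version / config-hash block embedded in every artifact."""
    from . import __version__
    blob = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "package": "lactokin",
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:12],
    }
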
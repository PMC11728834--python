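"""Packaged calibration constants and run-configuration validation."""

from __future__ import annotations

from functools import lru_cache

import yaml

from ._resources import read_text


@lru_cache(maxsize=None)
def calibration_constants() -> dict[str, float]:
    """Constants fixed by scripts/calibrate.py (permeability law, surfaces)."""
    return dict(yaml.safe_load(read_text("calibration.yaml")))
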
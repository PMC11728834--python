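"""Access to packaged data resources, with integrity checking.

Every packaged CSV/YAML is listed in ``data/checksums.json`` (regenerated by
``scripts/freeze_checksums.py``); a mismatch between the stored and computed
SHA-256 digest raises at load time so silently corrupted resources can never
parameterize a simulation.
"""

from __future__ import annotations

import hashlib
import json
from functools import lru_cache
from importlib import resources

REFERENCE_WEIGHT_KG = 73.0

_PACKAGE = "etrapbpk.data"


@lru_cache(maxsize=None)
def _manifest() -> dict[str, str]:
    with resources.files(_PACKAGE).joinpath("checksums.json").open("r") as fh:
        return json.load(fh)


@lru_cache(maxsize=None)
def read_text(name: str, verify: bool = True) -> str:
    text = resources.files(_PACKAGE).joinpath(name).read_text()
    if verify:
        expected = _manifest().get(name)
        if expected is not None:
            digest = hashlib.sha256(text.encode()).hexdigest()
            if digest != expected:
                raise RuntimeError(
                    f"packaged resource {name!r} failed its integrity check "
                    f"(sha256 {digest} != {expected})"
                )
    return text
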
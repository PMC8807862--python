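"""Run-configuration loading (packaged defaults plus user overrides)."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

_DEFAULTS = Path(__file__).parent / "config" / "defaults.yaml"


def _merge(base: dict, over: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Packaged default configuration, optionally deep-merged with a user file."""
    cfg = yaml.safe_load(_DEFAULTS.read_text())
    if path is not None:
        cfg = _merge(cfg, yaml.safe_load(Path(path).read_text()) or {})
    return cfg
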
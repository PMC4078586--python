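"""JSON persistence for fitted models."""

from __future__ import annotations

import json
from pathlib import Path

from .combined import CombinedModel
from .errors import FormatError
from .gravimetric import GravimetricModel
from .humidity import CorrectionFactorModel

_KINDS = {
    "cf": CorrectionFactorModel,
    "gravimetric": GravimetricModel,
    "combined": CombinedModel,
}


def model_to_dict(model) -> dict:
    return model.to_dict()


def model_from_dict(d: dict):
    kind = d.get("kind")
    if kind not in _KINDS:
        raise FormatError(f"unknown model kind {kind!r}")
    return _KINDS[kind].from_dict(d)


def save_model(model, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True) + "\n")


def load_model(path: str | Path):
    return model_from_dict(json.loads(Path(path).read_text()))
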
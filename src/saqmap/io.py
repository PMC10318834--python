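"""Model and table round-tripping: JSON model documents, cohort CSV."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

from . import __version__
from .direct import FittedDirectModel
from .mixtures import FittedALDVMM, FittedBetaMix
from .response import OrderedLogitModel
from .valuesets import DIMENSIONS

AnyModel = FittedDirectModel | FittedALDVMM | FittedBetaMix | Mapping[str, OrderedLogitModel]


def model_to_document(model: AnyModel) -> dict:
    if isinstance(model, (FittedDirectModel, FittedALDVMM, FittedBetaMix)):
        doc = model.to_dict()
    elif isinstance(model, Mapping):
        doc = {
            "method": "indirect",
            "dimensions": {d: model[d].to_dict() for d in DIMENSIONS},
        }
    else:
        raise TypeError(f"cannot serialise {type(model).__name__}")
    doc["package_version"] = __version__
    return doc


def save_model(model: AnyModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_document(model), indent=1))


def load_model(path: str | Path) -> AnyModel:
    doc = json.loads(Path(path).read_text())
    method = doc.get("method")
    if method in ("ols", "tobit", "glm", "clad", "rmm"):
        return FittedDirectModel.from_dict(doc)
    if method == "aldvmm":
        return FittedALDVMM.from_dict(doc)
    if method == "betamix":
        return FittedBetaMix.from_dict(doc)
    if method == "indirect":
        return {d: OrderedLogitModel.from_dict(b)
                for d, b in doc["dimensions"].items()}
    raise ValueError(f"unrecognised model document (method={method!r})")
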
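"""JSON serialization of fitted models and preprocessing state.

Models reload exactly: stored patterns, coefficients and hyperparameters
round-trip at full float precision (floats serialized via repr-faithful
JSON numbers).
"""

from __future__ import annotations

import json

import numpy as np

from .classifiers.knn import KNNModel
from .classifiers.pnn import PNNModel
from .classifiers.svm import BinarySVC, SVCModel
from .errors import DataError
from .preprocess import StandardizationParams


def standardizer_to_dict(p: StandardizationParams) -> dict:
    return {"mean": p.mean.tolist(), "std": p.std.tolist()}


def standardizer_from_dict(d: dict) -> StandardizationParams:
    return StandardizationParams(np.asarray(d["mean"]), np.asarray(d["std"]))


def model_to_dict(model) -> dict:
    if isinstance(model, PNNModel):
        return {
            "kind": "pnn",
            "X": model.X.tolist(),
            "y": model.y.tolist(),
            "sigma": model.sigma,
            "classes": list(model.classes),
        }
    if isinstance(model, KNNModel):
        return {
            "kind": "knn",
            "X": model.X.tolist(),
            "y": model.y.tolist(),
            "k": model.k,
            "classes": list(model.classes),
        }
    if isinstance(model, SVCModel):
        return {
            "kind": "svc",
            "C": model.C,
            "gamma": model.gamma,
            "classes": list(model.classes),
            "subproblems": [
                {
                    "classes": list(p.classes),
                    "X": p.X.tolist(),
                    "y": p.y.tolist(),
                    "alpha": p.alpha.tolist(),
                    "b": p.b,
                }
                for p in model.subproblems
            ],
        }
    raise DataError(f"cannot serialize object of type {type(model).__name__}")


def model_from_dict(d: dict):
    kind = d.get("kind")
    classes = tuple(d["classes"])
    if kind == "pnn":
        return PNNModel(
            X=np.asarray(d["X"], float),
            y=np.asarray(d["y"], object),
            sigma=float(d["sigma"]),
            classes=classes,
        )
    if kind == "knn":
        return KNNModel(
            X=np.asarray(d["X"], float),
            y=np.asarray(d["y"], object),
            k=int(d["k"]),
            classes=classes,
        )
    if kind == "svc":
        subs = tuple(
            BinarySVC(
                classes=tuple(p["classes"]),
                X=np.asarray(p["X"], float),
                y=np.asarray(p["y"], float),
                alpha=np.asarray(p["alpha"], float),
                b=float(p["b"]),
                gamma=float(d["gamma"]),
                C=float(d["C"]),
            )
            for p in d["subproblems"]
        )
        return SVCModel(subproblems=subs, C=float(d["C"]), gamma=float(d["gamma"]),
                        classes=classes)
    raise DataError(f"unknown model kind {kind!r}")


def save_model(model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, sort_keys=True)


def load_model(path):
    with open(path) as fh:
        return model_from_dict(json.load(fh))
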
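"""JSON checkpoints: parameter sets, feature-name manifest, config snapshot."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .networks import ModelBundle
from .stat_features import FeatureScaler


def save_checkpoint(bundle: ModelBundle, path,
                    feature_names: list[str] | None = None) -> Path:
    """Serialise all three parameter sets plus scaler and config to JSON."""
    path = Path(path)
    scaler = getattr(bundle, "scaler", None)
    payload = {
        "config": bundle.config,
        "feature_names": feature_names,
        "params": [p.data.tolist() for p in bundle.parameters()],
        "scaler": None if scaler is None else {
            "mean": scaler.mean_.tolist(), "scale": scaler.scale_.tolist()},
        "signal_scaler": None if getattr(bundle, "signal_scaler", None) is None
        else {k: v.tolist() for k, v in bundle.signal_scaler.items()},
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload))
    return path


def load_checkpoint(path) -> tuple[ModelBundle, list[str] | None]:
    payload = json.loads(Path(path).read_text())
    bundle = ModelBundle.create(**payload["config"])
    params = bundle.parameters()
    if len(params) != len(payload["params"]):
        raise ValueError("checkpoint parameter count mismatch")
    for p, data in zip(params, payload["params"]):
        arr = np.asarray(data, dtype=float)
        if arr.shape != p.data.shape:
            raise ValueError("checkpoint parameter shape mismatch")
        p.data = arr
    if payload["scaler"] is not None:
        scaler = FeatureScaler()
        scaler.mean_ = np.asarray(payload["scaler"]["mean"])
        scaler.scale_ = np.asarray(payload["scaler"]["scale"])
        bundle.scaler = scaler
    if payload.get("signal_scaler") is not None:
        bundle.signal_scaler = {k: np.asarray(v)
                                for k, v in payload["signal_scaler"].items()}
    return bundle, payload.get("feature_names")
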
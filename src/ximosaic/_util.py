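"""Shared helpers: seed derivation, the Hill response curve, small IO utilities."""
from __future__ import annotations

import hashlib
import json
from typing import Any

import numpy as np


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Derive a child seed from a master seed, a stage name and a replicate index.

    The scheme is a stable cryptographic hash truncated to 31 bits, so child
    streams are decorrelated and reproducible across platforms and sessions.
    """
    token = f"{int(master_seed)}|{stage}|{int(index)}".encode()
    digest = hashlib.sha256(token).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def hill(x: np.ndarray | float, x50: float, h: float) -> np.ndarray | float:
    """Saturating Hill response x^h / (x^h + x50^h), in [0, 1].

    ``x50 == 0`` is the uniform limit: the response is 1 for every x > 0.
    """
    if x50 < 0:
        raise ValueError("x50 must be >= 0")
    if h <= 0:
        raise ValueError("Hill exponent h must be positive")
    x = np.asarray(x, dtype=float)
    if x50 == 0:
        out = np.where(x > 0, 1.0, 0.0)
    else:
        xh = np.power(x, h)
        out = xh / (xh + x50**h)
    return float(out) if out.ndim == 0 else out


def canonical_json(obj: Any) -> str:
    """Deterministic JSON serialization (sorted keys, no whitespace drift)."""
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), default=_jsonable)


def _jsonable(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def config_hash(obj: Any) -> str:
    return hashlib.sha256(canonical_json(obj).encode()).hexdigest()[:16]
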
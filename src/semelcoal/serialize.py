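"""JSON (de)serialization of life-history parameter sets."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .life_history import LifeHistory

__all__ = ["to_json", "from_json", "load", "dump"]

_KNOWN = {"k", "n_juvenile", "p", "c", "N", "phi"}


def to_json(lh: LifeHistory) -> str:
    """Serialize to a flat JSON object {k, n_juvenile, p, c, N[, phi]}."""
    obj = {
        "k": lh.k,
        "n_juvenile": lh.n_juvenile,
        "p": lh.p.tolist(),
        "c": lh.c.tolist(),
        "N": lh.N,
    }
    if lh.phi is not None:
        obj["phi"] = lh.phi
    return json.dumps(obj, indent=2)


def from_json(text: str, lax: bool = False) -> LifeHistory:
    """Parse a life history; unknown fields are rejected unless ``lax``."""
    obj = json.loads(text)
    if not isinstance(obj, dict):
        raise ValueError("life-history JSON must be an object")
    unknown = set(obj) - _KNOWN
    if unknown and not lax:
        raise ValueError(f"unknown life-history fields: {sorted(unknown)}")
    for key in ("p", "c", "N"):
        if key not in obj:
            raise ValueError(f"missing required field {key!r}")
    p = np.asarray(obj["p"], dtype=float)
    c = np.asarray(obj["c"], dtype=float)
    if "k" in obj and int(obj["k"]) != len(p):
        raise ValueError(f"declared k={obj['k']} does not match len(p)={len(p)}")
    return LifeHistory(
        p=p,
        c=c,
        N=float(obj["N"]),
        n_juvenile=int(obj.get("n_juvenile", 2)),
        phi=None if obj.get("phi") is None else float(obj["phi"]),
    )


def dump(lh: LifeHistory, path) -> None:
    Path(path).write_text(to_json(lh) + "\n")


def load(path, lax: bool = False) -> LifeHistory:
    return from_json(Path(path).read_text(), lax=lax)
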
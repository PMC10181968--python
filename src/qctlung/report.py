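"""JSON analysis reports.

Schema (``report.json``)::

    {
      "software": {"name": "qctlung", "version": ...},
      "seed": <int or null>,
      "regions": [ {<QCTProfile fields>}, ... ],
      "models": { ... arbitrary fitted-model payload ... }
    }

Every payload object must be JSON-serializable after numpy scalar/array
coercion; anything else raises an explicit error rather than being dropped.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Any, Sequence

import numpy as np

from . import __version__
from .parenchyma import QCTProfile

__all__ = ["write_report", "read_report", "ReportSerializationError"]


class ReportSerializationError(TypeError):
    pass


def _coerce(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _coerce(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _coerce(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_coerce(v) for v in obj]
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    raise ReportSerializationError(
        f"cannot serialize object of type {type(obj).__name__} into a report"
    )


def write_report(
    path,
    *,
    regions: Sequence[QCTProfile] = (),
    models: dict | None = None,
    seed: int | None = None,
    extra: dict | None = None,
) -> dict:
    """Write a schema-conforming JSON report; returns the written payload."""
    payload = {
        "software": {"name": "qctlung", "version": __version__},
        "seed": seed,
        "regions": [_coerce(p.to_dict()) for p in regions],
    }
    if models is not None:
        payload["models"] = _coerce(models)
    if extra is not None:
        payload.update(_coerce(extra))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return payload


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
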
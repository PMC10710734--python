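"""Result writers/readers: CSV for tables, JSON for single results.

Floats round-trip exactly (17 significant digits); every JSON payload
carries a schema version so downstream readers can detect layout changes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Union

import numpy as np
import pandas as pd

__all__ = ["write_results", "read_results", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "to_dict"):
            return _jsonable(obj.to_dict())
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_results(result: Any, path: Union[str, Path], format: str | None = None) -> Path:
    """Write a DataFrame as CSV or any mapping/dataclass as JSON.

    The format is inferred from the suffix when not given.  Raises
    ``ValueError`` for unsupported formats.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        if isinstance(result, pd.DataFrame):
            frame = result
        else:
            frame = pd.DataFrame(result)
        frame.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "json":
        payload = {"schema_version": SCHEMA_VERSION, "result": _jsonable(result)}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    else:
        raise ValueError(f"unsupported format {fmt!r} (use 'csv' or 'json')")
    return path


def read_results(path: Union[str, Path], format: str | None = None):
    """Read back a file written by :func:`write_results`."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "json":
        payload = json.loads(path.read_text())
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {payload.get('schema_version')}")
        return payload["result"]
    raise ValueError(f"unsupported format {fmt!r} (use 'csv' or 'json')")
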
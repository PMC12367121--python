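"""Serialization helpers: atomic writes, config-stamped CSV and JSON.

Every artifact embeds the resolved configuration and the package version
so a run can be reproduced from its own output; writes go through a
temporary file and an atomic rename so a failed command leaves no partial
output behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict, is_dataclass
from pathlib import Path

import pandas as pd


def _package_version() -> str:
    from . import __version__

    return __version__


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_csv(path: str | Path, frame: pd.DataFrame, config: dict | None = None) -> None:
    """CSV with a ``#``-comment reproducibility header, written atomically."""
    header = [f"# version: {_package_version()}"]
    if config:
        header.append("# config: " + json.dumps(_jsonable(config), sort_keys=True))
    body = frame.to_csv(index=False, float_format="%.12g")
    atomic_write_text(path, "\n".join(header) + "\n" + body)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(path: str | Path, results, config: dict | None = None) -> None:
    payload = {
        "version": _package_version(),
        "config": _jsonable(config or {}),
        "results": _jsonable(results),
    }
    atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True) + "\n")
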
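"""Flat key=value configuration files and CSV conventions.

Config files are plain text, one ``key = value`` per line, ``#`` comments.
Keys carry their units in their names (``delta_t_ms``, ``tone_ipd_rad``,
``bandwidth_hz``); the in-memory representation is rad and rad/s throughout.
CSV output uses a stable column order and ``%.6g`` float formatting so that
write → read → write round-trips byte-identically.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["parse_config", "write_csv", "read_csv"]

FLOAT_FORMAT = "%.6g"


def _coerce(text: str):
    text = text.strip()
    for caster in (int, float):
        try:
            return caster(text)
        except ValueError:
            continue
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    return text


def parse_config(path) -> dict:
    """Parse a flat key=value config file into a dict with typed values."""
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = _coerce(value)
    return out


def write_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
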
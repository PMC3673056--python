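"""Shared readers/writers, configuration handling and run manifests.

All file writes are atomic (write to a temporary file in the destination
directory, then rename) so interrupted runs never leave truncated outputs.
Run manifests record the command, full configuration, seed, package version
and SHA-256 hashes of every artifact written.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path

import pandas as pd
import yaml

from .game import GameParams

__all__ = [
    "TraitTableError",
    "atomic_write",
    "write_json",
    "write_dataframe",
    "read_trait_csv",
    "load_config",
    "game_params_from_config",
    "build_manifest",
    "write_manifest",
]

TRAIT_COLUMNS = {
    "deception_count": "non-negative integer",
    "cooperativeness": "integer in {0, 1, 2, 3}",
    "neocortex_ratio": "positive real",
    "neocortex_volume": "positive real",
    "research_effort": "positive integer",
}
REQUIRED_COLUMNS = ("species", "deception_count", "cooperativeness", "research_effort")


class TraitTableError(ValueError):
    """Trait CSV fails validation."""


def atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json(path: str | Path, obj) -> None:
    atomic_write(path, json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_dataframe(path: str | Path, frame: pd.DataFrame, index: bool = False) -> None:
    atomic_write(path, frame.to_csv(index=index))


def read_trait_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a species trait table.

    Requires a header with at least ``species``, ``deception_count``,
    ``cooperativeness`` and ``research_effort``; the neocortex columns are
    validated when present (at least one is needed for the regression model
    structures). Errors name the offending column, species and CSV row.
    """
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise TraitTableError(f"missing required columns: {missing}")
    dupes = frame["species"][frame["species"].duplicated()].tolist()
    if dupes:
        raise TraitTableError(f"duplicated species rows: {sorted(set(dupes))}")
    for col, desc in TRAIT_COLUMNS.items():
        if col not in frame.columns:
            continue
        series = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[series.isna()].tolist()
        if bad:
            rows = [i + 2 for i in bad]  # 1-based, plus header line
            raise TraitTableError(f"non-numeric {col} (expected {desc}) at CSV rows {rows}")
        frame[col] = series
    _check_range(frame, "deception_count", lambda s: (s >= 0) & (s == s.round()))
    _check_range(frame, "cooperativeness", lambda s: s.isin([0, 1, 2, 3]))
    _check_range(frame, "research_effort", lambda s: (s > 0) & (s == s.round()))
    for col in ("neocortex_ratio", "neocortex_volume"):
        if col in frame.columns:
            _check_range(frame, col, lambda s: s > 0)
    for col in ("deception_count", "cooperativeness", "research_effort"):
        frame[col] = frame[col].astype(int)
    return frame


def _check_range(frame: pd.DataFrame, col: str, predicate) -> None:
    ok = predicate(frame[col])
    if not ok.all():
        bad = frame.loc[~ok, "species"].tolist()
        rows = [i + 2 for i in frame.index[~ok]]
        raise TraitTableError(
            f"invalid {col} (expected {TRAIT_COLUMNS[col]}) for species {bad} "
            f"at CSV rows {rows}"
        )


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a dict."""
    with open(path) as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, dict):
        raise ValueError(f"config {path!r} must be a mapping, got {type(config)}")
    return config


def game_params_from_config(config: dict) -> GameParams:
    """Build validated GameParams from a config mapping (keys b, c, s, d,
    q_mode, q)."""
    keys = {k: config[k] for k in ("b", "c", "s", "d") if k in config}
    missing = [k for k in ("b", "c", "s", "d") if k not in keys]
    if missing:
        raise ValueError(f"config missing game parameters: {missing}")
    return GameParams(
        q_mode=config.get("q_mode", "constant"),
        q=config.get("q"),
        **{k: float(v) for k, v in keys.items()},
    )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def build_manifest(command: str, config: dict, seed: int | None, outputs) -> dict:
    from . import __version__

    return {
        "command": command,
        "config": config,
        "seed": seed,
        "tacdec_version": __version__,
        "outputs": {
            str(p): _sha256(Path(p)) for p in outputs if Path(p).exists()
        },
    }


def write_manifest(path: str | Path, command: str, config: dict, seed, outputs) -> None:
    write_json(path, build_manifest(command, config, seed, outputs))
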
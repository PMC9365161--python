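"""Delimited-table input, result output, and run manifests.

Input is a delimited text file (TSV or CSV, header row) with one row per
participant; column roles (outcome, exposure, instrument(s), interaction
covariates) are bound by name. Output tables round-trip floats at 17
significant digits so a written result re-reads bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import Dataset
from .exceptions import InputError

__all__ = ["read_table", "write_table", "write_json", "RunManifest"]

logger = logging.getLogger("mrgxe")

FLOAT_FORMAT = "%.17g"


def _detect_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _numeric(frame: pd.DataFrame, col: str) -> np.ndarray:
    raw = frame[col]
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise InputError(
            f"non-numeric value {raw.iloc[row]!r} in column {col!r} at data row {row + 1}"
        )
    return vals.to_numpy(dtype=float)


def read_table(
    path,
    *,
    outcome: str,
    exposure: str,
    instrument: str | None = None,
    instruments: list[str] | None = None,
    covariates: list[str] | None = None,
    delimiter: str | None = None,
) -> Dataset:
    """Read a participant table and bind columns to analysis roles.

    Exactly one of ``instrument`` (single score/dosage column) or
    ``instruments`` (sub-instrument columns, e.g. individual variants) is
    required. Rows with a missing value in any bound column are dropped
    (listwise deletion), with per-column missingness logged.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    if (instrument is None) == (instruments is None):
        raise InputError("bind exactly one of instrument / instruments")
    delimiter = delimiter or _detect_delimiter(path)
    frame = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)

    roles: dict[str, str] = {}
    def bind(col: str, role: str) -> None:
        if col not in frame.columns:
            raise InputError(f"column {col!r} (role: {role}) not found in {path.name}")
        if col in roles:
            raise InputError(
                f"column {col!r} bound to conflicting roles: {roles[col]} and {role}"
            )
        roles[col] = role

    bind(outcome, "outcome")
    bind(exposure, "exposure")
    g_cols = [instrument] if instrument else list(instruments)
    for c in g_cols:
        bind(c, "instrument")
    for c in covariates or []:
        bind(c, "covariate")

    cols = {c: _numeric(frame, c) for c in roles}
    mask = np.ones(len(frame), dtype=bool)
    for c, v in cols.items():
        miss = ~np.isfinite(v)
        if miss.any():
            logger.info("column %r: %d missing value(s)", c, int(miss.sum()))
        mask &= ~miss
    dropped = int((~mask).sum())
    if dropped:
        logger.info("listwise deletion removed %d of %d rows", dropped, len(frame))

    z = None
    if covariates:
        z = pd.DataFrame({c: cols[c][mask] for c in covariates})
    kwargs = dict(y=cols[outcome][mask], x=cols[exposure][mask], z=z)
    if instrument:
        kwargs["g"] = cols[instrument][mask]
    else:
        kwargs["g_matrix"] = np.column_stack([cols[c][mask] for c in instruments])
    return Dataset(**kwargs)


def write_table(frame: pd.DataFrame, path) -> Path:
    """Write a result table as TSV with 17-significant-digit floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj


def write_json(obj, path) -> Path:
    """Write any result object (dataclasses included) as JSON; Python float
    repr preserves 17 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(obj), fh, indent=2, allow_nan=True)
        fh.write("\n")
    return path


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-identically: the command,
    its resolved parameters, input-file digests, seed, package version and a
    timestamp (informational only)."""

    command: str
    parameters: dict
    input_digests: dict[str, str]
    seed: int | None
    version: str
    timestamp: str

    @classmethod
    def create(cls, command: str, parameters: dict, inputs=(), seed=None) -> "RunManifest":
        digests = {str(p): _digest(Path(p)) for p in inputs}
        return cls(
            command=command,
            parameters=_jsonable(parameters),
            input_digests=digests,
            seed=seed,
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def save(self, path) -> Path:
        return write_json(self, path)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))
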
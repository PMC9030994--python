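"""Log-file schemas, CSV readers/writers with validation, and the run
manifest.

Every file the CLI writes is re-readable by these functions; writing then
reading a log yields identical records. Timestamps are ISO-8601 local
wall clock (single-time-zone deployment, no offsets). Schema versioning:
``SCHEMA_VERSION`` is recorded in each run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import simulate as _sim
from .types import DeliveryStatus, EMAKind, Rating, Slot

__all__ = [
    "SCHEMA_VERSION",
    "SCHEMAS",
    "SchemaError",
    "read_log",
    "write_log",
    "RunManifest",
    "write_bundle",
    "read_bundle",
    "file_digest",
]

SCHEMA_VERSION = "1"


class SchemaError(ValueError):
    """A log file violates its schema; the message names row and column."""


def _in_set(allowed: set[str], allow_empty: bool = False):
    def check(value) -> bool:
        s = "" if pd.isna(value) else str(value)
        if s == "":
            return allow_empty
        return s in allowed

    return check


def _bool_like(value) -> bool:
    return str(value) in {"True", "False", "true", "false"}


def _nonneg(value) -> bool:
    try:
        return pd.isna(value) or float(value) >= 0
    except (TypeError, ValueError):
        return False


#: schema name -> (column list, {column: validator})
SCHEMAS: dict[str, tuple[list[str], dict]] = {
    "events": (
        _sim.EVENT_COLUMNS,
        {
            "slot": _in_set({s.value for s in Slot}, allow_empty=True),
            "delivery_status": _in_set({d.value for d in DeliveryStatus}),
            "rating": _in_set({r.value for r in Rating}),
            "stale": _bool_like,
            "activity_call_ok": _bool_like,
            "weather_call_ok": _bool_like,
        },
    ),
    "ema": (
        _sim.EMA_COLUMNS,
        {
            "kind": _in_set({k.value for k in EMAKind}),
            "responded": _bool_like,
            "active_today": _in_set({"yes", "no"}, allow_empty=True),
        },
    ),
    "wear": (
        _sim.WEAR_COLUMNS,
        {
            "wear_hours": lambda v: _nonneg(v) and float(v) <= 24,
            "is_weekend": _bool_like,
        },
    ),
    "daily": (
        _sim.DAILY_COLUMNS,
        {"steps": _nonneg, "active_minutes": _nonneg},
    ),
    "survey": (
        _sim.SURVEY_COLUMNS,
        {"response": lambda v: str(v).isdigit() and 1 <= int(v) <= 5},
    ),
    "profiles": (_sim.PROFILE_COLUMNS, {"onboarded": _bool_like}),
}

#: non-string column types per schema; anything unlisted stays a string
_DTYPES: dict[str, dict[str, str]] = {
    "events": {
        "rule_id": "float",
        "stale": "bool",
        "activity_call_ok": "bool",
        "weather_call_ok": "bool",
    },
    "ema": {"week_index": "int", "responded": "bool"},
    "wear": {"wear_hours": "float", "is_weekend": "bool"},
    "daily": {
        "steps": "int",
        "active_minutes": "float",
        "goal_target": "float",
        "goal_met": "bool",
    },
    "survey": {"response": "int"},
    "profiles": {
        "baseline_steps": "float",
        "baseline_active_minutes": "float",
        "onboarded": "bool",
        "goal_increment": "float",
        "goal_target": "float",
        "self_efficacy": "float",
    },
}

_BOOL_MAP = {"True": True, "true": True, "False": False, "false": False}


def write_log(path: str | Path, frame: pd.DataFrame, schema: str) -> Path:
    """Write a log table as CSV after validating it against its schema."""
    path = Path(path)
    _validate(frame, schema, where=str(path))
    columns, _ = SCHEMAS[schema]
    frame = frame.reindex(columns=columns)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, lineterminator="\n")
    return path


def read_log(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV log.

    Columns are converted to the schema's declared types (missing
    numerics become NaN, missing strings stay empty), so a write/read
    cycle reproduces the original table exactly.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    columns, _ = SCHEMAS[schema]
    missing = [c for c in columns if c not in frame.columns]
    extra = [c for c in frame.columns if c not in columns]
    if missing or extra:
        raise SchemaError(
            f"{path}: column mismatch for schema {schema!r} "
            f"(missing {missing}, unexpected {extra})"
        )
    for col, kind in _DTYPES.get(schema, {}).items():
        frame[col] = _convert(frame[col], kind, col, where=str(path))
    _validate(frame, schema, where=str(path))
    return frame


def _convert(series: pd.Series, kind: str, col: str, where: str) -> pd.Series:
    if kind == "bool":
        unknown = ~series.isin(_BOOL_MAP)
        if unknown.any():
            idx = series.index[unknown][0]
            raise SchemaError(
                f"{where}: row {idx}, column {col}: invalid boolean {series[idx]!r}"
            )
        return series.map(_BOOL_MAP)
    numeric = pd.to_numeric(series.replace("", None), errors="coerce")
    bad = numeric.isna() & (series != "")
    if bad.any():
        idx = series.index[bad][0]
        raise SchemaError(
            f"{where}: row {idx}, column {col}: invalid number {series[idx]!r}"
        )
    if kind == "int":
        if numeric.isna().any():
            idx = series.index[numeric.isna()][0]
            raise SchemaError(f"{where}: row {idx}, column {col}: missing integer")
        return numeric.astype("int64")
    return numeric.astype("float64")


def _validate(frame: pd.DataFrame, schema: str, where: str) -> None:
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}")
    _, validators = SCHEMAS[schema]
    for col, check in validators.items():
        if col not in frame.columns:
            continue
        for idx, value in frame[col].items():
            if not check(value):
                raise SchemaError(
                    f"{where}: row {idx}, column {col}: invalid value {value!r}"
                )


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Inventory of one simulation run: version, config echo, seed, and
    per-file row counts and content digests."""

    version: str
    schema_version: str
    seed: int
    config: dict
    files: list[dict]

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    def verify(self, directory: str | Path) -> None:
        """Raise if any inventoried file is missing or its digest drifted."""
        directory = Path(directory)
        for entry in self.files:
            p = directory / entry["name"]
            if not p.exists():
                raise FileNotFoundError(f"manifest lists {entry['name']} but it is missing")
            digest = file_digest(p)
            if digest != entry["sha256"]:
                raise ValueError(
                    f"{entry['name']}: digest {digest} does not match manifest "
                    f"{entry['sha256']}"
                )


def write_bundle(logs: "_sim.TrialLogs", out_dir: str | Path) -> RunManifest:
    """Write a trial's log bundle as CSV files plus ``manifest.json``."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for name, frame in logs.frames().items():
        path = write_log(out_dir / f"{name}.csv", frame, name)
        files.append(
            {"name": path.name, "rows": int(len(frame)), "sha256": file_digest(path)}
        )
    manifest = RunManifest(
        version=__version__,
        schema_version=SCHEMA_VERSION,
        seed=logs.config.seed,
        config=logs.config.model_dump(mode="json"),
        files=files,
    )
    manifest.write(out_dir / "manifest.json")
    return manifest


def read_bundle(log_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read every log table present in a bundle directory."""
    log_dir = Path(log_dir)
    frames = {}
    for name in SCHEMAS:
        path = log_dir / f"{name}.csv"
        if path.exists():
            frames[name] = read_log(path, name)
    if not frames:
        raise FileNotFoundError(f"no log files found in {log_dir}")
    return frames
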
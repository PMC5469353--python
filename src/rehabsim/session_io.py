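"""Session-record CSV round-tripping, run configuration, packaged fixtures.

A session record is a plain CSV with the fixed channel set plus a JSON
sidecar (``<name>.meta.json``) carrying sample rate, joint, controller,
seed and parameters.  Fixtures: the study cohort table (17 subjects with
covariates and dropout flags) and the four per-joint controller parameter
sets, both shipped inside the package.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aan import JointSpec
from .subject import SESSION_COLUMNS, SessionRecord, SubjectProfile

__all__ = [
    "SchemaError",
    "FormatError",
    "read_session",
    "write_session",
    "load_fixtures",
    "load_cohort",
    "load_joints",
    "RunConfig",
    "write_manifest",
]

__version__ = "0.1.0"


class SchemaError(ValueError):
    """A required column is missing from a session CSV."""


class FormatError(ValueError):
    """Malformed session data (e.g., non-uniform timestamps)."""


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_session(record: SessionRecord, path) -> Path:
    """Write a session record as CSV plus its JSON metadata sidecar."""
    path = Path(path)
    record.data.to_csv(path, index=False, float_format="%.12g")
    meta = dict(record.meta)
    meta["sample_rate"] = record.sample_rate
    _meta_path(path).write_text(json.dumps(meta, indent=1, default=str))
    return path


def read_session(path, jitter_tol: float = 0.1) -> SessionRecord:
    """Read a session CSV, validating schema and timestamp uniformity.

    Raises :class:`SchemaError` naming the first missing column, and
    :class:`FormatError` when timestamp jitter exceeds ``jitter_tol``
    sample periods.
    """
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    for col in SESSION_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"session CSV missing required column {col!r}")
    df["event"] = df["event"].fillna("").astype(str)
    mp = _meta_path(path)
    meta = json.loads(mp.read_text()) if mp.exists() else {}
    rate = float(meta.get("sample_rate", 0.0))
    if rate <= 0:
        t = df["time"].to_numpy()
        rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    t = df["time"].to_numpy(dtype=float)
    if len(t) > 1:
        dtv = np.diff(t)
        period = 1.0 / rate
        if np.any(dtv <= 0):
            raise FormatError("non-monotone timestamps")
        # inter-movement gaps (> 1.5 periods) are fine; anything between a
        # clean sample step and a gap is jitter
        jitter = (np.abs(dtv - period) > jitter_tol * period) & (dtv < 1.5 * period)
        if np.any(jitter):
            raise FormatError(f"timestamp jitter exceeds {jitter_tol} sample periods")
    meta.pop("sample_rate", None)
    return SessionRecord(data=df, sample_rate=rate, meta=meta)


def _data_text(name: str) -> str:
    return resources.files("rehabsim.data").joinpath(name).read_text()


def load_cohort() -> pd.DataFrame:
    """Packaged cohort table: 17 enrolled subjects with covariates.

    Adds an ``age`` column (range midpoint) alongside the preserved
    ``age_lo``/``age_hi`` range.
    """
    import io as _io

    df = pd.read_csv(_io.StringIO(_data_text("cohort.csv")))
    df["age"] = (df["age_lo"] + df["age_hi"]) / 2.0
    df["dropout"] = df["dropout"].astype(bool)
    df["post_only"] = df["post_only"].astype(bool)
    return df


def load_joints() -> dict[str, JointSpec]:
    """Packaged per-joint controller parameters for the four trained DOFs."""
    raw = yaml.safe_load(_data_text("joints.yaml"))
    return {name: JointSpec(name=name, **params) for name, params in raw.items()}


def load_study() -> dict:
    """Trial-level constants (screening count, session plan)."""
    return yaml.safe_load(_data_text("study.yaml"))


def load_fixtures():
    """Convenience: ``(cohort_table, joint_specs)``."""
    return load_cohort(), load_joints()


@dataclass
class RunConfig:
    """Configuration of one simulated run (flat YAML, CLI flags override)."""

    joint: str = "elbow"
    controller: str = "aan"
    n_sessions: int = 10
    session_minutes: float = 90.0
    dt: float = 0.001
    sample_rate: float | None = None
    seed: int = 0
    outdir: str = "runs"
    subject: dict = field(default_factory=dict)
    st_base_fth: float = 1.0
    st_increment: float = 0.05
    t_st: float = 2.0
    keep_records: bool = False

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def profile(self) -> SubjectProfile:
        return SubjectProfile(**self.subject)


def write_manifest(outdir, config_text: str, seed: int) -> Path:
    """Record enough provenance to reproduce a run (config hash, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": int(seed),
        "version": __version__,
    }
    p = outdir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=1))
    return p
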
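"""Plain-text interchange: trial-log CSV, config JSON, and run manifests.

All intermediate artifacts are CSV or JSON so any toolchain can consume
them.  A manifest records the seeds and a hash of the configuration that
produced a set of files, making pipeline runs reproducible and resumable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .task import SessionConfig, TRIAL_COLUMNS

__all__ = [
    "write_trial_log",
    "read_trial_log",
    "load_config",
    "dump_config",
    "config_hash",
    "write_manifest",
]

_REQUIRED = [
    "participant",
    "block",
    "phase",
    "trial",
    "condition",
    "slow_deg",
    "fast_deg",
    "relevant_dim",
    "reward",
    "choice",
    "outcome",
    "correct",
]


def write_trial_log(trial_log: pd.DataFrame, path) -> None:
    """Write a trial log as CSV with the canonical column order."""
    cols = [c for c in TRIAL_COLUMNS if c in trial_log.columns]
    extra = [c for c in trial_log.columns if c not in cols]
    trial_log[cols + extra].to_csv(path, index=False)


def read_trial_log(path) -> pd.DataFrame:
    """Read a trial-log CSV, checking the required columns are present."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"trial log is missing required columns: {missing}")
    return df


def load_config(path) -> SessionConfig:
    """Load and validate a session configuration from a JSON file."""
    with open(path) as fh:
        return SessionConfig.model_validate(json.load(fh))


def dump_config(config: SessionConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write(config.model_dump_json(indent=2))


def config_hash(config: SessionConfig) -> str:
    """Stable hash of a configuration (sha256 of its canonical JSON)."""
    canonical = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_manifest(path, config: SessionConfig, seeds, files) -> None:
    """Record what produced a set of output files."""
    manifest = {
        "config_hash": config_hash(config),
        "config": config.model_dump(),
        "seeds": list(seeds),
        "files": [str(f) for f in files],
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
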
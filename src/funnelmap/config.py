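"""Run configuration: a single YAML file with one block per stage,
overridable by CLI flags, plus a reproducibility manifest per invocation."""

from __future__ import annotations

import hashlib
import json
import platform
import sys
from pathlib import Path

import numpy as np
import yaml

DEFAULTS: dict = {
    "simulate": {
        "final_size": 2000,
        "pool_size": 576,
        "crossover_rate": 3.0,
        "bp_per_marker": 44.0,
        "mean_depth": 3.8,
        "error_rate": 0.01,
        "trisomy_ix": False,
    },
    "haplotype": {
        "crossover_rate": 3.0,
        "error_rate": 0.01,
        "read_cutoff": 12000,
    },
    "ploidy": {"disome_threshold": 1.5},
    "scaffold": {"spacing": 2000},
    "structure": {"min_joint_markers": 50, "cluster_cutoff": 0.25},
    "linkfit": {"max_pairs": 20000, "grid_start": 0.5, "grid_stop": 6.0, "grid_step": 0.01},
    "qtl": {"n_threshold_reps": 1000, "n_phenotypes": 150, "h2": [0.0036], "alpha": 0.05},
    "scan": {"alpha": 0.05, "central_fraction": 0.95, "bottom_fraction": 0.95},
}


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML config file over the stage defaults."""
    cfg = {k: dict(v) for k, v in DEFAULTS.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for block, values in user.items():
            cfg.setdefault(block, {}).update(values or {})
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path, stage: str, params: dict, seed: int | None,
    inputs: list[str | Path] = (),
) -> Path:
    """Record the invocation: parameters, seed, input checksums, versions."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": seed,
        "parameters": params,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "platform": platform.platform(),
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
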
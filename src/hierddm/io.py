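"""Plain-text I/O: trial tables, posterior draws, run manifests.

All tables are CSV; draws are stored wide (one column per parameter, one
row per chain x iteration) next to a JSON metadata file so a fit can be
reloaded without refitting.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import TRIAL_COLUMNS
from .sampler import PosteriorSamples

__all__ = ["read_trials", "write_trials", "save_samples", "load_samples",
           "write_manifest", "read_manifest"]


def read_trials(path) -> pd.DataFrame:
    """Read a long-format trial table (one row per trial).

    Expected columns: subject_id, group, task, stimulus_type, correct,
    rt_ms.  Missing rt_ms/correct mark deadline non-responses.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str, "task": str,
                                  "stimulus_type": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path} lacks columns {missing}")
    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    if df["correct"].dtype == object:
        df["correct"] = df["correct"].map(
            {"True": 1.0, "False": 0.0, "1": 1.0, "0": 0.0}).astype(float)
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def save_samples(samples: PosteriorSamples, directory) -> None:
    """Persist a fit as draws.csv (wide) + samples_meta.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nc, ni, npar = samples.draws.shape
    wide = pd.DataFrame(samples.draws.reshape(nc * ni, npar),
                        columns=samples.param_names)
    wide.insert(0, "chain", np.repeat(np.arange(nc), ni))
    wide.insert(1, "iteration", np.tile(np.arange(ni), nc))
    wide.to_csv(directory / "draws.csv", index=False)
    meta = {"burn_in": samples.burn_in, "seed": samples.seed,
            "n_chains": nc, "n_iterations": ni,
            "param_names": samples.param_names, "meta": samples.meta}
    (directory / "samples_meta.json").write_text(json.dumps(meta, indent=1))


def load_samples(directory) -> PosteriorSamples:
    directory = Path(directory)
    meta = json.loads((directory / "samples_meta.json").read_text())
    wide = pd.read_csv(directory / "draws.csv")
    names = meta["param_names"]
    draws = wide[names].to_numpy().reshape(meta["n_chains"], meta["n_iterations"],
                                           len(names))
    return PosteriorSamples(draws=draws, param_names=names,
                            burn_in=meta["burn_in"], seed=meta["seed"],
                            meta=meta["meta"])


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
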
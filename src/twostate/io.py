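"""Writers: tidy CSV for trajectories and distributions, JSON for reports.

All array outputs are plain CSV and all reports JSON, so results diff
cleanly and regenerate byte-identically from a manifest (configuration plus
seeds); the manifest records a content hash of the resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fsp import ProbabilityVector, state_of_index
from .ssa import EnsembleSummary


def config_hash(config: dict) -> str:
    """Content hash of a configuration dict (stable key order)."""
    blob = json.dumps(config, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, config: dict, outputs: list) -> dict:
    manifest = {"config": config, "config_hash": config_hash(config),
                "outputs": sorted(str(o) for o in outputs)}
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def write_tidy_trajectory(path, times, values, species, unit: str,
                          cell_id: int | None = None) -> None:
    """Long-format CSV: (cell_id,) time, species, value, unit."""
    values = np.asarray(values)
    frame = pd.DataFrame({
        "time": np.repeat(np.asarray(times, dtype=float), len(species)),
        "species": np.tile(list(species), len(times)),
        "value": values.reshape(-1),
        "unit": unit,
    })
    if cell_id is not None:
        frame.insert(0, "cell_id", cell_id)
    frame.to_csv(path, index=False)


def write_ensemble_summary(path, summary: EnsembleSummary) -> None:
    rows = []
    for si, sp in enumerate(summary.species):
        rows.append(pd.DataFrame({
            "time": summary.times,
            "species": sp,
            "mean": summary.mean[:, si],
            "variance": summary.variance[:, si],
            "population_size": summary.population_size,
        }))
    pd.concat(rows).to_csv(path, index=False)


def write_probability_vector(path, pv: ProbabilityVector) -> None:
    """CSV of (state_index, P, Pm, probability) for one time point."""
    idx = np.arange(1, pv.space.n_states + 1)
    states = [state_of_index(i, pv.space) for i in idx]
    pd.DataFrame({
        "state_index": idx,
        "P": [s[0] for s in states],
        "Pm": [s[1] for s in states],
        "probability": pv.p,
        "time": pv.time,
    }).to_csv(path, index=False)


def write_heatmap_matrix(pvs, path, display_clip: float | None = None) -> pd.DataFrame:
    """Time-by-state matrix of raw probabilities, one row per time point.

    ``display_clip`` (e.g. 0.25 to mimic a saturated colour scale) writes an
    additional file ``<path>.clipped.csv``; the raw values are always
    preserved in the main file.
    """
    pvs = list(pvs)
    if not pvs:
        raise ValueError("no probability vectors to write")
    mat = np.stack([pv.p for pv in pvs])
    cols = [f"s{i}" for i in range(1, pvs[0].space.n_states + 1)]
    frame = pd.DataFrame(mat, columns=cols)
    frame.insert(0, "time", [pv.time for pv in pvs])
    frame.to_csv(path, index=False)
    if display_clip is not None:
        clipped = frame.copy()
        clipped[cols] = np.minimum(mat, display_clip)
        clipped.to_csv(str(path) + ".clipped.csv", index=False)
    return frame


def write_json_report(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
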
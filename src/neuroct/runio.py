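"""Result serialization: per-task time series plus a JSON manifest."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig, dump_config

__all__ = ["save_run"]


def _cost_dict(bd) -> dict:
    return {
        "F_P": bd.F_P, "F1_E": bd.F1_E, "F1_I": bd.F1_I,
        "F2_E": bd.F2_E, "F2_I": bd.F2_I,
        "W1": bd.weights.W1, "W2": bd.weights.W2, "total": bd.total,
    }


def save_run(task_results: dict, config: RunConfig, out_dir) -> dict:
    """Write controls, cost breakdowns and a manifest for a set of tasks.

    ``task_results`` maps task names to :class:`~neuroct.tasks.TaskResult`.
    Re-running with the same config and seed reproduces the summary costs
    bit for bit (the whole pipeline is deterministic given the seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(config, out / "config.yaml")
    entries = []
    for name, res in task_results.items():
        control = res.best.control
        csv_path = out / f"{name}_control.csv"
        t = control.t
        arr = np.column_stack([t, control.u_E_nA, control.u_I_nA])
        header = "t_ms,u_E_nA,u_I_nA"
        np.savetxt(csv_path, arr, delimiter=",", header=header, comments="")
        entries.append({
            "task": name,
            "point_nA": list(res.task.point_nA),
            "total_cost": res.best.cost.total,
            "cost": _cost_dict(res.best.cost),
            "iterations": res.best.iterations,
            "converged": res.best.converged,
            "skipped_initializations": len(res.failures),
            "files": [csv_path.name],
        })
    manifest = {
        "version": __version__,
        "rng_seed": config.rng_seed,
        "tasks": entries,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
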
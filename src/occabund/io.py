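"""Stable file contracts: long-format CSV tables, YAML configs, JSON results.

Column dictionaries
    detections.csv : species_id, cell_id, plot_id, y (0/1), area_m2
    cells.csv      : cell_id, habitat_area_km2, x1, x2, ecoregion
    aux.csv        : species_id, cell_id, state (presence|absence), source
    truth.csv      : species_id, cell_id, z, d, psi, N
    predictions.csv: species_id, cell_id, d_hat, psi_hat, m, z_known
    effects.csv    : kind (e1|u1|e2|u2|e3), species_id, cell_id, value

Floats are written with repr-level precision so a write/read round trip is
value-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import Dataset, FittedModel, ModelParams
from .simulate import SyntheticDataset

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_truth",
    "write_fit",
    "read_fit_params",
    "load_config",
    "dump_config",
]


def _to_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def write_dataset(ds: Dataset | SyntheticDataset, outdir: str | Path) -> dict:
    """Write the three tables (and the truth sidecar for synthetic data)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(ds, SyntheticDataset):
        data = ds.data
    else:
        data = ds
    paths = {
        "detections": outdir / "detections.csv",
        "cells": outdir / "cells.csv",
        "aux": outdir / "aux.csv",
    }
    _to_csv(data.detections, paths["detections"])
    _to_csv(data.cells, paths["cells"])
    _to_csv(data.aux, paths["aux"])
    if isinstance(ds, SyntheticDataset):
        paths["truth"] = outdir / "truth.csv"
        write_truth(ds, paths["truth"])
        paths["config"] = outdir / "sim_config.yaml"
        dump_config(ds.config.to_dict(), paths["config"])
    return {k: str(v) for k, v in paths.items()}


def write_truth(ds: SyntheticDataset, path: str | Path) -> None:
    t = ds.truth
    I, J = t["z"].shape
    ii, jj = np.meshgrid(np.arange(I), np.arange(J), indexing="ij")
    df = pd.DataFrame(
        {
            "species_id": t["species_ids"][ii.ravel()],
            "cell_id": t["cell_ids"][jj.ravel()],
            "z": t["z"].ravel(),
            "d": t["d"].ravel(),
            "psi": t["psi"].ravel(),
            "N": t["N"].ravel(),
        }
    )
    _to_csv(df, Path(path))


def read_dataset(indir: str | Path) -> Dataset:
    indir = Path(indir)
    det = pd.read_csv(indir / "detections.csv", float_precision="round_trip")
    cells = pd.read_csv(indir / "cells.csv", float_precision="round_trip")
    aux_path = indir / "aux.csv"
    aux = pd.read_csv(aux_path) if aux_path.exists() and aux_path.stat().st_size > 0 else None
    if aux is not None and len(aux) == 0:
        aux = None
    return Dataset(det, cells, aux)


def write_fit(fit: FittedModel, outdir: str | Path) -> dict:
    """Serialise a fit: parameters/convergence to JSON, effects and
    per-(species, cell) predictions to CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "params": fit.params.to_dict(),
        "loglik": fit.loglik,
        "converged": bool(fit.converged),
        "grad_norm": float(fit.grad_norm) if np.isfinite(fit.grad_norm) else None,
        "n_eval": fit.n_eval,
        "model_spec": fit.model_spec,
        "se": {k: float(v) for k, v in fit.se.items()},
        "param_names": list(fit.param_names),
        "wall_time_s": fit.wall_time_s,
    }
    (outdir / "fit.json").write_text(json.dumps(meta, indent=2))
    _to_csv(fit.predictions(), outdir / "predictions.csv")
    eff = fit.effects
    rows = []
    for kind, vals, ids in (("e1", eff.e1, fit.species), ("u1", eff.u1, fit.species),
                            ("e2", eff.e2, fit.cell_ids), ("u2", eff.u2, fit.cell_ids)):
        for ident, v in zip(ids, vals):
            rows.append({"kind": kind, "species_id": ident if kind in ("e1", "u1") else "",
                         "cell_id": ident if kind in ("e2", "u2") else "", "value": v})
    for (i, j), v in zip(eff.e3_pairs, eff.e3):
        rows.append({"kind": "e3", "species_id": fit.species[i], "cell_id": fit.cell_ids[j], "value": v})
    _to_csv(pd.DataFrame(rows), outdir / "effects.csv")
    return {"fit": str(outdir / "fit.json"), "predictions": str(outdir / "predictions.csv"),
            "effects": str(outdir / "effects.csv")}


def read_fit_params(path: str | Path) -> tuple[ModelParams, dict]:
    meta = json.loads(Path(path).read_text())
    return ModelParams.from_dict(meta["params"]), meta


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
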
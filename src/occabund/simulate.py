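"""Synthetic data with exactly the statistical structure the model assumes.

Generates landscapes (cells with habitat area and standardised covariates),
survey designs (plots with areas), detection-nondetection observations,
partially observed auxiliary occurrence data, and neutral / Poisson-lognormal
metacommunity SADs. Every downstream stage of the package is testable
against the retained ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import Dataset, ModelParams, M2_TO_KM2
from .untb import MetacommunitySAD

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_dataset", "simulate_neutral_sad"]


_LAWS = {"loguniform", "lognormal", "constant", "uniform"}


def _draw_law(rng: np.random.Generator, law: dict, size: int) -> np.ndarray:
    name = law.get("name")
    if name == "loguniform":
        lo, hi = float(law["low"]), float(law["high"])
        if not (0 < lo < hi):
            raise ValueError("loguniform needs 0 < low < high")
        return np.exp(rng.uniform(math.log(lo), math.log(hi), size))
    if name == "lognormal":
        return rng.lognormal(float(law["mean_log"]), float(law["sd_log"]), size)
    if name == "uniform":
        return rng.uniform(float(law["low"]), float(law["high"]), size)
    if name == "constant":
        return np.full(size, float(law["value"]))
    raise ValueError(f"unknown law: {name!r} (expected one of {sorted(_LAWS)})")


@dataclass
class SimulationConfig:
    """Study design and generative parameters for one synthetic dataset.

    Defaults emulate a vegetation-survey-style design: plot areas log-uniform
    on [10, 1000] m^2 (the reported surveys ranged 0.01-18,000 m^2 with a
    typical plot of ~100 m^2), habitat areas a few tens of km^2 per 10-km
    cell, and partially observed cell-level occupancy.
    """

    n_species: int = 30
    n_cells: int = 50
    plots_per_cell: int | dict | list = 10
    plot_area_law: dict = field(default_factory=lambda: {"name": "loguniform", "low": 10.0, "high": 1000.0})
    habitat_area_law: dict = field(default_factory=lambda: {"name": "lognormal", "mean_log": 3.4, "sd_log": 0.6})
    true_params: ModelParams = field(
        default_factory=lambda: ModelParams(
            mu=math.log(2000.0),  # ~2000 individuals per km^2, conditional on presence
            beta1=0.5, beta2=-0.3, beta3=0.2,
            eta=0.0, gamma1=0.5, gamma2=-0.5, gamma3=0.25,
            sigma1=1.0, sigma2=0.5, sigma3=0.5,
            tau1=1.0, tau2=0.5, rho=0.5,
        )
    )
    aux_presence_coverage: float = 0.5
    aux_absence_coverage: float = 0.3
    n_ecoregions: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_cells < 1:
            raise ValueError("need at least one species and one cell")
        for name in ("aux_presence_coverage", "aux_absence_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if isinstance(self.true_params, dict):
            self.true_params = ModelParams.from_dict(self.true_params)
        k = self._plot_counts()
        if np.any(k < 0) or not np.any(k > 0):
            raise ValueError("plot counts must be >= 0 with at least one positive")
        for law in (self.plot_area_law, self.habitat_area_law):
            if law.get("name") not in _LAWS:
                raise ValueError(f"unknown law: {law.get('name')!r}")
            if not all(np.isfinite(v) for kk, v in law.items() if kk != "name"):
                raise ValueError("law parameters must be finite")

    def _plot_counts(self) -> np.ndarray:
        if isinstance(self.plots_per_cell, int):
            return np.full(self.n_cells, self.plots_per_cell)
        if isinstance(self.plots_per_cell, dict):
            return np.array([int(self.plots_per_cell.get(j, 0)) for j in range(self.n_cells)])
        arr = np.asarray(self.plots_per_cell, dtype=int)
        if arr.size != self.n_cells:
            raise ValueError("plots_per_cell list must have one entry per cell")
        return arr

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_params"] = self.true_params.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "true_params" in d and isinstance(d["true_params"], dict):
            d["true_params"] = ModelParams.from_dict(d["true_params"])
        return cls(**d)


@dataclass
class SyntheticDataset:
    """Simulated tables plus the generating truth.

    truth holds the realised z, conditional density d, occurrence probability
    psi, random effects and the per-cell true abundance N_ij = d_ij A_j z_ij.
    """

    data: Dataset
    truth: dict
    config: SimulationConfig

    @property
    def detections(self) -> pd.DataFrame:
        return self.data.detections

    @property
    def cells(self) -> pd.DataFrame:
        return self.data.cells

    @property
    def aux(self) -> pd.DataFrame:
        return self.data.aux


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one dataset from the integrated model's generative process.

    Covariates are standardised to exact mean 0 / variance 1 across cells;
    (e2, u2) are drawn from the bivariate normal with correlation rho;
    z ~ Bernoulli(psi); y ~ Bernoulli(1 - exp(-z d a)). Deterministic for a
    fixed config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    p = config.true_params
    I, J = config.n_species, config.n_cells

    def standardise(x):
        s = np.std(x)
        if s == 0:
            return np.zeros_like(x)
        return (x - np.mean(x)) / s

    x1 = standardise(rng.normal(size=J))
    x2 = standardise(rng.normal(size=J))
    A = _draw_law(rng, config.habitat_area_law, J)

    e1 = rng.normal(0.0, p.sigma1, I) if p.sigma1 > 0 else np.zeros(I)
    u1 = rng.normal(0.0, p.tau1, I) if p.tau1 > 0 else np.zeros(I)
    if p.sigma2 > 0 and p.tau2 > 0:
        cov = np.array(
            [[p.sigma2 ** 2, p.rho * p.sigma2 * p.tau2], [p.rho * p.sigma2 * p.tau2, p.tau2 ** 2]]
        )
        eu = rng.multivariate_normal(np.zeros(2), cov, size=J)
        e2, u2 = eu[:, 0], eu[:, 1]
    else:
        e2 = rng.normal(0.0, p.sigma2, J) if p.sigma2 > 0 else np.zeros(J)
        u2 = rng.normal(0.0, p.tau2, J) if p.tau2 > 0 else np.zeros(J)
    e3 = rng.normal(0.0, p.sigma3, (I, J)) if p.sigma3 > 0 else np.zeros((I, J))

    xv = p.mu + p.beta1 * x1 + p.beta2 * x2 + p.beta3 * x1 * x2
    xw = p.eta + p.gamma1 * x1 + p.gamma2 * x2 + p.gamma3 * x1 * x2
    log_d = xv[None, :] + e1[:, None] + e2[None, :] + e3
    logit_psi = xw[None, :] + u1[:, None] + u2[None, :]
    d = np.exp(log_d)
    psi = expit(logit_psi)
    z = (rng.random((I, J)) < psi).astype(np.int8)

    k = config._plot_counts()
    cell_of_plot = np.repeat(np.arange(J), k)
    n_plots = len(cell_of_plot)
    areas = _draw_law(rng, config.plot_area_law, n_plots)
    plot_ids = np.concatenate([np.arange(kk) for kk in k]) if n_plots else np.array([], dtype=int)

    # detections: I x n_plots Bernoulli draws
    c = (z * d)[:, cell_of_plot] * areas[None, :] * M2_TO_KM2
    pdet = -np.expm1(-c)
    y = (rng.random((I, n_plots)) < pdet).astype(np.int8)

    species_ids = np.array([f"sp{i:04d}" for i in range(I)])
    cell_ids = np.array([f"c{j:04d}" for j in range(J)])
    det = pd.DataFrame(
        {
            "species_id": np.repeat(species_ids, n_plots),
            "cell_id": np.tile(cell_ids[cell_of_plot], I),
            "plot_id": np.tile(plot_ids, I),
            "y": y.ravel().astype(np.int64),
            "area_m2": np.tile(areas, I),
        }
    )
    ecoregion = rng.integers(0, config.n_ecoregions, J)
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "habitat_area_km2": A,
            "x1": x1,
            "x2": x2,
            "ecoregion": [f"eco{r}" for r in ecoregion],
        }
    )

    # auxiliary occurrence: never contradicts the truth
    reg_pres = (z == 1) & (rng.random((I, J)) < config.aux_presence_coverage)
    reg_abs = (z == 0) & (rng.random((I, J)) < config.aux_absence_coverage)
    pi, pj = np.nonzero(reg_pres)
    ai, aj = np.nonzero(reg_abs)
    aux = pd.DataFrame(
        {
            "species_id": np.concatenate([species_ids[pi], species_ids[ai]]),
            "cell_id": np.concatenate([cell_ids[pj], cell_ids[aj]]),
            "state": ["presence"] * len(pi) + ["absence"] * len(ai),
            "source": ["presence-source"] * len(pi) + ["absence-source"] * len(ai),
        }
    )

    truth = {
        "params": p,
        "z": z,
        "d": d,
        "psi": psi,
        "N": d * A[None, :] * z,
        "e1": e1,
        "u1": u1,
        "e2": e2,
        "u2": u2,
        "e3": e3,
        "species_ids": species_ids,
        "cell_ids": cell_ids,
    }
    return SyntheticDataset(data=Dataset(det, cells, aux), truth=truth, config=config)


def simulate_neutral_sad(mode: str, params: dict, j_m: int = 0, seed: int = 0) -> MetacommunitySAD:
    """Draw a metacommunity SAD.

    mode 'point_mutation': exact Ewens-distributed partition of j_m
    individuals via the sequential urn (each new individual founds a new
    species with probability theta/(theta + n - 1), otherwise copies a
    uniformly chosen earlier individual).

    mode 'poisson_lognormal': per-species abundances n_s ~ Poisson(lambda_s)
    with lambda_s lognormal (params: mean_log, sd_log, n_species); zero draws
    are rejected, so the realised metacommunity size is random.
    """
    rng = np.random.default_rng(seed)
    if mode == "point_mutation":
        theta = float(params["theta"])
        if theta <= 0:
            raise ValueError("theta must be > 0")
        if j_m < 1:
            raise ValueError("J_M must be >= 1")
        labels = np.empty(j_m, dtype=np.int64)
        u = rng.random(j_m)
        parent_pick = rng.random(j_m)
        n_species = 0
        for n in range(j_m):
            if u[n] < theta / (theta + n):
                labels[n] = n_species
                n_species += 1
            else:
                labels[n] = labels[int(parent_pick[n] * n)]
        abundance = np.bincount(labels, minlength=n_species).astype(float)
        return MetacommunitySAD(abundance[abundance > 0])
    if mode == "poisson_lognormal":
        s = int(params["n_species"])
        if s < 1:
            raise ValueError("n_species must be >= 1")
        mean_log, sd_log = float(params["mean_log"]), float(params["sd_log"])
        out = np.zeros(s)
        todo = np.arange(s)
        while len(todo):
            lam = rng.lognormal(mean_log, sd_log, len(todo))
            n = rng.poisson(lam)
            out[todo] = n
            todo = todo[n == 0]
        return MetacommunitySAD(out)
    raise ValueError(f"unknown mode: {mode!r}")
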
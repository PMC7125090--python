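"""Ecological estimators derived from the fitted hierarchical model.

All estimators share the occupancy weight
    w_ij = m_ij z_ij + (1 - m_ij) psi-hat_ij,
the known occupancy where auxiliary or detection data fix it and the model
estimate elsewhere:

    richness      S_j  = sum_i w_ij
    abundance     N_ij = d-hat_ij A_j w_ij            (individuals)
    regional      N*_i = sum_{j in subset} N_ij
    area of occ.  R_i  = sum_j A_j w_ij               (km^2)

plus Shannon entropy of abundance vectors, parametric-bootstrap standard
errors (auxiliary data held fixed), validation metrics and the red-list
abundance / AOO summary with the IUCN D2 flag (< 20 km^2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import Dataset, FitConfig, FittedModel, M2_TO_KM2, fit as fit_model

logger = logging.getLogger("occabund")

AOO_D2_THRESHOLD_KM2 = 20.0
REDLIST_CATEGORIES = ("NC", "NT", "VU", "EN", "CR")

__all__ = [
    "estimate_richness",
    "estimate_abundance",
    "cell_abundance",
    "estimate_aoo",
    "shannon_entropy",
    "cell_estimates",
    "species_estimates",
    "BootstrapResult",
    "parametric_bootstrap",
    "validation_metrics",
    "redlist_summary",
]


def _habitat_areas(fit: FittedModel, cells: pd.DataFrame) -> np.ndarray:
    c = cells.set_index("cell_id").loc[fit.cell_ids]
    return c["habitat_area_km2"].to_numpy(float)


def estimate_richness(fit: FittedModel, cell=None) -> np.ndarray | float:
    """Expected number of species present per cell: S_j = sum_i w_ij."""
    s = fit.occupancy_weight().sum(axis=0)
    if cell is None:
        return s
    if cell not in fit.j_index:
        raise KeyError(f"unknown cell: {cell}")
    return float(s[fit.j_index[cell]])


def cell_abundance(fit: FittedModel, cells: pd.DataFrame) -> np.ndarray:
    """(I, J) matrix of estimated abundance N_ij = d_ij A_j w_ij."""
    A = _habitat_areas(fit, cells)
    return fit.d_hat * A[None, :] * fit.occupancy_weight()


def estimate_abundance(fit: FittedModel, cells: pd.DataFrame, subset=None) -> pd.Series:
    """Per-species abundance summed over a cell subset (default: all cells)."""
    N = cell_abundance(fit, cells)
    if subset is None:
        idx = np.arange(len(fit.cell_ids))
    else:
        subset = list(subset)
        if not subset:
            raise ValueError("empty cell subset")
        missing = [c for c in subset if c not in fit.j_index]
        if missing:
            raise KeyError(f"cells not in fit: {missing[:5]}")
        idx = np.array([fit.j_index[c] for c in subset])
    return pd.Series(N[:, idx].sum(axis=1), index=fit.species, name="abundance")


def estimate_aoo(fit: FittedModel, cells: pd.DataFrame, species=None) -> pd.Series | float:
    """Area of occupancy R_i = sum_j A_j w_ij (km^2)."""
    A = _habitat_areas(fit, cells)
    r = (A[None, :] * fit.occupancy_weight()).sum(axis=1)
    out = pd.Series(r, index=fit.species, name="aoo_km2")
    if species is None:
        return out
    if species not in fit.i_index:
        raise KeyError(f"unknown species: {species}")
    return float(out.loc[species])


def shannon_entropy(n) -> float:
    """H = -sum q log q with q = N / sum(N), natural log, 0 log 0 := 0."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("abundances must be non-negative")
    total = n.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    q = n[n > 0] / total
    return float(-np.sum(q * np.log(q)))


def cell_estimates(fit: FittedModel, cells: pd.DataFrame) -> pd.DataFrame:
    """Per-cell richness, total abundance and Shannon entropy."""
    N = cell_abundance(fit, cells)
    rich = estimate_richness(fit)
    tot = N.sum(axis=0)
    ent = np.array([shannon_entropy(N[:, j]) if tot[j] > 0 else np.nan for j in range(N.shape[1])])
    return pd.DataFrame(
        {"cell_id": fit.cell_ids, "richness": rich, "abundance": tot, "shannon_entropy": ent}
    )


def species_estimates(fit: FittedModel, cells: pd.DataFrame) -> pd.DataFrame:
    """Per-species regional abundance and area of occupancy."""
    ab = estimate_abundance(fit, cells)
    aoo = estimate_aoo(fit, cells)
    return pd.DataFrame({"species_id": fit.species, "abundance": ab.to_numpy(), "aoo_km2": aoo.to_numpy()})


# --------------------------------------------------------------------------
# Parametric bootstrap
# --------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Standard errors of the derived quantities over bootstrap refits."""

    n_requested: int
    n_success: int
    cell_se: pd.DataFrame  # per-cell SEs of richness / abundance / entropy
    species_se: pd.DataFrame  # per-species SEs of abundance / aoo
    total_abundance_se: float
    total_abundance_replicates: np.ndarray
    # (n_success, I) per-replicate regional abundances, for propagating
    # uncertainty into downstream analyses (e.g. neutral-theory refits)
    species_abundance_replicates: np.ndarray | None = None


def parametric_bootstrap(
    fit: FittedModel,
    data: Dataset,
    cells: pd.DataFrame | None = None,
    B: int = 100,
    seed: int = 0,
    config: FitConfig | None = None,
) -> BootstrapResult:
    """Parametric-bootstrap SEs for the derived estimators.

    For each replicate, new random effects, occupancy states and detections
    are simulated from the fitted parameters with the same survey design; the
    auxiliary data are held fixed (z is not resimulated where m_ij = 1 by
    auxiliary sources). The model is refit (started at the original
    estimates) and the derived quantities recomputed; the SE of each quantity
    is its SD over the successful replicates.
    """
    if cells is None:
        cells = data.cells
    rng = np.random.default_rng(seed)
    p = fit.params
    I, J = len(fit.species), len(fit.cell_ids)
    occupancy = fit.model_spec == "integrated"
    config = config or FitConfig(compute_se=False)
    config = replace(config, compute_se=False, start=p)

    c_ord = cells.set_index("cell_id").loc[fit.cell_ids]
    x1 = c_ord["x1"].to_numpy(float)
    x2 = c_ord["x2"].to_numpy(float)
    xv = p.mu + p.beta1 * x1 + p.beta2 * x2 + p.beta3 * x1 * x2
    xw = p.eta + p.gamma1 * x1 + p.gamma2 * x2 + p.gamma3 * x1 * x2

    det0 = data.detections
    i_of = det0["species_id"].map(fit.i_index).to_numpy(int)
    j_of = det0["cell_id"].map(fit.j_index).to_numpy(int)
    areas = det0["area_m2"].to_numpy(float)

    # auxiliary-derived knowledge is fixed across replicates
    aux_m = np.zeros((I, J), dtype=bool)
    aux_z = np.zeros((I, J), dtype=np.int8)
    if occupancy and len(data.aux_resolved):
        ai = data.aux_resolved["species_id"].map(fit.i_index).to_numpy(int)
        aj = data.aux_resolved["cell_id"].map(fit.j_index).to_numpy(int)
        pres = (data.aux_resolved["state"] == "presence").to_numpy()
        aux_m[ai, aj] = True
        aux_z[ai[pres], aj[pres]] = 1

    rich_reps, tot_cell_reps, ent_reps = [], [], []
    ab_reps, aoo_reps, total_reps = [], [], []
    n_success = 0
    for b in range(B):
        e1 = rng.normal(0, p.sigma1, I) if p.sigma1 > 0 else np.zeros(I)
        u1 = rng.normal(0, p.tau1, I) if p.tau1 > 0 else np.zeros(I)
        if p.sigma2 > 0 and p.tau2 > 0:
            cov = np.array([[p.sigma2 ** 2, p.rho * p.sigma2 * p.tau2], [p.rho * p.sigma2 * p.tau2, p.tau2 ** 2]])
            eu = rng.multivariate_normal(np.zeros(2), cov, size=J)
            e2, u2 = eu[:, 0], eu[:, 1]
        else:
            e2 = rng.normal(0, p.sigma2, J) if p.sigma2 > 0 else np.zeros(J)
            u2 = rng.normal(0, p.tau2, J) if p.tau2 > 0 else np.zeros(J)
        e3 = rng.normal(0, p.sigma3, (I, J)) if p.sigma3 > 0 else np.zeros((I, J))
        d = np.exp(xv[None, :] + e1[:, None] + e2[None, :] + e3)
        if occupancy:
            psi = expit(xw[None, :] + u1[:, None] + u2[None, :])
            z = (rng.random((I, J)) < psi).astype(np.int8)
            z = np.where(aux_m, aux_z, z)
        else:
            z = np.ones((I, J), dtype=np.int8)
        pdet = -np.expm1(-(z[i_of, j_of] * d[i_of, j_of]) * areas * M2_TO_KM2)
        yb = (rng.random(len(det0)) < pdet).astype(np.int8)
        det_b = det0.assign(y=yb)
        try:
            data_b = Dataset(det_b, data.cells, data.aux)
            fit_b = fit_model(data_b, model_spec=fit.model_spec, config=config)
        except Exception as exc:  # refit failures are counted, not fatal
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            continue
        n_success += 1
        Nb = cell_abundance(fit_b, cells)
        rich_reps.append(estimate_richness(fit_b))
        tot_cell_reps.append(Nb.sum(axis=0))
        ent_reps.append(
            np.array([shannon_entropy(Nb[:, j]) if Nb[:, j].sum() > 0 else np.nan for j in range(J)])
        )
        ab = estimate_abundance(fit_b, cells)
        aoo = estimate_aoo(fit_b, cells)
        ab_reps.append(ab.reindex(fit.species).to_numpy())
        aoo_reps.append(aoo.reindex(fit.species).to_numpy())
        total_reps.append(float(Nb.sum()))

    if n_success == 0:
        raise RuntimeError("all bootstrap replicates failed")
    if n_success < 0.8 * B:
        warnings.warn(f"only {n_success}/{B} bootstrap replicates succeeded")

    def sd(reps):
        return np.std(np.stack(reps), axis=0, ddof=1) if len(reps) > 1 else np.zeros_like(reps[0])

    cell_se = pd.DataFrame(
        {
            "cell_id": fit.cell_ids,
            "richness_se": sd(rich_reps),
            "abundance_se": sd(tot_cell_reps),
            "shannon_entropy_se": sd(ent_reps),
        }
    )
    species_se = pd.DataFrame(
        {
            "species_id": fit.species,
            "abundance_se": sd(ab_reps),
            "aoo_km2_se": sd(aoo_reps),
        }
    )
    totals = np.array(total_reps)
    return BootstrapResult(
        n_requested=B,
        n_success=n_success,
        cell_se=cell_se,
        species_se=species_se,
        total_abundance_se=float(np.std(totals, ddof=1)) if len(totals) > 1 else 0.0,
        total_abundance_replicates=totals,
        species_abundance_replicates=np.stack(ab_reps),
    )


# --------------------------------------------------------------------------
# Validation metrics and red-list summary
# --------------------------------------------------------------------------


def validation_metrics(pred, obs) -> dict:
    """RMSE, Bias (arithmetic density scale) and Pearson correlation of log
    densities over pairs where both prediction and observation are positive.

    Pairs whose absence is indicated by auxiliary data must be excluded
    upstream.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size != obs.size or pred.size == 0:
        raise ValueError("need equally sized, non-empty prediction/observation vectors")
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err ** 2)))
    bias = float(np.mean(err))
    pos = (pred > 0) & (obs > 0)
    if pos.sum() < 2:
        raise ValueError("correlation undefined: fewer than two positive pairs")
    lp, lo = np.log(pred[pos]), np.log(obs[pos])
    if np.std(lp) == 0 or np.std(lo) == 0:
        raise ValueError("correlation undefined: zero variance in log densities")
    corr = float(np.corrcoef(lp, lo)[0, 1])
    return {"rmse": rmse, "bias": bias, "corr": corr}


def redlist_summary(
    species_est: pd.DataFrame,
    categories: pd.Series | dict,
    introduced: list | set = (),
) -> dict:
    """Red-list category summary of abundance / AOO plus the D2 flag list.

    ``species_est`` needs columns species_id, abundance, aoo_km2. Introduced
    species are excluded (outside the national red list's scope). Native
    species without an at-risk category ('NC') whose AOO falls below 20 km^2
    are flagged: they would qualify as Vulnerable under the IUCN D2
    criterion despite their unlisted status.
    """
    cat = pd.Series(categories)
    df = species_est.copy()
    df["category"] = df["species_id"].map(cat)
    introduced = set(introduced)
    df["introduced"] = df["species_id"].isin(introduced)
    native = df[~df["introduced"]].copy()
    unknown = set(native["category"].dropna()) - set(REDLIST_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown red-list categories: {sorted(unknown)}")
    if native["category"].isna().any():
        missing = native.loc[native["category"].isna(), "species_id"].tolist()
        raise ValueError(f"species without a category: {missing[:5]}")
    native["log10_abundance"] = np.log10(native["abundance"].where(native["abundance"] > 0))
    table = (
        native.groupby("category")
        .agg(
            n_species=("species_id", "size"),
            median_abundance=("abundance", "median"),
            mean_log10_abundance=("log10_abundance", "mean"),
            median_aoo_km2=("aoo_km2", "median"),
        )
        .reindex([c for c in REDLIST_CATEGORIES if c in set(native["category"])])
    )
    flagged = native[
        (native["category"] == "NC") & (native["aoo_km2"] < AOO_D2_THRESHOLD_KM2)
    ]["species_id"].tolist()
    return {"table": table, "d2_flagged": flagged, "n_excluded_introduced": int(df["introduced"].sum())}
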
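"""Zero-inflated hierarchical detection-nondetection model of species abundance.

The observation unit is a binary record y_ijk: detection (1) or nondetection
(0) of species i in sampling plot k of grid cell j, with known plot area a_jk.
Assuming individuals of each species follow a homogeneous Poisson point
process of (conditional) density d_ij within the cell's habitat, the
detection probability is

    p_ijk = 1 - exp(-z_ij * d_ij * a_jk),

where z_ij ~ Bernoulli(psi_ij) is the latent cell-level occupancy indicator.
Both linear predictors carry cell covariates (standardised AET and HII and
their interaction) and Gaussian random effects:

    log  d_ij  = mu  + b1*x1 + b2*x2 + b3*x1*x2 + e1_i + e2_j + e3_ij
    logit psi_ij = eta + g1*x1 + g2*x2 + g3*x1*x2 + u1_i + u2_j

with (e2_j, u2_j) bivariate normal with correlation rho, and all other
effects independent. Auxiliary occurrence information fixes z_ij where it is
known (m_ij = 1); elsewhere z is marginalised analytically. The Gaussian
random effects are integrated out with a joint Laplace approximation; when
only the species-by-cell effect e3 is active the marginal factorises over
(i, j) pairs and an adaptive Gauss-Hermite rule is used instead (the same
escalation lme4 performs via nAGQ).

Units: plot areas are m^2, habitat areas km^2, densities per km^2; the
conversion constant M2_TO_KM2 = 1e-6 is applied internally.
"""

from __future__ import annotations

import logging
import math
import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special
from scipy.special import expit

logger = logging.getLogger("occabund")

M2_TO_KM2 = 1e-6

# pair classes in the z-marginalised likelihood
_Z1, _Z0, _MIX = 0, 1, 2

__all__ = [
    "ModelParams",
    "RandomEffects",
    "Dataset",
    "FittedModel",
    "FitConfig",
    "detection_prob",
    "zi_detection_prob",
    "linear_predictors",
    "species_cell_loglik",
    "marginal_loglik",
    "fit",
    "crossvalidate_auc",
    "rank_auc",
]


# --------------------------------------------------------------------------
# Parameters and containers
# --------------------------------------------------------------------------


@dataclass
class ModelParams:
    """Fixed effects and variance components of the integrated model.

    SDs must be non-negative (a zero SD removes the corresponding random
    effect); rho is the correlation of the two cell-level effects.
    """

    mu: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    eta: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    gamma3: float = 0.0
    sigma1: float = 0.0
    sigma2: float = 0.0
    sigma3: float = 0.0
    tau1: float = 0.0
    tau2: float = 0.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma1", "sigma2", "sigma3", "tau1", "tau2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        vals = [getattr(self, f.name) for f in self.__dataclass_fields__.values()]  # type: ignore[attr-defined]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all parameters must be finite")

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: float(v) for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class RandomEffects:
    """Empirical-Bayes modes of the random effects.

    e3 is stored sparsely: values for the modelled (species, cell) pairs in
    ``e3_pairs`` (rows of species/cell integer codes); other pairs use its
    prior mean of zero.
    """

    e1: np.ndarray
    u1: np.ndarray
    e2: np.ndarray
    u2: np.ndarray
    e3: np.ndarray
    e3_pairs: np.ndarray  # (P, 2) integer codes (species, cell)


def detection_prob(d, a):
    """Probability of detecting at least one individual: 1 - exp(-d*a).

    ``d`` and ``a`` must use consistent units (e.g. d per m^2 with a in m^2).
    """
    d = np.asarray(d, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(d < 0) or np.any(a < 0):
        raise ValueError("density and area must be non-negative")
    out = -np.expm1(-d * a)
    return out if out.ndim else float(out)


def zi_detection_prob(z, d, a):
    """Zero-inflated detection probability: 0 if absent, 1-exp(-d*a) if present."""
    z = np.asarray(z)
    if not np.all((z == 0) | (z == 1)):
        raise ValueError("z must be 0 or 1")
    out = np.asarray(z, dtype=float) * np.asarray(detection_prob(d, a), dtype=float)
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# Input data
# --------------------------------------------------------------------------


class Dataset:
    """Validated bundle of the three input tables.

    detections: one row per species x plot with columns
        species_id, cell_id, plot_id, y, area_m2  (y for every modelled
        species at every plot, zeros included)
    cells: cell_id, habitat_area_km2, x1, x2[, ecoregion]
    aux: species_id, cell_id, state ('presence'|'absence')[, source]

    Conflicting auxiliary sources for one (species, cell) resolve to
    presence (absence evidence is treated conservatively); a detection
    y = 1 combined with auxiliary absence is a data contradiction and
    raises.
    """

    def __init__(self, detections: pd.DataFrame, cells: pd.DataFrame, aux: pd.DataFrame | None = None):
        self.detections = detections.copy()
        self.cells = cells.copy()
        if aux is None:
            aux = pd.DataFrame(columns=["species_id", "cell_id", "state", "source"])
        self.aux = aux.copy()
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        det, cells, aux = self.detections, self.cells, self.aux
        need = {"species_id", "cell_id", "plot_id", "y", "area_m2"}
        if not need.issubset(det.columns):
            raise ValueError(f"detections missing columns: {need - set(det.columns)}")
        need_c = {"cell_id", "habitat_area_km2", "x1", "x2"}
        if not need_c.issubset(cells.columns):
            raise ValueError(f"cells missing columns: {need_c - set(cells.columns)}")
        if cells["cell_id"].duplicated().any():
            raise ValueError("duplicate cell_id in cell table")
        if det.duplicated(["species_id", "cell_id", "plot_id"]).any():
            raise ValueError("duplicate (species, cell, plot) detection records")
        if (det["area_m2"] <= 0).any():
            raise ValueError("plot areas must be strictly positive")
        if not det["y"].isin([0, 1]).all():
            raise ValueError("y must be 0 or 1")
        if (cells["habitat_area_km2"] < 0).any():
            raise ValueError("habitat areas must be non-negative")
        unknown = set(det["cell_id"]) - set(cells["cell_id"])
        if unknown:
            raise ValueError(f"detections reference unknown cells: {sorted(unknown)[:5]}")
        if len(aux):
            if not set(aux["state"]).issubset({"presence", "absence"}):
                raise ValueError("aux state must be 'presence' or 'absence'")
        # resolve aux conflicts: presence has priority
        if len(aux):
            grp = aux.groupby(["species_id", "cell_id"])["state"]
            resolved = grp.agg(lambda s: "presence" if (s == "presence").any() else "absence")
            n_conflict = int(grp.nunique().gt(1).sum())
            if n_conflict:
                logger.warning(
                    "%d (species, cell) pairs have conflicting auxiliary sources; "
                    "resolved to presence", n_conflict,
                )
            self.aux_resolved = resolved.reset_index().rename(columns={"state": "state"})
        else:
            self.aux_resolved = pd.DataFrame(columns=["species_id", "cell_id", "state"])
        # detections contradicting auxiliary absence
        if len(self.aux_resolved):
            absent = self.aux_resolved[self.aux_resolved["state"] == "absence"]
            det1 = det[det["y"] == 1]
            bad = det1.merge(absent, on=["species_id", "cell_id"], how="inner")
            if len(bad):
                raise ValueError(
                    "data contradiction: detections recorded for pairs with "
                    f"auxiliary absence, e.g. {bad[['species_id', 'cell_id']].iloc[0].tolist()}"
                )

    # -- indexing ---------------------------------------------------------

    @property
    def species(self) -> np.ndarray:
        return np.unique(
            np.concatenate([
                self.detections["species_id"].to_numpy(),
                self.aux["species_id"].to_numpy() if len(self.aux) else np.array([], dtype=self.detections["species_id"].dtype),
            ])
        )

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cells["cell_id"].to_numpy()

    def subset_plots(self, keep: pd.Series) -> "Dataset":
        """New Dataset with only the detection rows where ``keep`` is True."""
        return Dataset(self.detections[keep].copy(), self.cells, self.aux)


# --------------------------------------------------------------------------
# Internal likelihood structure
# --------------------------------------------------------------------------


class _Structure:
    """Index arrays and per-pair aggregates for one model specification."""

    def __init__(self, data: Dataset, occupancy: bool, covariates: bool):
        self.occupancy = occupancy
        self.covariates = covariates
        det = data.detections
        self.species = data.species
        self.cell_ids = data.cell_ids
        self.i_index = {s: i for i, s in enumerate(self.species)}
        self.j_index = {c: j for j, c in enumerate(self.cell_ids)}
        self.I = len(self.species)
        self.J = len(self.cell_ids)

        cells = data.cells.set_index("cell_id").loc[self.cell_ids]
        self.A = cells["habitat_area_km2"].to_numpy(float)
        x1 = cells["x1"].to_numpy(float)
        x2 = cells["x2"].to_numpy(float)
        self.X = np.column_stack([np.ones(self.J), x1, x2, x1 * x2])

        di = det["species_id"].map(self.i_index).to_numpy()
        dj = det["cell_id"].map(self.j_index).to_numpy()
        y = det["y"].to_numpy()
        a_km2 = det["area_m2"].to_numpy(float) * M2_TO_KM2

        # total surveyed area per (i, j); plot cells are those with any record
        pair_key = di.astype(np.int64) * self.J + dj
        order = np.argsort(pair_key, kind="stable")
        pk, first = np.unique(pair_key[order], return_index=True)
        tot_area = np.bincount(np.searchsorted(pk, pair_key), weights=a_km2, minlength=len(pk))
        any_y = np.bincount(np.searchsorted(pk, pair_key), weights=y.astype(float), minlength=len(pk)) > 0

        # m / z from detections and auxiliary data
        m = np.zeros((self.I, self.J), dtype=bool)
        z = np.zeros((self.I, self.J), dtype=np.int8)
        pi, pj = (pk // self.J).astype(int), (pk % self.J).astype(int)
        m[pi[any_y], pj[any_y]] = True
        z[pi[any_y], pj[any_y]] = 1
        if occupancy and len(data.aux_resolved):
            ai = data.aux_resolved["species_id"].map(self.i_index).to_numpy()
            aj = data.aux_resolved["cell_id"].map(self.j_index)
            if aj.isna().any():
                raise ValueError("aux references cells absent from the cell table")
            aj = aj.to_numpy(int)
            pres = (data.aux_resolved["state"] == "presence").to_numpy()
            m[ai, aj] = True
            # presence priority: never demote a detection-derived presence
            z[ai[pres], aj[pres]] = 1
            demote = ~pres & (z[ai, aj] == 0)
            z[ai[demote], aj[demote]] = 0
        self.m, self.z = m, z

        # likelihood pairs: every species x plot cell, plus aux-only pairs
        plot_cells = np.unique(dj)
        ii, jj = np.meshgrid(np.arange(self.I), plot_cells, indexing="ij")
        pair_i = ii.ravel()
        pair_j = jj.ravel()
        tot_area_mat = np.zeros((self.I, self.J))
        tot_area_mat[pi, pj] = tot_area
        anyy_mat = np.zeros((self.I, self.J), dtype=bool)
        anyy_mat[pi[any_y], pj[any_y]] = True

        if occupancy:
            cls = np.where(
                m[pair_i, pair_j],
                np.where(z[pair_i, pair_j] == 1, _Z1, _Z0),
                _MIX,
            )
            # aux-only pairs (cells without plots, m = 1): contribute the
            # Bernoulli(z | psi) factor only
            in_plot_cell = np.zeros(self.J, dtype=bool)
            in_plot_cell[plot_cells] = True
            ao_i, ao_j = np.nonzero(m & ~in_plot_cell[None, :])
            pair_i = np.concatenate([pair_i, ao_i])
            pair_j = np.concatenate([pair_j, ao_j])
            cls = np.concatenate([cls, np.where(z[ao_i, ao_j] == 1, _Z1, _Z0)])
        else:
            cls = np.full(pair_i.shape, _Z1)

        self.pair_i = pair_i
        self.pair_j = pair_j
        self.cls = cls
        self.P = len(pair_i)
        # area of nondetection plots: total minus areas of detected plots
        det_mask = y == 1
        key = pair_i.astype(np.int64) * self.J + pair_j
        sorter = np.argsort(key, kind="stable")
        det_key = di[det_mask].astype(np.int64) * self.J + dj[det_mask]
        self.det_pair = sorter[np.searchsorted(key, det_key, sorter=sorter)]
        self.det_akm2 = a_km2[det_mask]
        a0 = tot_area_mat[pair_i, pair_j].copy()
        np.subtract.at(a0, self.det_pair, self.det_akm2)
        self.A0 = np.maximum(a0, 0.0)
        self.has_det = np.zeros(self.P, dtype=bool)
        self.has_det[self.det_pair] = True
        # pairs whose density predictor enters the likelihood
        self.v_active = ((cls == _Z1) & (self.has_det | (self.A0 > 0))) | ((cls == _MIX) & (self.A0 > 0))
        self.n_detect_rows = int(det_mask.sum())
        self.n_obs = len(det)

    # fixed-effect linear predictors per cell ------------------------------

    def cell_predictors(self, p: ModelParams) -> tuple[np.ndarray, np.ndarray]:
        bv = np.array([p.mu, p.beta1, p.beta2, p.beta3])
        bw = np.array([p.eta, p.gamma1, p.gamma2, p.gamma3])
        if not self.covariates:
            bv = np.array([p.mu, 0.0, 0.0, 0.0])
            bw = np.array([p.eta, 0.0, 0.0, 0.0])
        return self.X @ bv, self.X @ bw


# ---- per-pair likelihood derivatives --------------------------------------


def _h_ratio(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """h(c) = c/(e^c - 1) and c*h'(c), stable near 0.

    These are d/dv and d^2/dv^2 of log(1 - e^{-c}) with c = e^v * a.
    """
    small = c < 1e-6
    cs = np.where(small, 1.0, c)
    em = -np.expm1(-cs)  # 1 - e^{-c}
    ec = np.exp(-cs)
    h = np.where(small, 1.0 - c / 2.0 + c * c / 12.0, cs * ec / em)
    chp = np.where(
        small,
        -c / 2.0 + c * c / 6.0,
        cs * ec * (em - cs) / (em * em),
    )
    return h, chp


def _pair_terms(st: _Structure, p: ModelParams, v: np.ndarray, w: np.ndarray, want_derivs: bool = True):
    """Log-likelihood and (v, w) derivatives for every pair.

    v, w: per-pair linear predictors (w ignored when occupancy is off).
    Returns (ll_total, lv, lw, lvv, lvw, lww) with derivative arrays of
    length P (zeros where a predictor does not enter).
    """
    P = st.P
    ll = np.zeros(P)
    lv = np.zeros(P)
    lvv = np.zeros(P)
    lw = np.zeros(P)
    lww = np.zeros(P)
    lvw = np.zeros(P)

    with np.errstate(over="ignore", under="ignore", divide="ignore", invalid="ignore"):
        return _pair_terms_inner(st, v, w, want_derivs, ll, lv, lw, lvv, lvw, lww)


def _pair_terms_inner(st, v, w, want_derivs, ll, lv, lw, lvv, lvw, lww):
    P = st.P
    d = np.exp(v)
    z1 = st.cls == _Z1
    z0 = st.cls == _Z0
    mix = st.cls == _MIX

    # detected plots (only possible in Z1 pairs)
    c_det = d[st.det_pair] * st.det_akm2
    log1mexp = np.log(-np.expm1(-c_det))
    h, chp = _h_ratio(c_det)
    ll_det = np.zeros(P)
    np.add.at(ll_det, st.det_pair, log1mexp)
    g1 = np.zeros(P)
    np.add.at(g1, st.det_pair, h)
    g2 = np.zeros(P)
    np.add.at(g2, st.det_pair, chp)

    c0 = d * st.A0
    ll[z1] = ll_det[z1] - c0[z1]
    lv[z1] = g1[z1] - c0[z1]
    lvv[z1] = g2[z1] - c0[z1]

    if st.occupancy:
        psi = expit(w)
        q = psi * (1.0 - psi)
        # Bernoulli(z | psi) factors
        ll[z1] += np.log(psi[z1])
        lw[z1] = 1.0 - psi[z1]
        lww[z1] = -q[z1]
        ll[z0] = np.log1p(-psi[z0])
        lw[z0] = -psi[z0]
        lww[z0] = -q[z0]
        # z marginalised: log(psi * e^{-C} + 1 - psi), all plots nondetections.
        # For very large C the present-branch mass vanishes: all v-derivatives
        # go to 0 (guarded so inf * 0 cannot produce NaN).
        C = c0[mix]
        big = ~(C < 700.0)
        Cs = np.where(big, 1.0, C)
        E = np.exp(-Cs)
        A = psi[mix] * E
        S = A + 1.0 - psi[mix]
        ll[mix] = np.where(big, np.log1p(-psi[mix]), np.log(S))
        AC_S = A * Cs / S
        lv[mix] = np.where(big, 0.0, -AC_S)
        lvv[mix] = np.where(big, 0.0, A * Cs * Cs / S - AC_S - AC_S ** 2)
        qm = q[mix]
        lwS = qm * (E - 1.0) / S
        lw[mix] = np.where(big, -psi[mix], lwS)
        lww[mix] = np.where(big, -qm, qm * (1.0 - 2.0 * psi[mix]) * (E - 1.0) / S - lwS ** 2)
        lvw[mix] = np.where(big, 0.0, -qm * E * Cs / S + qm * (E - 1.0) * A * Cs / (S * S))

    total = float(ll.sum())
    if not want_derivs:
        return total, None, None, None, None, None
    return total, lv, lw, lvv, lvw, lww


# ---- latent layout and Laplace machinery ----------------------------------


class _Latent:
    """Active random-effect blocks for given variance parameters."""

    def __init__(self, st: _Structure, p: ModelParams):
        self.st = st
        self.p = p
        occ = st.occupancy
        self.use_e1 = p.sigma1 > 0
        self.use_e2 = p.sigma2 > 0
        self.use_e3 = p.sigma3 > 0
        self.use_u1 = occ and p.tau1 > 0
        self.use_u2 = occ and p.tau2 > 0
        I, J = st.I, st.J
        off = 0
        self.off_e1 = off if self.use_e1 else -1
        off += I if self.use_e1 else 0
        self.off_u1 = off if self.use_u1 else -1
        off += I if self.use_u1 else 0
        self.off_e2 = off if self.use_e2 else -1
        off += J if self.use_e2 else 0
        self.off_u2 = off if self.use_u2 else -1
        off += J if self.use_u2 else 0
        self.R = off
        self.e3_pairs = np.nonzero(st.v_active)[0] if self.use_e3 else np.zeros(0, dtype=int)
        self.Pv = len(self.e3_pairs)
        self.n = self.R + self.Pv

        # per-pair row indices into the dense (R+1)-sized workspace; R = dummy
        dummy = self.R
        pi, pj = st.pair_i, st.pair_j
        self.idx = np.full((st.P, 4), dummy, dtype=int)
        if self.use_e1:
            self.idx[:, 0] = self.off_e1 + pi
        if self.use_e2:
            self.idx[:, 1] = self.off_e2 + pj
        if self.use_u1:
            self.idx[:, 2] = self.off_u1 + pi
        if self.use_u2:
            self.idx[:, 3] = self.off_u2 + pj
        self.pair_e3_slot = np.full(st.P, -1, dtype=int)
        self.pair_e3_slot[self.e3_pairs] = np.arange(self.Pv)

        # prior precision for the dense part
        self.Q = np.zeros((self.R, self.R))
        self.logdet_q = 0.0
        if self.use_e1:
            self.Q[self.off_e1: self.off_e1 + I, self.off_e1: self.off_e1 + I] = np.eye(I) / p.sigma1 ** 2
            self.logdet_q += -2.0 * I * math.log(p.sigma1)
        if self.use_u1:
            self.Q[self.off_u1: self.off_u1 + I, self.off_u1: self.off_u1 + I] = np.eye(I) / p.tau1 ** 2
            self.logdet_q += -2.0 * I * math.log(p.tau1)
        if self.use_e2 and self.use_u2:
            s2, t2, r = p.sigma2, p.tau2, p.rho
            det = s2 ** 2 * t2 ** 2 * (1 - r ** 2)
            q11 = t2 ** 2 / det
            q22 = s2 ** 2 / det
            q12 = -r * s2 * t2 / det
            e2s = slice(self.off_e2, self.off_e2 + J)
            u2s = slice(self.off_u2, self.off_u2 + J)
            self.Q[e2s, e2s] = np.eye(J) * q11
            self.Q[u2s, u2s] = np.eye(J) * q22
            self.Q[self.off_e2 + np.arange(J), self.off_u2 + np.arange(J)] = q12
            self.Q[self.off_u2 + np.arange(J), self.off_e2 + np.arange(J)] = q12
            self.logdet_q += -J * math.log(det)
        elif self.use_e2:
            self.Q[self.off_e2: self.off_e2 + J, self.off_e2: self.off_e2 + J] = np.eye(J) / p.sigma2 ** 2
            self.logdet_q += -2.0 * J * math.log(p.sigma2)
        elif self.use_u2:
            self.Q[self.off_u2: self.off_u2 + J, self.off_u2: self.off_u2 + J] = np.eye(J) / p.tau2 ** 2
            self.logdet_q += -2.0 * J * math.log(p.tau2)
        if self.use_e3 and self.Pv:
            self.logdet_q += -2.0 * self.Pv * math.log(p.sigma3)

    # -- predictors from a latent vector -----------------------------------

    def predictors(self, b: np.ndarray, v_fixed: np.ndarray, w_fixed: np.ndarray):
        st = self.st
        v = v_fixed[st.pair_j].copy()
        w = w_fixed[st.pair_j].copy() if st.occupancy else np.zeros(st.P)
        if self.use_e1:
            v += b[self.off_e1 + st.pair_i]
        if self.use_e2:
            v += b[self.off_e2 + st.pair_j]
        if self.use_u1:
            w += b[self.off_u1 + st.pair_i]
        if self.use_u2:
            w += b[self.off_u2 + st.pair_j]
        if self.use_e3:
            sl = self.pair_e3_slot
            active = sl >= 0
            v[active] += b[self.R + sl[active]]
        return v, w

    def joint_ll(self, b: np.ndarray, v_fixed, w_fixed) -> float:
        """Data log-likelihood plus the prior quadratic form (no constants)."""
        v, w = self.predictors(b, v_fixed, w_fixed)
        ll, *_ = _pair_terms(self.st, self.p, v, w, want_derivs=False)
        br = b[: self.R]
        quad = float(br @ (self.Q @ br))
        if self.use_e3 and self.Pv:
            quad += float(b[self.R:] @ b[self.R:]) / self.p.sigma3 ** 2
        return ll - 0.5 * quad


_CV = np.array([1.0, 1.0, 0.0, 0.0])
_CW = np.array([0.0, 0.0, 1.0, 1.0])
_MVV = np.outer(_CV, _CV)
_MVW = np.outer(_CV, _CW) + np.outer(_CW, _CV)
_MWW = np.outer(_CW, _CW)


def _laplace_inner(lat: _Latent, v_fixed, w_fixed, b0=None, gtol: float = 1e-8, max_iter: int = 100):
    """Find the joint mode of the random effects and return Laplace pieces.

    Returns (b_hat, joint_ll_at_mode, logdet_precision, converged).
    The species-by-cell block is eliminated analytically (its negative
    Hessian is diagonal), leaving a dense Newton system of dimension 2I+2J.
    """
    st, p = lat.st, lat.p
    R, Pv = lat.R, lat.Pv
    n = R + Pv
    b = np.zeros(n) if b0 is None else b0.copy()
    if b.size != n:
        b = np.zeros(n)
    sig3_inv2 = 1.0 / p.sigma3 ** 2 if lat.use_e3 else 0.0

    def derivs(bvec):
        v, w = lat.predictors(bvec, v_fixed, w_fixed)
        ll, lv, lw, lvv, lvw, lww = _pair_terms(st, p, v, w)
        return ll, lv, lw, lvv, lvw, lww

    converged = False
    ll, lv, lw, lvv, lvw, lww = derivs(b)
    if not np.isfinite(ll) and b0 is not None:
        b = np.zeros(n)  # warm start landed in a non-finite region; restart
        ll, lv, lw, lvv, lvw, lww = derivs(b)
    if not np.isfinite(ll):
        raise FloatingPointError("log-likelihood non-finite at the prior mean")
    br = b[:R]
    quad = 0.5 * float(br @ (lat.Q @ br)) + (0.5 * sig3_inv2 * float(b[R:] @ b[R:]) if Pv else 0.0)
    obj = ll - quad
    ridge = 0.0
    chol = None
    D = None
    for it in range(max_iter):
        # gradient
        g = np.zeros(n + 1)  # last slot is the dummy sink
        np.add.at(g, lat.idx[:, 0], lv)
        np.add.at(g, lat.idx[:, 1], lv)
        np.add.at(g, lat.idx[:, 2], lw)
        np.add.at(g, lat.idx[:, 3], lw)
        g = g[:n + 1]
        g[:R] -= lat.Q @ b[:R]
        if Pv:
            g[R:n] = lv[lat.e3_pairs] - sig3_inv2 * b[R:n]
        grad = np.concatenate([g[:R], g[R:n]])
        gnorm = np.max(np.abs(grad)) if n else 0.0
        if gnorm < gtol:
            converged = True
            break

        avv = -lvv
        avw = -lvw
        aww = -lww
        # dense part: prior + per-pair 4x4 blocks
        M = np.zeros((R + 1, R + 1))
        M[:R, :R] = lat.Q
        vals = (
            avv[:, None, None] * _MVV[None]
            + avw[:, None, None] * _MVW[None]
            + aww[:, None, None] * _MWW[None]
        )
        np.add.at(M, (lat.idx[:, :, None], lat.idx[:, None, :]), vals)
        ep = lat.e3_pairs
        D_raw = sig3_inv2 + avv[ep] if Pv else np.zeros(0)
        # Levenberg damping on the full latent system: the e3 diagonal (and
        # hence the Schur complement) is rebuilt for each ridge attempt, so an
        # indefinite joint Hessian away from the mode is handled gracefully
        if Pv and np.min(D_raw) <= 1e-8:
            ridge = max(ridge, 1e-6 + 1.1 * max(0.0, -float(np.min(D_raw))))
        chol = None
        for attempt in range(20):
            S = M[:R, :R] + ridge * np.eye(R)
            rhs = g[:R].copy()
            if Pv:
                D = D_raw + ridge
                u_vals = np.stack([avv[ep], avv[ep], avw[ep], avw[ep]], axis=1)
                scaled = u_vals / D[:, None]
                corr_m = np.zeros((R + 1, R + 1))
                np.add.at(
                    corr_m,
                    (lat.idx[ep][:, :, None], lat.idx[ep][:, None, :]),
                    scaled[:, :, None] * u_vals[:, None, :],
                )
                S = S - corr_m[:R, :R]
                corr = np.zeros(R + 1)
                for col in range(4):
                    np.add.at(corr, lat.idx[ep][:, col], scaled[:, col] * g[R:n])
                rhs -= corr[:R]
            if R == 0:
                break
            try:
                chol = linalg.cho_factor(S, lower=True, check_finite=False)
                break
            except linalg.LinAlgError:
                ridge = max(ridge * 10.0, 1e-6)
        else:  # pragma: no cover
            raise FloatingPointError("random-effect Hessian could not be factorised")
        dr = linalg.cho_solve(chol, rhs, check_finite=False) if R else np.zeros(0)
        step = np.zeros(n)
        step[:R] = dr
        if Pv:
            if R:
                drx = np.concatenate([dr, [0.0]])
                md = (
                    avv[ep] * (drx[lat.idx[ep][:, 0]] + drx[lat.idx[ep][:, 1]])
                    + avw[ep] * (drx[lat.idx[ep][:, 2]] + drx[lat.idx[ep][:, 3]])
                )
            else:
                md = np.zeros(Pv)
            step[R:] = (g[R:n] - md) / D

        # backtracking line search on the joint objective
        t = 1.0
        for _ in range(40):
            bn = b + t * step
            lln, lvn, lwn, lvvn, lvwn, lwwn = derivs(bn)
            brn = bn[:R]
            quadn = 0.5 * float(brn @ (lat.Q @ brn)) + (
                0.5 * sig3_inv2 * float(bn[R:] @ bn[R:]) if Pv else 0.0
            )
            objn = lln - quadn
            if np.isfinite(objn) and objn >= obj - 1e-12:
                break
            t *= 0.5
        if not np.isfinite(objn):  # pragma: no cover
            raise FloatingPointError("joint objective became non-finite")
        improved = objn - obj
        b, obj = bn, objn
        ll, lv, lw, lvv, lvw, lww = lln, lvn, lwn, lvvn, lvwn, lwwn
        ridge = 0.0
        if improved < 1e-12 and it > 2:
            # objective has stagnated; accept if gradient is small-ish
            converged = True
            break

    # log-determinant of the negative Hessian at the mode
    avv, avw, aww = -lvv, -lvw, -lww
    M = np.zeros((R + 1, R + 1))
    M[:R, :R] = lat.Q
    vals = (
        avv[:, None, None] * _MVV[None]
        + avw[:, None, None] * _MVW[None]
        + aww[:, None, None] * _MWW[None]
    )
    np.add.at(M, (lat.idx[:, :, None], lat.idx[:, None, :]), vals)
    logdet = 0.0
    if Pv:
        ep = lat.e3_pairs
        D = sig3_inv2 + avv[ep]
        if np.any(D <= 0):
            raise FloatingPointError("negative curvature in the e3 block at the mode")
        logdet += float(np.sum(np.log(D)))
        u_vals = np.stack([avv[ep], avv[ep], avw[ep], avw[ep]], axis=1)
        scaled = u_vals / D[:, None]
        np.add.at(
            M,
            (lat.idx[ep][:, :, None], lat.idx[ep][:, None, :]),
            -(scaled[:, :, None] * u_vals[:, None, :]),
        )
    if R:
        try:
            cS = linalg.cholesky(M[:R, :R], lower=True, check_finite=False)
        except linalg.LinAlgError as exc:
            raise FloatingPointError("Hessian not positive definite at the mode") from exc
        logdet += 2.0 * float(np.sum(np.log(np.diag(cS))))
    return b, obj, logdet, converged


def _agq_e3_only(st: _Structure, p: ModelParams, v_fixed, w_fixed, nodes: int = 31) -> float:
    """Exact-to-quadrature marginal when only e3 is active.

    The marginal factorises over (i, j); each factor is a 1-D integral over
    the pair's e3 effect, evaluated with adaptive Gauss-Hermite centred and
    scaled at the conditional mode.
    """
    sig = p.sigma3
    base_v = v_fixed[st.pair_j]
    base_w = w_fixed[st.pair_j] if st.occupancy else np.zeros(st.P)
    act = st.v_active

    # contributions without any latent dependence
    _, lv, lw, lvv, lvw, lww = _pair_terms(st, p, base_v, base_w)
    ll0, *_ = _pair_terms(st, p, base_v, base_w, want_derivs=False)

    # per-pair log-likelihood as a function of t = e3 for active pairs:
    # iterate Newton on f(t) = ll_pair(v0 + t) - t^2/(2 sig^2)
    t_hat = np.zeros(st.P)
    for _ in range(60):
        v = base_v + t_hat
        _, lv, lw, lvv, lvw, lww = _pair_terms(st, p, v, base_w)
        g = lv - t_hat / sig ** 2
        h = lvv - 1.0 / sig ** 2
        step = np.where(act, g / h, 0.0)
        t_hat = t_hat - step
        if np.max(np.abs(step[act])) < 1e-12 if act.any() else True:
            break
    v = base_v + t_hat
    _, lv, lw, lvv, lvw, lww = _pair_terms(st, p, v, base_w)
    curv = 1.0 / sig ** 2 - lvv
    s_hat = 1.0 / np.sqrt(np.maximum(curv, 1e-300))

    x, wq = special.roots_hermite(nodes)
    # per-pair, per-node predictors; evaluate pair log-lik node by node
    log_terms = np.zeros((nodes, st.P))
    for k in range(nodes):
        tk = t_hat + math.sqrt(2.0) * s_hat * x[k]
        vk = base_v + tk
        llk = _pair_ll_vector(st, p, vk, base_w)
        log_terms[k] = (
            math.log(wq[k])
            + x[k] ** 2
            + llk
            - 0.5 * tk ** 2 / sig ** 2
            - 0.5 * math.log(2.0 * math.pi * sig ** 2)
            + 0.5 * math.log(2.0)
            + np.log(s_hat)
        )
    per_pair = special.logsumexp(log_terms, axis=0)
    # inactive pairs: no integral, plain contribution at t = 0
    ll_inact = _pair_ll_vector(st, p, base_v, base_w)
    out = float(np.sum(np.where(act, per_pair, ll_inact)))
    return out


def _pair_ll_vector(st: _Structure, p: ModelParams, v, w) -> np.ndarray:
    """Per-pair log-likelihood vector (no derivatives)."""
    with np.errstate(over="ignore", under="ignore", divide="ignore", invalid="ignore"):
        return _pair_ll_vector_inner(st, v, w)


def _pair_ll_vector_inner(st: _Structure, v, w) -> np.ndarray:
    P = st.P
    ll = np.zeros(P)
    d = np.exp(v)
    z1 = st.cls == _Z1
    z0 = st.cls == _Z0
    mix = st.cls == _MIX
    c_det = d[st.det_pair] * st.det_akm2
    ll_det = np.zeros(P)
    np.add.at(ll_det, st.det_pair, np.log(-np.expm1(-c_det)))
    c0 = d * st.A0
    ll[z1] = ll_det[z1] - c0[z1]
    if st.occupancy:
        psi = expit(w)
        ll[z1] += np.log(psi[z1])
        ll[z0] = np.log1p(-psi[z0])
        C = c0[mix]
        ll[mix] = np.log(psi[mix] * np.exp(-C) + 1.0 - psi[mix])
    return ll


# --------------------------------------------------------------------------
# Public likelihood operations
# --------------------------------------------------------------------------


def linear_predictors(params: ModelParams, effects: RandomEffects, cells: pd.DataFrame, covariates: bool = True):
    """(log d_ij, logit psi_ij) matrices for all species x cells.

    Cells must be ordered as in the fit; e3 enters only for its stored pairs
    (prior mean zero elsewhere).
    """
    x1 = cells["x1"].to_numpy(float)
    x2 = cells["x2"].to_numpy(float)
    X = np.column_stack([np.ones(len(cells)), x1, x2, x1 * x2])
    bv = np.array([params.mu, params.beta1, params.beta2, params.beta3])
    bw = np.array([params.eta, params.gamma1, params.gamma2, params.gamma3])
    if not covariates:
        bv[1:] = 0.0
        bw[1:] = 0.0
    vj = X @ bv
    wj = X @ bw
    log_d = vj[None, :] + effects.e1[:, None] + effects.e2[None, :]
    if effects.e3_pairs.size:
        log_d[effects.e3_pairs[:, 0], effects.e3_pairs[:, 1]] += effects.e3
    logit_psi = wj[None, :] + effects.u1[:, None] + effects.u2[None, :]
    return log_d, logit_psi


def species_cell_loglik(y, areas_m2, d, psi, aux_state: str | None) -> float:
    """Likelihood contribution of one (species, cell).

    ``aux_state`` is 'presence', 'absence' or None (z unknown). With z
    unknown the latent state is marginalised exactly:
    log[ psi * prod_k Bern(y_k | p_k) + (1-psi) * 1{all y_k = 0} ].
    """
    y = np.asarray(y, dtype=int)
    a = np.asarray(areas_m2, dtype=float) * M2_TO_KM2
    if y.size != a.size:
        raise ValueError("y and areas must align")
    c = d * a
    if aux_state == "absence" and np.any(y == 1):
        raise ValueError("data contradiction: detection with auxiliary absence")
    log_py_z1 = float(np.sum(np.where(y == 1, np.log(-np.expm1(-c)), -c)))
    if aux_state == "presence" or np.any(y == 1):
        return log_py_z1 + math.log(psi)
    if aux_state == "absence":
        return math.log1p(-psi)
    # z unknown, all y = 0
    return float(np.logaddexp(math.log(psi) + log_py_z1, math.log1p(-psi)))


def marginal_loglik(
    params: ModelParams,
    data: Dataset,
    model_spec: str = "integrated",
    method: str = "auto",
    covariates: bool = True,
    agq_nodes: int = 31,
    _warm=None,
) -> float:
    """Marginal log-likelihood of the data with random effects integrated out.

    ``method``: 'laplace' (joint Laplace approximation), 'agq' (adaptive
    Gauss-Hermite; only valid when e3 is the sole active random effect so
    the marginal factorises into 1-D integrals), or 'auto' (exact when no
    random effect is active, AGQ when only e3 is, Laplace otherwise).
    """
    occupancy = model_spec == "integrated"
    st = _Structure(data, occupancy=occupancy, covariates=covariates)
    return _marginal_loglik_st(st, params, method=method, agq_nodes=agq_nodes)


def _marginal_loglik_st(st: _Structure, params: ModelParams, method="auto", agq_nodes=31, warm=None):
    v_fixed, w_fixed = st.cell_predictors(params)
    lat = _Latent(st, params)
    only_e3 = lat.use_e3 and not (lat.use_e1 or lat.use_e2 or lat.use_u1 or lat.use_u2)
    none_active = lat.n == 0
    if method == "auto":
        method = "exact" if none_active else ("agq" if only_e3 else "laplace")
    if method == "agq":
        if not only_e3:
            raise ValueError("AGQ requires e3 to be the only active random effect")
        return _agq_e3_only(st, params, v_fixed, w_fixed, nodes=agq_nodes)
    if method == "exact" or none_active:
        ll, *_ = _pair_terms(st, params, *_base_predictors(st, v_fixed, w_fixed), want_derivs=False)
        return ll
    b, obj, logdet, ok = _laplace_inner(lat, v_fixed, w_fixed, b0=warm)
    if not ok:
        logger.warning("inner Newton did not fully converge")
    return obj + 0.5 * lat.logdet_q - 0.5 * logdet


def _base_predictors(st: _Structure, v_fixed, w_fixed):
    v = v_fixed[st.pair_j]
    w = w_fixed[st.pair_j] if st.occupancy else np.zeros(st.P)
    return v, w


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------


@dataclass
class FitConfig:
    """Optimiser settings for maximum marginal likelihood."""

    maxiter: int = 400
    gtol: float = 1e-5
    fd_step: float = 1e-5
    compute_se: bool = True
    covariates: bool = True
    start: ModelParams | None = None
    se_step: float = 1e-3
    fixed: dict = field(default_factory=dict)  # pin parameters, e.g. {"sigma3": 0.0}
    verbose: bool = False


@dataclass
class FittedModel:
    """Maximum marginal-likelihood fit of the hierarchical model."""

    params: ModelParams
    effects: RandomEffects
    loglik: float
    converged: bool
    grad_norm: float
    n_eval: int
    model_spec: str
    species: np.ndarray
    cell_ids: np.ndarray
    d_hat: np.ndarray  # (I, J) conditional density per km^2
    psi_hat: np.ndarray  # (I, J) occurrence probability
    m: np.ndarray  # (I, J) 1 where z is known
    z_known: np.ndarray  # (I, J) known z values (0 where unknown)
    se: dict = field(default_factory=dict)
    cov: np.ndarray | None = None
    param_names: list = field(default_factory=list)
    wall_time_s: float = 0.0

    @property
    def i_index(self):
        return {s: i for i, s in enumerate(self.species)}

    @property
    def j_index(self):
        return {c: j for j, c in enumerate(self.cell_ids)}

    def occupancy_weight(self) -> np.ndarray:
        """m*z + (1-m)*psi-hat: the bracket of the derived estimators."""
        m = self.m.astype(float)
        return m * self.z_known + (1.0 - m) * self.psi_hat

    def predictions(self) -> pd.DataFrame:
        ii, jj = np.meshgrid(np.arange(len(self.species)), np.arange(len(self.cell_ids)), indexing="ij")
        return pd.DataFrame(
            {
                "species_id": self.species[ii.ravel()],
                "cell_id": self.cell_ids[jj.ravel()],
                "d_hat": self.d_hat.ravel(),
                "psi_hat": self.psi_hat.ravel(),
                "m": self.m.ravel().astype(int),
                "z_known": self.z_known.ravel(),
            }
        )


def _pack_names(model_spec: str, covariates: bool, fixed: dict | None = None) -> list[str]:
    fixed = fixed or {}
    names = ["mu"]
    if covariates:
        names += ["beta1", "beta2", "beta3"]
    if model_spec == "integrated":
        names += ["eta"]
        if covariates:
            names += ["gamma1", "gamma2", "gamma3"]
    names += ["log_sigma1", "log_sigma2", "log_sigma3"]
    if model_spec == "integrated":
        names += ["log_tau1", "log_tau2", "atanh_rho"]

    def is_fixed(name):
        base = name[4:] if name.startswith("log_") else ("rho" if name == "atanh_rho" else name)
        return base in fixed

    return [n for n in names if not is_fixed(n)]


def _unpack(x: np.ndarray, names: list[str], fixed: dict | None = None) -> ModelParams:
    kw = dict(fixed or {})
    for name, val in zip(names, x):
        if name.startswith("log_"):
            kw[name[4:]] = math.exp(float(np.clip(val, math.log(1e-6), 20.0)))
        elif name == "atanh_rho":
            kw["rho"] = math.tanh(float(np.clip(val, -6.0, 6.0)))
        else:
            kw[name] = val
    return ModelParams(**kw)


def _pack(p: ModelParams, names: list[str]) -> np.ndarray:
    out = []
    for name in names:
        if name.startswith("log_"):
            out.append(math.log(max(getattr(p, name[4:]), 1e-8)))
        elif name == "atanh_rho":
            out.append(math.atanh(np.clip(p.rho, -0.999, 0.999)))
        else:
            out.append(getattr(p, name))
    return np.array(out)


def _default_start(st: _Structure, model_spec: str) -> ModelParams:
    det_frac = st.n_detect_rows / max(st.n_obs, 1)
    det_frac = min(max(det_frac, 1e-4), 0.95)
    mean_akm2 = float(np.mean(st.det_akm2)) if st.n_detect_rows else float(np.mean(st.A0[st.A0 > 0]) or 1e-4)
    mean_akm2 = max(mean_akm2, 1e-8)
    mu0 = math.log(max(-math.log1p(-det_frac) / mean_akm2, 1e-6))
    kw = dict(mu=mu0, sigma1=0.5, sigma2=0.5, sigma3=0.5)
    if model_spec == "integrated":
        occ_frac = float(np.mean(st.m & (st.z == 1))) + 0.05
        occ_frac = min(max(occ_frac, 0.05), 0.95)
        kw.update(eta=math.log(occ_frac / (1 - occ_frac)), tau1=0.5, tau2=0.5, rho=0.0)
    return ModelParams(**kw)


def fit(
    data: Dataset,
    model_spec: str = "integrated",
    config: FitConfig | None = None,
) -> FittedModel:
    """Fit the hierarchical model by maximum marginal likelihood.

    ``model_spec``: 'integrated' (zero-inflated with auxiliary occurrence
    data) or 'baseline_glmm' (cloglog Bernoulli GLMM without occupancy).
    SDs are optimised on the log scale and rho through atanh; the optimiser
    starts from moment-based intercepts, so the procedure is deterministic
    for fixed inputs.
    """
    config = config or FitConfig()
    if model_spec not in ("integrated", "baseline_glmm"):
        raise ValueError(f"unknown model_spec: {model_spec}")
    t0 = time.perf_counter()
    occupancy = model_spec == "integrated"
    st = _Structure(data, occupancy=occupancy, covariates=config.covariates)
    if st.n_detect_rows == 0:
        raise ValueError("no detections: the density intercept is not identifiable")
    if st.n_obs == 0:
        raise ValueError("empty detection table")
    for col, x in (("x1", st.X[:, 1]), ("x2", st.X[:, 2])):
        if config.covariates and np.allclose(np.var(x), 0.0):
            warnings.warn(f"covariate {col} is constant; its coefficient is not identifiable")

    names = _pack_names(model_spec, config.covariates, config.fixed)
    start = config.start or _default_start(st, model_spec)
    x0 = _pack(start, names)

    warm = {"b": None}
    n_eval = {"n": 0}

    def objective(x):
        p = _unpack(x, names, config.fixed)
        v_fixed, w_fixed = st.cell_predictors(p)
        lat = _Latent(st, p)
        n_eval["n"] += 1
        if lat.n == 0:  # no active random effects: exact likelihood
            val, *_ = _pair_terms(st, p, *_base_predictors(st, v_fixed, w_fixed), want_derivs=False)
            return -val if np.isfinite(val) else 1e10
        try:
            b, obj, logdet, _ = _laplace_inner(lat, v_fixed, w_fixed, b0=warm["b"])
        except FloatingPointError:
            return 1e10
        warm["b"] = b
        val = obj + 0.5 * lat.logdet_q - 0.5 * logdet
        return -val if np.isfinite(val) else 1e10

    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        options={
            "maxiter": config.maxiter,
            "gtol": config.gtol,
            "eps": config.fd_step,
            "maxcor": 20,
        },
    )
    p_hat = _unpack(res.x, names, config.fixed)
    loglik = -float(res.fun)

    # final mode and predictions
    v_fixed, w_fixed = st.cell_predictors(p_hat)
    lat = _Latent(st, p_hat)
    if lat.n:
        try:
            b, *_ = _laplace_inner(lat, v_fixed, w_fixed, b0=warm["b"])
        except FloatingPointError:
            # the warm start comes from the last exploratory evaluation and can
            # sit in a bad region; the prior mean is always a safe start
            b, *_ = _laplace_inner(lat, v_fixed, w_fixed, b0=None)
    else:
        b = np.zeros(0)
    effects = _extract_effects(st, lat, b)
    log_d, logit_psi = linear_predictors(
        p_hat, effects, pd.DataFrame({"x1": st.X[:, 1], "x2": st.X[:, 2]}), covariates=config.covariates
    )
    d_hat = np.exp(log_d)
    psi_hat = expit(logit_psi) if occupancy else np.ones_like(d_hat)

    se: dict = {}
    cov = None
    if config.compute_se:
        cov = _fd_covariance(objective, res.x, config.se_step)
        if cov is not None:
            sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
            se = dict(zip(names, sd))

    fitted = FittedModel(
        params=p_hat,
        effects=effects,
        loglik=loglik,
        converged=bool(res.success),
        grad_norm=float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan,
        n_eval=n_eval["n"],
        model_spec=model_spec,
        species=st.species,
        cell_ids=st.cell_ids,
        d_hat=d_hat,
        psi_hat=psi_hat,
        m=st.m.astype(int) if occupancy else np.ones((st.I, st.J), dtype=int) * 0,
        z_known=st.z.astype(int) if occupancy else np.zeros((st.I, st.J), dtype=int),
        se=se,
        cov=cov,
        param_names=names,
        wall_time_s=time.perf_counter() - t0,
    )
    if not res.success:
        logger.warning("optimiser did not report convergence: %s", res.message)
    return fitted


def _extract_effects(st: _Structure, lat: _Latent, b: np.ndarray) -> RandomEffects:
    I, J = st.I, st.J
    e1 = b[lat.off_e1: lat.off_e1 + I].copy() if lat.use_e1 else np.zeros(I)
    u1 = b[lat.off_u1: lat.off_u1 + I].copy() if lat.use_u1 else np.zeros(I)
    e2 = b[lat.off_e2: lat.off_e2 + J].copy() if lat.use_e2 else np.zeros(J)
    u2 = b[lat.off_u2: lat.off_u2 + J].copy() if lat.use_u2 else np.zeros(J)
    if lat.use_e3 and lat.Pv:
        pairs = np.column_stack([st.pair_i[lat.e3_pairs], st.pair_j[lat.e3_pairs]])
        e3 = b[lat.R:].copy()
    else:
        pairs = np.zeros((0, 2), dtype=int)
        e3 = np.zeros(0)
    return RandomEffects(e1=e1, u1=u1, e2=e2, u2=u2, e3=e3, e3_pairs=pairs)


def _fd_covariance(objective, x: np.ndarray, step: float) -> np.ndarray | None:
    """Observed-information covariance by central finite differences."""
    k = len(x)
    H = np.zeros((k, k))
    f0 = objective(x)
    hs = step * np.maximum(1.0, np.abs(x))
    for a in range(k):
        xa = x.copy()
        xa[a] += hs[a]
        fp = objective(xa)
        xa[a] -= 2 * hs[a]
        fm = objective(xa)
        H[a, a] = (fp - 2 * f0 + fm) / hs[a] ** 2
    for a in range(k):
        for c in range(a + 1, k):
            vals = {}
            for sa, sc in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                xac = x.copy()
                xac[a] += sa * hs[a]
                xac[c] += sc * hs[c]
                vals[(sa, sc)] = objective(xac)
            H[a, c] = H[c, a] = (
                vals[(1, 1)] - vals[(1, -1)] - vals[(-1, 1)] + vals[(-1, -1)]
            ) / (4.0 * hs[a] * hs[c])
    try:
        cov = linalg.inv(H)
    except linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)):
        return None
    return cov


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------


def rank_auc(y: np.ndarray, score: np.ndarray) -> float:
    """Mann-Whitney AUC with average ranks for ties."""
    from scipy.stats import rankdata

    y = np.asarray(y)
    score = np.asarray(score, dtype=float)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: a single outcome class")
    r = rankdata(score)
    return float((np.sum(r[y == 1]) - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def crossvalidate_auc(
    data: Dataset,
    n_folds: int = 10,
    seed: int = 0,
    model_spec: str = "integrated",
    config: FitConfig | None = None,
) -> tuple[float, float, list[float]]:
    """K-fold cross-validated AUC of plot-level detection predictions.

    Folds partition the plots. For each fold the model is refit on the
    training plots and held-out records are scored with
    psi-tilde * (1 - exp(-d_hat * a)), where psi-tilde is the known z when
    auxiliary data fixes it and psi-hat otherwise. Records whose (species,
    cell) has an auxiliary absence are excluded (structural zeros). Folds
    with a single outcome class are skipped with a warning. Returns
    (mean AUC, SD over folds, per-fold values).
    """
    if n_folds < 2:
        raise ValueError("need at least two folds")
    config = config or FitConfig(compute_se=False)
    det = data.detections
    plots = det[["cell_id", "plot_id"]].drop_duplicates().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    # balanced random partition of plots into folds
    fold_of = np.argsort(rng.random(len(plots))) % n_folds
    plots = plots.assign(fold=fold_of)
    det = det.merge(plots, on=["cell_id", "plot_id"], how="left")

    aux_absent = set()
    if len(data.aux_resolved):
        ab = data.aux_resolved[data.aux_resolved["state"] == "absence"]
        aux_absent = set(zip(ab["species_id"], ab["cell_id"]))

    aucs = []
    for f in range(n_folds):
        test = det[det["fold"] == f]
        train = data.subset_plots(det["fold"] != f)
        fitted = fit(train, model_spec=model_spec, config=replace(config, compute_se=False))
        ii = test["species_id"].map(fitted.i_index)
        jj = test["cell_id"].map(fitted.j_index)
        ok = ii.notna() & jj.notna()
        test = test[ok]
        ii = ii[ok].astype(int).to_numpy()
        jj = jj[ok].astype(int).to_numpy()
        keep = np.array(
            [(s, c) not in aux_absent for s, c in zip(test["species_id"], test["cell_id"])]
        )
        if not keep.any():
            warnings.warn(f"fold {f}: all records excluded")
            continue
        ii, jj = ii[keep], jj[keep]
        test = test[keep]
        d = fitted.d_hat[ii, jj]
        psi = fitted.psi_hat[ii, jj]
        m = fitted.m[ii, jj].astype(bool)
        zk = fitted.z_known[ii, jj]
        psi_t = np.where(m, zk.astype(float), psi)
        p = psi_t * (-np.expm1(-d * test["area_m2"].to_numpy(float) * M2_TO_KM2))
        yv = test["y"].to_numpy()
        if yv.min() == yv.max():
            warnings.warn(f"fold {f}: single outcome class, skipped")
            continue
        aucs.append(rank_auc(yv, p))
    if not aucs:
        raise ValueError("no fold produced a defined AUC")
    return float(np.mean(aucs)), float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0, aucs
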
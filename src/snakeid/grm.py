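"""Hierarchical Bayesian graded response model of identification accuracy.

Each response is an ordinal accuracy score y in {0,1,2,3}.  The model places
a two-parameter logistic (cumulative logit) distribution over the four
categories:

    P(y <= k) = logistic(alpha * (tau_{k+1} - eta)),   k = 0,1,2

with linear predictor (higher eta => higher scores)

    eta   = theta_j + x' beta + b_photo + b_species
    alpha = exp(delta0 + d_photo + d_species)

theta_j is participant ability (sd fixed at 1, which sets the latent scale);
(b, d) are photo- and species-level difficulty/discrimination deviations,
each pair bivariate normal with free sds and correlation.  Fixed effects x
cover snake family, photo region, home-region match (plus region
interactions), photo quality and the taxa-repeat learning covariate.

Sampling is adaptive HMC (``snakeid._hmc``) on an unconstrained
parameterization: ordered-transform thresholds, log-scale sds, tanh-scale
correlations and non-centred group effects.  Gradients are analytic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._hmc import sample_chain
from .taxonomy import REGIONS

FAMILIES = (
    "Boidae",
    "Colubridae",
    "Cylindrophiidae",
    "Elapidae",
    "Lamprophiidae",
    "Leptotyphlopidae",
    "Pythonidae",
    "Typhlopidae",
    "Viperidae",
)


# ---------------------------------------------------------------------------
# category probabilities
# ---------------------------------------------------------------------------

def _check_tau(tau) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    if tau.shape[-1] != 3 or not np.all(np.diff(tau, axis=-1) > 0):
        raise ValueError("tau must be a strictly increasing 3-vector")
    return tau


def category_probs(eta, alpha, tau) -> np.ndarray:
    """Probabilities of the four ordinal accuracy categories.

    ``P(y<=k) = logistic(alpha*(tau_{k+1}-eta))``; category probabilities are
    adjacent differences.  Broadcasts over ``eta``/``alpha``; the trailing
    axis of the result has length 4 and sums to 1.
    """
    tau = _check_tau(tau)
    eta = np.asarray(eta, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    cum = expit(alpha[..., None] * (tau - eta[..., None]))  # (..., 3)
    p = np.empty(eta.shape + (4,))
    p[..., 0] = cum[..., 0]
    p[..., 1] = cum[..., 1] - cum[..., 0]
    p[..., 2] = cum[..., 2] - cum[..., 1]
    p[..., 3] = 1.0 - cum[..., 2]
    return p


def expected_score(eta, alpha, tau) -> np.ndarray:
    """Posterior-predictive mean of the ordinal score treated as numeric."""
    p = category_probs(eta, alpha, tau)
    return p @ np.arange(4.0)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Fixed-effect structure of one candidate model.

    Reference levels: family Boidae, region Africa — a Boidae photo from
    Africa seen by a non-home participant at first exposure has an all-zero
    fixed-effect row.  All candidate models include family, photo region and
    taxa-repeat; the flags add home-region, its region interaction, and photo
    quality.
    """

    name: str = "full"
    families: tuple = FAMILIES
    regions: tuple = REGIONS
    include_home: bool = True
    include_home_interaction: bool = True
    include_quality: bool = False
    group_effects: bool = True

    def __post_init__(self):
        if self.include_home_interaction and not self.include_home:
            raise ValueError("interaction spec must include the home_region main effect")

    @property
    def columns(self) -> list[str]:
        cols = list(self.families[1:]) + list(self.regions[1:])
        if self.include_home:
            cols.append("home_region = T")
        cols.append("taxa_repeat")
        if self.include_quality:
            cols.append("quality = low")
        if self.include_home_interaction:
            cols += [f"{r}: home_region = T" for r in self.regions[1:]]
        return cols


@dataclass
class DesignMatrices:
    """Numeric design for the GRM likelihood."""

    X: np.ndarray                # (n, K)
    colnames: list[str]
    y: np.ndarray                # (n,) ints in 0..3
    participant_idx: np.ndarray  # (n,) index into participant_ids, -1 = unseen
    photo_idx: np.ndarray
    species_idx: np.ndarray
    participant_ids: list
    photo_ids: list
    species_ids: list
    spec: DesignSpec

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)


def _codes(values: pd.Series, levels: Optional[list] = None):
    if levels is None:
        levels = sorted(values.unique().tolist())
    lookup = {v: i for i, v in enumerate(levels)}
    codes = np.array([lookup.get(v, -1) for v in values], dtype=np.int64)
    return codes, levels


def build_design(
    responses: pd.DataFrame,
    spec: DesignSpec,
    like: Optional[DesignMatrices] = None,
) -> DesignMatrices:
    """Dummy-code a scored response table for one candidate model.

    Requires columns ``score``, ``family``, ``photo_region``, ``home_region``,
    ``taxa_repeat``, ``participant_id``, ``photo_id``, ``true_species`` (and
    ``quality`` with values high/low when the spec includes it).  Passing
    ``like`` reuses another design's participant/photo/species index maps so
    train and test matrices share group levels (unseen units code to -1,
    i.e. group deviations of zero at prediction time).
    """
    for col, levels in (("family", spec.families), ("photo_region", spec.regions),
                        ("home_region", spec.regions)):
        unseen = set(responses[col].unique()) - set(levels)
        if unseen:
            raise ValueError(f"unseen {col} level(s): {sorted(unseen)}")

    n = len(responses)
    cols = spec.columns
    X = np.zeros((n, len(cols)))
    pos = {c: i for i, c in enumerate(cols)}

    fam = responses["family"].to_numpy()
    reg = responses["photo_region"].to_numpy()
    home = (responses["photo_region"] == responses["home_region"]).to_numpy()
    for f in spec.families[1:]:
        X[fam == f, pos[f]] = 1.0
    for r in spec.regions[1:]:
        X[reg == r, pos[r]] = 1.0
    if spec.include_home:
        X[home, pos["home_region = T"]] = 1.0
    X[:, pos["taxa_repeat"]] = responses["taxa_repeat"].to_numpy(dtype=float)
    if spec.include_quality:
        q = responses["quality"].astype(str).str.lower().to_numpy()
        bad = set(q) - {"high", "low"}
        if bad:
            raise ValueError(f"unseen quality level(s): {sorted(bad)}")
        X[q == "low", pos["quality = low"]] = 1.0
    if spec.include_home_interaction:
        for r in spec.regions[1:]:
            X[(reg == r) & home, pos[f"{r}: home_region = T"]] = 1.0

    y = responses["score"].to_numpy(dtype=np.int64)
    if y.min() < 0 or y.max() > 3:
        raise ValueError("scores must lie in 0..3")

    p_idx, p_ids = _codes(responses["participant_id"],
                          like.participant_ids if like else None)
    i_idx, i_ids = _codes(responses["photo_id"], like.photo_ids if like else None)
    s_idx, s_ids = _codes(responses["true_species"], like.species_ids if like else None)
    if like is None and spec.group_effects:
        # every response must map to exactly one unit of each grouping factor
        assert (p_idx >= 0).all() and (i_idx >= 0).all() and (s_idx >= 0).all()

    return DesignMatrices(X, cols, y, p_idx, i_idx, s_idx, p_ids, i_ids, s_ids, spec)


# ---------------------------------------------------------------------------
# parameters & pointwise likelihood
# ---------------------------------------------------------------------------

@dataclass
class GRMParameters:
    """One set of model parameters on the constrained scale."""

    tau: np.ndarray
    beta: np.ndarray
    delta0: float = 0.0
    theta: Optional[np.ndarray] = None
    photo_b: Optional[np.ndarray] = None
    photo_d: Optional[np.ndarray] = None
    species_b: Optional[np.ndarray] = None
    species_d: Optional[np.ndarray] = None
    sd_photo_b: float = 0.0
    sd_photo_d: float = 0.0
    cor_photo: float = 0.0
    sd_species_b: float = 0.0
    sd_species_d: float = 0.0
    cor_species: float = 0.0


def _gather(effect: Optional[np.ndarray], idx: np.ndarray) -> np.ndarray:
    """Group deviation per observation; unseen units (idx==-1) get 0."""
    if effect is None:
        return np.zeros(idx.shape)
    out = np.where(idx >= 0, effect[np.clip(idx, 0, None)], 0.0)
    return out


def linear_predictor(params: GRMParameters, design: DesignMatrices):
    """(eta, alpha) per observation for one parameter set."""
    eta = design.X @ params.beta
    eta += _gather(params.theta, design.participant_idx)
    eta += _gather(params.photo_b, design.photo_idx)
    eta += _gather(params.species_b, design.species_idx)
    log_alpha = params.delta0 + _gather(params.photo_d, design.photo_idx) \
        + _gather(params.species_d, design.species_idx)
    return eta, np.exp(log_alpha)


def log_likelihood(params: GRMParameters, design: DesignMatrices) -> np.ndarray:
    """Pointwise log-likelihood vector (one element per response)."""
    if not np.all(np.isfinite(params.tau)) or not np.all(np.isfinite(params.beta)):
        raise ValueError("non-finite parameter")
    _check_tau(params.tau)
    eta, alpha = linear_predictor(params, design)
    p = category_probs(eta, alpha, params.tau)
    sel = p[np.arange(design.n_obs), design.y]
    return np.log(np.clip(sel, 1e-300, None))


# ---------------------------------------------------------------------------
# priors and unconstrained log posterior with analytic gradient
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Priors:
    """Weakly-informative defaults; all overridable."""

    sd_beta: float = 2.5
    sd_tau: float = 2.5
    sd_delta0: float = 1.0
    sd_group: float = 1.0     # half-normal scale for all group-level sds
    lkj_eta: float = 2.0      # weakly-regularizing correlation prior


class _Layout:
    """Slices of the unconstrained parameter vector."""

    def __init__(self, K: int, J: int, I: int, S: int,
                 group_effects: bool, fix_discrimination: bool):
        self.group_effects = group_effects
        self.fix_discrimination = fix_discrimination
        i = 0

        def take(size):
            nonlocal i
            sl = slice(i, i + size)
            i += size
            return sl

        self.a_tau = take(3)
        self.beta = take(K)
        self.delta0 = None if fix_discrimination else take(1)
        if group_effects:
            self.theta = take(J)
            self.z1p = take(I)
            self.z2p = take(I)
            self.z1s = take(S)
            self.z2s = take(S)
            self.phi_p = take(3)   # log sd_b, log sd_d, atanh rho
            self.phi_s = take(3)
        self.dim = i


def _unpack_tau(a: np.ndarray):
    t1 = a[0]
    t2 = t1 + np.exp(a[1])
    t3 = t2 + np.exp(a[2])
    return np.array([t1, t2, t3])


def _unpack(q: np.ndarray, lay: _Layout, design: DesignMatrices) -> GRMParameters:
    tau = _unpack_tau(q[lay.a_tau])
    beta = q[lay.beta]
    delta0 = 0.0 if lay.fix_discrimination else float(q[lay.delta0][0])
    params = GRMParameters(tau=tau, beta=beta, delta0=delta0)
    if lay.group_effects:
        lsb, lsd, u = q[lay.phi_p]
        sd_b, sd_d, rho = np.exp(lsb), np.exp(lsd), np.tanh(u)
        z1, z2 = q[lay.z1p], q[lay.z2p]
        params.photo_b = sd_b * z1
        params.photo_d = sd_d * (rho * z1 + np.sqrt(1 - rho**2) * z2)
        params.sd_photo_b, params.sd_photo_d, params.cor_photo = sd_b, sd_d, rho
        lsb, lsd, u = q[lay.phi_s]
        sd_b, sd_d, rho = np.exp(lsb), np.exp(lsd), np.tanh(u)
        z1, z2 = q[lay.z1s], q[lay.z2s]
        params.species_b = sd_b * z1
        params.species_d = sd_d * (rho * z1 + np.sqrt(1 - rho**2) * z2)
        params.sd_species_b, params.sd_species_d, params.cor_species = sd_b, sd_d, rho
        params.theta = q[lay.theta]
    return params


def make_log_posterior(design: DesignMatrices, priors: Priors,
                       fix_discrimination: bool = False):
    """Build ``logp_and_grad(q)`` for HMC, plus the parameter layout.

    The likelihood term and its gradient are fully vectorized; gradients are
    exact (verified against finite differences in the test suite).
    """
    X = design.X
    y = design.y
    n, K = X.shape
    J = len(design.participant_ids)
    I = len(design.photo_ids)
    S = len(design.species_ids)
    group = design.spec.group_effects
    lay = _Layout(K, J, I, S, group, fix_discrimination)

    j_idx, i_idx, s_idx = design.participant_idx, design.photo_idx, design.species_idx
    rows = np.arange(n)

    def logp_grad(q: np.ndarray):
        if not np.all(np.isfinite(q)):
            return -np.inf, np.zeros(lay.dim)
        grad = np.zeros(lay.dim)

        # --- thresholds (ordered transform; exp clipped so far-out proposals
        # get a finite, very low density instead of overflow) ---
        a = q[lay.a_tau]
        e2, e3 = np.exp(min(a[1], 30.0)), np.exp(min(a[2], 30.0))
        tau = np.array([a[0], a[0] + e2, a[0] + e2 + e3])

        beta = q[lay.beta]
        delta0 = 0.0 if fix_discrimination else q[lay.delta0][0]

        eta = X @ beta
        log_alpha = np.full(n, delta0)
        if group:
            theta = q[lay.theta]
            lsb_p, lsd_p, u_p = np.clip(q[lay.phi_p], -30.0, 30.0)
            sdb_p, sdd_p, rho_p = np.exp(lsb_p), np.exp(lsd_p), np.tanh(u_p)
            sq_p = np.sqrt(1 - rho_p**2)
            z1p, z2p = q[lay.z1p], q[lay.z2p]
            b_p = sdb_p * z1p
            d_p = sdd_p * (rho_p * z1p + sq_p * z2p)
            lsb_s, lsd_s, u_s = np.clip(q[lay.phi_s], -30.0, 30.0)
            sdb_s, sdd_s, rho_s = np.exp(lsb_s), np.exp(lsd_s), np.tanh(u_s)
            sq_s = np.sqrt(1 - rho_s**2)
            z1s, z2s = q[lay.z1s], q[lay.z2s]
            b_s = sdb_s * z1s
            d_s = sdd_s * (rho_s * z1s + sq_s * z2s)
            eta = eta + theta[j_idx] + b_p[i_idx] + b_s[s_idx]
            log_alpha = log_alpha + d_p[i_idx] + d_s[s_idx]
        alpha = np.exp(log_alpha)

        # --- ordinal likelihood ---
        tau_ext = np.concatenate(([-np.inf], tau, [np.inf]))
        cl = alpha * (tau_ext[y] - eta)
        cu = alpha * (tau_ext[y + 1] - eta)
        sl, su = expit(cl), expit(cu)
        # P = su - sl, in a cancellation-resistant product form
        P = np.clip(su * (1.0 - sl) - sl * (1.0 - su), 1e-300, None)
        loglik = float(np.sum(np.log(P)))

        spl = sl * (1.0 - sl)
        spu = su * (1.0 - su)
        g_eta = alpha * (spl - spu) / P
        cl_spl = np.where(np.isfinite(cl), cl, 0.0) * spl
        cu_spu = np.where(np.isfinite(cu), cu, 0.0) * spu
        g_la = (cu_spu - cl_spl) / P            # d/d log(alpha)

        w_u = alpha * spu / P                   # -> tau index y (y<3)
        w_l = alpha * spl / P                   # -> tau index y-1 (y>0)
        g_tau = np.bincount(y, weights=w_u, minlength=4)[:3] \
            - np.bincount(np.maximum(y - 1, 0), weights=w_l, minlength=4)[:3]

        # --- priors ---
        logp = loglik
        logp += -0.5 * np.sum(tau**2) / priors.sd_tau**2 + a[1] + a[2]
        g_tau = g_tau - tau / priors.sd_tau**2
        grad[lay.a_tau] = [g_tau.sum(), (g_tau[1] + g_tau[2]) * e2 + 1.0,
                           g_tau[2] * e3 + 1.0]

        logp += -0.5 * np.sum(beta**2) / priors.sd_beta**2
        grad[lay.beta] = X.T @ g_eta - beta / priors.sd_beta**2

        if not fix_discrimination:
            logp += -0.5 * delta0**2 / priors.sd_delta0**2
            grad[lay.delta0] = np.sum(g_la) - delta0 / priors.sd_delta0**2

        if group:
            # participant ability, sd fixed at 1
            logp += -0.5 * np.sum(theta**2)
            grad[lay.theta] = np.bincount(j_idx, weights=g_eta, minlength=J) - theta

            for (z1, z2, b, d, sdb, sdd, rho, sq, u, idx, zsl1, zsl2, phi, size) in (
                (z1p, z2p, b_p, d_p, sdb_p, sdd_p, rho_p, sq_p, u_p,
                 i_idx, lay.z1p, lay.z2p, lay.phi_p, I),
                (z1s, z2s, b_s, d_s, sdb_s, sdd_s, rho_s, sq_s, u_s,
                 s_idx, lay.z1s, lay.z2s, lay.phi_s, S),
            ):
                g_b = np.bincount(idx, weights=g_eta, minlength=size)
                g_d = np.bincount(idx, weights=g_la, minlength=size)
                logp += -0.5 * np.sum(z1**2) - 0.5 * np.sum(z2**2)
                grad[zsl1] = g_b * sdb + g_d * sdd * rho - z1
                grad[zsl2] = g_d * sdd * sq - z2
                # half-normal(sd_group) on sds, incl. log-jacobian of exp
                logp += -0.5 * (sdb**2 + sdd**2) / priors.sd_group**2 \
                    + np.log(sdb) + np.log(sdd)
                g_lsb = np.sum(g_b * b) - sdb**2 / priors.sd_group**2 + 1.0
                g_lsd = np.sum(g_d * d) - sdd**2 / priors.sd_group**2 + 1.0
                # LKJ(eta) on the 2x2 correlation + tanh jacobian
                logp += priors.lkj_eta * np.log1p(-rho**2)
                g_u = np.sum(g_d * sdd * (z1 * (1 - rho**2) - rho * z2 * sq)) \
                    - 2.0 * priors.lkj_eta * rho
                grad[phi] = [g_lsb, g_lsd, g_u]

        return logp, grad

    return logp_grad, lay


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class GRMPosterior:
    """Posterior draws across chains plus pointwise log-likelihood."""

    draws: dict                     # name -> (chains, draws, ...) arrays
    colnames: list[str]
    participant_ids: list
    photo_ids: list
    species_ids: list
    spec: DesignSpec
    log_lik: Optional[np.ndarray]   # (chains, draws, n_obs) or None
    metadata: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws["tau"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["tau"].shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains flattened: (chains*draws, ...)."""
        arr = self.draws[name]
        return arr.reshape((-1,) + arr.shape[2:])

    def params_at(self, flat_index: int) -> GRMParameters:
        """Constrained parameter set of one flattened draw."""
        g = lambda name: self.stacked(name)[flat_index] if name in self.draws else None
        kw = {}
        for scalar in ("sd_photo_b", "sd_photo_d", "cor_photo",
                       "sd_species_b", "sd_species_d", "cor_species"):
            if scalar in self.draws:
                kw[scalar] = float(self.stacked(scalar)[flat_index])
        return GRMParameters(
            tau=g("tau"), beta=g("beta"),
            delta0=float(self.stacked("delta0")[flat_index]) if "delta0" in self.draws else 0.0,
            theta=g("theta"), photo_b=g("photo_b"), photo_d=g("photo_d"),
            species_b=g("species_b"), species_d=g("species_d"), **kw,
        )

    def to_inference_data(self):
        import arviz as az

        posterior = {}
        dims = {}
        coords = {
            "threshold": [1, 2, 3],
            "coef": self.colnames,
            "participant": list(self.participant_ids),
            "photo": list(self.photo_ids),
            "species": list(self.species_ids),
        }
        dim_map = {"tau": ["threshold"], "beta": ["coef"], "theta": ["participant"],
                   "photo_b": ["photo"], "photo_d": ["photo"],
                   "species_b": ["species"], "species_d": ["species"]}
        for name, arr in self.draws.items():
            posterior[name] = arr
            if name in dim_map:
                dims[name] = dim_map[name]
        kwargs = {}
        if self.log_lik is not None:
            kwargs["log_likelihood"] = {"y": self.log_lik}
        return az.from_dict(posterior=posterior, coords=coords, dims=dims, **kwargs)

    def summary(self) -> pd.DataFrame:
        """Posterior medians and 95% credible intervals, one row per parameter."""
        rows = []

        def add(label, samples):
            q = np.quantile(samples, [0.5, 0.025, 0.975])
            rows.append({"parameter": label, "estimate": q[0],
                         "l95": q[1], "u95": q[2]})

        tau = self.stacked("tau")
        for k in range(3):
            add(f"intercept [{k + 1}]", tau[:, k])
        if "delta0" in self.draws:
            add("discrimination", self.stacked("delta0"))
        beta = self.stacked("beta")
        for k, c in enumerate(self.colnames):
            add(c, beta[:, k])
        for name, label in (("sd_photo_b", "sd(photo difficulty)"),
                            ("sd_photo_d", "sd(photo discrimination)"),
                            ("cor_photo", "cor(photo diff x disc)"),
                            ("sd_species_b", "sd(species difficulty)"),
                            ("sd_species_d", "sd(species discrimination)"),
                            ("cor_species", "cor(species diff x disc)")):
            if name in self.draws:
                add(label, self.stacked(name))
        return pd.DataFrame(rows)

    # -- plain-text serialization ------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        flat = {}
        names = []
        for name, arr in self.draws.items():
            st = arr.reshape(arr.shape[0] * arr.shape[1], -1)
            for k in range(st.shape[1]):
                suffix = f"[{k}]" if st.shape[1] > 1 else ""
                flat[f"{name}{suffix}"] = st[:, k]
                names.append(f"{name}{suffix}")
        df = pd.DataFrame(flat)
        df.insert(0, "chain", np.repeat(np.arange(self.n_chains), self.n_draws))
        df.insert(1, "draw", np.tile(np.arange(self.n_draws), self.n_chains))
        df.to_csv(directory / "posterior.csv", index=False)
        meta = dict(self.metadata)
        meta.update({
            "colnames": self.colnames,
            "participant_ids": list(map(str, self.participant_ids)),
            "photo_ids": list(map(str, self.photo_ids)),
            "species_ids": list(map(str, self.species_ids)),
            "shapes": {k: list(v.shape) for k, v in self.draws.items()},
            "spec": {
                "name": self.spec.name,
                "include_home": self.spec.include_home,
                "include_home_interaction": self.spec.include_home_interaction,
                "include_quality": self.spec.include_quality,
                "group_effects": self.spec.group_effects,
            },
        })
        (directory / "metadata.json").write_text(json.dumps(meta, indent=1))
        if self.log_lik is not None:
            ll = self.log_lik.reshape(-1, self.log_lik.shape[-1])
            pd.DataFrame(ll).to_csv(directory / "log_lik.csv", index=False)

    @classmethod
    def load(cls, directory) -> "GRMPosterior":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        df = pd.read_csv(directory / "posterior.csv")
        chains = int(df["chain"].max()) + 1
        ndraw = int(df["draw"].max()) + 1
        draws = {}
        for name, shape in meta["shapes"].items():
            width = int(np.prod(shape[2:])) if len(shape) > 2 else 1
            cols = [f"{name}[{k}]" for k in range(width)] if width > 1 else [name]
            arr = df[cols].to_numpy().reshape(tuple(shape))
            draws[name] = arr
        log_lik = None
        llp = directory / "log_lik.csv"
        if llp.exists():
            ll = pd.read_csv(llp).to_numpy()
            log_lik = ll.reshape(chains, ndraw, -1)
        spec = DesignSpec(
            name=meta["spec"]["name"],
            include_home=meta["spec"]["include_home"],
            include_home_interaction=meta["spec"]["include_home_interaction"],
            include_quality=meta["spec"]["include_quality"],
            group_effects=meta["spec"]["group_effects"],
        )
        return cls(draws, meta["colnames"], meta["participant_ids"],
                   meta["photo_ids"], meta["species_ids"], spec, log_lik,
                   {k: meta[k] for k in ("chains", "warmup", "draws", "seed")
                    if k in meta})


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _loglik_for_draws(tau, eta, log_alpha, y):
    """Pointwise log-likelihood for a block of draws.

    tau (D,3), eta (D,n), log_alpha (D,n) -> (D,n).
    """
    alpha = np.exp(log_alpha)
    tau_ext = np.concatenate(
        [np.full((tau.shape[0], 1), -np.inf), tau, np.full((tau.shape[0], 1), np.inf)],
        axis=1,
    )
    cl = alpha * (tau_ext[:, y] - eta)
    cu = alpha * (tau_ext[:, y + 1] - eta)
    sl, su = expit(cl), expit(cu)
    P = np.clip(su * (1.0 - sl) - sl * (1.0 - su), 1e-300, None)
    return np.log(P)


def compute_pointwise_loglik(post: GRMPosterior, design: DesignMatrices,
                             include_group_effects: bool = True,
                             chunk: int = 100) -> np.ndarray:
    """(chains, draws, n_obs) pointwise log-likelihood on any design."""
    C, D = post.n_chains, post.n_draws
    S = C * D
    n = design.n_obs
    out = np.empty((S, n))
    for start in range(0, S, chunk):
        sl = slice(start, min(start + chunk, S))
        eta, la = _draw_eta_logalpha(post, design, sl, include_group_effects)
        out[sl] = _loglik_for_draws(post.stacked("tau")[sl], eta, la, design.y)
    return out.reshape(C, D, n)


def _draw_eta_logalpha(post: GRMPosterior, design: DesignMatrices,
                       draw_slice, include_group_effects: bool):
    """(eta, log_alpha) arrays of shape (d, n) for a block of flat draws."""
    beta = post.stacked("beta")[draw_slice]
    eta = beta @ design.X.T
    la = np.zeros_like(eta)
    if "delta0" in post.draws:
        la += post.stacked("delta0")[draw_slice][:, None]
    if include_group_effects and "theta" in post.draws:
        def dev(name, idx):
            arr = post.stacked(name)[draw_slice]
            padded = np.concatenate([arr, np.zeros((arr.shape[0], 1))], axis=1)
            return padded[:, np.where(idx >= 0, idx, padded.shape[1] - 1)]

        eta += dev("theta", design.participant_idx)
        eta += dev("photo_b", design.photo_idx)
        eta += dev("species_b", design.species_idx)
        la += dev("photo_d", design.photo_idx)
        la += dev("species_d", design.species_idx)
    return eta, la


def fit_grm(
    design: DesignMatrices,
    priors: Optional[Priors] = None,
    *,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    seed: int,
    max_leapfrog: int = 24,
    target_accept: float = 0.8,
    fix_discrimination: bool = False,
    compute_loglik: bool = True,
) -> GRMPosterior:
    """Sample the GRM posterior with adaptive HMC.

    Seeds are mandatory.  Divergences and acceptance statistics are recorded
    in the posterior metadata; they are reported, never silently dropped.
    """
    priors = priors or Priors()
    logp_grad, lay = make_log_posterior(design, priors, fix_discrimination)
    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(chains)

    all_draws = []
    meta_chains = []
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        q0 = 0.1 * rng.standard_normal(lay.dim)
        # start thresholds spread out so the ordered transform is well-scaled
        q0[lay.a_tau] = np.array([-1.5, 0.0, 0.0]) + 0.1 * rng.standard_normal(3)
        res = sample_chain(logp_grad, q0, warmup, draws, rng,
                           max_leapfrog=max_leapfrog, target_accept=target_accept)
        all_draws.append(res.draws)
        meta_chains.append({"accept_rate": res.accept_rate,
                            "step_size": res.step_size,
                            "n_divergent": res.n_divergent})

    raw = np.asarray(all_draws)  # (C, D, dim)
    C, D = chains, draws
    K = len(design.colnames)

    def block(sl, shape=None):
        arr = raw[:, :, sl]
        return arr if shape is None else arr.reshape((C, D) + shape)

    out: dict[str, np.ndarray] = {}
    a = raw[:, :, lay.a_tau]
    tau = np.empty((C, D, 3))
    tau[..., 0] = a[..., 0]
    tau[..., 1] = tau[..., 0] + np.exp(a[..., 1])
    tau[..., 2] = tau[..., 1] + np.exp(a[..., 2])
    out["tau"] = tau
    out["beta"] = block(lay.beta)
    if not fix_discrimination:
        out["delta0"] = raw[:, :, lay.delta0].reshape(C, D)
    if design.spec.group_effects:
        out["theta"] = block(lay.theta)
        for prefix, zsl1, zsl2, phi in (("photo", lay.z1p, lay.z2p, lay.phi_p),
                                        ("species", lay.z1s, lay.z2s, lay.phi_s)):
            z1, z2 = block(zsl1), block(zsl2)
            lsb = raw[:, :, phi][..., 0]
            lsd = raw[:, :, phi][..., 1]
            u = raw[:, :, phi][..., 2]
            sdb, sdd, rho = np.exp(lsb), np.exp(lsd), np.tanh(u)
            out[f"{prefix}_b"] = sdb[..., None] * z1
            out[f"{prefix}_d"] = sdd[..., None] * (
                rho[..., None] * z1 + np.sqrt(1 - rho[..., None] ** 2) * z2)
            out[f"sd_{prefix}_b"] = sdb
            out[f"sd_{prefix}_d"] = sdd
            out[f"cor_{prefix}"] = rho

    post = GRMPosterior(
        draws=out,
        colnames=list(design.colnames),
        participant_ids=list(design.participant_ids),
        photo_ids=list(design.photo_ids),
        species_ids=list(design.species_ids),
        spec=design.spec,
        log_lik=None,
        metadata={"chains": chains, "warmup": warmup, "draws": draws,
                  "seed": seed, "sampler": meta_chains},
    )
    if compute_loglik:
        post.log_lik = compute_pointwise_loglik(post, design)
    return post


def convergence_diagnostics(post: GRMPosterior,
                            include_unit_effects: bool = False) -> pd.DataFrame:
    """Rank-normalized split-chain Rhat and bulk/tail ESS per parameter.

    With a single chain Rhat is undefined and reported as NaN.  By default
    per-unit group deviations are summarized through their sds/correlations
    only; pass ``include_unit_effects=True`` for every unit-level parameter.
    """
    import arviz as az

    rows = []
    single = post.n_chains < 2

    def add(label, arr):
        # arr: (chains, draws)
        ds = az.convert_to_dataset(np.asarray(arr))
        if single:
            rhat = np.nan
        else:
            rhat = float(np.asarray(az.rhat(ds)["x"]))
        ess_b = float(np.asarray(az.ess(ds, method="bulk")["x"]))
        ess_t = float(np.asarray(az.ess(ds, method="tail")["x"]))
        rows.append({"parameter": label, "rhat": rhat,
                     "ess_bulk": ess_b, "ess_tail": ess_t})

    for k in range(3):
        add(f"intercept [{k + 1}]", post.draws["tau"][..., k])
    if "delta0" in post.draws:
        add("discrimination", post.draws["delta0"])
    for k, c in enumerate(post.colnames):
        add(c, post.draws["beta"][..., k])
    for name in ("sd_photo_b", "sd_photo_d", "cor_photo",
                 "sd_species_b", "sd_species_d", "cor_species"):
        if name in post.draws:
            add(name, post.draws[name])
    if include_unit_effects:
        for name in ("theta", "photo_b", "photo_d", "species_b", "species_d"):
            if name in post.draws:
                arr = post.draws[name]
                for k in range(arr.shape[-1]):
                    add(f"{name}[{k}]", arr[..., k])
    return pd.DataFrame(rows)
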
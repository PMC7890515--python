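"""Train/test splitting, PSIS-LOO model comparison, Bayesian R² and MAE.

The candidate set is a grid of six fixed-effect structures, all containing
photo region, snake family and the taxa-repeat learning covariate; the
candidates add photo quality and/or the home-region effect, plus one variant
with a home-region x photo-region interaction (with and without quality).
Models are compared by approximate leave-one-out cross-validation
(Pareto-smoothed importance sampling); predictive accuracy on held-out
responses is summarized with Bayesian R² and mean absolute error in score
units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .grm import (DesignMatrices, DesignSpec, GRMPosterior, _draw_eta_logalpha,
                  category_probs)


def model_grid(families=None, regions=None) -> list[DesignSpec]:
    """The six candidate fixed-effect structures."""
    kw = {}
    if families is not None:
        kw["families"] = tuple(families)
    if regions is not None:
        kw["regions"] = tuple(regions)
    specs = [
        DesignSpec(name="base", include_home=False,
                   include_home_interaction=False, include_quality=False, **kw),
        DesignSpec(name="quality", include_home=False,
                   include_home_interaction=False, include_quality=True, **kw),
        DesignSpec(name="home", include_home=True,
                   include_home_interaction=False, include_quality=False, **kw),
        DesignSpec(name="home_quality", include_home=True,
                   include_home_interaction=False, include_quality=True, **kw),
        DesignSpec(name="home_x_region", include_home=True,
                   include_home_interaction=True, include_quality=False, **kw),
        DesignSpec(name="home_x_region_quality", include_home=True,
                   include_home_interaction=True, include_quality=True, **kw),
    ]
    assert len(specs) == 6
    return specs


def split_train_test(
    responses: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
    min_responses: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random split stratified by participant.

    Each participant contributes ``round(train_fraction * n)`` responses to
    the training set (within one response of the target share); the split is
    an exact disjoint partition and deterministic under ``seed``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    counts = responses.groupby("participant_id").size()
    too_few = counts[counts < min_responses]
    if len(too_few):
        raise ValueError(
            f"participants with fewer than {min_responses} responses: "
            f"{sorted(too_few.index.tolist())}")
    rng = np.random.default_rng(seed)
    train_mask = np.zeros(len(responses), dtype=bool)
    positions = {pid: np.flatnonzero(responses["participant_id"].to_numpy() == pid)
                 for pid in counts.index}
    for pid in counts.index:
        pos = positions[pid]
        n_train = int(round(train_fraction * pos.size))
        n_train = min(max(n_train, 1), pos.size - 1)  # both sides non-empty
        chosen = rng.choice(pos, size=n_train, replace=False)
        train_mask[chosen] = True
    return responses.iloc[train_mask.nonzero()[0]], responses.iloc[(~train_mask).nonzero()[0]]


@dataclass
class LooResult:
    """PSIS-LOO estimate for one fitted model."""

    elpd_loo: float
    se: float
    p_loo: float
    pareto_k: np.ndarray
    n_obs: int
    name: str = ""

    @property
    def looic(self) -> float:
        return -2.0 * self.elpd_loo

    @property
    def n_bad_k(self) -> int:
        """Observations whose Pareto shape exceeds the 0.7 reliability bound."""
        return int(np.sum(self.pareto_k > 0.7))


def psis_loo(log_lik: np.ndarray, name: str = "") -> LooResult:
    """Pareto-smoothed importance-sampling LOO from pointwise log-likelihoods.

    ``log_lik`` has shape (chains, draws, n_obs) or (draws, n_obs).  Follows
    the standard published PSIS recipe (tail fraction min(0.2 S, 3 sqrt(S)),
    k > 0.7 flagged); degenerate observations yield a diagnostic k, not a
    crash.
    """
    import arviz as az

    ll = np.asarray(log_lik, dtype=float)
    if ll.ndim == 2:
        ll = ll[None, ...]
    if not np.all(np.isfinite(ll)):
        raise ValueError("log-likelihood draws must be finite")
    # a posterior group is required for the relative-efficiency correction
    idata = az.from_dict(posterior={"lp": ll.mean(axis=-1)},
                         log_likelihood={"y": ll})
    with np.errstate(over="ignore", invalid="ignore"):
        res = az.loo(idata, pointwise=True)
    return LooResult(
        elpd_loo=float(res.elpd_loo),
        se=float(res.se),
        p_loo=float(res.p_loo),
        pareto_k=np.asarray(res.pareto_k),
        n_obs=ll.shape[-1],
        name=name,
    )


def compare_models(loos: Sequence[LooResult]) -> pd.DataFrame:
    """Ranked comparison table, ascending LOOIC; best model has delta 0."""
    if len({r.n_obs for r in loos}) != 1:
        raise ValueError("models were fitted to different observation sets")
    rows = [{"model": r.name, "elpd_loo": r.elpd_loo, "se": r.se,
             "p_loo": r.p_loo, "looic": r.looic, "n_bad_k": r.n_bad_k}
            for r in loos]
    out = pd.DataFrame(rows).sort_values("looic", kind="mergesort").reset_index(drop=True)
    out["d_looic"] = out["looic"] - out["looic"].iloc[0]
    return out


# ---------------------------------------------------------------------------
# predictive summaries
# ---------------------------------------------------------------------------

def _predictive_moments(post: GRMPosterior, design: DesignMatrices,
                        include_group_effects: bool, chunk: int = 200):
    """Per-draw expected score and residual variance, chunked over draws.

    Yields (mu, var) blocks of shape (d, n): the conditional mean of the
    numeric score and its conditional variance under each draw.
    """
    S = post.n_chains * post.n_draws
    k = np.arange(4.0)
    tau_all = post.stacked("tau")
    for start in range(0, S, chunk):
        sl = slice(start, min(start + chunk, S))
        eta, la = _draw_eta_logalpha(post, design, sl, include_group_effects)
        tau = tau_all[sl]
        alpha = np.exp(la)
        # cumulative probabilities per draw/obs
        from scipy.special import expit
        cum = expit(alpha[..., None] * (tau[:, None, :] - eta[..., None]))
        p = np.empty(cum.shape[:-1] + (4,))
        p[..., 0] = cum[..., 0]
        p[..., 1] = cum[..., 1] - cum[..., 0]
        p[..., 2] = cum[..., 2] - cum[..., 1]
        p[..., 3] = 1 - cum[..., 2]
        mu = p @ k
        var = p @ (k**2) - mu**2
        yield mu, var


def bayes_r2(post: GRMPosterior, design: DesignMatrices,
             include_group_effects: bool = True) -> np.ndarray:
    """Draw-wise Bayesian R² distribution.

    Per draw: var(expected score over observations) divided by itself plus
    the mean conditional score variance.  Values lie in [0, 1].
    """
    parts = []
    for mu, var in _predictive_moments(post, design, include_group_effects):
        var_fit = mu.var(axis=1)
        var_res = var.mean(axis=1)
        total = var_fit + var_res
        if np.any(total == 0):
            raise ZeroDivisionError("zero total predictive variance")
        parts.append(var_fit / total)
    return np.concatenate(parts)


def heldout_mae(post: GRMPosterior, test_design: DesignMatrices,
                include_group_effects: bool = True) -> float:
    """Mean absolute error of the posterior-mean expected score (score units).

    With group effects, deviations of participants/photos/species unseen in
    training are set to 0 (new-cluster convention); without, all group
    deviations are zeroed.
    """
    if test_design.n_obs == 0:
        raise ValueError("empty test set")
    S = post.n_chains * post.n_draws
    mean_mu = np.zeros(test_design.n_obs)
    for mu, _ in _predictive_moments(post, test_design, include_group_effects):
        mean_mu += mu.sum(axis=0)
    mean_mu /= S
    return float(np.mean(np.abs(test_design.y - mean_mu)))
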
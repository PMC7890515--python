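"""GRM likelihood, design coding, gradients, sampling and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import snakeid as sk
from snakeid import reference as ref
from snakeid.grm import (DesignSpec, GRMParameters, Priors, build_design,
                         category_probs, convergence_diagnostics, fit_grm,
                         log_likelihood, make_log_posterior)


# ---------------------------------------------------------------------------
# category probabilities
# ---------------------------------------------------------------------------

class TestCategoryProbs:
    @given(st.floats(-8, 8), st.floats(-2, 2),
           st.floats(-3, 0), st.floats(0.05, 2), st.floats(0.05, 2))
    @settings(deadline=None, max_examples=200)
    def test_simplex_and_monotone(self, eta, log_alpha, t1, gap1, gap2):
        tau = np.array([t1, t1 + gap1, t1 + gap1 + gap2])
        p = category_probs(eta, np.exp(log_alpha), tau)
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p >= 0).all()
        # survival probabilities decrease across nested levels
        surv = 1.0 - np.cumsum(p)[:3]
        assert surv[0] >= surv[1] >= surv[2] - 1e-15

    def test_eta_monotonicity_and_alpha_sharpening(self):
        tau = np.array([-1.0, 0.0, 1.0])
        etas = np.linspace(-4, 4, 41)
        p3 = category_probs(etas, 1.0, tau)[:, 3]
        assert (np.diff(p3) > 0).all()
        # slope at eta = tau_k scales with alpha
        eps = 1e-4
        for alpha in (0.5, 1.0, 3.0):
            lo, hi = category_probs(np.array([1.0 - eps, 1.0 + eps]), alpha, tau)[:, 3]
            slope = (hi - lo) / (2 * eps)
            assert abs(slope - alpha / 4) < 1e-3  # logistic'(0) = 1/4

    def test_limits(self):
        tau = np.array([-1.0, 0.0, 1.0])
        assert category_probs(60.0, 1.0, tau)[3] > 1 - 1e-12
        # huge discrimination with eta between tau2 and tau3 -> all mass on 2
        p = category_probs(0.5, 1e6, tau)
        assert p[2] > 1 - 1e-9

    def test_unordered_tau_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            category_probs(0.0, 1.0, np.array([0.0, -1.0, 1.0]))
        with pytest.raises(ValueError, match="positive"):
            category_probs(0.0, -1.0, np.array([-1.0, 0.0, 1.0]))

    def test_reference_first_photo_prediction(self):
        """Reference medians give ~16% species-level accuracy for the first
        photo of a North American colubrid seen by an outsider."""
        eta = ref.FAMILY_EFFECTS["Colubridae"] + ref.REGION_EFFECTS["NorthAmerica"]
        p = category_probs(eta, np.exp(ref.DISCRIMINATION), ref.THRESHOLDS)
        assert abs(p[3] - 0.17) <= 0.02


# ---------------------------------------------------------------------------
# design coding
# ---------------------------------------------------------------------------

def _toy_responses(n=60, seed=0):
    rng = np.random.default_rng(seed)
    fams = np.array(["Boidae", "Colubridae", "Viperidae"])
    regs = np.array(["Africa", "Asia", "NorthAmerica"])
    return pd.DataFrame({
        "participant_id": rng.integers(0, 6, n).astype(str),
        "photo_id": rng.integers(0, 12, n).astype(str),
        "true_species": rng.integers(0, 4, n).astype(str),
        "family": fams[rng.integers(0, 3, n)],
        "photo_region": regs[rng.integers(0, 3, n)],
        "home_region": regs[rng.integers(0, 3, n)],
        "taxa_repeat": rng.integers(0, 5, n),
        "quality": rng.choice(["high", "low"], n),
        "score": rng.integers(0, 4, n),
    })


class TestBuildDesign:
    def test_reference_cell_is_all_zero(self):
        df = pd.DataFrame([{
            "participant_id": "p", "photo_id": "i", "true_species": "s",
            "family": "Boidae", "photo_region": "Africa",
            "home_region": "Asia", "taxa_repeat": 0, "score": 0,
        }])
        d = build_design(df, DesignSpec(name="full"))
        assert (d.X == 0).all()

    def test_full_model_reproduces_published_column_layout(self):
        d = build_design(_toy_responses(), DesignSpec(name="full"))
        expected = [
            "Colubridae", "Cylindrophiidae", "Elapidae", "Lamprophiidae",
            "Leptotyphlopidae", "Pythonidae", "Typhlopidae", "Viperidae",
            "Asia", "Australasia", "Europe", "NorthAmerica", "SouthAmerica",
            "home_region = T", "taxa_repeat",
            "Asia: home_region = T", "Australasia: home_region = T",
            "Europe: home_region = T", "NorthAmerica: home_region = T",
            "SouthAmerica: home_region = T",
        ]
        assert d.colnames == expected
        assert len(d.colnames) == 20

    def test_grid_column_counts_match_term_enumeration(self):
        """Each candidate's column count equals its enumerated term list:
        8 family + 5 region + 1 repeat, plus optional home (1), quality (1)
        and region-by-home interaction (5)."""
        df = _toy_responses()
        for spec in sk.model_grid():
            expected = 8 + 5 + 1
            expected += spec.include_home
            expected += spec.include_quality
            expected += 5 * spec.include_home_interaction
            d = build_design(df, spec)
            assert len(d.colnames) == expected

    def test_unseen_level_is_listed_in_error(self):
        df = _toy_responses()
        df.loc[0, "family"] = "Acrochordidae"
        with pytest.raises(ValueError, match="Acrochordidae"):
            build_design(df, DesignSpec(name="full"))

    def test_interaction_without_main_effect_rejected(self):
        with pytest.raises(ValueError, match="main effect"):
            DesignSpec(name="bad", include_home=False, include_home_interaction=True)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _naive_loglik(params, design):
    """Independent brute-force evaluator: per observation, build the four
    category masses from plain logistic calls and pick the observed one."""
    out = np.empty(design.n_obs)
    for i in range(design.n_obs):
        eta = float(design.X[i] @ params.beta)
        la = params.delta0
        if params.theta is not None:
            eta += params.theta[design.participant_idx[i]]
            eta += params.photo_b[design.photo_idx[i]]
            eta += params.species_b[design.species_idx[i]]
            la += params.photo_d[design.photo_idx[i]]
            la += params.species_d[design.species_idx[i]]
        alpha = np.exp(la)
        cum = [1.0 / (1.0 + np.exp(-alpha * (t - eta))) for t in params.tau]
        masses = [cum[0], cum[1] - cum[0], cum[2] - cum[1], 1.0 - cum[2]]
        out[i] = np.log(masses[design.y[i]])
    return out


class TestLogLikelihood:
    def _params(self, design, seed=0):
        rng = np.random.default_rng(seed)
        return GRMParameters(
            tau=np.array([-1.5, -0.3, 0.8]),
            beta=0.5 * rng.standard_normal(len(design.colnames)),
            delta0=0.2,
            theta=rng.standard_normal(len(design.participant_ids)),
            photo_b=0.5 * rng.standard_normal(len(design.photo_ids)),
            photo_d=0.2 * rng.standard_normal(len(design.photo_ids)),
            species_b=0.5 * rng.standard_normal(len(design.species_ids)),
            species_d=0.2 * rng.standard_normal(len(design.species_ids)),
        )

    def test_matches_naive_evaluator(self):
        design = build_design(_toy_responses(n=40, seed=2), DesignSpec(name="full"))
        params = self._params(design)
        got = log_likelihood(params, design)
        expected = _naive_loglik(params, design)
        idx = np.random.default_rng(0).choice(design.n_obs, 5, replace=False)
        np.testing.assert_allclose(got[idx], expected[idx], atol=1e-10)

    def test_location_invariance(self):
        design = build_design(_toy_responses(n=40, seed=3), DesignSpec(name="full"))
        params = self._params(design, seed=1)
        base = log_likelihood(params, design)
        c = 0.73
        shifted = GRMParameters(
            tau=params.tau + c, beta=params.beta, delta0=params.delta0,
            theta=params.theta + c, photo_b=params.photo_b,
            photo_d=params.photo_d, species_b=params.species_b,
            species_d=params.species_d)
        np.testing.assert_allclose(log_likelihood(shifted, design), base, atol=1e-9)

    def test_non_finite_parameter_rejected(self):
        design = build_design(_toy_responses(n=10), DesignSpec(name="full"))
        params = self._params(design)
        params.beta = params.beta.copy()
        params.beta[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            log_likelihood(params, design)


def test_log_posterior_gradient_matches_finite_differences():
    design = build_design(_toy_responses(n=80, seed=5),
                          DesignSpec(name="full", include_quality=True))
    logp_grad, lay = make_log_posterior(design, Priors())
    rng = np.random.default_rng(8)
    q = 0.3 * rng.standard_normal(lay.dim)
    _, grad = logp_grad(q)
    eps = 1e-6
    for i in rng.choice(lay.dim, 30, replace=False):
        qp, qm = q.copy(), q.copy()
        qp[i] += eps
        qm[i] -= eps
        fd = (logp_grad(qp)[0] - logp_grad(qm)[0]) / (2 * eps)
        assert abs(fd - grad[i]) < 1e-5 * max(1.0, abs(fd))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

class TestFitGrm:
    def test_posterior_matches_ordinal_mle_in_reduced_model(self):
        """With alpha fixed at 1 and no group effects the GRM is a standard
        proportional-odds model; the posterior centre must agree with a
        directly fitted ordinal MLE."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        cfg = sk.SimConfig(
            n_participants=40, n_species=10, photos_per_species=4,
            photos_per_participant=40, family_allocation={"Colubridae": 10},
            sd_participant=0.0, sd_photo_b=0.0, sd_photo_d=0.0,
            sd_species_b=0.0, sd_species_d=0.0, delta0=0.0, seed=12)
        responses, _ = sk.simulate_challenge(cfg)
        regions = tuple(["Africa"] + sorted(
            (set(responses["photo_region"]) | set(responses["home_region"]))
            - {"Africa"}))
        spec = DesignSpec(name="po", families=("Colubridae",), regions=regions,
                          include_home=True, include_home_interaction=False,
                          group_effects=False)
        design = build_design(responses, spec)
        post = fit_grm(design, chains=2, warmup=250, draws=250, seed=5,
                       fix_discrimination=True, compute_loglik=False,
                       max_leapfrog=16)
        mle = OrderedModel(responses["score"], design.X, distr="logit").fit(
            method="bfgs", disp=0)
        k = design.X.shape[1]
        post_beta = post.stacked("beta").mean(axis=0)
        np.testing.assert_allclose(post_beta, mle.params[:k], atol=0.15)
        cuts = np.concatenate([[mle.params[k]],
                               mle.params[k] + np.cumsum(np.exp(mle.params[k + 1:]))])
        np.testing.assert_allclose(post.stacked("tau").mean(axis=0), cuts, atol=0.15)

    def test_recovery_fit_converges_and_keeps_ability_scale(self, recovery_fits):
        _, _, post = recovery_fits[0]
        diag = convergence_diagnostics(post)
        assert (diag["rhat"] < 1.1).all()
        assert (diag["ess_bulk"] > 25).all()
        # the participant-ability scale is fixed, not estimated
        assert "sd_participant" not in post.draws
        ll = post.log_lik
        assert ll is not None and np.isfinite(ll).all()

    def test_divergences_are_reported(self, recovery_fits):
        _, _, post = recovery_fits[0]
        for chain in post.metadata["sampler"]:
            assert "n_divergent" in chain and "accept_rate" in chain


class TestConvergenceDiagnostics:
    def _posterior(self, draws_dict):
        from snakeid.grm import GRMPosterior
        return GRMPosterior(draws=draws_dict, colnames=[], participant_ids=[],
                            photo_ids=[], species_ids=[],
                            spec=DesignSpec(name="x"), log_lik=None)

    def test_identical_chains_have_rhat_near_one(self):
        rng = np.random.default_rng(0)
        one = rng.standard_normal(400)
        arr = np.stack([one, one])[..., None] * np.ones(3)
        post = self._posterior({"tau": np.sort(arr, axis=-1),
                                "beta": arr[..., :1]})
        post.colnames = ["b0"]
        diag = convergence_diagnostics(post)
        assert np.allclose(diag["rhat"], 1.0, atol=0.01)

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(1)
        c1 = rng.standard_normal(400)
        c2 = rng.standard_normal(400) + 5.0
        arr = np.stack([c1, c2])[..., None] * np.ones(3)
        post = self._posterior({"tau": np.sort(arr, axis=-1) +
                                np.array([0.0, 1.0, 2.0]),
                                "beta": arr[..., :1]})
        post.colnames = ["b0"]
        diag = convergence_diagnostics(post)
        assert (diag["rhat"] > 1.1).all()

    def test_iid_draws_have_ess_near_draw_count(self):
        rng = np.random.default_rng(2)
        arr = rng.standard_normal((4, 500))[..., None] * np.ones(3)
        post = self._posterior({"tau": np.sort(arr, axis=-1),
                                "beta": arr[..., :1]})
        post.colnames = ["b0"]
        diag = convergence_diagnostics(post)
        assert (diag["ess_bulk"] > 1200).all()  # 2000 draws, sampling error

    def test_single_chain_rhat_undefined(self):
        rng = np.random.default_rng(3)
        arr = rng.standard_normal((1, 200))[..., None] * np.ones(3)
        post = self._posterior({"tau": np.sort(arr, axis=-1),
                                "beta": arr[..., :1]})
        post.colnames = ["b0"]
        diag = convergence_diagnostics(post)
        assert diag["rhat"].isna().all()


def test_posterior_save_load_round_trip(tmp_path, small_challenge):
    _, _, responses, _ = small_challenge
    spec = [s for s in sk.model_grid() if s.name == "base"][0]
    design = build_design(responses, spec)
    post = fit_grm(design, chains=1, warmup=80, draws=60, seed=2,
                   max_leapfrog=8)
    post.save(tmp_path / "post")
    loaded = sk.GRMPosterior.load(tmp_path / "post")
    for name, arr in post.draws.items():
        np.testing.assert_allclose(loaded.draws[name], arr, rtol=0, atol=1e-12)
    np.testing.assert_allclose(loaded.log_lik, post.log_lik, atol=1e-12)
    assert loaded.spec.name == "base"
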
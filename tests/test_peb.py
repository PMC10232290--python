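"""Tests for the parametric empirical Bayes second level."""

import numpy as np
import pytest

from pedcm.inversion import GaussianBelief
from pedcm.microcircuit import MicrocircuitParameters
from pedcm.peb import (
    GROUP_ORDER,
    ParameterGroupMap,
    build_design_matrix,
    default_group_map,
    fit_peb,
    restrict_model,
)

PARAMS = [
    "gamma:AMPA:ss->sp", "gamma:AMPA:ss->si",
    "gamma:NMDA:ss->sp", "gamma:NMDA:ss->si",
    "gamma:GABA:si->sp", "gamma:GABA:si->ss",
]
GM = ParameterGroupMap({
    "gamma:AMPA:ss->sp": "sup_AMPA", "gamma:AMPA:ss->si": "sup_AMPA",
    "gamma:NMDA:ss->sp": "sup_NMDA", "gamma:NMDA:ss->si": "sup_NMDA",
    "gamma:GABA:si->sp": "sup_GABA", "gamma:GABA:si->ss": "sup_GABA",
})


def make_cohort(rng, n=12, beta=0.3, group="sup_AMPA", obs_sd=0.02, re_sd=0.05):
    """Linear-level synthetic cohort of first-level posteriors."""
    c = rng.uniform(-1, 1, n)
    c = (c - c.mean()) / c.std()
    posteriors = []
    for i in range(n):
        mu = np.array([
            beta * c[i] if GM.group_of(p) == group else 0.0 for p in PARAMS
        ]) + rng.normal(0, re_sd, len(PARAMS))
        obs = mu + rng.normal(0, obs_sd, len(PARAMS))
        posteriors.append(GaussianBelief(PARAMS, obs, np.eye(len(PARAMS)) * obs_sd**2))
    return c, posteriors


class TestDesignMatrix:
    def test_centering_example(self):
        X = build_design_matrix(np.array([2.0, 4.0, 6.0]), "density")
        np.testing.assert_allclose(X.X[:, 1], [-2.0, 0.0, 2.0])
        np.testing.assert_array_equal(X.X[:, 0], 1.0)

    def test_single_covariate_shape(self):
        X = build_design_matrix(np.arange(7.0), "density")
        assert X.X.shape == (7, 2)
        assert X.names == ["mean", "density"]

    def test_two_covariate_column_order(self):
        C = np.column_stack([np.arange(5.0), np.arange(5.0)[::-1] ** 2])
        X = build_design_matrix(C, ["c1", "c2"])
        assert X.names == ["mean", "c1", "c2"]

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            build_design_matrix(np.ones(5), "density")

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            build_design_matrix(np.array([1.0, 2.0]), "density")


class TestFitPeb:
    def test_identical_posteriors_give_zero_covariate_effect(self, rng):
        shared = rng.normal(0, 0.3, len(PARAMS))
        posteriors = [
            GaussianBelief(PARAMS, shared.copy(), np.eye(len(PARAMS)) * 0.01)
            for _ in range(10)
        ]
        X = build_design_matrix(rng.normal(size=10), "density")
        res = fit_peb(posteriors, X, GM)
        for nm, v in zip(res.beta.names, res.beta.mean):
            reg, _, par = nm.partition(":")
            if reg == "density":
                assert abs(v) < 1e-6
            else:
                j = PARAMS.index(par)
                assert v == pytest.approx(shared[j], abs=0.05)

    def test_recovers_known_effect(self):
        rng = np.random.default_rng(7)
        c, posteriors = make_cohort(rng, beta=0.3, group="sup_AMPA")
        X = build_design_matrix(c, "density")
        res = fit_peb(posteriors, X, GM)
        for p in GM.members("sup_AMPA"):
            j = res.beta.names.index(f"density:{p}")
            assert res.beta.mean[j] == pytest.approx(0.3, abs=0.1)

    def test_infinite_variance_subject_has_no_influence(self, rng):
        c, posteriors = make_cohort(rng)
        X = build_design_matrix(c, "density")
        big = 1e12
        loose = GaussianBelief(PARAMS, posteriors[0].mean + 5.0, np.eye(len(PARAMS)) * big)
        loose2 = GaussianBelief(PARAMS, posteriors[0].mean - 7.0, np.eye(len(PARAMS)) * big)
        res1 = fit_peb([loose] + posteriors[1:], X, GM)
        res2 = fit_peb([loose2] + posteriors[1:], X, GM)
        assert np.max(np.abs(res1.beta.mean - res2.beta.mean)) < 1e-6

    def test_precision_weighting_leave_one_out(self, rng):
        # perturbing a tight subject moves beta more than perturbing a loose one
        c, posteriors = make_cohort(rng)
        X = build_design_matrix(c, "density")
        base = fit_peb(posteriors, X, GM).beta.mean

        def shift(i, var):
            alt = list(posteriors)
            alt[i] = GaussianBelief(PARAMS, posteriors[i].mean + 0.5, np.eye(len(PARAMS)) * var)
            return np.max(np.abs(fit_peb(alt, X, GM).beta.mean - base))

        assert shift(0, 0.02**2) > shift(0, 10.0)

    def test_centering_invariance(self):
        rng = np.random.default_rng(11)
        c, posteriors = make_cohort(rng)
        res1 = fit_peb(posteriors, build_design_matrix(c, "density"), GM)
        res2 = fit_peb(posteriors, build_design_matrix(c + 100.0, "density"), GM)
        cov_idx = [i for i, nm in enumerate(res1.beta.names) if nm.startswith("density:")]
        assert np.max(np.abs(res1.beta.mean[cov_idx] - res2.beta.mean[cov_idx])) < 1e-8
        assert res1.free_energy == pytest.approx(res2.free_energy, abs=1e-6)

    def test_rank_deficient_design_rejected(self, rng):
        c = rng.normal(size=8)
        C = np.column_stack([c, 2 * c])
        with pytest.raises(ValueError, match="rank"):
            build_design_matrix(C, ["c1", "c2"])

    def test_mismatched_parameter_indices_rejected(self, rng):
        c, posteriors = make_cohort(rng)
        bad = GaussianBelief([p.upper() for p in PARAMS], posteriors[1].mean,
                             posteriors[1].cov)
        with pytest.raises(ValueError, match="index"):
            fit_peb([posteriors[0], bad] + posteriors[2:],
                    build_design_matrix(c, "density"), GM)

    def test_sign_recovery_over_seeded_cohorts(self):
        # over 20 seeded cohorts the fitted sign matches the generating sign
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            c, posteriors = make_cohort(rng, beta=0.3, obs_sd=0.05, re_sd=0.1)
            res = fit_peb(posteriors, build_design_matrix(c, "density"), GM)
            vals = [res.beta.mean[res.beta.names.index(f"density:{p}")]
                    for p in GM.members("sup_AMPA")]
            hits += all(v > 0 for v in vals)
        assert hits >= 19


class TestGroupMap:
    def test_default_map_partitions_all_gains(self):
        p = MicrocircuitParameters()
        gm = default_group_map(p)
        assert len(gm.assignment) == 22
        counts = {g: len(gm.members(g)) for g in GROUP_ORDER}
        assert counts == {"sup_AMPA": 4, "sup_NMDA": 4, "sup_GABA": 3,
                          "deep_AMPA": 4, "deep_NMDA": 4, "deep_GABA": 3}

    def test_granular_counts_as_superficial(self):
        p = MicrocircuitParameters()
        gm = default_group_map(p)
        assert gm.group_of("gamma:AMPA:sp->ss") == "sup_AMPA"
        assert gm.group_of("gamma:AMPA:sp->dp") == "deep_AMPA"


class TestRestrictModel:
    @pytest.fixture()
    def full_prior(self, rng):
        c, posteriors = make_cohort(rng)
        res = fit_peb(posteriors, build_design_matrix(c, "density"), GM)
        return res.beta_prior

    def test_full_mask_is_identity(self, full_prior):
        rp = restrict_model(full_prior, (True,) * 6, GM)
        np.testing.assert_array_equal(rp.cov, full_prior.cov)

    def test_single_group_mask_pins_other_groups(self, full_prior):
        mask = tuple(g == "sup_AMPA" for g in GROUP_ORDER)
        rp = restrict_model(full_prior, mask, GM)
        for i, nm in enumerate(rp.names):
            reg, _, par = nm.partition(":")
            if reg == "mean":
                assert rp.cov[i, i] == full_prior.cov[i, i]
            elif GM.group_of(par) == "sup_AMPA":
                assert rp.cov[i, i] == full_prior.cov[i, i]
            else:
                assert rp.cov[i, i] == 0.0

    def test_only_covariate_blocks_change(self, full_prior):
        mask = tuple(g in ("sup_NMDA",) for g in GROUP_ORDER)
        rp = restrict_model(full_prior, mask, GM)
        diff = np.argwhere(rp.cov != full_prior.cov)
        for i, j in diff:
            assert not (rp.names[i].startswith("mean:") and rp.names[j].startswith("mean:"))

    def test_empty_mask_rejected(self, full_prior):
        with pytest.raises(ValueError, match="all-excluded"):
            restrict_model(full_prior, (False,) * 6, GM)
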
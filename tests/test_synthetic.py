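"""Synthetic-experiment generator: clones, noise and the reference panel."""

import numpy as np
import pytest

import chokinet as ck


class TestMakeClone:
    def test_parental_returns_base_kinetics_unchanged(self, base_params):
        out = ck.make_clone(ck.CLONES["parental"], base_params)
        assert out.vmax == base_params.vmax
        assert out.affinity == base_params.affinity
        assert out.regulatory == base_params.regulatory
        assert out.clone == "parental"

    def test_multiplicative_override(self, base_params):
        spec = ck.CloneSpec("x", {"vmax.PDH": 1.75}, leaky_mab_fraction=0.1)
        out = ck.make_clone(spec, base_params)
        assert out.vmax["PDH"] == pytest.approx(
            1.75 * base_params.vmax["PDH"])
        changed = {k for k in out.vmax if out.vmax[k] != base_params.vmax[k]}
        assert changed == {"PDH"}

    def test_reapplication_guarded_by_provenance(self, base_params):
        """Overrides are multiplicative, so deriving a clone from an
        already derived set would compound them; the provenance tag
        forbids it."""
        low = ck.make_clone(ck.COMPARISON_CLONES["low"], base_params)
        with pytest.raises(ValueError, match="clone"):
            ck.make_clone(ck.COMPARISON_CLONES["low"], low)

    def test_unknown_override_rejected(self, base_params):
        with pytest.raises(KeyError):
            ck.make_clone(ck.CloneSpec("x", {"vmax.NOPE": 2.0}), base_params)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ck.CloneSpec("x", {"vmax.PDH": 0.0})
        with pytest.raises(ValueError):
            ck.CloneSpec("x", leaky_mab_fraction=1.5)


class TestNoiseModel:
    def test_zero_cv_reproduces_truth(self, parental_truth):
        obs, traj = parental_truth
        t = np.array([0.0, 24.0, 48.0])
        for m in ("GLC", "Xv"):
            sub = obs.records[obs.records["variable"] == m]
            for rep in (1, 2):
                vals = sub[sub["replicate"] == rep].sort_values("time_h")
                got = np.interp(t, vals["time_h"], vals["value"])
                assert np.allclose(got, traj.value(m, t), rtol=1e-12)

    def test_same_seed_is_reproducible(self, net):
        nm = ck.NoiseModel(cv=0.05, seed=123)
        a, _ = ck.generate_experiment(ck.CLONES["parental"], noise=nm,
                                      net=net)
        b, _ = ck.generate_experiment(ck.CLONES["parental"], noise=nm,
                                      net=net)
        assert a.records.equals(b.records)

    def test_empirical_cv_matches_nominal(self):
        """Pooled empirical CV of the noise generator stays within
        [0.03, 0.07] for a nominal 5% CV (Monte Carlo over 10 seeds)."""
        truth = np.array([30.0, 25.0, 18.0, 12.0, 8.0, 6.0, 5.0])
        nm = ck.NoiseModel(cv=0.05, replicates=2)
        draws = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            draws.append(nm.sample(truth, rng))
            draws.append(nm.sample(truth, rng))
        draws = np.array(draws)
        cv = np.std(draws / truth, ddof=1)
        assert 0.03 < cv < 0.07

    def test_log_domain_unbiased(self):
        """Noise is centred in the log domain to Monte-Carlo precision."""
        nm = ck.NoiseModel(cv=0.05)
        rng = np.random.default_rng(0)
        samples = nm.sample(np.full(20000, 10.0), rng)
        assert np.mean(np.log(samples / 10.0)) == pytest.approx(
            0.0, abs=3 * 0.05 / np.sqrt(20000))

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError):
            ck.NoiseModel(cv=-0.1)
        with pytest.raises(ValueError):
            ck.NoiseModel(replicates=0)


class TestGenerateExperiment:
    def test_observation_design(self, parental_noisy):
        obs, _ = parental_noisy
        assert set(obs.variables) == set(ck.MEASURED_VARIABLES)
        sub = obs.records[obs.records["variable"] == "GLC"]
        assert sorted(sub["replicate"].unique()) == [1, 2]
        assert len(sub) == 2 * 7          # duplicate flasks, 7 sample times

    def test_ground_truth_recoverable(self, parental_truth):
        obs, traj = parental_truth
        assert ck.wssres(obs, traj) == pytest.approx(0.0, abs=1e-12)


@pytest.fixture(scope="module")
def panel(net, base_params):
    return ck.reference_panel(seed=5, net=net, base=base_params)


class TestReferencePanel:

    def test_five_cultures(self, panel):
        assert set(panel) == {"parental", "low_induced", "low_control",
                              "high_induced", "high_control"}

    def test_parental_has_no_induction_and_no_mab(self, panel):
        obs, traj = panel["parental"]
        assert traj.schedule.induced is False
        assert traj.states["mAb"].max() == 0.0

    def test_leaky_expression_in_non_induced_producers(self, panel):
        """Non-induced producer cultures still accumulate antibody through
        the leaky expression of the inducible system, more so in the
        high producer."""
        _, high_ctrl = panel["high_control"]
        _, low_ctrl = panel["low_control"]
        assert high_ctrl.states["mAb"].iloc[-1] > 0
        assert low_ctrl.states["mAb"].iloc[-1] > 0
        assert high_ctrl.states["mAb"].iloc[-1] > \
            low_ctrl.states["mAb"].iloc[-1]

    def test_induction_pairs_share_kinetics(self, panel):
        """Within a clone the +/- induction cultures coincide up to the
        induction event."""
        _, ind = panel["high_induced"]
        _, ctrl = panel["high_control"]
        pre = [t for t in ind.times if t <= 48.0]
        for m in ("Xv", "GLC", "GLN"):
            assert np.allclose(ind.value(m, pre), ctrl.value(m, pre),
                               rtol=1e-4)


class TestFixturePhenomenology:
    """Qualitative checks on the noise-free ground truth."""

    def test_glutamine_depletes_before_120h(self, parental_truth):
        _, traj = parental_truth
        t_dep = traj.times[np.argmax(traj.states["GLN"].to_numpy() < 0.1)]
        assert 48.0 < t_dep < 120.0

    def test_glucose_never_limiting(self, parental_truth, high_truth):
        for _, traj in (parental_truth, high_truth):
            assert traj.states["GLC"].min() > 5.0

    def test_growth_stops_at_glutamine_depletion(self, parental_truth):
        _, traj = parental_truth
        t = traj.times
        gln = traj.states["GLN"].to_numpy()
        mu = traj.derived["mu"].to_numpy()
        t_dep = t[np.argmax(gln < 0.1)]
        mu_exp = np.interp(24.0, t, mu)
        assert np.interp(t_dep + 12.0, t, mu) < 0.15 * mu_exp

    def test_high_producer_consumes_lactate_after_depletion(self,
                                                            high_truth):
        _, traj = high_truth
        t = traj.times
        gln = traj.states["GLN"].to_numpy()
        t_dep = t[np.argmax(gln < 0.1)]
        ldh_post = traj.net_fluxes["LDH"].to_numpy()[t >= t_dep + 10.0]
        assert ldh_post.min() < 0.0

    def test_alanine_produced_then_consumed(self, parental_truth):
        _, traj = parental_truth
        ala = traj.states["ALA"]
        assert ala.loc[72.0] > ala.iloc[0]          # produced early
        assert ala.iloc[-1] < ala.max()             # consumed after peak

    def test_extracellular_glutamate_increases(self, parental_truth):
        _, traj = parental_truth
        glu = traj.states["GLU_x"].to_numpy()
        assert glu[-1] > glu[0]

    def test_nucleotide_ratio_homeostasis_in_exponential_phase(
            self, parental_truth):
        _, traj = parental_truth
        for t in (24.0, 48.0, 72.0):
            assert 5.0 < traj.value("ATP_ADP_ratio", [t])[0] < 15.0
            assert 0.03 < traj.value("NADH_NAD_ratio", [t])[0] < 0.07
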
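"""Monte-Carlo envelopes, additivity verdicts and CA-vs-GRA comparison."""
import numpy as np
import pytest

from gramix import (Envelope, LigandParams, MixtureDesign, MixtureSpec, Normal,
                    PlateDesign, Uniform, additivity_test, compare_models,
                    log_grid, mc_envelope, predict_curve_ca, predict_curve_gra,
                    simulate_curve, uniform_pct)

SPEC = MixtureSpec(
    (("A", LigandParams(1.0, 1e-9, 1.0)), ("B", LigandParams(1.8, 3e-10, 1.5))),
    (0.5, 0.5))
GRID = log_grid(6e-10, 2, 12)
DESIGN = MixtureDesign(spec=SPEC, kind="fixed_ratio", grid=GRID)


def exact_uncertainty(spec):
    return [{"a": Normal(p.a, 0.0), "c": Normal(p.c, 0.0), "n": Normal(p.n, 0.0)}
            for p in spec.params]


class TestMcEnvelope:
    def test_degenerate_distributions_collapse_to_prediction(self, scale):
        env = mc_envelope(DESIGN, scale, exact_uncertainty(SPEC),
                          model="GRA", n_sims=1000, seed=0)
        pred = predict_curve_gra(DESIGN, scale).mean_responses
        np.testing.assert_allclose(env.lower, pred, rtol=1e-12)
        np.testing.assert_allclose(env.median, pred, rtol=1e-12)
        np.testing.assert_allclose(env.upper, pred, rtol=1e-12)

    def test_same_seed_reproduces_envelope_bitwise(self, scale):
        unc = uniform_pct(SPEC.params, 0.10)
        e1 = mc_envelope(DESIGN, scale, unc, model="GRA", n_sims=2000, seed=99)
        e2 = mc_envelope(DESIGN, scale, unc, model="GRA", n_sims=2000, seed=99)
        np.testing.assert_array_equal(e1.lower, e2.lower)
        np.testing.assert_array_equal(e1.upper, e2.upper)

    def test_band_width_grows_with_potency_uncertainty(self, scale):
        widths = []
        for rel_sd in (0.02, 0.10, 0.25):
            unc = [{"a": Normal(p.a, 0.0), "c": Normal(p.c, rel_sd * p.c),
                    "n": Normal(p.n, 0.0)} for p in SPEC.params]
            env = mc_envelope(DESIGN, scale, unc, model="GRA",
                              n_sims=4000, seed=5)
            widths.append(np.trapezoid(env.upper - env.lower, np.log10(env.grid)))
        assert widths[0] < widths[1] < widths[2]

    def test_inconsistent_uncertainty_rejected(self, scale):
        bad = [{"a": Normal(p.a, 0.0), "c": Normal(-1.0, 0.01), "n": Normal(p.n, 0.0)}
               for p in SPEC.params]
        with pytest.raises(ValueError, match="inconsistent"):
            mc_envelope(DESIGN, scale, bad, model="GRA", n_sims=1000, seed=0)

    def test_minimum_draw_count_enforced(self, scale):
        with pytest.raises(ValueError, match="n_sims"):
            mc_envelope(DESIGN, scale, exact_uncertainty(SPEC), n_sims=100, seed=0)

    def test_ca_envelope_matches_gra_when_only_potency_varies(self, scale):
        # draws keep a = n = 1, where CA and GRA coincide curve-by-curve,
        # so the two envelopes must agree to interpolation accuracy
        spec = MixtureSpec(
            (("A", LigandParams(1.0, 1e-9, 1.0)), ("B", LigandParams(1.0, 4e-9, 1.0))),
            (0.5, 0.5))
        design = MixtureDesign(spec=spec, kind="fixed_ratio", grid=log_grid(2e-9, 2, 10))
        unc = [{"a": Normal(p.a, 0.0), "c": Uniform(0.9 * p.c, 1.1 * p.c),
                "n": Normal(p.n, 0.0)} for p in spec.params]
        ca = mc_envelope(design, scale, unc, model="CA", n_sims=4000, seed=1)
        gra = mc_envelope(design, scale, unc, model="GRA", n_sims=4000, seed=1)
        for band in ("lower", "median", "upper"):
            np.testing.assert_allclose(getattr(ca, band), getattr(gra, band),
                                       atol=0.05)


@pytest.fixture(scope="module")
def envelope():
    from gramix import ReferenceScale
    scale = ReferenceScale()
    return mc_envelope(DESIGN, scale, uniform_pct(SPEC.params, 0.10),
                       model="GRA", n_sims=4000, seed=3), scale


class TestAdditivityVerdict:

    def test_median_curve_is_additive_everywhere(self, envelope):
        env, scale = envelope
        obs = simulate_curve(SPEC, PlateDesign(), scale, noise_fraction=0.0,
                             seed=0, concentrations=GRID)
        verdict = additivity_test(obs, env)
        assert verdict.overall == "additive"
        assert verdict.counts["above"] == 0 and verdict.counts["below"] == 0

    def test_same_model_noise_rarely_rejected(self, envelope):
        # nominal coverage: curves from the generating model with 7% noise
        # should be called additive in at least 90% of trials
        env, scale = envelope
        additive = 0
        for seed in range(100):
            obs = simulate_curve(SPEC, PlateDesign(), scale, seed=seed,
                                 concentrations=GRID)
            if additivity_test(obs, env).overall == "additive":
                additive += 1
        assert additive >= 90

    def test_genuine_left_shift_detected_as_synergy(self, envelope):
        # true mixture twice as potent as modelled: EC50 halved
        env, scale = envelope
        shifted = MixtureSpec(
            tuple((cid, LigandParams(p.a, p.c / 2.0, p.n))
                  for cid, p in SPEC.components),
            SPEC.fractions)
        hits = 0
        for seed in range(20):
            obs = simulate_curve(shifted, PlateDesign(), scale, seed=seed,
                                 concentrations=GRID)
            if additivity_test(obs, env).overall == "synergy_candidate":
                hits += 1
        assert hits > 10

    def test_baseline_padding_does_not_change_verdict(self, envelope):
        env, scale = envelope
        obs = simulate_curve(SPEC, PlateDesign(), scale, seed=4,
                             concentrations=GRID)
        verdict = additivity_test(obs, env)
        # pad the envelope and the observation with deep-baseline doses
        pad = np.array([GRID[0] / 1e4, GRID[0] / 1e3])
        env_pad = Envelope(
            grid=np.concatenate([pad, env.grid]),
            lower=np.concatenate([[scale.y0, scale.y0], env.lower]),
            median=np.concatenate([[scale.y0, scale.y0], env.median]),
            upper=np.concatenate([[scale.y0 + 0.5, scale.y0 + 0.5], env.upper]),
            n_sims=env.n_sims, seed=env.seed, model=env.model)
        obs_pad = simulate_curve(SPEC, PlateDesign(), scale, seed=4,
                                 concentrations=np.concatenate([pad, GRID]))
        verdict_pad = additivity_test(obs_pad, env_pad)
        assert verdict_pad.overall == verdict.overall

    def test_disjoint_ranges_rejected(self, envelope, scale):
        env, _ = envelope
        obs = simulate_curve(SPEC, PlateDesign(), scale, seed=0,
                             concentrations=GRID * 1e6)
        with pytest.raises(ValueError, match="overlap"):
            additivity_test(obs, env)


class TestCompareModels:
    def test_exact_gra_observation_gives_gra_zero_rmse(self, scale):
        gra_pred = predict_curve_gra(DESIGN, scale)
        ca_pred = predict_curve_ca(DESIGN, scale)
        cmp_ = compare_models(gra_pred, ca_pred, gra_pred)
        assert cmp_.winner == "GRA"
        assert cmp_.rmse_gra == pytest.approx(0.0, abs=1e-12)

    def test_parallel_world_is_a_tie(self, scale):
        # all a = n = 1: CA and GRA predictions coincide, so against any
        # observation their RMSEs agree to solver precision
        spec = MixtureSpec(
            (("A", LigandParams(1.0, 1e-9, 1.0)), ("B", LigandParams(1.0, 4e-9, 1.0))),
            (0.5, 0.5))
        design = MixtureDesign(spec=spec, kind="fixed_ratio", grid=log_grid(2e-9, 2, 10))
        gra_pred = predict_curve_gra(design, scale)
        ca_pred = predict_curve_ca(design, scale)
        obs = simulate_curve(spec, PlateDesign(), scale, seed=9,
                             concentrations=design.grid)
        cmp_ = compare_models(obs, ca_pred, gra_pred)
        assert cmp_.winner == "tie"

    def test_gra_outperforms_ca_for_supra_agonist_mixtures(self, scale):
        # non-parallel curves (supra-agonist at a=1.9): GRA should win most runs
        spec = MixtureSpec(
            (("A", LigandParams(1.0, 1e-9, 1.0)), ("B", LigandParams(1.9, 3e-10, 1.5))),
            (0.5, 0.5))
        design = MixtureDesign(spec=spec, kind="fixed_ratio", grid=log_grid(6e-10, 2, 12))
        gra_pred = predict_curve_gra(design, scale)
        ca_pred = predict_curve_ca(design, scale)
        wins = 0
        for seed in range(20):
            obs = simulate_curve(spec, PlateDesign(), scale, seed=seed,
                                 concentrations=design.grid)
            if compare_models(obs, ca_pred, gra_pred).winner == "GRA":
                wins += 1
        assert wins > 10
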
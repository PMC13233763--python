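import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glytrace.core_io import SchemaError
from glytrace.sirm import (
    Mid,
    TracerModel,
    build_correction_matrix,
    convolve_mids,
    correct_natural_abundance,
    fit_tracer_model,
    forward_convolve_na,
    predict_mids,
)


def random_mid(n_carbons: int, k: int, seed: int) -> Mid:
    rng = np.random.default_rng(seed)
    f = rng.dirichlet(np.ones(k + 1))
    return Mid("x", n_carbons, f)


class TestCorrectionMatrix:
    def test_no_natural_abundance_is_identity(self):
        C = build_correction_matrix(1, 0.0).matrix
        np.testing.assert_allclose(C, np.eye(2))

    def test_two_carbon_entries_match_binomial(self):
        C = build_correction_matrix(2, 0.0107).matrix
        assert C[0, 0] == pytest.approx((1 - 0.0107) ** 2)
        assert C[1, 0] == pytest.approx(2 * 0.0107 * (1 - 0.0107))
        assert C[2, 0] == pytest.approx(0.0107**2)
        assert C[1, 1] == pytest.approx(1 - 0.0107)
        assert C[2, 2] == 1.0

    @given(n=st.integers(1, 20), p13=st.floats(0.0, 0.5))
    @settings(deadline=None, max_examples=30)
    def test_columns_are_probability_masses(self, n, p13):
        C = build_correction_matrix(n, p13).matrix
        assert np.all(C >= 0)
        np.testing.assert_allclose(C.sum(axis=0), 1.0, atol=1e-12)
        assert np.allclose(C, np.tril(C))
        for j in range(n + 1):
            assert C[j, j] == pytest.approx((1 - p13) ** (n - j))


class TestForwardConvolve:
    def test_unlabeled_no_na_is_delta(self):
        out = forward_convolve_na(Mid("x", 2, [1.0, 0.0, 0.0]), p13=0.0)
        np.testing.assert_allclose(out, [1, 0, 0])

    def test_fully_labeled_single_carbon(self):
        for p13 in (0.0, 0.0107, 0.3):
            out = forward_convolve_na(Mid("x", 1, [0.0, 1.0]), p13=p13)
            np.testing.assert_allclose(out, [0, 1])

    def test_output_sums_to_one(self):
        mid = random_mid(5, 3, seed=1)
        assert forward_convolve_na(mid).sum() == pytest.approx(1.0)


class TestCorrectNaturalAbundance:
    def test_p13_zero_is_plain_normalization(self):
        raw = np.array([30.0, 50.0, 20.0])
        mid = correct_natural_abundance(raw, 3, p13=0.0)
        np.testing.assert_allclose(mid.fractions, raw / raw.sum())

    def test_recovers_unlabeled_pool(self):
        raw = forward_convolve_na(Mid("x", 2, [1.0, 0.0, 0.0])) * 5e5
        mid = correct_natural_abundance(raw, 2)
        np.testing.assert_allclose(mid.fractions, [1, 0, 0], atol=1e-6)

    def test_recovers_glycine_mixture(self):
        raw = forward_convolve_na(Mid("glycine", 2, [0.45, 0.55])) * 1e6
        mid = correct_natural_abundance(raw, 2)
        np.testing.assert_allclose(mid.fractions[:2], [0.45, 0.55], atol=1e-6)
        assert mid.fractions[2:].sum() == pytest.approx(0.0, abs=1e-6)

    @given(
        n=st.integers(1, 20),
        seed=st.integers(0, 10_000),
        scale=st.floats(1e2, 1e8),
    )
    @settings(deadline=None, max_examples=50)
    def test_roundtrip_property(self, n, seed, scale):
        """correct(forward_convolve(mid)) == mid for noise-free input."""
        k = min(n, 1 + seed % 3)
        mid = random_mid(n, k, seed)
        raw = forward_convolve_na(mid) * scale
        rec = correct_natural_abundance(raw, n)
        np.testing.assert_allclose(rec.fractions[: k + 1], mid.fractions, atol=1e-6)

    def test_truncated_observation_many_carbons(self):
        """A 15-carbon metabolite measured only to M+2 with label reach 1."""
        mid = Mid("SAM", 15, [0.8, 0.2])
        full = forward_convolve_na(mid)
        rec = correct_natural_abundance(full[:3] * 1e6, 15, max_label=1)
        np.testing.assert_allclose(rec.fractions, [0.8, 0.2], atol=1e-6)

    def test_rejects_bad_input(self):
        with pytest.raises(SchemaError, match="all-zero"):
            correct_natural_abundance(np.zeros(3), 2)
        with pytest.raises(SchemaError, match="negative"):
            correct_natural_abundance(np.array([1.0, -2.0]), 2)


class TestConvolveMids:
    def test_fully_labeled_condensation(self):
        ala = Mid("ALA", 5, [0.0, 1.0])
        pbg = convolve_mids(ala, ala)
        np.testing.assert_allclose(pbg.fractions, [0, 0, 1])
        assert pbg.n_carbons == 10

    def test_half_labeled_enumeration(self):
        x = Mid("x", 1, [0.5, 0.5])
        out = convolve_mids(x, x)
        np.testing.assert_allclose(out.fractions, [0.25, 0.5, 0.25])

    def test_delta_identity(self):
        x = random_mid(3, 2, seed=2)
        out = convolve_mids(x, Mid("d", 1, [1.0]))
        np.testing.assert_allclose(out.fractions[:3], x.fractions)

    @given(seed=st.integers(0, 1000))
    @settings(deadline=None, max_examples=20)
    def test_pbg_m1_closed_form(self, seed):
        """PBG M+1 = 2 p (1 - p) where p is the ALA M+1 fraction."""
        p = np.random.default_rng(seed).uniform(0, 1)
        ala = Mid("ALA", 5, [1 - p, p])
        pbg = convolve_mids(ala, ala)
        assert pbg.fractions[1] == pytest.approx(2 * p * (1 - p), abs=1e-12)


def _mc_serine_mid(g, f, s, n_mol=1_000_000, seed=0):
    """Monte-Carlo atom-fate oracle: simulate serine molecules one
    precursor at a time (glycine backbone + one-carbon unit)."""
    rng = np.random.default_rng(seed)
    new = rng.random(n_mol) < s
    backbone = rng.random(n_mol) < g
    one_c = rng.random(n_mol) < f
    labels = np.where(new, backbone.astype(int) + one_c.astype(int), 0)
    return np.bincount(labels, minlength=3) / n_mol


class TestPredictMids:
    def test_pure_shmt_backbone_labeling(self):
        mids = predict_mids(TracerModel(g=1, f=0, s=1))
        np.testing.assert_allclose(mids["serine"].fractions, [0, 1, 0], atol=1e-12)

    def test_backbone_plus_hot_one_carbon(self):
        mids = predict_mids(TracerModel(g=1, f=1, s=1))
        np.testing.assert_allclose(mids["serine"].fractions, [0, 0, 1], atol=1e-12)

    def test_heme_stoichiometry_anchor(self):
        mids = predict_mids(TracerModel(g=1, a=1))
        np.testing.assert_allclose(mids["ALA"].fractions, [0, 1])
        np.testing.assert_allclose(mids["PBG"].fractions, [0, 0, 1])

    def test_sah_always_unlabeled(self):
        mids = predict_mids(TracerModel(g=1, f=1, s=1, m=1, q=1, a=1))
        np.testing.assert_allclose(mids["SAH"].fractions, [1, 0])

    def test_serine_m1_against_monte_carlo(self):
        """Seeded million-molecule simulation of the SHMT condensation."""
        g, f, s = 0.55, 0.0, 0.73
        mc = _mc_serine_mid(g, f, s, seed=42)
        pred = predict_mids(TracerModel(g=g, f=f, s=s))["serine"].fractions
        assert pred[1] == pytest.approx(0.4015, abs=1e-9)
        np.testing.assert_allclose(pred, mc, atol=2e-3)

    @given(theta=st.lists(st.floats(0, 1), min_size=6, max_size=6))
    @settings(deadline=None, max_examples=50)
    def test_all_predictions_are_probability_vectors(self, theta):
        mids = predict_mids(TracerModel.from_array(np.array(theta)))
        for mid in mids.values():
            assert np.all(mid.fractions >= -1e-12)
            assert mid.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    @given(seed=st.integers(0, 500))
    @settings(deadline=None, max_examples=20)
    def test_serine_m2_monotone_in_f_and_g(self, seed):
        rng = np.random.default_rng(seed)
        g, f, s = rng.uniform(0, 0.95, 3)
        base = predict_mids(TracerModel(g=g, f=f, s=s))["serine"].fractions[2]
        up_f = predict_mids(TracerModel(g=g, f=f + 0.05, s=s))["serine"].fractions[2]
        up_g = predict_mids(TracerModel(g=g + 0.05, f=f, s=s))["serine"].fractions[2]
        assert up_f >= base - 1e-12
        assert up_g >= base - 1e-12


class TestFitTracerModel:
    def test_noise_free_self_consistency(self):
        truth = TracerModel(g=0.55, f=0.0, s=0.73, m=0.0, q=0.0, a=0.3)
        rep = fit_tracer_model(predict_mids(truth), seed=1)
        assert rep.theta.g == pytest.approx(0.55, abs=1e-4)
        assert rep.theta.s == pytest.approx(0.73, abs=1e-4)
        assert rep.theta.a == pytest.approx(0.30, abs=1e-4)
        for p in ("f", "m", "q"):
            assert not rep.identified[p]
            assert getattr(rep.theta, p) == 0.0

    def test_full_uptake_direct_readout(self):
        obs = {
            "glycine": Mid("glycine", 2, [0.0, 1.0]),
            "serine": Mid("serine", 3, [0.4, 0.3, 0.3]),
        }
        rep = fit_tracer_model(obs, seed=0)
        assert rep.theta.g == 1.0

    def test_requires_glycine_and_serine(self):
        with pytest.raises(SchemaError, match="glycine and serine"):
            fit_tracer_model({"glycine": Mid("glycine", 2, [0.5, 0.5])})

    def test_invariant_to_metabolite_order_and_scaling(self):
        truth = TracerModel(g=0.9, f=0.6, s=0.5, m=0.3, q=0.8, a=0.4)
        mids = predict_mids(truth)
        rep1 = fit_tracer_model(dict(sorted(mids.items())), seed=3)
        rep2 = fit_tracer_model(dict(sorted(mids.items(), reverse=True)), seed=3)
        np.testing.assert_allclose(rep1.theta.as_array(), rep2.theta.as_array(), atol=1e-9)

    def test_noisy_recovery_short(self):
        """Multinomial ion-count noise: identified parameters within 0.05."""
        from glytrace.pipeline import correct_isotopologue_table, pooled_mids
        from glytrace.synthdata import GroundTruth, gen_sirm_experiment

        truth = TracerModel(g=0.95, f=0.8, s=0.6, m=0.25, q=0.9, a=0.5)
        errs = []
        for seed in range(5):
            gt = GroundTruth(seed=seed, cell_models=("X",), conditions=("TR",),
                             n_replicates=5, ion_counts=10_000, tracer_params={"TR": truth})
            corr = correct_isotopologue_table(gen_sirm_experiment(gt))
            rep = fit_tracer_model(pooled_mids(corr, sorted(corr["sample_id"].unique())), seed=seed)
            errs.append(np.abs(rep.theta.as_array() - truth.as_array()))
        assert np.median(np.array(errs), axis=0).max() < 0.05
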
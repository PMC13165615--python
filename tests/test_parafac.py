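"""Non-negative PARAFAC: recovery, diagnostics, model-order selection."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from eemkit.parafac import (
    EEMTensor,
    component_scores_vs_level,
    core_consistency,
    explained_variance,
    fit_parafac,
    select_components,
)


def rank1_tensor(shape=(6, 7, 8), seed=0):
    rng = np.random.default_rng(seed)
    a, b, c = (rng.random(s) + 0.1 for s in shape)
    return np.einsum("i,j,k->ijk", a, b, c), (a, b, c)


def cosine(u, v):
    return float(np.abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)))


class TestFitParafac:
    def test_rank1_exact_recovery(self):
        X, (a, b, c) = rank1_tensor()
        m = fit_parafac(X, 1)
        assert explained_variance(m, X) == pytest.approx(100.0, abs=1e-6)
        assert cosine(m.scores[:, 0], a) >= 0.9999
        assert cosine(m.emission_loadings[:, 0], b) >= 0.9999
        assert cosine(m.excitation_loadings[:, 0], c) >= 0.9999

    def test_two_fluorophore_loading_recovery(self, noiseless_rank2_study, grid):
        """F=2 on the noiseless bovine-only stack recovers the tryptophan
        and riboflavin emission/excitation profiles (cosine >= 0.99)."""
        t = EEMTensor.from_dataset(noiseless_rank2_study)
        m = fit_parafac(t, 2)  # components sorted by emission peak
        em = grid.emission_nm
        ex = grid.excitation_nm
        tr_em = np.exp(-((em - 350.0) ** 2) / (2 * 25.0**2))
        tr_ex = np.exp(-((ex - 290.0) ** 2) / (2 * 15.0**2))
        rb_em = np.exp(-((em - 525.0) ** 2) / (2 * 30.0**2))
        rb_ex = np.exp(-((ex - 380.0) ** 2) / (2 * 22.0**2)) + np.exp(
            -((ex - 460.0) ** 2) / (2 * 22.0**2)
        )
        assert cosine(m.emission_loadings[:, 0], tr_em) >= 0.99
        assert cosine(m.excitation_loadings[:, 0], tr_ex) >= 0.99
        assert cosine(m.emission_loadings[:, 1], rb_em) >= 0.99
        assert cosine(m.excitation_loadings[:, 1], rb_ex) >= 0.99

    def test_factors_non_negative(self, noiseless_rank2_study):
        t = EEMTensor.from_dataset(noiseless_rank2_study)
        m = fit_parafac(t, 2)
        for mat in m.factors:
            assert mat.min() >= 0

    def test_residual_monotone_decreasing(self, noiseless_rank2_study):
        t = EEMTensor.from_dataset(noiseless_rank2_study)
        m = fit_parafac(t, 2)
        h = np.array(m.residual_history)
        assert np.all(np.diff(h) <= 1e-9)

    def test_f_larger_than_dimension_rejected(self):
        X, _ = rank1_tensor(shape=(3, 7, 8))
        with pytest.raises(ValueError, match="exceeds"):
            fit_parafac(X, 4)

    def test_zero_tensor_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_parafac(np.zeros((3, 4, 5)), 1)

    def test_als_matches_multirestart_oracle(self):
        """Sanity, not an optimality proof: on tiny random tensors a
        moderately restarted fit reaches the residual a 200-restart
        brute-force random-init search finds (within a small slack)."""
        rng = np.random.default_rng(42)
        for trial in range(3):
            X = rng.random((3, 3, 3))
            norm = float(np.sum(X * X))
            base = fit_parafac(X, 2, max_iter=500, seed=trial, n_restarts=50)
            best = min(
                fit_parafac(X, 2, max_iter=200, seed=1000 + r, init="random").fit_residual_ss
                for r in range(200)
            )
            assert base.fit_residual_ss <= best + 1e-4 * norm


class TestExplainedVariance:
    def test_perfect_reconstruction_is_100(self):
        X, _ = rank1_tensor()
        m = fit_parafac(X, 1)
        assert explained_variance(m, X) == pytest.approx(100.0, abs=1e-6)

    def test_zero_model_is_0(self):
        X, _ = rank1_tensor()
        m = fit_parafac(X, 1)
        m.scores[:] = 0.0
        assert explained_variance(m, X) == pytest.approx(0.0)

    def test_zero_tensor_rejected(self):
        X, _ = rank1_tensor()
        m = fit_parafac(X, 1)
        with pytest.raises(ValueError, match="zero"):
            explained_variance(m, np.zeros_like(X))

    def test_rank1_fit_of_rank2_tensor_matches_bruteforce(self):
        """EV at F=1 on a rank-2 tensor equals the best rank-1 share found
        by a restarted brute-force ALS oracle."""
        rng = np.random.default_rng(7)
        X = (
            np.einsum("i,j,k->ijk", rng.random(4) + 0.2, rng.random(5) + 0.2, rng.random(6) + 0.2)
            + np.einsum("i,j,k->ijk", rng.random(4) + 0.2, rng.random(5) + 0.2, rng.random(6) + 0.2)
        )
        m = fit_parafac(X, 1)
        ev = explained_variance(m, X)
        assert ev < 100.0
        best_res = min(
            fit_parafac(X, 1, max_iter=300, seed=r, init="random").fit_residual_ss
            for r in range(50)
        )
        ev_oracle = 100.0 * (1.0 - best_res / float(np.sum(X * X)))
        assert ev == pytest.approx(ev_oracle, abs=1e-3)

    def test_monotone_in_F(self, noiseless_rank2_study):
        t = EEMTensor.from_dataset(noiseless_rank2_study)
        evs = [explained_variance(fit_parafac(t, F), t) for F in (1, 2, 3)]
        assert evs[1] >= evs[0] - 1e-6
        assert evs[2] >= evs[1] - 1e-6


class TestCoreConsistency:
    def test_one_component_is_exactly_100(self, default_study, scatter_mask):
        """At any single-component ALS stationary point the 1x1x1 LS core
        equals 1, so the diagnostic is exactly 100."""
        t = EEMTensor.from_dataset(default_study, scatter_mask)
        m = fit_parafac(t, 1)
        cc = core_consistency(m, t)
        assert cc == pytest.approx(100.0, abs=1e-6)
        # analytic check: g = <X, a x b x c> / (|a|^2 |b|^2 |c|^2) = 1
        a, b, c = m.scores[:, 0], m.emission_loadings[:, 0], m.excitation_loadings[:, 0]
        g = np.einsum("ijk,i,j,k->", t.values, a, b, c) / (
            (a @ a) * (b @ b) * (c @ c)
        )
        assert g == pytest.approx(1.0, abs=1e-9)

    def test_rank2_model_on_rank2ish_data_high(self, zero_coconut_specs):
        """F=2 on the two-fluorophore study with realistic noise keeps the
        diagnostic near 100 (valid trilinear model)."""
        from eemkit.synthetic import NoiseSpec, StudyDesign, generate_study

        noise = NoiseSpec(scatter_amplitude_1st=0.0, scatter_amplitude_2nd=0.0)
        ds = generate_study(StudyDesign(seed=31), coconut_specs=zero_coconut_specs,
                            noise=noise)
        t = EEMTensor.from_dataset(ds)
        m = fit_parafac(t, 2)
        assert core_consistency(m, t) >= 99.0

    def test_core_matches_normal_equations_oracle(self):
        """The pinv-based LS core equals the explicit normal-equations
        solution of min ||X - G x (A,B,C)||."""
        rng = np.random.default_rng(3)
        X = rng.random((5, 6, 7))
        m = fit_parafac(X, 2, max_iter=200)
        A, B, C = m.factors
        K = np.einsum("ia,jb,kc->ijkabc", A, B, C).reshape(5 * 6 * 7, 8)
        g, *_ = np.linalg.lstsq(K, X.ravel(), rcond=None)
        T = np.zeros(8)
        T[0] = T[-1] = 1.0  # superdiagonal of a 2x2x2 core
        cc_oracle = 100.0 * (1.0 - float(np.sum((g - T) ** 2)) / 2.0)
        assert core_consistency(m, X) == pytest.approx(cc_oracle, abs=1e-6)

    def test_degenerate_factors_raise(self, noiseless_rank2_study):
        t = EEMTensor.from_dataset(noiseless_rank2_study)
        m = fit_parafac(t, 2)
        m.scores[:, 1] = m.scores[:, 0]  # exactly collinear
        with pytest.raises(ValueError, match="degenerate"):
            core_consistency(m, t)


class TestSelectComponents:
    def test_rank2_study_selects_two(self, zero_coconut_specs):
        from eemkit.synthetic import EEMDataset, StudyDesign, generate_study
        from eemkit.preprocess import build_scatter_mask, preprocess_sample

        ds = generate_study(StudyDesign(seed=17), coconut_specs=zero_coconut_specs)
        mask = build_scatter_mask(ds.grid)
        clean = EEMDataset([preprocess_sample(s, mask) for s in ds])
        t = EEMTensor.from_dataset(clean, mask)
        diag = select_components(t, range(1, 4))
        assert diag.selected_F == 2
        assert diag.explained_variance_pct[1] > diag.explained_variance_pct[0]

    def test_rank1_tensor_selects_one(self):
        X, _ = rank1_tensor(shape=(6, 7, 8))
        diag = select_components(X, range(1, 3))
        assert diag.selected_F == 1

    def test_unreachable_threshold_falls_back_with_warning(self):
        X, _ = rank1_tensor()
        with pytest.warns(UserWarning, match="falling back"):
            diag = select_components(X, range(1, 3), corcondia_threshold=101.0)
        assert diag.selected_F == 1


class TestScoresVsLevel:
    def test_noiseless_scores_strictly_decrease(self, noiseless_rank2_study):
        t = EEMTensor.from_dataset(noiseless_rank2_study)
        m = fit_parafac(t, 2)
        tab = component_scores_vs_level(m, t.labels)
        for col in ("component_1", "component_2"):
            assert np.all(np.diff(tab[col].to_numpy()) < 0)

    def test_tryptophan_score_spearman(self, clean_default_study, scatter_mask):
        """Per-sample tryptophan-like scores anti-correlate with the
        adulteration level (rho <= -0.95) on the default study."""
        t = EEMTensor.from_dataset(clean_default_study, scatter_mask)
        m = fit_parafac(t, 2)  # component 1 = lower emission peak = tryptophan
        rho = spearmanr(t.labels, m.scores[:, 0]).statistic
        assert rho <= -0.95

    def test_single_level_one_row(self):
        X, _ = rank1_tensor(shape=(4, 5, 6))
        m = fit_parafac(X, 1)
        tab = component_scores_vs_level(m, np.zeros(4))
        assert len(tab) == 1

    def test_label_mismatch_rejected(self):
        X, _ = rank1_tensor(shape=(4, 5, 6))
        m = fit_parafac(X, 1)
        with pytest.raises(ValueError, match="align"):
            component_scores_vs_level(m, np.zeros(5))
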
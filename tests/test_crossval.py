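"""Cross-validation, CV-ANOVA and |w*| selection: oracles, calibration and
recovery behaviour."""
import dataclasses

import numpy as np
import pytest
import scipy.stats

import chemopls as cp
from chemopls.preprocess import fit_scaling


def loo_press_oracle(X, labels, n_pred, n_ortho, mode="unit_variance"):
    """Independently coded leave-one-out PRESS: per left-out sample, refit
    scaling and model on the rest and predict the dummy response."""
    classes, Y = cp.encode_classes(labels)
    n = X.shape[0]
    press = 0.0
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        params = fit_scaling(X[tr], mode=mode)
        model = cp.fit_oplsda(params.apply(X[tr]),
                              [l for l, k in zip(labels, tr) if k],
                              n_pred=n_pred, n_ortho=n_ortho)
        _, _, yhat, _ = cp.predict(model, params.apply(X[[i]]))
        press += float(((Y[i] - yhat[0]) ** 2).sum())
    return press


class TestFolds:
    def test_partition_every_sample_once(self):
        labels = ["a"] * 11 + ["b"] * 7
        folds = cp.assign_folds(labels, 5, seed=3)
        assert folds.shape == (18,)
        assert set(folds) <= set(range(5))
        # stratified: class counts per fold differ by at most one
        for cls in ("a", "b"):
            counts = np.bincount(folds[[l == cls for l in labels]], minlength=5)
            assert counts.max() - counts.min() <= 1

    def test_deterministic_given_seed(self):
        labels = ["a"] * 10 + ["b"] * 10
        f1 = cp.assign_folds(labels, 7, seed=5)
        f2 = cp.assign_folds(labels, 7, seed=5)
        np.testing.assert_array_equal(f1, f2)
        assert not np.array_equal(f1, cp.assign_folds(labels, 7, seed=6))

    def test_fold_emptying_class_raises(self):
        X = np.random.default_rng(0).standard_normal((8, 4))
        labels = ["a"] * 6 + ["b"] * 2
        with pytest.raises(cp.FoldError):
            cp.cross_validate(X, labels, n_folds=4, seed=0)


class TestCrossValidate:
    def test_loo_matches_independent_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((12, 6)) + 5
        labels = ["a"] * 6 + ["b"] * 6
        cv = cp.cross_validate(X, labels, n_pred=1, n_ortho=1, n_folds=12, seed=0)
        press = loo_press_oracle(X, labels, 1, 1)
        assert abs(cv.press - press) <= 1e-10 * max(press, 1.0)

    def test_each_sample_out_of_fold_once(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((21, 5))
        labels = ["a"] * 10 + ["b"] * 11
        cv = cp.cross_validate(X, labels, n_folds=7, seed=1)
        assert len(cv.folds) == 21
        assert cv.q2 <= 1.0

    def test_strong_separation_gives_high_q2(self, strong_effect_config):
        """delta = 2 on a 50-metabolite panel, 18/class: cross-validated Q2
        comfortably exceeds 0.5 (log intensities, the generator's own scale)."""
        cfg = dataclasses.replace(strong_effect_config, n_metabolites=50, seed=4)
        _, pel, _ = cp.generate(cfg)
        prep = cp.preprocess_stratum(pel)
        cv = cp.cross_validate(prep.matrix(),
                               list(prep.sample_meta["class_label"]),
                               n_pred=1, n_ortho=0, n_folds=7, seed=4,
                               log_transform=True)
        assert cv.q2 > 0.5

    def test_label_permutation_degrades_q2(self, strong_effect_config):
        cfg = dataclasses.replace(strong_effect_config, n_metabolites=100, seed=5)
        _, pel, _ = cp.generate(cfg)
        prep = cp.preprocess_stratum(pel)
        X = prep.matrix()
        labels = list(prep.sample_meta["class_label"])
        q2_true = cp.cross_validate(X, labels, 1, 0, 7, seed=5).q2
        rng = np.random.default_rng(99)
        worse = 0
        n_perm = 20
        for _ in range(n_perm):
            perm = rng.permutation(len(labels))
            q2p = cp.cross_validate(X, [labels[i] for i in perm], 1, 0, 7,
                                    seed=5).q2
            worse += q2p < q2_true
        assert worse >= int(0.95 * n_perm)

    def test_class_coding_invariance_of_q2_and_p(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((14, 8)) + 4
        la = ["a"] * 7 + ["b"] * 7
        lb = ["b"] * 7 + ["a"] * 7
        cva = cp.cross_validate(X, la, 1, 1, 7, seed=2)
        cvb = cp.cross_validate(X, lb, 1, 1, 7, seed=2)
        assert abs(cva.press - cvb.press) <= 1e-10
        assert abs(cva.q2 - cvb.q2) <= 1e-10
        assert abs(cva.p - cvb.p) <= 1e-10
        np.testing.assert_allclose(cva.tcv, -cvb.tcv, atol=1e-10)


class TestCvAnova:
    def _cv_stub(self, press, ss_tot, n):
        return cp.CvResult(tcv=np.zeros((n, 1)), yhat_cv=np.zeros((n, 1)),
                           press=press, ss_tot=ss_tot, q2=1 - press / ss_tot,
                           f=0.0, df1=1, df2=n - 2, p=1.0,
                           folds=np.zeros(n, dtype=int), n_pred=1, n_ortho=0)

    def test_no_explained_variation(self):
        f, df1, df2, p = cp.cv_anova(self._cv_stub(10.0, 10.0, 20), a_model=2)
        assert f == 0.0 and p == 1.0

    def test_worked_arithmetic_and_f_cdf_oracle(self):
        f, df1, df2, p = cp.cv_anova(self._cv_stub(2.0, 10.0, 20), a_model=2)
        assert (df1, df2) == (2, 17)
        assert abs(f - 34.0) < 1e-12
        assert abs(p - float(scipy.stats.f.sf(34.0, 2, 17))) < 1e-15

    def test_perfect_prediction(self):
        f, _, _, p = cp.cv_anova(self._cv_stub(0.0, 10.0, 20), a_model=2)
        assert np.isinf(f) and p == 0.0

    def test_model_larger_than_data_rejected(self):
        with pytest.raises(cp.DataError):
            cp.cv_anova(self._cv_stub(1.0, 2.0, 4), a_model=3)


class TestChooseOrthogonal:
    def test_class_only_data_needs_none(self):
        rng = np.random.default_rng(1)
        labels = ["a"] * 9 + ["b"] * 9
        y = np.array([1.0] * 9 + [-1.0] * 9)
        X = np.outer(y, rng.standard_normal(12)) + 0.01 * rng.standard_normal((18, 12))
        assert cp.choose_orthogonal(X + 10, labels, max_ortho=3, n_folds=6,
                                    seed=1) == 0

    def test_max_ortho_zero(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((12, 6)) + 5
        assert cp.choose_orthogonal(X, ["a"] * 6 + ["b"] * 6, max_ortho=0,
                                    seed=0) == 0

    def test_strong_latent_factor_detected(self):
        """A strong class-independent cell-line factor makes the greedy rule
        add at least one orthogonal component in >= 90% of runs (log scale)."""
        hits = 0
        n_runs = 25
        for seed in range(n_runs):
            cfg = cp.SyntheticConfig(
                n_lines_per_class=3, n_reps_per_line=6, n_media_controls=0,
                n_metabolites=50, planted_effects={j: 2.0 for j in range(10)},
                pathway_blocks=[], orthogonal_strength=10.0,
                orthogonal_level="line", sample_load_cv=0.0, seed=seed,
            )
            _, pel, _ = cp.generate(cfg)
            prep = cp.preprocess_stratum(pel)
            k = cp.choose_orthogonal(prep.matrix(),
                                     list(prep.sample_meta["class_label"]),
                                     n_pred=1, max_ortho=3, n_folds=7,
                                     seed=seed, log_transform=True)
            hits += k >= 1
        assert hits >= int(0.9 * n_runs)


class TestSelectVariables:
    def _data(self, seed=0, m=30):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((16, m)) + 5
        X[:8, :3] += 2.5
        return X, ["a"] * 8 + ["b"] * 8

    def test_tau_zero_retains_all(self):
        X, labels = self._data()
        sel = cp.select_variables(X, labels, tau=0.0, seed=0)
        assert sel.discarded == []
        assert len(sel.retained) == X.shape[1]
        assert sel.final_model is sel.initial_model

    def test_retained_union_discarded_is_everything(self):
        X, labels = self._data(seed=1)
        sel = cp.select_variables(X, labels, tau=0.05, seed=1)
        assert sorted(sel.retained + sel.discarded) == sorted(
            f"var{j}" for j in range(X.shape[1]))
        np.testing.assert_array_equal(
            np.sort(np.flatnonzero(sel.w_abs >= 0.05)),
            np.sort([int(v[3:]) for v in sel.retained]))

    def test_selection_collapse_raises(self):
        X, labels = self._data(seed=2)
        with pytest.raises(cp.SelectionCollapseError):
            cp.select_variables(X, labels, tau=10.0, seed=2)

    def test_planted_metabolites_recovered(self, strong_effect_config):
        """All 10 planted delta = 2 metabolites survive the |w*| >= 0.05
        discard step on a 400-metabolite panel."""
        cfg = dataclasses.replace(strong_effect_config, seed=6)
        _, pel, truth = cp.generate(cfg)
        prep = cp.preprocess_stratum(pel)
        sel = cp.select_variables(prep.matrix(),
                                  list(prep.sample_meta["class_label"]),
                                  metabolite_ids=prep.metabolite_ids,
                                  tau=0.05, n_pred=1, n_ortho=0, n_folds=7,
                                  seed=6)
        planted = {mid for mid, _d in truth.planted}
        assert planted <= set(sel.retained)
        assert len(sel.retained) < prep.n_metabolites
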
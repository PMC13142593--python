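"""Diagnostic evaluation: ROC/AUC vs pairwise-concordance oracle, Youden vs
exhaustive scan, DeLong/bootstrap CIs, CV and external regimes, MANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panelforge.diagnostics import (auc_confidence, external_validation,
                                    fit_panel_model, pca_manova, repeated_cv_auc,
                                    roc_auc, score_subjects, youden_threshold)
from panelforge.matrix import CohortMatrix
from panelforge.preprocess import zscore_standardize
from panelforge.signatures import Signature
from panelforge.simulate import SimStudyConfig, simulate_cohort


def brute_force_auc(scores, y):
    """Pairwise concordance count (+1/2 for ties) over case/control pairs."""
    cases = [s for s, l in zip(scores, y) if l == 1]
    controls = [s for s, l in zip(scores, y) if l == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


def brute_force_youden(scores, y):
    """Exhaustive scan over all cutpoints of the rule score >= t."""
    best = (-1.0, None)
    for t in sorted(set(scores)) + [np.inf]:
        sens = np.mean([s >= t for s, l in zip(scores, y) if l == 1])
        spec = np.mean([s < t for s, l in zip(scores, y) if l == 0])
        j = sens + spec - 1
        if j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and best[1] is not None
                                   and spec > best[2]):
            best = (j, t, spec)
    return best[0]


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        assert auc == 1.0

    def test_label_swap_antisymmetry(self):
        _, auc = roc_auc([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0])
        assert auc == 0.0

    def test_hand_example(self):
        # controls {3,1}, cases {2,4}: concordant pairs (2>1, 4>3, 4>1) = 3/4
        _, auc = roc_auc([3.0, 1.0, 2.0, 4.0], [0, 0, 1, 1])
        assert auc == 0.75

    @given(st.lists(st.integers(-5, 5), min_size=4, max_size=50),
           st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_pairwise_oracle(self, scores, data):
        y = data.draw(st.lists(st.booleans(), min_size=len(scores),
                               max_size=len(scores)))
        y = [int(v) for v in y]
        if sum(y) in (0, len(y)):
            y[0] = 1 - y[0]
        if sum(y) in (0, len(y)):
            return
        s = [float(v) for v in scores]
        _, auc = roc_auc(s, y)
        assert auc == pytest.approx(brute_force_auc(s, y), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        s = rng.normal(size=60)
        y = (rng.random(60) < 0.5).astype(int)
        y[0], y[1] = 0, 1
        _, a1 = roc_auc(s, y)
        _, a2 = roc_auc(np.exp(3 * s) + 7, y)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestYouden:
    def test_perfect_separation_j_one(self):
        pts, _ = roc_auc([1.0, 2.0, 5.0, 6.0], [0, 0, 1, 1])
        t, sens, spec = youden_threshold(pts)
        assert sens + spec - 1 == pytest.approx(1.0)
        assert 2.0 < t <= 5.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(6, 80))
            s = np.round(rng.normal(size=n), 1)
            y = (rng.random(n) < 0.4).astype(int)
            if y.sum() in (0, n):
                continue
            pts, _ = roc_auc(s, y)
            _, sens, spec = youden_threshold(pts)
            assert sens + spec - 1 == pytest.approx(brute_force_youden(s, y), abs=1e-9)

    def test_all_identical_scores_j_zero(self):
        pts, _ = roc_auc([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1])
        _, sens, spec = youden_threshold(pts)
        assert sens + spec - 1 == pytest.approx(0.0)


class TestAucConfidence:
    def test_degenerate_variance_collapses(self):
        lo, hi = auc_confidence([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1], "delong")
        assert lo == hi == 1.0

    def test_bootstrap_deterministic(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        y = [0, 1] * 20
        a = auc_confidence(s, y, "bootstrap", seed=5, n_boot=200)
        b = auc_confidence(s, y, "bootstrap", seed=5, n_boot=200)
        assert a == b

    def test_delong_coverage_near_nominal(self):
        # true AUC 0.76 for a 1-sd shift; CI should cover it ~95% of runs
        rng = np.random.default_rng(99)
        true_auc = 0.7602499389  # Phi(1/sqrt(2))
        hits = 0
        runs = 200
        for _ in range(runs):
            controls = rng.normal(0, 1, 60)
            cases = rng.normal(1, 1, 60)
            s = np.r_[controls, cases]
            y = np.r_[np.zeros(60), np.ones(60)]
            lo, hi = auc_confidence(s, y, "delong")
            hits += lo <= true_auc <= hi
        assert 0.90 <= hits / runs <= 0.99


class TestPanelModel:
    def test_separable_data_finite_coefficients(self):
        data = pd.DataFrame([np.r_[np.ones(10) * 2, -np.ones(10) * 2]],
                            index=["G1"], columns=[f"s{i}" for i in range(20)])
        m = CohortMatrix("c", "mass_spec", data, scale="zscore")
        labels = {f"s{i}": ("case" if i < 10 else "control") for i in range(20)}
        sig = Signature("one", ["G1"])
        model = fit_panel_model((m, labels), sig)
        assert np.isfinite(model.coef).all()
        scores = score_subjects(model, m)
        _, auc = roc_auc(scores, labels)
        assert auc == 1.0

    def test_permuted_labels_give_null_coefficients(self):
        rng = np.random.default_rng(23)
        n = 300
        data = pd.DataFrame(rng.normal(size=(3, n)), index=["A", "B", "C"],
                            columns=[f"s{i}" for i in range(n)])
        m = CohortMatrix("c", "mass_spec", data, scale="zscore")
        labels = {f"s{i}": ("case" if rng.random() < 0.5 else "control")
                  for i in range(n)}
        model = fit_panel_model((m, labels), Signature("p", ["A", "B", "C"]))
        # logistic SE ~ 2/sqrt(n) on standardized inputs under the null
        assert np.all(np.abs(model.coef) < 3 * 2 / np.sqrt(n))

    def test_single_class_errors(self):
        data = pd.DataFrame(np.ones((1, 4)), index=["A"],
                            columns=list("abcd"))
        m = CohortMatrix("c", "mass_spec", data, scale="zscore")
        with pytest.raises(ValueError, match="single class"):
            fit_panel_model((m, {k: "case" for k in "abcd"}), Signature("s", ["A"]))

    def test_score_at_zero_equals_intercept(self, labeled_cohort):
        m, labels, _ = labeled_cohort
        sig = Signature("mk", ["MK0", "MK1"])
        model = fit_panel_model((m, labels), sig)
        zero = CohortMatrix("z", "mass_spec",
                            pd.DataFrame(np.zeros((2, 3)), index=["MK0", "MK1"],
                                         columns=["x", "y", "z"]), scale="zscore")
        scores = score_subjects(model, zero)
        assert np.allclose(scores, model.intercept)

    def test_zero_overlap_errors(self, labeled_cohort):
        m, labels, _ = labeled_cohort
        model = fit_panel_model((m, labels), Signature("mk", ["MK0"]))
        other = CohortMatrix("o", "mass_spec",
                             pd.DataFrame(np.zeros((1, 2)), index=["ZZZ"],
                                          columns=["x", "y"]), scale="zscore")
        with pytest.raises(ValueError, match="overlap"):
            score_subjects(model, other)


class TestValidationRegimes:
    def test_cv_detects_strong_signal(self, labeled_cohort):
        m, labels, _ = labeled_cohort
        sig = Signature("mk", [f"MK{i}" for i in range(5)])
        res = repeated_cv_auc(m, labels, sig, repeats=3, seed=2)
        assert res.auc >= 0.95
        assert res.ci_low <= res.auc <= res.ci_high

    def test_cv_deterministic(self, labeled_cohort):
        m, labels, _ = labeled_cohort
        sig = Signature("mk", ["MK0", "MK1"])
        r1 = repeated_cv_auc(m, labels, sig, repeats=2, seed=7)
        r2 = repeated_cv_auc(m, labels, sig, repeats=2, seed=7)
        assert r1.auc == r2.auc and r1.details["repeat_aucs"] == r2.details["repeat_aucs"]

    def test_cv_k_too_large_errors(self, labeled_cohort):
        m, labels, _ = labeled_cohort
        with pytest.raises(ValueError, match="smaller k"):
            repeated_cv_auc(m, labels, Signature("mk", ["MK0"]), k=50)

    def test_external_close_to_cv_on_same_generator(self):
        def gen(seed, cid):
            cfg = SimStudyConfig(cohort_id=cid, n_case=100, n_control=100,
                                 n_proteins=30, seed=seed, noise_sd=0.8,
                                 planted_markers=[(f"MK{i}", 1.0) for i in range(4)],
                                 missing_beta=(0.0, 0.0))
            m, subjects, _ = simulate_cohort(cfg)
            labels = {s.subject_id: ("case" if s.is_at_positive else "control")
                      for s in subjects}
            return zscore_standardize(m), labels

        m_tr, lab_tr = gen(1, "train")
        m_te, lab_te = gen(2, "test")
        sig = Signature("mk", [f"MK{i}" for i in range(4)])
        cv = repeated_cv_auc(m_tr, lab_tr, sig, repeats=3, seed=3)
        model = fit_panel_model((m_tr, lab_tr), sig)
        ext = external_validation(model, (m_te, lab_te))
        assert abs(ext.auc - cv.auc) < 0.05

    def test_platform_shift_removed_by_zscore(self):
        cfg = SimStudyConfig(cohort_id="a", n_case=40, n_control=40, n_proteins=20,
                             seed=6, planted_markers=[("MK0", 1.2)],
                             missing_beta=(0.0, 0.0))
        m, subjects, _ = simulate_cohort(cfg)
        labels = {s.subject_id: ("case" if s.is_at_positive else "control")
                  for s in subjects}
        mz = zscore_standardize(m)
        shifted = m.with_data(m.data * 1.7 + 3.0)
        sz = zscore_standardize(shifted)
        sig = Signature("mk", ["MK0"])
        model = fit_panel_model((mz, labels), sig)
        a1 = external_validation(model, (mz, labels)).auc
        a2 = external_validation(model, (sz, labels)).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_null_selectivity(self):
        # identical generating distributions -> AUC ~ 0.5 (the "A-T- MCI vs
        # A-T- CU" selectivity check)
        rng = np.random.default_rng(31)
        n = 150
        genes = [f"G{i:04d}" for i in range(5)]
        data = pd.DataFrame(rng.normal(size=(5, 2 * n)), index=genes,
                            columns=[f"s{i}" for i in range(2 * n)])
        m = CohortMatrix("c", "mass_spec", data, scale="zscore")
        labels = {f"s{i}": ("case" if i < n else "control") for i in range(2 * n)}
        train_cfg = SimStudyConfig(cohort_id="tr", n_case=60, n_control=60,
                                   n_proteins=5, seed=1, background_prefix="G",
                                   missing_beta=(0.0, 0.0))
        m_tr, subj, _ = simulate_cohort(train_cfg)
        lab_tr = {s.subject_id: ("case" if s.is_at_positive else "control")
                  for s in subj}
        model = fit_panel_model((zscore_standardize(m_tr), lab_tr),
                                Signature("g", genes))
        res = external_validation(model, (m, labels))
        assert 0.4 <= res.auc <= 0.6


class TestPcaManova:
    def _null_matrix(self, seed, n=40, p=30):
        rng = np.random.default_rng(seed)
        data = pd.DataFrame(rng.normal(size=(p, n)),
                            index=[f"G{i}" for i in range(p)],
                            columns=[f"s{i}" for i in range(n)])
        m = CohortMatrix("c", "mass_spec", data, scale="zscore")
        groups = {f"s{i}": ("a" if i < n // 2 else "b") for i in range(n)}
        return m, groups

    def test_one_component_reduces_to_ss_ratio(self):
        m, groups = self._null_matrix(3)
        res = pca_manova(m, groups, n_components=1)
        # recompute: Pillai = SSB/SST of the single component
        from sklearn.decomposition import PCA
        pc = PCA(n_components=1).fit_transform(m.data.T.to_numpy()).ravel()
        g = np.array([groups[s] == "a" for s in m.subjects])
        grand = pc.mean()
        ssb = sum(len(pc[idx]) * (pc[idx].mean() - grand) ** 2
                  for idx in (g, ~g))
        sst = ((pc - grand) ** 2).sum()
        assert res.pillai_trace == pytest.approx(ssb / sst, abs=1e-9)

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(12)
        n, p = 100, 20
        data = rng.normal(size=(p, n))
        data[:5, :50] += 3.0  # 3-sd shift on 5 proteins for group a
        m = CohortMatrix("c", "mass_spec",
                         pd.DataFrame(data, index=[f"G{i}" for i in range(p)],
                                      columns=[f"s{i}" for i in range(n)]),
                         scale="zscore")
        groups = {f"s{i}": ("a" if i < 50 else "b") for i in range(n)}
        res = pca_manova(m, groups, n_components=3)
        assert res.p_value < 0.05
        assert res.pillai_trace <= 1.0 + 1e-12  # min(groups-1, components) = 1

    def test_null_p_roughly_uniform(self):
        ps = [pca_manova(*self._null_matrix(1000 + i), n_components=3).p_value
              for i in range(60)]
        from scipy import stats as ss
        assert ss.kstest(ps, "uniform").pvalue > 0.01

    def test_too_many_components_rejected(self):
        m, groups = self._null_matrix(4, n=10, p=8)
        with pytest.raises(ValueError):
            pca_manova(m, groups, n_components=9)
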
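"""Discovery funnel: differential abundance, thresholds, vote counting,
concordance, coverage and down-selection — checked against brute-force
oracles and planted synthetic truth."""

import itertools

import numpy as np
import pandas as pd
import pytest

from panelforge.discovery import (DAPRecord, DiscoveryConfig, concordant_direction,
                                  coverage_filter, differential_abundance, filter_daps,
                                  run_funnel, vote_count)
from panelforge.matrix import CohortMatrix
from panelforge.preprocess import zscore_standardize
from panelforge.simulate import SimStudyConfig, simulate_cohort, simulate_multi_study


def _rec(gene, lfc, p, study="s1"):
    return DAPRecord(gene, study, lfc, p)


def _log2_matrix(values, columns):
    arr = np.asarray(values, dtype=float)
    data = pd.DataFrame(arr, index=[f"P{i}" for i in range(arr.shape[0])],
                        columns=columns)
    return CohortMatrix("c", "mass_spec", data, scale="log2")


class TestDifferentialAbundance:
    def test_simple_shift(self):
        # case mean 4, control mean 3 on log2 scale -> log2fc exactly 1
        cols = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        values = np.array([[4.0, 4.1, 3.9, 4.0, 3.0, 3.1, 2.9, 3.0]])
        m = _log2_matrix(values, cols)
        labels = {c: ("case" if c.startswith("a") else "control") for c in cols}
        recs = differential_abundance(m, labels)
        assert len(recs) == 1
        assert recs[0].log2fc == pytest.approx(1.0)

    def test_identical_groups_fail_filter(self):
        rng = np.random.default_rng(0)
        cols = [f"s{i}" for i in range(20)]
        m = _log2_matrix(rng.normal(5, 0.2, size=(10, 20)), cols)
        labels = {c: ("case" if i < 10 else "control") for i, c in enumerate(cols)}
        recs = differential_abundance(m, labels)
        assert sum(r.passes_filter for r in recs) == 0 or \
            np.mean([r.passes_filter for r in recs]) < 0.2  # rare chance hits only

    def test_power_for_planted_shift(self):
        # shift +1.0, n=30/30, sd 0.3 -> detected in >= 99% of proteins
        rng = np.random.default_rng(1)
        cols = [f"s{i}" for i in range(60)]
        case = rng.normal(5.0 + 1.0, 0.3, size=(200, 30))
        ctrl = rng.normal(5.0, 0.3, size=(200, 30))
        m = _log2_matrix(np.hstack([case, ctrl]), cols)
        labels = {c: ("case" if i < 30 else "control") for i, c in enumerate(cols)}
        recs = differential_abundance(m, labels)
        assert np.mean([r.passes_filter for r in recs]) >= 0.99

    def test_sparse_protein_skipped(self):
        cols = [f"s{i}" for i in range(8)]
        values = np.full((2, 8), 5.0)
        values[0, :6] = np.nan  # only 2 observed in the case group
        values[1] = np.arange(8, dtype=float)
        m = _log2_matrix(values, cols)
        labels = {c: ("case" if i < 4 else "control") for i, c in enumerate(cols)}
        recs = differential_abundance(m, labels)
        assert [r.gene_symbol for r in recs] == ["P1"]

    def test_small_groups_rejected(self):
        cols = ["a1", "a2", "b1", "b2"]
        m = _log2_matrix(np.ones((1, 4)), cols)
        labels = {"a1": "case", "a2": "case", "b1": "control", "b2": "control"}
        with pytest.raises(ValueError, match="three"):
            differential_abundance(m, labels)


class TestFilterDaps:
    @pytest.mark.parametrize("lfc,p,kept", [
        (0.7, 0.01, True),
        (0.59, 0.001, False),
        (0.60, 0.049, True),    # inclusive effect boundary
        (0.60, 0.05, False),    # strict p boundary
        (-0.8, 0.02, True),     # downregulated side
        (0.0, 1e-9, False),
    ])
    def test_boundaries(self, lfc, p, kept):
        out = filter_daps([_rec("G", lfc, p)])
        assert (len(out) == 1) is kept

    def test_idempotent_and_order_preserving(self):
        recs = [_rec(f"G{i}", 0.3 + 0.1 * i, 0.01) for i in range(10)]
        once = filter_daps(recs)
        assert filter_daps(once) == once
        genes = [r.gene_symbol for r in once]
        assert genes == sorted(genes, key=lambda g: int(g[1:]))


class TestVoteCount:
    def _brute_force(self, per_study, min_studies=2):
        """Nested-loop intersection oracle."""
        genes = sorted({r.gene_symbol for recs in per_study.values() for r in recs})
        out = {}
        for g in genes:
            hits = []
            for study in sorted(per_study):
                best = None
                for r in per_study[study]:
                    if r.gene_symbol == g and (best is None or
                                               abs(r.log2fc) > abs(best.log2fc)):
                        best = r
                if best is not None:
                    hits.append((study, 1 if best.log2fc > 0 else -1))
            if len(hits) >= min_studies:
                out[g] = [s for _, s in hits]
        return out

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            n_studies = rng.integers(2, 6)
            per_study = {}
            for j in range(n_studies):
                genes = rng.choice(100, size=rng.integers(5, 60), replace=False)
                per_study[f"s{j}"] = [
                    _rec(f"G{g}", float(rng.normal()) or 0.1,
                         float(rng.uniform(1e-6, 1)), f"s{j}")
                    for g in genes]
            tallies = vote_count(per_study)
            oracle = self._brute_force(per_study)
            assert {t.gene_symbol: t.signs for t in tallies} == oracle

    def test_membership_examples(self):
        per = {"s1": [_rec("A", 1.0, 0.01, "s1"), _rec("B", 1.0, 0.01, "s1")],
               "s2": [_rec("A", -1.0, 0.01, "s2")],
               "s3": [_rec("C", 1.0, 0.01, "s3")]}
        tallies = vote_count(per)
        assert [t.gene_symbol for t in tallies] == ["A"]
        assert tallies[0].n_studies_present == 2
        assert not tallies[0].concordant

    def test_multi_analyte_single_sign(self):
        per = {"s1": [_rec("A", 0.7, 0.01, "s1"), _rec("A", -2.0, 0.01, "s1")],
               "s2": [_rec("A", -1.0, 0.01, "s2")]}
        tallies = vote_count(per)
        assert tallies[0].signs == [-1, -1]  # |−2| beats |0.7| within s1

    def test_needs_two_studies(self):
        with pytest.raises(ValueError):
            vote_count({"s1": []})


class TestConcordance:
    def test_examples(self):
        from panelforge.discovery import VoteTally
        keep = VoteTally("A", [1, 1, 1], ["s1", "s2", "s3"])
        drop = VoteTally("B", [1, -1], ["s1", "s2"])
        out = concordant_direction([keep, drop])
        assert [t.gene_symbol for t in out] == ["A"]
        assert out[0].concordant

    def test_full_concordance_retains_all_shared(self):
        shared = [(f"MK{i:02d}", 1.2 if i % 2 else -1.2) for i in range(8)]
        cfgs = [SimStudyConfig(cohort_id=f"s{j}", seed=50 + j, n_proteins=80,
                               noise_sd=0.3, missing_beta=(0.0, 0.0))
                for j in range(3)]
        bundles, _ = simulate_multi_study(cfgs, shared, 1.0, seed=9)
        per = {}
        for m, subjects, _ in bundles:
            mz = zscore_standardize(m)
            labels = {s.subject_id: ("case" if s.is_at_positive else "control")
                      for s in subjects}
            per[m.cohort_id] = filter_daps(differential_abundance(m, labels))
        tallies = concordant_direction(vote_count(per))
        got = {t.gene_symbol for t in tallies}
        assert {g for g, _ in shared} <= got


class TestCoverageAndFunnel:
    def test_coverage_filter(self):
        m1 = _log2_matrix(np.ones((2, 3)), ["a", "b", "c"])  # P0, P1
        data = pd.DataFrame(np.ones((1, 3)), index=["P0"], columns=["d", "e", "f"])
        m2 = CohortMatrix("c2", "aptamer", data, scale="log2")
        kept = coverage_filter(["P0", "P1"], [m1, m2])
        assert kept == ["P0"]
        with pytest.raises(ValueError):
            coverage_filter(["P0"], [])

    def test_funnel_monotone(self):
        cfgs = [SimStudyConfig(cohort_id=f"s{j}", seed=70 + j, n_proteins=100,
                               study_specific_hits=4) for j in range(4)]
        bundles, _ = simulate_multi_study(cfgs, [(f"MK{i}", 1.0) for i in range(6)],
                                          1.0, seed=4)
        per, mats = {}, []
        for m, subjects, _ in bundles:
            labels = {s.subject_id: ("case" if s.is_at_positive else "control")
                      for s in subjects}
            per[m.cohort_id] = differential_abundance(m, labels)
            mats.append(m)
        funnel = run_funnel(per, mats)
        n_filtered = len({r.gene_symbol for recs in funnel["filtered"].values()
                          for r in recs})
        assert n_filtered >= len(funnel["shared"]) >= len(funnel["concordant"]) \
            >= len(funnel["candidates"])


class TestDownSelect:
    def test_informative_panel_recovered_across_seeds(self):
        from panelforge.discovery import down_select_panel

        wins = 0
        for seed in range(20):
            cfg = SimStudyConfig(
                cohort_id="t", n_case=100, n_control=100, n_proteins=5,
                seed=900 + seed, noise_sd=1.0, missing_beta=(0.0, 0.0),
                planted_markers=[("INF1", 1.5), ("INF2", 1.5), ("INF3", 1.5)],
                background_prefix="NOISE")
            m, subjects, _ = simulate_cohort(cfg)
            mz = zscore_standardize(m)
            labels = {s.subject_id: ("case" if s.is_at_positive else "control")
                      for s in subjects}
            sig = down_select_panel(["INF1", "INF2", "INF3", "NOISE0000", "NOISE0001"],
                                    [(mz, labels)], seed=seed)
            if sorted(sig.gene_symbols) == ["INF1", "INF2", "INF3"]:
                wins += 1
        assert wins >= 18

    def test_single_candidate_returned(self):
        from panelforge.discovery import down_select_panel

        sig = down_select_panel(["ONLY"], [])
        assert sig.gene_symbols == ["ONLY"]

    def test_constant_protein_never_selected(self):
        from panelforge.discovery import down_select_panel

        cfg = SimStudyConfig(cohort_id="t", n_case=60, n_control=60, n_proteins=4,
                             seed=5, noise_sd=0.8, missing_beta=(0.0, 0.0),
                             planted_markers=[("INF1", 1.5), ("INF2", 1.5)],
                             background_prefix="NZ")
        m, subjects, _ = simulate_cohort(cfg)
        # append an exactly constant protein on the z scale
        mz = zscore_standardize(m)
        const = pd.DataFrame(np.zeros((1, len(mz.subjects))), index=["FLAT"],
                             columns=mz.subjects)
        mz = mz.with_data(pd.concat([mz.data, const]))
        labels = {s.subject_id: ("case" if s.is_at_positive else "control")
                  for s in subjects}
        with_flat = down_select_panel(["INF1", "INF2", "FLAT"], [(mz, labels)], seed=1)
        without = down_select_panel(["INF1", "INF2"], [(mz, labels)], seed=1)
        assert sorted(set(with_flat.gene_symbols) - {"FLAT"}) == sorted(without.gene_symbols)
        assert "FLAT" not in with_flat.gene_symbols
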
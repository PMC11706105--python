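"""Drug aggregation, RS/OC scoring, Ward clustering and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from revscreen.containers import (
    CandidateScore,
    DiseaseProfile,
    DrugProfile,
    InvalidParameterError,
    SignatureProfile,
)
from revscreen.prioritize import (
    REFERENCE_COLUMN,
    aggregate_drug_profile,
    cluster_signatures,
    overall_coverage,
    rank_candidates,
    regulation_score,
    score_drugs,
    _pairwise_minkowski,
)
from revscreen.simulate import simulate_signature_library

from oracles import brute_force_oc, brute_force_rs, brute_force_ward, partitions_equal


class TestAggregateDrugProfile:
    def test_single_signature_identity(self):
        s = SignatureProfile("s1", "d", "lib", {"A": -1.0, "B": 2.0})
        dp = aggregate_drug_profile([s])
        assert dp.entries == s.entries and dp.n_signatures == 1

    def test_median_by_hand(self):
        sigs = [
            SignatureProfile("s1", "d", "lib", {"A": -1.0, "B": -1.0}),
            SignatureProfile("s2", "d", "lib", {"A": -2.0, "B": -3.0}),
            SignatureProfile("s3", "d", "lib", {"A": 4.0}),
        ]
        dp = aggregate_drug_profile(sigs)
        assert dp.entries["A"] == pytest.approx(-1.0)   # median(-1,-2,4)
        assert dp.entries["B"] == pytest.approx(-2.0)   # median of observed (-1,-3)

    def test_mixed_perturbagens_rejected(self):
        sigs = [SignatureProfile("s1", "d1", "lib"), SignatureProfile("s2", "d2", "lib")]
        with pytest.raises(InvalidParameterError):
            aggregate_drug_profile(sigs)
        with pytest.raises(InvalidParameterError):
            aggregate_drug_profile([])


class TestRegulationScore:
    def test_worked_example_and_oracle(self, toy_profile, toy_drug):
        rs, deltas = regulation_score(toy_profile, toy_drug)
        assert rs == pytest.approx(1.875)
        assert deltas == {"g1": 3.0, "g2": 1.5, "g3": 0.0}
        assert rs == pytest.approx(brute_force_rs(toy_profile.entries, toy_drug.entries))

    def test_identical_drug_scores_zero(self, wide_profile):
        drug = DrugProfile("same", dict(wide_profile.entries), 1)
        rs, _ = regulation_score(wide_profile, drug)
        assert rs == 0.0

    def test_exact_inverse_of_unit_profile_scores_two(self):
        prof = DiseaseProfile({f"G{i}": (-1.0) ** i for i in range(10)})
        drug = DrugProfile("inv", {g: -v for g, v in prof.entries.items()}, 1)
        rs, _ = regulation_score(prof, drug)
        assert rs == pytest.approx(2.0)

    def test_zero_product_contributes_zero(self, toy_profile):
        drug = DrugProfile("z", {"g1": 0.0, "g2": -5.0}, 1)
        rs, deltas = regulation_score(toy_profile, drug)
        assert deltas["g1"] == 0.0 and deltas["g2"] == 0.0
        assert rs == 0.0

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_oracle_and_homogeneity(self, seed, c):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(20)]
        prof = DiseaseProfile({g: float(v) for g, v in
                               zip(genes, rng.normal(0, 2, 20)) if v != 0})
        keep = rng.random(20) > 0.3
        drug = DrugProfile("d", {g: float(v) for g, v, k in
                                 zip(genes, rng.normal(0, 2, 20), keep) if k}, 1)
        rs, _ = regulation_score(prof, drug)
        assert rs == pytest.approx(brute_force_rs(prof.entries, drug.entries))
        # joint rescaling by c > 0 rescales RS by c
        prof_c = DiseaseProfile({g: c * v for g, v in prof.entries.items()})
        drug_c = DrugProfile("d", {g: c * v for g, v in drug.entries.items()}, 1)
        rs_c, _ = regulation_score(prof_c, drug_c)
        assert rs_c == pytest.approx(c * rs)

    def test_adding_reversed_gene_never_decreases(self, toy_profile):
        base = DrugProfile("d", {"g1": -1.0}, 1)
        more = DrugProfile("d", {"g1": -1.0, "g2": 0.5}, 1)
        assert regulation_score(toy_profile, more)[0] >= regulation_score(toy_profile, base)[0]


class TestOverallCoverage:
    def test_worked_example(self, toy_profile, toy_drug):
        oc, a, g = overall_coverage(toy_profile, toy_drug)
        assert (a, g) == (2, 3)
        assert oc == pytest.approx(2 / 3)
        assert (oc, a, g) == brute_force_oc(toy_profile.entries, toy_drug.entries)

    def test_exact_inverse_and_disjoint(self, wide_profile):
        inv = DrugProfile("inv", {g: -v for g, v in wide_profile.entries.items()}, 1)
        assert overall_coverage(wide_profile, inv)[0] == pytest.approx(1.0)
        none = DrugProfile("none", {"ZZZ": 1.0}, 1)
        assert overall_coverage(wide_profile, none)[0] == 0.0

    def test_monotone_in_reversed_set_and_bounded(self, wide_profile):
        rng = np.random.default_rng(0)
        entries = {}
        prev = 0.0
        for g, v in wide_profile.entries.items():
            entries[g] = -v
            oc, a, n = overall_coverage(wide_profile, DrugProfile("d", dict(entries), 1))
            assert 0.0 <= oc <= 1.0 and oc >= prev
            prev = oc


class TestClusterSignatures:
    def _complete_sigs(self, X, genes):
        return [
            SignatureProfile(f"s{j}", f"d{j}", "lib",
                             {g: float(X[i, j]) for i, g in enumerate(genes)})
            for j in range(X.shape[1])
        ]

    def test_identical_columns_merge_first(self):
        genes = [f"G{i}" for i in range(6)]
        prof = DiseaseProfile(dict(zip(genes, [2.0, 1.5, 1.2, -1.1, -1.6, -2.2])))
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, size=(6, 4))
        X[:, 1] = X[:, 0]
        clusters = cluster_signatures(prof, self._complete_sigs(X, genes),
                                      k=2, append_reference=False)
        assert clusters.linkage[0, 2] == pytest.approx(0.0)
        assert {int(clusters.linkage[0, 0]), int(clusters.linkage[0, 1])} == {0, 1}

    @given(st.integers(0, 2**31 - 1), st.integers(3, 6), st.integers(2, 4))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle_complete_data(self, seed, n_cols, k):
        """On complete matrices the Ward merge heights and the k-cut
        partition equal a naive rescanning agglomerator's."""
        rng = np.random.default_rng(seed)
        n_genes = 8
        genes = [f"G{i}" for i in range(n_genes)]
        prof = DiseaseProfile({g: float(v) if v != 0 else 1.0
                               for g, v in zip(genes, rng.normal(0, 2, n_genes))})
        X = rng.normal(0, 1, size=(n_genes, n_cols))
        sigs = self._complete_sigs(X, genes)
        k = min(k, n_cols)
        clusters = cluster_signatures(prof, sigs, k=k, append_reference=False)
        M = np.array([[s.entries[g] for s in sigs] for g in prof.genes])
        D = _pairwise_minkowski(M, 2.0)
        heights, partition = brute_force_ward(D, k)
        assert np.allclose(np.sort(clusters.linkage[:, 2]), np.sort(heights), atol=1e-8)
        got = {}
        ids = [s.signature_id for s in sigs]
        for c, lab in clusters.labels.items():
            got.setdefault(lab, set()).add(ids.index(c))
        assert partitions_equal(list(got.values()), partition)

    def test_planted_reversers_and_mimics_separate(self, wide_profile):
        rhos = [1.0, 1.0, 1.0, -1.0, -1.0, -1.0]
        sigs, truth = simulate_signature_library(wide_profile, 6, 1, rhos,
                                                 noise_sd=0.2, missing_prob=0.0, seed=5)
        clusters = cluster_signatures(wide_profile, sigs, k=2, append_reference=True)
        lab = clusters.labels
        reversers = {lab[s.signature_id] for s in sigs[:3]}
        mimics = {lab[s.signature_id] for s in sigs[3:]}
        assert len(reversers) == 1 and len(mimics) == 1 and reversers != mimics
        # the disease profile itself co-clusters with the mimics
        assert clusters.reference_label in mimics

    def test_disconnected_column_excluded(self, wide_profile):
        sigs, _ = simulate_signature_library(wide_profile, 3, 1, [1.0, 0.5, 0.2],
                                             noise_sd=0.1, missing_prob=0.0, seed=6)
        lonely = SignatureProfile("lonely", "x", "lib", {"NOT_IN_PROFILE": 1.0})
        clusters = cluster_signatures(wide_profile, sigs + [lonely], k=2,
                                      append_reference=False)
        assert clusters.excluded == ["lonely"]
        assert "lonely" not in clusters.labels

    def test_k_larger_than_columns_rejected(self, wide_profile):
        sigs, _ = simulate_signature_library(wide_profile, 2, 1, [1.0, 0.5],
                                             noise_sd=0.1, missing_prob=0.0, seed=7)
        with pytest.raises(InvalidParameterError):
            cluster_signatures(wide_profile, sigs, k=5, append_reference=False)


class TestRanking:
    def test_planted_rho_recovery(self, wide_profile):
        """RS ranking recovers the planted reversal strengths: Spearman
        correlation between per-drug RS and rho >= 0.9 on a 20-drug library
        (3 signatures each, noise_sd 0.3, 20% missing)."""
        rng = np.random.default_rng(20)
        rhos = list(rng.uniform(0, 1, 20))
        sigs, truth = simulate_signature_library(wide_profile, 20, 3, rhos,
                                                 noise_sd=0.3, missing_prob=0.2, seed=20)
        scores = score_drugs(wide_profile, sigs)
        rs_by = {s.drug: s.rs for s in scores}
        drugs = sorted(truth.drug_rho)
        rho = spearmanr([rs_by[d] for d in drugs],
                        [truth.drug_rho[d] for d in drugs]).statistic
        assert rho >= 0.9

    def test_single_candidate_rank_one(self):
        out = rank_candidates([CandidateScore("only", 1.0, 0.5, 5, 10)])
        assert out[0].rank == 1

    def test_published_rs_ordering(self):
        """Ordering by descending RS reproduces the published top-six order."""
        table = [
            ("Romidepsin", 2.093, 0.610), ("Docetaxel", 1.664, 0.519),
            ("Ciclopirox", 1.653, 0.601), ("Cabozantinib", 1.652, 0.657),
            ("Epirubicin Hydrochloride", 1.641, 0.591), ("Axitinib", 1.633, 0.594),
        ]
        rng = np.random.default_rng(0)
        shuffled = list(table)
        rng.shuffle(shuffled)
        scores = [CandidateScore(d, rs, oc, 0, 1) for d, rs, oc in shuffled]
        ranked = rank_candidates(scores)
        assert [s.drug for s in ranked] == [d for d, _, _ in table]

    def test_tie_broken_by_oc_then_name(self):
        scores = [
            CandidateScore("bdrug", 1.0, 0.5, 1, 2),
            CandidateScore("adrug", 1.0, 0.5, 1, 2),
            CandidateScore("cdrug", 1.0, 0.7, 1, 2),
        ]
        ranked = rank_candidates(scores)
        assert [s.drug for s in ranked] == ["cdrug", "adrug", "bdrug"]

    def test_annotation_filters(self):
        import pandas as pd

        scores = [CandidateScore("a", 2.0, 0.5, 1, 2), CandidateScore("b", 1.0, 0.5, 1, 2)]
        ann = pd.DataFrame({"drug": ["A", "b"], "bbb": [0.95, 0.5], "prior_trials": [0, 0]})
        out = rank_candidates(scores, ann, require_no_prior_trials=True, bbb_min=0.9)
        assert [s.drug for s in out] == ["a"]

    def test_missing_annotation_column_errors(self):
        import pandas as pd

        scores = [CandidateScore("a", 2.0, 0.5, 1, 2)]
        ann = pd.DataFrame({"drug": ["a"], "bbb": [0.95]})
        with pytest.raises(InvalidParameterError, match="prior_trials"):
            rank_candidates(scores, ann, require_no_prior_trials=True)
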
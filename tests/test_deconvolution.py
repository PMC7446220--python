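import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import running_sum_es_oracle
from synodeconv.deconvolution import (
    associate_with_response,
    compare_longitudinal,
    derive_signature,
    enrichment_score,
    rank_genes,
    score_samples,
    EnrichmentScoreMatrix,
)
from synodeconv.io import ExpressionMatrix, GeneSignature, Scale
from synodeconv.synthetic import generate_cohort, generate_reference_profiles


def _ranked(n):
    return [f"g{i:03d}" for i in range(n)]


class TestDeriveSignature:
    def test_recovers_planted_markers(self, reference_profiles):
        for t in reference_profiles.cell_types:
            sig = derive_signature(
                reference_profiles.to_frame(), target_type=t, n_top=40, min_fc=1.5
            )
            assert sig.gene_ids == reference_profiles.marker_map[t]

    def test_n_top_one_is_argmax(self, reference_profiles):
        frame = reference_profiles.to_frame()
        t = reference_profiles.cell_types[0]
        sig = derive_signature(frame, target_type=t, n_top=1, min_fc=1.1)
        log_fc = frame[t] - frame.drop(columns=[t]).max(axis=1)
        assert sig.gene_ids == frozenset({log_fc.idxmax()})

    def test_tie_broken_by_gene_id(self):
        import pandas as pd

        frame = pd.DataFrame(
            {"A": [9.0, 9.0, 5.0], "B": [5.0, 5.0, 5.0]}, index=["gB", "gA", "gC"]
        )
        sig = derive_signature(frame, target_type="A", n_top=1, min_fc=1.5)
        assert sig.gene_ids == frozenset({"gA"})

    def test_empty_signature_is_error(self):
        import pandas as pd

        frame = pd.DataFrame({"A": [5.0, 5.0], "B": [5.0, 5.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="empty"):
            derive_signature(frame, target_type="A", n_top=10, min_fc=1.5)

    def test_needs_two_types(self):
        import pandas as pd

        frame = pd.DataFrame({"A": [5.0]}, index=["g1"])
        with pytest.raises(ValueError, match="2 cell types"):
            derive_signature(frame, target_type="A", n_top=1, min_fc=1.0)


class TestRankGenes:
    def _matrix(self, mapping, sample="s1"):
        genes = tuple(mapping)
        values = np.array([[mapping[g]] for g in genes], dtype=float)
        return ExpressionMatrix(genes, (sample,), values, Scale.log2)

    def test_descending_order(self):
        m = self._matrix({"A": 3.0, "B": 1.0, "C": 2.0})
        assert rank_genes(m, "s1") == ("A", "C", "B")

    def test_tie_rule_ascending_gene_id(self):
        m = self._matrix({"B": 2.0, "A": 2.0})
        assert rank_genes(m, "s1") == ("A", "B")

    def test_row_order_invariance(self):
        m1 = self._matrix({"A": 3.0, "B": 1.0, "C": 2.0})
        m2 = self._matrix({"C": 2.0, "A": 3.0, "B": 1.0})
        assert rank_genes(m1, "s1") == rank_genes(m2, "s1")

    def test_unknown_sample(self):
        m = self._matrix({"A": 1.0})
        with pytest.raises(KeyError):
            rank_genes(m, "nope")


class TestEnrichmentScore:
    def test_top_two_of_ten(self):
        ranked = _ranked(10)
        sig = GeneSignature("s", frozenset(ranked[:2]))
        assert enrichment_score(ranked, sig) == pytest.approx(1.0)

    def test_bottom_two_of_ten(self):
        ranked = _ranked(10)
        sig = GeneSignature("s", frozenset(ranked[-2:]))
        assert enrichment_score(ranked, sig) == pytest.approx(-1.0)

    def test_even_interleaving_small_magnitude(self):
        # hits at every 5th position of 10: max deviation is one hit step
        # minus accumulated misses; verify against the oracle
        ranked = _ranked(10)
        sig = GeneSignature("s", frozenset([ranked[4], ranked[9]]))
        assert enrichment_score(ranked, sig) == pytest.approx(
            running_sum_es_oracle(ranked, sig.gene_ids)
        )

    def test_exhaustive_all_placements_n12(self):
        # every signature placement for N <= 12, |S| in {1,2,3}: exact match
        for n in range(3, 13):
            ranked = _ranked(n)
            for size in (1, 2, 3):
                if size >= n:
                    continue
                for combo in itertools.combinations(range(n), size):
                    sig = GeneSignature("s", frozenset(ranked[i] for i in combo))
                    assert enrichment_score(ranked, sig) == pytest.approx(
                        running_sum_es_oracle(ranked, sig.gene_ids), abs=0
                    )

    def test_monotone_placement_property(self):
        # moving one signature gene strictly up never decreases a positive ES
        for n in range(4, 13):
            ranked = _ranked(n)
            for combo in itertools.combinations(range(n), 2):
                es = enrichment_score(ranked, GeneSignature("s", frozenset(ranked[i] for i in combo)))
                if es <= 0:
                    continue
                for pos in range(2):
                    i = combo[pos]
                    if i == 0 or (pos == 1 and combo[0] == i - 1):
                        continue
                    moved = list(combo)
                    moved[pos] = i - 1
                    es_up = enrichment_score(
                        ranked, GeneSignature("s", frozenset(ranked[j] for j in moved))
                    )
                    assert es_up >= es - 1e-12

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="no genes"):
            enrichment_score(_ranked(5), GeneSignature("s", frozenset({"zzz"})))

    def test_full_coverage_rejected(self):
        ranked = _ranked(4)
        with pytest.raises(ValueError, match="entire"):
            enrichment_score(ranked, GeneSignature("s", frozenset(ranked)))

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_random_instances_match_oracle(self, data):
        n = data.draw(st.integers(3, 60))
        size = data.draw(st.integers(1, n - 1))
        seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(seed)
        ranked = _ranked(n)
        sig_genes = frozenset(rng.choice(ranked, size=size, replace=False))
        es = enrichment_score(ranked, GeneSignature("s", sig_genes))
        assert es == running_sum_es_oracle(ranked, sig_genes)
        assert -1.0 <= es <= 1.0


class TestScoreSamples:
    def test_affine_invariance(self, cohort):
        matrix, _, _ = cohort
        sig = GeneSignature("s", frozenset(matrix.genes[:25]))
        base = score_samples(matrix, [sig])
        transformed = ExpressionMatrix(
            matrix.genes, matrix.samples, matrix.values * 3.7 + 11.0, matrix.scale
        )
        np.testing.assert_array_equal(
            score_samples(transformed, [sig]).scores, base.scores
        )

    def test_duplicate_signature_identical_columns(self, cohort):
        matrix, _, _ = cohort
        sig = GeneSignature("a", frozenset(matrix.genes[:20]))
        sig2 = GeneSignature("b", sig.gene_ids)
        scores = score_samples(matrix, [sig, sig2])
        np.testing.assert_array_equal(scores.scores[:, 0], scores.scores[:, 1])

    def test_absent_signature_rejected(self, cohort):
        matrix, _, _ = cohort
        with pytest.raises(ValueError, match="no genes"):
            score_samples(matrix, [GeneSignature("x", frozenset({"NOPE"}))])

    def test_missing_genes_dropped_with_log(self, cohort, caplog):
        import logging

        matrix, _, _ = cohort
        sig = GeneSignature("s", frozenset(matrix.genes[:10]) | {"ABSENT1", "ABSENT2"})
        with caplog.at_level(logging.INFO, logger="synodeconv.deconvolution"):
            score_samples(matrix, [sig])
        assert any("2/12" in rec.getMessage() for rec in caplog.records)

    def test_pure_sample_scores_high(self, reference_profiles):
        # a pure single-type sample ranks its own signature near the top
        ref = reference_profiles
        t = ref.cell_types[0]
        pure = np.exp2(ref.mean_log2) @ np.eye(len(ref.cell_types))[0]
        mixed_cols = [
            np.log2(np.exp2(ref.mean_log2) @ np.full(len(ref.cell_types), 0.25))
        ] * 8
        values = np.column_stack([np.log2(pure)] + mixed_cols)
        m = ExpressionMatrix(
            ref.genes, tuple(f"s{i}" for i in range(9)), values, Scale.log2
        )
        sig = GeneSignature(t, ref.marker_map[t])
        scores = score_samples(m, [sig]).scores[:, 0]
        assert scores[0] == scores.max()


def _score_matrix(sheet, values_by_sample, signature="TPH"):
    samples = tuple(values_by_sample)
    return EnrichmentScoreMatrix(
        samples=samples,
        signatures=(signature,),
        scores=np.array([[values_by_sample[s]] for s in samples]),
    )


class TestAssociation:
    def test_identical_scores_p1_direction_none(self, small_sheet):
        scores = _score_matrix(small_sheet, {r.sample_id: 0.3 for r in small_sheet})
        res = associate_with_response(scores, small_sheet, timepoint="week0")[0]
        assert res.p_value == 1.0
        assert res.direction == "none"

    def test_synthetic_cohort_direction(self, reference_profiles):
        hits = 0
        for seed in range(10):
            m, sheet, _ = generate_cohort(reference_profiles, seed=seed)
            sig = GeneSignature("TPH", reference_profiles.marker_map["TPH"])
            scores = score_samples(m, [sig])
            r = associate_with_response(scores, sheet, timepoint="week0")[0]
            if r.direction == "lower_in_responders" and r.p_value < 0.05:
                hits += 1
        assert hits >= 7

    def test_good_vs_rest_grouping(self, cohort):
        m, sheet, _ = cohort
        sig = GeneSignature("TPH", frozenset(m.genes[:30]))
        scores = score_samples(m, [sig])
        res = associate_with_response(scores, sheet, timepoint="week0", grouping="good_vs_rest")
        assert len(res) == 1

    def test_degenerate_group_rejected(self, cohort):
        m, sheet, _ = cohort
        sig = GeneSignature("TPH", frozenset(m.genes[:30]))
        scores = score_samples(m.subset_samples(m.samples[:4]), [sig])
        with pytest.raises(ValueError, match=">=2"):
            associate_with_response(scores, sheet, timepoint="week0")


class TestLongitudinal:
    def test_equal_timepoints_p1(self, small_sheet):
        per_patient = {"P1": 0.1, "P2": 0.2, "P3": -0.1, "P4": 0.05}
        values = {r.sample_id: per_patient[r.patient_id] for r in small_sheet}
        scores = _score_matrix(small_sheet, values)
        out = compare_longitudinal(scores, small_sheet, "TPH")
        for res in out["paired"]:
            assert res.p_value == 1.0
            assert res.mean_change == 0.0

    def test_constant_shift_recovered_exactly(self, small_sheet):
        delta = 0.17
        values = {}
        rng = np.random.default_rng(0)
        for r in small_sheet:
            base = rng.uniform(-0.3, 0.3)
            values[r.sample_id] = base
        # apply +delta to all week20 samples of the 'none' group
        for r in small_sheet:
            if r.timepoint == "week20" and r.response == "none":
                values[r.sample_id] = values[small_sheet.sample_of(r.patient_id, "week0")] + delta
        scores = _score_matrix(small_sheet, values)
        out = compare_longitudinal(scores, small_sheet, "TPH")
        by_group = {r.group: r for r in out["paired"]}
        assert by_group["none"].mean_change == pytest.approx(delta)

    def test_no_pairs_rejected(self, small_sheet):
        week0_only = {r.sample_id: 0.1 for r in small_sheet if r.timepoint == "week0"}
        scores = _score_matrix(small_sheet, week0_only)
        with pytest.raises(ValueError, match="both timepoints"):
            compare_longitudinal(scores, small_sheet, "TPH")
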
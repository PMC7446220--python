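import numpy as np
import pytest

from synodeconv.io import Scale
from synodeconv.synthetic import (
    PlantedTerm,
    generate_cohort,
    generate_go_annotation,
    generate_qpcr,
    generate_reference_profiles,
)


class TestReferenceProfiles:
    def test_marker_construction(self):
        ref = generate_reference_profiles(
            n_genes=100, cell_types=("a", "b", "c", "d"), n_markers_per_type=10,
            marker_effect=2.0, seed=1,
        )
        all_markers = set().union(*ref.marker_map.values())
        assert len(all_markers) == 40
        gene_idx = {g: i for i, g in enumerate(ref.genes)}
        for t, markers in ref.marker_map.items():
            k = ref.type_index(t)
            for g in markers:
                row = ref.mean_log2[gene_idx[g]]
                others = np.delete(row, k)
                assert row[k] == pytest.approx(others[0] + 2.0)
                assert np.all(row[k] > others)

    def test_zero_markers(self):
        ref = generate_reference_profiles(50, ("a", "b"), n_markers_per_type=0, seed=3)
        assert all(len(v) == 0 for v in ref.marker_map.values())

    def test_determinism(self):
        r1 = generate_reference_profiles(80, n_markers_per_type=5, seed=7)
        r2 = generate_reference_profiles(80, n_markers_per_type=5, seed=7)
        np.testing.assert_array_equal(r1.mean_log2, r2.mean_log2)
        assert r1.marker_map == r2.marker_map

    def test_infeasible_allocation(self):
        with pytest.raises(ValueError, match="cannot place"):
            generate_reference_profiles(10, ("a", "b"), n_markers_per_type=6, seed=0)

    def test_bad_effect(self):
        with pytest.raises(ValueError, match="positive"):
            generate_reference_profiles(10, ("a", "b"), n_markers_per_type=1,
                                        marker_effect=0.0, seed=0)


class TestCohort:
    def test_identity_mixture(self):
        # noise-free, single cell type with weight 1: every column equals
        # that type's profile exactly
        ref = generate_reference_profiles(60, cell_types=("only",), n_markers_per_type=0, seed=2)
        m, sheet, truth = generate_cohort(ref, noise_sd=0.0, n_de_genes=0, seed=2)
        for j in range(m.n_samples):
            np.testing.assert_allclose(m.values[:, j], ref.mean_log2[:, 0], atol=1e-9)

    def test_exact_group_difference_without_jitter(self, reference_profiles):
        m, sheet, truth = generate_cohort(
            reference_profiles, tph_fraction_resp=0.05, tph_fraction_nonresp=0.15,
            tph_jitter=0.0, seed=4,
        )
        resp = [truth.fractions[s]["TPH"] for s in sheet.samples_where(responder=True)]
        non = [truth.fractions[s]["TPH"] for s in sheet.samples_where(responder=False)]
        assert np.mean(non) - np.mean(resp) == pytest.approx(0.10, abs=1e-12)

    def test_mixture_consistency_linear_scale(self, reference_profiles):
        # noise-free, no batch: linear expression equals the weighted sum
        # of linear reference profiles
        ref = reference_profiles
        m, sheet, truth = generate_cohort(ref, noise_sd=0.0, n_de_genes=0, seed=5)
        linear_ref = np.exp2(ref.mean_log2)
        for s in m.samples:
            w = np.array([truth.fractions[s][t] for t in ref.cell_types])
            np.testing.assert_allclose(
                np.exp2(m.column(s)), linear_ref @ w, rtol=1e-9, atol=1e-9
            )

    def test_fractions_sum_to_one(self, cohort):
        _, _, truth = cohort
        for f in truth.fractions.values():
            assert sum(f.values()) == pytest.approx(1.0, abs=1e-9)

    def test_determinism(self, reference_profiles):
        a = generate_cohort(reference_profiles, seed=9)
        b = generate_cohort(reference_profiles, seed=9)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        assert a[1] == b[1]
        assert a[2].fractions == b[2].fractions

    def test_paired_design(self, cohort):
        _, sheet, _ = cohort
        assert len(sheet.paired_patients()) == 11
        assert len(sheet) == 22

    def test_batch_shift_applied(self, reference_profiles):
        shifts = {"b1": 0.0, "b2": 1.0}
        m, sheet, truth = generate_cohort(
            reference_profiles, noise_sd=0.0, n_de_genes=0, tph_jitter=0.0,
            batches=shifts, seed=6,
        )
        assert truth.batch_shifts == shifts
        batches = sheet.batches()
        b1 = [s for s in m.samples if batches[s] == "b1"]
        b2 = [s for s in m.samples if batches[s] == "b2"]
        assert b1 and b2
        # round-robin balances patients across batches
        assert abs(len(b1) - len(b2)) <= 2

    def test_de_effect_planted_both_timepoints(self, reference_profiles):
        m, sheet, truth = generate_cohort(
            reference_profiles, noise_sd=0.0, tph_jitter=0.0, n_de_genes=10,
            de_effect=1.5, seed=8,
        )
        gi = {g: i for i, g in enumerate(m.genes)}
        resp = sheet.samples_where(responder=True)
        non = sheet.samples_where(responder=False)
        for g in truth.de_genes_up_resp:
            diff = (
                m.values[gi[g], [m.sample_index(s) for s in resp]].mean()
                - m.values[gi[g], [m.sample_index(s) for s in non]].mean()
            )
            assert diff == pytest.approx(1.5, abs=0.15)  # mixture noise only

    def test_invalid_args(self, reference_profiles):
        with pytest.raises(ValueError, match="noise_sd"):
            generate_cohort(reference_profiles, noise_sd=-1, seed=0)
        with pytest.raises(ValueError, match="tph_fraction_resp"):
            generate_cohort(reference_profiles, tph_fraction_resp=1.5, seed=0)


class TestGoAnnotation:
    def test_planted_overlap_exact(self):
        genes = [f"G{i}" for i in range(200)]
        de = frozenset(genes[:20])
        ann, planted = generate_go_annotation(
            genes, n_terms=5, planted=[PlantedTerm("p", de, size=10, overlap_fraction=0.8)],
            seed=1,
        )
        members = ann.genes_of(planted[0])
        assert len(members) == 10
        assert len(members & de) == 8

    def test_zero_terms(self):
        genes = [f"G{i}" for i in range(50)]
        ann, planted = generate_go_annotation(genes, n_terms=0, seed=0)
        assert len(ann) == 0
        assert planted == ()

    def test_determinism(self):
        genes = [f"G{i}" for i in range(100)]
        a, _ = generate_go_annotation(genes, n_terms=10, seed=5)
        b, _ = generate_go_annotation(genes, n_terms=10, seed=5)
        assert dict(a.terms) == dict(b.terms)

    def test_infeasible_planting(self):
        genes = [f"G{i}" for i in range(30)]
        with pytest.raises(ValueError, match="cannot draw"):
            generate_go_annotation(
                genes, n_terms=0, term_size_range=(5, 20),
                planted=[PlantedTerm("p", frozenset(genes[:2]), size=10, overlap_fraction=0.8)],
                seed=0,
            )

    def test_oversized_terms_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            generate_go_annotation([f"G{i}" for i in range(10)], term_size_range=(5, 50), seed=0)


class TestQpcr:
    def test_linear_map(self, cohort):
        m, _, _ = cohort
        table = generate_qpcr(
            m, target_genes=[m.genes[5]], endogenous_gene=m.genes[0],
            slope=-1.0, intercept=30.0, noise_sd=0.0, seed=1,
        )
        s = m.samples[0]
        expected = 30.0 - m.values[5, 0]
        assert table.ct(s, m.genes[5]) == pytest.approx(expected, abs=1e-12)

    def test_determinism(self, cohort):
        m, _, _ = cohort
        kwargs = dict(target_genes=[m.genes[3]], endogenous_gene=m.genes[0],
                      noise_sd=0.5, seed=9)
        assert generate_qpcr(m, **kwargs).rows == generate_qpcr(m, **kwargs).rows

    def test_missing_gene(self, cohort):
        m, _, _ = cohort
        with pytest.raises(KeyError, match="NOPE"):
            generate_qpcr(m, target_genes=["NOPE"], endogenous_gene=m.genes[0], seed=0)

    def test_positive_slope_rejected(self, cohort):
        m, _, _ = cohort
        with pytest.raises(ValueError, match="negative"):
            generate_qpcr(m, target_genes=[m.genes[1]], endogenous_gene=m.genes[0],
                          slope=1.0, seed=0)


def test_scale_is_log2(cohort):
    assert cohort[0].scale == Scale.log2
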
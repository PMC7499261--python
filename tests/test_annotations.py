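import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from stratld import (Annotation, AnnotationMatrix, RegionSet,
                     aggregate_across_tissues, allelic_effect,
                     gene_score_to_snp_annotation, local_content,
                     quantile_match, restrict_to_regions)
from stratld.annotations import AnnotationError

from conftest import toy_panel


class TestAggregation:
    def test_definitional_values(self):
        panel = toy_panel(1)
        mat = AnnotationMatrix(panel, [
            Annotation("t1", [0.0], "probabilistic"),
            Annotation("t2", [1.0], "probabilistic")])
        assert aggregate_across_tissues(mat, "max").values[0] == 1.0
        assert aggregate_across_tissues(mat, "avg").values[0] == 0.5
        equal = AnnotationMatrix(panel, [
            Annotation(f"t{i}", [0.2], "probabilistic") for i in range(3)])
        assert aggregate_across_tissues(equal, "avg").values[0] == pytest.approx(0.2)

    def test_max_dominates_avg_pointwise(self, prob_matrix):
        mx = aggregate_across_tissues(prob_matrix, "max")
        av = aggregate_across_tissues(prob_matrix, "avg")
        assert np.all(mx.values >= av.values)
        assert len(mx.values) == prob_matrix.panel.m

    def test_idempotent_on_single_tissue(self, prob_matrix):
        single = prob_matrix.subset(["tissue0"])
        for method in ("avg", "max"):
            out = aggregate_across_tissues(single, method)
            np.testing.assert_array_equal(out.values, single["tissue0"].values)

    def test_errors(self, prob_matrix):
        with pytest.raises(AnnotationError):
            aggregate_across_tissues(AnnotationMatrix(toy_panel(3)), "avg")
        bad = AnnotationMatrix(toy_panel(3),
                               [Annotation("c", [2.0, -1.0, 0.0], "continuous")])
        with pytest.raises(AnnotationError, match="probabilistic"):
            aggregate_across_tissues(bad, "avg")


class TestQuantileMatch:
    def test_identity_and_rank_mapping(self):
        src = Annotation("s", [0.1, 5.0, 3.0], "continuous")
        ref = Annotation("r", [0.2, 0.9, 0.5], "probabilistic")
        out = quantile_match(src, ref)
        np.testing.assert_allclose(out.values, [0.2, 0.9, 0.5])
        self_matched = quantile_match(src, src)
        np.testing.assert_allclose(self_matched.values, src.values)

    def test_sorted_output_equals_sorted_reference(self, rng):
        src = Annotation("s", rng.normal(size=200), "continuous")
        ref = Annotation("r", rng.uniform(0, 1, 200), "probabilistic")
        out = quantile_match(src, ref)
        np.testing.assert_allclose(np.sort(out.values), np.sort(ref.values))
        assert out.values.min() >= 0 and out.values.max() <= 1
        rho = stats.spearmanr(src.values, out.values).statistic
        assert rho == pytest.approx(1.0)

    def test_constant_source_error(self):
        src = Annotation("flat", np.ones(5), "continuous")
        ref = Annotation("r", np.arange(5.0), "continuous")
        with pytest.raises(AnnotationError, match="flat"):
            quantile_match(src, ref)

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=40,
                    unique=True))
    def test_monotone_property(self, values):
        src = Annotation("s", values, "continuous")
        ref = Annotation("r", np.linspace(0, 1, len(values)), "probabilistic")
        out = quantile_match(src, ref)
        order = np.argsort(src.values)
        assert np.all(np.diff(out.values[order]) >= 0)
        np.testing.assert_allclose(np.sort(out.values), np.sort(ref.values))


class TestAllelicEffect:
    def test_values_and_symmetry(self):
        ref = Annotation("ref", [0.8, 0.5, 0.3], "probabilistic")
        alt = Annotation("alt", [0.3, 0.5, 0.9], "probabilistic")
        out = allelic_effect(ref, alt)
        np.testing.assert_allclose(out.values, [0.5, 0.0, 0.6])
        swapped = allelic_effect(alt, ref)
        np.testing.assert_array_equal(out.values, swapped.values)
        assert out.kind == "probabilistic"
        zero = allelic_effect(ref, ref)
        assert zero.size == 0.0

    def test_size_is_mean_absolute_difference(self, rng):
        a = Annotation("a", rng.uniform(0, 1, 100), "probabilistic")
        b = Annotation("b", rng.uniform(0, 1, 100), "probabilistic")
        out = allelic_effect(a, b)
        assert out.size == pytest.approx(np.abs(a.values - b.values).mean())

    def test_panel_mismatch(self):
        a = Annotation("a", [0.1, 0.2], "probabilistic")
        b = Annotation("b", [0.1], "probabilistic")
        with pytest.raises(AnnotationError):
            allelic_effect(a, b)


class TestRegions:
    def test_boundary_convention(self):
        # 1-based half-open [100, 200) == 0-based [99, 199): SNPs at
        # positions 100 and 150 retained, 200 zeroed
        panel = toy_panel(3, spacing=50, start=100)  # pos 100, 150, 200
        ann = Annotation("a", [1.0, 1.0, 1.0], "binary")
        regions = RegionSet(pd.DataFrame(
            {"chrom": ["chr1"], "start": [99], "end": [199]}), "toy")
        out = restrict_to_regions(ann, regions, panel)
        np.testing.assert_array_equal(out.values, [1.0, 1.0, 0.0])

    def test_identity_empty_and_monotone(self, rng):
        panel = toy_panel(20)
        ann = Annotation("a", rng.uniform(0, 1, 20), "probabilistic")
        everywhere = RegionSet(pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [10**6]}), "all")
        np.testing.assert_array_equal(
            restrict_to_regions(ann, everywhere, panel).values, ann.values)
        empty = RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]))
        assert restrict_to_regions(ann, empty, panel).size == 0.0
        half = RegionSet(pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [int(panel.pos[9])]}),
            "half")
        restricted = restrict_to_regions(ann, half, panel)
        assert restricted.size <= ann.size
        # superset composition is a no-op
        again = restrict_to_regions(restricted, everywhere, panel)
        np.testing.assert_array_equal(again.values, restricted.values)

    def test_merge_overlapping(self):
        regions = RegionSet(pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 50], "end": [60, 100]}))
        assert len(regions) == 1
        assert regions.intervals.iloc[0]["end"] == 100


class TestLocalContent:
    def _source(self, seq):
        return {"chr1": seq}

    def test_zero_and_saturated(self):
        panel = toy_panel(1, start=11)
        allA = local_content(self._source("A" * 25), panel, 5, "gc")
        assert allA.values[0] == 0.0
        assert local_content(self._source("A" * 25), panel, 5, "cpg").values[0] == 0.0
        cg = local_content(self._source("CG" * 13), panel, 5, "gc")
        assert cg.values[0] == 1.0

    def test_toy_window_oracle(self):
        seq = "ACGTACGTACGTACGTACGT"  # 20 bp, SNP centred so window == seq
        panel = toy_panel(1, start=10)
        gc = local_content(self._source(seq), panel, 10, "gc")
        cpg = local_content(self._source(seq), panel, 10, "cpg")
        # enumeration oracle on the exact window the annotation saw
        start = panel.pos[0] - 1 - 10
        window = seq[max(0, start):panel.pos[0] - 1 + 11]
        gc_expected = sum(ch in "GC" for ch in window) / len(window)
        cpg_expected = sum(window[i:i + 2] == "CG"
                           for i in range(len(window) - 1)) / (len(window) - 1)
        assert gc.values[0] == pytest.approx(gc_expected)
        assert cpg.values[0] == pytest.approx(cpg_expected)
        assert gc_expected == pytest.approx(0.5)

    def test_gc_size_dominates_cpg(self, rng):
        bases = rng.choice(list("ACGT"), size=4000)
        seq = "".join(bases)
        panel = toy_panel(10, spacing=300, start=500)
        gc = local_content(self._source(seq), panel, 100, "gc")
        cpg = local_content(self._source(seq), panel, 100, "cpg")
        assert gc.size >= cpg.size

    def test_missing_chromosome(self):
        panel = toy_panel(1)
        with pytest.raises(AnnotationError, match="chr1"):
            local_content({"chr2": "ACGT"}, panel, 2, "gc")

    def test_n_bases_excluded(self):
        panel = toy_panel(1, start=3)
        ann = local_content(self._source("NNGCN"), panel, 2, "gc")
        assert ann.values[0] == 1.0  # only G and C are countable


class TestGeneScores:
    def test_window_and_overlap_rule(self):
        panel = toy_panel(3, spacing=1000, start=1000)  # pos 1000,2000,3000
        genes = pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [900, 1500], "end": [1100, 2600],
            "score": [0.2, 0.9]})
        out = gene_score_to_snp_annotation(genes, panel, window_bp=0)
        np.testing.assert_allclose(out.values, [0.2, 0.9, 0.0])
        # widen windows so gene 1 covers SNP 1 as well -> max rule
        out2 = gene_score_to_snp_annotation(genes, panel, window_bp=1000)
        assert out2.values[0] == pytest.approx(0.9)

    def test_nonfinite_score(self):
        panel = toy_panel(1)
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10],
                              "score": [np.nan]})
        with pytest.raises(AnnotationError):
            gene_score_to_snp_annotation(genes, panel, 0)
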
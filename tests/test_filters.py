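"""Filter I/II/IV behavior, thresholds and oracle equivalence."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_random_config, make_random_table
from oracles import brute_filter_one
from gprior.filters import (
    FilterConfig,
    cadd_percentile_to_threshold,
    filter_four,
    filter_one,
    filter_two,
    is_private,
)
from gprior.genelists import GeneListCollection
from gprior.varmodel import Annotation, CohortTable, GenotypeCall, VariantRecord


def _variant(annotations, genotypes, **kw):
    defaults = dict(chrom="chr1", pos=100, ref="A", alt="T", qual=60.0, site_depth=40)
    defaults.update(kw)
    return VariantRecord(**defaults, annotations=annotations, genotypes=genotypes)


def _table(variants, samples=("S1", "S2")):
    return CohortTable(samples=list(samples), variants=variants)


class TestCaddPercentileConvention:
    def test_closed_form_values(self):
        assert cadd_percentile_to_threshold(90.0) == pytest.approx(10.0)
        assert cadd_percentile_to_threshold(99.0) == pytest.approx(20.0)
        # a variant in the 99.8th percentile has scaled score ~27
        assert cadd_percentile_to_threshold(99.8) == pytest.approx(26.99, abs=0.01)

    @pytest.mark.parametrize("bad", [0.0, 100.0, -5.0, 120.0])
    def test_out_of_range_percentile_raises(self, bad):
        with pytest.raises(ValueError):
            cadd_percentile_to_threshold(bad)


class TestIsPrivate:
    def _rec(self, ref_afs):
        ann = Annotation("G1", "G1.t1", "MODERATE", ref_afs=ref_afs)
        return _variant([ann], [GenotypeCall("S1", 1), GenotypeCall("S2", 0)])

    def test_observed_in_one_set_is_not_private(self):
        assert not is_private(self._rec({"gnomAD": 0.001}))

    def test_absent_everywhere_is_private(self):
        assert is_private(self._rec({}))

    def test_zero_frequency_counts_as_unobserved(self):
        assert is_private(self._rec({"gnomAD": 0.0}))

    def test_matches_brute_force_on_random_table(self):
        from oracles import brute_is_private

        rng = np.random.default_rng(5)
        table, _, _ = make_random_table(rng, 200, 4)
        for rec in table.variants:
            assert is_private(rec) == brute_is_private(rec)


class TestFilterOne:
    LISTS = GeneListCollection.from_dict(
        {"l1": {"LISTED"}, "l2": {"LISTED"}, "l3": {"OTHER"}}
    )

    def _run(self, ann_kw, lists=None, dosage=1, config=None):
        ann = Annotation("GENE1", "GENE1.t1", **ann_kw)
        rec = _variant([ann], [GenotypeCall("S1", dosage), GenotypeCall("S2", 0)])
        return filter_one(_table([rec]), lists or self.LISTS, config or FilterConfig())

    def test_score_clause_on_constrained_gene(self):
        # moderate impact, rare everywhere, 99.8th-percentile score, pLI 0.999
        hits = self._run(
            dict(
                impact="MODERATE",
                cadd_scaled=27.0,
                pli=0.999,
                ref_afs={"1000G": 0.0002, "gnomAD": 4.7e-05},
            )
        )
        assert len(hits) == 1
        assert hits[0].criterion == "score"
        assert hits[0].sample_id == "S1"

    def test_low_impact_never_hits(self):
        hits = self._run(
            dict(impact="LOW", cadd_scaled=35.0, pli=0.999, ref_afs={})
        )
        assert hits == []

    def test_af_at_threshold_fails(self):
        # the frequency clause is strict: 0.05 is not < 0.05
        hits = self._run(
            dict(impact="MODERATE", cadd_scaled=27.0, pli=0.999,
                 ref_afs={"gnomAD": 0.05})
        )
        assert hits == []

    def test_af_above_threshold_fails(self):
        hits = self._run(
            dict(impact="HIGH", cadd_scaled=27.0, pli=0.999,
                 ref_afs={"gnomAD": 0.06})
        )
        assert hits == []

    def test_absent_reference_entries_pass(self):
        hits = self._run(
            dict(impact="HIGH", cadd_scaled=27.0, pli=0.999, ref_afs={})
        )
        assert len(hits) == 1
        assert hits[0].private

    def test_list_clause_and_criterion_both(self):
        ann = Annotation(
            "LISTED", "LISTED.t1", "MODERATE", cadd_scaled=3.0, pli=0.2
        )
        rec = _variant([ann], [GenotypeCall("S1", 1), GenotypeCall("S2", 0)])
        hits = filter_one(_table([rec]), self.LISTS, FilterConfig())
        assert len(hits) == 1 and hits[0].criterion == "list"

        ann2 = Annotation(
            "LISTED", "LISTED.t1", "MODERATE", cadd_scaled=27.0, pli=0.999
        )
        rec2 = _variant([ann2], [GenotypeCall("S1", 1), GenotypeCall("S2", 0)])
        hits2 = filter_one(_table([rec2]), self.LISTS, FilterConfig())
        assert hits2[0].criterion == "both"

    def test_absent_scores_cannot_satisfy_score_clause(self):
        for kw in (dict(cadd_scaled=None, pli=0.999), dict(cadd_scaled=27.0, pli=None)):
            hits = self._run(dict(impact="HIGH", ref_afs={}, **kw))
            assert hits == []

    def test_missing_genotype_is_not_a_carrier(self):
        ann = Annotation("GENE1", "GENE1.t1", "HIGH", cadd_scaled=27.0, pli=0.999)
        rec = _variant(
            [ann],
            [GenotypeCall("S1", 0, missing=True), GenotypeCall("S2", 0)],
        )
        assert filter_one(_table([rec]), self.LISTS, FilterConfig()) == []

    def test_hemizygous_carrier_counts(self):
        ann = Annotation("GENE1", "GENE1.t1", "HIGH", cadd_scaled=27.0, pli=0.999)
        rec = _variant(
            [ann], [GenotypeCall("S1", 1, ploidy=1), GenotypeCall("S2", 0)]
        )
        hits = filter_one(_table([rec]), self.LISTS, FilterConfig())
        assert [h.sample_id for h in hits] == ["S1"]

    def test_qualifying_transcripts_cover_all_damaging_annotations(self):
        anns = [
            Annotation("GENE1", "GENE1.t1", "HIGH", cadd_scaled=27.0, pli=0.999),
            Annotation("GENE1", "GENE1.t2", "MODERATE", cadd_scaled=5.0, pli=0.999),
            Annotation("GENE1", "GENE1.t3", "MODIFIER", cadd_scaled=27.0, pli=0.999),
        ]
        rec = _variant(anns, [GenotypeCall("S1", 1), GenotypeCall("S2", 0)])
        hits = filter_one(_table([rec]), self.LISTS, FilterConfig())
        assert hits[0].qualifying_transcripts == ("GENE1.t1", "GENE1.t2")

    def test_permuting_records_permutes_but_preserves_hit_set(self):
        rng = np.random.default_rng(17)
        table, lists, _ = make_random_table(rng, 120, 5)
        config = FilterConfig()
        forward = filter_one(table, lists, config)
        reversed_table = CohortTable(
            samples=table.samples, variants=list(reversed(table.variants))
        )
        backward = filter_one(reversed_table, lists, config)
        as_set = lambda hits: {(h.variant.key, h.sample_id, h.gene_symbol) for h in hits}
        assert as_set(forward) == as_set(backward)

    def test_oracle_equivalence_on_random_table(self):
        rng = np.random.default_rng(23)
        table, lists, _ = make_random_table(rng, 500, 8)
        config = make_random_config(rng, 8)
        hits = filter_one(table, lists, config)
        got = {(h.variant.key, h.sample_id, h.gene_symbol) for h in hits}
        assert got == brute_filter_one(table, lists, config)


def _make_hits(gene_counts):
    """Hits with the requested number of occurrences per gene."""
    from gprior.filters import Hit

    hits = []
    for gene, n in gene_counts.items():
        for i in range(n):
            rec = _variant(
                [Annotation(gene, f"{gene}.t1", "HIGH", cadd_scaled=27.0, pli=0.99)],
                [GenotypeCall("S1", 1), GenotypeCall("S2", 0)],
                pos=100 + i,
            )
            hits.append(Hit(rec, "S1", gene, (f"{gene}.t1",), "score", False, 30))
    return hits


class TestFilterTwo:
    def test_six_hits_all_removed(self):
        result = filter_two(_make_hits({"G1": 6}), FilterConfig())
        assert result.hits == []
        assert result.removed_genes == {"G1": 6}

    def test_exactly_five_hits_kept(self):
        # the cap is strict: > 5 removes, == 5 survives
        result = filter_two(_make_hits({"G1": 5}), FilterConfig())
        assert len(result.hits) == 5
        assert result.removed_genes == {}

    def test_infinite_cap_is_identity(self):
        hits = _make_hits({"G1": 8, "G2": 3})
        result = filter_two(hits, FilterConfig(max_hits_per_gene=10**9))
        assert result.hits == hits

    def test_variant_counting_unit(self):
        # 6 occurrences of 3 unique variants: removed in occurrence mode,
        # kept when counting unique variants per gene
        from gprior.filters import Hit

        hits = []
        for i in range(3):
            rec = _variant(
                [Annotation("G1", "G1.t1", "HIGH", cadd_scaled=27.0, pli=0.99)],
                [GenotypeCall("S1", 1), GenotypeCall("S2", 1)],
                pos=100 + i,
            )
            for s in ("S1", "S2"):
                hits.append(Hit(rec, s, "G1", ("G1.t1",), "score", False, 30))
        assert filter_two(hits, FilterConfig()).hits == []
        kept = filter_two(hits, FilterConfig(filter2_unit="variant"))
        assert len(kept.hits) == 6

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(3)
        counts = {f"G{i}": int(rng.integers(1, 9)) for i in range(12)}
        hits = _make_hits(counts)
        result = filter_two(hits, FilterConfig(max_hits_per_gene=4))
        assert set(id(h) for h in result.hits) <= set(id(h) for h in hits)


class TestFilterFour:
    @staticmethod
    def _hit(private, depth, pos):
        from gprior.filters import Hit

        ref_afs = {} if private else {"gnomAD": 0.001}
        rec = _variant(
            [Annotation("G1", "G1.t1", "HIGH", cadd_scaled=27.0, pli=0.99,
                        ref_afs=ref_afs)],
            [GenotypeCall("S1", 1, 2, depth), GenotypeCall("S2", 0)],
            pos=pos,
        )
        return Hit(rec, "S1", "G1", ("G1.t1",), "score", private, depth)

    def test_private_below_range_removed(self):
        hits = [self._hit(False, 18, 1), self._hit(False, 42, 2), self._hit(True, 7, 3)]
        result = filter_four(hits)
        assert result.depth_range == (18, 42)
        assert [h.depth for h in result.removed] == [7]

    def test_private_inside_closed_range_kept(self):
        hits = [self._hit(False, 18, 1), self._hit(False, 42, 2),
                self._hit(True, 30, 3), self._hit(True, 18, 4)]
        result = filter_four(hits)
        assert len(result.hits) == 4

    def test_no_private_hits_is_identity(self):
        hits = [self._hit(False, 18, 1), self._hit(False, 42, 2)]
        result = filter_four(hits)
        assert result.hits == hits and result.removed == []

    def test_no_nonprivate_hits_passes_through_with_no_range(self):
        hits = [self._hit(True, 5, 1), self._hit(True, 90, 2)]
        result = filter_four(hits)
        assert result.hits == hits
        assert result.depth_range is None


class TestFilterConfig:
    def test_yaml_round_trip_is_lossless(self, tmp_path):
        config = FilterConfig(af_threshold=0.01, replicates=50, seed=7)
        path = tmp_path / "config.yaml"
        config.to_yaml(path)
        assert FilterConfig.from_yaml(path) == config

    @pytest.mark.parametrize(
        "kw",
        [
            {"af_threshold": 1.5},
            {"cadd_percentile": 100.0},
            {"pli_threshold": -0.1},
            {"min_list_membership": 0},
            {"max_hits_per_gene": 0},
            {"seed": -1},
            {"cadd_mode": "nope"},
        ],
    )
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ValueError):
            FilterConfig(**kw)
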
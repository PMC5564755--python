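"""Filter-cascade behaviour: boundaries, aggregation, ordering properties."""

import dataclasses
import warnings

import pytest
from scipy.stats import binom

from fusionnominate import filters, io
from fusionnominate.io import FusionCall
from fusionnominate.stats import DetectionContingency


def make_call(sample="S1", g5="A", g3="B", disc=7, split=7, mm=0, tot=None, prob=0.9):
    return FusionCall(
        sample_id=sample, gene5=g5, gene3=g3, chrom5="1", chrom3="1",
        breakpoint5=100, breakpoint3=200, strand5="+", strand3="+",
        discordant_pairs=disc, split_reads=split, multimap_spanning=mm,
        total_spanning=tot if tot is not None else disc, probability=prob,
    )


def tiny_manifest(n_pairs=3):
    samples = []
    for i in range(1, n_pairs + 1):
        samples.append(io.ManifestSample(f"T{i}", "tumor", f"P{i}", 10**7))
        samples.append(io.ManifestSample(f"B{i}", "benign", f"P{i}", 10**7))
    return io.CohortManifest(samples=samples)


T = filters.FilterThresholds()


class TestInitialCriteria:
    @pytest.mark.parametrize("disc,split,prob,expected", [
        (5, 1, 0.05, True),    # all boundaries inclusive
        (4, 10, 0.99, False),  # one discordant pair short
        (7, 7, 0.9, True),
        (5, 0, 0.99, False),
        (5, 1, 0.049, False),
    ])
    def test_boundaries(self, disc, split, prob, expected):
        call = make_call(disc=disc, split=split, prob=prob)
        assert filters.call_passes_initial(call, T) is expected


class TestAggregation:
    def test_idempotent_and_keeps_best_split(self):
        man = tiny_manifest()
        m = filters.aggregate_gene_pairs(
            [make_call(sample="T1", split=3), make_call(sample="T1", split=9, mm=2, tot=12)],
            man, T)
        assert m.positive_samples(("A", "B")) == ["T1"]
        sup = m.support(("A", "B"), "T1")
        assert sup.split_reads == 9 and sup.total_spanning == 12

    def test_unknown_sample_rejected(self):
        with pytest.raises(io.ValidationError, match="absent from manifest"):
            filters.aggregate_gene_pairs([make_call(sample="ghost")], tiny_manifest(), T)

    def test_benign_only_pair_has_zero_tumor_count(self):
        man = tiny_manifest()
        m = filters.aggregate_gene_pairs([make_call(sample="B1")], man, T)
        assert m.tumor_positive_count(("A", "B")) == 0
        assert m.benign_positive_count(("A", "B")) == 1

    def test_reciprocal_orientations_are_distinct_pairs(self):
        man = tiny_manifest()
        m = filters.aggregate_gene_pairs(
            [make_call(sample="T1", g5="A", g3="B"),
             make_call(sample="T1", g5="B", g3="A")], man, T)
        assert set(m.pairs) == {("A", "B"), ("B", "A")}

    def test_planted_detection_count_within_binomial_interval(self, cohort, cascade_result):
        """Bernoulli planting at rate 0.6 over 94 tumors lands in the 99% interval."""
        _, truth = cohort
        m = cascade_result.matrix
        n_tumors = 94
        lo, hi = binom.ppf([0.005, 0.995], n_tumors, 0.6)
        for pair, pf in truth.planted.items():
            assert lo <= m.tumor_positive_count(pair) <= hi


class TestSingleFilters:
    def test_recurrence_boundary_inclusive(self):
        man = tiny_manifest(6)
        calls5 = [make_call(sample=f"T{i}") for i in range(1, 6)]
        m = filters.aggregate_gene_pairs(calls5, man, T)
        kept, removed = filters.recurrence_filter(m, T)
        assert kept == [("A", "B")] and not removed

        m4 = filters.aggregate_gene_pairs(calls5[:4], man, T)
        kept, removed = filters.recurrence_filter(m4, T)
        assert not kept and "recurrence" in removed[("A", "B")]

    @pytest.mark.parametrize("mm,tot,ratio,removed", [
        (0, 50, 0.0, False),
        (40, 50, 0.8, True),
        (30, 50, 0.6, False),  # removal is strictly greater than the cutoff
    ])
    def test_multimap_ratio_boundary(self, mm, tot, ratio, removed):
        man = tiny_manifest()
        m = filters.aggregate_gene_pairs(
            [make_call(sample="T1", mm=mm, tot=tot, disc=tot)], man, T)
        r = filters.multimap_ratio(m, ("A", "B"))
        assert r == pytest.approx(ratio)
        assert (r > T.max_multimap_ratio) is removed

    def test_multimap_zero_total_warns(self):
        man = tiny_manifest()
        m = filters.aggregate_gene_pairs([make_call(sample="T1", tot=0, mm=0)], man, T)
        with pytest.warns(UserWarning, match="zero total"):
            assert filters.multimap_ratio(m, ("A", "B")) == 0.0

    def test_biotype_and_overlap_rules(self):
        genes = {
            "PC1": io.GeneModel("PC1", "PC1", "1", "+", 100, 500, "protein_coding"),
            "LINC": io.GeneModel("LINC", "LINC", "1", "+", 800, 900, "lincRNA"),
            "PSE": io.GeneModel("PSE", "PSE", "1", "+", 2000, 2500, "processed_pseudogene"),
            "NEST": io.GeneModel("NEST", "NEST", "1", "+", 200, 400, "protein_coding"),
        }
        db = io.AnnotationDB(genes, {})
        assert filters.biotype_overlap_filter(("PC1", "LINC"), db, T) == (True, None)
        keep, reason = filters.biotype_overlap_filter(("PC1", "PSE"), db, T)
        assert not keep and "pseudogene" in reason
        keep, reason = filters.biotype_overlap_filter(("PC1", "NEST"), db, T)
        assert not keep and "overlap" in reason
        keep, reason = filters.biotype_overlap_filter(("PC1", "GHOST"), db, T)
        assert not keep and "unannotated" in reason


class TestCascade:
    def test_empty_call_set(self):
        res = filters.run_cascade([], tiny_manifest(), None)
        assert res.records == []
        assert all(e.n_after == 0 for e in res.log.entries)

    def test_log_monotone_and_reasons_unique(self, cascade_result):
        res = cascade_result
        assert res.log.is_monotone()
        survivors = set(res.surviving_pairs)
        assert survivors.isdisjoint(res.removed)
        # each removed pair carries exactly one reason; survivors none
        assert all(isinstance(r, str) and r for r in res.removed.values())

    def test_planted_fusions_survive_artifact_removed(self, cohort, cascade_result):
        _, truth = cohort
        res = cascade_result
        survivors = set(res.surviving_pairs)
        enriched = {p for p, c in truth.categories.items() if c == "enriched"}
        artifact = {p for p, c in truth.categories.items() if c == "artifact"}
        assert enriched <= survivors
        for p in artifact:
            assert p not in survivors
            assert res.removed[p].startswith("multimap")

    def test_relaxing_filters_gives_superset(self, cohort_inputs, cascade_result):
        """Disabling any stage can only grow the survivor set."""
        calls, manifest, db = cohort_inputs
        tight = set(cascade_result.surviving_pairs)
        relaxed_thresholds = [
            dataclasses.replace(T, min_tumor_samples=1),
            dataclasses.replace(T, alpha=0.999999),
            dataclasses.replace(T, max_multimap_ratio=1.0),
            dataclasses.replace(T, allowed_biotypes=frozenset(
                {"protein_coding", "lincRNA", "miRNA", "processed_pseudogene"})),
        ]
        for t in relaxed_thresholds:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                loose = set(filters.run_cascade(calls, manifest, db, t).surviving_pairs)
            assert tight <= loose

    def test_multimap_and_biotype_filters_commute(self, cohort_inputs, cascade_result):
        calls, manifest, db = cohort_inputs
        m = cascade_result.matrix
        pairs = m.pairs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mm_pass = {p for p in pairs
                       if filters.multimap_ratio(m, p) <= T.max_multimap_ratio}
        bio_pass = {p for p in pairs if filters.biotype_overlap_filter(p, db, T)[0]}
        order_a = {p for p in pairs if p in mm_pass and p in bio_pass}
        order_b = {p for p in pairs if p in bio_pass and p in mm_pass}
        assert order_a == order_b

    def test_alpha_near_one_disables_statistical_stages(self, cohort_inputs):
        calls, manifest, db = cohort_inputs
        t = dataclasses.replace(T, alpha=0.999999)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = filters.run_cascade(calls, manifest, db, t)
        stages = {e.stage: e for e in res.log.entries}
        # only degenerate pairs (p == 1.0 exactly, i.e. no paired-tumor
        # positives) can still fall at the enrichment stage under p < alpha
        enrichment_removed = [p for p, r in res.removed.items()
                              if r.startswith("enrichment")]
        assert all(res.matrix.contingency(p).a == 0 for p in enrichment_removed)
        overexpr_removed = [r for r in res.removed.values()
                            if r.startswith("overexpression")]
        assert all("p=1 " in r for r in overexpr_removed)
        assert stages["biotype_overlap"] is res.log.entries[-1]


class TestThresholdValidation:
    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            filters.FilterThresholds(alpha=0.0)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filters.FilterThresholds(min_tumor_samples=-1)


class TestContingencyFromMatrix:
    def test_paired_contingency_margins(self, cascade_result, cohort):
        _, truth = cohort
        m = cascade_result.matrix
        for pair in truth.planted:
            ct = m.contingency(pair)
            assert ct.n_tumor == 44 and ct.n_benign == 44
            assert ct == DetectionContingency(ct.a, 44 - ct.a, ct.c, 44 - ct.c)
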
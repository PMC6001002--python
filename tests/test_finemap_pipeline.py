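"""QC filter and four-step cascade: boundary semantics, per-step oracles,
commutativity, and planted-truth recovery."""
import numpy as np
import pytest

from recfine.consequence_annotator import Consequence, classify_variant
from recfine.errors import MissingAnnotationError
from recfine.finemap_pipeline import (
    QcParams,
    qc_filter,
    run_cascade,
    step1_unique_to_case,
    step2_homozygous,
    step3_impact_partition,
    step4_novelty,
)
from recfine.io_formats import KnownVariantCatalogue, VariantRecord, VariantTable


def rec(pos, gt=(1, 1), depth=10.0, call_rate=1.0, ref="A", alt="C", chrom="1"):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alts=(alt,),
                         genotypes=(gt,), mean_depth=depth, call_rate=call_rate)


def case_table(records):
    return VariantTable(["case"], records)


class TestQcFilter:
    @pytest.mark.parametrize("depth,call_rate,kept", [
        (2.0, 1.0, False),   # below depth band
        (3.0, 1.0, True),    # lower bound inclusive
        (25.0, 0.71, True),  # upper bound inclusive, call rate just above
        (25.01, 1.0, False),
        (10.0, 0.7, False),  # call-rate cut is strict
        (10.0, 0.701, True),
    ])
    def test_boundary_semantics(self, depth, call_rate, kept):
        table = case_table([rec(100, depth=depth, call_rate=call_rate)])
        assert (len(qc_filter(table, QcParams())) == 1) is kept

    def test_survivors_match_linear_scan(self):
        rng = np.random.default_rng(21)
        records = [
            rec(int(p), depth=round(float(d), 2), call_rate=round(float(c), 3))
            for p, d, c in zip(
                rng.choice(100_000, size=1000, replace=False) + 1,
                rng.uniform(0, 40, size=1000),
                rng.uniform(0.3, 1.0, size=1000),
            )
        ]
        table = case_table(records)
        params = QcParams()
        got = {r.pos for r in qc_filter(table, params)}
        expected = {
            r.pos
            for r in records
            if 3.0 <= r.mean_depth <= 25.0 and r.call_rate > 0.7
        }
        assert got == expected


class TestStep1:
    def make_controls(self, carriers):
        """Two-sample control table; ``carriers`` maps pos -> genotypes."""
        records = [
            VariantRecord(chrom="1", pos=pos, ref="A", alts=("C",),
                          genotypes=gts, mean_depth=10.0,
                          call_rate=sum(g != (None, None) for g in gts) / len(gts))
            for pos, gts in carriers.items()
        ]
        return VariantTable(["c1", "c2"], records)

    def test_control_carrier_removes_allele(self):
        case = case_table([rec(100, gt=(1, 1))])
        controls = self.make_controls({100: ((0, 1), (0, 0))})
        assert len(step1_unique_to_case(case, controls)) == 0

    def test_hom_ref_control_does_not_disqualify(self):
        case = case_table([rec(100, gt=(1, 1))])
        controls = self.make_controls({100: ((0, 0), (0, 0))})
        assert len(step1_unique_to_case(case, controls)) == 1

    def test_missing_control_counts_as_non_carrier(self):
        case = case_table([rec(100, gt=(1, 1))])
        controls = self.make_controls({100: ((None, None), (0, 0))})
        assert len(step1_unique_to_case(case, controls)) == 1

    def test_absent_site_is_unique(self):
        case = case_table([rec(53688583, gt=(1, 1), ref="C", alt="T")])
        controls = self.make_controls({100: ((0, 1), (0, 1))})
        out = step1_unique_to_case(case, controls)
        assert [r.pos for r in out] == [53688583]

    def test_matches_set_difference_oracle(self, small_cohort):
        """Survivors equal a brute-force set difference over every control
        genotype."""
        _, cohort = small_cohort
        got = {r.keys()[0] for r in step1_unique_to_case(cohort.case, cohort.controls)}
        control_alleles = set()
        for crec in cohort.controls.records:
            for gt in crec.genotypes:
                for a in gt:
                    if a is not None and a > 0:
                        control_alleles.add((crec.chrom, crec.pos, crec.alts[a - 1]))
        expected = set()
        for crec in cohort.case.records:
            a, b = crec.genotypes[0]
            alts = {x for x in (a, b) if x is not None and x > 0}
            for x in alts:
                if (crec.chrom, crec.pos, crec.alts[x - 1]) not in control_alleles:
                    expected.add(crec.keys()[0])
                    break
        assert got == expected


class TestStep2:
    def test_genotype_selection(self):
        table = case_table([
            rec(100, gt=(0, 1)),
            rec(200, gt=(1, 1)),
            rec(300, gt=(None, None)),
            rec(400, gt=(0, 0)),
        ])
        out = step2_homozygous(table, "case")
        assert [r.pos for r in out] == [200]

    def test_unknown_sample(self):
        with pytest.raises(LookupError):
            step2_homozygous(case_table([rec(1)]), "nope")

    def test_matches_genotype_scan_oracle(self, small_cohort):
        _, cohort = small_cohort
        out = step2_homozygous(cohort.case, "adw_case")
        expected = sum(
            1 for r in cohort.case.records
            if r.genotypes[0][0] is not None
            and r.genotypes[0][0] == r.genotypes[0][1] != 0
        )
        assert len(out) == expected


def cons_for(record, term):
    key = record.keys()[0]
    from recfine.consequence_annotator import impact_of

    return {key: [Consequence(key, "g", term, impact_of(term))]}


class TestStep3:
    def test_any_high_or_moderate_wins(self):
        r = rec(100)
        key = r.keys()[0]
        consequences = {
            key: [
                Consequence(key, "g", "downstream_gene_variant", "modifier"),
                Consequence(key, "g", "missense_variant", "moderate"),
            ]
        }
        hm, lm = step3_impact_partition(case_table([r]), consequences)
        assert len(hm) == 1 and len(lm) == 0

    def test_modifier_only_goes_low(self):
        r = rec(100)
        hm, lm = step3_impact_partition(case_table([r]), cons_for(r, "intron_variant"))
        assert len(hm) == 0 and len(lm) == 1

    def test_partition_law(self, table1):
        hm, lm = step3_impact_partition(table1.variants, table1.consequences)
        assert len(hm) + len(lm) == len(table1.variants)

    def test_unannotated_record_errors(self):
        with pytest.raises(MissingAnnotationError):
            step3_impact_partition(case_table([rec(100)]), {})


class TestStep4:
    def test_empty_catalogue_is_identity(self):
        table = case_table([rec(100), rec(200)])
        assert len(step4_novelty(table, KnownVariantCatalogue())) == 2

    def test_table1_leaves_single_candidate(self, table1):
        out = step4_novelty(table1.variants, table1.catalogue)
        assert [r.keys()[0] for r in out] == [("1", 53688583, "C", "T")]

    def test_matches_anti_join_oracle(self, small_cohort):
        _, cohort = small_cohort
        out = step4_novelty(cohort.case, cohort.catalogue)
        expected = {
            r.keys()[0]
            for r in cohort.case.records
            if r.keys()[0] not in cohort.catalogue.entries
        }
        assert {r.keys()[0] for r in out} == expected


class TestCascade:
    def test_table1_step3_step4_counts(self, table1):
        """The printed candidate table: 11 high/moderate rows, 10 catalogued
        exclusions, one final candidate."""
        hm, lm = step3_impact_partition(table1.variants, table1.consequences)
        assert len(hm) == 11 and len(lm) == 0
        final = step4_novelty(hm, table1.catalogue)
        assert len(final) == 1
        assert final.records[0].pos == 53688583

    def test_steps_1_and_2_commute(self, small_cohort):
        _, cohort = small_cohort
        a = step2_homozygous(
            step1_unique_to_case(cohort.case, cohort.controls), "adw_case"
        )
        b = step1_unique_to_case(
            step2_homozygous(cohort.case, "adw_case"), cohort.controls
        )
        assert [r.sort_key for r in a] == [r.sort_key for r in b]

    def test_planted_truth_recovery_and_trace(self, small_cohort):
        _, cohort = small_cohort
        candidates, low_novel, trace = run_cascade(
            cohort.case, cohort.controls, cohort.genes, cohort.reference,
            cohort.catalogue,
        )
        assert trace.final_candidates == [cohort.truth.causal_variant]
        # each step is a subset of its predecessor
        assert (trace.n_input >= trace.n_after_qc >= trace.n_unique
                >= trace.n_homozygous >= trace.n_high_moderate + trace.n_low_modifier
                >= trace.n_novel + trace.n_low_modifier_novel)
        assert trace.n_high_moderate + trace.n_low_modifier == trace.n_homozygous
        # low/modifier novel branch holds the QC-passing intergenic
        # case-unique homs
        qc_pass = {
            r.keys()[0] for r in cohort.case.records
            if 3.0 <= r.mean_depth <= 25.0 and r.call_rate > 0.7
        }
        expected_low = {
            k for k, label in cohort.truth.labels.items()
            if label == "case-unique-hom" and k in qc_pass
        }
        got_low = {r.keys()[0] for r in low_novel.records}
        assert expected_low <= got_low

    def test_final_set_equals_per_variant_predicate_oracle(self, small_cohort):
        """An independent per-variant test of all four predicates agrees
        with the composed cascade."""
        _, cohort = small_cohort
        candidates, _, _ = run_cascade(
            cohort.case, cohort.controls, cohort.genes, cohort.reference,
            cohort.catalogue,
        )
        control_alleles = set()
        for crec in cohort.controls.records:
            for gt in crec.genotypes:
                for a in gt:
                    if a is not None and a > 0:
                        control_alleles.add((crec.chrom, crec.pos, crec.alts[a - 1]))
        expected = set()
        for r in cohort.case.records:
            if not (3.0 <= r.mean_depth <= 25.0 and r.call_rate > 0.7):
                continue
            a, b = r.genotypes[0]
            if a is None or a != b or a == 0:
                continue
            key = (r.chrom, r.pos, r.ref, r.alts[a - 1])
            if (r.chrom, r.pos, r.alts[a - 1]) in control_alleles:
                continue
            if key in cohort.catalogue.entries:
                continue
            cons = classify_variant(r, cohort.genes, cohort.reference)
            if any(c.impact in ("high", "moderate") for c in cons):
                expected.add(key)
        assert {r.keys()[0] for r in candidates.records} == expected

    def test_case_mirroring_a_control_yields_nothing(self, small_cohort):
        """If the case carries only alleles a control also carries, no
        candidate survives step 1."""
        _, cohort = small_cohort
        mirrored = []
        for r in cohort.controls.records:
            gt = r.genotypes[0]
            if gt != (None, None) and (gt[0] or gt[1]):
                mirrored.append(
                    VariantRecord(chrom=r.chrom, pos=r.pos, ref=r.ref,
                                  alts=r.alts, genotypes=(gt,),
                                  mean_depth=10.0, call_rate=1.0)
                )
        case = VariantTable(["case"], mirrored)
        assert len(step1_unique_to_case(case, cohort.controls)) == 0
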
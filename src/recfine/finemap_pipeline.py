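"""Site QC and the four-step candidate-variant filtering cascade.

The cascade mirrors the standard recessive-trait fine-mapping design:

1. keep alleles present in the case and absent from every control,
2. keep sites where the case is homozygous for the unique alternate allele,
3. partition by consequence impact into a high/moderate branch (candidate
   protein-altering variants) and a low/modifier branch (non-coding),
4. screen both branches against a known-variant catalogue, keeping novel
   variants only.

Boundary semantics follow the published phrasing exactly: the depth window
is inclusive ("between 3 and 25") and the call-rate cut is strict ("> 0.7").
Missing control genotypes count as non-carriers — the call-rate filter
already bounds missingness.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .consequence_annotator import Consequence, classify_variant
from .errors import MissingAnnotationError, ValidationError
from .io_formats import (
    GeneModel,
    KnownVariantCatalogue,
    VariantKey,
    VariantTable,
)

__all__ = [
    "QcParams",
    "FilterTrace",
    "qc_filter",
    "step1_unique_to_case",
    "step2_homozygous",
    "step3_impact_partition",
    "step4_novelty",
    "run_cascade",
]


@dataclass
class QcParams:
    """Site-level QC window: depth band (inclusive) and call-rate cut
    (strict)."""

    depth_min: float = 3.0
    depth_max: float = 25.0
    min_call_rate: float = 0.7

    def __post_init__(self) -> None:
        if not self.depth_min < self.depth_max:
            raise ValidationError("depth_min must be < depth_max")
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValidationError("min_call_rate must be in [0, 1]")


@dataclass
class FilterTrace:
    """Per-step survivor counts — the cascade's audit trail."""

    n_input: int = 0
    n_after_qc: int = 0
    n_unique: int = 0
    n_homozygous: int = 0
    n_high_moderate: int = 0
    n_low_modifier: int = 0
    n_novel: int = 0
    n_low_modifier_novel: int = 0
    final_candidates: List[VariantKey] = field(default_factory=list)

    def as_dict(self) -> Dict[str, object]:
        return {
            "n_input": self.n_input,
            "n_after_qc": self.n_after_qc,
            "n_unique": self.n_unique,
            "n_homozygous": self.n_homozygous,
            "n_high_moderate": self.n_high_moderate,
            "n_low_modifier": self.n_low_modifier,
            "n_novel": self.n_novel,
            "n_low_modifier_novel": self.n_low_modifier_novel,
            "final_candidates": [list(k) for k in self.final_candidates],
        }


def qc_filter(table: VariantTable, params: QcParams) -> VariantTable:
    """Keep records with depth_min <= mean_depth <= depth_max and
    call_rate > min_call_rate."""
    return table.subset(
        rec
        for rec in table.records
        if params.depth_min <= rec.mean_depth <= params.depth_max
        and rec.call_rate > params.min_call_rate
    )


def _control_carried_alleles(controls: VariantTable) -> Set[Tuple[str, int, str]]:
    """(chrom, pos, alt) alleles carried by at least one control sample."""
    carried: Set[Tuple[str, int, str]] = set()
    for rec in controls.records:
        for si in range(len(controls.sample_names)):
            for alt in rec.carried_alts(si):
                carried.add((rec.chrom, rec.pos, alt))
    return carried


def step1_unique_to_case(case: VariantTable, controls: VariantTable) -> VariantTable:
    """Keep records with at least one alternate allele that the case carries
    and no control sample carries (allele-level comparison per position).

    A control that is homozygous-reference at the site does not disqualify
    the allele; a heterozygous carrier does.
    """
    if len(case.sample_names) != 1:
        raise ValidationError("step 1 expects a single-sample case table")
    carried = _control_carried_alleles(controls)
    kept = []
    for rec in case.records:
        case_alts = rec.carried_alts(0)
        if any((rec.chrom, rec.pos, alt) not in carried for alt in case_alts):
            kept.append(rec)
    return case.subset(kept)


def step2_homozygous(table: VariantTable, sample: str) -> VariantTable:
    """Keep records where the sample is homozygous for an alternate allele;
    heterozygous and missing genotypes are removed."""
    si = table.sample_index(sample)
    return table.subset(rec for rec in table.records if rec.is_hom_alt(si))


def step3_impact_partition(
    table: VariantTable,
    consequences: Mapping[VariantKey, Sequence[Consequence]],
) -> Tuple[VariantTable, VariantTable]:
    """Split by maximum consequence severity.

    A record goes to the high/moderate branch if ANY consequence of any of
    its alternate alleles is high or moderate impact; otherwise to the
    low/modifier branch. The two outputs partition the input.
    """
    hm, lm = [], []
    for rec in table.records:
        rec_cons: List[Consequence] = []
        for key in rec.keys():
            rec_cons.extend(consequences.get(key, ()))
        if not rec_cons:
            raise MissingAnnotationError(
                f"record {rec.chrom}:{rec.pos} has no consequence annotation"
            )
        if any(c.impact in ("high", "moderate") for c in rec_cons):
            hm.append(rec)
        else:
            lm.append(rec)
    return table.subset(hm), table.subset(lm)


def step4_novelty(table: VariantTable, catalogue: KnownVariantCatalogue) -> VariantTable:
    """Keep records with at least one (chrom, pos, ref, alt) key absent from
    the catalogue (novel variants)."""
    return table.subset(
        rec
        for rec in table.records
        if any(key not in catalogue for key in rec.keys())
    )


def run_cascade(
    case: VariantTable,
    controls: VariantTable,
    genes: Sequence[GeneModel],
    reference: Mapping[str, str],
    catalogue: KnownVariantCatalogue,
    qc: Optional[QcParams] = None,
    window: int = 5000,
) -> Tuple[VariantTable, VariantTable, FilterTrace]:
    """QC + four-step cascade.

    Returns the high/moderate novel candidates, the low/modifier novel
    branch (the non-coding analogue), and the populated
    :class:`FilterTrace`. Each step's output is a subset of its input.
    """
    qc = qc or QcParams()
    sample = case.sample_names[0]
    trace = FilterTrace(n_input=len(case))

    after_qc = qc_filter(case, qc)
    trace.n_after_qc = len(after_qc)

    unique = step1_unique_to_case(after_qc, controls)
    trace.n_unique = len(unique)

    hom = step2_homozygous(unique, sample)
    trace.n_homozygous = len(hom)

    consequences: Dict[VariantKey, List[Consequence]] = {}
    for rec in hom.records:
        for cons in classify_variant(rec, genes, reference, window=window):
            consequences.setdefault(cons.variant_key, []).append(cons)

    high_moderate, low_modifier = step3_impact_partition(hom, consequences)
    trace.n_high_moderate = len(high_moderate)
    trace.n_low_modifier = len(low_modifier)

    candidates = step4_novelty(high_moderate, catalogue)
    trace.n_novel = len(candidates)
    low_novel = step4_novelty(low_modifier, catalogue)
    trace.n_low_modifier_novel = len(low_novel)

    trace.final_candidates = [key for rec in candidates.records for key in rec.keys()]
    return candidates, low_novel, trace
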
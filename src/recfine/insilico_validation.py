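"""In-silico PCR-RFLP genotyping and ddCt relative-expression analysis.

PCR is modeled as exact primer matching on a linear template: the forward
primer must match the top strand and the reverse primer's reverse complement
must match downstream; the amplicon spans 5' end to 5' end inclusive, and a
unique product is required. Restriction digestion is modeled as top-strand
IUPAC-motif matching with a fixed cut offset — only fragment sizes are
observable on a gel, so double-strand overhangs are ignored.

Relative expression follows the standard ddCt scheme: per sample,
dCt = mean(Ct_target) - mean(Ct_housekeeping); ddCt subtracts the mean dCt
of the calibrator group; fold change = 2**(-ddCt). Group summaries use the
geometric mean of fold changes (equivalently 2**(-mean ddCt)), so the
calibrator group's summary fold change is exactly 1.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd
from scipy import stats as sps

from .errors import (
    AmbiguousProductError,
    AmpliconNotFoundError,
    RecordError,
    ValidationError,
)
from .io_formats import VariantRecord

__all__ = [
    "PrimerPair",
    "Enzyme",
    "DigestResult",
    "CtTable",
    "DdctResult",
    "DDEI",
    "find_amplicon",
    "digest",
    "genotype_gel_pattern",
    "ddct",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: IUPAC nucleotide codes -> matched bases.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PrimerPair:
    """Forward/reverse primers, both written 5'->3'."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            seq = seq.upper()
            if len(seq) < 15:
                raise ValidationError(f"{name} primer shorter than 15 nt")
            if not set(seq) <= set("ACGT"):
                raise ValidationError(f"{name} primer contains non-ACGT bases")
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()


@dataclass
class Enzyme:
    """A restriction endonuclease: IUPAC recognition motif and the cut
    position as bp from the motif's 5' end on the top strand."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        self.recognition = self.recognition.upper()
        if not set(self.recognition) <= set(IUPAC):
            raise ValidationError(
                f"{self.name}: recognition motif contains non-IUPAC codes"
            )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValidationError(f"{self.name}: cut offset outside motif")


#: DdeI cuts C^TNAG (after the first base).
DDEI = Enzyme("DdeI", "CTNAG", 1)


@dataclass
class DigestResult:
    """Fragments of a linear digest; lengths always sum to the substrate."""

    fragment_lengths: Counter
    cut_positions: List[int]  # 0-based: cut between position i-1 and i

    @property
    def sorted_lengths(self) -> Tuple[int, ...]:
        return tuple(sorted(self.fragment_lengths.elements()))


def find_amplicon(template: str, primers: PrimerPair) -> Tuple[Tuple[int, int], str]:
    """Locate the unique PCR product of a primer pair on a template.

    Returns the 1-based closed template interval and the amplicon sequence
    (5' end of the forward primer site through the 5' end of the reverse
    primer site). Raises if there is no product or more than one.
    """
    template = template.upper()
    if not set(template) <= set("ACGT"):
        raise RecordError("template contains non-ACGT bases")
    fwd, rev_rc = primers.forward, revcomp(primers.reverse)

    def all_hits(needle: str) -> List[int]:
        hits, start = [], template.find(needle)
        while start != -1:
            hits.append(start)
            start = template.find(needle, start + 1)
        return hits

    products = []
    for f in all_hits(fwd):
        for r in all_hits(rev_rc):
            if r >= f + len(fwd):  # reverse site strictly downstream
                products.append((f, r + len(rev_rc)))  # half-open on template
    if not products:
        raise AmpliconNotFoundError(
            f"primers {primers.forward}/{primers.reverse} produce no product"
        )
    if len(products) > 1:
        raise AmbiguousProductError(
            f"{len(products)} products for primer pair", loci=products
        )
    s, e = products[0]
    return (s + 1, e), template[s:e]


def _motif_hits(substrate: str, motif: str) -> List[int]:
    """All 0-based start positions where the IUPAC motif matches the top
    strand (overlapping matches allowed)."""
    m = len(motif)
    allowed = [frozenset(IUPAC[c]) for c in motif]
    hits = []
    for i in range(len(substrate) - m + 1):
        if all(substrate[i + k] in allowed[k] for k in range(m)):
            hits.append(i)
    return hits


def digest(substrate: str, enzyme: Enzyme) -> DigestResult:
    """Digest a linear substrate: cut at every top-strand motif match
    (match start + cut offset); fragments are the inter-cut intervals."""
    substrate = substrate.upper()
    cuts = sorted({h + enzyme.cut_offset for h in _motif_hits(substrate, enzyme.recognition)})
    cuts = [c for c in cuts if 0 < c < len(substrate)]
    bounds = [0] + cuts + [len(substrate)]
    lengths = Counter(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(fragment_lengths=lengths, cut_positions=cuts)


def _apply_allele(template: str, variant: VariantRecord, allele_index: int) -> str:
    """Substitute one allele of the variant into the template (template
    coordinates, 1-based)."""
    pos0 = variant.pos - 1
    if template[pos0 : pos0 + len(variant.ref)].upper() != variant.ref:
        raise RecordError(
            f"template does not carry REF {variant.ref!r} at position {variant.pos}"
        )
    allele = variant.ref if allele_index == 0 else variant.alts[allele_index - 1]
    return template[:pos0] + allele + template[pos0 + len(variant.ref):]


def genotype_gel_pattern(
    template: str,
    primers: PrimerPair,
    enzyme: Enzyme,
    variant: VariantRecord,
    genotype: Tuple[int, int],
) -> Dict[int, Counter]:
    """Predicted gel pattern per allele of a genotype.

    Amplifies each allele's template, digests the amplicon and returns
    {allele_index: fragment-length multiset}. A homozygote contributes one
    allele's digest; a heterozygote's observable gel pattern is the union of
    the two per-allele multisets.
    """
    template = template.upper()
    interval, _ = find_amplicon(template, primers)
    if not interval[0] <= variant.pos <= interval[1]:
        raise ValidationError(
            f"variant at {variant.pos} lies outside amplicon {interval}"
        )
    patterns: Dict[int, Counter] = {}
    for allele in sorted(set(genotype)):
        if allele is None:
            raise RecordError("cannot predict a gel pattern for a missing allele")
        allele_template = _apply_allele(template, variant, allele)
        _, amplicon = find_amplicon(allele_template, primers)
        patterns[allele] = digest(amplicon, enzyme).fragment_lengths
    return patterns


def gel_bands(patterns: Mapping[int, Counter]) -> Tuple[int, ...]:
    """Band sizes visible on a gel: the union of the per-allele multisets."""
    union: Counter = Counter()
    for pat in patterns.values():
        union |= pat
    return tuple(sorted(union.elements()))


# ---------------------------------------------------------------------------
# ddCt
# ---------------------------------------------------------------------------

@dataclass
class CtTable:
    """Replicate Ct values per sample for a target and a housekeeping gene.

    ``data`` columns: sample, group, gene, ct (one row per technical
    replicate). ``calibrator_group`` names the group against which ddCt is
    computed (typically the normal-sized controls).
    """

    data: pd.DataFrame
    target_gene: str
    housekeeping_gene: str
    calibrator_group: str

    def __post_init__(self) -> None:
        required = {"sample", "group", "gene", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"Ct table missing column(s): {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValidationError("Ct values must be > 0")
        genes = set(self.data["gene"])
        for gene in (self.target_gene, self.housekeeping_gene):
            if gene not in genes:
                raise ValidationError(f"no Ct rows for gene {gene!r}")
        groups = set(self.data["group"])
        if self.calibrator_group not in groups:
            raise ValidationError(
                f"calibrator group {self.calibrator_group!r} not in table"
            )


@dataclass
class DdctResult:
    """Per-sample dCt/ddCt/fold change plus per-group summary."""

    per_sample: pd.DataFrame
    group_summary: pd.DataFrame
    test_statistic: Optional[float]
    p_value: Optional[float]


def ddct(ct: CtTable) -> DdctResult:
    """Relative expression by the ddCt method.

    Per sample, dCt = mean(Ct_target) - mean(Ct_housekeeping); ddCt
    subtracts the calibrator-group mean dCt; fold change = 2**(-ddCt).
    Group summaries report the mean +/- sd of dCt and the geometric-mean
    fold change; a two-sided Welch t-test on dCt between case and calibrator
    groups is reported descriptively when both groups have >= 2 samples.
    """
    rows = []
    for (sample, group), sub in ct.data.groupby(["sample", "group"], sort=True):
        target = sub.loc[sub["gene"] == ct.target_gene, "ct"]
        housekeeping = sub.loc[sub["gene"] == ct.housekeeping_gene, "ct"]
        if target.empty or housekeeping.empty:
            raise ValidationError(
                f"sample {sample!r} lacks replicates for target or housekeeping gene"
            )
        rows.append(
            {
                "sample": sample,
                "group": group,
                "dct": target.mean() - housekeeping.mean(),
            }
        )
    per_sample = pd.DataFrame(rows)
    calib = per_sample.loc[per_sample["group"] == ct.calibrator_group, "dct"]
    per_sample["ddct"] = per_sample["dct"] - calib.mean()
    per_sample["fold_change"] = 2.0 ** (-per_sample["ddct"])

    summary = (
        per_sample.groupby("group")
        .agg(
            n=("sample", "size"),
            mean_dct=("dct", "mean"),
            sd_dct=("dct", "std"),
            mean_ddct=("ddct", "mean"),
        )
        .reset_index()
    )
    summary["fold_change"] = 2.0 ** (-summary["mean_ddct"])

    stat = pval = None
    other = per_sample.loc[per_sample["group"] != ct.calibrator_group, "dct"]
    if len(calib) >= 2 and len(other) >= 2:
        res = sps.ttest_ind(other, calib, equal_var=False)
        stat, pval = float(res.statistic), float(res.pvalue)
    return DdctResult(per_sample, summary, stat, pval)


def read_ct_csv(
    path, target_gene: str, housekeeping_gene: str, calibrator_group: str
) -> CtTable:
    """Load a Ct table from CSV (columns sample, group, gene, ct)."""
    return CtTable(pd.read_csv(path), target_gene, housekeeping_gene, calibrator_group)
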
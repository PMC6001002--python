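"""Variant consequence classification, impact categories, protein effects.

Classifies SNVs and small indels against :class:`~recfine.io_formats.GeneModel`
gene models by re-splicing the coding sequence and comparing codons, emits
Sequence Ontology-style terms with HGVS c./p. descriptions, and derives
protein-level truncation and transmembrane-domain disruption for stop-gain
variants.

Conventions (documented, parameterized where the field varies):

* impact is a pure function of the consequence term (high / moderate / low /
  modifier), the standard SnpEff/VEP-style tiering;
* ``splice_region_variant`` covers positions within 3 bp of a splice junction
  on the exonic side or within 8 bp on the intronic side;
* upstream/downstream calls use a 5 kb window by default;
* HGVS c. numbering is strictly CDS-anchored (c.1 = A of the start codon).
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .errors import ReferenceMismatchError, ValidationError
from .io_formats import GeneModel, VariantRecord, VariantKey

__all__ = [
    "Consequence",
    "ProteinEffect",
    "DomainSet",
    "DomainImpactReport",
    "TranscriptSequence",
    "TERMS",
    "classify_variant",
    "impact_of",
    "protein_effect",
    "domain_overlap",
    "parse_hgvs_p",
    "DEFAULT_TM_DOMAINS",
]

#: term -> impact category. Total over the vocabulary the classifier emits,
#: plus the canonical splice donor/acceptor terms for completeness.
_IMPACT: Dict[str, str] = {
    "stop_gained": "high",
    "stop_lost": "high",
    "frameshift_variant": "high",
    "splice_acceptor_variant": "high",
    "splice_donor_variant": "high",
    "missense_variant": "moderate",
    "inframe_indel": "moderate",
    "synonymous_variant": "low",
    "splice_region_variant": "low",
    "intron_variant": "modifier",
    "5_prime_UTR_variant": "modifier",
    "3_prime_UTR_variant": "modifier",
    "upstream_gene_variant": "modifier",
    "downstream_gene_variant": "modifier",
    "non_coding_transcript_variant": "modifier",
    "intergenic_variant": "modifier",
}

TERMS = tuple(_IMPACT)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def impact_of(term: str) -> str:
    """Impact category for a consequence term (fixed total mapping)."""
    try:
        return _IMPACT[term]
    except KeyError:
        raise LookupError(f"unknown consequence term {term!r}") from None


@dataclass
class Consequence:
    """One consequence of one alternate allele on one feature."""

    variant_key: VariantKey
    gene_id: Optional[str]
    term: str
    impact: str
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    protein_position: Optional[int] = None
    sift: Optional[float] = None


@dataclass
class ProteinEffect:
    """Protein-level outcome of a premature stop codon."""

    full_length: int
    stop_position: Optional[int]
    retained_residues: int
    truncation_fraction: float


@dataclass
class DomainSet:
    """Named residue intervals (1-based closed) on a protein."""

    protein_id: str
    domains: Dict[str, Tuple[int, int]]

    def validate(self, full_length: int) -> None:
        for name, (s, e) in self.domains.items():
            if not 1 <= s <= e <= full_length:
                raise ValidationError(
                    f"{self.protein_id}: domain {name} ({s}-{e}) outside "
                    f"[1, {full_length}]"
                )


#: TMEM263-like topology: two membrane-spanning helices.
DEFAULT_TM_DOMAINS = DomainSet("TMEM263-like", {"TMR1": (38, 60), "TMR2": (80, 102)})


@dataclass
class DomainImpactReport:
    """Per-domain status after truncation: intact / disrupted / lost."""

    protein_id: str
    status: Dict[str, str]

    @property
    def disrupted(self) -> List[str]:
        return [d for d, s in self.status.items() if s == "disrupted"]

    @property
    def lost(self) -> List[str]:
        return [d for d, s in self.status.items() if s == "lost"]


class TranscriptSequence:
    """Spliced coding sequence of a gene plus a genomic<->CDS coordinate map.

    The CDS string is in transcript orientation (reverse-complemented for
    minus-strand genes); ``genomic_positions[i]`` is the genomic position of
    CDS base i+1.
    """

    def __init__(self, gene: GeneModel, reference: Mapping[str, str]):
        if gene.biotype != "protein_coding":
            raise ValidationError(f"{gene.gene_id}: no CDS to splice")
        seq = reference[gene.chrom]
        plus = "".join(seq[s - 1 : e] for s, e in gene.cds).upper()
        positions = [p for s, e in gene.cds for p in range(s, e + 1)]
        if gene.strand == "-":
            plus = plus.translate(_COMPLEMENT)[::-1]
            positions = positions[::-1]
        self.gene = gene
        self.cds_seq = plus
        self.genomic_positions = positions
        self._index = {p: i + 1 for i, p in enumerate(positions)}

    def cds_index(self, pos: int) -> Optional[int]:
        """1-based CDS coordinate of a genomic position, or None."""
        return self._index.get(pos)

    @property
    def protein_length(self) -> int:
        """Residues excluding the terminal stop codon."""
        n = len(self.cds_seq) // 3
        return n - 1 if self.cds_seq[-3:] in ("TAA", "TAG", "TGA") else n

    def protein(self) -> str:
        return str(Seq(self.cds_seq).translate())


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def _hgvs_p(ref_aa: str, position: int, alt_aa: str) -> str:
    if alt_aa == "*":
        return f"p.({_aa3(ref_aa)}{position}*)"
    if ref_aa == alt_aa:
        return f"p.({_aa3(ref_aa)}{position}=)"
    return f"p.({_aa3(ref_aa)}{position}{_aa3(alt_aa)})"


_HGVS_P_RE = re.compile(r"^p\.\(([A-Z][a-z]{2})(\d+)(\*|=|[A-Z][a-z]{2})\)$")

_AA_1 = {
    seq3(a): a
    for a in "ACDEFGHIKLMNPQRSTVWY"
}
_AA_1["Ter"] = "*"


def parse_hgvs_p(s: str) -> Tuple[int, str, str]:
    """Parse a p.(RefPosAlt) string back to (residue, ref_aa, alt_aa).

    ``alt_aa`` is '*' for a stop, and equals ``ref_aa`` for a synonymous
    description (the '=' form).
    """
    m = _HGVS_P_RE.match(s)
    if m is None:
        raise ValueError(f"not a recognised HGVS p. description: {s!r}")
    ref3, pos, alt = m.groups()
    ref_aa = _AA_1[ref3]
    if alt == "*":
        alt_aa = "*"
    elif alt == "=":
        alt_aa = ref_aa
    else:
        alt_aa = _AA_1[alt]
    return int(pos), ref_aa, alt_aa


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _splice_region(gene: GeneModel, pos: int, exonic: bool) -> bool:
    """Within 3 bp (exonic) or 8 bp (intronic) of an internal splice junction."""
    if len(gene.exons) < 2:
        return False
    junctions = []  # genomic positions of last/first exonic base at junctions
    for i, (s, e) in enumerate(gene.exons):
        if i > 0:
            junctions.append(("start", s))
        if i < len(gene.exons) - 1:
            junctions.append(("end", e))
    for kind, j in junctions:
        if exonic:
            if abs(pos - j) <= 2 and (
                (kind == "end" and pos <= j) or (kind == "start" and pos >= j)
            ):
                return True
        else:
            if kind == "end" and 1 <= pos - j <= 8:
                return True
            if kind == "start" and 1 <= j - pos <= 8:
                return True
    return False


def _utr_side(gene: GeneModel, pos: int) -> str:
    cds_start, cds_end = gene.cds[0][0], gene.cds[-1][1]
    before = pos < cds_start
    if gene.strand == "+":
        return "5_prime_UTR_variant" if before else "3_prime_UTR_variant"
    return "3_prime_UTR_variant" if before else "5_prime_UTR_variant"


def _coding_snv(
    tx: TranscriptSequence, pos: int, ref: str, alt: str
) -> Tuple[str, str, str, int]:
    """Classify a CDS SNV by codon comparison.

    Returns (term, hgvs_c, hgvs_p, protein_position).
    """
    gene = tx.gene
    c = tx.cds_index(pos)
    assert c is not None
    ref_t, alt_t = ref, alt
    if gene.strand == "-":
        ref_t = ref.translate(_COMPLEMENT)
        alt_t = alt.translate(_COMPLEMENT)
    if tx.cds_seq[c - 1] != ref_t:
        raise ReferenceMismatchError(
            f"{gene.gene_id}: REF {ref!r} at {gene.chrom}:{pos} disagrees with "
            f"reference CDS base {tx.cds_seq[c - 1]!r} (transcript strand)"
        )
    codon_idx = (c - 1) // 3  # 0-based
    offset = (c - 1) % 3
    ref_codon = tx.cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    alt_codon = ref_codon[:offset] + alt_t + ref_codon[offset + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == ref_aa:
        term = "synonymous_variant"
    elif alt_aa == "*":
        term = "stop_gained"
    elif ref_aa == "*":
        term = "stop_lost"
    else:
        term = "missense_variant"
    ppos = codon_idx + 1
    return term, f"c.{c}{ref_t}>{alt_t}", _hgvs_p(ref_aa, ppos, alt_aa), ppos


def _classify_allele_for_gene(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene: GeneModel,
    reference: Optional[Mapping[str, str]],
    window: int,
) -> List[Tuple[str, Optional[str], Optional[str], Optional[int]]]:
    out: List[Tuple[str, Optional[str], Optional[str], Optional[int]]] = []
    if gene.contains(pos):
        exonic = gene.in_exon(pos)
        if exonic:
            if gene.biotype == "lincRNA":
                out.append(("non_coding_transcript_variant", None, None, None))
            elif gene.in_cds(pos):
                if len(ref) == 1 and len(alt) == 1:
                    if reference is None:
                        raise ReferenceMismatchError(
                            f"reference sequence required to classify CDS variant "
                            f"at {chrom}:{pos}"
                        )
                    tx = TranscriptSequence(gene, reference)
                    out.append(_coding_snv(tx, pos, ref, alt))
                else:
                    term = (
                        "inframe_indel"
                        if abs(len(ref) - len(alt)) % 3 == 0
                        else "frameshift_variant"
                    )
                    out.append((term, None, None, None))
            else:
                out.append((_utr_side(gene, pos), None, None, None))
        else:
            out.append(("intron_variant", None, None, None))
        if _splice_region(gene, pos, exonic):
            out.append(("splice_region_variant", None, None, None))
    elif gene.start - window <= pos < gene.start:
        term = "upstream_gene_variant" if gene.strand == "+" else "downstream_gene_variant"
        out.append((term, None, None, None))
    elif gene.end < pos <= gene.end + window:
        term = "downstream_gene_variant" if gene.strand == "+" else "upstream_gene_variant"
        out.append((term, None, None, None))
    return out


def classify_variant(
    v: VariantRecord,
    genes: Sequence[GeneModel],
    reference: Optional[Mapping[str, str]] = None,
    window: int = 5000,
    sift: Optional[Mapping[VariantKey, float]] = None,
) -> List[Consequence]:
    """Classify every alternate allele of a variant against the gene models.

    Every overlapping feature yields one :class:`Consequence` per allele;
    alleles overlapping nothing within ``window`` bp of a gene are
    ``intergenic_variant``. CDS SNVs are classified strand-aware by codon
    comparison of the reference versus alternate spliced CDS, which requires
    ``reference``; a REF allele disagreeing with the reference sequence
    raises :class:`~recfine.errors.ReferenceMismatchError`.
    """
    consequences: List[Consequence] = []
    for alt in v.alts:
        key = (v.chrom, v.pos, v.ref, alt)
        found = False
        for gene in genes:
            if gene.chrom != v.chrom:
                continue
            for term, hgvs_c, hgvs_p, ppos in _classify_allele_for_gene(
                v.chrom, v.pos, v.ref, alt, gene, reference, window
            ):
                found = True
                consequences.append(
                    Consequence(
                        variant_key=key,
                        gene_id=gene.gene_id,
                        term=term,
                        impact=impact_of(term),
                        hgvs_c=hgvs_c,
                        hgvs_p=hgvs_p,
                        protein_position=ppos,
                        sift=(sift or {}).get(key),
                    )
                )
        if not found:
            consequences.append(
                Consequence(
                    variant_key=key,
                    gene_id=None,
                    term="intergenic_variant",
                    impact="modifier",
                )
            )
    return consequences


def protein_effect(stop_consequence: Consequence, full_length: int) -> ProteinEffect:
    """Truncation arithmetic for a stop-gain consequence.

    ``retained_residues = stop_position - 1``;
    ``truncation_fraction = retained / full_length``.
    """
    if stop_consequence.term != "stop_gained":
        raise ValidationError(
            f"protein_effect requires a stop_gained consequence, got "
            f"{stop_consequence.term}"
        )
    stop = stop_consequence.protein_position
    if stop is None:
        raise ValidationError("stop_gained consequence lacks a protein position")
    if stop > full_length:
        raise ValidationError(
            f"stop position {stop} beyond protein length {full_length}"
        )
    retained = stop - 1
    return ProteinEffect(
        full_length=full_length,
        stop_position=stop,
        retained_residues=retained,
        truncation_fraction=retained / full_length,
    )


def domain_overlap(effect: ProteinEffect, domains: DomainSet) -> DomainImpactReport:
    """Classify each domain as disrupted (stop inside it), lost (entirely
    downstream of the retained residues) or intact."""
    domains.validate(effect.full_length)
    status: Dict[str, str] = {}
    stop = effect.stop_position
    for name, (s, e) in domains.domains.items():
        if stop is not None and s <= stop <= e:
            status[name] = "disrupted"
        elif s > effect.retained_residues:
            status[name] = "lost"
        else:
            status[name] = "intact"
    return DomainImpactReport(domains.protein_id, status)
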
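"""Synthetic cohorts and packaged fixtures with planted ground truth.

The simulator emulates the study design that motivates the pipeline: a
single sequenced case genome that is autozygous across a multi-Mb
low-heterozygosity tract containing a homozygous stop-gain variant absent
from every control and from the known-variant catalogue, against a cohort
of polymorphic controls. Per-site depths are log-normal around the target
coverage so a realistic fraction of sites violates the depth QC window, and
control genotypes carry missingness so the call-rate filter is exercised.

Also packaged here: the printed candidate-table fixture (11 case-unique
records, 10 of them catalogued), the TMEM263-like gene fixture whose G>A
change turns the tryptophan codon 59 into a stop, and the PCR-RFLP fixture
whose variant allele gains a DdeI site splitting the amplicon into 109 and
184 bp fragments.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Set, Tuple

import numpy as np

from .consequence_annotator import Consequence, DomainSet
from .errors import ValidationError
from .io_formats import (
    GeneModel,
    KnownVariantCatalogue,
    VariantKey,
    VariantRecord,
    VariantTable,
    write_catalogue,
    write_gene_models,
    write_vcf,
)
from .insilico_validation import DDEI, Enzyme, PrimerPair, _motif_hits

__all__ = [
    "SimulationParams",
    "TruthSet",
    "SimulatedCohort",
    "simulate_cohort",
    "write_cohort",
    "Table1Fixture",
    "make_table1_fixture",
    "RflpFixture",
    "make_rflp_fixture",
    "GeneFixture",
    "make_gene_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_CASE_SAMPLE = "adw_case"

# codons (no stops) cycled to fill synthetic coding sequence
_FILL_CODONS = [
    "GCT", "GAA", "CTG", "AAG", "GAT", "TTC", "GGA", "CAT", "ATC", "AAA",
    "TTA", "ATG", "AAC", "CCA", "CAG", "AGA", "AGC", "ACA", "GTG", "TAC",
]


def make_cds(n_residues: int, trp_at: Optional[int] = None) -> str:
    """Deterministic coding sequence of ``n_residues`` amino acids plus a
    TAA stop; codon ``trp_at`` (1-based) is TGG when requested.

    The codon preceding the tryptophan is forced to end in CT, so the
    G>A stop-gain (..CT TGG.. -> ..CT TAG..) also creates a DdeI site
    (CTNAG) — the allele configuration a PCR-RFLP assay exploits."""
    codons = ["ATG"]
    for i in range(2, n_residues + 1):
        codons.append("TGG" if i == trp_at else _FILL_CODONS[i % len(_FILL_CODONS)])
    codons.append("TAA")
    if trp_at is not None and trp_at > 2:
        codons[trp_at - 2] = "ACT"  # Thr
    return "".join(codons)


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Study conditions for one simulated cohort.

    Densities are per kb of the relevant region; ``snp_density`` is the
    heterozygous SNP density outside the planted tract, scaled by
    ``residual_roh_snp_rate`` inside it. ``depth_mean``/``depth_sd`` are the
    log-normal median and log-sd of per-site depth (the default median
    matches the study's 9.1x coverage, and the default sd puts roughly 8% of
    sites outside the 3-25x QC window). ``n_controls`` defaults to the
    study's 261 White Leghorn controls; tests scale it down for speed.
    """

    segment_length: int = 5_000_000
    chrom: str = "1"
    n_controls: int = 261
    snp_density: float = 2.0
    roh_interval: Tuple[int, int] = (2_000_000, 2_500_000)
    residual_roh_snp_rate: float = 0.02
    depth_mean: float = 9.1
    depth_sd: float = 0.6
    missing_rate: float = 0.05
    seed: int = 0
    # densities the study does not pin down, defaulting off snp_density
    hom_snp_density: Optional[float] = None  # homozygous-alt sites, whole segment
    control_only_density: Optional[float] = None  # sites absent from the case
    unique_het_fraction: float = 0.05  # share of background hets private to the case
    unique_hom_fraction: float = 0.0005  # share of hom sites private to the case

    def __post_init__(self) -> None:
        if self.hom_snp_density is None:
            self.hom_snp_density = self.snp_density
        if self.control_only_density is None:
            self.control_only_density = self.snp_density
        s, e = self.roh_interval
        if not (1 <= s < e <= self.segment_length):
            raise ValidationError(
                f"roh_interval {self.roh_interval} not within segment "
                f"[1, {self.segment_length}]"
            )
        if self.n_controls < 1:
            raise ValidationError("n_controls must be >= 1")
        for name in ("residual_roh_snp_rate", "missing_rate", "unique_het_fraction",
                     "unique_hom_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")


@dataclass
class TruthSet:
    """Planted ground truth: the causal variant, the autozygous tract, and a
    provenance label for every simulated variant key."""

    causal_variant: VariantKey
    planted_roh: Tuple[int, int]
    labels: Dict[VariantKey, str] = field(default_factory=dict)


@dataclass
class SimulatedCohort:
    case: VariantTable
    controls: VariantTable
    reference: Dict[str, str]
    genes: List[GeneModel]
    catalogue: KnownVariantCatalogue
    truth: TruthSet

    def __iter__(self) -> Iterator:
        return iter(
            (self.case, self.controls, self.reference, self.genes,
             self.catalogue, self.truth)
        )


def _draw_unique_positions(
    rng: np.random.Generator,
    low: int,
    high: int,
    n: int,
    taken: Set[int],
) -> List[int]:
    """n distinct 1-based positions in [low, high], avoiding ``taken``."""
    if n == 0:
        return []
    if high - low + 1 - len(taken) < n:
        raise ValidationError("segment too small for requested variant count")
    out: List[int] = []
    while len(out) < n:
        draw = rng.integers(low, high + 1, size=max(2 * (n - len(out)), 16))
        for p in draw:
            p = int(p)
            if p not in taken:
                taken.add(p)
                out.append(p)
                if len(out) == n:
                    break
    return out


def _depth(rng: np.random.Generator, params: SimulationParams) -> float:
    return round(float(np.exp(rng.normal(np.log(params.depth_mean), params.depth_sd))), 2)


def _alt_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[int(rng.integers(0, 3))]


def _control_genotypes(
    rng: np.random.Generator, n: int, freq: float, missing_rate: float
) -> Tuple[Tuple[Optional[int], Optional[int]], ...]:
    """Control genotype vector from an allele frequency, with missingness;
    at least one non-missing carrier is guaranteed."""
    alleles = (rng.random((n, 2)) < freq).astype(int)
    missing = rng.random(n) < missing_rate
    gts: List[Tuple[Optional[int], Optional[int]]] = []
    for i in range(n):
        if missing[i]:
            gts.append((None, None))
        else:
            gts.append((int(alleles[i, 0]), int(alleles[i, 1])))
    if not any(g != (None, None) and (g[0] or g[1]) for g in gts):
        gts[0] = (0, 1)
    return tuple(gts)


def _call_rate(gts: Sequence[Tuple[Optional[int], Optional[int]]]) -> float:
    called = sum(1 for g in gts if all(a is not None for a in g))
    return called / len(gts)


def _plant_gene(
    gene_id: str,
    chrom: str,
    cds_start: int,
    n_residues: int,
    strand: str,
    reference: np.ndarray,
    trp_at: Optional[int] = None,
    utr: int = 150,
) -> GeneModel:
    """Write a synthetic coding gene into the reference array and return its
    model. Exon extends ``utr`` bp past the CDS on both sides."""
    cds = make_cds(n_residues, trp_at=trp_at)
    cds_end = cds_start + len(cds) - 1
    if cds_start - utr < 1 or cds_end + utr > len(reference):
        raise ValidationError(f"gene {gene_id} does not fit in the segment")
    plus = cds
    if strand == "-":
        plus = cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    reference[cds_start - 1 : cds_end] = np.frombuffer(plus.encode(), dtype="S1")
    return GeneModel(
        gene_id=gene_id,
        biotype="protein_coding",
        strand=strand,
        chrom=chrom,
        exons=[(cds_start - utr, cds_end + utr)],
        cds=[(cds_start, cds_end)],
    )


def simulate_cohort(params: SimulationParams) -> SimulatedCohort:
    """Generate a case/control cohort with planted truth.

    Deterministic given ``params.seed``. The causal stop-gain variant is
    homozygous-alt in the case, absent from every control and from the
    catalogue, QC-safe by construction, and sits at the centre of the
    planted tract inside the planted gene. Shared and control-only variants
    are catalogued; case-unique variants are novel. Case-unique homozygous
    variants are placed outside gene exons so only the causal variant can
    reach the high/moderate branch.
    """
    rng = np.random.default_rng(params.seed)
    L = params.segment_length
    chrom = params.chrom
    roh_s, roh_e = params.roh_interval
    reference = rng.choice(_BASES, size=L)

    # -- genes ------------------------------------------------------------
    genes: List[GeneModel] = []
    n_res = 116  # TMEM263-like length
    cds_len = (n_res + 1) * 3
    cds_start = (roh_s + roh_e) // 2 - 175
    if not (roh_s <= cds_start and cds_start + cds_len - 1 <= roh_e):
        raise ValidationError("planted tract too small to hold the causal gene")
    causal_gene = _plant_gene("GENE_CAUSAL", chrom, cds_start, n_res, "+",
                              reference, trp_at=59)
    genes.append(causal_gene)
    causal_pos = cds_start + 175  # second base of codon 59 (TGG)

    for gid, frac, strand in (("GENE_DECOY1", 0.15, "+"), ("GENE_DECOY2", 0.8, "-")):
        start = int(L * frac)
        end = start + 300 + 2 * 150
        if end < roh_s or start > roh_e:
            if 1 < start - 150 and end < L:
                genes.append(
                    _plant_gene(gid, chrom, start, 99, strand, reference)
                )
    linc_start = int(L * 0.55)
    if (linc_start > roh_e or linc_start + 2000 < roh_s) and linc_start + 2000 < L:
        genes.append(
            GeneModel(
                gene_id="LINC_DECOY",
                biotype="lincRNA",
                strand="+",
                chrom=chrom,
                exons=[(linc_start, linc_start + 800),
                       (linc_start + 1400, linc_start + 2000)],
            )
        )

    ref_str = reference.tobytes().decode()
    refmap = {chrom: ref_str}

    # -- variant positions -------------------------------------------------
    taken: Set[int] = {causal_pos}
    roh_len = roh_e - roh_s + 1
    bg_len = L - roh_len

    def poisson(rate_per_kb: float, length: int) -> int:
        return int(rng.poisson(rate_per_kb * length / 1000.0))

    n_shared_hom = poisson(params.hom_snp_density, L)
    n_unique_hom = int(round(params.unique_hom_fraction * n_shared_hom))
    n_shared_hom -= n_unique_hom
    n_shared_het = poisson(params.snp_density * (1 - params.unique_het_fraction), bg_len)
    n_unique_het_out = poisson(params.snp_density * params.unique_het_fraction, bg_len)
    n_unique_het_in = poisson(params.snp_density * params.residual_roh_snp_rate, roh_len)
    n_control_only = poisson(params.control_only_density, L)

    def outside_roh(n: int) -> List[int]:
        out: List[int] = []
        while len(out) < n:
            batch = _draw_unique_positions(rng, 1, L, n - len(out), taken)
            out.extend(p for p in batch if not roh_s <= p <= roh_e)
        return out

    # exclusion zone so case-unique hom variants stay intergenic
    def intergenic(n: int) -> List[int]:
        out: List[int] = []
        while len(out) < n:
            batch = _draw_unique_positions(rng, 1, L, n - len(out), taken)
            out.extend(
                p for p in batch
                if not any(g.start - 10 <= p <= g.end + 10 for g in genes)
            )
        return out

    pos_shared_hom = _draw_unique_positions(rng, 1, L, n_shared_hom, taken)
    pos_shared_het = outside_roh(n_shared_het)
    pos_unique_het_out = outside_roh(n_unique_het_out)
    pos_unique_het_in = _draw_unique_positions(rng, roh_s, roh_e, n_unique_het_in, taken)
    pos_unique_hom = intergenic(n_unique_hom)
    pos_control_only = _draw_unique_positions(rng, 1, L, n_control_only, taken)

    # -- records -----------------------------------------------------------
    case_records: List[VariantRecord] = []
    control_records: List[VariantRecord] = []
    catalogue = KnownVariantCatalogue()
    labels: Dict[VariantKey, str] = {}
    n_ctrl = params.n_controls
    cat_idx = 0

    def site(pos: int) -> Tuple[str, str]:
        ref = ref_str[pos - 1]
        return ref, _alt_base(rng, ref)

    def add_case(pos: int, ref: str, alt: str, gt, label: str,
                 depth: Optional[float] = None) -> None:
        rec = VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alts=(alt,), genotypes=(gt,),
            mean_depth=_depth(rng, params) if depth is None else depth,
            call_rate=1.0,
        )
        case_records.append(rec)
        labels[(chrom, pos, ref, alt)] = label

    def add_control(pos: int, ref: str, alt: str) -> None:
        gts = _control_genotypes(rng, n_ctrl, float(rng.uniform(0.1, 0.9)),
                                 params.missing_rate)
        control_records.append(
            VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alts=(alt,), genotypes=gts,
                mean_depth=_depth(rng, params), call_rate=_call_rate(gts),
            )
        )

    def catalogued(pos: int, ref: str, alt: str) -> None:
        nonlocal cat_idx
        catalogue.add(chrom, pos, ref, alt, f"cat{cat_idx:06d}")
        cat_idx += 1

    for pos in sorted(pos_shared_hom):
        ref, alt = site(pos)
        add_case(pos, ref, alt, (1, 1), "shared")
        add_control(pos, ref, alt)
        catalogued(pos, ref, alt)
    for pos in sorted(pos_shared_het):
        ref, alt = site(pos)
        add_case(pos, ref, alt, (0, 1), "shared")
        add_control(pos, ref, alt)
        catalogued(pos, ref, alt)
    for pos in sorted(pos_unique_het_out):
        ref, alt = site(pos)
        add_case(pos, ref, alt, (0, 1), "case-unique-het")
    for pos in sorted(pos_unique_het_in):
        ref, alt = site(pos)
        add_case(pos, ref, alt, (0, 1), "case-unique-het")
    for pos in sorted(pos_unique_hom):
        ref, alt = site(pos)
        add_case(pos, ref, alt, (1, 1), "case-unique-hom")
    for pos in sorted(pos_control_only):
        ref, alt = site(pos)
        add_control(pos, ref, alt)
        labels[(chrom, pos, ref, alt)] = "control-only"
        catalogued(pos, ref, alt)

    assert ref_str[causal_pos - 1] == "G"
    add_case(causal_pos, "G", "A", (1, 1), "causal", depth=params.depth_mean)
    causal_key = (chrom, causal_pos, "G", "A")
    labels[causal_key] = "causal"

    case = VariantTable([_CASE_SAMPLE], case_records)
    controls = VariantTable(
        [f"control_{i:03d}" for i in range(n_ctrl)], control_records
    )
    truth = TruthSet(causal_variant=causal_key, planted_roh=(roh_s, roh_e),
                     labels=labels)
    return SimulatedCohort(case, controls, refmap, genes, catalogue, truth)


def write_cohort(cohort: SimulatedCohort, out_dir, params: Optional[SimulationParams] = None) -> Dict[str, Path]:
    """Write a cohort to disk in the formats the io module reads
    (VCF / FASTA / GFF3 / TSV) plus a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "case_vcf": out / "case.vcf",
        "controls_vcf": out / "controls.vcf",
        "reference_fasta": out / "reference.fa",
        "genes_gff": out / "genes.gff3",
        "catalogue_tsv": out / "catalogue.tsv",
        "truth_json": out / "truth.json",
    }
    header = {"seed": params.seed} if params is not None else None
    write_vcf(cohort.case, paths["case_vcf"], extra_header=header)
    write_vcf(cohort.controls, paths["controls_vcf"], extra_header=header)
    with open(paths["reference_fasta"], "w") as fh:
        for name, seq in cohort.reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    write_gene_models(cohort.genes, paths["genes_gff"])
    write_catalogue(cohort.catalogue, paths["catalogue_tsv"])
    truth = {
        "causal_variant": list(cohort.truth.causal_variant),
        "planted_roh": list(cohort.truth.planted_roh),
        "labels": {"|".join(map(str, k)): v for k, v in sorted(cohort.truth.labels.items())},
    }
    paths["truth_json"].write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return paths


# ---------------------------------------------------------------------------
# printed candidate-table fixture
# ---------------------------------------------------------------------------

# (pos, rsid or None, ref, alt, gene, [(term, impact)...])
# Impacts are stored as printed in the source table; note that the PRDM4
# intron record is printed as Moderate although the term->impact mapping
# would say modifier — the fixture reproduces the printed table.
_TABLE1_ROWS = [
    (52195787, "rs736218372", "TC", "CT", "HMGXB4",
     [("missense_variant", "moderate")]),
    (53369104, "rs14825651", "AA", "TT", "ASCL4",
     [("missense_variant", "moderate"), ("splice_region_variant", "low")]),
    (53369406, "rs741302250", "G", "A", "ASCL4",
     [("missense_variant", "moderate")]),
    (53376828, "rs733697531", "C", "T", "PRDM4",
     [("intron_variant", "moderate")]),
    (53380585, "rs313232660", "G", "A", "PRDM4",
     [("missense_variant", "moderate")]),
    (53683208, "rs15270486", "A", "G", "MTERF2",
     [("missense_variant", "moderate")]),
    (53688583, None, "C", "T", "TMEM263",
     [("stop_gained", "high")]),
    (54232753, "rs732172030", "G", "A", "C12orf75",
     [("missense_variant", "moderate")]),
    (54834890, "rs733216275", "AT", "GA", "STAB2",
     [("downstream_gene_variant", "modifier"), ("missense_variant", "moderate")]),
    (54838941, "rs14827457;rs14827458", "TG", "CC", "STAB2",
     [("missense_variant", "moderate"), ("upstream_gene_variant", "modifier")]),
    (55461367, "rs13869828", "A", "G", "PARPBP",
     [("missense_variant", "moderate")]),
]


@dataclass
class Table1Fixture:
    variants: VariantTable
    catalogue: KnownVariantCatalogue
    consequences: Dict[VariantKey, List[Consequence]]
    notes: Dict[str, str]


def make_table1_fixture() -> Table1Fixture:
    """The published list of 11 case-unique homozygous candidates on
    chromosome 1, with their printed consequences and the 10 catalogued
    identifiers; the TMEM263 stop-gain is the only uncatalogued record."""
    records = []
    catalogue = KnownVariantCatalogue()
    consequences: Dict[VariantKey, List[Consequence]] = {}
    for pos, rsid, ref, alt, gene, terms in _TABLE1_ROWS:
        rec = VariantRecord(
            chrom="1", pos=pos, ref=ref, alts=(alt,), genotypes=((1, 1),),
            mean_depth=9.1, call_rate=1.0, id=rsid,
        )
        records.append(rec)
        key = ("1", pos, ref, alt)
        consequences[key] = [
            Consequence(variant_key=key, gene_id=gene, term=term, impact=impact)
            for term, impact in terms
        ]
        if rsid is not None:
            catalogue.add("1", pos, ref, alt, rsid)
    notes = {
        "hgvs_alias": "NM_001006244.1:c.433G>A is the published transcript-level "
                      "label for the TMEM263 stop-gain; strict CDS-anchored "
                      "numbering of the fixture transcript gives c.176G>A, "
                      "p.(Trp59*).",
        "printed_impact": "the PRDM4 intron record carries its printed impact "
                          "(moderate), not the term-derived one (modifier).",
    }
    return Table1Fixture(
        variants=VariantTable([_CASE_SAMPLE], records),
        catalogue=catalogue,
        consequences=consequences,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# TMEM263-like gene fixture
# ---------------------------------------------------------------------------

@dataclass
class GeneFixture:
    """A synthetic TMEM263-like gene: 116-residue protein on the minus
    strand whose genomic C>T (transcript G>A) turns codon 59 (TGG, Trp)
    into TAG (stop)."""

    reference: Dict[str, str]
    gene: GeneModel
    variant: VariantRecord
    domains: DomainSet
    protein_length: int


def make_gene_fixture() -> GeneFixture:
    """Build the packaged gene fixture (synthetic sequence; deterministic)."""
    rng = np.random.default_rng(263)
    chrom = "1_tmem_fragment"
    length = 900
    cds_start, cds_end = 301, 651
    seq = rng.choice(_BASES, size=length)
    cds = make_cds(116, trp_at=59)
    minus_plus = cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    seq[cds_start - 1 : cds_end] = np.frombuffer(minus_plus.encode(), dtype="S1")
    reference = {chrom: seq.tobytes().decode()}
    gene = GeneModel(
        gene_id="TMEM263_like",
        biotype="protein_coding",
        strand="-",
        chrom=chrom,
        exons=[(cds_start - 50, cds_end + 50)],
        cds=[(cds_start, cds_end)],
    )
    pos = cds_end - 175  # genomic position of CDS base 176 on the minus strand
    assert reference[chrom][pos - 1] == "C"
    variant = VariantRecord(
        chrom=chrom, pos=pos, ref="C", alts=("T",), genotypes=((1, 1),),
        mean_depth=9.1, call_rate=1.0,
    )
    return GeneFixture(
        reference=reference,
        gene=gene,
        variant=variant,
        domains=DomainSet("TMEM263-like", {"TMR1": (38, 60), "TMR2": (80, 102)}),
        protein_length=116,
    )


# ---------------------------------------------------------------------------
# PCR-RFLP fixture
# ---------------------------------------------------------------------------

_RFLP_FORWARD = "GTTCAATCAAAGACCACCCG"
_RFLP_REVERSE = "TTGGCTTTAGTCAGACTTGTCCT"
_AMPLICON_LEN = 293  # 109 + 184: fragment-sum conservation wins over the
#                      printed 294 bp gel estimate (off by 1)
_CUT_LEFT = 109


@dataclass
class RflpFixture:
    """Synthetic PCR-RFLP template: the variant allele gains a DdeI site
    cutting the 293 bp amplicon into 109 + 184 bp; the reference allele is
    uncut."""

    template: str
    primers: PrimerPair
    enzyme: Enzyme
    variant: VariantRecord  # template coordinates; samples: case, control
    genotypes: Dict[str, Tuple[int, int]]
    amplicon_variant_pos: int  # 1-based within the amplicon


def make_rflp_fixture() -> RflpFixture:
    """Build the packaged RFLP fixture (synthetic template; deterministic).

    The published primers delimit the amplicon; a CTTGG>CTTAG change at
    amplicon position 112 creates the single DdeI site (C^TNAG) cut after
    amplicon base 109.
    """
    primers = PrimerPair(_RFLP_FORWARD, _RFLP_REVERSE)
    rev_rc = _RFLP_REVERSE.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    fill_len = _AMPLICON_LEN - len(_RFLP_FORWARD) - len(rev_rc)
    flank = 30
    var_amp_pos = 112  # 1-based in amplicon; ref G -> alt A
    rng = np.random.default_rng(109184)
    for _ in range(1000):
        filler = "".join(
            "ACGT"[i] for i in rng.integers(0, 4, size=fill_len)
        )
        amplicon = _RFLP_FORWARD + filler + rev_rc
        # plant CTTGG at amplicon positions 109..113
        amplicon = amplicon[:108] + "CTTGG" + amplicon[113:]
        var_amplicon = amplicon[:111] + "A" + amplicon[112:]
        left = "".join("ACGT"[i] for i in rng.integers(0, 4, size=flank))
        right = "".join("ACGT"[i] for i in rng.integers(0, 4, size=flank))
        template = left + amplicon + right
        var_template = left + var_amplicon + right
        if _motif_hits(amplicon, DDEI.recognition):
            continue
        if _motif_hits(var_amplicon, DDEI.recognition) != [108]:
            continue
        if template.count(_RFLP_FORWARD) != 1 or template.count(rev_rc) != 1:
            continue
        if var_template.count(_RFLP_FORWARD) != 1 or var_template.count(rev_rc) != 1:
            continue
        break
    else:  # pragma: no cover - the fixed seed converges immediately
        raise RuntimeError("could not construct RFLP fixture template")
    assert amplicon[var_amp_pos - 1] == "G"
    variant = VariantRecord(
        chrom="rflp_template",
        pos=flank + var_amp_pos,
        ref="G",
        alts=("A",),
        genotypes=((1, 1), (0, 0)),
        mean_depth=9.1,
        call_rate=1.0,
    )
    return RflpFixture(
        template=template,
        primers=primers,
        enzyme=DDEI,
        variant=variant,
        genotypes={"adw": (1, 1), "wt": (0, 0)},
        amplicon_variant_pos=var_amp_pos,
    )
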
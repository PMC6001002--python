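"""Domain types and readers/writers for the formats the pipeline touches.

All coordinates at module interfaces are 1-based closed, matching VCF and
GFF3; BED output is 0-based half-open, matching BED. Any internal half-open
arithmetic is invisible at the interfaces.

VCF is read and written through :mod:`pysam`, GFF3 through :mod:`gffutils`,
tabular catalogues through :mod:`pandas`. All readers accept gzip-compressed
input.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import pysam

from .errors import FormatError, RecordError, ValidationError

__all__ = [
    "VariantRecord",
    "VariantTable",
    "GeneModel",
    "KnownVariantCatalogue",
    "read_vcf",
    "write_vcf",
    "read_gene_models",
    "write_gene_models",
    "read_catalogue",
    "write_catalogue",
    "write_bed",
    "normalize_variant",
    "MISSING_GT",
]

_ACGT = frozenset("ACGT")

#: Genotype value used for a missing call (diploid, both alleles unknown).
MISSING_GT: Tuple[Optional[int], Optional[int]] = (None, None)

Genotype = Tuple[Optional[int], Optional[int]]
VariantKey = Tuple[str, int, str, str]


def _check_allele(allele: str, pos: int) -> None:
    if not allele or not set(allele) <= _ACGT:
        raise RecordError(
            f"non-ACGT allele {allele!r} at position {pos} "
            "(ambiguity codes and symbolic alleles are rejected)"
        )


@dataclass
class VariantRecord:
    """One VCF site: alleles, per-sample genotypes, site QC fields.

    Multi-allelic sites are kept un-split; ``alts`` is ordered as in the
    source file. ``mean_depth`` is the per-site read depth averaged over
    non-missing samples (quantized to 3 decimals so the VCF round-trip
    through a 32-bit INFO Float is lossless); ``call_rate`` is the fraction
    of samples with a non-missing genotype.
    """

    chrom: str
    pos: int
    ref: str
    alts: Tuple[str, ...]
    genotypes: Tuple[Genotype, ...]
    mean_depth: float
    call_rate: float
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise RecordError(f"position must be >= 1, got {self.pos}")
        self.alts = tuple(self.alts)
        _check_allele(self.ref, self.pos)
        for alt in self.alts:
            _check_allele(alt, self.pos)
        if self.ref in self.alts:
            raise RecordError(
                f"ALT duplicates REF allele {self.ref!r} at {self.chrom}:{self.pos}"
            )
        if len(set(self.alts)) != len(self.alts):
            raise RecordError(f"duplicate ALT alleles at {self.chrom}:{self.pos}")
        if not 0.0 <= self.call_rate <= 1.0:
            raise RecordError(
                f"call_rate {self.call_rate} outside [0, 1] at {self.chrom}:{self.pos}"
            )
        self.mean_depth = round(float(self.mean_depth), 3)
        self.call_rate = round(float(self.call_rate), 6)
        self.genotypes = tuple(tuple(gt) for gt in self.genotypes)
        n_alleles = 1 + len(self.alts)
        for gt in self.genotypes:
            for a in gt:
                if a is not None and not 0 <= a < n_alleles:
                    raise RecordError(
                        f"genotype allele index {a} out of range at "
                        f"{self.chrom}:{self.pos}"
                    )

    # -- genotype helpers -------------------------------------------------

    def genotype(self, sample_index: int) -> Genotype:
        return self.genotypes[sample_index]

    def is_missing(self, sample_index: int) -> bool:
        return any(a is None for a in self.genotypes[sample_index])

    def is_het(self, sample_index: int) -> bool:
        a, b = self.genotypes[sample_index]
        return a is not None and b is not None and a != b

    def is_hom_alt(self, sample_index: int) -> bool:
        a, b = self.genotypes[sample_index]
        return a is not None and a == b and a > 0

    def carried_alts(self, sample_index: int) -> Tuple[str, ...]:
        """Alternate allele strings carried by the sample (ignoring missing)."""
        return tuple(
            self.alts[a - 1]
            for a in set(self.genotypes[sample_index])
            if a is not None and a > 0
        )

    def keys(self) -> Tuple[VariantKey, ...]:
        """One (chrom, pos, ref, alt) key per alternate allele."""
        return tuple((self.chrom, self.pos, self.ref, alt) for alt in self.alts)

    @property
    def sort_key(self) -> Tuple[str, int, str, Tuple[str, ...]]:
        return (self.chrom, self.pos, self.ref, self.alts)


@dataclass
class VariantTable:
    """An ordered collection of :class:`VariantRecord` for a fixed sample set.

    Records are kept sorted by (chrom, pos, ref, alts); every record carries
    one genotype per sample in ``sample_names``.
    """

    sample_names: List[str]
    records: List[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_names = list(self.sample_names)
        n = len(self.sample_names)
        for rec in self.records:
            if len(rec.genotypes) != n:
                raise ValidationError(
                    f"record {rec.chrom}:{rec.pos} has {len(rec.genotypes)} "
                    f"genotypes for {n} samples"
                )
        self.records = sorted(self.records, key=lambda r: r.sort_key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_names.index(sample)
        except ValueError:
            raise LookupError(
                f"unknown sample {sample!r}; table has {self.sample_names}"
            ) from None

    def subset(self, records: Iterable[VariantRecord]) -> "VariantTable":
        return VariantTable(self.sample_names, list(records))


@dataclass
class GeneModel:
    """Exon/CDS layout of one gene in genomic coordinates.

    Intervals are 1-based closed, non-overlapping, and sorted by genomic
    start regardless of strand (transcript order is derived from ``strand``).
    ``cds`` is empty for lincRNA models.
    """

    gene_id: str
    biotype: str  # "protein_coding" | "lincRNA"
    strand: str  # "+" | "-"
    chrom: str
    exons: List[Tuple[int, int]]
    cds: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.biotype not in ("protein_coding", "lincRNA"):
            raise ValidationError(f"{self.gene_id}: bad biotype {self.biotype!r}")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        self.cds = sorted((int(s), int(e)) for s, e in self.cds)
        for name, ivals in (("exon", self.exons), ("CDS", self.cds)):
            prev_end = 0
            for s, e in ivals:
                if s < 1 or e < s:
                    raise ValidationError(f"{self.gene_id}: bad {name} ({s}, {e})")
                if s <= prev_end:
                    raise ValidationError(f"{self.gene_id}: overlapping {name}s")
                prev_end = e
        for s, e in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise ValidationError(
                    f"{self.gene_id}: CDS ({s}, {e}) not contained in any exon"
                )
        if self.biotype == "protein_coding":
            if not self.cds:
                raise ValidationError(f"{self.gene_id}: protein_coding without CDS")
            if self.cds_length % 3 != 0:
                raise ValidationError(
                    f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
                )
        elif self.cds:
            raise ValidationError(f"{self.gene_id}: lincRNA with CDS intervals")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)


@dataclass
class KnownVariantCatalogue:
    """dbSNP-like registry of previously observed variants.

    Maps (chrom, pos, ref, alt) keys to database identifiers; used by the
    novelty screen to exclude variants segregating in other populations.
    """

    entries: Dict[VariantKey, str] = field(default_factory=dict)

    def __contains__(self, key: VariantKey) -> bool:
        return tuple(key) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def id_of(self, key: VariantKey) -> Optional[str]:
        return self.entries.get(tuple(key))

    def add(self, chrom: str, pos: int, ref: str, alt: str, ident: str) -> None:
        self.entries[(str(chrom), int(pos), ref, alt)] = ident


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _record_mean_depth(rec: "pysam.VariantRecord", n_samples: int) -> float:
    """Site mean depth: per-sample DP mean over non-missing samples when
    FORMAT/DP is present, else INFO/MDP, else INFO/DP divided by the number
    of samples."""
    depths = []
    for smp in rec.samples.values():
        dp = smp.get("DP")
        if dp is not None:
            depths.append(dp)
    if depths:
        return sum(depths) / len(depths)
    if "MDP" in rec.info:
        return float(rec.info["MDP"])
    if "DP" in rec.info:
        return float(rec.info["DP"]) / max(n_samples, 1)
    raise RecordError(
        f"no depth retrievable (FORMAT/DP, INFO/MDP or INFO/DP) at "
        f"{rec.chrom}:{rec.pos}"
    )


def read_vcf(path) -> VariantTable:
    """Read a VCF 4.x file into a :class:`VariantTable`.

    Multi-allelic sites are retained as single records; missing genotypes
    are preserved. ``call_rate`` is recomputed from the genotype columns.
    """
    path = str(path)
    tmp = None
    try:
        vf = pysam.VariantFile(path)
    except NotImplementedError:
        # plain gzip (not bgzf): htslib cannot seek it; decompress first
        import gzip
        import tempfile

        tmp = tempfile.NamedTemporaryFile("wb", suffix=".vcf", delete=False)
        with gzip.open(path, "rb") as fh:
            tmp.write(fh.read())
        tmp.close()
        vf = pysam.VariantFile(tmp.name)
    except (ValueError, OSError) as exc:
        if isinstance(exc, FileNotFoundError):
            raise
        raise FormatError(f"malformed VCF header in {path}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        records: List[VariantRecord] = []
        for rec in vf:
            if rec.alts is None:
                raise RecordError(f"record without ALT at {rec.chrom}:{rec.pos}")
            genotypes: List[Genotype] = []
            n_called = 0
            for smp in rec.samples.values():
                gt = smp.get("GT")
                if gt is None or len(gt) == 0 or all(a is None for a in gt):
                    genotypes.append(MISSING_GT)
                    continue
                if len(gt) == 1:
                    gt = (gt[0], gt[0])
                genotypes.append((gt[0], gt[1]))
                if all(a is not None for a in gt[:2]):
                    n_called += 1
            call_rate = n_called / len(samples) if samples else 1.0
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts),
                    genotypes=tuple(genotypes),
                    mean_depth=_record_mean_depth(rec, len(samples)),
                    call_rate=call_rate,
                    id=rec.id,
                )
            )
    if tmp is not None:
        import os

        os.unlink(tmp.name)
    return VariantTable(samples, records)


def write_vcf(table: VariantTable, path, extra_header: Optional[Mapping[str, str]] = None) -> None:
    """Write a :class:`VariantTable` as VCF 4.2.

    The header records the pipeline name and any ``extra_header`` key/value
    pairs as ``##recfine_<key>=<value>`` comment lines. Output ordering is
    deterministic (table order, i.e. coordinate-sorted).
    """
    header = pysam.VariantHeader()
    header.add_line("##source=recfine")
    for key, value in (extra_header or {}).items():
        header.add_line(f"##recfine_{key}={value}")
    for contig in sorted({rec.chrom for rec in table.records}):
        header.contigs.add(contig)
    header.info.add("MDP", 1, "Float", "Mean per-site depth over non-missing samples")
    header.formats.add("GT", 1, "String", "Genotype")
    for sample in table.sample_names:
        header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in table.records:
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref,) + rec.alts,
                id=rec.id,
            )
            vrec.info["MDP"] = rec.mean_depth
            for sample, gt in zip(table.sample_names, rec.genotypes):
                vrec.samples[sample]["GT"] = gt
                vrec.samples[sample].phased = False
            out.write(vrec)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _biotype_of(feature, has_cds: bool) -> str:
    for key in ("biotype", "gene_biotype", "gene_type"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return "protein_coding" if has_cds else "lincRNA"


def read_gene_models(path) -> List[GeneModel]:
    """Read gene models (gene/mRNA/exon/CDS features) from GFF3.

    One :class:`GeneModel` per gene feature; GFF3's 1-based closed intervals
    are preserved verbatim. CDS intervals not contained in exons raise a
    validation error naming the gene.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc
    models: List[GeneModel] = []
    for gene in db.features_of_type(("gene", "ncRNA_gene"), order_by="start"):
        exons = sorted(
            (f.start, f.end) for f in db.children(gene, featuretype="exon")
        )
        cds = sorted((f.start, f.end) for f in db.children(gene, featuretype="CDS"))
        if not exons:
            exons = [(gene.start, gene.end)]
        models.append(
            GeneModel(
                gene_id=gene.id,
                biotype=_biotype_of(gene, bool(cds)),
                strand=gene.strand,
                chrom=gene.seqid,
                exons=exons,
                cds=cds,
            )
        )
    return models


def write_gene_models(models: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS rows)."""
    lines = ["##gff-version 3"]
    for g in sorted(models, key=lambda m: (m.chrom, m.start)):
        attrs = f"ID={g.gene_id};biotype={g.biotype}"
        ftype = "gene" if g.biotype == "protein_coding" else "ncRNA_gene"
        lines.append(
            f"{g.chrom}\trecfine\t{ftype}\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        tid = f"{g.gene_id}.t1"
        ttype = "mRNA" if g.biotype == "protein_coding" else "lincRNA"
        lines.append(
            f"{g.chrom}\trecfine\t{ttype}\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={tid};Parent={g.gene_id}"
        )
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append(
                f"{g.chrom}\trecfine\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={tid}.exon{i};Parent={tid}"
            )
        for i, (s, e) in enumerate(g.cds, 1):
            lines.append(
                f"{g.chrom}\trecfine\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                f"ID={tid}.cds{i};Parent={tid}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Catalogue / BED
# ---------------------------------------------------------------------------

_CATALOGUE_COLUMNS = ["chrom", "pos", "ref", "alt", "id"]


def read_catalogue(path) -> KnownVariantCatalogue:
    """Read a known-variant catalogue from TSV (columns chrom pos ref alt id).

    Duplicate (chrom, pos, ref, alt) keys are collapsed to the first entry
    with a warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse catalogue {path}: {exc}") from exc
    missing = [c for c in _CATALOGUE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"catalogue {path} missing column(s): {', '.join(missing)}")
    cat = KnownVariantCatalogue()
    n_dup = 0
    for row in df.itertuples(index=False):
        key = (str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        if key in cat.entries:
            n_dup += 1
            continue
        cat.entries[key] = str(row.id)
    if n_dup:
        warnings.warn(f"catalogue {path}: collapsed {n_dup} duplicate key(s)")
    return cat


def write_catalogue(cat: KnownVariantCatalogue, path) -> None:
    rows = [
        {"chrom": c, "pos": p, "ref": r, "alt": a, "id": i}
        for (c, p, r, a), i in sorted(cat.entries.items())
    ]
    pd.DataFrame(rows, columns=_CATALOGUE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_bed(intervals: Iterable[Tuple[str, int, int, str]], path) -> None:
    """Write (chrom, start, end, name) 1-based closed intervals as BED
    (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# Allele normalization
# ---------------------------------------------------------------------------

def normalize_variant(
    chrom: str, pos: int, ref: str, alt: str, reference: Mapping[str, str]
) -> Tuple[str, int, str, str]:
    """Left-normalize an allele pair against the reference sequence.

    Trims shared suffix/prefix bases, then shifts indels left while the
    trailing base of the longer allele equals the base preceding the site
    (the standard vt/bcftools normalization); SNVs pass through unchanged.
    Needed so allele-identity comparisons across files use a canonical form.
    """
    seq = reference[chrom]
    ref, alt = ref.upper(), alt.upper()
    while True:
        # shared trailing base: drop it; if an allele empties, pull in the
        # preceding reference base (this is what shifts an indel left)
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1 or pos > 1):
            if len(ref) == 1 and len(alt) == 1:
                break
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    raise RecordError(
                        f"cannot left-normalize {chrom}:{pos} at contig start"
                    )
                prev = seq[pos - 2].upper()
                ref, alt = prev + ref, prev + alt
                pos -= 1
            continue
        break
    # shared leading base beyond the anchor: trim and advance
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt
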
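# Methods

`recfine` implements the fine-mapping workflow used to identify a recessive
causal variant from a single affected genome compared against a control
cohort: autozygosity mapping by runs of homozygosity (ROH), a four-step
candidate filtering cascade, consequence annotation with protein-level
effects, and in-silico validation (PCR-RFLP genotyping and ddCt relative
expression). The motivating use case is autosomal dwarfism (adw) in chicken,
a recessive growth-deficiency trait fine-mapped to a TMEM263 stop-gain, and
the packaged fixtures mirror that system; the machinery itself is generic.

## Model and assumptions

The trait is assumed fully penetrant, recessive, and monogenic, so the
affected individual is autozygous (identical by descent) around the causal
locus and homozygous for the causal allele. The causal allele is assumed
absent from unaffected control genomes of the source population and from
public variant catalogues. Under these assumptions the causal variant is the
intersection of four predicates, evaluated per alternate allele after site
QC:

1. **case-unique** — carried by the case, carried by zero controls. The
   comparison is allele-level at each position: a homozygous-reference
   control does not disqualify an allele, a heterozygous carrier does.
   Missing control genotypes count as non-carriers; the call-rate filter
   already bounds missingness.
2. **homozygous** — the case genotype is homozygous for the unique
   alternate allele; heterozygous and missing genotypes drop out.
3. **protein-altering** — at least one consequence of the allele is of
   high or moderate impact. Variants whose consequences are all low or
   modifier form the non-coding branch, which is retained and reported
   separately after the novelty screen.
4. **novel** — the (chrom, pos, ref, alt) key is absent from the
   known-variant catalogue.

Steps 1 and 2 commute (both are per-allele predicates); the composed
cascade equals the per-variant conjunction of the four predicates, and both
facts are asserted by tests.

### Site QC

Records enter the cascade only if the site mean depth lies in the inclusive
band [3, 25] (multiples of per-site read depth, x) and the genotype call
rate is strictly greater than 0.7. Mean depth is the arithmetic mean of
per-sample FORMAT/DP over non-missing samples when available, else a
site-level INFO value divided by the sample count; which samples enter the
mean is a documented choice exposed through the reader rather than a claim
about any particular upstream caller.

## ROH detection

The genome segment is tiled into fixed windows (default 10 kb) anchored at
position 1; a trailing partial window is never evaluable. Per window the
focal sample's heterozygous call count and the mean site depth over all its
records are collected. Counting heterozygous calls is the default
(`count_mode="het"`): an ROH estimates autozygosity and a homozygous-alt
site is not evidence of heterozygosity; counting all variant sites is
available as `count_mode="all"`.

Against the averages over evaluable windows, an autozygous stretch must:

* start and end at a *seed* window with count < 0.25x the average;
* contain no evaluable window above 2x the average (a relaxed per-window
  bound that bridges local assembly or alignment artifacts inside a
  stretch);
* span at least 10 evaluable windows;
* keep its mean count at or below 0.25x the average.

The endpoint-seed requirement is deliberate: with only "a seed window
exists somewhere in the run", the relaxed 2x interior bound would let a
maximal stretch absorb ~15 windows of ordinary background on each flank
before the mean bound binds, smearing boundaries by >100 kb. Requiring
seeds at both ends pins boundaries to the autozygous windows themselves;
the relaxed bound then does what it is for — tolerating artifact windows
*inside* a stretch. Windows that are non-evaluable (depth outside the
0.5–2x band, or no covered sites) neither count nor break a run, up to a
configurable gap of 2 consecutive windows.

Calling enumerates qualifying runs (seeds are sparse, so this is cheap),
keeps inclusion-maximal ones, and resolves overlaps deterministically: the
union when the union itself qualifies, otherwise the run with more
evaluable windows, leftmost on ties. Tests assert exact equivalence with an
exhaustive oracle that enumerates every window run and re-tests the
criteria naively, on segments up to 200 windows.

The monotonicity property (tightening the stretch-mean bound never
increases total called bp) is asserted on seeded realistic profiles
(Poisson background with planted low-het tracts). On adversarial,
hand-crafted count vectors the overlap-resolution rule could in principle
trade one long stretch for two disjoint shorter ones; such profiles do not
arise from the generative process the caller is designed for.

## Consequence annotation

Gene models are exon/CDS interval sets in 1-based closed genomic
coordinates. CDS SNVs are classified strand-aware by codon comparison of
the reference versus alternate spliced CDS: synonymous, missense,
stop-gain, stop-loss. Indels in CDS are frameshift (length change not a
multiple of 3) or in-frame. Exonic non-CDS positions are 5'/3' UTR by
transcript orientation; lincRNA exons are non-coding transcript variants;
positions between exons are intronic. `splice_region_variant` covers
positions within 3 bp of a splice junction on the exonic side or within
8 bp on the intronic side — the common annotator convention, since the term
is used in the field without a universal definition. Upstream/downstream
calls use a 5 kb window (parameterized). A variant may carry one
consequence per overlapping feature; impact (high / moderate / low /
modifier) is a pure function of the term, following the standard
SnpEff/VEP-style tiering.

HGVS c. numbering is strictly CDS-anchored (c.1 = A of ATG), and p.
descriptions use the three-letter code with `*` for a stop, e.g.
`p.(Trp59*)`. For a stop at residue *s* of a protein of length *L*, the
retained peptide is residues 1..s-1 and the truncation fraction is
(s-1)/L. A named protein domain is *disrupted* if the stop falls inside it,
*lost* if it lies entirely downstream of the retained residues, *intact*
otherwise. The default domain set is the TMEM263-like topology with two
membrane-spanning helices at residues 38–60 and 80–102, so a stop at
residue 59 disrupts TMR1 and loses TMR2 (58 retained residues, 50%
truncation of a 116-residue protein).

Tests assert exact agreement with a translate-and-diff oracle — mutate the
genome, re-splice, translate the whole protein, diff — over every possible
SNV of random 300-nt coding sequences, on both strands, spliced and
unspliced.

## In-silico PCR-RFLP

PCR is exact primer matching: the forward primer on the top strand, the
reverse primer's reverse complement strictly downstream; the amplicon spans
5' end to 5' end inclusive and must be unique (multiple products raise an
error listing loci). Mismatch-tolerant matching is out of scope — the
modeled assay is standard PCR with validated primers. Digestion finds all
top-strand matches of an IUPAC recognition motif (overlaps allowed) and
cuts at a fixed offset from the motif start; fragments are the inter-cut
intervals, so their lengths always sum to the substrate length.
Double-strand overhangs are ignored because only fragment sizes are
observable on a gel. The shipped enzyme table holds DdeI (C^TNAG, cut after
the first base); others can be supplied as `Enzyme` objects or CLI specs.

The packaged RFLP fixture uses a 293-bp amplicon: the variant allele's
single DdeI site cuts it into 109 + 184 bp and the reference allele is
uncut. 293 rather than 294 bp is a deliberate choice — fragment lengths
must sum to the amplicon length, so the fragment sizes are treated as exact
and the undigested size as derived (gel estimates round).

## ddCt relative expression

Per sample, dCt = mean(Ct_target) − mean(Ct_housekeeping) over technical
replicates; ddCt subtracts the calibrator-group mean dCt; fold change =
2^(−ddCt). Group summaries report mean ± sd of dCt and the geometric-mean
fold change (2^(−mean ddCt)), which makes the calibrator group's summary
fold change exactly 1. A two-sided Welch t-test on dCt between groups is
reported descriptively when both groups have at least two samples; the
choice of test is configurable territory, so the result is attached to the
output rather than gating anything. Fold changes are invariant under any
global Ct shift, asserted by test.

## Synthetic cohorts

`simulate_cohort` plants: a 116-residue coding gene at the centre of the
autozygous tract whose codon 59 is TGG, with the causal G>A at the codon's
second base; heterozygous SNPs at `snp_density` per kb outside the tract
(default 2.0/kb, a realistic layer-chicken heterozygosity) and at
`residual_roh_snp_rate` times that inside it (default 0.02); homozygous-alt
sites at the same density everywhere (these anchor window depth without
breaking ROH); control-only sites; and a small set of case-unique
homozygous intergenic variants that survive to the non-coding branch.
Shared and control-only variants are catalogued; case-unique variants are
novel. Depths are log-normal with median 9.1x (the coverage of the
motivating study) and log-sd 0.6, so ~8% of sites violate the QC band; the
causal site is QC-safe by construction. Control genotypes are drawn from a
per-site allele frequency ~ Uniform(0.1, 0.9) with 5% missingness and a
guaranteed carrier, since a shared site with zero drawn carriers would
silently become case-unique.

What the simulator does **not** emulate: linkage disequilibrium and
recombination structure, indels and structural variants, alignment
artifacts correlated along the genome, population allele-frequency spectra,
and genotyping error. Passing the planted-truth tests therefore shows the
pipeline's logic is correct under the stated model, not that the thresholds
are optimal for any particular real dataset.

Determinism: one `numpy` generator seeded from `SimulationParams.seed`
drives every draw, and identical parameters produce byte-identical output
files (asserted by test).

## Numerical and interface choices

* `mean_depth` is quantized to 3 decimals at record construction: VCF INFO
  Float is 32-bit on disk, and quantization makes the write/read round-trip
  exactly lossless.
* All interface coordinates are 1-based closed (VCF/GFF3); BED output is
  0-based half-open. Window tiling anchors at position 1; trailing partial
  windows are excluded from evaluation.
* Indel comparison assumes left-normalized alleles; `normalize_variant`
  implements the standard trim-and-shift algorithm for inputs that need it.
* Degenerate inputs fail loudly: zero evaluable windows, a baseline of zero
  SNPs, unknown sample names, unannotated records in the impact partition,
  and reference/REF disagreements all raise typed errors.

## Problem sizes in tests

The default suite runs the simulator at 0.6–1.5 Mb with 6–12 controls for
unit-level checks, and the recovery suite at 5 Mb with 20 controls over 20
seeds — sizes at which every property is exercised (thousands of variants
per category, 500 windows, multi-candidate traces) while the whole suite
stays fast enough to run on every change. The control-cohort default of 261
matches the motivating study and is used when callers do not override it.

## Known limitations

* Step 1 treats missing control genotypes as non-carriers; a cohort with
  pathological missingness at exactly the causal site could leak a false
  unique allele (bounded by the call-rate filter).
* The annotator classifies against gene models independently; it does not
  collapse consequences across transcripts of the same gene (each model is
  one transcript).
* SIFT-style deleteriousness scores are consumed as optional pre-supplied
  annotations, never computed.
* The ROH caller is single-sample; multi-sample ROH sharing and IBD between
  individuals are out of scope.
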
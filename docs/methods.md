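# Methods

`splicem6a` implements a desk-scale computational pipeline around 3′
splice-site N6-methyladenosine (m⁶A). The biological picture it serves:
the conserved methyltransferase METTL16 (worm METT-10) methylates the
acceptor adenosine of select 3′ splice sites when its recognition motif
(UACAGAGA / UACAGAAA class, with the motif's AG being the acceptor AG)
sits in a stem-loop; the mark blocks U2AF35 from reading the acceptor
and shifts splicing toward an upstream cryptic acceptor (AS isoform) or
intron retention (IR isoform), away from the protein-coding (PC)
isoform. The package provides the four analyses such a study needs —
a genome-wide motif+structure screen, PC/AS/IR quantification,
a differential IP/input enrichment test between genotypes, and metagene
coverage profiles — plus a fully seeded synthetic-data generator that
the test-suite uses to demonstrate parameter recovery.

## Coordinates

All annotation-facing code uses 1-based fully closed intervals (GTF
convention); bedGraph coverage is 0-based half-open. Exactly two named
helpers (`one_based_to_bed`, `bed_to_one_based`) perform the
conversion. Under the inclusive convention the worm SAM-synthetase
canonical intron chrIV:5848949–5849317 has length 369 nt, which is the
reading that reconciles the published RT-PCR product sizes (fully
spliced 133 bp + 369 retained nt = 502 bp intron-retained product;
148 + 369 = 517 bp for the transgene reporter). The analogous
arithmetic for the *alternative* acceptor is off by one under any
single convention (276-nt alternative intron vs the 225/239-bp AS
products) — the AS coordinate convention of the source data is
ambiguous — so AS amplicon arithmetic is deliberately not exposed as a
validated quantity.

A 3′ splice site is stored with its intron interval and the genomic
coordinate of the methylatable acceptor A: `intron_end − 1` on '+',
`intron_start + 1` on '−'. Non-AG acceptors are kept and flagged
rather than dropped, so annotation noise cannot abort a genome-wide
run; the anchored motif scan excludes them naturally. Windows
containing N are skipped with reason `ambiguous_base` (folding over N
is undefined).

## Motif + structure screen

Acceptor-centred windows (default flank 20 → 41 nt, the methylatable A
at the centre) are scanned for motifs in a single register: motif
positions `methyl_index`..`methyl_index+1` must coincide with the
acceptor AG. There is no sliding match — the screen targets the
splice-site adenosine specifically, and one hit per (site, motif) is
emitted.

Folding uses deterministic base-pair maximization (Nussinov dynamic
programming) over Watson–Crick plus G·U pairs with a minimum hairpin
loop of 3 nt. The downstream similarity statistic consumes only the
dot-bracket string — it counts positions paired in both the candidate
and a reference hairpin — so a maximum-pairing engine is sufficient for
rank behaviour, and it makes reruns byte-identical. Determinism of the
traceback is pinned: a position is left unpaired only if no pairing of
it achieves the optimum; otherwise it pairs with the smallest
admissible partner achieving the optimum. Thermodynamic folds from an
external tool can be injected as a precomputed window→dot-bracket
mapping and take precedence over the internal engine.

Ranking sorts by similarity descending, ties broken by (contig,
coordinate), with 1-based competition ranks (ties share the better
rank). Motif-positive but structure-poor sites are retained with their
low scores; no score cutoff is imposed, because none is biologically
established. The reference hairpin is configurable (dot-bracket string
or a sequence folded by the same engine); the synthetic datasets carry
their own designed reference in the truth manifest.

The screen reports both the acceptor-unique site count (its working
set; sites shared by transcripts are de-duplicated on contig/strand/
acceptor position) and the transcript-redundant count, since annotation
databases quote either convention.

## Isoform quantification

For a locus with canonical intron (methylatable acceptor) and a nested
alternative intron sharing the donor:

* PC = unique-read count of the junction exactly matching the canonical
  intron (both ends; near-miss junctions within ±1 nt are tallied into
  a QC column instead of being merged, so coordinate-dialect errors
  surface);
* AS = count of the junction exactly matching the alternative intron;
* IR = mean per-base coverage over the canonical intron trimmed by 10
  nt on both sides (symmetric trimming avoids splice-junction edge
  artifacts);

all scaled to rpm (count × 10⁶ / library size). The library size is
always supplied explicitly as total mapped reads — junction tables
undercount the library and are never used to infer it. Because rpm is
linear, trimming-then-averaging and averaging-then-scaling commute.

## Differential methylation (interaction LRT)

Per gene, counts from the 2×2×replicates design (assay ∈ {input, ip} ×
genotype ∈ {WT, KO}) are modelled as negative binomial with log link
and log size-factor offsets:

    full:    log μ = offset + β₀ + β₁·IP + β₂·KO + β₃·IP:KO
    reduced: log μ = offset + β₀ + β₁·IP + β₂·KO

β₃ (reported in log2) is the change of IP/input enrichment in the KO;
genes losing methylation have β₃ < 0. Size factors are median-of-ratios
against the geometric-mean pseudo-reference over genes positive in all
samples, rescaled so the median factor is 1 (an unperturbed majority of
samples keeps factor 1.0; with no all-positive gene the code falls back
to library-size factors with a warning). The test statistic LR =
2(ℓ_full − ℓ_reduced) uses a dispersion shared by both fits.

Two small-sample corrections matter at triplicate sample sizes, and
both were chosen after measuring null calibration on simulated data
(the package's own simulations; see `tests/test_acceptance.py`):

1. **Dispersion** is estimated per gene by Cox–Reid *adjusted* profile
   maximum likelihood under the full model (the adjustment subtracts
   ½ log det X′WX), bounded to [10⁻⁸, 10]. Plain profile ML is biased
   low when four mean parameters are fit on 12 observations and makes
   the test anticonservative.
2. **Reference distribution**: LR is referred to F(1, n − p) rather
   than χ²(1). The χ² reference is exact only for known dispersion;
   with per-gene estimated dispersion the F reference absorbs the
   estimation uncertainty (the quasi-likelihood logic of edgeR's QL
   F-test). The two references coincide as residual df grows.

Genes with total count < 10 (configurable) are excluded before fitting
and flagged `low_count`; failed or non-converged fits are flagged and
excluded from the Benjamini–Hochberg adjustment (m is reduced
accordingly). Target calling selects padj ≤ threshold (default 0.1)
with the requested interaction sign. Dispersion-shrinkage toward a
fitted trend, outlier refitting and Wald tests are out of scope.

Relative splice-site usage divides junction rpm by host-gene rpm per
sample; samples with zero gene expression yield undefined usage, and
sites undefined in an entire genotype are flagged and excluded from the
KO−WT delta ranking.

## Metagene profiles

Genome coverage is projected onto transcript coordinates by exon-wise
concatenation (minus strand reversed). The 5′UTR, CDS and 3′UTR each
contribute 100 equal-width *fractional* bins: bin k of a length-L
region covers continuous positions [kL/100, (k+1)L/100), computed
exactly through the cumulative integral of the coverage step function,
so regions need not be divisible by 100. Regions shorter than 100 nt
(configurable; applied to all three regions) are excluded from their
region's bins only. Bins with zero contributors are NaN, never
zero-filled.

The stop-codon profile is the per-position mean over ±500 nt around the
first base of the stop codon. `TranscriptModel.cds` follows the GTF
convention of excluding the stop codon, so the centre is the first
transcript position after the CDS 3′ end; out-of-transcript positions
are clipped, and the contributor count decays accordingly.

## Synthetic data

The generator defines the conditions under which the pipeline is
validated:

* **Genome/annotation** — two-exon genes on alternating strands of one
  contig, intron lengths uniform on [200, 800] nt, all acceptors forced
  to end in AG. Structured (methylatable) acceptors carry the 9-mer
  motif UACAGAAAC in the loop of a designed hairpin with an 8-bp GC
  stem, padded with low-pairing A/C filler; the 41-nt window is placed
  so the methylated A is the acceptor A. Unstructured motif controls
  keep the motif but draw their flanks from a low-pairing {A, C}
  alphabet and are accepted only if their fold shares ≤ 3 paired
  positions with the structured reference (≤ 100 redraws, then error).
  A literal shuffle of the structured flanks was rejected as a control
  design: shuffling preserves the G-rich/C-rich flank composition, and
  under base-pair maximization such flanks re-form a stem at nearly the
  same positions, so a shuffled "control" is not actually unstructured.
  Background acceptors are verified to carry no anchored motif.
* **Splicing data** — per gene and sample, 10⁴ junction-depth molecules
  split Multinomial(PC, AS, IR). Methylated genes use genotype-specific
  weights, default WT (0.08, 0.46, 0.46) vs KO (0.64, 0.18, 0.18),
  i.e. an 8-fold PC increase on loss of methylation, mirroring the
  magnitude reported for the worm SAM-synthetase locus; unmethylated
  genes splice efficiently (KO-like weights) in both genotypes. PC/AS
  molecules become junction rows in the spliced-aligner table dialect;
  IR molecules become uniform coverage over the canonical intron; exons
  get coverage equal to total expression. The alternative-acceptor
  retained segment is *not* added to intron coverage — IR coverage
  represents the intron-retention signal alone, a simplification
  relative to real read pileups.
* **IP/input counts** — NB counts with μ = base mean × size factor ×
  enrichment, dispersion 0.05, base means log-uniform on [100, 1000],
  true size factors uniform on [0.7, 1.3] (geometric mean 1), and
  enrichment 4 in WT-IP samples of methylated genes only (loss of
  methylation in the KO), 1 elsewhere. Triplicates per cell match the
  original study design.

Every output stream derives from the master seed via a stable per-file
label (CRC32 of the label seeds a dedicated PCG64 generator), so adding
an output never perturbs existing ones and fixed seeds give
byte-identical files. The truth manifest (JSON) records methylation
status, structure class, loci, weights, NB means, enrichments and size
factors — enough to recompute every expected statistic.

What the generator does *not* emulate: read-level sequencing (fragment
lengths, errors, positional bias), overlapping genes, multi-isoform
loci beyond the three-isoform model, genewise dispersion variation, and
batch effects. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated model, not robustness to
real-library artifacts.

## Problem sizes used in validation

The shipped test-suite and acceptance script validate at: 50-gene
genomes (3 structured + 3 unstructured planted acceptors) for the
screen; 2,000 null genes for LRT calibration (rejection at α = 0.05
within 3 Monte-Carlo SE); 500 genes with 10% planted 4-fold enrichment
loss for power (≥ 0.9 at padj ≤ 0.1); 2,000 genes with 10% non-null
for effect recovery (mean log2 interaction within ±0.25 of −2); 10⁴
junction reads for isoform recovery (within 3 binomial SD; PC
fold-change within 10%). Folding is checked against an exhaustive
enumeration oracle for all lengths ≤ 12 and an independently formulated
DP on 200 random 20-mers.

## Known limitations

* The folder maximizes pair count, not free energy; its dot-brackets
  are not thermodynamic predictions. Use the external-fold injection
  for Turner-rule structures.
* The interaction test assumes a common dispersion per gene across all
  four cells and no outlier handling.
* Effect estimates inherit the composition bias of median-of-ratios
  normalization when a large fraction of genes is truly perturbed; with
  ≤ 10% non-null genes the bias is negligible (see the effect-recovery
  test).
* Junction matching is exact by design; systematically shifted aligner
  dialects appear in the near-miss QC column rather than being
  auto-corrected.
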
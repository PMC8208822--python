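"""Seeded synthetic datasets with machine-readable ground truth.

The generator emulates, at desk scale, the three data layers of a
splice-site m6A study:

1. a toy genome + annotation in which some acceptor windows carry the
   methylation motif inside a designed perfect stem-loop (methylatable),
   some carry the motif in a deliberately low-pairing context (motif
   controls), and the rest are ordinary acceptors;
2. condition-dependent splice-isoform mixtures (PC/AS/IR) realized as
   junction counts plus bedGraph coverage, with the intron-retention
   signal as uniform intron coverage;
3. negative-binomial IP/input count matrices over a WT/KO x input/IP
   triplicate design, in which methylated genes are IP-enriched in the
   WT only — modelling loss of methylation in the KO.

Every output derives from one master seed through per-output named
streams, so adding a file never perturbs the others, and a fixed seed
reproduces byte-identical files.  The accompanying
:class:`TruthManifest` records everything needed to recompute expected
statistics exactly.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genome import GenomeSequence, TranscriptModel, reverse_complement, write_fasta
from .isoforms import CoverageTrack, LocusDefinition
from .screen import DEFAULT_MOTIFS, fold_nussinov, structure_similarity

WINDOW_FLANK = 20
WINDOW_LEN = 2 * WINDOW_FLANK + 1

#: 9-mer methylation motif planted at synthetic acceptors (methylated A at
#: position 4; the trailing C mirrors the worm SAM-synthetase context).
PLANTED_MOTIF = "UACAGAAAC"

#: Designed structured acceptor window: an 8-bp GC stem flanking the motif
#: loop, padded with low-pairing A/C filler; the acceptor AG sits at window
#: positions 21-22 (1-based) with the methylatable A at the centre.
_STEM5 = "GGCAGCGC"
_STEM3 = "GCGCUGCC"  # reverse complement of _STEM5
STRUCTURED_WINDOW = "ACACACACA" + _STEM5 + PLANTED_MOTIF + _STEM3 + "ACACACA"
assert len(STRUCTURED_WINDOW) == WINDOW_LEN
assert STRUCTURED_WINDOW[20:22] == "AG"

#: Maximum number of paired positions an unstructured control's fold may
#: share with the structured reference.
MAX_CONTROL_SIMILARITY = 3


def _rng(seed: int, label: str) -> np.random.Generator:
    """Independent stream derived from the master seed by a stable label."""
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of a synthetic dataset.

    ``isoform_weights`` maps genotype -> (PC, AS, IR) proportions for
    *methylated* loci; unmethylated loci splice efficiently in both
    genotypes (KO-like weights).  The defaults mirror the biological
    situation: inefficient canonical splicing in WT (methylated
    acceptor) and an eight-fold higher PC fraction once methylation is
    lost.
    """

    seed: int = 0
    n_genes: int = 50
    n_planted_structured: int = 3
    n_planted_unstructured: int = 3
    isoform_weights: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "WT": (0.08, 0.46, 0.46),
            "KO": (0.64, 0.18, 0.18),
        }
    )
    junction_depth: int = 10_000
    coverage_depth: int | None = None  # exon depth; None -> total molecules
    nb_mean_range: tuple[float, float] = (100.0, 1000.0)
    nb_dispersion: float = 0.05
    ip_enrichment: float = 4.0
    replicates: int = 3
    n_methylated: int | None = None  # None -> the structured planted genes
    intron_len_range: tuple[int, int] = (200, 800)
    exon_len: int = 320
    alt_acceptor_offset: int = 93  # alternative acceptor this far upstream

    def __post_init__(self) -> None:
        for genotype, weights in self.isoform_weights.items():
            w = np.asarray(weights, dtype=float)
            if (w < 0).any() or (w > 1).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"isoform weights for {genotype!r} must lie in [0,1] and sum to 1"
                )
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_planted_structured + self.n_planted_unstructured > self.n_genes:
            raise ValueError("more planted genes than genes")


@dataclass
class TruthManifest:
    """Ground truth of one synthetic dataset (JSON-serializable)."""

    seed: int
    reference_structure: str = ""
    genes: dict[str, dict] = field(default_factory=dict)
    isoform_weights: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    nb_means: dict[str, float] = field(default_factory=dict)
    wt_ip_enrichment: dict[str, float] = field(default_factory=dict)
    size_factors: dict[str, float] = field(default_factory=dict)
    library_sizes: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        return cls(**json.loads(text))

    def methylated_genes(self) -> list[str]:
        return [g for g, info in self.genes.items() if info.get("methylated")]


def _random_window(rng: np.random.Generator, avoid_motifs: list[str]) -> str:
    """A background acceptor window: ends the intron in AG, carries no
    anchored motif."""
    while True:
        chars = rng.choice(list("ACGU"), size=WINDOW_LEN)
        chars[20], chars[21] = "A", "G"
        window = "".join(chars)
        anchored = window[WINDOW_FLANK - 3 :]
        if not any(anchored.startswith(m) for m in avoid_motifs):
            return window


def _unstructured_window(
    rng: np.random.Generator, reference_structure: str, max_attempts: int = 100
) -> str:
    """Motif-bearing window whose fold shares < 4 paired positions with the
    structured reference; flanks are drawn from a low-pairing {A,C}
    alphabet and re-drawn until the structure check passes."""
    for _ in range(max_attempts):
        left = "".join(rng.choice(list("AC"), size=17))
        right = "".join(rng.choice(list("AC"), size=WINDOW_LEN - 17 - len(PLANTED_MOTIF)))
        window = left + PLANTED_MOTIF + right
        fold = fold_nussinov(window)
        if structure_similarity(fold, reference_structure) <= MAX_CONTROL_SIMILARITY:
            return window
    raise RuntimeError(
        f"failed to draw an unstructured control window in {max_attempts} attempts"
    )


def _transcripts_to_gtf(transcripts: list[TranscriptModel]) -> str:
    lines = []
    for tx in transcripts:
        attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
        for start, end in tx.exons:
            lines.append(
                f"{tx.contig}\tsim\texon\t{start}\t{end}\t.\t{tx.strand}\t.\t{attrs}"
            )
        if tx.cds is not None:
            for start, end in tx.exons:
                lo, hi = max(start, tx.cds[0]), min(end, tx.cds[1])
                if lo <= hi:
                    lines.append(
                        f"{tx.contig}\tsim\tCDS\t{lo}\t{hi}\t.\t{tx.strand}\t0\t{attrs}"
                    )
    return "\n".join(lines) + ("\n" if lines else "")


def build_toy_genome(
    config: SyntheticConfig,
) -> tuple[GenomeSequence, list[TranscriptModel], TruthManifest]:
    """Generate the toy genome, transcript models and truth manifest.

    Each gene is a two-exon transcript on alternating strands of a
    single contig; the 41-nt acceptor window of its intron is
    overwritten with the structured, unstructured-control or background
    design.  The structured reference fold (of the designed stem-loop)
    is recorded in the manifest.
    """
    rng = _rng(config.seed, "genome")
    reference_structure = fold_nussinov(STRUCTURED_WINDOW)

    contig = "chrSim"
    gap = 100
    pos = gap  # 1-based coordinate of the next gene start
    pieces: list[str] = []
    genome_len = 0

    def _extend_random(until: int) -> None:
        nonlocal genome_len
        if until > genome_len:
            pieces.append("".join(rng.choice(list("ACGT"), size=until - genome_len)))
            genome_len = until

    transcripts: list[TranscriptModel] = []
    manifest = TruthManifest(seed=config.seed)
    windows: list[tuple[int, str, str]] = []  # (window genomic start, strand, dna)

    statuses = (
        ["structured"] * config.n_planted_structured
        + ["unstructured"] * config.n_planted_unstructured
        + ["none"] * (config.n_genes - config.n_planted_structured - config.n_planted_unstructured)
    )
    for idx, status in enumerate(statuses):
        gene_id = f"gene{idx + 1:04d}"
        strand = "+" if idx % 2 == 0 else "-"
        intron_len = int(rng.integers(config.intron_len_range[0], config.intron_len_range[1] + 1))
        exon1 = (pos, pos + config.exon_len - 1)
        intron = (exon1[1] + 1, exon1[1] + intron_len)
        exon2 = (intron[1] + 1, intron[1] + config.exon_len)
        cds = (exon1[0] + config.exon_len // 2, exon2[1] - config.exon_len // 2)
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gene_id}.t1",
                gene_id=gene_id,
                contig=contig,
                strand=strand,
                exons=(exon1, exon2),
                cds=cds,
            )
        )
        if status == "structured":
            window = STRUCTURED_WINDOW
        elif status == "unstructured":
            window = _unstructured_window(rng, reference_structure)
        else:
            window = _random_window(rng, [m.sequence for m in DEFAULT_MOTIFS])
        # genomic placement of the sense window around the acceptor A
        if strand == "+":
            target_a = intron[1] - 1
            dna = window.replace("U", "T")
        else:
            target_a = intron[0] + 1
            dna = reverse_complement(window.replace("U", "T"))
        win_start = target_a - WINDOW_FLANK
        windows.append((win_start, strand, dna))
        if strand == "+":
            alt_intron = (intron[0], intron[1] - config.alt_acceptor_offset)
        else:
            alt_intron = (intron[0] + config.alt_acceptor_offset, intron[1])
        manifest.genes[gene_id] = {
            "structure": status,
            "methylated": status == "structured",
            "strand": strand,
            "contig": contig,
            "canonical_intron": list(intron),
            "alternative_intron": list(alt_intron),
            "target_a": target_a,
            "window": window,
        }
        pos = exon2[1] + gap + 1

    _extend_random(pos)
    sequence = list("".join(pieces))
    for win_start, _strand, dna in windows:
        sequence[win_start - 1 : win_start + WINDOW_LEN - 1] = dna
    genome = GenomeSequence({contig: "".join(sequence)})

    manifest.genes = dict(sorted(manifest.genes.items()))
    manifest.isoform_weights = {
        genotype: {
            gene: list(
                config.isoform_weights[genotype]
                if info["methylated"]
                else config.isoform_weights["KO"]
            )
            for gene, info in manifest.genes.items()
        }
        for genotype in config.isoform_weights
    }
    manifest.reference_structure = reference_structure
    return genome, transcripts, manifest


def locus_from_manifest(manifest: TruthManifest, gene: str) -> LocusDefinition:
    info = manifest.genes[gene]
    return LocusDefinition(
        locus_id=gene,
        contig=info["contig"],
        canonical_intron=tuple(info["canonical_intron"]),
        alternative_intron=tuple(info["alternative_intron"]),
    )


@dataclass
class SplicingSample:
    """Simulated junction + coverage data for one sample."""

    sample: str
    genotype: str
    junctions: list[tuple[str, int, int, int, int, int, int]]  # SJ dialect rows
    coverage: CoverageTrack
    library_size: int

    def junction_tsv(self) -> str:
        return "".join(
            "\t".join(str(v) for v in row) + "\n" for row in self.junctions
        )


def simulate_splicing_data(
    config: SyntheticConfig,
    manifest: TruthManifest,
    transcripts: list[TranscriptModel] | None = None,
) -> dict[str, SplicingSample]:
    """Draw per-sample junction counts and coverage for every locus.

    For each gene and sample, ``junction_depth`` molecules are split
    Multinomial(PC, AS, IR) with the genotype's weights (unmethylated
    genes use the efficient KO-like weights in both genotypes).  PC and
    AS molecules become spliced-junction reads on the canonical and
    alternative introns; IR molecules become uniform coverage over the
    canonical intron; exon coverage reflects total expression.
    """
    exon_map = {tx.gene_id: tx.exons for tx in transcripts} if transcripts else {}
    samples: dict[str, SplicingSample] = {}
    for genotype in ("WT", "KO"):
        for rep in range(1, config.replicates + 1):
            sample_id = f"{genotype}_rep{rep}"
            rng = _rng(config.seed, f"splice:{sample_id}")
            junction_rows = []
            cov_rows: list[tuple[int, int, float]] = []
            library_size = 0
            for gene, info in manifest.genes.items():
                weights = manifest.isoform_weights[genotype][gene]
                n_pc, n_as, n_ir = rng.multinomial(config.junction_depth, weights)
                total = int(n_pc + n_as + n_ir)
                library_size += total
                strand_code = 1 if info["strand"] == "+" else 2
                cs, ce = info["canonical_intron"]
                als, ale = info["alternative_intron"]
                if n_pc > 0:
                    junction_rows.append(
                        (info["contig"], cs, ce, strand_code, 1, 1, int(n_pc))
                    )
                if n_as > 0:
                    junction_rows.append(
                        (info["contig"], als, ale, strand_code, 1, 0, int(n_as))
                    )
                exon_depth = (
                    config.coverage_depth if config.coverage_depth is not None else total
                )
                for start, end in exon_map.get(
                    gene, ((cs - config.exon_len, cs - 1), (ce + 1, ce + config.exon_len))
                ):
                    cov_rows.append((start - 1, end, float(exon_depth)))
                if n_ir > 0:
                    cov_rows.append((cs - 1, ce, float(n_ir)))
            junction_rows.sort(key=lambda r: (r[0], r[1], r[2]))
            cov_rows.sort()
            contig = next(iter(manifest.genes.values()))["contig"] if manifest.genes else "chrSim"
            track = CoverageTrack()
            if cov_rows:
                track.intervals[contig] = (
                    np.array([r[0] for r in cov_rows], dtype=np.int64),
                    np.array([r[1] for r in cov_rows], dtype=np.int64),
                    np.array([r[2] for r in cov_rows], dtype=float),
                )
            samples[sample_id] = SplicingSample(
                sample=sample_id,
                genotype=genotype,
                junctions=junction_rows,
                coverage=track,
                library_size=library_size,
            )
            manifest.library_sizes[sample_id] = library_size
    return samples


@dataclass
class SimulatedCounts:
    """An IP/input x WT/KO count matrix with its metadata and truth."""

    counts: pd.DataFrame  # genes x samples
    samples: pd.DataFrame  # sample, assay, genotype, replicate
    true_size_factors: pd.Series
    nb_means: pd.Series
    wt_ip_enrichment: pd.Series


def simulate_ip_counts(
    config: SyntheticConfig,
    manifest: TruthManifest | None = None,
) -> SimulatedCounts:
    """Draw NB counts for the input/IP x WT/KO x replicate design.

    ``mu = base_mean * size_factor * enrichment`` with enrichment
    ``config.ip_enrichment`` in WT-IP samples of methylated genes and 1
    elsewhere; counts are NB with dispersion ``config.nb_dispersion``.
    When no manifest is supplied, the first ``n_methylated`` genes
    (default: the number of structured planted genes) are methylated.
    """
    if manifest is not None:
        gene_ids = list(manifest.genes)
        methylated = np.array(
            [manifest.genes[g]["methylated"] for g in gene_ids], dtype=bool
        )
    else:
        n_meth = (
            config.n_methylated
            if config.n_methylated is not None
            else config.n_planted_structured
        )
        gene_ids = [f"gene{i + 1:04d}" for i in range(config.n_genes)]
        methylated = np.arange(config.n_genes) < n_meth

    sample_rows = []
    for assay in ("input", "ip"):
        for genotype in ("WT", "KO"):
            for rep in range(1, config.replicates + 1):
                sample_rows.append(
                    {
                        "sample": f"{assay}_{genotype}_{rep}",
                        "assay": assay,
                        "genotype": genotype,
                        "replicate": rep,
                    }
                )
    samples = pd.DataFrame(sample_rows)

    rng_mean = _rng(config.seed, "nbmeans")
    lo, hi = config.nb_mean_range
    base_means = np.exp(rng_mean.uniform(np.log(lo), np.log(hi), size=len(gene_ids)))

    rng_sf = _rng(config.seed, "sizefactors")
    true_sf = rng_sf.uniform(0.7, 1.3, size=len(samples))
    true_sf /= np.exp(np.mean(np.log(true_sf)))  # geometric mean 1

    enrich_gene = np.where(methylated, config.ip_enrichment, 1.0)
    is_wt_ip = (
        (samples["assay"] == "ip") & (samples["genotype"] == "WT")
    ).to_numpy()
    mu = base_means[:, None] * true_sf[None, :]
    mu = mu * np.where(is_wt_ip[None, :], enrich_gene[:, None], 1.0)

    rng_counts = _rng(config.seed, "counts")
    disp = config.nb_dispersion
    counts = rng_counts.negative_binomial(n=1.0 / disp, p=1.0 / (1.0 + disp * mu))
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples["sample"])
    counts_df.index.name = "gene"

    result = SimulatedCounts(
        counts=counts_df,
        samples=samples,
        true_size_factors=pd.Series(true_sf, index=samples["sample"]),
        nb_means=pd.Series(base_means, index=gene_ids),
        wt_ip_enrichment=pd.Series(enrich_gene, index=gene_ids),
    )
    if manifest is not None:
        manifest.nb_means = {g: float(m) for g, m in result.nb_means.items()}
        manifest.wt_ip_enrichment = {
            g: float(e) for g, e in result.wt_ip_enrichment.items()
        }
        manifest.size_factors = {
            s: float(f) for s, f in result.true_size_factors.items()
        }
    return result


def write_dataset(config: SyntheticConfig, outdir: str | Path) -> TruthManifest:
    """Generate a full dataset on disk: FASTA, GTF, per-sample junction
    TSV + bedGraph, counts TSV, sample sheet and manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, transcripts, manifest = build_toy_genome(config)
    write_fasta(genome, outdir / "genome.fa")
    (outdir / "annotation.gtf").write_text(_transcripts_to_gtf(transcripts))
    splicing = simulate_splicing_data(config, manifest, transcripts)
    for sample_id, sample in splicing.items():
        (outdir / f"{sample_id}.SJ.tsv").write_text(sample.junction_tsv())
        (outdir / f"{sample_id}.bedgraph").write_text(sample.coverage.to_bedgraph())
    sim = simulate_ip_counts(config, manifest)
    sim.counts.to_csv(outdir / "counts.tsv", sep="\t")
    sim.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
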
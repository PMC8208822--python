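# splicem6a

Analysis of N6-methyladenosine (m⁶A) at 3′ splice sites.

The conserved methyltransferase METTL16 (METT-10 in *C. elegans*)
methylates the acceptor adenosine of a 3′ splice site when its
recognition motif — the UACm⁶AGAGA / UACm⁶AGAAA class, in which the AG
following the methylated A *is* the acceptor AG — is presented in a
stem-loop. The mark prevents U2AF35 from recognizing the acceptor,
suppressing the protein-coding (PC) splice isoform in favour of an
upstream cryptic acceptor (AS isoform) or intron retention (IR), the
mechanism by which worms tune SAM-synthetase (*sams*) expression to
diet. `splicem6a` packages the computational side of such a study for
genomicists working with m⁶A-IP-seq (meRIP) and RNA-seq data:

* **screen** — enumerate annotated 3′ splice sites from FASTA + GTF,
  find motifs anchored on the acceptor AG in 41-nt windows, fold each
  window by deterministic base-pair maximization, and rank candidates
  by the number of paired positions their dot-bracket shares with a
  reference hairpin;
* **quantify** — PC/AS/IR isoform abundances from spliced-aligner
  junction tables and bedGraph coverage, rpm-normalized
  (rpm = count × 10⁶ / library size);
* **diffmeth** — a per-gene negative-binomial GLM likelihood-ratio
  test for genotype-dependent loss of IP/input enrichment, comparing
  `~ assay + genotype + assay:genotype` against `~ assay + genotype`
  with log size-factor offsets and a shared Cox–Reid-profiled
  dispersion; targets are genes with padj ≤ 0.1 and a negative
  interaction (enrichment lost in the knockout);
* **usage** — relative 3′ splice-site usage (junction rpm / gene rpm)
  and its KO − WT change;
* **metagene** — 100-bin coverage metaprofiles over 5′UTR / CDS /
  3′UTR and ±500 nt stop-codon profiles;
* **simulate** — seeded synthetic genomes, splicing data and IP/input
  count matrices with a machine-readable truth manifest.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Generate a 50-gene toy dataset (3 methylatable stem-loop acceptors,
3 motif-only controls), run the screen, quantify isoforms at a
methylated locus, and test for loss of enrichment:

```python
from splicem6a.simulate import (SyntheticConfig, build_toy_genome,
                                simulate_splicing_data, simulate_ip_counts,
                                locus_from_manifest)
from splicem6a.screen import run_screen
from splicem6a.isoforms import quantify_isoforms, JunctionRecord
from splicem6a.diffmeth import nb_lrt_interaction, call_targets

cfg = SyntheticConfig(seed=7)
genome, transcripts, manifest = build_toy_genome(cfg)

res = run_screen(genome, transcripts, reference=manifest.reference_structure)
print(f"sites examined = {res.n_sites_examined}, motif hits = {res.n_motif_hits}")
print(res.table[["name", "motif", "similarity", "rank"]].head(6).to_string(index=False))
```

```
sites examined = 50, motif hits = 6
                name    motif  similarity  rank
gene0001:gene0001.t1 UACAGAAA          20     1
gene0002:gene0002.t1 UACAGAAA          20     1
gene0003:gene0003.t1 UACAGAAA          20     1
gene0004:gene0004.t1 UACAGAAA           3     4
gene0005:gene0005.t1 UACAGAAA           3     4
gene0006:gene0006.t1 UACAGAAA           3     4
```

All six motif-bearing acceptors are found; the three whose windows fold
into the reference hairpin (similarity 20 of a possible 20 paired
positions) outrank the three scrambled-context controls (similarity 3).

```python
samples = simulate_splicing_data(cfg, manifest, transcripts)
gene = manifest.methylated_genes()[0]
locus = locus_from_manifest(manifest, gene)
for sid in ("WT_rep1", "KO_rep1"):
    s = samples[sid]
    junctions = [JunctionRecord(r[0], r[1], r[2], r[3], r[6]) for r in s.junctions]
    q = quantify_isoforms(junctions, s.coverage, locus, s.library_size)
    print(f"{gene} {sid}: PC={q.pc_rpm:.1f} AS={q.as_rpm:.1f} IR={q.ir_rpm:.1f} rpm")
```

```
gene0001 WT_rep1: PC=1598.0 AS=9354.0 IR=9048.0 rpm
gene0001 KO_rep1: PC=13082.0 AS=3354.0 IR=3564.0 rpm
```

The methylated acceptor is used ~8× more once methylation is lost
(13082/1598 ≈ 8.2), with AS and IR dropping correspondingly — the
planted condition difference.

```python
sim = simulate_ip_counts(cfg, manifest)
lrt = nb_lrt_interaction(sim.counts, sim.samples)
print(call_targets(lrt, threshold=0.1, direction="decrease"))
```

```
['gene0001', 'gene0002', 'gene0003']
```

Exactly the three methylated genes show a significant loss of IP/input
enrichment in the KO (log2 interaction estimates −2.34, −1.79, −1.88
against a planted −2).

The same operations are available from the shell:

```sh
splicem6a simulate --seed 7 --outdir toy/
splicem6a screen --genome toy/genome.fa --gtf toy/annotation.gtf \
    --reference-seq $(python -c "from splicem6a.simulate import STRUCTURED_WINDOW; print(STRUCTURED_WINDOW)") \
    --out screen.tsv
splicem6a diffmeth --counts toy/counts.tsv --samples toy/samples.tsv --out lrt.tsv
```

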
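"""Motif scanning, base-pair-maximization folding and hairpin ranking."""

import functools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicem6a.genome import GenomeSequence, SpliceSite
from splicem6a.screen import (
    DEFAULT_MOTIFS,
    FoldError,
    MethylMotif,
    can_pair,
    fold_nussinov,
    paired_positions,
    rank_candidates,
    run_screen,
    scan_motifs,
    structure_similarity,
    validate_dot_bracket,
)
from splicem6a.simulate import STRUCTURED_WINDOW, SyntheticConfig, build_toy_genome


# --- independent oracles -------------------------------------------------

def max_pairs_exhaustive(seq, min_loop=3, allow_gu=True):
    """Maximum pair count by explicit enumeration of all non-crossing
    pair sets (exponential; for short sequences only)."""

    def best(positions):
        if len(positions) < 2:
            return 0
        i = positions[0]
        # i unpaired
        result = best(positions[1:])
        for idx in range(1, len(positions)):
            k = positions[idx]
            if k - i <= min_loop:
                continue
            if can_pair(seq[i], seq[k], allow_gu):
                inside = [p for p in positions[1:idx]]
                outside = [p for p in positions[idx + 1:]]
                result = max(result, 1 + best(inside) + best(outside))
        return result

    return best(list(range(len(seq))))


def max_pairs_suffix_dp(seq, min_loop=3, allow_gu=True):
    """Maximum pair count via a right-anchored recursion (pairs the *last*
    position or leaves it unpaired) — an independent formulation of the
    optimum used to check longer sequences."""

    @functools.lru_cache(maxsize=None)
    def rec(i, j):  # [i, j) half-open
        if j - i <= min_loop:
            return 0
        result = rec(i, j - 1)  # j-1 unpaired
        for k in range(i, j - min_loop - 1):
            if can_pair(seq[k], seq[j - 1], allow_gu):
                result = max(result, 1 + rec(i, k) + rec(k + 1, j - 1))
        return result

    return rec(0, len(seq))


def _random_rna(rng, length):
    return "".join(rng.choice(list("ACGU"), size=length))


# --- folding -------------------------------------------------------------

class TestFoldNussinov:
    def test_unpairable_sequence_is_unpaired(self):
        assert fold_nussinov("AAAAA") == "....."

    def test_four_pair_hairpin(self):
        structure = fold_nussinov("GGGGAAAACCCC")
        assert paired_positions(structure) == 2 * 4
        assert max_pairs_exhaustive("GGGGAAAACCCC") == 4

    def test_min_loop_enforced(self):
        assert fold_nussinov("GAAAC") == "(...)"
        assert fold_nussinov("GAAC") == "...."

    def test_invalid_alphabet_is_error(self):
        with pytest.raises(FoldError):
            fold_nussinov("ACGT")  # DNA alphabet

    def test_structures_are_valid_and_deterministic(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            seq = _random_rna(rng, int(rng.integers(1, 30)))
            s1 = fold_nussinov(seq)
            validate_dot_bracket(s1, min_loop=3)
            assert s1 == fold_nussinov(seq)

    @pytest.mark.parametrize("allow_gu", [True, False])
    def test_matches_exhaustive_oracle_short(self, allow_gu):
        rng = np.random.default_rng(11)
        for length in range(1, 13):
            for _ in range(5):
                seq = _random_rna(rng, length)
                got = paired_positions(fold_nussinov(seq, allow_gu=allow_gu)) // 2
                assert got == max_pairs_exhaustive(seq, allow_gu=allow_gu), seq

    def test_matches_suffix_dp_on_20mers(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            seq = _random_rna(rng, 20)
            got = paired_positions(fold_nussinov(seq)) // 2
            assert got == max_pairs_suffix_dp(seq), seq


# --- similarity ----------------------------------------------------------

class TestStructureSimilarity:
    @pytest.mark.parametrize(
        "candidate,reference,expected",
        [
            ("(((...)))", "(((...)))", 6),
            (".........", "(((...)))", 0),
            ("..(...)..", "(((...)))", 2),
        ],
    )
    def test_examples(self, candidate, reference, expected):
        assert structure_similarity(candidate, reference) == expected

    def test_length_mismatch_is_error(self):
        with pytest.raises(FoldError):
            structure_similarity("()", "(.)")

    @given(st.integers(0, 2**32 - 1), st.integers(5, 25))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_bounds_and_self(self, seed, length):
        rng = np.random.default_rng(seed)
        x = fold_nussinov(_random_rna(rng, length))
        y = fold_nussinov(_random_rna(rng, length))
        s = structure_similarity(x, y)
        assert s == structure_similarity(y, x)
        assert 0 <= s <= min(paired_positions(x), paired_positions(y))
        assert structure_similarity(x, x) == paired_positions(x)


# --- motif scanning ------------------------------------------------------

def _site_and_genome(intron_tail, exon_head):
    """Genome whose single '+' acceptor has the given sense context."""
    intron_dna = ("T" * (100 - len(intron_tail)) + intron_tail).replace("U", "T")
    exon_dna = (exon_head + "C" * (100 - len(exon_head))).replace("U", "T")
    seq = "G" * 100 + intron_dna + exon_dna
    genome = GenomeSequence({"c1": seq})
    site = SpliceSite(
        contig="c1", strand="+", intron_start=101, intron_end=200,
        acceptor_ag=(199, 200), target_a=199, gene_id="g", transcript_id="t",
    )
    return genome, site


class TestScanMotifs:
    def test_sams_like_variant_motif(self):
        genome, site = _site_and_genome("UACAG", "AAAC")
        hits = scan_motifs([site], genome)
        assert [h.motif.sequence for h in hits] == ["UACAGAAA"]
        assert hits[0].window[20:22] == "AG"

    def test_consensus_motif(self):
        genome, site = _site_and_genome("UACAG", "AGAA")
        hits = scan_motifs([site], genome)
        assert [h.motif.sequence for h in hits] == ["UACAGAGA"]

    def test_mismatch_in_intron_is_no_hit(self):
        genome, site = _site_and_genome("UUCAG", "AAAC")
        assert scan_motifs([site], genome) == []

    def test_ambiguous_window_skipped(self):
        genome, site = _site_and_genome("UACAG", "AAAC")
        contigs = dict(genome.contigs)
        contigs["c1"] = contigs["c1"][:190] + "N" + contigs["c1"][191:]
        assert scan_motifs([site], GenomeSequence(contigs)) == []

    def test_motif_invariants(self):
        with pytest.raises(ValueError):
            MethylMotif("UACTGAGA")  # T not RNA
        with pytest.raises(ValueError):
            MethylMotif("UACAAAGA")  # no AG at methyl position


# --- ranking and the full screen ----------------------------------------

class TestRanking:
    def test_identical_windows_share_rank_one(self):
        genome, site = _site_and_genome("UACAG", "AAAC")
        hits = scan_motifs([site], genome) * 3
        reference = fold_nussinov(hits[0].window)
        cands = rank_candidates(hits, reference)
        assert [c.rank for c in cands] == [1, 1, 1]

    def test_empty_hits_empty_output(self):
        assert rank_candidates([], "." * 41) == []

    def test_external_fold_injection(self):
        genome, site = _site_and_genome("UACAG", "AAAC")
        (hit,) = scan_motifs([site], genome)
        forced = "." * 41
        (cand,) = rank_candidates([hit], fold_nussinov(hit.window),
                                  external_folds={hit.window: forced})
        assert cand.structure == forced
        assert cand.similarity == 0


class TestRunScreen:
    def test_recovers_planted_sites(self, toy_dataset):
        genome, transcripts, manifest = toy_dataset
        result = run_screen(genome, transcripts, reference=manifest.reference_structure)
        assert result.n_sites_examined == 50
        assert result.n_motif_hits == 6
        structured = {g for g, i in manifest.genes.items() if i["structure"] == "structured"}
        unstructured = {g for g, i in manifest.genes.items() if i["structure"] == "unstructured"}
        table = result.table
        found = set(table["name"].str.split(":").str[0])
        assert structured | unstructured <= found
        top3 = set(table.head(3)["name"].str.split(":").str[0])
        assert top3 == structured
        mean_rank = table.assign(gene=table["name"].str.split(":").str[0]).groupby(
            lambda i: table.loc[i, "name"].split(":")[0] in structured
        )["rank"].mean()
        assert mean_rank[True] < mean_rank[False]

    def test_reference_seq_equivalent_to_prefolded(self, toy_dataset):
        genome, transcripts, manifest = toy_dataset
        by_struct = run_screen(genome, transcripts, reference=manifest.reference_structure)
        by_seq = run_screen(genome, transcripts, reference_seq=STRUCTURED_WINDOW)
        assert by_struct.table.equals(by_seq.table)

    def test_empty_motif_set_yields_no_hits(self, toy_dataset):
        genome, transcripts, manifest = toy_dataset
        result = run_screen(genome, transcripts, motifs=[],
                            reference=manifest.reference_structure)
        assert result.n_motif_hits == 0 and result.table.empty

    def test_deterministic_and_order_invariant(self, toy_dataset):
        genome, transcripts, manifest = toy_dataset
        ref = manifest.reference_structure
        a = run_screen(genome, transcripts, reference=ref).table.to_csv(sep="\t")
        b = run_screen(genome, transcripts, reference=ref).table.to_csv(sep="\t")
        shuffled = list(transcripts)[::-1]
        c = run_screen(genome, shuffled, reference=ref).table.to_csv(sep="\t")
        assert a == b == c
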
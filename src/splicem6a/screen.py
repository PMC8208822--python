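"""Motif + secondary-structure screen for methylatable 3' splice sites.

METTL16/METT-10 methylates the acceptor adenosine of a 3' splice site
only when the methylation motif (UACAGAGA / UACAGAAA class; the AG after
the methylated A *is* the acceptor AG) sits in a stem-loop context.  The
screen therefore (1) scans acceptor-centred sequence windows for motifs
anchored on the acceptor AG, (2) folds each window by deterministic
base-pair maximization, and (3) ranks hits by how many paired positions
their fold shares with a reference hairpin.

The folding engine is pluggable: ``rank_candidates``/``run_screen``
accept a precomputed ``external_folds`` mapping (window sequence ->
dot-bracket) so folds from a thermodynamic tool can be injected; the
built-in default is :func:`fold_nussinov`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome import (
    GenomeBoundsError,
    GenomeSequence,
    SpliceSite,
    TranscriptModel,
    classify_acceptor,
    enumerate_3ss,
    fetch_window,
)

logger = logging.getLogger(__name__)

RNA_ALPHABET = set("ACGU")

#: Watson-Crick plus wobble pairs considered by the folder.
_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "U"), ("U", "G")}

#: Default METTL16/METT-10 methylation motifs (methylated A at position 4,
#: 1-based; the following G completes the acceptor AG).
DEFAULT_MOTIFS: tuple["MethylMotif", ...]


class FoldError(ValueError):
    """Invalid sequence or structure input to the folding/scoring routines."""


@dataclass(frozen=True)
class MethylMotif:
    """A methylation motif with the methylated A at ``methyl_index`` (1-based)."""

    sequence: str
    methyl_index: int = 4

    def __post_init__(self) -> None:
        if set(self.sequence) - RNA_ALPHABET:
            raise ValueError(f"motif {self.sequence!r} is not an RNA string")
        i = self.methyl_index - 1
        if not (0 <= i < len(self.sequence) - 1):
            raise ValueError("methyl_index outside motif")
        if self.sequence[i] != "A" or self.sequence[i + 1] != "G":
            raise ValueError(
                f"motif {self.sequence!r}: positions {self.methyl_index}-"
                f"{self.methyl_index + 1} must be the acceptor 'AG'"
            )


DEFAULT_MOTIFS = (MethylMotif("UACAGAGA"), MethylMotif("UACAGAAA"))


@dataclass(frozen=True)
class MotifHit:
    """A splice site whose acceptor-anchored window matches a motif."""

    site: SpliceSite
    motif: MethylMotif
    window: str


@dataclass(frozen=True)
class HairpinCandidate:
    hit: MotifHit
    structure: str
    similarity: int
    rank: int


def validate_dot_bracket(structure: str, min_loop: int = 0) -> None:
    """Check a dot-bracket string is balanced, non-crossing and respects
    a minimum hairpin-loop size.  Raises :class:`FoldError` otherwise.
    """
    if set(structure) - set("()."):
        raise FoldError(f"invalid dot-bracket characters in {structure!r}")
    stack: list[int] = []
    for i, char in enumerate(structure):
        if char == "(":
            stack.append(i)
        elif char == ")":
            if not stack:
                raise FoldError("unbalanced ')' in dot-bracket string")
            j = stack.pop()
            if i - j - 1 < min_loop:
                raise FoldError(
                    f"hairpin loop shorter than {min_loop} at positions {j}-{i}"
                )
    if stack:
        raise FoldError("unbalanced '(' in dot-bracket string")


def can_pair(a: str, b: str, allow_gu: bool = True) -> bool:
    pair = (a, b)
    return pair in _WC_PAIRS or (allow_gu and pair in _GU_PAIRS)


def fold_nussinov(seq: str, min_loop: int = 3, allow_gu: bool = True) -> str:
    """Fold an RNA sequence by base-pair maximization (Nussinov DP).

    Returns a dot-bracket string with the maximum number of base pairs
    (Watson-Crick plus G.U when ``allow_gu``) subject to hairpin loops of
    at least ``min_loop`` unpaired bases.  The traceback is fully
    deterministic: position ``i`` is left unpaired only if no pairing of
    ``i`` achieves the optimum, otherwise ``i`` pairs with the smallest
    admissible partner achieving it.
    """
    if set(seq) - RNA_ALPHABET:
        raise FoldError(f"sequence contains non-RNA characters: {seq!r}")
    n = len(seq)
    # M[i][j] = max pairs within seq[i..j] (0-based, inclusive)
    M = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if can_pair(seq[i], seq[k], allow_gu):
                    inner = M[i + 1][k - 1] if k - 1 > i + 1 else 0
                    outer = M[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + inner + outer
                    if cand > best:
                        best = cand
            M[i][j] = best

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i < min_loop + 1:
            continue
        target = M[i][j]
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if can_pair(seq[i], seq[k], allow_gu):
                inner = M[i + 1][k - 1] if k - 1 > i + 1 else 0
                outer = M[k + 1][j] if k + 1 <= j else 0
                if 1 + inner + outer == target:
                    structure[i] = "("
                    structure[k] = ")"
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return "".join(structure)


def paired_positions(structure: str) -> int:
    """Number of positions that are '(' or ')'."""
    return sum(1 for c in structure if c in "()")


def structure_similarity(candidate: str, reference: str) -> int:
    """Count positions paired ('(' or ')') in *both* structures.

    This is the hairpin-similarity statistic used to rank candidate
    acceptor windows against a bona fide target hairpin.
    """
    if len(candidate) != len(reference):
        raise FoldError(
            f"structure length mismatch: {len(candidate)} vs {len(reference)}"
        )
    return sum(
        1 for c, r in zip(candidate, reference) if c in "()" and r in "()"
    )


def scan_motifs(
    sites: Iterable[SpliceSite],
    genome: GenomeSequence,
    motifs: Sequence[MethylMotif] = DEFAULT_MOTIFS,
    flank: int = 20,
) -> list[MotifHit]:
    """Scan acceptor-centred windows for motifs anchored on the acceptor AG.

    A hit is emitted iff the window matches the motif in the single
    register that places motif positions ``methyl_index``/``methyl_index+1``
    on the acceptor A and G (no sliding); at most one hit per
    (site, motif).  Out-of-bounds or N-containing windows are skipped
    with a logged reason.
    """
    for motif in motifs:
        if flank < len(motif.sequence):
            raise ValueError("flank must be >= motif length")
    hits = []
    for site in sites:
        try:
            window = fetch_window(genome, site, flank)
        except GenomeBoundsError as exc:
            logger.warning("skipping site %s:%d: %s", site.contig, site.target_a, exc)
            continue
        if "N" in window:
            logger.warning(
                "skipping site %s:%d: ambiguous_base", site.contig, site.target_a
            )
            continue
        site = classify_acceptor(site, genome)
        for motif in motifs:
            start = flank - (motif.methyl_index - 1)  # 0-based window offset
            if start < 0 or start + len(motif.sequence) > len(window):
                continue
            if window[start : start + len(motif.sequence)] == motif.sequence:
                hits.append(MotifHit(site=site, motif=motif, window=window))
    return hits


def _competition_ranks(scores: Sequence[int]) -> list[int]:
    """1-based competition ranking ("1224") for scores sorted descending."""
    ranks = []
    for idx, score in enumerate(scores):
        if idx > 0 and score == scores[idx - 1]:
            ranks.append(ranks[-1])
        else:
            ranks.append(idx + 1)
    return ranks


def rank_candidates(
    hits: Sequence[MotifHit],
    reference: str,
    min_loop: int = 3,
    allow_gu: bool = True,
    external_folds: Mapping[str, str] | None = None,
) -> list[HairpinCandidate]:
    """Fold each hit window, score against a reference dot-bracket, rank.

    Candidates are sorted by similarity descending with ties broken by
    (contig, coordinate) ascending; ranks are 1-based competition ranks
    (ties share the better rank).  ``external_folds`` may inject
    precomputed dot-brackets keyed by window sequence.
    """
    validate_dot_bracket(reference)
    if not hits:
        return []
    scored = []
    for hit in hits:
        if external_folds is not None and hit.window in external_folds:
            structure = external_folds[hit.window]
            validate_dot_bracket(structure)
        else:
            structure = fold_nussinov(hit.window, min_loop=min_loop, allow_gu=allow_gu)
        if len(structure) != len(reference):
            raise FoldError(
                "reference structure length does not match window length"
            )
        scored.append((hit, structure, structure_similarity(structure, reference)))
    scored.sort(key=lambda t: (-t[2], t[0].site.contig, t[0].site.target_a))
    ranks = _competition_ranks([s for _, _, s in scored])
    return [
        HairpinCandidate(hit=h, structure=st, similarity=sim, rank=rank)
        for (h, st, sim), rank in zip(scored, ranks)
    ]


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of a genome-wide acceptor screen.

    ``n_sites_examined`` counts acceptor-unique sites (the screen's
    working set); ``n_sites_redundant`` counts one site per intron per
    transcript before de-duplication, since annotation databases report
    both conventions.
    """

    table: pd.DataFrame
    n_sites_examined: int
    n_motif_hits: int
    n_sites_redundant: int = 0


def run_screen(
    genome: GenomeSequence,
    transcripts: Iterable[TranscriptModel],
    motifs: Sequence[MethylMotif] = DEFAULT_MOTIFS,
    reference: str | None = None,
    reference_seq: str | None = None,
    flank: int = 20,
    min_loop: int = 3,
    allow_gu: bool = True,
    external_folds: Mapping[str, str] | None = None,
) -> ScreenResult:
    """Full screen: enumerate acceptors -> motif scan -> fold -> rank.

    The reference hairpin may be supplied either as a dot-bracket string
    (``reference``) or as a sequence (``reference_seq``) folded by the
    same engine.  The output table carries BED6-style columns plus
    window, dot-bracket, similarity and rank, in a deterministic order.
    """
    if (reference is None) == (reference_seq is None):
        raise ValueError("supply exactly one of reference / reference_seq")
    if reference is None:
        reference = fold_nussinov(reference_seq, min_loop=min_loop, allow_gu=allow_gu)
    transcripts = list(transcripts)
    n_redundant = len(enumerate_3ss(transcripts, deduplicate=False))
    sites = enumerate_3ss(transcripts)
    hits = scan_motifs(sites, genome, motifs, flank=flank)
    candidates = rank_candidates(
        hits, reference, min_loop=min_loop, allow_gu=allow_gu,
        external_folds=external_folds,
    )
    rows = []
    for cand in candidates:
        site = cand.hit.site
        lo, hi = min(site.acceptor_ag), max(site.acceptor_ag)
        rows.append(
            {
                "contig": site.contig,
                "start": lo - 1,  # BED 0-based half-open
                "end": hi,
                "name": f"{site.gene_id}:{site.transcript_id}",
                "score": 0,
                "strand": site.strand,
                "motif": cand.hit.motif.sequence,
                "window": cand.hit.window,
                "structure": cand.structure,
                "similarity": cand.similarity,
                "rank": cand.rank,
                "canonical_acceptor": bool(site.canonical),
            }
        )
    columns = [
        "contig", "start", "end", "name", "score", "strand",
        "motif", "window", "structure", "similarity", "rank",
        "canonical_acceptor",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return ScreenResult(
        table=table, n_sites_examined=len(sites), n_motif_hits=len(hits),
        n_sites_redundant=n_redundant,
    )
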
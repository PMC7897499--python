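"""Enumeration of unannotated upstream ORFs.

Monitoring substrates are encoded immediately 5' of their regulatory target
gene, on the same strand.  This module scans the strand-aware upstream
window of a located target gene for open reading frames that

(a) lie on the target's strand,
(b) start with ATG/GTG/TTG and end with a stop codon entirely inside the
    window (the window ends at the target start, so an ORF never overlaps
    its own target),
(c) encode ``min_len_aa``-``max_len_aa`` residues (stop excluded),
(d) overlap no annotated gene by more than ``overlap_tolerance_nt``, the
    operational stand-in for "no previously assigned function", and
(e) end within ``max_gap_to_target_nt`` of the target start.

Among nested ORFs sharing a stop codon, only the longest one passing the
size and overlap filters is reported, i.e. the most upstream usable start
of each frame.  Windows truncated at a contig edge are flagged on the
returned candidates rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import (
    START_CODONS,
    STOP_CODONS,
    CandidateORF,
    Genome,
    reverse_complement,
    translate,
)
from .targets import TargetGene

__all__ = ["OrfSearchParams", "find_upstream_orfs"]


@dataclass
class OrfSearchParams:
    """Knobs of the upstream ORF search (criteria 1 and 2 of the screen)."""

    min_len_aa: int = 80
    max_len_aa: int = 200
    upstream_window_nt: int = 1000
    max_gap_to_target_nt: int = 500
    start_codons: tuple[str, ...] = START_CODONS
    overlap_tolerance_nt: int = 30

    def __post_init__(self) -> None:
        if not (0 < self.min_len_aa <= self.max_len_aa):
            raise ValueError("require 0 < min_len_aa <= max_len_aa")
        if self.upstream_window_nt <= 0 or self.max_gap_to_target_nt <= 0:
            raise ValueError("windows must be positive")
        if self.overlap_tolerance_nt < 0:
            raise ValueError("overlap tolerance must be >= 0")


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def find_upstream_orfs(
    genome: Genome,
    target: TargetGene,
    params: OrfSearchParams | None = None,
) -> list[CandidateORF]:
    """Return candidate ORFs in the upstream window of ``target``.

    Coordinates of the returned candidates are genomic (0-based half-open,
    stop codon included); ``distance_nt`` is the strand-aware gap between
    the ORF's stop codon end and the target start.
    """
    params = params or OrfSearchParams()
    gene = target.gene
    n = len(genome)

    if gene.strand == "+":
        win_start = max(0, gene.start - params.upstream_window_nt)
        win_end = gene.start
        truncated = gene.start - params.upstream_window_nt < 0
        window = genome.sequence[win_start:win_end]
    else:
        win_start = gene.end
        win_end = min(n, gene.end + params.upstream_window_nt)
        truncated = gene.end + params.upstream_window_nt > n
        window = reverse_complement(genome.sequence[win_start:win_end])
    w = len(window)
    if w < 3 * (params.min_len_aa + 2):
        return []

    candidates: list[CandidateORF] = []
    stops = set(STOP_CODONS)
    starts = set(params.start_codons)
    for frame in range(3):
        # start codons seen since the previous in-frame stop, upstream first
        start_positions: list[int] = []
        for pos in range(frame, w - 2, 3):
            codon = window[pos : pos + 3]
            if codon in starts:
                start_positions.append(pos)
            if codon in stops:
                stop_end = pos + 3
                gap = w - stop_end
                if gap <= params.max_gap_to_target_nt:
                    orf = _best_orf_for_stop(
                        genome, gene, params, window, win_start, win_end,
                        start_positions, stop_end, gap, truncated,
                    )
                    if orf is not None:
                        candidates.append(orf)
                start_positions = []
    candidates.sort(key=lambda c: (c.start, c.end, c.strand))
    return candidates


def _best_orf_for_stop(
    genome: Genome,
    gene,
    params: OrfSearchParams,
    window: str,
    win_start: int,
    win_end: int,
    start_positions: list[int],
    stop_end: int,
    gap: int,
    truncated: bool,
):
    """Longest ORF for one stop codon that passes the size and overlap filters."""
    for s in start_positions:  # most upstream (longest) first
        aa_len = (stop_end - s) // 3 - 1
        if not (params.min_len_aa <= aa_len <= params.max_len_aa):
            continue
        # map oriented window coordinates back to the genome
        if gene.strand == "+":
            g_start, g_end = win_start + s, win_start + stop_end
        else:
            g_start, g_end = win_end - stop_end, win_end - s
        bad = False
        for other in genome.genes:
            if _overlap(g_start, g_end, other.start, other.end) > params.overlap_tolerance_nt:
                bad = True
                break
        if bad:
            continue
        protein = translate(genome.sequence[g_start:g_end], gene.strand)
        return CandidateORF(
            candidate_id=f"{genome.genome_id}:{gene.gene_id}:{g_start}-{g_end}:{gene.strand}",
            genome_id=genome.genome_id,
            target_gene_id=gene.gene_id,
            start=g_start,
            end=g_end,
            strand=gene.strand,
            protein=protein,
            distance_nt=gap,
            edge_truncated=truncated,
        )
    return None


def candidates_gff3_features(candidates):
    """Candidate ORFs as (type, start, end, strand, attributes) tuples for
    :func:`arrestscan.genome.write_gff3`'s ``extra_features``."""
    return [
        (
            "ORF",
            c.start,
            c.end,
            c.strand,
            f"ID={c.candidate_id};target={c.target_gene_id};distance_nt={c.distance_nt}",
        )
        for c in candidates
    ]
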
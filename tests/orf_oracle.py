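"""Brute-force six-frame ORF enumeration oracle.

Independent of the implementation in ``arrestscan.orfs``: enumerates every
(start codon, stop codon) in-frame pair over the whole contig on both
strands, then applies the screen's filters one by one.  Used to check set
equality of the candidate ORFs.
"""

from arrestscan.genome import STOP_CODONS, reverse_complement, translate


def sixframe_orfs(seq: str):
    """All (start, end, strand) ORFs: start codon .. stop codon inclusive,
    genomic 0-based half-open coordinates, no internal stop."""
    out = []
    n = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for frame in range(3):
            starts = []
            for pos in range(frame, n - 2, 3):
                codon = s[pos : pos + 3]
                if codon in ("ATG", "GTG", "TTG"):
                    starts.append(pos)
                if codon in STOP_CODONS:
                    for st in starts:
                        if strand == "+":
                            out.append((st, pos + 3, "+"))
                        else:
                            out.append((n - (pos + 3), n - st, "-"))
                    starts = []
    return out


def oracle_upstream_orfs(genome, target, params):
    """Filtered candidate set: same rules as the screen, derived independently."""
    gene = target.gene
    n = len(genome)
    if gene.strand == "+":
        win_start = max(0, gene.start - params.upstream_window_nt)
        win_end = gene.start
    else:
        win_start = gene.end
        win_end = min(n, gene.end + params.upstream_window_nt)

    survivors = []
    for (start, end, strand) in sixframe_orfs(genome.sequence):
        if strand != gene.strand:
            continue
        if start < win_start or end > win_end:
            continue
        gap = (win_end - end) if strand == "+" else (start - win_start)
        if gap > params.max_gap_to_target_nt:
            continue
        aa_len = (end - start) // 3 - 1
        if not (params.min_len_aa <= aa_len <= params.max_len_aa):
            continue
        if any(
            min(end, g.end) - max(start, g.start) > params.overlap_tolerance_nt
            for g in genome.genes
        ):
            continue
        survivors.append((start, end, strand))

    # longest ORF per stop position: group by the stop codon's genomic locus
    best = {}
    for (start, end, strand) in survivors:
        stop_key = (end, strand) if strand == "+" else (start, strand)
        length = end - start
        if stop_key not in best or length > best[stop_key][1] - best[stop_key][0]:
            best[stop_key] = (start, end, strand)
    return sorted(best.values())


def candidate_set(cands):
    return sorted((c.start, c.end, c.strand) for c in cands)
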
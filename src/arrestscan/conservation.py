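"""Homolog clustering and C-terminal conservation scoring.

Candidate upstream ORFs from different genomes are clustered into homolog
groups by single-linkage on the pairwise identity of their globally aligned
C-terminal windows, and each group's last ``K`` alignment columns are
scored for conservation.  This stands in for the database homology search +
multiple alignment step of the original screen, which only needs a
judgement of whether the C-terminal region — where the arrest sequence
resides — is mutually conserved among apparent homologs.

The conservation statistic per column is the modal-residue fraction: the
count of the most frequent non-gap residue divided by the number of group
members.  Gaps count against conservation (a homolog missing part of its
C-terminus is evidence against a conserved arrest function there).  A
Shannon-entropy alternative is available via ``statistic="entropy"``.

Alignment is Needleman–Wunsch with affine gaps (Gotoh): a gap of length L
costs ``gap_open + (L - 1) * gap_extend``.  Traceback tie-breaks prefer
diagonal > up (gap in the second sequence) > left, so alignments are
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "AlignParams",
    "Alignment",
    "HomologGroup",
    "ConservationProfile",
    "global_align",
    "cluster_homologs",
    "cterm_conservation",
    "write_group_alignment_fasta",
    "write_conservation_tsv",
]

NEG_INF = float("-inf")


@dataclass
class AlignParams:
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0  # score of the first residue of a gap
    gap_extend: float = -1.0  # score of each further gap residue
    cluster_identity_threshold: float = 0.35
    cterm_window_K: int = 30
    conservation_threshold: float = 0.7

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        for t in (self.cluster_identity_threshold, self.conservation_threshold):
            if not (0 < t <= 1):
                raise ValueError("thresholds must lie in (0, 1]")
        if self.cterm_window_K <= 0:
            raise ValueError("cterm_window_K must be positive")


@dataclass(frozen=True)
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float  # matches / alignment columns


def global_align(a: str, b: str, params: AlignParams | None = None) -> Alignment:
    """Optimal global alignment of two protein sequences (Gotoh).

    ``identity`` is the fraction of alignment columns whose residues are
    identical.  Raises on empty input.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    p = params or AlignParams()
    n, m = len(a), len(b)
    open_, ext = p.gap_open, p.gap_extend

    # M: a[i] aligned to b[j]; X: gap in b (consumes a); Y: gap in a (consumes b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + (i - 1) * ext
    for j in range(1, m + 1):
        Y[0][j] = open_ + (j - 1) * ext
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            sub = p.match if ai == b[j - 1] else p.mismatch
            Mi[j] = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1]) + sub
            Xi[j] = max(Mi1[j] + open_, Xi1[j] + ext, Yi1[j] + open_)
            Yi[j] = max(Mi[j - 1] + open_, Yi[j - 1] + ext, Xi[j - 1] + open_)

    # traceback, preferring diagonal > up > left
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][i][j])
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            prev = max(
                ("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][i - 1][j - 1]
            )
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            i, j, state = i - 1, j - 1, prev
        elif state == "X":
            if i > 1 or j > 0:
                cand = {
                    "M": M[i - 1][j] + open_,
                    "X": X[i - 1][j] + ext,
                    "Y": Y[i - 1][j] + open_,
                }
                prev = max(("M", "X", "Y"), key=lambda s: cand[s])
            else:
                prev = "M"
            ra.append(a[i - 1])
            rb.append("-")
            i, state = i - 1, prev
        else:  # Y
            if j > 1 or i > 0:
                cand = {
                    "M": M[i][j - 1] + open_,
                    "Y": Y[i][j - 1] + ext,
                    "X": X[i][j - 1] + open_,
                }
                prev = max(("M", "Y", "X"), key=lambda s: cand[s])
            else:
                prev = "M"
            rb.append(b[j - 1])
            ra.append("-")
            j, state = j - 1, prev
    aligned_a = "".join(reversed(ra))
    aligned_b = "".join(reversed(rb))
    matches = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    score = max(M[n][m], X[n][m], Y[n][m])
    return Alignment(aligned_a, aligned_b, score, matches / len(aligned_a))


@dataclass
class ConservationProfile:
    """Per-column conservation over the last K columns of a group alignment.

    ``member_agreement[i]`` is member i's mean pairwise column agreement
    with the other members (fraction of columns sharing an identical
    non-gap residue, averaged over partners).  It guards against
    single-linkage outliers: a sequence chance-attached to a conserved
    group scores low here even when the group's modal-fraction mean stays
    above threshold.
    """

    columns: list[tuple[str, float]]  # (modal residue or '-', fraction in [0,1])
    mean_conservation: float
    matrix: list[str] = field(default_factory=list)  # one gapped row per member
    member_agreement: list[float] = field(default_factory=list)


@dataclass
class HomologGroup:
    group_id: str
    members: list[str]  # candidate_ids, sorted
    proteins: dict[str, str]  # candidate_id -> full protein
    profile: ConservationProfile | None = None

    @property
    def mean_conservation(self) -> float:
        return self.profile.mean_conservation if self.profile else float("nan")


def _cterm_window(protein: str, K: int) -> str:
    return protein[-K:]


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def cluster_homologs(candidates, params: AlignParams | None = None) -> list[HomologGroup]:
    """Single-linkage clustering of candidates on C-terminal window identity.

    Two candidates are linked when the identity of their globally aligned
    C-terminal ``K``-windows is >= ``cluster_identity_threshold``.
    Singleton clusters are dropped (conservation is undefined for one
    member).  Group membership and ids are invariant under input
    permutation.
    """
    p = params or AlignParams()
    cands = sorted(candidates, key=lambda c: c.candidate_id)
    if not cands:
        return []
    ids = [c.candidate_id for c in cands]
    if len(set(ids)) != len(ids):
        raise ValueError("candidate_ids must be unique for clustering")
    windows = {c.candidate_id: _cterm_window(c.protein, p.cterm_window_K) for c in cands}
    uf = _UnionFind(ids)
    # identical windows recur across genomes (conserved families); memoize
    cache: dict[tuple[str, str], float] = {}
    for i in range(len(cands)):
        for j in range(i + 1, len(cands)):
            wa, wb = windows[ids[i]], windows[ids[j]]
            key = (wa, wb) if wa <= wb else (wb, wa)
            ident = cache.get(key)
            if ident is None:
                ident = global_align(key[0], key[1], p).identity
                cache[key] = ident
            if ident >= p.cluster_identity_threshold:
                uf.union(ids[i], ids[j])
    clusters: dict[str, list[str]] = {}
    for cid in ids:
        clusters.setdefault(uf.find(cid), []).append(cid)
    groups: list[HomologGroup] = []
    proteins = {c.candidate_id: c.protein for c in cands}
    for k, (root, members) in enumerate(sorted(clusters.items())):
        if len(members) < 2:
            continue
        members = sorted(members)
        groups.append(
            HomologGroup(
                group_id=f"HG{len(groups) + 1:03d}",
                members=members,
                proteins={m: proteins[m] for m in members},
            )
        )
    return groups


def _column_score(column: list[str], n_members: int, statistic: str) -> tuple[str, float]:
    counts: dict[str, int] = {}
    for r in column:
        if r != "-":
            counts[r] = counts.get(r, 0) + 1
    if not counts:
        return "-", 0.0
    modal = max(sorted(counts), key=lambda r: counts[r])
    if statistic == "modal":
        return modal, counts[modal] / n_members
    # entropy alternative: 1 - H/Hmax with gaps pooled as a 21st state
    n_gap = n_members - sum(counts.values())
    probs = [v / n_members for v in counts.values()]
    if n_gap:
        probs.append(n_gap / n_members)
    h = -sum(q * math.log2(q) for q in probs if q > 0)
    hmax = math.log2(21)
    return modal, 1.0 - h / hmax


def cterm_conservation(
    group: HomologGroup,
    K: int | None = None,
    params: AlignParams | None = None,
    statistic: str = "modal",
    anchor_motif: str | None = None,
) -> ConservationProfile:
    """Score per-column conservation of a group's C-terminal region.

    Members are aligned to the group's longest member (reference-anchored
    progressive alignment; ties broken by candidate id), insertions
    relative to the reference are dropped, and the last ``K`` reference
    columns are scored.  Members shorter than ``K`` contribute leading
    gaps.  With ``anchor_motif``, members are right-justified on the last
    occurrence of the motif instead of being aligned, mirroring a
    motif-anchored manual alignment.
    """
    p = params or AlignParams()
    K = K if K is not None else p.cterm_window_K
    if len(group.members) < 2:
        raise ValueError("conservation is undefined for groups of size < 2")
    ref_id = max(group.members, key=lambda m: (len(group.proteins[m]), m))
    ref = _cterm_window(group.proteins[ref_id], K)
    if anchor_motif is not None:
        # right-justify every member on the end of its last motif occurrence,
        # keeping the reference's number of residues after the motif
        ref_pos = ref.rfind(anchor_motif)
        suffix = len(ref) - (ref_pos + len(anchor_motif)) if ref_pos >= 0 else 0
    rows: list[str] = []
    for m in group.members:
        seq = group.proteins[m]
        if anchor_motif is not None:
            pos = seq.rfind(anchor_motif)
            if pos < 0:
                rows.append(_cterm_window(seq, K).rjust(len(ref), "-"))
            else:
                end = min(len(seq), pos + len(anchor_motif) + suffix)
                win = seq[max(0, end - K) : end]
                rows.append(win.rjust(len(ref), "-"))
            continue
        if m == ref_id:
            rows.append(ref)
            continue
        win = _cterm_window(seq, K)
        aln = global_align(ref, win, p)
        row = []
        for ra, rb in zip(aln.aligned_a, aln.aligned_b):
            if ra == "-":
                continue  # insertion relative to the reference
            row.append(rb)
        rows.append("".join(row).rjust(len(ref), "-"))
    n = len(group.members)
    cols: list[tuple[str, float]] = []
    for j in range(len(ref)):
        cols.append(_column_score([r[j] for r in rows], n, statistic))
    mean = sum(f for _, f in cols) / len(cols)
    ncol = len(ref)
    agreement = []
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if j == i:
                continue
            same = sum(
                1 for a, b in zip(rows[i], rows[j]) if a == b and a != "-"
            )
            acc += same / ncol
        agreement.append(acc / (n - 1))
    return ConservationProfile(
        columns=cols, mean_conservation=mean, matrix=rows, member_agreement=agreement
    )


def write_group_alignment_fasta(group: HomologGroup, path) -> None:
    """Export a group's C-terminal alignment rows as gapped FASTA."""
    if group.profile is None:
        raise ValueError("group has no conservation profile; run cterm_conservation first")
    with open(path, "w") as fh:
        for member, row in zip(group.members, group.profile.matrix):
            fh.write(f">{member}\n{row}\n")


def write_conservation_tsv(profile: ConservationProfile, path) -> None:
    """Per-column profile as TSV: column index, modal residue, fraction."""
    with open(path, "w") as fh:
        fh.write("column\tmodal_residue\tfraction\n")
        for i, (residue, frac) in enumerate(profile.columns, start=1):
            fh.write(f"{i}\t{residue}\t{frac:.6g}\n")
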
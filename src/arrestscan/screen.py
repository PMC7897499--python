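"""Orchestration of the five-criterion monitoring-substrate screen.

For each genome of a panel the screen locates sec/yidC-class target genes,
enumerates upstream ORFs, and evaluates five criteria per candidate:

c1  the ORF lies immediately upstream of the target (same strand, stop
    codon end within ``max_gap_to_target_nt`` of the target start);
c2  it encodes a small protein (``min_len_aa``-``max_len_aa`` residues);
c3  the protein carries an N-terminal topogenic signal (TM or SS);
c4  at least ``min_exposed_aa`` residues separate the signal end from the
    C-terminus, so the signal clears the ribosomal exit tunnel while the
    arrest site occupies the peptidyl transferase center;
c5  the C-terminal region is conserved among apparent homologs found
    panel-wide (clustered group with mean conservation above threshold).

All enumerated candidates are reported with per-criterion booleans, not
only the passers.  So that ORFs failing c1/c2 are visible at all, the
enumeration pass uses relaxed *reporting* bounds (``report_min_len_aa``,
``report_window_nt``) and then grades c1/c2 against the screening bounds;
``find_upstream_orfs`` with the screening params would already have
filtered them out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .conservation import AlignParams, cluster_homologs, cterm_conservation
from .genome import CandidateORF, Genome
from .orfs import OrfSearchParams, find_upstream_orfs
from .targets import DEFAULT_TARGET_KEYWORDS, TargetGene, locate_targets
from .topology import TopogenicSignal, detect_topogenic_signal

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "exposure_check",
    "run_screen",
    "write_candidates_table",
    "read_candidates_table",
]


@dataclass
class TopologyParams:
    tm_threshold: float = 1.6
    tm_min_len: int = 15
    ss_h_min_len: int = 7
    ss_h_threshold: float = 2.0
    search_limit: int = 45
    tm_window: int = 19
    ss_window: int = 7


@dataclass
class ScreenConfig:
    """Bundle of all screen parameters (YAML-overridable via config module)."""

    orf_search: OrfSearchParams = field(default_factory=OrfSearchParams)
    topology: TopologyParams = field(default_factory=TopologyParams)
    align: AlignParams = field(default_factory=AlignParams)
    target_keywords: dict = field(default_factory=lambda: dict(DEFAULT_TARGET_KEYWORDS))
    min_exposed_aa: int = 40
    exposure_comparator: str = ">="  # ">=" (at least 40) or ">" (strictly more)
    group_within_target_class: bool = False
    # relaxed enumeration bounds used only so that c1/c2 failures get reported
    report_min_len_aa: int = 40
    report_max_len_aa: int = 400
    report_window_nt: int = 3000


@dataclass
class ScreenResult:
    """Per-candidate screen verdict with per-criterion attribution."""

    candidate: CandidateORF
    target_class: str
    c1_upstream: bool
    c2_size: bool
    c3_signal: bool
    signal: TopogenicSignal
    c4_exposure: bool
    exposed_len: int
    c5_conserved: bool
    group_id: str = ""
    mean_conservation: float = float("nan")

    @property
    def verdict(self) -> bool:
        return (
            self.c1_upstream
            and self.c2_size
            and self.c3_signal
            and self.c4_exposure
            and self.c5_conserved
        )


def exposure_check(
    candidate: CandidateORF,
    signal: TopogenicSignal,
    min_exposed: int = 40,
    comparator: str = ">=",
) -> tuple[bool, int]:
    """Criterion 4: exposed hydrophilic domain between signal end and C-terminus.

    Returns ``(passed, exposed_len)`` with ``exposed_len = len(protein) -
    signal_end``.  Raises if called with a signal of kind ``none``.
    """
    if signal.kind == "none":
        raise ValueError("exposure_check requires a detected topogenic signal")
    exposed = len(candidate.protein) - signal.signal_end
    if comparator == ">=":
        return exposed >= min_exposed, exposed
    if comparator == ">":
        return exposed > min_exposed, exposed
    raise ValueError(f"unknown comparator {comparator!r}")


def _report_params(cfg: ScreenConfig) -> OrfSearchParams:
    base = cfg.orf_search
    return OrfSearchParams(
        min_len_aa=min(cfg.report_min_len_aa, base.min_len_aa),
        max_len_aa=max(cfg.report_max_len_aa, base.max_len_aa),
        upstream_window_nt=max(cfg.report_window_nt, base.upstream_window_nt),
        max_gap_to_target_nt=max(cfg.report_window_nt, base.max_gap_to_target_nt),
        start_codons=base.start_codons,
        overlap_tolerance_nt=base.overlap_tolerance_nt,
    )


def run_screen(panel: list[Genome], config: ScreenConfig | None = None) -> list[ScreenResult]:
    """Run the full five-criterion screen over a genome panel.

    Returns one :class:`ScreenResult` per enumerated (target, ORF) pair,
    sorted by (genome_id, start, target gene).  Conservation (c5) is scored
    panel-wide across all enumerated candidates unless
    ``group_within_target_class`` restricts grouping to candidates of the
    same target class.
    """
    cfg = config or ScreenConfig()
    report_params = _report_params(cfg)
    base = cfg.orf_search
    top = cfg.topology

    rows: list[ScreenResult] = []
    for genome in panel:
        for target in locate_targets(genome, cfg.target_keywords):
            for cand in find_upstream_orfs(genome, target, report_params):
                extent = (
                    target.gene.start - cand.start
                    if cand.strand == "+"
                    else cand.end - target.gene.end
                )
                c1 = (
                    cand.distance_nt <= base.max_gap_to_target_nt
                    and extent <= base.upstream_window_nt
                )
                c2 = base.min_len_aa <= cand.length_aa <= base.max_len_aa
                signal = detect_topogenic_signal(
                    cand.protein,
                    tm_threshold=top.tm_threshold,
                    tm_min_len=top.tm_min_len,
                    ss_h_min_len=top.ss_h_min_len,
                    ss_h_threshold=top.ss_h_threshold,
                    search_limit=top.search_limit,
                    tm_window=top.tm_window,
                    ss_window=top.ss_window,
                )
                c3 = signal.kind != "none"
                if c3:
                    c4, exposed = exposure_check(
                        cand, signal, cfg.min_exposed_aa, cfg.exposure_comparator
                    )
                else:
                    # no signal: the whole chain is exposed by convention
                    exposed = len(cand.protein)
                    c4 = exposed >= cfg.min_exposed_aa
                rows.append(
                    ScreenResult(
                        candidate=cand,
                        target_class=target.target_class,
                        c1_upstream=c1,
                        c2_size=c2,
                        c3_signal=c3,
                        signal=signal,
                        c4_exposure=c4,
                        exposed_len=exposed,
                        c5_conserved=False,
                    )
                )

    _score_conservation(rows, cfg)
    rows.sort(key=lambda r: (r.candidate.genome_id, r.candidate.start, r.candidate.target_gene_id))
    return rows


def _score_conservation(rows: list[ScreenResult], cfg: ScreenConfig) -> None:
    """Cluster candidates and fill in c5 on each row in place."""
    if not rows:
        return
    # the same ORF reported under several targets enters clustering once
    unique: dict[tuple, ScreenResult] = {}
    for r in rows:
        key = (r.candidate.genome_id, r.candidate.start, r.candidate.end, r.candidate.strand)
        unique.setdefault(key, r)

    def class_key(r: ScreenResult) -> str:
        return r.target_class if cfg.group_within_target_class else "all"

    by_class: dict[str, list[ScreenResult]] = {}
    for r in unique.values():
        by_class.setdefault(class_key(r), []).append(r)

    # membership keyed by ORF coordinates: the same ORF reported under several
    # targets (whose candidate_ids differ) must receive the same c5 verdict
    membership: dict[tuple, tuple[str, float, float]] = {}
    for cls, members in sorted(by_class.items()):
        cands = _dedup_candidates([m.candidate for m in members])
        coords = {c.candidate_id: (c.genome_id, c.start, c.end, c.strand) for c in cands}
        groups = cluster_homologs(cands, cfg.align)
        for g in groups:
            profile = cterm_conservation(g, cfg.align.cterm_window_K, cfg.align)
            g.profile = profile
            gid = g.group_id if cls == "all" else f"{cls}:{g.group_id}"
            for cid, agree in zip(g.members, profile.member_agreement):
                membership[coords[cid]] = (gid, profile.mean_conservation, agree)
    thr = cfg.align.conservation_threshold
    for r in rows:
        c = r.candidate
        hit = membership.get((c.genome_id, c.start, c.end, c.strand))
        if hit is not None:
            gid, mean, agree = hit
            r.group_id = gid
            r.mean_conservation = mean
            # the group must be conserved AND this member must agree with it:
            # the agreement term keeps single-linkage outliers (sequences
            # chance-attached at the identity threshold) from inheriting a
            # conserved group's verdict
            r.c5_conserved = mean >= thr and agree >= thr


def _dedup_candidates(cands: list[CandidateORF]) -> list[CandidateORF]:
    seen: dict[tuple, CandidateORF] = {}
    for c in sorted(cands, key=lambda c: c.candidate_id):
        seen.setdefault((c.genome_id, c.start, c.end, c.strand), c)
    return list(seen.values())


_COLUMNS = [
    "candidate_id",
    "genome_id",
    "target_gene_id",
    "target_class",
    "start",
    "end",
    "strand",
    "distance_nt",
    "protein_length",
    "c1_upstream",
    "c2_size",
    "c3_signal",
    "signal_kind",
    "signal_start",
    "signal_end",
    "c4_exposure",
    "exposed_len",
    "c5_conserved",
    "group_id",
    "mean_conservation",
    "verdict",
    "protein",
]


def results_frame(results: list[ScreenResult]) -> pd.DataFrame:
    recs = []
    for r in sorted(results, key=lambda r: (r.candidate.genome_id, r.candidate.start, r.candidate.target_gene_id)):
        c = r.candidate
        recs.append(
            {
                "candidate_id": c.candidate_id,
                "genome_id": c.genome_id,
                "target_gene_id": c.target_gene_id,
                "target_class": r.target_class,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "distance_nt": c.distance_nt,
                "protein_length": c.length_aa,
                "c1_upstream": r.c1_upstream,
                "c2_size": r.c2_size,
                "c3_signal": r.c3_signal,
                "signal_kind": r.signal.kind,
                "signal_start": r.signal.signal_start,
                "signal_end": r.signal.signal_end,
                "c4_exposure": r.c4_exposure,
                "exposed_len": r.exposed_len,
                "c5_conserved": r.c5_conserved,
                "group_id": r.group_id,
                "mean_conservation": r.mean_conservation,
                "verdict": r.verdict,
                "protein": c.protein,
            }
        )
    return pd.DataFrame(recs, columns=_COLUMNS)


def write_candidates_table(results: list[ScreenResult], path) -> None:
    """Write one TSV row per candidate, deterministic column order and sort."""
    results_frame(results).to_csv(path, sep="\t", index=False)


def read_candidates_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
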
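"""N-terminal topogenic-signal detection from hydropathy.

A transparent, self-contained predictor of whether a protein's N-terminus
carries a topogenic signal — either an uncleaved transmembrane anchor (TM)
or a cleavable secretion signal sequence (SS).  The screen only needs the
binary decision plus the C-terminal boundary of the hydrophobic element
(from which the exposed hydrophilic domain is counted), so a windowed
Kyte–Doolittle hydropathy heuristic is used:

* **TM**: a run of at least ``tm_min_len`` residues whose window-19 mean
  hydropathy is >= ``tm_threshold``, starting within the first
  ``search_limit`` residues.
* **SS**: failing that, a positively charged n-region (>= 1 Lys/Arg within
  the first 5 residues) followed, within the first 35 residues, by an
  h-region run of at least ``ss_h_min_len`` residues with window-7 mean
  hydropathy >= ``ss_h_threshold``.

Window means are only defined where the full window fits inside the
sequence, so reported run boundaries are conservative near the termini.
The TM/SS distinction is reported for provenance only; both kinds satisfy
the screen's topogenic-signal criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

__all__ = ["HydropathyProfile", "TopogenicSignal", "hydropathy_profile", "detect_topogenic_signal"]


@dataclass
class HydropathyProfile:
    """Windowed mean Kyte–Doolittle scores.

    ``scores[i]`` is the arithmetic mean over residues ``centers[i] -
    window//2 .. centers[i] + window//2`` (1-based residue numbering);
    centers run from ``window//2 + 1`` to ``len - window//2``.
    """

    scores: np.ndarray
    window: int

    def center_residues(self, length: int) -> np.ndarray:
        half = self.window // 2
        return np.arange(half + 1, length - half + 1)


@dataclass(frozen=True)
class TopogenicSignal:
    """A detected N-terminal topogenic signal.

    ``signal_start``/``signal_end`` are 1-based residues bounding the
    detected hydrophobic run; ``score`` is the mean raw hydropathy over the
    run; ``n_region_charge`` counts Lys/Arg within the first 5 residues.
    """

    kind: str  # "TM" | "SS" | "none"
    signal_start: int = 0
    signal_end: int = 0
    score: float = 0.0
    n_region_charge: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("TM", "SS", "none"):
            raise ValueError(f"unknown signal kind {self.kind!r}")
        if self.kind != "none" and not (1 <= self.signal_start < self.signal_end):
            raise ValueError("require 1 <= signal_start < signal_end for TM/SS")


def hydropathy_profile(protein: str, window: int = 19) -> HydropathyProfile:
    """Sliding-window mean of Kyte–Doolittle hydropathy values."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(protein):
        raise ValueError(f"protein ({len(protein)} aa) shorter than window {window}")
    vals = np.array([KYTE_DOOLITTLE[a] for a in protein], dtype=float)
    kernel = np.ones(window) / window
    return HydropathyProfile(scores=np.convolve(vals, kernel, mode="valid"), window=window)


def _runs_at_least(mask: np.ndarray, min_len: int):
    """Yield (start_idx, end_idx) of maximal True runs of length >= min_len."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        if idx[e] - idx[s] + 1 >= min_len:
            yield int(idx[s]), int(idx[e])


def detect_topogenic_signal(
    protein: str,
    tm_threshold: float = 1.6,
    tm_min_len: int = 15,
    ss_h_min_len: int = 7,
    ss_h_threshold: float = 2.0,
    search_limit: int = 45,
    tm_window: int = 19,
    ss_window: int = 7,
) -> TopogenicSignal:
    """Classify the N-terminus of ``protein`` as TM, SS or none.

    Short or ambiguous sequences yield ``kind="none"`` rather than raising.
    ``signal_end`` (the last residue of the detected hydrophobic run) is the
    boundary from which the exposed hydrophilic domain is counted.
    """
    n_charge = sum(1 for a in protein[:5] if a in "KR")

    # TM: long hydrophobic run whose start lies in the N-terminal search window
    if len(protein) >= tm_window:
        prof = hydropathy_profile(protein, tm_window)
        centers = prof.center_residues(len(protein))
        for s, e in _runs_at_least(prof.scores >= tm_threshold, tm_min_len):
            start_res, end_res = int(centers[s]), int(centers[e])
            if start_res <= search_limit:
                seg = protein[start_res - 1 : end_res]
                score = float(np.mean([KYTE_DOOLITTLE[a] for a in seg]))
                return TopogenicSignal("TM", start_res, end_res, score, n_charge)

    # SS: charged n-region then a shorter h-region within the first 35 residues
    if n_charge >= 1 and len(protein) >= ss_window:
        prof = hydropathy_profile(protein, ss_window)
        centers = prof.center_residues(len(protein))
        for s, e in _runs_at_least(prof.scores >= ss_h_threshold, ss_h_min_len):
            start_res, end_res = int(centers[s]), int(centers[e])
            if start_res <= 35 and start_res <= search_limit:
                seg = protein[start_res - 1 : end_res]
                score = float(np.mean([KYTE_DOOLITTLE[a] for a in seg]))
                return TopogenicSignal("SS", start_res, end_res, score, n_charge)

    return TopogenicSignal("none", n_region_charge=n_charge)
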
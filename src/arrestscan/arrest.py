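"""Arrest-site analyses: toeprint mapping, motif scan, construct design,
reporter classification.

Toeprint mapping
----------------
A ribosome stalled with a peptidyl-tRNA in its P-site blocks reverse
transcription 15-17 nucleotides downstream of the first nucleotide of the
P-site codon.  Because that 3-nt uncertainty window equals the codon size,
a single reverse-transcription stop usually admits two adjacent P-site
codons; the mapper therefore returns the full candidate *set* and declares
a consensus only when it is a singleton (which happens exactly when the
stop sits 17 nt downstream of a codon's first nucleotide).  Replicate
bands are combined by intersecting candidate sets.

Construct design
----------------
``design_internal_frameshift`` scrambles the amino acids of a codon
segment while leaving the mRNA almost untouched: delete the first
nucleotide of the segment's first codon and insert one nucleotide after
its last codon.  Shift-created in-frame stop codons are pre-empted by
synonymous changes to the original codons that would create them.
``design_synonymous_block`` maximally mutates a codon block at the
nucleotide level without changing any amino acid, to separate mRNA-level
from peptide-level effects.

Reporter classification
-----------------------
A lacZ reporter fused downstream of the arrest sequence reads out arrest
escape: a mutant/wildtype activity ratio of >= 3 is classified as
arrest-deficient, <= 1/3 as arrest-enhanced.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .genome import STOP_CODONS, TranslationError, translate_frame

__all__ = [
    "ToeprintParams",
    "ToeprintAssignment",
    "ReporterRecord",
    "DesignError",
    "map_toeprint_to_psite",
    "consensus_over_replicates",
    "scan_arrest_motif",
    "design_internal_frameshift",
    "design_synonymous_block",
    "classify_arrest_deficiency",
]

ARREST_MOTIF = re.compile(r"(?=(RAP[GP]))")

_FWD = CodonTable.unambiguous_dna_by_id[11].forward_table
_SYNONYMS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _FWD.items():
    _SYNONYMS.setdefault(_aa, ())
    _SYNONYMS[_aa] = tuple(sorted(_SYNONYMS[_aa] + (_codon,)))


class DesignError(ValueError):
    """A construct cannot be designed under the stated rules."""


@dataclass(frozen=True)
class ToeprintParams:
    """Offset window between P-site codon first nucleotide and the RT stop."""

    offset_min: int = 15
    offset_max: int = 17

    def __post_init__(self) -> None:
        if not (0 < self.offset_min <= self.offset_max):
            raise ValueError("require 0 < offset_min <= offset_max")


@dataclass(frozen=True)
class ToeprintAssignment:
    stop_nt: int  # 1-based mRNA position of the RT stop
    candidate_psite_codons: frozenset[int]  # 1-based codon indices
    consensus_psite: int | None  # defined iff the candidate set is a singleton

    @property
    def asite(self) -> int | None:
        return None if self.consensus_psite is None else self.consensus_psite + 1


@dataclass(frozen=True)
class ReporterRecord:
    """Mean beta-galactosidase activity of one reporter construct."""

    construct_id: str
    activity_AU: float
    sd: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if self.activity_AU < 0:
            raise ValueError("activity_AU must be >= 0")
        if self.n < 1:
            raise ValueError("replicate count must be >= 1")


def map_toeprint_to_psite(
    stop_nt: int,
    orf_start_nt: int,
    params: ToeprintParams | None = None,
) -> ToeprintAssignment:
    """Map a reverse-transcription stop position to candidate P-site codons.

    ``stop_nt`` and ``orf_start_nt`` are 1-based positions on the same mRNA
    axis; the reading frame begins at ``orf_start_nt``.  For each offset o
    in the window, the candidate P-site first nucleotide is ``stop_nt - o``
    and the codon index ``(p - orf_start_nt) // 3 + 1``.  Offsets reaching
    upstream of the ORF start are clipped (relevant only for stalls at the
    initiator codon); if no offset lands in frame the stop cannot come from
    a ribosome on this ORF and a ``ValueError`` is raised.
    """
    p = params or ToeprintParams()
    first_nts = [
        q
        for o in range(p.offset_min, p.offset_max + 1)
        if (q := stop_nt - o) >= orf_start_nt
    ]
    if not first_nts:
        raise ValueError(
            f"offset window precedes the ORF start (stop={stop_nt}, start={orf_start_nt})"
        )
    codons = frozenset((q - orf_start_nt) // 3 + 1 for q in first_nts)
    consensus = next(iter(codons)) if len(codons) == 1 else None
    return ToeprintAssignment(stop_nt, codons, consensus)


def consensus_over_replicates(assignments) -> int | None:
    """Intersect candidate sets from replicate toeprint bands.

    Returns the consensus codon, or ``None`` (with a warning) when more
    than one codon survives; an empty intersection raises, since the bands
    then cannot come from one stalled ribosome position.
    """
    assignments = list(assignments)
    if not assignments:
        raise ValueError("no assignments given")
    common = set(assignments[0].candidate_psite_codons)
    for a in assignments[1:]:
        common &= a.candidate_psite_codons
    if not common:
        raise ValueError("replicate candidate sets have empty intersection")
    if len(common) > 1:
        warnings.warn(
            f"P-site ambiguous across replicates: candidates {sorted(common)}",
            stacklevel=2,
        )
        return None
    return common.pop()


def scan_arrest_motif(protein: str) -> list[tuple[int, int, str]]:
    """All occurrences of the arrest motif Arg-Ala-Pro-(Gly|Pro).

    Returns 1-based inclusive (start, end, matched) tuples; overlapping
    matches are all reported.
    """
    return [(m.start() + 1, m.start() + 4, m.group(1)) for m in ARREST_MOTIF.finditer(protein)]


def _synonyms_of(codon: str) -> tuple[str, ...]:
    aa = _FWD.get(codon)
    if aa is None:
        return ()
    return tuple(c for c in _SYNONYMS[aa] if c != codon)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


@dataclass
class FrameshiftLog:
    first_codon: int
    last_codon: int
    deleted_nt: str
    inserted_nt: str
    synonymous_fixes: list[tuple[int, str, str]] = field(default_factory=list)


def _apply_shift(codons: list[str], first: int, last: int, insert_nt: str) -> str:
    seq = "".join(codons)
    del_pos = 3 * (first - 1)  # 0-based position of the deleted nucleotide
    return seq[:del_pos] + seq[del_pos + 1 : 3 * last] + insert_nt + seq[3 * last :]


def design_internal_frameshift(
    cds: str,
    first_codon: int,
    last_codon: int,
    insert_rule: str = "reuse-deleted",
):
    """Design an internal frameshift over codons ``first_codon..last_codon``.

    Deletes the first nucleotide of ``first_codon`` and inserts one
    nucleotide after ``last_codon``, scrambling the segment's amino acids.
    Any in-frame stop the shift would create is pre-empted by a synonymous
    mutation of the original codon that contributes its first two
    nucleotides (falling back to the following codon), chosen to minimise
    nucleotide changes and then lexicographically.  Returns
    ``(mutated_cds, FrameshiftLog)``.

    The result has the same length as the input, an unchanged translation
    outside the segment, and no internal stop codons.
    """
    cds = cds.upper()
    n = len(cds) // 3
    if len(cds) % 3 != 0:
        raise TranslationError("CDS length not divisible by 3")
    aa = translate_frame(cds)
    if not aa.endswith("*") or "*" in aa[:-1]:
        raise TranslationError("CDS must end with a stop codon and contain no internal stop")
    if not (1 <= first_codon <= last_codon < n):
        raise DesignError("require 1 <= first_codon <= last_codon < stop codon index")
    if insert_rule == "reuse-deleted":
        insert_nt = None
    elif insert_rule in "ACGT" and len(insert_rule) == 1:
        insert_nt = insert_rule
    else:
        raise ValueError(f"unknown insert_rule {insert_rule!r}")

    codons = [cds[3 * i : 3 * i + 3] for i in range(n)]
    original = list(codons)
    fixes: list[tuple[int, str, str]] = []
    tried: set[tuple[int, str]] = set()

    for _ in range(4 * (last_codon - first_codon + 2)):
        deleted = codons[first_codon - 1][0]
        ins = deleted if insert_nt is None else insert_nt
        mutated = _apply_shift(codons, first_codon, last_codon, ins)
        offending = None
        for k in range(first_codon, last_codon + 1):
            if mutated[3 * (k - 1) : 3 * k] in STOP_CODONS:
                offending = k
                break
        if offending is None:
            log = FrameshiftLog(
                first_codon=first_codon,
                last_codon=last_codon,
                deleted_nt=codons[first_codon - 1][0],
                inserted_nt=ins,
                synonymous_fixes=fixes,
            )
            return mutated, log
        if not _fix_shift_stop(codons, original, offending, last_codon, fixes, tried,
                               first_codon, insert_nt):
            raise DesignError(
                f"no synonymous fix removes the stop created at shifted codon {offending}"
            )
    raise DesignError("frameshift design did not converge")


def _fix_shift_stop(
    codons: list[str],
    original: list[str],
    k: int,
    last_codon: int,
    fixes: list[tuple[int, str, str]],
    tried: set[tuple[int, str]],
    first_codon: int,
    insert_nt: str | None,
) -> bool:
    """Synonymously mutate an original codon to kill the stop at shifted codon k.

    Shifted codon k is built from the last two nucleotides of original codon
    k plus the first nucleotide of codon k+1 (or the inserted nucleotide
    when k == last_codon), so those are the codons worth changing.
    """
    targets = [k] if k == last_codon else [k, k + 1]
    for j in targets:
        current = codons[j - 1]
        options = sorted(
            (c for c in _synonyms_of(original[j - 1]) if (j, c) not in tried and c != current),
            key=lambda c: (_hamming(c, original[j - 1]), c),
        )
        for c in options:
            trial = list(codons)
            trial[j - 1] = c
            deleted = trial[first_codon - 1][0]
            ins = deleted if insert_nt is None else insert_nt
            mutated = _apply_shift(trial, first_codon, last_codon, ins)
            if mutated[3 * (k - 1) : 3 * k] not in STOP_CODONS:
                codons[j - 1] = c
                tried.add((j, c))
                fixes.append((j, original[j - 1], c))
                return True
    return False


def design_synonymous_block(cds: str, first_codon: int, last_codon: int) -> str:
    """Replace codons ``first_codon..last_codon`` by maximally distant synonyms.

    Each codon is swapped for the synonymous codon with the largest
    nucleotide Hamming distance (ties broken lexicographically); Met/Trp
    codons, which have no synonym, are left unchanged with a warning.  The
    translation is invariant by construction.
    """
    cds = cds.upper()
    n = len(cds) // 3
    if len(cds) % 3 != 0:
        raise TranslationError("CDS length not divisible by 3")
    if not (1 <= first_codon <= last_codon <= n):
        raise DesignError("codon block out of range")
    codons = [cds[3 * i : 3 * i + 3] for i in range(n)]
    for k in range(first_codon, last_codon + 1):
        codon = codons[k - 1]
        if codon in STOP_CODONS:
            raise DesignError(f"codon {k} is a stop codon; synonymous block must be coding")
        options = _synonyms_of(codon)
        if not options:
            warnings.warn(f"codon {k} ({codon}) has no synonym; left unchanged", stacklevel=2)
            continue
        best = max(options, key=lambda c: (_hamming(c, codon), tuple(-ord(x) for x in c)))
        codons[k - 1] = best
    return "".join(codons)


def classify_arrest_deficiency(
    wt: ReporterRecord,
    mut: ReporterRecord,
    fold_threshold: float = 3.0,
) -> tuple[float, bool, bool]:
    """Classify a reporter mutant relative to wildtype.

    Returns ``(fold, deficient, enhanced)`` where ``fold = mut/wt`` mean
    activity, ``deficient`` iff fold >= ``fold_threshold`` (the mutant
    escapes arrest) and ``enhanced`` iff fold <= 1/``fold_threshold``.
    """
    if wt.activity_AU == 0:
        raise ValueError("wildtype activity is zero; fold change undefined")
    fold = mut.activity_AU / wt.activity_AU
    return fold, fold >= fold_threshold, fold <= 1.0 / fold_threshold
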
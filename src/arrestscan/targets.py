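"""Identification of sec/yidC-class target genes by annotation keywords.

The screen starts from genes of the Sec translocation machinery (secY,
secE, secG, secA, secD, secF, or the fused secDF) and the YidC insertase
family (yidC, and its synonyms oxaA and spoIIIJ), found by keyword matching
against gene names and product annotations rather than by homology search.

Matching is case-insensitive and token-based: a keyword hits a gene when it
equals a whole token of the gene name or product annotation, optionally
followed by a paralog-numbering digit suffix (so keyword ``yidc`` matches
the gene name ``yidC2`` but the token ``secyeg`` does not match ``secy``).
When a gene matches keywords of several classes, the class whose matched
keyword is longest wins; this keeps a fused ``secDF`` gene from being
double-reported as secD and secF.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .genome import GeneRecord, Genome

__all__ = ["TargetGene", "DEFAULT_TARGET_KEYWORDS", "locate_targets"]

#: class -> lowercase keyword tokens searched in gene names and product annotations
DEFAULT_TARGET_KEYWORDS: dict[str, frozenset[str]] = {
    "yidC": frozenset({"yidc", "oxaa", "spoiiij"}),
    "secDF": frozenset({"secdf"}),
    "secD": frozenset({"secd"}),
    "secF": frozenset({"secf"}),
    "secY": frozenset({"secy"}),
    "secE": frozenset({"sece"}),
    "secA": frozenset({"seca"}),
    "secG": frozenset({"secg"}),
}

_TOKEN_SPLIT = re.compile(r"[^A-Za-z0-9]+")


@dataclass(frozen=True)
class TargetGene:
    """A located target gene together with the class its keyword defined."""

    gene: GeneRecord
    target_class: str
    matched_keyword: str


def _token_matches(token: str, keyword: str) -> bool:
    if token == keyword:
        return True
    # allow a paralog-numbering suffix: yidc2, secdf2 ...
    return token.startswith(keyword) and token[len(keyword) :].isdigit()


def _gene_tokens(gene: GeneRecord) -> set[str]:
    tokens = {t.lower() for t in _TOKEN_SPLIT.split(gene.name) if t}
    tokens.update(gene.product_keywords)
    return tokens


def locate_targets(
    genome: Genome,
    keyword_map: dict[str, frozenset[str]] | None = None,
) -> list[TargetGene]:
    """Find sec/yidC-class genes in ``genome`` by keyword matching.

    Returns one :class:`TargetGene` per matching gene, carrying the class of
    the longest matched keyword.  Genomes without matches yield an empty
    list (silent failure, as an incompletely annotated genome simply drops
    out of the screen).  The result is sorted by gene start and independent
    of the input gene ordering.
    """
    kw_map = keyword_map if keyword_map is not None else DEFAULT_TARGET_KEYWORDS
    out: list[TargetGene] = []
    for gene in genome.genes:
        tokens = _gene_tokens(gene)
        best: tuple[int, str, str] | None = None  # (keyword length, class, keyword)
        for cls, keywords in kw_map.items():
            for kw in keywords:
                if any(_token_matches(t, kw) for t in tokens):
                    cand = (len(kw), cls, kw)
                    if best is None or cand[0] > best[0]:
                        best = cand
        if best is not None:
            out.append(TargetGene(gene=gene, target_class=best[1], matched_keyword=best[2]))
    out.sort(key=lambda t: (t.gene.start, t.gene.gene_id))
    return out
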
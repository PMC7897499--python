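"""Toeprint mapping, motif scanning, construct design, reporter classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arrestscan.arrest import (
    DesignError,
    ReporterRecord,
    ToeprintParams,
    classify_arrest_deficiency,
    consensus_over_replicates,
    design_internal_frameshift,
    design_synonymous_block,
    map_toeprint_to_psite,
    scan_arrest_motif,
)
from arrestscan.genome import STOP_CODONS, translate, translate_frame


class TestToeprintMapping:
    def test_unambiguous_stop(self):
        """A stop 17 nt after a codon's first nucleotide pins the P-site."""
        a = map_toeprint_to_psite(381, 1)
        assert a.candidate_psite_codons == frozenset({122})
        assert a.consensus_psite == 122
        assert a.asite == 123

    def test_ambiguous_stop_spans_codon_boundary(self):
        a = map_toeprint_to_psite(325, 1)
        assert a.candidate_psite_codons == frozenset({103, 104})
        assert a.consensus_psite is None
        assert a.asite is None

    def test_stop_too_close_to_start_rejected(self):
        with pytest.raises(ValueError, match="precedes the ORF start"):
            map_toeprint_to_psite(10, 1)

    @given(codon=st.integers(1, 200), offset=st.integers(15, 17), start=st.integers(1, 50))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_roundtrip_containment(self, codon, offset, start):
        """The true P-site codon is always inside the candidate set."""
        first_nt = start + 3 * (codon - 1)
        a = map_toeprint_to_psite(first_nt + offset, start)
        assert codon in a.candidate_psite_codons

    @given(codon=st.integers(1, 200), start=st.integers(1, 50))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_singleton_iff_offset_17(self, codon, start):
        """Unambiguity characterization: only the +17 stop pins one codon.

        The initiator codon is the one exception: shorter offsets reach
        upstream of the ORF start and are clipped, so the set collapses to
        the initiator anyway.
        """
        first_nt = start + 3 * (codon - 1)
        for offset in (15, 16, 17):
            a = map_toeprint_to_psite(first_nt + offset, start)
            if offset == 17 or codon == 1:
                assert a.consensus_psite == codon
            else:
                assert a.consensus_psite is None

    def test_consensus_over_replicates(self):
        from arrestscan.arrest import ToeprintAssignment

        mk = lambda codons: ToeprintAssignment(
            stop_nt=0, candidate_psite_codons=frozenset(codons),
            consensus_psite=next(iter(codons)) if len(codons) == 1 else None,
        )
        assert consensus_over_replicates([mk({122}), mk({121, 122})]) == 122
        assert consensus_over_replicates([mk({103, 104}), mk({104, 105})]) == 104
        with pytest.raises(ValueError):
            consensus_over_replicates([mk({103}), mk({105})])
        with pytest.warns(UserWarning):
            assert consensus_over_replicates([mk({103, 104})]) is None


class TestMotifScan:
    def test_published_motif_positions(self):
        """RAPG ending at 105 and RAPP ending at 123, as in ApcA and ApdA."""
        apca_like = "M" + "X" * 100 + "RAPG" + "DDD"
        apca_like = apca_like.replace("X", "S")
        assert scan_arrest_motif(apca_like) == [(102, 105, "RAPG")]
        apda_like = "M" + "S" * 118 + "RAPP" + "EEEEE"
        assert scan_arrest_motif(apda_like) == [(120, 123, "RAPP")]

    def test_fourth_residue_must_be_g_or_p(self):
        assert scan_arrest_motif("MARAPA") == []

    def test_overlapping_matches_all_reported(self):
        assert scan_arrest_motif("RAPRAPP") == [(4, 7, "RAPP")]
        assert scan_arrest_motif("RAPGRAPP") == [(1, 4, "RAPG"), (5, 8, "RAPP")]


def _random_cds(rng, n_codons=None):
    from arrestscan.synthetic import _reverse_translate

    n = n_codons or int(rng.integers(30, 150))
    aas = "ACDEFGHIKLMNPQRSTVWY"
    protein = "M" + "".join(rng.choice(list(aas), size=n - 1))
    return _reverse_translate(protein, rng) + "TAA"


class TestFrameshiftDesign:
    def test_toy_segment_scrambles_only_inside(self):
        cds = "ATGGCTCGTGAATAA"  # M A R E *
        mutated, log = design_internal_frameshift(cds, 2, 3)
        assert len(mutated) == len(cds)
        before, after = translate(cds), translate(mutated)
        assert before[0] == after[0] and before[3] == after[3]
        assert before[1:3] != after[1:3]
        assert log.deleted_nt == cds[3]

    def test_invalid_segment_rejected(self):
        cds = "ATGGCTCGTGAATAA"
        with pytest.raises(DesignError):
            design_internal_frameshift(cds, 3, 2)
        with pytest.raises(DesignError):
            design_internal_frameshift(cds, 2, 5)  # touches the stop codon

    def test_shift_created_stop_gets_synonymous_fix(self):
        # codon 3 = TTA: shifted reading TA+x can form a stop; construct one
        # M(ATG) L(CTT) L(TTA) A(GCT) *  -> shift of codons 2..4 creates TTT TAG CTx?
        cds = "ATG" + "CTT" + "TTA" + "GCT" + "TAA"
        mutated, log = design_internal_frameshift(cds, 2, 4)
        aa = translate_frame(mutated)
        assert "*" not in aa[:-1] and aa.endswith("*")
        assert log.synonymous_fixes  # the TAG stop had to be pre-empted

    def test_unfixable_atg_junction_raises(self):
        """An ATG whose shift forms TGA with a following A-locked codon
        (here Ile, all of whose synonyms start with A) has no synonymous fix."""
        cds = "ATG" + "GCT" + "ATG" + "ATT" + "GAA" + "TAA"
        with pytest.raises(DesignError, match="codon 3"):
            design_internal_frameshift(cds, 2, 5)

    def test_random_cds_invariants(self):
        """Length, flanking translation and stop-freedom over random designs.

        Unfixable segments (ATG junctions, see above) raise; a designable
        segment is then re-drawn, as when choosing workable constructs.
        """
        rng = np.random.default_rng(99)
        designed = 0
        for _ in range(200):
            cds = _random_cds(rng)
            n = len(cds) // 3
            for _attempt in range(10):
                first = int(rng.integers(2, n - 2))
                last = int(rng.integers(first, n - 1))
                try:
                    mutated, _ = design_internal_frameshift(cds, first, last)
                    break
                except DesignError:
                    continue
            else:
                continue
            designed += 1
            assert len(mutated) == len(cds)
            aa_in, aa_out = translate_frame(cds), translate_frame(mutated)
            assert "*" not in aa_out[:-1]
            assert aa_out[: first - 1] == aa_in[: first - 1]
            assert aa_out[last:] == aa_in[last:]
        assert designed >= 198  # a designable segment nearly always exists


class TestSynonymousDesign:
    def test_arg_codon_max_distance(self):
        """CGT's most distant synonyms are AGA/AGG; ties break lexicographically."""
        out = design_synonymous_block("ATGCGTTAA", 2, 2)
        assert out == "ATGAGATAA"

    def test_met_trp_unchanged_with_warning(self):
        with pytest.warns(UserWarning):
            out = design_synonymous_block("ATGTGGTAA", 1, 2)
        assert out == "ATGTGGTAA"

    @given(st.integers(0, 10_000))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_translation_invariant(self, seed):
        import warnings

        rng = np.random.default_rng(seed)
        cds = _random_cds(rng, n_codons=int(rng.integers(10, 60)))
        n = len(cds) // 3
        first = int(rng.integers(1, n - 1))
        last = int(rng.integers(first, n - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # Met/Trp have no synonym
            out = design_synonymous_block(cds, first, last)
        assert translate_frame(out) == translate_frame(cds)

    def test_stop_codon_in_block_rejected(self):
        with pytest.raises(DesignError):
            design_synonymous_block("ATGCGTTAA", 3, 3)


class TestReporterClassification:
    def test_published_frameshift_fold_change(self):
        """Wildtype 14.6 AU vs whole-domain frameshift 78.4 AU: deficient."""
        wt = ReporterRecord("wt", 14.6, sd=1.0, n=3)
        fs = ReporterRecord("fs62-108", 78.4, sd=3.0, n=3)
        fold, deficient, enhanced = classify_arrest_deficiency(wt, fs)
        assert fold == pytest.approx(78.4 / 14.6)
        assert deficient and not enhanced

    def test_neutral_and_enhanced(self):
        wt = ReporterRecord("wt", 12.3)
        assert classify_arrest_deficiency(wt, ReporterRecord("m", 12.3)) == (1.0, False, False)
        fold, deficient, enhanced = classify_arrest_deficiency(wt, ReporterRecord("m", 3.0))
        assert enhanced and not deficient

    def test_zero_wildtype_rejected(self):
        with pytest.raises(ValueError):
            classify_arrest_deficiency(ReporterRecord("wt", 0.0), ReporterRecord("m", 5.0))

    def test_threshold_boundary(self):
        wt = ReporterRecord("wt", 10.0)
        assert classify_arrest_deficiency(wt, ReporterRecord("m", 30.0))[1] is True
        assert classify_arrest_deficiency(wt, ReporterRecord("m", 29.9))[1] is False
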
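"""Global alignment, homolog clustering and C-terminal conservation."""

import numpy as np
import pytest
from Bio import Align

from arrestscan.conservation import (
    AlignParams,
    HomologGroup,
    cluster_homologs,
    cterm_conservation,
    global_align,
)
from arrestscan.genome import CandidateORF
from arrestscan.synthetic import mutate_homolog


def _cand(cid, protein):
    n = len(protein)
    return CandidateORF(
        candidate_id=cid, genome_id=cid.split(":")[0], target_gene_id="t",
        start=0, end=3 * (n + 1), strand="+", protein=protein, distance_nt=10,
    )


def _biopython_aligner(p: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = p.match
    aligner.mismatch_score = p.mismatch
    aligner.open_gap_score = p.gap_open
    aligner.extend_gap_score = p.gap_extend
    return aligner


class TestGlobalAlign:
    def test_self_alignment(self):
        aln = global_align("MARAPG", "MARAPG")
        assert aln.identity == 1.0
        assert aln.score == 12  # six matches at +2

    def test_toy_pair_identity(self):
        # MAR vs M: one match over three columns whichever gap layout is optimal
        aln = global_align("MAR", "M")
        assert aln.identity == pytest.approx(1 / 3)
        assert len(aln.aligned_a) == 3

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "MAR")

    def test_symmetry_of_identity(self, rng):
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(50):
            a = "".join(rng.choice(aas, size=rng.integers(5, 25)))
            b = "".join(rng.choice(aas, size=rng.integers(5, 25)))
            assert global_align(a, b).identity == pytest.approx(global_align(b, a).identity)

    def test_scores_match_biopython_aligner(self, rng):
        """Independent oracle: optimal score equals Bio.Align.PairwiseAligner."""
        p = AlignParams()
        aligner = _biopython_aligner(p)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(60):
            a = "".join(rng.choice(aas, size=rng.integers(3, 30)))
            b = "".join(rng.choice(aas, size=rng.integers(3, 30)))
            assert global_align(a, b, p).score == pytest.approx(aligner.score(a, b))

    def test_alignment_is_deterministic(self):
        a1 = global_align("MARAP", "MRAP")
        a2 = global_align("MARAP", "MRAP")
        assert (a1.aligned_a, a1.aligned_b) == (a2.aligned_a, a2.aligned_b)


class TestClusterHomologs:
    def test_planted_family_forms_one_group(self, rng):
        base = "".join(np.random.default_rng(3).choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
        cands = [
            _cand(f"G{i}:c", mutate_homolog(base, 0.10, frozenset(), rng))
            for i in range(5)
        ]
        groups = cluster_homologs(cands)
        assert len(groups) == 1
        assert len(groups[0].members) == 5

    def test_unrelated_proteins_form_no_group(self, rng):
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        a = "".join(rng.choice(aas, size=100))
        b = "".join(rng.choice(aas, size=100))
        assert cluster_homologs([_cand("G1:a", a), _cand("G2:b", b)]) == []

    def test_permutation_invariance(self, rng):
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=90))
        cands = [_cand(f"G{i}:c", mutate_homolog(base, 0.05, frozenset(), rng)) for i in range(4)]
        g1 = cluster_homologs(cands)
        g2 = cluster_homologs(list(reversed(cands)))
        assert [g.members for g in g1] == [g.members for g in g2]

    def test_removing_member_never_grows_group(self, rng):
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=90))
        cands = [_cand(f"G{i}:c", mutate_homolog(base, 0.05, frozenset(), rng)) for i in range(5)]
        full = cluster_homologs(cands)
        reduced = cluster_homologs(cands[:-1])
        max_full = max((len(g.members) for g in full), default=0)
        max_reduced = max((len(g.members) for g in reduced), default=0)
        assert max_reduced <= max_full


def _group(tails):
    proteins = {f"G{i}:c": t for i, t in enumerate(tails)}
    return HomologGroup(group_id="HG001", members=sorted(proteins), proteins=proteins)


class TestCtermConservation:
    def test_identical_tails_score_one(self):
        tail = "DESTKNQRAPGDESTKNQDESTKNQDESTK"
        prof = cterm_conservation(_group([tail] * 4), K=30)
        assert prof.mean_conservation == 1.0
        assert all(f == 1.0 for _, f in prof.columns)
        assert all(a == 1.0 for a in prof.member_agreement)

    def test_single_split_column(self):
        """One column split 2/2: that column scores 0.5, the mean (29 + 0.5)/30."""
        tail = "DESTKNQRAPGDESTKNQDESTKNQDESTK"
        variant = tail[:10] + "W" + tail[11:]
        prof = cterm_conservation(_group([tail, tail, variant, variant]), K=30)
        per_col = sorted(f for _, f in prof.columns)
        assert per_col[0] == 0.5
        assert all(f == 1.0 for f in per_col[1:])
        assert prof.mean_conservation == pytest.approx((29 + 0.5) / 30)

    def test_gap_counts_against_conservation(self):
        """A member shorter than K: its missing column scores 3/4."""
        tail = "DESTKNQRAPGDESTKNQDESTKNQDESTK"
        short = tail[1:]  # 29 residues -> one leading gap
        prof = cterm_conservation(_group([tail, tail, tail, short]), K=30)
        fracs = [f for _, f in prof.columns]
        assert fracs[0] == 0.75
        assert all(f == 1.0 for f in fracs[1:])

    def test_group_of_one_rejected(self):
        with pytest.raises(ValueError):
            cterm_conservation(_group(["DESTK" * 6]), K=30)

    def test_outlier_member_has_low_agreement(self, rng):
        tail = "DESTKNQRAPGDESTKNQDESTKNQDESTK"
        outlier = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=30))
        grp = _group([tail, tail, tail, outlier])
        prof = cterm_conservation(grp, K=30)
        agree = dict(zip(grp.members, prof.member_agreement))
        # members are sorted G0..G3; G3 carries the outlier tail
        assert agree["G3:c"] < 0.5
        assert agree["G0:c"] > 0.6

    def test_anchor_motif_right_justifies(self):
        tail = "DESTKNQDESTKNQDESTKNQDERAPGKNQ"
        shifted = "AA" + tail[:-2]  # motif two columns earlier
        prof_plain = cterm_conservation(_group([tail, tail, shifted]), K=30)
        prof_anchor = cterm_conservation(
            _group([tail, tail, shifted]), K=30, anchor_motif="RAPG"
        )
        assert prof_anchor.mean_conservation >= prof_plain.mean_conservation

    def test_entropy_statistic_orders_like_modal(self):
        tail = "DESTKNQRAPGDESTKNQDESTKNQDESTK"
        variant = tail[:5] + "WW" + tail[7:]
        grp = _group([tail, tail, tail, variant])
        modal = cterm_conservation(grp, K=30, statistic="modal")
        entropy = cterm_conservation(grp, K=30, statistic="entropy")
        assert entropy.mean_conservation < 1.0
        assert modal.mean_conservation < 1.0


class TestExports:
    def test_alignment_fasta_and_profile_tsv(self, tmp_path):
        from arrestscan.conservation import (
            write_conservation_tsv,
            write_group_alignment_fasta,
        )

        tail = "DESTKNQRAPGDESTKNQDESTKNQDESTK"
        grp = _group([tail, tail, tail])
        grp.profile = cterm_conservation(grp, K=30)
        write_group_alignment_fasta(grp, tmp_path / "aln.fasta")
        lines = (tmp_path / "aln.fasta").read_text().splitlines()
        assert lines[0].startswith(">") and lines[1] == tail
        write_conservation_tsv(grp.profile, tmp_path / "prof.tsv")
        rows = (tmp_path / "prof.tsv").read_text().splitlines()
        assert rows[0] == "column\tmodal_residue\tfraction"
        assert len(rows) == 31 and rows[1].endswith("\t1")
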
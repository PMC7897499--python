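"""Synthetic multi-species genome panels with planted candidates and decoys.

The generator emulates the statistical structure the screen assumes: small
bacterial chromosome segments in which sec/yidC-class target genes carry,
immediately upstream and on the same strand, an unannotated ORF encoding a
monitoring-substrate-like protein — hydrophobic N-terminal topogenic
element, hydrophilic linker, and a C-terminal 30-residue region conserved
across the planted homolog family and containing an R-A-P-[G/P] block.

Alongside the true candidates, per-criterion decoy families are planted,
each violating exactly one screen criterion:

==================  ==========================================  =========
class               construction                                 fails
==================  ==========================================  =========
short               60-codon ORF                                 c2 (size)
no_signal           hydrophilic N-terminus                       c3 (signal)
short_exposure      signal run ending 30 residues from the end   c4 (exposure)
scrambled_tail      independent random C-terminal 30-mer         c5 (conservation)
wrong_strand        antisense placement                          orientation (never enumerated)
far_from_target     stop codon 2 kb upstream of the target       c1 (distance)
==================  ==========================================  =========

Every genome receives one member of each requested decoy family, one
target gene per requested class, filler annotation and random intergenic
sequence, plus a truth manifest (JSON) recording all planted coordinates.
Generation is reproducible from the seed (numpy PCG64 via
``default_rng``).  Proteins are reverse-translated with a uniform choice
over synonymous codons drawn independently per genome, so homologous
proteins are conserved while their CDSs diverge at synonymous sites, as in
real cross-species comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .genome import Genome, GeneRecord, reverse_complement, translate
from .arrest import _SYNONYMS  # aa -> synonymous codons, table 11

__all__ = [
    "PanelConfig",
    "TruthManifest",
    "PlantedFeature",
    "generate_panel",
    "mutate_homolog",
    "write_panel",
    "load_manifest",
]

DECOY_CLASSES = (
    "short",
    "no_signal",
    "short_exposure",
    "scrambled_tail",
    "wrong_strand",
    "far_from_target",
)

DECOY_FAILS = {
    "short": "c2",
    "no_signal": "c3",
    "short_exposure": "c4",
    "scrambled_tail": "c5",
    "wrong_strand": "absent",
    "far_from_target": "c1",
}

#: which target-gene class hosts each planted feature slot
FAMILY_TARGET_CLASSES = ("yidC", "secDF")
DECOY_TARGET_CLASSES = {
    "short": "secA",
    "no_signal": "secY",
    "short_exposure": "secE",
    "scrambled_tail": "secG",
    "wrong_strand": "secF",
    "far_from_target": "secD",
}

_TARGET_ANNOTATION = {
    "yidC": ("yidC2", "membrane protein insertase YidC2"),
    "secDF": ("secDF2", "protein translocase subunit SecDF"),
    "secA": ("secA", "preprotein translocase subunit SecA"),
    "secY": ("secY", "preprotein translocase subunit SecY"),
    "secE": ("secE", "preprotein translocase subunit SecE"),
    "secG": ("secG", "preprotein translocase subunit SecG"),
    "secD": ("secD", "protein translocase subunit SecD"),
    "secF": ("secF", "protein translocase subunit SecF"),
}

HYDROPHOBIC = "LIVFA"
HYDROPHOBIC_W = np.array([0.35, 0.25, 0.20, 0.10, 0.10])
#: hydrophilic alphabet; Ala is its only residue with positive hydropathy and
#: is capped to runs of <= 4 so no spurious topogenic signal can arise
HYDROPHILIC = "DEKRSTNQGHPA"
AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class PanelConfig:
    n_species: int = 10
    seed: int = 0
    n_plant_families: int = 2
    plant_family_size: int = 5
    plant_lengths: tuple[int, ...] = (108, 128)  # residues per family
    motif_tail_offsets: tuple[int, ...] = (3, 5)  # residues after the motif end
    tail_divergence_rate: float = 0.0
    conserved_tail_positions: frozenset[int] = frozenset()  # 1-based in the 30-mer
    signal_kind_mix: float = 0.5  # fraction TM (vs SS) among planted members
    decoy_classes: tuple[str, ...] = DECOY_CLASSES
    intergenic_gc: float = 0.5
    tail_len: int = 30
    plant_distance_nt: int = 30
    far_distance_nt: int = 2000

    def __post_init__(self) -> None:
        if not (0 <= self.tail_divergence_rate < 1):
            raise ValueError("tail_divergence_rate must lie in [0, 1)")
        if not (0 < self.intergenic_gc < 1):
            raise ValueError("intergenic_gc must lie in (0, 1)")
        if self.plant_family_size > self.n_species:
            raise ValueError("plant_family_size cannot exceed n_species")
        if len(self.plant_lengths) < self.n_plant_families:
            raise ValueError("need one planted length per family")
        for L in self.plant_lengths[: self.n_plant_families]:
            if not (80 <= L <= 200):
                raise ValueError(f"planted length {L} outside the screen's 80-200 aa range")
        unknown = set(self.decoy_classes) - set(DECOY_CLASSES)
        if unknown:
            raise ValueError(f"unknown decoy classes: {sorted(unknown)}")


@dataclass
class PlantedFeature:
    """One planted ORF (true candidate or decoy) in genome coordinates."""

    kind: str  # "family" or decoy class name
    family_id: str
    genome_id: str
    target_gene_id: str
    target_class: str
    start: int
    end: int
    strand: str
    protein: str
    signal_kind: str = "none"
    signal_start: int = 0
    signal_end: int = 0
    motif_start: int = 0
    motif_end: int = 0
    fails: str = ""  # expected failing criterion for decoys, "" for true plants


@dataclass
class TruthManifest:
    seed: int
    rng: str
    config: dict
    planted: list[PlantedFeature] = field(default_factory=list)

    def by_genome(self) -> dict[str, list[PlantedFeature]]:
        out: dict[str, list[PlantedFeature]] = {}
        for f in self.planted:
            out.setdefault(f.genome_id, []).append(f)
        return out

    def true_candidates(self) -> list[PlantedFeature]:
        return [f for f in self.planted if f.kind == "family"]

    def decoys(self) -> list[PlantedFeature]:
        return [f for f in self.planted if f.kind != "family"]

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "rng": self.rng,
                "config": self.config,
                "planted": [asdict(f) for f in self.planted],
            },
            indent=1,
            sort_keys=True,
        )


def load_manifest(path) -> TruthManifest:
    with open(path) as fh:
        data = json.load(fh)
    return TruthManifest(
        seed=data["seed"],
        rng=data["rng"],
        config=data["config"],
        planted=[PlantedFeature(**f) for f in data["planted"]],
    )


# ---------------------------------------------------------------- sampling


def _random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p)) if n else ""


def _random_hydrophilic(n: int, rng: np.random.Generator) -> str:
    """Hydrophilic residues with Ala runs capped at 4 (rejection of long runs)."""
    out: list[str] = []
    run = 0
    while len(out) < n:
        aa = HYDROPHILIC[rng.integers(len(HYDROPHILIC))]
        if aa == "A":
            run += 1
            if run > 4:
                continue
        else:
            run = 0
        out.append(aa)
    return "".join(out)


def _random_hydrophobic(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(HYDROPHOBIC), size=n, p=HYDROPHOBIC_W))


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        opts = _SYNONYMS[aa]
        codons.append(opts[rng.integers(len(opts))])
    return "".join(codons)


def mutate_homolog(
    protein: str,
    rate: float,
    conserved_positions: frozenset[int] | set[int],
    rng: np.random.Generator,
) -> str:
    """Substitute each non-conserved residue with probability ``rate``.

    ``conserved_positions`` are 1-based residue indices never touched.
    Substitutions are uniform over the 19 other amino acids.
    """
    out = list(protein)
    for i in range(len(out)):
        if (i + 1) in conserved_positions:
            continue
        if rng.random() < rate:
            choices = [a for a in AA20 if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


# ------------------------------------------------------------- protein design


def _make_signal(kind: str, rng: np.random.Generator) -> tuple[str, int, int]:
    """Return (signal segment, hydrophobic start, hydrophobic end), 1-based."""
    if kind == "TM":
        seg = "M" + "".join(rng.choice(list("KR"), size=2)) + _random_hydrophobic(30, rng)
        return seg, 4, 33
    if kind == "SS":
        seg = "M" + "".join(rng.choice(list("KR"), size=2)) + _random_hydrophobic(12, rng)
        return seg, 4, 15
    raise ValueError(kind)


def _family_tail(rng: np.random.Generator, tail_len: int, motif_offset: int | None) -> tuple[str, int]:
    """A conserved C-terminal tail; motif RAP[G/P] ends ``motif_offset`` residues
    before the tail end (None -> no motif).  Returns (tail, motif start in tail)."""
    tail = list(_random_hydrophilic(tail_len, rng))
    motif_start = 0
    if motif_offset is not None:
        last = "G" if rng.random() < 0.5 else "P"
        motif = "RAP" + last
        start = tail_len - motif_offset - 4  # 0-based
        tail[start : start + 4] = motif
        motif_start = start + 1
    return "".join(tail), motif_start


def _assemble(signal_seg: str, total_len: int, tail: str, rng: np.random.Generator) -> str:
    linker = _random_hydrophilic(total_len - len(signal_seg) - len(tail), rng)
    return signal_seg + linker + tail


# ------------------------------------------------------------- genome builder


class _GenomeBuilder:
    def __init__(self, genome_id: str, cfg: PanelConfig, rng: np.random.Generator):
        self.genome_id = genome_id
        self.cfg = cfg
        self.rng = rng
        self.seq_parts: list[str] = []
        self.length = 0
        self.genes: list[GeneRecord] = []
        self.features: list[PlantedFeature] = []
        self._gene_counter = 0

    def _emit(self, dna: str) -> int:
        start = self.length
        self.seq_parts.append(dna)
        self.length += len(dna)
        return start

    def add_intergenic(self, n: int) -> None:
        self._emit(_random_dna(n, self.cfg.intergenic_gc, self.rng))

    def add_gene(self, target_class: str | None, length: int = 900, strand: str = "+") -> GeneRecord:
        self._gene_counter += 1
        if target_class is None:
            name, product = "", "hypothetical protein"
            gid = f"{self.genome_id}_g{self._gene_counter:02d}"
        else:
            name, product = _TARGET_ANNOTATION[target_class]
            gid = f"{self.genome_id}_{name}"
        start = self._emit(_random_dna(length, self.cfg.intergenic_gc, self.rng))
        rec = GeneRecord(
            gene_id=gid,
            start=start,
            end=start + length,
            strand=strand,
            name=name,
            product_keywords=tuple(product.lower().split()),
        )
        self.genes.append(rec)
        return rec

    def add_block(
        self,
        target_class: str,
        protein: str | None,
        feature: PlantedFeature | None,
        distance_nt: int,
        block_strand: str = "+",
        orf_antisense: bool = False,
    ) -> None:
        """One [spacer, insulator, ORF, gap, target gene, spacer] block.

        Built in the orientation of the target's coding strand; when
        ``block_strand`` is '-', the whole block is reverse-complemented and
        coordinates are remapped.  ``orf_antisense`` flips only the ORF
        (the wrong_strand decoy).
        """
        cfg, rng = self.cfg, self.rng
        pre = _random_dna(int(rng.integers(40, 81)), cfg.intergenic_gc, rng)
        parts: list[str] = [pre]
        orf_local: tuple[int, int] | None = None
        if protein is not None:
            parts.append("TAA")  # in-frame insulator: no upstream start extends the ORF
            cds = _reverse_translate(protein, rng) + "TAA"
            if orf_antisense:
                cds = reverse_complement(cds)
            local_start = sum(len(x) for x in parts)
            parts.append(cds)
            orf_local = (local_start, local_start + len(cds))
        parts.append(_random_dna(distance_nt, cfg.intergenic_gc, rng))
        gene_local_start = sum(len(x) for x in parts)
        gene_len = 900
        parts.append(_random_dna(gene_len, cfg.intergenic_gc, rng))
        parts.append(_random_dna(int(rng.integers(80, 121)), cfg.intergenic_gc, rng))
        block = "".join(parts)

        if block_strand == "+":
            offset = self._emit(block)
            gene_start = offset + gene_local_start
            gene_strand = "+"
            if orf_local:
                orf_start, orf_end = offset + orf_local[0], offset + orf_local[1]
                orf_strand = "-" if orf_antisense else "+"
        else:
            offset = self._emit(reverse_complement(block))
            L = len(block)
            gene_start = offset + (L - gene_local_start - gene_len)
            gene_strand = "-"
            if orf_local:
                orf_start = offset + (L - orf_local[1])
                orf_end = offset + (L - orf_local[0])
                orf_strand = "+" if orf_antisense else "-"

        name, product = _TARGET_ANNOTATION[target_class]
        gid = f"{self.genome_id}_{name}"
        self.genes.append(
            GeneRecord(
                gene_id=gid,
                start=gene_start,
                end=gene_start + gene_len,
                strand=gene_strand,
                name=name,
                product_keywords=tuple(product.lower().split()),
            )
        )
        if feature is not None and orf_local is not None:
            feature.genome_id = self.genome_id
            feature.target_gene_id = gid
            feature.target_class = target_class
            feature.start = orf_start
            feature.end = orf_end
            feature.strand = orf_strand
            self.features.append(feature)

    def build(self) -> Genome:
        return Genome(self.genome_id, "".join(self.seq_parts), list(self.genes))


def plant_decoy(builder: _GenomeBuilder, decoy_class: str, family_tails: dict,
                cfg: PanelConfig, rng: np.random.Generator) -> None:
    """Append one decoy block of ``decoy_class`` to the genome under construction."""
    if decoy_class not in DECOY_CLASSES:
        raise ValueError(f"unknown decoy class {decoy_class!r}")
    tail = family_tails[decoy_class]
    target_class = DECOY_TARGET_CLASSES[decoy_class]
    kind = "SS"
    total = 108
    distance = cfg.plant_distance_nt
    antisense = False

    if decoy_class == "short":
        total = 60
    elif decoy_class == "no_signal":
        kind = "none"
    elif decoy_class == "short_exposure":
        total = 80
    elif decoy_class == "scrambled_tail":
        tail, _ = _family_tail(rng, cfg.tail_len, None)  # fresh tail per genome
        kind = "TM"
    elif decoy_class == "wrong_strand":
        kind = "TM"
        antisense = True
    elif decoy_class == "far_from_target":
        kind = "TM"
        distance = cfg.far_distance_nt

    if decoy_class == "short_exposure":
        # hydrophobic run placed so that it ends ~30 residues before the C-terminus
        nterm = "M" + _random_hydrophilic(21, rng) + _random_hydrophobic(28, rng)
        protein = nterm + tail  # hydrophobic residues 23-50, tail 51-80
        sig = ("TM", 23, 50)
    elif kind == "none":
        protein = "M" + _random_hydrophilic(total - 1 - len(tail), rng) + tail
        sig = ("none", 0, 0)
    else:
        seg, h_start, h_end = _make_signal(kind, rng)
        protein = _assemble(seg, total, tail, rng)
        sig = (kind, h_start, h_end)

    feature = PlantedFeature(
        kind=decoy_class,
        family_id=f"decoy_{decoy_class}",
        genome_id="",
        target_gene_id="",
        target_class=target_class,
        start=0,
        end=0,
        strand="+",
        protein=protein,
        signal_kind=sig[0],
        signal_start=sig[1],
        signal_end=sig[2],
        fails=DECOY_FAILS[decoy_class],
    )
    builder.add_block(
        target_class,
        protein,
        feature,
        distance_nt=distance,
        block_strand="+",
        orf_antisense=antisense,
    )


def generate_panel(config: PanelConfig | None = None) -> tuple[list[Genome], TruthManifest]:
    """Generate a genome panel plus its truth manifest, reproducibly from the seed."""
    cfg = config or PanelConfig()
    rng = np.random.default_rng(cfg.seed)

    # family-level shared material: conserved tails, member assignment
    families = []
    for f in range(cfg.n_plant_families):
        tail, motif_in_tail = _family_tail(rng, cfg.tail_len, cfg.motif_tail_offsets[f])
        members = {
            (f * cfg.plant_family_size + k) % cfg.n_species
            for k in range(cfg.plant_family_size)
        }
        families.append(
            {
                "family_id": f"FAM{f + 1}",
                "target_class": FAMILY_TARGET_CLASSES[f % len(FAMILY_TARGET_CLASSES)],
                "length": cfg.plant_lengths[f],
                "tail": tail,
                "motif_in_tail": motif_in_tail,
                "strand": "+" if f % 2 == 0 else "-",
                "members": members,
            }
        )
    decoy_tails = {cls: _family_tail(rng, cfg.tail_len, None)[0] for cls in DECOY_CLASSES}

    genomes: list[Genome] = []
    manifest = TruthManifest(
        seed=cfg.seed,
        rng="numpy default_rng (PCG64)",
        config={k: (sorted(v) if isinstance(v, frozenset) else list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(cfg).items()},
    )
    for s in range(cfg.n_species):
        gid = f"SYN{s + 1:03d}"
        b = _GenomeBuilder(gid, cfg, rng)
        b.add_intergenic(int(rng.integers(60, 141)))
        for fam in families:
            if s in fam["members"]:
                kind = "TM" if rng.random() < cfg.signal_kind_mix else "SS"
                seg, h_start, h_end = _make_signal(kind, rng)
                tail = fam["tail"]
                if cfg.tail_divergence_rate > 0:
                    conserved = set(cfg.conserved_tail_positions)
                    if fam["motif_in_tail"]:
                        conserved.update(range(fam["motif_in_tail"], fam["motif_in_tail"] + 4))
                    tail = mutate_homolog(tail, cfg.tail_divergence_rate, conserved, rng)
                protein = _assemble(seg, fam["length"], tail, rng)
                tail_start = fam["length"] - cfg.tail_len  # 0-based offset of the tail
                feature = PlantedFeature(
                    kind="family",
                    family_id=fam["family_id"],
                    genome_id="",
                    target_gene_id="",
                    target_class=fam["target_class"],
                    start=0,
                    end=0,
                    strand="+",
                    protein=protein,
                    signal_kind=kind,
                    signal_start=h_start,
                    signal_end=h_end,
                    motif_start=tail_start + fam["motif_in_tail"],
                    motif_end=tail_start + fam["motif_in_tail"] + 3,
                )
                b.add_block(
                    fam["target_class"],
                    protein,
                    feature,
                    distance_nt=cfg.plant_distance_nt,
                    block_strand=fam["strand"],
                )
            else:
                # the target gene is present in every genome; no upstream ORF here
                b.add_block(fam["target_class"], None, None,
                            distance_nt=cfg.plant_distance_nt, block_strand=fam["strand"])
        for cls in cfg.decoy_classes:
            plant_decoy(b, cls, decoy_tails, cfg, rng)
        b.add_gene(None, length=int(rng.integers(300, 601)))
        b.add_intergenic(int(rng.integers(60, 141)))
        genome = b.build()
        _verify_features(genome, b.features)
        genomes.append(genome)
        manifest.planted.extend(b.features)
    return genomes, manifest


def _verify_features(genome: Genome, features: list[PlantedFeature]) -> None:
    for f in features:
        prot = translate(genome.sequence[f.start : f.end], f.strand)
        if prot != f.protein:
            raise AssertionError(
                f"manifest/genome inconsistency for {f.family_id} in {f.genome_id}"
            )


def write_panel(genomes: list[Genome], manifest: TruthManifest, outdir) -> None:
    """Write per-genome FASTA + GFF3 and ``truth.json`` under ``outdir``."""
    import os
    from .genome import write_genome

    os.makedirs(outdir, exist_ok=True)
    for g in genomes:
        write_genome(g, os.path.join(outdir, f"{g.genome_id}.fasta"),
                     os.path.join(outdir, f"{g.genome_id}.gff3"))
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        fh.write(manifest.to_json())
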
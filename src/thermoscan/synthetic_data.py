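"""Synthetic gene and cohort generators.

These fixtures emulate the statistical structure the scanning pipeline
assumes so that every stage is testable without downloads:

* random-composition transcripts with controllable GC fraction;
* planted thermodynamically stable, sequence-ordered GC hairpins — the
  low-z signal the scanner and consensus must recover;
* "thermometer" genes: tandem arrays of marginal AU-stem hairpins whose
  ensembles loosen between a moderate and a hot temperature (a large
  positive ΔED signal at every window);
* labelled cohorts of many genes (with toy gene models) for the
  population-level ΔED statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .io_tracks import Feature, GeneModel

__all__ = [
    "PlantedElement",
    "SyntheticGeneSpec",
    "SyntheticGene",
    "random_sequence",
    "plant_hairpin",
    "hairpin_pairs",
    "thermometer_tandem",
    "make_cohort",
    "write_cohort",
]

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

_STEM_ALPHABET = {"GC": "GC", "AU": "AU", "mixed": "ACGU"}

# Loop/spacer letters chosen so they cannot pair with the stem they close.
_LOOP_FOR = {"GC": "A", "AU": "C", "mixed": "A"}


@dataclass(frozen=True)
class PlantedElement:
    kind: str  # stable_hairpin | thermometer
    position: int
    stem_length: int
    loop_length: int
    composition: str  # GC | AU | mixed

    @property
    def length(self) -> int:
        return 2 * self.stem_length + self.loop_length

    @property
    def end(self) -> int:
        return self.position + self.length


@dataclass(frozen=True)
class SyntheticGeneSpec:
    gene_id: str
    length: int
    gc_fraction: float
    planted_elements: Tuple[PlantedElement, ...] = ()
    family: str = "other"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must be in [0, 1]")
        spans = sorted((e.position, e.end) for e in self.planted_elements)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("planted elements overlap")
        for e in self.planted_elements:
            if e.position < 0 or e.end > self.length:
                raise ValueError(
                    f"element at {e.position} (length {e.length}) outside gene of length {self.length}"
                )


@dataclass(frozen=True)
class SyntheticGene:
    spec: SyntheticGeneSpec
    sequence: str
    model: GeneModel


def _rng_of(rng=None, seed=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def random_sequence(length: int, gc_fraction: float = 0.5, seed=None, rng=None) -> str:
    """i.i.d. letters with P(G)=P(C)=gc/2 and P(A)=P(U)=(1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _rng_of(rng, seed)
    g = gc_fraction / 2.0
    a = (1.0 - gc_fraction) / 2.0
    return "".join(rng.choice(list("GCAU"), size=length, p=[g, g, a, a]))


def _make_stem(stem_length: int, composition: str, rng: np.random.Generator) -> str:
    alphabet = _STEM_ALPHABET.get(composition)
    if alphabet is None:
        raise ValueError(f"unknown stem composition {composition!r}")
    return "".join(rng.choice(list(alphabet), size=stem_length))


def build_hairpin(stem_length: int, loop_length: int, composition: str,
                  rng: np.random.Generator) -> str:
    """One perfect inverted repeat: stem + loop + reverse complement."""
    stem = _make_stem(stem_length, composition, rng)
    loop = _LOOP_FOR[composition] * loop_length
    return stem + loop + stem.translate(_COMPLEMENT)[::-1]


def hairpin_pairs(position: int, stem_length: int, loop_length: int) -> frozenset:
    """The stem base pairs a planted hairpin is designed to form, in
    transcript coordinates."""
    total = 2 * stem_length + loop_length
    return frozenset(
        (position + k, position + total - 1 - k) for k in range(stem_length)
    )


def plant_hairpin(
    background: str,
    position: int,
    stem_length: int,
    loop_length: int,
    composition: str = "GC",
    rng=None,
    seed=None,
) -> str:
    """Overwrite ``background`` at ``position`` with one hairpin element."""
    rng = _rng_of(rng, seed)
    hp = build_hairpin(stem_length, loop_length, composition, rng)
    if position < 0 or position + len(hp) > len(background):
        raise ValueError(
            f"hairpin of length {len(hp)} at position {position} does not fit "
            f"in background of length {len(background)}"
        )
    return background[:position] + hp + background[position + len(hp):]


def thermometer_tandem(
    length: int,
    stem_length: int = 14,
    loop_length: int = 4,
    spacer: int = 8,
    rng=None,
    seed=None,
) -> str:
    """A tandem array of one marginal AU-stem hairpin.

    The repeat unit is (AU stem + C loop + complement stem + A/C spacer);
    identical units tile the gene so that every scanning window contains a
    full marginal duplex — junction-spanning halves of adjacent identical
    units re-form the same hairpin.  AU stems sit near their melting
    regime, so the ensemble loosens with temperature (positive ΔED).
    """
    rng = _rng_of(rng, seed)
    unit = build_hairpin(stem_length, loop_length, "AU", rng)
    unit += "".join(rng.choice(list("AC"), size=spacer))
    reps = length // len(unit) + 1
    return (unit * reps)[:length]


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def _toy_gene_model(gene_id: str, length: int, genomic_start: int,
                    strand: str) -> GeneModel:
    """Two-exon layout with UTRs: 5'UTR within exon 1, an intron in the
    middle, 3'UTR within exon 2."""
    e1_end = max(int(0.45 * length), 1)
    e2_start = min(int(0.70 * length), length - 1)
    iso = f"{gene_id}_T001"
    features = (
        Feature("5'UTR", 0, max(int(0.10 * length), 1), iso),
        Feature("exon", 0, e1_end, iso),
        Feature("intron", e1_end, e2_start, iso),
        Feature("exon", e2_start, length, iso),
        Feature("3'UTR", min(int(0.90 * length), length - 1), length, iso),
    )
    return GeneModel(
        gene_id=gene_id,
        chromosome="chr1",
        genomic_start=genomic_start,
        strand=strand,
        length=length,
        features=features,
    )


def make_cohort(
    families: Dict[str, int],
    thermometer_fraction: float = 0.0,
    seed: int = 0,
    gene_length: int = 400,
    gc_fraction: float = 0.5,
    stable_hairpin_fraction: float = 0.0,
) -> List[SyntheticGene]:
    """A labelled cohort of synthetic genes with toy gene models.

    ``thermometer_fraction`` of genes (chosen at random) are tandem
    thermometer arrays; ``stable_hairpin_fraction`` carry one planted
    12-bp GC hairpin; the rest are plain random transcripts.  The same
    seed reproduces the cohort exactly.
    """
    n_genes = sum(families.values())
    if n_genes < 2:
        raise ValueError("a cohort needs >= 2 genes")
    rng = np.random.default_rng(seed)
    labels = [fam for fam, count in sorted(families.items()) for _ in range(count)]
    kinds = np.array(["null"] * n_genes, dtype=object)
    n_therm = int(round(thermometer_fraction * n_genes))
    n_stable = int(round(stable_hairpin_fraction * n_genes))
    order = rng.permutation(n_genes)
    kinds[order[:n_therm]] = "thermometer"
    kinds[order[n_therm:n_therm + n_stable]] = "stable_hairpin"

    genes: List[SyntheticGene] = []
    genomic_cursor = 1000
    for idx in range(n_genes):
        gene_id = f"SYNT{idx + 1:06d}"
        gene_seed = int(rng.integers(0, 2**31 - 1))
        grng = np.random.default_rng(gene_seed)
        elements: Tuple[PlantedElement, ...] = ()
        if kinds[idx] == "thermometer":
            stem, loop, spacer = 14, 4, 8
            seq = thermometer_tandem(gene_length, stem, loop, spacer, rng=grng)
            unit = 2 * stem + loop + spacer
            elements = tuple(
                PlantedElement("thermometer", p, stem, loop, "AU")
                for p in range(0, gene_length - (2 * stem + loop) + 1, unit)
            )
        elif kinds[idx] == "stable_hairpin":
            seq = random_sequence(gene_length, gc_fraction, rng=grng)
            stem, loop = 12, 4
            pos = int(grng.integers(20, gene_length - (2 * stem + loop) - 20))
            seq = plant_hairpin(seq, pos, stem, loop, "GC", rng=grng)
            elements = (PlantedElement("stable_hairpin", pos, stem, loop, "GC"),)
        else:
            seq = random_sequence(gene_length, gc_fraction, rng=grng)
        strand = "+" if grng.random() < 0.5 else "-"
        model = _toy_gene_model(gene_id, gene_length, genomic_cursor, strand)
        genomic_cursor += gene_length + 500
        genes.append(
            SyntheticGene(
                spec=SyntheticGeneSpec(
                    gene_id=gene_id,
                    length=gene_length,
                    gc_fraction=gc_fraction,
                    planted_elements=elements,
                    family=labels[idx],
                    seed=gene_seed,
                ),
                sequence=seq,
                model=model,
            )
        )
    return genes


def write_cohort(genes: List[SyntheticGene], outdir) -> None:
    """Emit per-gene FASTA files, one cohort GFF3, a family map, and a
    manifest TSV of every planted element."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_dir = outdir / "fasta"
    fasta_dir.mkdir(exist_ok=True)
    with open(outdir / "cohort.gff3", "w") as gff:
        gff.write("##gff-version 3\n")
        for g in genes:
            m = g.model
            with open(fasta_dir / f"{m.gene_id}.fasta", "w") as fa:
                fa.write(f">{m.gene_id}\n")
                for k in range(0, len(g.sequence), 60):
                    fa.write(g.sequence[k:k + 60] + "\n")
            gs, ge = m.genomic_start + 1, m.genomic_start + m.length
            gff.write(
                f"{m.chromosome}\tthermoscan\tgene\t{gs}\t{ge}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            iso = f"{m.gene_id}_T001"
            gff.write(
                f"{m.chromosome}\tthermoscan\tmRNA\t{gs}\t{ge}\t.\t{m.strand}\t.\t"
                f"ID={iso};Parent={m.gene_id}\n"
            )
            for f in m.features:
                if f.type == "intron":
                    continue  # derivable; GFF3 carries exons and UTRs
                gtype = {"exon": "exon", "5'UTR": "five_prime_UTR",
                         "3'UTR": "three_prime_UTR", "CDS": "CDS"}[f.type]
                if m.strand == "+":
                    a, b = m.genomic_start + f.start + 1, m.genomic_start + f.end
                else:
                    a = m.genomic_start + m.length - f.end + 1
                    b = m.genomic_start + m.length - f.start
                gff.write(
                    f"{m.chromosome}\tthermoscan\t{gtype}\t{a}\t{b}\t.\t{m.strand}\t.\t"
                    f"ID={iso}.{gtype}.{f.start};Parent={iso}\n"
                )
    with open(outdir / "families.tsv", "w") as fh:
        fh.write("gene_id\tfamily\tkind\n")
        for g in genes:
            kind = g.spec.planted_elements[0].kind if g.spec.planted_elements else "null"
            fh.write(f"{g.spec.gene_id}\t{g.spec.family}\t{kind}\n")
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("gene_id\tkind\tposition\tstem_length\tloop_length\tcomposition\n")
        for g in genes:
            for e in g.spec.planted_elements:
                fh.write(
                    f"{g.spec.gene_id}\t{e.kind}\t{e.position}\t{e.stem_length}\t"
                    f"{e.loop_length}\t{e.composition}\n"
                )
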
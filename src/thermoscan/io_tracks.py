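"""File formats and transcript↔genome coordinate mapping.

Internal coordinates are 0-based half-open throughout the package; every
file written here uses 1-based inclusive coordinates (GFF3/wig/CT
convention).  Readers exist for every format this module writes that the
pipeline needs back (scan TSV lives in :mod:`thermoscan.scanner`).

The "bp" arc dialect (there is no formal standard) is pinned as:

    color:<TAB>r,g,b<TAB>label          (one line per z-score color class)
    chrom<TAB>i<TAB>i<TAB>j<TAB>j<TAB>color_index<TAB>mean_z

with 1-based inclusive single-nucleotide anchors and color classes,
matching the z bins used for browser arcs: z >= 0 gray, z < 0 yellow,
z <= -1 green, z <= -2 blue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .structure import find_crossings, pairs_to_dbn, validate_pairs

__all__ = [
    "GeneModel",
    "Feature",
    "read_fasta",
    "read_gene_model",
    "to_genome",
    "label_region",
    "write_wig",
    "write_bp_track",
    "write_dbn",
    "write_ct",
    "read_ct",
    "write_stockholm",
]


@dataclass(frozen=True)
class Feature:
    type: str  # exon | intron | 5'UTR | 3'UTR | CDS
    start: int  # transcript coordinates, 0-based half-open
    end: int
    isoform_id: str


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    genomic_start: int  # 0-based
    strand: str  # '+' or '-'
    length: int
    features: Tuple[Feature, ...] = ()

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for f in self.features:
            if not (0 <= f.start < f.end <= self.length):
                raise ValueError(f"feature {f} outside [0, {self.length})")

    @classmethod
    def identity(cls, gene_id: str, length: int) -> "GeneModel":
        """Placeholder model when no GFF3 is available: the transcript is
        its own '+'-strand contig starting at 0."""
        return cls(gene_id=gene_id, chromosome=gene_id, genomic_start=0,
                   strand="+", length=length)


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------


def read_fasta(path) -> List[Tuple[str, str]]:
    """All records of a FASTA file as (id, uppercased sequence).

    The raw alphabet is kept (T is mapped to U only at fold time)."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def _to_local(g_start: int, g_end: int, gene_start: int, gene_end: int, strand: str):
    """Genomic (0-based half-open) interval -> transcript-oriented local
    interval within the gene span."""
    if strand == "+":
        return g_start - gene_start, g_end - gene_start
    return gene_end - g_end, gene_end - g_start


def read_gene_model(gff3_path, gene_id: str) -> GeneModel:
    """Build a :class:`GeneModel` from a GFF3 file.

    Transcript coordinates run 5'->3' along the gene's genomic span
    (introns included, since scans run on the unspliced gene sequence);
    introns are derived per isoform as gaps between exons."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    try:
        gene = db[gene_id]
    except gffutils.FeatureNotFoundError:
        raise ValueError(f"{gff3_path}: gene {gene_id!r} not found") from None
    gene_start = gene.start - 1  # GFF3 is 1-based inclusive
    gene_end = gene.end
    strand = gene.strand
    length = gene_end - gene_start
    type_map = {
        "exon": "exon",
        "five_prime_UTR": "5'UTR",
        "three_prime_UTR": "3'UTR",
        "CDS": "CDS",
    }
    features: List[Feature] = []
    for mrna in db.children(gene, featuretype=("mRNA", "transcript")):
        iso = mrna.id
        exons = []
        for child in db.children(mrna):
            ftype = type_map.get(child.featuretype)
            if ftype is None:
                continue
            s, e = _to_local(child.start - 1, child.end, gene_start, gene_end, strand)
            features.append(Feature(ftype, s, e, iso))
            if ftype == "exon":
                exons.append((s, e))
        exons.sort()
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{gff3_path}: isoform {iso}: exons [{s1},{e1}) and [{s2},{e2}) overlap"
                )
            if s2 > e1:
                features.append(Feature("intron", e1, s2, iso))
    features.sort(key=lambda f: (f.isoform_id, f.start, f.end, f.type))
    return GeneModel(
        gene_id=gene_id,
        chromosome=gene.seqid,
        genomic_start=gene_start,
        strand=strand,
        length=length,
        features=tuple(features),
    )


def to_genome(pos: int, model: GeneModel) -> Tuple[str, int]:
    """Transcript position -> (chromosome, 0-based genomic position)."""
    if not (0 <= pos < model.length):
        raise ValueError(f"position {pos} outside transcript [0, {model.length})")
    if model.strand == "+":
        return model.chromosome, model.genomic_start + pos
    return model.chromosome, model.genomic_start + model.length - 1 - pos


def from_genome(genomic_pos: int, model: GeneModel) -> int:
    """Inverse of :func:`to_genome` (same chromosome assumed)."""
    if model.strand == "+":
        pos = genomic_pos - model.genomic_start
    else:
        pos = model.genomic_start + model.length - 1 - genomic_pos
    if not (0 <= pos < model.length):
        raise ValueError(f"genomic position {genomic_pos} outside the gene span")
    return pos


def pair_to_genome(pair: Tuple[int, int], model: GeneModel) -> Tuple[int, int]:
    """Map both endpoints and reorder so the smaller genomic coordinate
    comes first."""
    _, a = to_genome(pair[0], model)
    _, b = to_genome(pair[1], model)
    return (a, b) if a < b else (b, a)


def label_region(model: GeneModel, start: int, end: int) -> Optional[str]:
    """Feature types overlapping [start, end) across all isoforms, joined
    5'->3' (e.g. "5'UTR/intron" for a junction-spanning region)."""
    hits = []
    for f in model.features:
        if f.type == "CDS":
            continue
        if f.start < end and start < f.end and f.type not in hits:
            hits.append(f.type)
    return "/".join(hits) if hits else None


# ---------------------------------------------------------------------------
# wig / bp tracks
# ---------------------------------------------------------------------------


def write_wig(
    values: Mapping[int, float],
    model: GeneModel,
    track_name: str,
    path,
    metadata: Optional[dict] = None,
) -> None:
    """fixedStep wig of a per-window metric keyed by window start.

    Values are anchored at the window START position, mapped to genomic
    coordinates; minus-strand genes are emitted in ascending genomic
    order.  A gap in the transcript-position stream opens a new fixedStep
    block."""
    if not values:
        raise ValueError("no values to write")
    genomic = sorted(
        (to_genome(s, model)[1], v) for s, v in values.items()
    )
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{track_name}"\n')
        for key, val in (metadata or {}).items():
            fh.write(f"# {key} = {val}\n")
        prev = None
        for gpos, v in genomic:
            if prev is None or gpos != prev + 1:
                fh.write(f"fixedStep chrom={model.chromosome} start={gpos + 1} step=1\n")
            fh.write(format(v, ".6g") + "\n")
            prev = gpos


_BP_CLASSES = [
    # (label, rgb); index in this list is the color index in data rows
    ("z>=0", "128,128,128"),   # gray
    ("z<0", "255,210,0"),      # yellow
    ("z<=-1", "46,139,87"),    # green
    ("z<=-2", "30,60,255"),    # blue
]


def z_color_index(z: float) -> int:
    if z <= -2:
        return 3
    if z <= -1:
        return 2
    if z < 0:
        return 1
    return 0


def write_bp_track(
    pairs_mean_z: Mapping[Tuple[int, int], float],
    model: GeneModel,
    path,
    metadata: Optional[dict] = None,
) -> None:
    """Browser arc track of base pairs colored by mean z bin."""
    with open(path, "w") as fh:
        for label, rgb in _BP_CLASSES:
            fh.write(f"color:\t{rgb}\t{label}\n")
        for key, val in (metadata or {}).items():
            fh.write(f"# {key} = {val}\n")
        rows = []
        for pair, z in pairs_mean_z.items():
            a, b = pair_to_genome(pair, model)
            rows.append((a, b, z_color_index(z), z))
        for a, b, ci, z in sorted(rows):
            fh.write(
                f"{model.chromosome}\t{a + 1}\t{a + 1}\t{b + 1}\t{b + 1}\t{ci}\t{z:.4f}\n"
            )


def read_bp_track(path):
    """Rows of a bp arc file as (chrom, i, j, color_index, z) with 0-based
    endpoint positions."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("color:", "#")) or not line.strip():
                continue
            chrom, a, _a2, b, _b2, ci, z = line.rstrip("\n").split("\t")
            rows.append((chrom, int(a) - 1, int(b) - 1, int(ci), float(z)))
    return rows


# ---------------------------------------------------------------------------
# dbn / CT / Stockholm
# ---------------------------------------------------------------------------


def write_dbn(sequence: str, pairs: Iterable[Tuple[int, int]], path, header: str = "structure") -> None:
    dbn = pairs_to_dbn(set(map(tuple, pairs)), len(sequence))
    with open(path, "w") as fh:
        fh.write(f">{header}\n{sequence}\n{dbn}\n")


def write_ct(sequence: str, pairs: Iterable[Tuple[int, int]], path, title: str = "structure") -> None:
    """Standard 6-column connectivity table, 1-based."""
    pairs = set(map(tuple, pairs))
    validate_pairs(pairs, len(sequence))
    if find_crossings(pairs):
        raise ValueError("crossing pairs cannot be written to CT; resolve first")
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    n = len(sequence)
    with open(path, "w") as fh:
        fh.write(f"{n}\t{title}\n")
        for i in range(n):
            fh.write(
                f"{i + 1}\t{sequence[i]}\t{i}\t{(i + 2) if i + 1 < n else 0}\t"
                f"{partner.get(i, -1) + 1}\t{i + 1}\n"
            )


def read_ct(path):
    """Returns (sequence, pairs).  Verifies index consistency and pairing
    symmetry."""
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty CT file")
        n = int(header.split()[0])
        chars = []
        pairs = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 CT columns")
            idx = int(fields[0])
            if idx != len(chars) + 1:
                raise ValueError(f"{path}: line {lineno}: index {idx} out of order")
            chars.append(fields[1])
            partner = int(fields[4])
            if partner > 0:
                pairs.add((min(idx, partner) - 1, max(idx, partner) - 1))
    if len(chars) != n:
        raise ValueError(f"{path}: header promises {n} bases, found {len(chars)}")
    for i, j in pairs:
        if j >= n:
            raise ValueError(f"{path}: pair ({i + 1}, {j + 1}) outside sequence")
    return "".join(chars), frozenset(pairs)


def write_stockholm(
    sequences: List[Tuple[str, str]],
    ss_cons: str,
    path,
) -> None:
    """Minimal Stockholm 1.0 alignment with a consensus structure line."""
    if not sequences:
        raise ValueError("empty alignment")
    lengths = {len(s) for _, s in sequences}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must all have the same length")
    (length,) = lengths
    if len(ss_cons) != length:
        raise ValueError("SS_cons length must equal the alignment length")
    aln = MultipleSeqAlignment(
        [SeqRecord(Seq(s), id=name, description="") for name, s in sequences]
    )
    aln.column_annotations["secondary_structure"] = ss_cons
    AlignIO.write(aln, str(path), "stockholm")
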
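"""z-weighted consensus pairing across overlapping scan windows.

Every window's MFE structure votes for its base pairs in transcript
coordinates; each pair accumulates the z-scores of the windows that
predicted it.  Competition between mutually exclusive pairs is resolved by
mutual-best selection on mean z (most negative wins), so the consensus is
biased toward sequence-ordered stability.  Threshold filtering and motif
extraction then recover the contiguous low-z structured regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Tuple

from .scanner import WindowRecord
from .structure import pairs_to_dbn, resolve_crossings

__all__ = [
    "PairEvidence",
    "ConsensusModel",
    "Motif",
    "accumulate_pair_evidence",
    "resolve_competition",
    "filter_by_threshold",
    "extract_motifs",
    "trim_motif",
]

Pair = Tuple[int, int]


@dataclass
class PairEvidence:
    """Windows' z-score votes for one transcript-coordinate base pair."""

    i: int
    j: int
    z_values: List[float] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.z_values)

    @property
    def mean_z(self) -> float:
        return sum(self.z_values) / len(self.z_values)

    @property
    def min_z(self) -> float:
        return min(self.z_values)


@dataclass(frozen=True)
class ConsensusModel:
    """Per-position pairing partners with per-pair z statistics."""

    length: int
    partner: Tuple[int, ...]  # -1 = unpaired
    pair_mean_z: Dict[Pair, float]
    pair_min_z: Dict[Pair, float]
    provenance: Dict[Pair, int]  # pair -> number of supporting windows

    @property
    def pairs(self) -> FrozenSet[Pair]:
        return frozenset(
            (i, j) for i, j in enumerate(self.partner) if j >= 0 and i < j
        )


@dataclass(frozen=True)
class Motif:
    """A contiguous structured region extracted from the consensus."""

    start: int
    end: int  # half-open
    dbn: str
    pairs: Dict[Pair, float]  # pair (transcript coords) -> mean z
    min_window_z: float
    region_label: Optional[str] = None

    @property
    def mean_z(self) -> float:
        return sum(self.pairs.values()) / len(self.pairs)


def accumulate_pair_evidence(records: List[WindowRecord]) -> Dict[Pair, PairEvidence]:
    """Map each window's MFE pairs to transcript coordinates and collect
    the window z-scores supporting each pair."""
    evidence: Dict[Pair, PairEvidence] = {}
    for rec in records:
        if rec.z_score is None:
            raise ValueError(
                "consensus requires a full scan with a shuffled null "
                "(scan-only records carry no z-scores)"
            )
        for li, lj in rec.mfe_pairs:
            key = (rec.start + li, rec.start + lj)
            ev = evidence.get(key)
            if ev is None:
                evidence[key] = ev = PairEvidence(*key)
            ev.z_values.append(rec.z_score)
    return evidence


def resolve_competition(evidence: Dict[Pair, PairEvidence], length: int) -> ConsensusModel:
    """Mutual-best selection: each position prefers its lowest-mean-z
    candidate pair; a pair enters the consensus only if both endpoints
    prefer it.  Ties break by higher count, then smaller span, then
    smaller i."""
    by_position: Dict[int, List[PairEvidence]] = {}
    for ev in evidence.values():
        by_position.setdefault(ev.i, []).append(ev)
        by_position.setdefault(ev.j, []).append(ev)

    def rank(ev: PairEvidence):
        return (ev.mean_z, -ev.count, ev.j - ev.i, ev.i)

    best: Dict[int, Pair] = {}
    for pos, cands in by_position.items():
        winner = min(cands, key=rank)
        best[pos] = (winner.i, winner.j)
    partner = [-1] * length
    pair_mean_z: Dict[Pair, float] = {}
    pair_min_z: Dict[Pair, float] = {}
    provenance: Dict[Pair, int] = {}
    for (i, j), ev in evidence.items():
        if best.get(i) == (i, j) and best.get(j) == (i, j):
            partner[i] = j
            partner[j] = i
            pair_mean_z[(i, j)] = ev.mean_z
            pair_min_z[(i, j)] = ev.min_z
            provenance[(i, j)] = ev.count
    return ConsensusModel(
        length=length,
        partner=tuple(partner),
        pair_mean_z=pair_mean_z,
        pair_min_z=pair_min_z,
        provenance=provenance,
    )


def filter_by_threshold(model: ConsensusModel, threshold: Optional[float]) -> FrozenSet[Pair]:
    """Consensus pairs with mean z <= threshold; ``None`` keeps all."""
    if threshold is None:
        return model.pairs
    return frozenset(p for p in model.pairs if model.pair_mean_z[p] <= threshold)


def _nested_subset(pairs: Dict[Pair, float]) -> Dict[Pair, float]:
    """Drop crossing pairs, lowest |mean z| first (i.e. keep the
    strongest-evidence pairs)."""
    kept, _dropped = resolve_crossings(pairs, lambda p: abs(pairs[tuple(p)]))
    return {p: pairs[p] for p in sorted(kept)}


def extract_motifs(
    model: ConsensusModel,
    threshold: Optional[float],
    min_gap: int = 10,
) -> List[Motif]:
    """Group threshold-surviving pairs into disjoint motifs.

    Two pairs share a motif when their spans overlap or are separated by
    fewer than ``min_gap`` nucleotides.  Motifs are returned 5'->3'; each
    reports its coordinate hull, a nested dot-bracket, and the lowest
    contributing window z."""
    surviving = sorted(filter_by_threshold(model, threshold))
    if not surviving:
        return []
    groups: List[List[Pair]] = [[surviving[0]]]
    cur_end = surviving[0][1]
    for p in surviving[1:]:
        if p[0] <= cur_end + min_gap:
            groups[-1].append(p)
        else:
            groups.append([p])
        cur_end = max(cur_end, p[1])
    motifs = []
    for grp in groups:
        start = min(i for i, _ in grp)
        end = max(j for _, j in grp) + 1
        pair_z = _nested_subset({p: model.pair_mean_z[p] for p in grp})
        local = {(i - start, j - start) for i, j in pair_z}
        motifs.append(
            Motif(
                start=start,
                end=end,
                dbn=pairs_to_dbn(local, end - start),
                pairs=pair_z,
                min_window_z=min(model.pair_min_z[p] for p in pair_z),
            )
        )
    return motifs


def trim_motif(motif: Motif) -> Motif:
    """Remove unpaired nucleotides from the 5' and 3' ends (idempotent)."""
    if not motif.pairs:
        raise ValueError("cannot trim a motif with no pairs")
    new_start = min(i for i, _ in motif.pairs)
    new_end = max(j for _, j in motif.pairs) + 1
    if new_start == motif.start and new_end == motif.end:
        return motif
    local = {(i - new_start, j - new_start) for i, j in motif.pairs}
    return replace(
        motif,
        start=new_start,
        end=new_end,
        dbn=pairs_to_dbn(local, new_end - new_start),
    )


def write_motif_txt(
    motifs: List[Motif],
    sequence: str,
    gene_id: str,
    path,
) -> None:
    """Motif text export: per motif a header line (gene id, 1-based
    inclusive coordinates, min window z, mean pair z), the motif sequence,
    and its dot-bracket."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(
                f">{gene_id}\t{m.start + 1}\t{m.end}\t"
                f"min_window_z={m.min_window_z:.4f}\tmean_z={m.mean_z:.4f}"
                + (f"\tregion={m.region_label}" if m.region_label else "")
                + "\n"
            )
            fh.write(sequence[m.start:m.end] + "\n")
            fh.write(m.dbn + "\n")
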
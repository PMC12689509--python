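"""Sliding-window scan with a shuffled-sequence thermodynamic null.

A full scan folds every window, shuffles each window's sequence
``num_shuffles`` times (mononucleotide shuffling preserves composition
exactly), refolds the shuffles, and reports the thermodynamic z-score
z = (MFE_native − mean MFE_shuffled) / sd(MFE_shuffled).  Scan-only runs
(``compute_null=False``) skip the shuffle/refold step and report only the
per-window thermodynamic metrics — this is the mode used for the two
temperatures of the ΔED screen.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .fold_backend import normalize_rna

__all__ = [
    "ScanConfig",
    "WindowRecord",
    "window_iter",
    "mononucleotide_shuffle",
    "z_score",
    "scan",
    "write_scan_tsv",
    "read_scan_tsv",
]

FLAG_SHORT = "short"
FLAG_DEGENERATE_NULL = "degenerate_null"


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters; defaults mirror a standard full run
    (120-nt window, 1-nt step, 100 mononucleotide shuffles)."""

    window_size: int = 120
    step: int = 1
    num_shuffles: int = 100
    temperature_celsius: float = 37.0
    seed: int = 1
    compute_null: bool = True

    def __post_init__(self):
        if self.window_size < 10:
            raise ValueError("window_size must be >= 10")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.num_shuffles < 0:
            raise ValueError("num_shuffles must be >= 0")
        if self.compute_null and self.num_shuffles < 2:
            raise ValueError("compute_null requires num_shuffles >= 2 (sd needs >= 2 values)")


@dataclass(frozen=True)
class WindowRecord:
    """Per-window metrics; ``start``/``end`` are 0-based half-open
    transcript coordinates, pairs are window-local."""

    start: int
    end: int
    sequence: str
    mfe_kcal_mol: float
    ensemble_diversity: float
    centroid_dbn: str
    mfe_pairs: FrozenSet[Tuple[int, int]]
    gc_fraction: float
    shuffled_mean: Optional[float] = None
    shuffled_sd: Optional[float] = None
    z_score: Optional[float] = None
    p_value: Optional[float] = None
    flags: Tuple[str, ...] = ()

    @property
    def has_null(self) -> bool:
        return self.z_score is not None


def window_iter(sequence_length: int, window_size: int, step: int) -> List[Tuple[int, int]]:
    """Window coordinates [k*step, k*step + window_size) with end <=
    sequence_length; a sequence shorter than the window yields one
    whole-sequence window (flagged short by :func:`scan`)."""
    if sequence_length < 1:
        raise ValueError("sequence_length must be >= 1")
    if sequence_length < window_size:
        return [(0, sequence_length)]
    return [
        (s, s + window_size)
        for s in range(0, sequence_length - window_size + 1, step)
    ]


def mononucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Uniform random permutation of the sequence's characters."""
    arr = np.frombuffer(sequence.encode(), dtype="S1")
    return b"".join(rng.permutation(arr)).decode()


def z_score(native_mfe: float, shuffled_mfes: Sequence[float]) -> float:
    """(native − mean) / sample sd of the shuffled MFEs; 0.0 when the null
    is degenerate (sd = 0) — callers flag that window."""
    if len(shuffled_mfes) < 2:
        raise ValueError("z-score needs >= 2 shuffled MFE values")
    mean = statistics.fmean(shuffled_mfes)
    sd = statistics.stdev(shuffled_mfes)
    if sd == 0.0:
        return 0.0
    return (native_mfe - mean) / sd


def _window_rng(master_seed: int, window_start: int) -> np.random.Generator:
    # substream keyed by (seed, window start): results do not depend on
    # evaluation order or parallel scheduling
    return np.random.default_rng([int(master_seed), int(window_start)])


def scan(sequence: str, config: ScanConfig, backend) -> List[WindowRecord]:
    """Fold every window of ``sequence``; with ``config.compute_null``,
    also build the shuffled-MFE null and z-score per window."""
    seq = normalize_rna(sequence)
    records: List[WindowRecord] = []
    for start, end in window_iter(len(seq), config.window_size, config.step):
        wseq = seq[start:end]
        flags: list[str] = []
        if end - start < config.window_size:
            flags.append(FLAG_SHORT)
        try:
            fr = backend.fold(wseq, config.temperature_celsius)
        except Exception as exc:  # attach window coordinates for debugging
            raise RuntimeError(f"folding failed in window [{start}, {end}): {exc}") from exc
        gc = (wseq.count("G") + wseq.count("C")) / len(wseq)
        rec = WindowRecord(
            start=start,
            end=end,
            sequence=wseq,
            mfe_kcal_mol=fr.mfe_kcal_mol,
            ensemble_diversity=fr.ensemble_diversity,
            centroid_dbn=fr.centroid_dbn,
            mfe_pairs=fr.mfe_pairs,
            gc_fraction=gc,
        )
        if config.compute_null:
            rng = _window_rng(config.seed, start)
            shuffled = [
                backend.mfe(mononucleotide_shuffle(wseq, rng), config.temperature_celsius)
                for _ in range(config.num_shuffles)
            ]
            mean = statistics.fmean(shuffled)
            sd = statistics.stdev(shuffled)
            z = z_score(fr.mfe_kcal_mol, shuffled)
            if sd == 0.0:
                flags.append(FLAG_DEGENERATE_NULL)
            p = sum(1 for m in shuffled if m <= fr.mfe_kcal_mol) / len(shuffled)
            rec = replace(
                rec,
                shuffled_mean=mean,
                shuffled_sd=sd,
                z_score=z,
                p_value=p,
            )
        records.append(replace(rec, flags=tuple(flags)))
    return records


# ---------------------------------------------------------------------------
# TSV serialization (1-based inclusive coordinates in files)
# ---------------------------------------------------------------------------

_COLUMNS = [
    "start",
    "end",
    "sequence",
    "mfe_kcal_mol",
    "delta_g_kcal_mol",  # synonym of the windowed MFE
    "shuffled_mean",
    "shuffled_sd",
    "z_score",
    "p_value",
    "ensemble_diversity",
    "centroid_dbn",
    "mfe_pairs",
    "gc_fraction",
    "flags",
]

_NA = "NA"


def _fmt(x: Optional[float]) -> str:
    return _NA if x is None else format(float(x), ".12g")


def _fmt_pairs(pairs: FrozenSet[Tuple[int, int]]) -> str:
    if not pairs:
        return "."
    return ";".join(f"{i + 1}-{j + 1}" for i, j in sorted(pairs))


def _parse_pairs(text: str) -> FrozenSet[Tuple[int, int]]:
    if text == ".":
        return frozenset()
    out = set()
    for tok in text.split(";"):
        i, j = tok.split("-")
        out.add((int(i) - 1, int(j) - 1))
    return frozenset(out)


def write_scan_tsv(records: List[WindowRecord], path, metadata: Optional[dict] = None) -> None:
    """One row per window, tab-separated, with '#' metadata comment lines.
    File coordinates are 1-based inclusive."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key} = {value}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in records:
            row = [
                str(r.start + 1),
                str(r.end),  # half-open end == 1-based inclusive end
                r.sequence,
                _fmt(r.mfe_kcal_mol),
                _fmt(r.mfe_kcal_mol),
                _fmt(r.shuffled_mean),
                _fmt(r.shuffled_sd),
                _fmt(r.z_score),
                _fmt(r.p_value),
                _fmt(r.ensemble_diversity),
                r.centroid_dbn,
                _fmt_pairs(r.mfe_pairs),
                _fmt(r.gc_fraction),
                ";".join(r.flags) if r.flags else ".",
            ]
            fh.write("\t".join(row) + "\n")


def read_scan_tsv(path):
    """Inverse of :func:`write_scan_tsv`.

    Returns ``(records, metadata)``.  Column order in the file is not
    assumed — the header row is authoritative.
    """
    metadata: dict = {}
    records: List[WindowRecord] = []
    header: Optional[list] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    k, v = body.split("=", 1)
                    metadata[k.strip()] = v.strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = set(_COLUMNS) - set(header)
                if missing:
                    raise ValueError(
                        f"{path}: malformed header on line {lineno}: missing columns {sorted(missing)}"
                    )
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header)} columns, found {len(fields)}"
                )
            d = dict(zip(header, fields))

            def opt(key):
                return None if d[key] == _NA else float(d[key])

            flags = tuple(d["flags"].split(";")) if d["flags"] != "." else ()
            records.append(
                WindowRecord(
                    start=int(d["start"]) - 1,
                    end=int(d["end"]),
                    sequence=d["sequence"],
                    mfe_kcal_mol=float(d["mfe_kcal_mol"]),
                    ensemble_diversity=float(d["ensemble_diversity"]),
                    centroid_dbn=d["centroid_dbn"],
                    mfe_pairs=_parse_pairs(d["mfe_pairs"]),
                    gc_fraction=float(d["gc_fraction"]),
                    shuffled_mean=opt("shuffled_mean"),
                    shuffled_sd=opt("shuffled_sd"),
                    z_score=opt("z_score"),
                    p_value=opt("p_value"),
                    flags=flags,
                )
            )
    if header is None:
        raise ValueError(f"{path}: no header row found")
    return records, metadata
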
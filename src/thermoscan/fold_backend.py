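"""Folding backends: a uniform single-sequence folding contract.

Two engines satisfy the contract:

* :class:`ViennaRNABackend` — the production engine, delegating to the
  ViennaRNA partition-function machinery at a caller-chosen temperature.
* :class:`ToyBackend` — a minimal additive per-pair energy model solved
  exactly by dynamic programming, paired with
  :func:`enumerate_structures` / :func:`ensemble_from_enumeration`, an
  exhaustive-enumeration oracle used to verify the dynamic path in tests
  and to keep statistical calibration suites fast and engine-independent.

All energies are kcal/mol; temperatures are degrees Celsius; ensemble
diversity (ED) is the expected base-pair distance between two structures
drawn independently from the Boltzmann ensemble, ED = sum over pairs of
2*p*(1-p).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Tuple

import numpy as np

from . import _kernels
from .structure import base_pair_distance, pairs_to_dbn, resolve_crossings

__all__ = [
    "GAS_CONSTANT_KCAL",
    "FoldResult",
    "ToyEnergyParams",
    "ToyBackend",
    "ViennaRNABackend",
    "fold",
    "enumerate_structures",
    "ensemble_from_enumeration",
    "base_pair_distance",
    "normalize_rna",
]

#: Gas constant in kcal mol^-1 K^-1; RT = GAS_CONSTANT_KCAL * (T_celsius + 273.15).
GAS_CONSTANT_KCAL = 0.0019872

# IUPAC nucleotide codes; T is read as U, lowercase accepted.  Ambiguity
# codes and N are carried through but never pair under the toy model.
_IUPAC = set("ACGUTNRYSWKMBDHV")

_ENCODE = {"A": 0, "C": 1, "G": 2, "U": 3}

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def normalize_rna(sequence: str) -> str:
    """Uppercase, map T to U, and validate against the IUPAC alphabet."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper().replace("T", "U")
    for ch in seq:
        if ch not in _IUPAC:
            raise ValueError(f"invalid nucleotide character {ch!r}")
    return seq


def _encode(seq: str) -> np.ndarray:
    return np.array([_ENCODE.get(c, 4) for c in seq], dtype=np.int64)


def rt_kcal(temperature_celsius: float) -> float:
    return GAS_CONSTANT_KCAL * (temperature_celsius + 273.15)


@dataclass(frozen=True)
class FoldResult:
    """Thermodynamic folding summary for one sequence at one temperature."""

    sequence: str
    temperature_celsius: float
    mfe_kcal_mol: float
    mfe_pairs: FrozenSet[Tuple[int, int]]
    pair_probabilities: Dict[Tuple[int, int], float]
    ensemble_diversity: float
    centroid_pairs: FrozenSet[Tuple[int, int]]
    centroid_dbn: str


@dataclass(frozen=True)
class ToyEnergyParams:
    """Additive per-pair energies (kcal/mol) with a minimum hairpin loop.

    Defaults: GC/CG -3.0, AU/UA -2.0, GU/UG -1.0, min_loop 3.
    """

    gc: float = -3.0
    au: float = -2.0
    gu: float = -1.0
    min_loop: int = 3

    def __post_init__(self):
        if any(e > 0 for e in (self.gc, self.au, self.gu)):
            raise ValueError("pair energies must be <= 0")
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")

    def energy_matrix(self) -> np.ndarray:
        m = np.full((5, 5), np.inf)
        a, c, g, u = 0, 1, 2, 3
        m[g, c] = m[c, g] = self.gc
        m[a, u] = m[u, a] = self.au
        m[g, u] = m[u, g] = self.gu
        return m

    def pair_energy(self, a: str, b: str) -> float:
        m = self.energy_matrix()
        return m[_ENCODE.get(a, 4), _ENCODE.get(b, 4)]


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle
# ---------------------------------------------------------------------------

_ENUM_GUARD = 18


def enumerate_structures(
    sequence: str,
    params: ToyEnergyParams | None = None,
    max_length: int = _ENUM_GUARD,
) -> List[Tuple[FrozenSet[Tuple[int, int]], float]]:
    """All nested structures of ``sequence`` with their toy-model energies.

    Includes the empty structure.  Refuses sequences longer than
    ``max_length`` — enumeration is exponential and meant for oracles only.
    """
    params = params or ToyEnergyParams()
    seq = normalize_rna(sequence)
    n = len(seq)
    if n > max_length:
        raise ValueError(
            f"enumeration limited to length {max_length} (got {n}); "
            "use a dynamic-programming backend for longer sequences"
        )
    emat = params.energy_matrix()
    enc = _encode(seq)
    candidates = [
        (i, j)
        for i in range(n)
        for j in range(i + params.min_loop + 1, n)
        if np.isfinite(emat[enc[i], enc[j]])
    ]

    results: List[Tuple[FrozenSet[Tuple[int, int]], float]] = []

    def extend(chosen: list, start: int) -> None:
        results.append(
            (
                frozenset(chosen),
                float(sum(emat[enc[i], enc[j]] for i, j in chosen)),
            )
        )
        for idx in range(start, len(candidates)):
            i, j = candidates[idx]
            ok = True
            for a, b in chosen:
                # nested: disjoint occupancy and no crossing
                if len({i, j} & {a, b}) > 0 or (a < i < b < j) or (i < a < j < b):
                    ok = False
                    break
            if ok:
                chosen.append((i, j))
                extend(chosen, idx + 1)
                chosen.pop()

    extend([], 0)
    return results


def ensemble_from_enumeration(
    structures: List[Tuple[FrozenSet[Tuple[int, int]], float]],
    temperature_celsius: float,
):
    """Boltzmann ensemble statistics from an explicit structure list.

    Returns ``(pair_probabilities, ensemble_diversity, centroid_pairs)``
    with weights w(S) ∝ exp(-E(S)/RT), p(i,j) the marginal pair
    probability, ED = Σ 2 p (1-p), and centroid = {(i,j): p > 0.5}.
    """
    if not structures:
        raise ValueError("empty structure list")
    rt = rt_kcal(temperature_celsius)
    energies = np.array([e for _, e in structures])
    w = np.exp(-(energies - energies.min()) / rt)
    w /= w.sum()
    probs: Dict[Tuple[int, int], float] = {}
    for (pairs, _), wt in zip(structures, w):
        for p in pairs:
            probs[p] = probs.get(p, 0.0) + wt
    ed = float(sum(2.0 * p * (1.0 - p) for p in probs.values()))
    centroid = frozenset(p for p, v in probs.items() if v > 0.5)
    return probs, ed, centroid


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------


def _partner_to_pairs(partner: np.ndarray) -> FrozenSet[Tuple[int, int]]:
    return frozenset(
        (int(i), int(j)) for i, j in enumerate(partner) if j >= 0 and i < j
    )


def _centroid_dbn(centroid: set, probs: Dict[Tuple[int, int], float], n: int):
    """Dot-bracket for the centroid; crossing pairs (possible in principle
    for a >0.5 threshold only in degenerate models) are dropped lowest
    probability first."""
    kept, dropped = resolve_crossings(centroid, lambda p: probs.get(tuple(p), 0.0))
    return pairs_to_dbn(kept, n), frozenset(map(tuple, kept)), dropped


@dataclass(frozen=True)
class ToyBackend:
    """Exact dynamic programming under :class:`ToyEnergyParams`.

    Same recursion structure as the enumeration oracle (each nested
    structure counted exactly once), so the two agree to rounding error.
    """

    params: ToyEnergyParams = field(default_factory=ToyEnergyParams)
    name: str = "toy"

    @property
    def version(self) -> str:
        return "1"

    @property
    def settings(self) -> dict:
        return {
            "pair_energies": {"GC": self.params.gc, "AU": self.params.au, "GU": self.params.gu},
            "min_loop": self.params.min_loop,
        }

    def mfe(self, sequence: str, temperature_celsius: float) -> float:
        seq = normalize_rna(sequence)
        enc = _encode(seq)
        W = _kernels.mfe_fill(enc, self.params.energy_matrix(), self.params.min_loop)
        return float(W[0, len(seq)])

    def fold(self, sequence: str, temperature_celsius: float) -> FoldResult:
        _check_temperature(temperature_celsius)
        seq = normalize_rna(sequence)
        enc = _encode(seq)
        emat = self.params.energy_matrix()
        ml = self.params.min_loop
        n = len(seq)
        W = _kernels.mfe_fill(enc, emat, ml)
        partner = _kernels.mfe_traceback(enc, emat, ml, W)
        rt = rt_kcal(temperature_celsius)
        Q = _kernels.pf_fill(enc, emat, ml, rt)
        P = _kernels.pair_probabilities(enc, emat, ml, rt, Q)
        probs = {
            (int(i), int(j)): float(P[i, j])
            for i, j in zip(*np.nonzero(P > 1e-12))
        }
        ed = float(np.sum(2.0 * P * (1.0 - P)))
        centroid = {p for p, v in probs.items() if v > 0.5}
        dbn, centroid_kept, _ = _centroid_dbn(centroid, probs, n)
        return FoldResult(
            sequence=seq,
            temperature_celsius=float(temperature_celsius),
            mfe_kcal_mol=float(W[0, n]),
            mfe_pairs=_partner_to_pairs(partner),
            pair_probabilities=probs,
            ensemble_diversity=ed,
            centroid_pairs=centroid_kept,
            centroid_dbn=dbn,
        )


class ViennaRNABackend:
    """ViennaRNA nearest-neighbor engine at a set temperature.

    MFE and structure come from the minimum-free-energy fold; pair
    probabilities, centroid, and ensemble diversity from the partition
    function.  ED is the engine's own mean base-pair distance of the
    Boltzmann ensemble.
    """

    name = "ViennaRNA"

    def __init__(self):
        import RNA  # deferred so the toy backend works without the bindings

        self._RNA = RNA

    @property
    def version(self) -> str:
        return self._RNA.__version__

    @property
    def settings(self) -> dict:
        return {"dangles": 2, "noLP": 0, "parameters": "default Turner"}

    def _compound(self, seq: str, temperature_celsius: float):
        md = self._RNA.md()
        md.temperature = float(temperature_celsius)
        return self._RNA.fold_compound(seq, md)

    def mfe(self, sequence: str, temperature_celsius: float) -> float:
        _check_temperature(temperature_celsius)
        seq = normalize_rna(sequence)
        fc = self._compound(seq, temperature_celsius)
        _, e = fc.mfe()
        return float(e)

    def fold(self, sequence: str, temperature_celsius: float) -> FoldResult:
        _check_temperature(temperature_celsius)
        seq = normalize_rna(sequence)
        n = len(seq)
        fc = self._compound(seq, temperature_celsius)
        mfe_dbn, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)
        fc.pf()
        bpp = fc.bpp()  # 1-based upper-triangular matrix
        probs: Dict[Tuple[int, int], float] = {}
        for i in range(1, n + 1):
            row = bpp[i]
            for j in range(i + 1, n + 1):
                p = row[j]
                if p > 1e-9:
                    probs[(i - 1, j - 1)] = float(min(p, 1.0))
        centroid_dbn, _ = fc.centroid()
        from .structure import dbn_to_pairs

        return FoldResult(
            sequence=seq,
            temperature_celsius=float(temperature_celsius),
            mfe_kcal_mol=float(mfe),
            mfe_pairs=dbn_to_pairs(mfe_dbn),
            pair_probabilities=probs,
            ensemble_diversity=float(fc.mean_bp_distance()),
            centroid_pairs=dbn_to_pairs(centroid_dbn),
            centroid_dbn=centroid_dbn,
        )


def _check_temperature(temperature_celsius: float) -> None:
    if not (0.0 <= float(temperature_celsius) <= 100.0):
        raise ValueError(
            f"temperature {temperature_celsius} outside supported range 0-100 degrees C"
        )


def get_backend(name: str):
    """Backend factory: ``"vienna"`` or ``"toy"``."""
    if name.lower() in {"vienna", "viennarna", "rnafold"}:
        return ViennaRNABackend()
    if name.lower() == "toy":
        return ToyBackend()
    raise ValueError(f"unknown folding backend {name!r}")


def fold(sequence: str, temperature_celsius: float, backend=None) -> FoldResult:
    """Fold one sequence at one temperature with the given backend
    (default: ViennaRNA)."""
    backend = backend or ViennaRNABackend()
    return backend.fold(sequence, temperature_celsius)
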
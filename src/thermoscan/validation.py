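"""Self-contained benchmark computations on synthetic inputs.

Each function regenerates its inputs from a seed, runs the relevant part
of the pipeline, and returns summary numbers.  They are shared by the
test suite and by ``scripts/acceptance.py`` so that reported numbers are
always recomputed from scratch.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .consensus import accumulate_pair_evidence, filter_by_threshold, resolve_competition
from .fold_backend import (
    ToyBackend,
    ensemble_from_enumeration,
    enumerate_structures,
    get_backend,
)
from .scanner import ScanConfig, scan
from .synthetic_data import hairpin_pairs, plant_hairpin, random_sequence, thermometer_tandem
from .thermo_diff import one_sample_t_test

__all__ = [
    "oracle_agreement",
    "null_calibration",
    "planted_stem_recovery",
    "t_test_type_one_error",
    "real_engine_delta_ed",
]


def oracle_agreement(seed: int, n_sequences: int = 30) -> Dict[str, float]:
    """Maximum absolute disagreement between the dynamic-programming
    ensemble and exhaustive enumeration over random short sequences."""
    backend = ToyBackend()
    rng = np.random.default_rng(seed)
    worst_ed = 0.0
    worst_p = 0.0
    for _ in range(n_sequences):
        n = int(rng.integers(5, 15))
        seq = "".join(rng.choice(list("ACGU"), n))
        probs, ed, centroid = ensemble_from_enumeration(
            enumerate_structures(seq), 37.0
        )
        fr = backend.fold(seq, 37.0)
        worst_ed = max(worst_ed, abs(ed - fr.ensemble_diversity))
        for k in set(probs) | set(fr.pair_probabilities):
            worst_p = max(
                worst_p,
                abs(probs.get(k, 0.0) - fr.pair_probabilities.get(k, 0.0)),
            )
        if centroid != fr.centroid_pairs:
            worst_p = max(worst_p, 1.0)
    return {"max_ed_error": worst_ed, "max_pair_prob_error": worst_p,
            "n": n_sequences}


def null_calibration(
    seed: int,
    n_sequences: int = 30,
    seq_length: int = 47,
    window: int = 40,
    shuffles: int = 50,
) -> Dict[str, float]:
    """Window z-scores on i.i.d. random sequences: mean and extreme-tail
    fraction (defaults give >= 200 windows)."""
    backend = ToyBackend()
    rng = np.random.default_rng(seed)
    zs = []
    for k in range(n_sequences):
        seq = "".join(rng.choice(list("ACGU"), seq_length))
        cfg = ScanConfig(window_size=window, step=1, num_shuffles=shuffles,
                         seed=seed * 1000 + k)
        zs.extend(r.z_score for r in scan(seq, cfg, backend))
    zs = np.array(zs)
    return {
        "mean_z": float(zs.mean()),
        "fraction_abs_z_gt_3": float(np.mean(np.abs(zs) > 3.0)),
        "n": int(zs.size),
    }


def planted_stem_recovery(seed: int, n_fixtures: int = 20) -> Dict[str, float]:
    """Fraction of planted 12-bp GC-stem pairs recovered in the z <= -1
    consensus across seeded fixtures."""
    backend = ToyBackend()
    found = 0
    total = 0
    for k in range(n_fixtures):
        rng = np.random.default_rng(seed + k)
        seq = random_sequence(200, 0.5, rng=rng)
        seq = plant_hairpin(seq, 80, 12, 4, "GC", rng=rng)
        planted = hairpin_pairs(80, 12, 4)
        records = scan(
            seq,
            ScanConfig(window_size=40, step=1, num_shuffles=50, seed=seed + k),
            backend,
        )
        model = resolve_competition(accumulate_pair_evidence(records), len(seq))
        found += len(planted & filter_by_threshold(model, -1.0))
        total += len(planted)
    return {"recovery_fraction": found / total, "n": n_fixtures}


def _gene_mean_delta_ed(seq: str, backend, window: int, step: int) -> float:
    lo = scan(seq, ScanConfig(window_size=window, step=step, num_shuffles=0,
                              temperature_celsius=28.0, compute_null=False), backend)
    hi = scan(seq, ScanConfig(window_size=window, step=step, num_shuffles=0,
                              temperature_celsius=42.0, compute_null=False), backend)
    return float(np.mean([h.ensemble_diversity - l.ensemble_diversity
                          for l, h in zip(lo, hi)]))


def t_test_type_one_error(
    seed: int,
    n_genes: int = 200,
    gene_length: int = 79,
    n_draws: int = 500,
    family_size: int = 25,
    alpha: float = 0.05,
) -> Dict[str, float]:
    """Rejection rate of the family t-test when families are drawn from a
    null cohort (no thermometer structures)."""
    backend = ToyBackend()
    rng = np.random.default_rng(seed)
    means = np.array([
        _gene_mean_delta_ed("".join(rng.choice(list("ACGU"), gene_length)),
                            backend, 40, 1)
        for _ in range(n_genes)
    ])
    reference = means.mean()
    rejections = 0
    for _ in range(n_draws):
        family = rng.choice(means, size=family_size, replace=True)
        res = one_sample_t_test(family, reference)
        if res.p_value < alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_draws, "n": n_draws,
            "cohort_means": means}


def real_engine_delta_ed(
    seed: int,
    n_sequences: int = 50,
    seq_length: int = 500,
    window: int = 120,
    step: int = 10,
) -> Dict[str, float]:
    """Mean per-window ΔED(42 − 28 C) over random transcripts with the
    production thermodynamic engine."""
    backend = get_backend("vienna")
    rng = np.random.default_rng(seed)
    gene_means = [
        _gene_mean_delta_ed(
            "".join(rng.choice(list("ACGU"), seq_length)), backend, window, step
        )
        for _ in range(n_sequences)
    ]
    gene_means = np.array(gene_means)
    return {
        "mean_delta_ed": float(gene_means.mean()),
        "fraction_genes_positive": float(np.mean(gene_means > 0)),
        "n": n_sequences,
    }
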
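import numpy as np
import pytest

from thermoscan.fold_backend import ToyBackend
from thermoscan.scanner import ScanConfig, scan


@pytest.fixture(scope="session")
def toy_backend():
    return ToyBackend()


def gene_mean_delta_ed(seq, backend, window=40, step=1):
    """Per-gene mean ΔED(42−28) via two scan-only runs."""
    lo = scan(seq, ScanConfig(window_size=window, step=step, num_shuffles=0,
                              temperature_celsius=28.0, compute_null=False), backend)
    hi = scan(seq, ScanConfig(window_size=window, step=step, num_shuffles=0,
                              temperature_celsius=42.0, compute_null=False), backend)
    return float(np.mean([h.ensemble_diversity - l.ensemble_diversity
                          for l, h in zip(lo, hi)]))


@pytest.fixture(scope="session")
def null_cohort_means(toy_backend):
    """Per-gene mean ΔED for 200 independent random 79-nt genes (40 windows
    each at window 40): the null cohort for calibration checks."""
    rng = np.random.default_rng(20240901)
    means = [
        gene_mean_delta_ed("".join(rng.choice(list("ACGU"), 79)), toy_backend)
        for _ in range(200)
    ]
    return np.array(means)
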
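"""Temperature-differential ensemble-diversity (ΔED) screen.

Two scan-only runs of the same gene at a lower and a higher temperature
are aligned window-by-window; ΔED = ED(high) − ED(low), so positive
values mean the window samples a larger structural ensemble when heated
(the melting direction) and negative values mean temperature-induced
gain of order.  Per-gene means feed cohort statistics (mean, sd, median,
quartiles), per-gene standard scores, and a one-sample t-test comparing a
gene family's mean ΔED against a reference (e.g. transcriptome-wide)
mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .scanner import WindowRecord
from .structure import base_pair_distance, dbn_to_pairs

__all__ = [
    "DeltaEDRecord",
    "GeneThermoSummary",
    "PopulationStats",
    "TTestResult",
    "delta_ed",
    "gene_summary",
    "population_stats",
    "standard_score",
    "one_sample_t_test",
    "top_delta_windows",
    "centroid_shift",
]


@dataclass(frozen=True)
class DeltaEDRecord:
    window_start: int
    ed_low: float
    ed_high: float

    @property
    def delta_ed(self) -> float:
        return self.ed_high - self.ed_low


@dataclass(frozen=True)
class GeneThermoSummary:
    gene_id: str
    n_windows: int
    mean_delta_ed: float
    sd_delta_ed: Optional[float]  # None (undefined) for a single window
    max_window: Tuple[int, float]
    min_window: Tuple[int, float]
    n_excluded: int = 0


@dataclass(frozen=True)
class PopulationStats:
    n_genes: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class TTestResult:
    n: int
    family_mean: float
    standard_error: float
    t_statistic: float
    degrees_freedom: int
    p_value: float


def delta_ed(
    scan_low: List[WindowRecord],
    scan_high: List[WindowRecord],
    exclude_flagged: bool = True,
) -> List[DeltaEDRecord]:
    """Per-window ED(high) − ED(low) for two scans of the same sequence.

    Windows are matched strictly by start coordinate; a mismatch in the
    window sets is an error (silent misalignment would fabricate signal).
    Flagged (short/degenerate) windows are excluded by default.
    """

    def usable(recs):
        return {
            r.start: r for r in recs if not (exclude_flagged and r.flags)
        }

    low, high = usable(scan_low), usable(scan_high)
    if set(low) != set(high):
        diff = sorted(set(low) ^ set(high))
        raise ValueError(
            f"window sets differ between the two scans (first mismatch at start {diff[0]})"
        )
    return [
        DeltaEDRecord(
            window_start=s,
            ed_low=low[s].ensemble_diversity,
            ed_high=high[s].ensemble_diversity,
        )
        for s in sorted(low)
    ]


def gene_summary(
    gene_id: str,
    records: List[DeltaEDRecord],
    n_excluded: int = 0,
) -> GeneThermoSummary:
    if not records:
        raise ValueError(f"gene {gene_id}: no ΔED windows to summarize")
    deltas = np.array([r.delta_ed for r in records])
    imax = int(np.argmax(deltas))
    imin = int(np.argmin(deltas))
    return GeneThermoSummary(
        gene_id=gene_id,
        n_windows=len(records),
        mean_delta_ed=float(deltas.mean()),
        sd_delta_ed=float(deltas.std(ddof=1)) if len(records) > 1 else None,
        max_window=(records[imax].window_start, float(deltas[imax])),
        min_window=(records[imin].window_start, float(deltas[imin])),
        n_excluded=n_excluded,
    )


def population_stats(summaries: Sequence[GeneThermoSummary]) -> PopulationStats:
    """Cohort statistics over per-gene mean ΔED.  Quartiles use linear
    interpolation (numpy's default percentile method)."""
    if len(summaries) < 2:
        raise ValueError("population statistics need >= 2 genes")
    means = np.array([s.mean_delta_ed for s in summaries])
    q1, med, q3 = np.percentile(means, [25, 50, 75], method="linear")
    return PopulationStats(
        n_genes=len(summaries),
        mean=float(means.mean()),
        sd=float(means.std(ddof=1)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def standard_score(gene: GeneThermoSummary, pop: PopulationStats) -> float:
    """Gene mean ΔED in population-sd units from the population mean."""
    if pop.sd == 0:
        raise ValueError("population sd is zero; standard score undefined")
    return (gene.mean_delta_ed - pop.mean) / pop.sd


def one_sample_t_test(family_means: Sequence[float], reference_mean: float) -> TTestResult:
    """Two-sided one-sample t-test of a family's per-gene mean ΔED values
    against a fixed reference mean."""
    x = np.asarray(family_means, dtype=float)
    if x.size < 2:
        raise ValueError("t-test needs >= 2 family members")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("t-test undefined for zero-variance family")
    res = stats.ttest_1samp(x, popmean=reference_mean)
    se = sd / np.sqrt(x.size)
    return TTestResult(
        n=int(x.size),
        family_mean=float(x.mean()),
        standard_error=float(se),
        t_statistic=float(res.statistic),
        degrees_freedom=int(x.size - 1),
        p_value=float(res.pvalue),
    )


def top_delta_windows(
    records: List[DeltaEDRecord],
    k: int,
    mode: str = "absolute",
) -> List[DeltaEDRecord]:
    """The k most extreme ΔED windows (mode: positive | negative |
    absolute); ties keep ascending coordinate order."""
    if not records:
        raise ValueError("no ΔED records")
    key = {
        "positive": lambda r: -r.delta_ed,
        "negative": lambda r: r.delta_ed,
        "absolute": lambda r: -abs(r.delta_ed),
    }.get(mode)
    if key is None:
        raise ValueError(f"unknown mode {mode!r}")
    ranked = sorted(records, key=lambda r: (key(r), r.window_start))
    return ranked[: min(k, len(ranked))]


def centroid_shift(record_low: WindowRecord, record_high: WindowRecord):
    """Centroid comparison between temperatures for one window: base-pair
    distance plus the pairs unique to each temperature."""
    if (record_low.start, record_low.end) != (record_high.start, record_high.end):
        raise ValueError(
            f"window mismatch: [{record_low.start}, {record_low.end}) vs "
            f"[{record_high.start}, {record_high.end})"
        )
    low = dbn_to_pairs(record_low.centroid_dbn)
    high = dbn_to_pairs(record_high.centroid_dbn)
    return (
        base_pair_distance(low, high),
        frozenset(high - low),  # gained at the higher temperature
        frozenset(low - high),  # lost at the higher temperature
    )
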
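"""Per-gene and cohort orchestration.

A gene run reproduces a browsable dataset folder:

    <out>/<gene_id>/
        <gene_id>.fasta
        <gene_id>_<chrom>/
            win_<W>_step_<s>.tsv            (full run, z-scored)
            win_<W>_step_<s>_<T>C.tsv       (scan-only temperatures)
            igv_files/                      (wig tracks + bp arcs)
            extracted_structures/           (.txt/.dbn/.ct per z threshold)
            run_metadata.json

A cohort run maps the gene runs over a FASTA directory and aggregates
per-gene ΔED summaries into cohort statistics, per-family standard
scores, and the one-sample family t-test.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import __version__
from .consensus import (
    accumulate_pair_evidence,
    extract_motifs,
    filter_by_threshold,
    resolve_competition,
    trim_motif,
    write_motif_txt,
)
from .fold_backend import get_backend
from .io_tracks import (
    GeneModel,
    label_region,
    read_fasta,
    read_gene_model,
    write_bp_track,
    write_ct,
    write_dbn,
    write_wig,
)
from .scanner import ScanConfig, scan, write_scan_tsv
from .structure import resolve_crossings
from .thermo_diff import (
    GeneThermoSummary,
    delta_ed,
    gene_summary,
    one_sample_t_test,
    population_stats,
    standard_score,
)

log = logging.getLogger("thermoscan")

__all__ = ["RunConfig", "run_gene", "run_cohort"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a multi-temperature gene run.

    Exactly one temperature is the "full" run (shuffled null + z-scores +
    consensus); the others are scan-only and feed the ΔED comparison.
    Defaults mirror a standard production screen: full run at 37 C,
    scan-only runs at 28 C and 42 C, window 120, step 1, 100 shuffles.
    """

    full_temperature: float = 37.0
    scan_temperatures: Tuple[float, ...] = (28.0, 42.0)
    window_size: int = 120
    step: int = 1
    num_shuffles: int = 100
    seed: int = 1
    backend: str = "vienna"
    thresholds: Tuple[Optional[float], ...] = (None, -1.0, -2.0)
    motif_min_gap: int = 10
    force: bool = False

    def __post_init__(self):
        if len(self.scan_temperatures) not in (0, 2):
            raise ValueError("scan_temperatures must be empty or exactly two (low, high)")


def _gene_seed(master_seed: int, gene_id: str) -> int:
    return (int(master_seed) + zlib.crc32(gene_id.encode())) % (2**31 - 1)


def _metadata(config: RunConfig, backend, gene_id: str, seed: int) -> dict:
    return {
        "tool": f"thermoscan {__version__}",
        "engine": backend.name,
        "engine_version": backend.version,
        "engine_settings": backend.settings,
        "gene_id": gene_id,
        "window_size": config.window_size,
        "step": config.step,
        "num_shuffles": config.num_shuffles,
        "full_temperature_celsius": config.full_temperature,
        "scan_temperatures_celsius": list(config.scan_temperatures),
        "seed": seed,
    }


def run_gene(
    gene_id: str,
    sequence: str,
    config: RunConfig,
    out_root,
    model: Optional[GeneModel] = None,
    backend=None,
) -> Tuple[Path, Optional[GeneThermoSummary]]:
    """Run one gene end to end; returns the gene folder and, when two
    scan-only temperatures were configured, its ΔED summary."""
    backend = backend or get_backend(config.backend)
    model = model or GeneModel.identity(gene_id, len(sequence))
    seed = _gene_seed(config.seed, gene_id)

    gene_dir = Path(out_root) / gene_id
    sub = gene_dir / f"{gene_id}_{model.chromosome}"
    if sub.exists() and any(sub.iterdir()) and not config.force:
        raise FileExistsError(f"{sub} exists and is not empty (use force to overwrite)")
    igv = sub / "igv_files"
    extracted = sub / "extracted_structures"
    for d in (gene_dir, sub, igv, extracted):
        d.mkdir(parents=True, exist_ok=True)

    with open(gene_dir / f"{gene_id}.fasta", "w") as fh:
        fh.write(f">{gene_id}\n")
        for k in range(0, len(sequence), 60):
            fh.write(sequence[k:k + 60] + "\n")

    meta = _metadata(config, backend, gene_id, seed)
    w, s = config.window_size, config.step

    # --- full run: null + z + consensus -----------------------------------
    full_cfg = ScanConfig(
        window_size=w, step=s, num_shuffles=config.num_shuffles,
        temperature_celsius=config.full_temperature, seed=seed, compute_null=True,
    )
    full_records = scan(sequence, full_cfg, backend)
    write_scan_tsv(
        full_records, sub / f"win_{w}_step_{s}.tsv",
        metadata={**meta, "temperature_celsius": config.full_temperature, "mode": "full"},
    )
    write_wig({r.start: r.z_score for r in full_records if r.z_score is not None},
              model, f"{gene_id} z-score", igv / "zscore.wig", metadata=meta)
    write_wig({r.start: r.mfe_kcal_mol for r in full_records},
              model, f"{gene_id} MFE", igv / "mfe.wig", metadata=meta)
    write_wig({r.start: r.ensemble_diversity for r in full_records},
              model, f"{gene_id} ED", igv / "ed.wig", metadata=meta)

    consensus_model = resolve_competition(
        accumulate_pair_evidence(full_records), len(sequence)
    )
    write_bp_track(consensus_model.pair_mean_z, model, igv / "consensus.bp", metadata=meta)

    for thr in config.thresholds:
        tag = "no_filter" if thr is None else f"z{thr:g}"
        pairs = filter_by_threshold(consensus_model, thr)
        nested, dropped = resolve_crossings(
            pairs, lambda p: abs(consensus_model.pair_mean_z[tuple(p)])
        )
        if dropped:
            log.warning("%s: dropped %d crossing pairs at threshold %s",
                        gene_id, len(dropped), tag)
        write_dbn(sequence, nested, extracted / f"consensus_{tag}.dbn",
                  header=f"{gene_id} {tag}")
        write_ct(sequence, nested, extracted / f"consensus_{tag}.ct",
                 title=f"{gene_id} {tag}")
        motifs = [trim_motif(m) for m in
                  extract_motifs(consensus_model, thr, config.motif_min_gap)]
        motifs = [
            dataclasses.replace(m, region_label=label_region(model, m.start, m.end))
            for m in motifs
        ]
        write_motif_txt(motifs, sequence, gene_id, extracted / f"motifs_{tag}.txt")

    # --- scan-only temperatures and ΔED -----------------------------------
    summary: Optional[GeneThermoSummary] = None
    if len(config.scan_temperatures) == 2:
        lo_t, hi_t = sorted(config.scan_temperatures)
        scans = {}
        for t in (lo_t, hi_t):
            cfg = ScanConfig(window_size=w, step=s, num_shuffles=0,
                             temperature_celsius=t, seed=seed, compute_null=False)
            scans[t] = scan(sequence, cfg, backend)
            write_scan_tsv(
                scans[t], sub / f"win_{w}_step_{s}_{t:g}C.tsv",
                metadata={**meta, "temperature_celsius": t, "mode": "scan-only"},
            )
        records = delta_ed(scans[lo_t], scans[hi_t])
        n_excluded = len(scans[lo_t]) - len(records)
        if records:
            write_wig({r.window_start: r.delta_ed for r in records}, model,
                      f"{gene_id} dED {hi_t:g}-{lo_t:g}C", igv / "delta_ed.wig",
                      metadata=meta)
            summary = gene_summary(gene_id, records, n_excluded=n_excluded)

    with open(sub / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return gene_dir, summary


def run_cohort(
    fasta_paths: Sequence,
    config: RunConfig,
    out_root,
    gff3_path=None,
    families: Optional[Dict[str, str]] = None,
    family_of_interest: Optional[str] = None,
) -> dict:
    """Run every gene FASTA, aggregate ΔED summaries, and write the cohort
    table.  Per-gene failures are logged and skipped; the returned status
    is nonzero if any gene failed."""
    fasta_paths = sorted(Path(p) for p in fasta_paths)
    if not fasta_paths:
        raise ValueError("no FASTA files to run")
    backend = get_backend(config.backend)
    summaries: List[GeneThermoSummary] = []
    failures: List[str] = []
    for path in fasta_paths:
        try:
            records = read_fasta(path)
            for gene_id, seq in records:
                gmodel = None
                if gff3_path is not None:
                    gmodel = read_gene_model(gff3_path, gene_id)
                _, summ = run_gene(gene_id, seq, config, out_root,
                                   model=gmodel, backend=backend)
                if summ is not None:
                    summaries.append(summ)
                log.info("finished %s (%d nt)", gene_id, len(seq))
        except Exception as exc:
            log.error("gene run failed for %s: %s", path, exc)
            failures.append(str(path))

    result: dict = {"n_genes": len(summaries), "failures": failures,
                    "status": 1 if failures else 0}
    if len(summaries) >= 2:
        pop = population_stats(summaries)
        result["population"] = asdict(pop)
        rows = []
        fam_means: Dict[str, List[float]] = {}
        for summ in summaries:
            fam = (families or {}).get(summ.gene_id, "other")
            fam_means.setdefault(fam, []).append(summ.mean_delta_ed)
            rows.append((summ, fam, standard_score(summ, pop)))
        if family_of_interest is not None:
            means = fam_means.get(family_of_interest, [])
            if len(means) >= 2:
                result["family_t_test"] = asdict(
                    one_sample_t_test(means, pop.mean)
                )
            else:
                log.warning("family %r has < 2 members; t-test refused",
                            family_of_interest)
        out = Path(out_root)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "cohort_summary.tsv", "w") as fh:
            for key, value in result.get("population", {}).items():
                fh.write(f"# population_{key} = {value}\n")
            for key, value in result.get("family_t_test", {}).items():
                fh.write(f"# ttest_{key} = {value}\n")
            fh.write("gene_id\tfamily\tn_windows\tn_excluded\tmean_delta_ed\t"
                     "sd_delta_ed\tmax_window\tmax_delta_ed\tmin_window\t"
                     "min_delta_ed\tstandard_score\n")
            for summ, fam, score in rows:
                fh.write(
                    f"{summ.gene_id}\t{fam}\t{summ.n_windows}\t{summ.n_excluded}\t"
                    f"{summ.mean_delta_ed:.6g}\t"
                    f"{'NA' if summ.sd_delta_ed is None else format(summ.sd_delta_ed, '.6g')}\t"
                    f"{summ.max_window[0] + 1}\t{summ.max_window[1]:.6g}\t"
                    f"{summ.min_window[0] + 1}\t{summ.min_window[1]:.6g}\t"
                    f"{score:.6g}\n"
                )
    return result
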
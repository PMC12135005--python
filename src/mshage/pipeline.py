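"""End-to-end orchestration of the WGS/WES benchmarking experiment.

One master seed fans out to named sub-seeds (simulation, per-arm singleton
phasing, exome-adjustment draws), so the WGS and WES arms share the same
simulated history: the WES dataset is literally the exome-masked copy of the
WGS dataset, and the arm comparison is paired.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import __version__
from ._rng import subseed
from .evaluation import EvalReport, compute_metrics, evaluate, match_pairs, write_report
from .haplotypes import HaplotypeDataset
from .intervals import ExomeMask, filter_to_exome
from .msh import EstimatorConfig, estimate_all, estimates_to_frame, phase_singletons, write_estimates
from .synthetic_data import (
    ModelConfig,
    SimulationResult,
    exclude_recurrent_sites,
    simulate,
    write_true_ages,
    write_vcf,
)

__all__ = ["RunManifest", "run_simulate", "run_all", "ArmResult"]

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seeds, outputs, timings."""

    config: dict
    seeds: dict
    outputs: list[str] = field(default_factory=list)
    stages: list[dict] = field(default_factory=list)
    version: str = __version__

    def add_stage(self, name: str, **info) -> None:
        self.stages.append({"stage": name, "time": time.time(), **info})

    def write(self, path) -> None:
        for out in self.outputs:
            if not Path(out).exists():
                raise FileNotFoundError(f"manifest lists a missing output: {out}")
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
            fh.write("\n")


def run_simulate(config: ModelConfig, outdir) -> RunManifest:
    """Simulate, drop multi-hit sites, and write VCF + truth + config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dict(line.split("=", 1) for line in config.echo_lines()),
        seeds={"master": config.seed},
    )
    result = exclude_recurrent_sites(simulate(config))
    manifest.add_stage("simulate", n_sites=result.haplotypes.n_sites)
    vcf_path = outdir / f"{config.model_id}_wgs.vcf"
    ages_path = outdir / "true_ages.tsv"
    echo_path = outdir / "config_echo.txt"
    write_vcf(result, vcf_path)
    write_true_ages(result.true_ages, ages_path)
    echo_path.write_text("\n".join(config.echo_lines()) + "\n")
    manifest.outputs += [str(vcf_path), str(ages_path), str(echo_path)]
    manifest.write(outdir / "manifest.json")
    return manifest


@dataclass
class ArmResult:
    """One arm (WGS or WES) of the paired benchmark."""

    name: str
    dataset: HaplotypeDataset
    estimates: list
    report: EvalReport


def _estimate_arm(
    name: str,
    ds: HaplotypeDataset,
    truth,
    base_config: EstimatorConfig,
    master_seed: int,
    n_genomes: int,
) -> ArmResult:
    k_lo, _ = base_config.k_bounds()
    if k_lo <= 1:
        # one phasing seed for both arms: identical inputs (e.g. a mask
        # covering the whole region) then phase identically
        ds = phase_singletons(ds, seed=subseed(master_seed, "phasing"))
    config = replace(base_config, seed=subseed(master_seed, "adjust", name))
    estimates = estimate_all(ds, config)
    report = evaluate(truth, estimates, n_genomes=n_genomes)
    return ArmResult(name=name, dataset=ds, estimates=estimates, report=report)


def run_all(
    model_config: ModelConfig,
    mask: ExomeMask,
    estimator_config: EstimatorConfig | None = None,
    outdir=None,
) -> dict:
    """Full paired experiment: simulate -> WGS and WES arms -> reports.

    Returns a dict with both :class:`ArmResult` objects and the percent
    change in Pearson r between arms, 100 * (1 - r_WES / r_WGS).
    """
    master = model_config.seed
    base = estimator_config or EstimatorConfig(
        mu=model_config.mu,
        genetic_map=model_config.genetic_map,
        flat_recomb_rate=model_config.flat_recomb_rate,
    )
    if base.genetic_map is None and base.flat_recomb_rate is None:
        base = replace(base, flat_recomb_rate=model_config.flat_recomb_rate)

    result = exclude_recurrent_sites(simulate(model_config))
    truth = result.true_ages
    wgs_ds = result.haplotypes
    wes_ds = filter_to_exome(wgs_ds, mask)
    logger.info(
        "run_all: %d WGS variants, %d after exome masking (%.1f%% of region in exons)",
        wgs_ds.n_sites,
        wes_ds.n_sites,
        100.0 * mask.total_bp / model_config.seq_length_bp,
    )

    wgs_cfg = replace(base, exome_mode=False, mask=None)
    wes_cfg = replace(base, exome_mode=True, mask=mask)
    wgs = _estimate_arm("wgs", wgs_ds, truth, wgs_cfg, master, model_config.n_genomes)
    wes = _estimate_arm("wes", wes_ds, truth, wes_cfg, master, model_config.n_genomes)

    pct_change = 100.0 * (1.0 - wes.report.pearson_r / wgs.report.pearson_r)
    out = {
        "wgs": wgs,
        "wes": wes,
        "pearson_pct_change": pct_change,
        "simulation": result,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = RunManifest(
            config=dict(line.split("=", 1) for line in model_config.echo_lines()),
            seeds={
                "master": master,
                "simulate": subseed(master, "ancestry"),
                "phasing": subseed(master, "phasing"),
                "adjust_wes": subseed(master, "adjust", "wes"),
            },
        )
        paths = {
            "wgs_vcf": outdir / "wgs.vcf",
            "wes_vcf": outdir / "wes.vcf",
            "true_ages": outdir / "true_ages.tsv",
        }
        write_vcf(result, paths["wgs_vcf"])
        if wes_ds.n_sites:
            write_vcf(replace(result, haplotypes=wes_ds,
                              true_ages=truth[truth["position"].isin(wes_ds.positions)].reset_index(drop=True),
                              mutation_counts=result.mutation_counts[mask.contains(wgs_ds.positions)]),
                      paths["wes_vcf"])
        write_true_ages(truth, paths["true_ages"])
        for arm in (wgs, wes):
            est_path = outdir / f"estimates_{arm.name}.tsv"
            rep_path = outdir / f"report_{arm.name}.txt"
            bins_path = outdir / f"bins_{arm.name}.csv"
            write_estimates(arm.estimates, est_path)
            write_report(arm.report, rep_path, bins_path)
            paths[f"estimates_{arm.name}"] = est_path
            paths[f"report_{arm.name}"] = rep_path
        summary = outdir / "summary.txt"
        summary.write_text(
            "\n".join(
                [
                    f"pearson_r_wgs={wgs.report.pearson_r:.4f}",
                    f"pearson_r_wes={wes.report.pearson_r:.4f}",
                    f"pearson_pct_change={pct_change:.2f}",
                    f"spearman_rho_wgs={wgs.report.spearman_rho:.4f}",
                    f"spearman_rho_wes={wes.report.spearman_rho:.4f}",
                ]
            )
            + "\n"
        )
        manifest.outputs = [str(p) for p in paths.values()] + [str(summary)]
        manifest.add_stage("run_all", n_wgs=wgs_ds.n_sites, n_wes=wes_ds.n_sites)
        manifest.write(outdir / "manifest.json")
        out["manifest"] = manifest
    return out
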
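"""Pipeline orchestration: simulate -> qc -> relmat -> fit -> crossval.

Each stage writes its artifacts plus an entry in ``manifest.json``
recording the hash of the configuration fields it depends on; a rerun
skips stages whose outputs exist under a matching hash, so editing e.g.
only the MCMC schedule recomputes the cross-validation stage alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import io as gio
from .config import RunConfig
from .crossval import run_study
from .lmm import ai_reml, design_from_phenotypes
from .popsim import default_architectures, simulate_population
from .qc import filter_snps, impute_missing
from .relmat import genomic_g_matrix, pedigree_a_matrix
from .wgr import MCMCConfig

__all__ = ["run_pipeline", "STAGES"]

log = logging.getLogger("gpcross")

_POP_KEYS = (
    "n_f0", "n_f1", "n_sires_f1", "n_f2", "n_snps", "n_chromosomes",
    "map_length_cm", "divergence", "n_qtl", "n_hatches", "missing_rate",
    "traits", "seed",
)
_QC_KEYS = _POP_KEYS + ("min_call_rate", "min_maf")
_RELMAT_KEYS = _QC_KEYS + ("g_ridge",)
_FIT_KEYS = _QC_KEYS
_CV_KEYS = _RELMAT_KEYS + (
    "models", "scenarios", "k_folds", "pi", "include_full_data",
    "mcmc_cycles", "mcmc_burn_in", "mcmc_thin",
)


def _load_manifest(outdir: Path) -> dict:
    path = outdir / "manifest.json"
    if path.exists():
        return json.loads(path.read_text())
    return {"stages": {}}


def _save_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _fresh(outdir: Path, manifest: dict, stage: str, digest: str, outputs: list[str]) -> bool:
    ok = manifest["stages"].get(stage, {}).get("hash") == digest
    return ok and all((outdir / o).exists() for o in outputs)


def _mark(manifest: dict, stage: str, digest: str, outputs: list[str]) -> None:
    manifest["stages"][stage] = {"hash": digest, "outputs": outputs}


def stage_simulate(config: RunConfig, outdir: Path) -> None:
    archs = {
        t: a for t, a in default_architectures(
            n_qtl=config.n_qtl, n_hatches=config.n_hatches
        ).items() if t in config.traits
    }
    pop = simulate_population(
        n_f0=config.n_f0, n_f1=config.n_f1, n_sires_f1=config.n_sires_f1,
        n_f2=config.n_f2, n_snps=config.n_snps, n_chromosomes=config.n_chromosomes,
        map_length_cm=config.map_length_cm, divergence=config.divergence,
        architectures=archs, n_hatches=config.n_hatches,
        missing_rate=config.missing_rate, seed=config.seed,
    )
    gio.write_pedigree(pop.pedigree, outdir / "pedigree.csv")
    gio.write_genotypes_tsv(pop.genotypes, outdir / "genotypes.tsv", outdir / "snp_map.csv")
    gio.write_phenotypes(pop.phenotypes, outdir / "phenotypes.csv")


def _load_population(outdir: Path, qc: bool = False):
    from .popsim import SimulatedPopulation

    ped = gio.read_pedigree(outdir / "pedigree.csv")
    suffix = "_qc" if qc else ""
    geno = gio.read_genotypes(
        outdir / f"genotypes{suffix}.tsv", map_path=outdir / f"snp_map{suffix}.csv"
    )
    phen = gio.read_phenotypes(outdir / "phenotypes.csv")
    return SimulatedPopulation(pedigree=ped, genotypes=geno, phenotypes=phen)


def stage_qc(config: RunConfig, outdir: Path) -> None:
    pop = _load_population(outdir)
    filtered, report = filter_snps(pop.genotypes, config.min_call_rate, config.min_maf)
    imputed = impute_missing(filtered)
    gio.write_genotypes_tsv(imputed, outdir / "genotypes_qc.tsv", outdir / "snp_map_qc.csv")
    (outdir / "qc_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    log.info("%s", report)


def stage_relmat(config: RunConfig, outdir: Path) -> None:
    pop = _load_population(outdir, qc=True)
    A = pedigree_a_matrix(pop.pedigree)
    G = genomic_g_matrix(pop.genotypes, ridge=config.g_ridge)
    gio.write_relationship_matrix(A, outdir / "A.tsv")
    gio.write_relationship_matrix(G, outdir / "G.tsv")


def stage_fit(config: RunConfig, outdir: Path) -> None:
    """Full-data pedigree variance components per trait."""
    pop = _load_population(outdir, qc=True)
    A = pedigree_a_matrix(pop.pedigree)
    rows = []
    for trait in pop.phenotypes.traits:
        design = design_from_phenotypes(pop.phenotypes.for_trait(trait))
        vc = ai_reml(design, A)
        rows.append(
            (trait, vc.sigma_a2, vc.sigma_e2, vc.h2, vc.se_h2, vc.converged, vc.n_iter)
        )
        log.info("trait %s: h2 = %.3f +- %.3f", trait, vc.h2, vc.se_h2)
    pd.DataFrame(
        rows, columns=["trait", "sigma_a2", "sigma_e2", "h2", "se_h2", "converged", "n_iter"]
    ).to_csv(outdir / "variance_components.csv", index=False)


def stage_crossval(config: RunConfig, outdir: Path) -> None:
    pop = _load_population(outdir, qc=True)
    mcmc = MCMCConfig(config.mcmc_cycles, config.mcmc_burn_in, config.mcmc_thin)
    report = run_study(
        pop,
        traits=list(config.traits),
        models=config.models,
        scenarios=config.scenarios,
        k=config.k_folds,
        qc_thresholds=(0.0, 0.0),  # QC already applied upstream
        mcmc=mcmc,
        seed=config.seed,
        include_full_data=config.include_full_data,
        g_ridge=config.g_ridge,
        pi=config.pi,
    )
    report.to_csv(outdir / "evaluation.csv")
    report.paired_tests.to_csv(outdir / "paired_tests.csv", index=False)
    with open(outdir / "summary_tables.txt", "w") as fh:
        for stat in ("accuracy", "slope"):
            fh.write(f"== pooled {stat} ==\n")
            fh.write(report.summary_table(stat).round(3).to_string())
            fh.write("\n\n")


STAGES = {
    "simulate": (stage_simulate, _POP_KEYS,
                 ["pedigree.csv", "genotypes.tsv", "snp_map.csv", "phenotypes.csv"]),
    "qc": (stage_qc, _QC_KEYS, ["genotypes_qc.tsv", "snp_map_qc.csv", "qc_report.json"]),
    "relmat": (stage_relmat, _RELMAT_KEYS, ["A.tsv", "G.tsv"]),
    "fit": (stage_fit, _FIT_KEYS, ["variance_components.csv"]),
    "crossval": (stage_crossval, _CV_KEYS,
                 ["evaluation.csv", "paired_tests.csv", "summary_tables.txt"]),
}


def run_pipeline(config: RunConfig, outdir, stages=None) -> dict:
    """Execute the pipeline; returns {stage: 'run' | 'skipped'}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(outdir)
    manifest["config"] = config.to_dict()
    status = {}
    for name, (fn, keys, outputs) in STAGES.items():
        if stages is not None and name not in stages:
            continue
        digest = config.stage_hash(*keys)
        if _fresh(outdir, manifest, name, digest, outputs):
            log.info("stage %s: up to date, skipped", name)
            status[name] = "skipped"
            continue
        log.info("stage %s: running", name)
        try:
            fn(config, outdir)
        except Exception:
            log.exception("stage %s failed; partial outputs retained", name)
            _save_manifest(outdir, manifest)
            raise
        _mark(manifest, name, digest, outputs)
        status[name] = "run"
    _save_manifest(outdir, manifest)
    return status
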
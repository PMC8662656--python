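"""Reproducible orchestration of the analysis stages.

A single structured config (YAML) drives the run: simulate genotypes
under a chosen scenario, decorate them with GBS noise, filter, prune to
one SNP per locus, compute diversity/F_ST/PCA tables, directional
migration, and a desk-scale ABC analysis.  Every random draw derives
from the master seed through a per-stage ``SeedSequence`` spawn, and a
manifest records every output file with a content hash.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import abc as abc_mod
from . import migration as mig_mod
from . import popstats
from .coalescent import simulate_dataset
from .demography import (
    PriorSpec,
    SampleConfig,
    ScenarioParams,
    published_median_params,
)
from .filtering import (
    FilterConfig,
    add_gbs_noise,
    apply_filters,
    records_to_matrix,
    select_one_snp_per_locus,
)
from .vcfio import write_popmap, write_vcf

_STAGE_NAMES = ("simulate", "noise", "filter", "stats", "migration", "abc")


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "outdir": "ventseep_run",
    "stages": list(_STAGE_NAMES),
    "simulate": {
        "scenario": 1,
        "params": "published_medians",    # or a {name: value} mapping
        "sample_sizes": {"JR": 12, "OH": 25, "KK": 21, "OT": 63},
        "n_loci": 2000,
    },
    "noise": {"depth_mean": 30.0, "missing_rate": 0.05, "dispersion": 5.0},
    "filter": {},                      # FilterConfig overrides
    "stats": {"n_permutations": 1000},
    "abc": {
        "n_sims": 1500,
        "n_loci": 300,
        "sample_sizes": {"JR": 10, "OH": 10, "KK": 10, "OT": 10},
        "n_closest": 100,
        "closest_fraction": 0.05,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    settings: dict[str, Any] = field(default_factory=lambda: dict(DEFAULT_CONFIG))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls(settings=_merge(DEFAULT_CONFIG, user))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.settings, fh, sort_keys=False)

    def __getitem__(self, key):
        return self.settings[key]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    settings = config.settings
    outdir = Path(settings["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    master = int(settings["seed"])
    stages = settings["stages"]
    manifest: dict[str, Any] = {
        "seed": master, "stages": [], "outputs": {}, "stage_seeds": {},
    }

    def record(stage: str, t0: float, **extra):
        manifest["stages"].append(
            {"name": stage, "wall_time_s": round(time.time() - t0, 3), **extra}
        )

    def add_output(name: str, path: Path):
        manifest["outputs"][name] = {
            "path": str(path), "sha256": _sha256(path),
        }

    current_stage = "init"
    try:
        gm = None
        if "simulate" in stages:
            current_stage = "simulate"
            t0 = time.time()
            sim = settings["simulate"]
            seed = _stage_seed(master, "simulate")
            manifest["stage_seeds"]["simulate"] = seed
            sc = SampleConfig(sizes={k: int(v) for k, v in sim["sample_sizes"].items()})
            if sim["params"] == "published_medians":
                params = published_median_params()
            else:
                params = ScenarioParams(scenario_id=int(sim["scenario"]), **sim["params"])
            gm = simulate_dataset(params, sc, int(sim["n_loci"]), seed)
            pm_path = outdir / "popmap.tsv"
            write_popmap(gm.popmap(), pm_path)
            add_output("popmap", pm_path)
            record("simulate", t0, n_loci=gm.n_loci, n_individuals=gm.n_individuals)

        records = None
        samples = None
        if "noise" in stages:
            current_stage = "noise"
            t0 = time.time()
            seed = _stage_seed(master, "noise")
            manifest["stage_seeds"]["noise"] = seed
            nz = settings["noise"]
            records = add_gbs_noise(
                gm, depth_mean=float(nz["depth_mean"]),
                missing_rate=float(nz["missing_rate"]),
                dispersion=float(nz["dispersion"]), rng_seed=seed,
            )
            samples = list(gm.individuals)
            vcf_path = outdir / "raw.vcf"
            write_vcf(records, samples, vcf_path)
            add_output("raw_vcf", vcf_path)
            record("noise", t0)

        if "filter" in stages and records is not None:
            current_stage = "filter"
            t0 = time.time()
            fc = FilterConfig(**settings["filter"])
            survivors, report = apply_filters(records, fc)
            pruned = select_one_snp_per_locus(
                survivors, rng_seed=_stage_seed(master, "prune")
            )
            rep_path = outdir / "filter_report.tsv"
            report.to_tsv(rep_path)
            add_output("filter_report", rep_path)
            vcf_path = outdir / "filtered.vcf"
            write_vcf(survivors, samples, vcf_path)
            add_output("filtered_vcf", vcf_path)
            gm = records_to_matrix(pruned, samples, gm.popmap())
            record("filter", t0, n_snps=report.final_snps,
                   n_scaffolds=report.final_scaffolds)

        if "stats" in stages:
            current_stage = "stats"
            t0 = time.time()
            seed = _stage_seed(master, "stats")
            manifest["stage_seeds"]["stats"] = seed
            gs = popstats.group_summary(gm)
            gs_path = outdir / "group_stats.tsv"
            gs.to_csv(gs_path, sep="\t")
            add_output("group_stats", gs_path)
            fst = popstats.fst_matrix(
                gm, n_perm=int(settings["stats"]["n_permutations"]), rng_seed=seed
            )
            fst_path = outdir / "fst_matrix.tsv"
            fst.to_csv(fst_path, sep="\t")
            add_output("fst_matrix", fst_path)
            pca = popstats.genotype_pca(gm)
            pca_path = outdir / "pca_coords.tsv"
            pca.coords.to_csv(pca_path, sep="\t")
            add_output("pca_coords", pca_path)
            record("stats", t0)

        if "migration" in stages:
            current_stage = "migration"
            t0 = time.time()
            mm = mig_mod.relative_migration(gm)
            mig_path = outdir / "migration.tsv"
            mm.values.to_csv(mig_path, sep="\t")
            add_output("migration", mig_path)
            record("migration", t0)

        if "abc" in stages:
            current_stage = "abc"
            t0 = time.time()
            seed = _stage_seed(master, "abc")
            manifest["stage_seeds"]["abc"] = seed
            ab = settings["abc"]
            sc = SampleConfig(sizes={k: int(v) for k, v in ab["sample_sizes"].items()})
            prior = PriorSpec()
            table = abc_mod.build_reference_table(
                prior, [1, 2, 3], sc, int(ab["n_sims"]), int(ab["n_loci"]),
                rng_seed=seed,
            )
            table_path = outdir / "reference_table.tsv"
            table.save(table_path)
            add_output("reference_table", table_path)
            obs_gm = _downsample_to(gm, sc, rng_seed=seed + 1)
            obs = abc_mod.summary_stats(obs_gm, sc.groups)
            direct = abc_mod.posterior_prob_direct(
                table, obs, n_closest=int(ab["n_closest"])
            )
            logistic = abc_mod.posterior_prob_logistic(
                table, obs, closest_fraction=float(ab["closest_fraction"])
            )
            mc_path = outdir / "abc_model_choice.tsv"
            import pandas as pd

            frame = pd.concat(
                [direct.to_frame(), logistic.to_frame()], ignore_index=True
            )
            frame.to_csv(mc_path, sep="\t", index=False)
            add_output("abc_model_choice", mc_path)
            est = abc_mod.estimate_parameters(
                table, obs, direct.best,
                closest_fraction=float(ab["closest_fraction"]),
            )
            par_path = outdir / "abc_params.tsv"
            est.summary.to_csv(par_path, sep="\t")
            add_output("abc_params", par_path)
            record("abc", t0, best_direct=direct.best, best_logistic=logistic.best)
    except Exception as exc:
        manifest["failed_stage"] = current_stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _downsample_to(gm, sample_config: SampleConfig, rng_seed: int = 0):
    """Random per-group subsample so observed data match the ABC design."""
    from .demography import GenotypeMatrix

    rng = np.random.default_rng(rng_seed)
    keep = []
    for g in sample_config.groups:
        idx = gm.group_index(g)
        n = sample_config.sizes[g]
        if idx.size < n:
            raise ValueError(f"group {g} has only {idx.size} individuals, need {n}")
        keep.extend(rng.choice(idx, size=n, replace=False))
    keep = np.sort(np.asarray(keep))
    return GenotypeMatrix(
        gm.genotypes[keep],
        [gm.individuals[i] for i in keep],
        gm.groups[keep],
        gm.loci.copy(),
    )
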
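"""Configuration-driven pipeline tying the stages together.

Stages run in dependency order: simulate -> qc -> score -> pcs ->
structure-gwas -> ps-geo -> attenuate -> null-traits -> admixmap. Each
stage writes tab-separated artifacts into the run directory exactly once
and a JSON manifest records the seed, per-stage row counts and SHA-256
digests of every output.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simpop import (
    SimulationConfig,
    simulate_source_freqs,
    simulate_cohort,
    build_reference_panel,
    true_weight_table,
)
from .qc import QCRules, apply_variant_qc
from .scores import build_ps, greedy_clump, ztransform
from .geo_assoc import compute_pcs, structure_gwas, genomic_lambda, ps_geo_battery
from .attenuation import fit_adjustment_tiers, geo_matched_traits, rescale_unadjusted
from .admixmap import estimate_admixture, bootstrap_regional_ci

ALL_STAGES = [
    "simulate",
    "qc",
    "score",
    "pcs",
    "structure-gwas",
    "ps-geo",
    "attenuate",
    "null-traits",
    "admixmap",
]


@dataclass
class PSSpec:
    trait: str
    mode: str = "weighted"
    p_threshold: float = 5e-8


@dataclass
class RunConfig:
    seed: int
    simulation: SimulationConfig
    qc_rules: QCRules = field(default_factory=QCRules)
    ps_specs: list[PSSpec] = field(default_factory=list)
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    n_pcs: int = 10
    pc_counts: tuple[int, int] = (10, 40)
    n_boot: int = 500
    n_bins: int = 100
    n_panel: int = 200
    clump_window_kb: float = 250.0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "simulation" in d and not isinstance(d["simulation"], SimulationConfig):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "qc_rules" in d and not isinstance(d["qc_rules"], QCRules):
            d["qc_rules"] = QCRules(**d["qc_rules"])
        if "ps_specs" in d:
            d["ps_specs"] = [p if isinstance(p, PSSpec) else PSSpec(**p) for p in d["ps_specs"]]
        if "pc_counts" in d:
            d["pc_counts"] = tuple(d["pc_counts"])
        if "seed" not in d:
            raise ValueError("run config must set a seed (reproducibility by default)")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    if path.exists():
        raise FileExistsError(f"artifact {path} already exists (outputs are write-once)")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


STAGE_DEPS = {
    "qc": ["simulate"],
    "score": ["qc"],
    "pcs": ["qc"],
    "structure-gwas": ["pcs"],
    "ps-geo": ["score", "pcs"],
    "attenuate": ["score", "pcs"],
    "null-traits": ["simulate"],
    "admixmap": ["simulate"],
}


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the requested stages and return the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in ALL_STAGES if s in config.stages]
    for s in stages:
        missing = [d for d in STAGE_DEPS.get(s, []) if d not in stages]
        if missing:
            raise ValueError(f"stage {s!r} requires upstream stage(s) {missing}")
    manifest: dict = {
        "geostrat_version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    # --- simulate ---------------------------------------------------------
    src = simulate_source_freqs(config.simulation)
    sim = simulate_cohort(config.simulation, src)
    keep = sim.cohort.table["participation"].to_numpy()
    cohort = sim.cohort
    geno = sim.genotypes
    traits = sim.traits
    if "simulate" in stages:
        _write(cohort.table, out / "cohort.tsv")
        _write(traits.table, out / "traits.tsv")
        _write(geno.variants, out / "variants.tsv")
        geno_df = pd.DataFrame(geno.dosages, columns=geno.variants["variant_id"])
        geno_df.insert(0, "id", geno.sample_ids)
        _write(geno_df, out / "genotypes.tsv")
        adm = pd.DataFrame(
            sim.admixture, columns=[f"region{k+1}" for k in range(sim.admixture.shape[1])]
        )
        adm.insert(0, "id", geno.sample_ids)
        _write(adm, out / "admixture_true.tsv")
        manifest["stages"]["simulate"] = {
            "n_individuals": int(cohort.n),
            "n_variants": int(geno.n_variants),
            "n_participating": int(keep.sum()),
        }

    # --- qc ---------------------------------------------------------------
    if "qc" in stages:
        geno, removal_log = apply_variant_qc(geno, config.qc_rules)
        _write(removal_log, out / "variant_removal_log.tsv")
        manifest["stages"]["qc"] = {
            "n_variants_kept": int(geno.n_variants),
            "n_variants_removed": int(len(removal_log)),
        }

    # --- score ------------------------------------------------------------
    ps_z: dict[str, object] = {}
    if "score" in stages:
        score_rows = []
        for spec in config.ps_specs or [PSSpec(t.name) for t in config.simulation.trait_specs]:
            table = true_weight_table(sim, spec.trait)
            clumped = greedy_clump(table, config.clump_window_kb, spec.p_threshold)
            raw = build_ps(geno, clumped, mode=spec.mode, p_threshold=spec.p_threshold)
            z = ztransform(raw)
            label = f"{spec.trait}_{spec.mode}_{spec.p_threshold:g}"
            ps_z[label] = z
            score_rows.append(
                pd.DataFrame(
                    {"id": z.scores.index, "ps": label, "score_z": z.scores.values}
                )
            )
        _write(pd.concat(score_rows, ignore_index=True), out / "polygenic_scores.tsv")
        manifest["stages"]["score"] = {
            "n_scores": len(ps_z),
            "n_variants_used": {k: int(v.n_variants_used) for k, v in ps_z.items()},
        }

    # --- pcs ----------------------------------------------------------------
    pcs = None
    if "pcs" in stages:
        n_pcs = min(config.n_pcs, geno.n_samples - 2, geno.n_variants - 2)
        if n_pcs < config.n_pcs:
            warnings.warn(f"capping n_pcs at {n_pcs}")
        pcs = compute_pcs(geno, n_pcs=n_pcs)
        pc_df = pcs.frame()
        pc_df.insert(0, "id", geno.sample_ids)
        _write(pc_df, out / "pcs.tsv")
        manifest["stages"]["pcs"] = {
            "n_pcs": int(pcs.n_pcs),
            "top_eigenvalue": float(pcs.eigenvalues[0]),
        }

    # --- structure-gwas -----------------------------------------------------
    if "structure-gwas" in stages:
        gwas_frames, lambdas = [], {}
        for axis in ("north_south", "east_west"):
            for tier in (1, 4):
                res = structure_gwas(geno, cohort, axis, tier, pcs, config.pc_counts)
                gwas_frames.append(res.table)
                lambdas[f"{axis}_tier{tier}"] = genomic_lambda(res.table["p"].to_numpy())
        _write(pd.concat(gwas_frames, ignore_index=True), out / "structure_gwas.tsv")
        manifest["stages"]["structure-gwas"] = {"genomic_lambda": lambdas}

    # --- ps-geo -------------------------------------------------------------
    if "ps-geo" in stages:
        tier_table = ps_geo_battery(ps_z, cohort, pcs, pc_counts=config.pc_counts)
        _write(tier_table, out / "ps_geo_tiers.tsv")
        manifest["stages"]["ps-geo"] = {"n_rows": int(len(tier_table))}

    # --- attenuate ----------------------------------------------------------
    if "attenuate" in stages:
        att_frames = []
        for label, z in ps_z.items():
            for trait_name in traits.meta["name"]:
                rep = fit_adjustment_tiers(
                    traits.table[trait_name].to_numpy(),
                    z,
                    cohort,
                    pcs,
                    pc_counts=(config.pc_counts[1], config.pc_counts[1]),
                    trait_name=trait_name,
                    ps_label=label,
                )
                resc = rescale_unadjusted(rep)
                resc.insert(0, "trait", trait_name)
                resc.insert(0, "ps", label)
                att_frames.append(resc)
        _write(pd.concat(att_frames, ignore_index=True), out / "attenuation.tsv")
        manifest["stages"]["attenuate"] = {"n_rows": int(sum(len(f) for f in att_frames))}

    # --- null-traits ----------------------------------------------------------
    if "null-traits" in stages:
        null_cols = {}
        for trait_name in traits.meta["name"]:
            nt = geo_matched_traits(
                traits.table[trait_name].to_numpy(), cohort, config.n_bins, config.seed
            )
            null_cols[f"{trait_name}_geonull"] = nt.values.to_numpy()
        null_df = pd.DataFrame({"id": geno.sample_ids, **null_cols})
        _write(null_df, out / "null_traits.tsv")
        with open(out / "null_traits_meta.json", "w") as fh:
            json.dump({"seed": config.seed, "n_bins": config.n_bins}, fh)
        manifest["stages"]["null-traits"] = {"n_traits": len(null_cols)}

    # --- admixmap -------------------------------------------------------------
    if "admixmap" in stages:
        panel = build_reference_panel(sim.source_freqs, config.n_panel, config.seed)
        adm = estimate_admixture(sim.genotypes.dosages, panel)
        first_trait = traits.meta["name"].iloc[0]
        est = bootstrap_regional_ci(
            adm, traits.table[first_trait].to_numpy(), config.n_boot, config.seed
        )
        panel.to_tsv(str(out / "reference_panel.tsv"))
        _write(est.frame(), out / "regional_estimates.tsv")
        manifest["stages"]["admixmap"] = {
            "trait": str(first_trait),
            "n_regions": len(est.labels),
            "n_boot": config.n_boot,
        }

    manifest["artifacts"] = {
        p.name: _digest(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
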
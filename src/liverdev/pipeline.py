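"""End-to-end pipeline: simulate -> normalize -> classify -> profiles -> enrich.

A single :class:`PipelineConfig` (typically loaded from YAML) drives every
stage; all outputs are TSV files plus a JSON run manifest recording the
config hash, seed and package version, so repeated runs with the same
config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from liverdev import __version__, arraynorm, enrich, profiles, synthdata, tfsclass
from liverdev.design import COMPARISON_IDS, ExperimentDesign
from liverdev.synthdata import NoiseParams
from liverdev.tfsclass import Thresholds

log = logging.getLogger("liverdev")

FLOAT_FMT = "%.6g"


@dataclass
class SimulateConfig:
    n_probes: int = 2000
    n_redundant_genes: int = 40
    replicates_per_comparison: int = 2
    class_proportions: dict = field(
        default_factory=lambda: dict(synthdata.DEFAULT_CLASS_PROPORTIONS))
    effect_fold_range: tuple = (2.0, 4.0)


@dataclass
class StemConfig:
    m: int = 30
    c: int = 2
    B: int = 200
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "liverdev_out"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    noise: NoiseParams = field(default_factory=NoiseParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    lowess_span: float = 0.3
    stem: StemConfig = field(default_factory=StemConfig)
    input_dir: str | None = None  # pre-existing probe tables instead of simulating
    external_sets: dict = field(default_factory=dict)  # name -> gene-list path
    synthetic_external_sets: bool = True  # build demo external sets if none given

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulate" in d and d["simulate"] is not None:
            d["simulate"] = SimulateConfig(**d["simulate"])
        if "noise" in d and d["noise"] is not None:
            d["noise"] = NoiseParams(**d["noise"])
        if "thresholds" in d and d["thresholds"] is not None:
            d["thresholds"] = Thresholds(**d["thresholds"])
        if "stem" in d and d["stem"] is not None:
            d["stem"] = StemConfig(**d["stem"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, **kw)


def stage_simulate(cfg: PipelineConfig, outdir: Path):
    sim = cfg.simulate
    design = ExperimentDesign(
        n_probes=sim.n_probes,
        n_redundant_genes=sim.n_redundant_genes,
        replicates_per_comparison=sim.replicates_per_comparison,
        seed=cfg.seed,
    )
    truth = synthdata.generate_truth(
        design.n_genes, sim.class_proportions,
        tuple(sim.effect_fold_range), seed=cfg.seed,
    )
    arrays = synthdata.simulate_arrays(truth, design, cfg.noise)
    synthdata.write_simulation(arrays, truth, outdir / "simulated")
    log.info("simulate: %d probes, %d genes, %d arrays",
             design.n_probes, design.n_genes, len(arrays))
    return truth, arrays


def load_arrays(input_dir: Path) -> list[synthdata.ArrayData]:
    """Load probe tables per a design manifest (as written by simulate)."""
    manifest = pd.read_csv(input_dir / "design_manifest.tsv", sep="\t")
    arrays = []
    for _, row in manifest.iterrows():
        table = pd.read_csv(input_dir / row["file"], sep="\t")
        arrays.append(synthdata.ArrayData(
            comparison_id=row["comparison_id"],
            replicate=int(row["replicate"]),
            swapped=bool(row["dye_swapped"]),
            red_sample=row["red_sample"],
            green_sample=row["green_sample"],
            table=table,
        ))
    return arrays


def stage_normalize(cfg: PipelineConfig, arrays, outdir: Path):
    by_comp: dict[str, list] = {}
    for arr in arrays:
        by_comp.setdefault(arr.comparison_id, []).append(arr)
    summaries = arraynorm.summarize_experiment(
        by_comp, cfg.noise.sigma_add, cfg.noise.sigma_mult, span=cfg.lowess_span,
    )
    for cid, s in summaries.items():
        _write(s, outdir / "summaries" / f"{cid}.tsv", index=False)
        n_sig = int((s["p_value"] < cfg.thresholds.p_cut).sum())
        log.info("normalize %s: %d probes, %d at p < %g (expect %.1f by chance)",
                 cid, len(s), n_sig, cfg.thresholds.p_cut,
                 cfg.thresholds.p_cut * len(s))
    return summaries


def stage_classify(cfg: PipelineConfig, summaries, outdir: Path):
    probes = tfsclass.probe_table(summaries, cfg.thresholds)
    deduped = tfsclass.remove_redundant_probes(probes)
    master = tfsclass.classify_table(deduped, cfg.thresholds)
    counts = tfsclass.summarize_counts(master)
    _write(probes, outdir / "probes_all.tsv", index=False)
    _write(deduped, outdir / "probes_deduplicated.tsv", index=False)
    _write(master, outdir / "master_classification.tsv", index=False)
    for name, tbl in counts.items():
        _write(tbl, outdir / "counts" / f"{name}.tsv")
    log.info("classify: %d probes -> %d after redundancy removal; "
             "%d regulated genes",
             len(probes), len(deduped), int(master["regulated"].sum()))
    return deduped, master


def _ratio_matrix(deduped: pd.DataFrame, gene_ids) -> pd.DataFrame:
    cols = [f"ratio_{i}" for i in range(1, 8)]
    sub = deduped[deduped["gene_id"].isin(set(gene_ids))]
    mat = sub.set_index("probe_id")[cols]
    mat.columns = list(COMPARISON_IDS)
    return mat.dropna()


def stage_profiles(cfg: PipelineConfig, deduped, master, outdir: Path):
    reg = master[master["regulated"]]
    universes = {
        "sex_specific": reg.loc[reg["sex_class"] != "sex-independent", "gene_id"],
        "sex_independent": reg.loc[reg["sex_class"] == "sex-independent", "gene_id"],
    }
    candidates = profiles.enumerate_candidates(T=7, c=cfg.stem.c)
    model = profiles.select_model_profiles(candidates, cfg.stem.m)
    results = {}
    for name, genes in universes.items():
        mat = _ratio_matrix(deduped, genes)
        if len(mat) < 2:
            log.info("profiles %s: fewer than 2 genes, skipping", name)
            continue
        assign = profiles.assign_genes(mat, model)
        signif = profiles.profile_significance(
            assign, mat, model, B=cfg.stem.B, seed=cfg.seed,
            alpha=cfg.stem.alpha,
        )
        profile_tbl = pd.DataFrame(
            model, columns=[f"v{i}" for i in range(1, 8)])
        profile_tbl.insert(0, "profile_id", np.arange(len(model)))
        profile_tbl = profile_tbl.merge(signif, on="profile_id")
        _write(assign, outdir / "profiles" / f"{name}_assignments.tsv", index=False)
        _write(profile_tbl, outdir / "profiles" / f"{name}_profiles.tsv", index=False)
        box_rows = []
        for pid, grp in assign.groupby("profile_id"):
            if pid == profiles.FLAT_PROFILE:
                continue
            stats5 = profiles.profile_box_stats(mat.loc[grp["gene_id"]])
            stats5.insert(0, "profile_id", pid)
            box_rows.append(stats5.reset_index(names="comparison"))
        if box_rows:
            _write(pd.concat(box_rows, ignore_index=True),
                   outdir / "profiles" / f"{name}_box_stats.tsv", index=False)
        leaf_order, linkage = profiles.hierarchical_cluster(mat, axis="genes")
        _write(pd.DataFrame({"probe_id": leaf_order}),
               outdir / "profiles" / f"{name}_leaf_order.tsv", index=False)
        (outdir / "profiles" / f"{name}_tree.nwk").write_text(
            profiles.linkage_to_newick(linkage, list(mat.index)))
        results[name] = (assign, signif)
        log.info("profiles %s: %d genes, %d/%d significant profiles", name,
                 len(mat), int(signif["significant"].sum()), len(signif))
    return results


def _synthetic_external_sets(master: pd.DataFrame, seed: int):
    """Demo external regulation sets: each one enriched for a developmental
    set by mixing 60%% of it with random background genes."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(77,)))
    background = master["gene_id"].unique()
    reg = master[master["regulated"]]
    dev_sets = {
        "up_male_3to8": set(reg.loc[reg["dev_male_38"] == "U", "gene_id"]),
        "down_male_3to8": set(reg.loc[reg["dev_male_38"] == "D", "gene_id"]),
        "up_female_3to8": set(reg.loc[reg["dev_female_38"] == "U", "gene_id"]),
        "down_female_3to8": set(reg.loc[reg["dev_female_38"] == "D", "gene_id"]),
    }
    external = {}
    for name, genes in dev_sets.items():
        genes = sorted(genes)
        take = rng.choice(len(genes), size=int(0.6 * len(genes)), replace=False) \
            if genes else []
        rand = rng.choice(background, size=min(len(background), 200), replace=False)
        external[f"responders_like_{name}"] = \
            {genes[i] for i in take} | set(rand)
    return dev_sets, external


def stage_enrich(cfg: PipelineConfig, master, outdir: Path):
    reg = master[master["regulated"]]
    dev_sets = {
        "up_male_3to8": set(reg.loc[reg["dev_male_38"] == "U", "gene_id"]),
        "down_male_3to8": set(reg.loc[reg["dev_male_38"] == "D", "gene_id"]),
        "up_female_3to8": set(reg.loc[reg["dev_female_38"] == "U", "gene_id"]),
        "down_female_3to8": set(reg.loc[reg["dev_female_38"] == "D", "gene_id"]),
    }
    if cfg.external_sets:
        external = {name: enrich.read_gene_list(path)
                    for name, path in cfg.external_sets.items()}
    elif cfg.synthetic_external_sets:
        _, external = _synthetic_external_sets(master, cfg.seed)
    else:
        log.info("enrich: no external sets configured, skipping")
        return None
    background = set(master["gene_id"])
    table = enrich.enrichment_matrix(dev_sets, external, background)
    _write(table, outdir / "enrichment.tsv", index=False)
    log.info("enrich: %d tests, %d significant", len(table),
             int(table["significant"].sum()))
    return table


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the in-memory stage outputs."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.input_dir is not None:
        arrays = load_arrays(Path(cfg.input_dir))
        truth = None
    else:
        truth, arrays = stage_simulate(cfg, outdir)
    summaries = stage_normalize(cfg, arrays, outdir)
    deduped, master = stage_classify(cfg, summaries, outdir)
    profile_results = stage_profiles(cfg, deduped, master, outdir)
    enrichment = stage_enrich(cfg, master, outdir)
    manifest = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_arrays": len(arrays),
        "n_probes": int(len(arrays[0].table)),
        "n_regulated_genes": int(master["regulated"].sum()),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "truth": truth, "arrays": arrays, "summaries": summaries,
        "deduped": deduped, "master": master,
        "profiles": profile_results, "enrichment": enrichment,
        "manifest": manifest,
    }
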
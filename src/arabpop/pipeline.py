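"""Pipeline orchestration: flat validated configuration, stage execution
on synthetic inputs, structured logging and provenance echoing."""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from arabpop import __version__, qc, roh, structure
from arabpop import fstats as fstats_mod
from arabpop import imputeval as imp_mod
from arabpop import synthdata, ylineage
from arabpop.vcfio import write_qmatrix, write_vcf

ALL_STAGES = ("simulate", "qc", "structure", "fstats", "roh", "ylineage",
              "imputeval")

DEFAULTS: dict[str, dict] = {
    "simulate": {
        "k": 3, "n_sites": 24000, "chrom_mb": 25, "drift": 0.08,
        "group_size": 30, "missing_rate": 0.002, "roh_tracts_per_class": 10,
        "het_error": 0.002,
        "y_clusters": 4, "y_cluster_size": 12, "y_depth_years": 12000.0,
        "y_mu": 0.76e-9, "y_region_bp": 10_000_000,
    },
    "qc": {
        "max_missingness": 0.01, "mac_min": 3, "hwe_p": 1e-5,
        "sample_missingness_max": 0.05, "per_chrom_missingness_max": 0.20,
        "sd_multiplier": 3.0,
    },
    "structure": {
        "ld_r2_max": 0.2, "ld_window": 50, "ld_step": 5,
        "n_components": 5, "dominant_threshold": 0.5,
    },
    "fstats": {"block_size_bp": 5_000_000, "z_threshold": -3.0},
    "roh": {
        "het_emission_error": 1e-3, "expected_az_bp": 1_000_000.0,
        "expected_hw_bp": 10_000_000.0, "min_quality": 50.0,
    },
    "ylineage": {
        "min_support": 0.9, "large_min": 10,
        "grid": [1e-5, 5e-5, 1e-4, 5e-4, 1e-3, 4e-3],
        "mu": 0.76e-9, "region_bp": 10_000_000, "years_per_generation": 30.0,
    },
    "imputeval": {
        "n_ref": 20, "n_target": 8, "array_fraction": 0.3,
        "n_permutations": 5, "quality_min": 0.5,
    },
}


@dataclass
class PipelineConfig:
    seed: int = 0
    out: str = "arabpop_out"
    stages: tuple = ALL_STAGES
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {}
        for mod, defaults in DEFAULTS.items():
            given = self.params.get(mod, {})
            unknown = set(given) - set(defaults)
            if unknown:
                raise ValueError(f"unknown config keys in [{mod}]: {sorted(unknown)}")
            merged[mod] = {**defaults, **given}
        unknown_mods = set(self.params) - set(DEFAULTS)
        if unknown_mods:
            raise ValueError(f"unknown config sections: {sorted(unknown_mods)}")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        self.params = merged

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        top = {k: raw.pop(k) for k in ("seed", "out", "stages") if k in raw}
        if "stages" in top:
            top["stages"] = tuple(top["stages"])
        return cls(params=raw, **top)

    def echo(self, outdir: str) -> None:
        doc = {"seed": self.seed, "out": self.out,
               "stages": list(self.stages), **self.params}
        with open(os.path.join(outdir, "config_echo.yaml"), "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


class _RunLog:
    def __init__(self, path: str):
        self.path = path
        self.records: list[dict] = []

    def log(self, stage: str, level: str = "INFO", **fields) -> None:
        rec = {"stage": stage, "level": level, "time": round(time.time(), 3),
               **fields}
        self.records.append(rec)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> str:
    """Execute the configured stages on a synthetic cohort; returns outdir.

    Stage failures raise with the stage name; artifacts written before the
    failure are retained.
    """
    outdir = config.out
    os.makedirs(outdir, exist_ok=True)
    config.echo(outdir)
    log = _RunLog(os.path.join(outdir, "run_log.jsonl"))
    log.log("pipeline", version=__version__, seed=config.seed,
            stages=list(config.stages))
    state: dict = {}
    for stage in config.stages:
        t0 = time.time()
        try:
            _STAGE_FNS[stage](config, state, outdir, log)
        except Exception as exc:
            log.log(stage, level="ERROR", error=str(exc))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        log.log(stage, seconds=round(time.time() - t0, 2))
    return outdir


def _stage_simulate(cfg: PipelineConfig, st: dict, outdir: str, log) -> None:
    p = cfg.params["simulate"]
    lengths = {"1": p["chrom_mb"] * 1_000_000, "2": p["chrom_mb"] * 1_000_000}
    model = synthdata.AncestralModel.uniform(
        K=p["k"], n_sites=p["n_sites"], drift=p["drift"], seed=cfg.seed,
        chrom_lengths=lengths)
    spec = synthdata.AdmixSpec.unadmixed(
        {f"POP{g}": p["group_size"] for g in range(p["k"])}, K=p["k"])
    cohort = synthdata.simulate_admixed_cohort(model, spec,
                                               missing_rate=p["missing_rate"])
    tracts = [synthdata.TractClass("short", p["roh_tracts_per_class"], (300_000, 700_000)),
              synthdata.TractClass("medium", p["roh_tracts_per_class"], (1_000_000, 2_500_000)),
              synthdata.TractClass("long", p["roh_tracts_per_class"], (4_000_000, 9_000_000))]
    cohort = synthdata.plant_roh(cohort, tracts, het_error=p["het_error"])
    cohort.write(os.path.join(outdir, "simulate"))
    st["cohort"] = cohort
    st["ylocus"] = synthdata.simulate_y_locus(
        n_clusters=p["y_clusters"], sizes=p["y_cluster_size"], mu=p["y_mu"],
        region_len_bp=p["y_region_bp"], depth_years=p["y_depth_years"],
        seed=cfg.seed)
    st["ylocus"].write(os.path.join(outdir, "simulate"))
    log.log("simulate", n_samples=cohort.genotypes.n_samples,
            n_sites=cohort.genotypes.n_sites,
            n_planted_roh=len(cohort.true_roh))


def _stage_qc(cfg: PipelineConfig, st: dict, outdir: str, log) -> None:
    p = cfg.params["qc"]
    gm = st["cohort"].genotypes
    report, retained = qc.sample_qc(
        gm, total_missingness_max=p["sample_missingness_max"],
        per_chrom_missingness_max=p["per_chrom_missingness_max"],
        sd_multiplier=p["sd_multiplier"])
    keep_idx = [i for i, s in enumerate(gm.samples) if s in set(retained)]
    gm2 = gm.take_samples(keep_idx)
    spec = qc.VariantFilterSpec(max_missingness=p["max_missingness"],
                                min_minor_allele_count=p["mac_min"],
                                hwe_p_threshold=p["hwe_p"])
    clean, counts = qc.variant_filter(gm2, spec)
    d = os.path.join(outdir, "qc")
    os.makedirs(d, exist_ok=True)
    report.table.to_csv(os.path.join(d, "sample_qc.tsv"), sep="\t", index=False)
    write_vcf(clean, os.path.join(d, "clean.vcf"))
    st["clean"] = clean
    log.log("qc", samples_in=gm.n_samples, samples_retained=len(retained),
            sites_in=gm2.n_sites, sites_retained=clean.n_sites,
            exclusions=counts)


def _stage_structure(cfg: PipelineConfig, st: dict, outdir: str, log) -> None:
    p = cfg.params["structure"]
    gm = st["clean"]
    kept = structure.ld_prune(gm, r2_max=p["ld_r2_max"],
                              window_snps=p["ld_window"], step_snps=p["ld_step"])
    pruned = gm.take_sites(kept)
    res = structure.pca(pruned, n_components=p["n_components"])
    assign = structure.assign_dominant_ancestry(
        st["cohort"].true_Q, threshold=p["dominant_threshold"])
    d = os.path.join(outdir, "structure")
    os.makedirs(d, exist_ok=True)
    import pandas as pd
    pd.DataFrame(res.scores,
                 columns=[f"PC{k+1}" for k in range(res.scores.shape[1])]) \
        .assign(sample=gm.samples).to_csv(os.path.join(d, "pca_scores.tsv"),
                                          sep="\t", index=False)
    assign.to_frame().to_csv(os.path.join(d, "ancestry_assignment.tsv"),
                             sep="\t", index=False)
    write_qmatrix(st["cohort"].true_Q, os.path.join(d, "qmatrix.tsv"))
    st["pruned"] = pruned
    log.log("structure", sites_pruned_in=gm.n_sites, sites_kept=len(kept),
            threshold=p["dominant_threshold"])


def _stage_fstats(cfg: PipelineConfig, st: dict, outdir: str, log) -> None:
    p = cfg.params["fstats"]
    gm = st["clean"]
    pops = st["cohort"].genotypes.populations
    labels = {s: pops[i] for i, s in enumerate(st["cohort"].genotypes.samples)
              if s in set(gm.samples)}
    table = fstats_mod.SiteFrequencyTable.from_genotypes(gm, labels)
    names = table.populations
    import pandas as pd
    rows = []
    for i, p1 in enumerate(names):
        for p2 in names[i + 1:]:
            mean_fst, _ = fstats_mod.fst_pairwise(table, p1, p2)
            rows.append((p1, p2, mean_fst))
    f3_rows = []
    results = []
    for c in names:
        donors = [x for x in names if x != c]
        for i, a in enumerate(donors):
            for b in donors[i + 1:]:
                res = fstats_mod.f3_statistic(table, a, b, c,
                                              block_size_bp=p["block_size_bp"])
                results.append(res)
                f3_rows.append((a, b, c, res.statistic, res.se, res.z,
                                res.n_blocks, res.n_sites_used))
    nets = fstats_mod.build_admixture_network(results,
                                              z_threshold=p["z_threshold"])
    d = os.path.join(outdir, "fstats")
    os.makedirs(d, exist_ok=True)
    pd.DataFrame(rows, columns=["pop1", "pop2", "hudson_fst"]) \
        .to_csv(os.path.join(d, "fst.tsv"), sep="\t", index=False)
    pd.DataFrame(f3_rows, columns=["A", "B", "C", "f3", "se", "z", "blocks",
                                   "sites"]) \
        .to_csv(os.path.join(d, "f3.tsv"), sep="\t", index=False)
    edges = pd.concat([n.to_frame() for n in nets.values()]) if nets \
        else pd.DataFrame(columns=["donor_a", "donor_b", "z", "target"])
    edges.to_csv(os.path.join(d, "admixture_network.tsv"), sep="\t", index=False)
    log.log("fstats", n_f3=len(f3_rows), n_network_edges=int(len(edges)))


def _stage_roh(cfg: PipelineConfig, st: dict, outdir: str, log) -> None:
    p = cfg.params["roh"]
    gm = st["cohort"].genotypes
    params = roh.ROHParams(het_emission_error=p["het_emission_error"],
                           expected_az_bp=p["expected_az_bp"],
                           expected_hw_bp=p["expected_hw_bp"],
                           min_quality=p["min_quality"])
    segments = roh.call_roh(gm, params)
    labels = dict(zip(gm.samples, gm.populations)) \
        if gm.populations is not None else {}
    models = roh.fit_roh_classes(segments, labels)
    finb = roh.inbreeding_f(gm)
    summary = roh.roh_summaries(segments, gene_bed=[])
    d = os.path.join(outdir, "roh")
    os.makedirs(d, exist_ok=True)
    roh.segments_to_frame(segments).to_csv(os.path.join(d, "segments.tsv"),
                                           sep="\t", index=False)
    finb.table.to_csv(os.path.join(d, "inbreeding.tsv"), sep="\t", index=False)
    summary.to_csv(os.path.join(d, "summary.tsv"), sep="\t", index=False)
    log.log("roh", n_segments=len(segments), n_models=len(models))


def _stage_ylineage(cfg: PipelineConfig, st: dict, outdir: str, log) -> None:
    p = cfg.params["ylineage"]
    sim = st["ylocus"]
    stree = ylineage.SupportTree.from_newick(sim.newick)
    collapsed = ylineage.collapse_low_support(stree, min_support=p["min_support"])
    cutoff, tally = ylineage.scan_cutoffs(collapsed, p["grid"],
                                          large_min=p["large_min"])
    clusters, _ = ylineage.pick_clusters(collapsed, cutoff)
    _, haplogroups = ylineage.informative_snps(sim.haplotypes, clusters)
    ylineage.date_lineages(haplogroups, mu=p["mu"], L=p["region_bp"],
                           seed=cfg.seed)
    d = os.path.join(outdir, "ylineage")
    os.makedirs(d, exist_ok=True)
    tally.to_csv(os.path.join(d, "cutoff_tally.tsv"), sep="\t", index=False)
    ylineage.haplogroup_report(haplogroups) \
        .to_csv(os.path.join(d, "haplogroups.tsv"), sep="\t", index=False)
    log.log("ylineage", chosen_cutoff=cutoff, n_clusters=len(clusters),
            n_haplogroups=len(haplogroups))


def _stage_imputeval(cfg: PipelineConfig, st: dict, outdir: str, log) -> None:
    p = cfg.params["imputeval"]
    cohort = st["cohort"]
    d = os.path.join(outdir, "imputeval")
    os.makedirs(d, exist_ok=True)
    sat = imp_mod.saturation_curve(cohort.genotypes,
                                   n_permutations=p["n_permutations"],
                                   seed=cfg.seed)
    ref_path, tgt_path, man_path = synthdata.make_panel_pair(
        cohort, n_ref=p["n_ref"], n_target=p["n_target"],
        array_fraction=p["array_fraction"], outdir=d)
    from arabpop.vcfio import read_manifest, read_vcf
    panel = read_vcf(ref_path)
    truth = read_vcf(tgt_path)
    manifest = read_manifest(man_path)
    pseudo, typed, withheld, _ = imp_mod.make_pseudo_array(truth, manifest)
    dos, qual = imp_mod.impute_naive(pseudo, panel, typed, withheld,
                                     method="nearest_haplotype")
    table = imp_mod.aggregate_r2(truth, dos, withheld, panel=panel,
                                 quality=qual, quality_min=p["quality_min"])
    import pandas as pd
    pd.DataFrame({"k": np.arange(1, len(sat.mean_curve) + 1),
                  "mean_sites": sat.mean_curve}) \
        .to_csv(os.path.join(d, "saturation.tsv"), sep="\t", index=False)
    table.to_csv(os.path.join(d, "aggregate_r2.tsv"), sep="\t", index=False)
    log.log("imputeval", growth_per_100=sat.growth_per_100,
            n_withheld=int(len(withheld)))


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "structure": _stage_structure,
    "fstats": _stage_fstats,
    "roh": _stage_roh,
    "ylineage": _stage_ylineage,
    "imputeval": _stage_imputeval,
}
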
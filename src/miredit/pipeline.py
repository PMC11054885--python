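"""End-to-end orchestration: simulate -> filter -> align -> call ->
characterize -> differential -> retarget -> enrich -> summarize.

Every stage reads the previous stage's artifact and writes its own
into the run directory; a manifest records the seed and parameters so
a run is reproducible byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .caller import (
    CallerParams,
    build_pileup,
    call_sites,
    pool_pileups,
    quantify_levels,
    site_counts_long,
    sites_to_table,
    write_site_table,
)
from .characterize import (
    background_contexts,
    cluster_trajectories,
    conservation_match,
    extract_context,
    extract_flank,
    flank_preference,
    matches_to_table,
)
from .differential import pairwise_differential, select_seed_differential
from .enrich import PathwayCollection, compare_wt_et_pathways, hypergeom_enrich
from .io import read_fasta, read_gmt, read_snp_positions, write_fastq
from .preprocess import ReadFilterParams, align_unique, filter_reads
from .retarget import ScanParams, apply_edit, diff_target_sets, hits_to_table, scan_targets, wildtype_variant
from .simulate import SimConfig, generate_downstream_fixtures, generate_reference, make_planted_sites, simulate_reads

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "miredit_run"
    rng_seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    read_filter: ReadFilterParams = field(default_factory=ReadFilterParams)
    caller: CallerParams = field(default_factory=CallerParams)
    diff_alpha: float = 0.05
    cluster_c: int = 4
    cluster_m: float = 1.25
    conservation_evalue: float = 1e-3
    conservation_identity: float = 85.0
    scan: ScanParams = field(default_factory=ScanParams)
    enrich_alpha: float = 0.05
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # one seed drives every stage
        self.sim.rng_seed = self.rng_seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, sub_cls in (("sim", SimConfig), ("read_filter", ReadFilterParams), ("caller", CallerParams), ("scan", ScanParams)):
            if key in kwargs and isinstance(kwargs[key], dict):
                block = dict(kwargs[key])
                for tuple_field in ("hairpin_len_range", "mature_len_range", "stages", "phred_values", "phred_probs"):
                    if tuple_field in block and isinstance(block[tuple_field], list):
                        block[tuple_field] = tuple(block[tuple_field])
                kwargs[key] = sub_cls(**block)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, default_flow_style=False)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the artifact paths and key tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    artifacts: dict = {"out_dir": out}

    # -- simulate -------------------------------------------------------
    logger.info("stage simulate")
    ref = generate_reference(config.sim)
    ref.save(out / "hairpins.fa", out / "matures.gff3")
    sites_truth = make_planted_sites(ref, config.sim)
    reads, truth, read_counts = simulate_reads(ref, sites_truth, config.sim)
    truth.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    read_counts.to_csv(out / "truth_read_counts.tsv", sep="\t", index=False)
    for sample, rds in reads.items():
        write_fastq(out / f"{sample}.fastq", rds)
    fixtures = generate_downstream_fixtures(ref, sites_truth, config.sim, out)
    sample_stages = {sample: stage for stage, sample in config.sim.samples}
    artifacts["reference"] = ref
    artifacts["fixtures"] = fixtures
    artifacts["truth"] = truth

    # -- filter + align -------------------------------------------------
    logger.info("stage filter/align")
    pileups = {}
    qc_rows = []
    for sample, rds in reads.items():
        kept, report = filter_reads(rds, config.read_filter)
        qc_rows.append({"sample": sample, "total": report.total, "kept": report.kept, **report.removed})
        alns = align_unique(kept, ref, trim3=config.read_filter.trim3)
        pileups[sample] = build_pileup(alns, ref, q_min=config.caller.q_min)
    pd.DataFrame(qc_rows).to_csv(out / "qc_report.tsv", sep="\t", index=False)

    # -- call -----------------------------------------------------------
    logger.info("stage call")
    snps = read_snp_positions(fixtures["snp_vcf"])
    called = call_sites(pileups, ref, config.caller, snps, sample_stages)
    called = quantify_levels(called, sample_stages)
    stages = list(config.sim.stages)
    write_site_table(out / "editing_sites.tsv", called, stages)
    artifacts["sites"] = called

    # -- characterize ---------------------------------------------------
    logger.info("stage characterize")
    pooled = pool_pileups(pileups)
    called_pos = {(s.hairpin_id, s.position) for s in called}
    flank_tables = []
    for etype in sorted({s.editing_type for s in called}):
        e_sites = [s for s in called if s.editing_type == etype]
        contexts = [extract_context(ref, s.hairpin_id, s.position) for s in e_sites]
        bg = background_contexts(ref, pooled, called_pos, e_sites[0].ref, config.caller.min_coverage)
        if not bg:
            logger.warning("no background positions for %s; skipping flank profile", etype)
            continue
        tab = flank_preference(contexts, bg)
        tab.insert(0, "editing_type", etype)
        flank_tables.append(tab)
    if flank_tables:
        pd.concat(flank_tables).to_csv(out / "flank_profiles.tsv", sep="\t", index=False)

    traj = pd.DataFrame(
        {stage: [s.stage_levels.get(stage, np.nan) for s in called] for stage in stages},
        index=[s.site_id for s in called],
    ).dropna()
    clustering = None
    c_eff = min(config.cluster_c, max(1, int((traj.var(axis=1, ddof=0) > 0).sum())))
    if len(traj) >= c_eff and c_eff >= 1 and len(traj) > 0:
        try:
            clustering = cluster_trajectories(traj, c=c_eff, m=config.cluster_m, rng_seed=config.rng_seed)
            clustering.memberships.assign(label=clustering.labels).to_csv(
                out / "trajectory_clusters.tsv", sep="\t"
            )
        except ValueError as exc:
            logger.warning("trajectory clustering skipped: %s", exc)
    artifacts["clustering"] = clustering

    site_db = pd.read_csv(fixtures["conservation_db"], sep="\t")
    queries = {s.site_id: extract_flank(ref, s.hairpin_id, s.position) for s in called}
    matches = conservation_match(
        queries, site_db, config.conservation_evalue, config.conservation_identity
    )
    matches_to_table(matches).to_csv(out / "conservation.tsv", sep="\t", index=False)
    artifacts["conservation"] = matches

    # -- differential ---------------------------------------------------
    logger.info("stage differential")
    counts = site_counts_long(called, sample_stages)
    diff = pairwise_differential(counts, stages, alpha=config.diff_alpha) if len(counts) else pd.DataFrame()
    diff.to_csv(out / "differential.tsv", sep="\t", index=False)
    site_table = sites_to_table(called, stages)
    seed_table = select_seed_differential(diff, site_table, alpha=config.diff_alpha)
    seed_table.to_csv(out / "seed_differential.tsv", sep="\t", index=False)
    artifacts["differential"] = diff
    artifacts["seed_table"] = seed_table

    # -- retarget + enrich ---------------------------------------------
    logger.info("stage retarget/enrich")
    utrs = read_fasta(fixtures["utr_fasta"])
    pathways = read_gmt(fixtures["gmt"])
    collection = PathwayCollection(pathways, set(utrs))
    gainloss_rows = []
    enrich_written = False
    seed_sites = [s for s in called if s.seed]
    # evaluate the designed focal site first so the planted pathway
    # gain/loss is measured on the variant the UTRs were built around
    focal = fixtures["focal_site"]
    seed_sites.sort(key=lambda s: (s.hairpin_id, s.position) != (focal.hairpin_id, focal.position))
    for site in seed_sites:
        ann = ref.mature_by_id(site.mature_id)
        mature = ref.mature_seq(ann)
        wt = wildtype_variant(site.mature_id, mature)
        et = apply_edit(site.mature_id, mature, site.mature_position, site.ref, site.alt)
        wt_set = scan_targets(wt, utrs, config.scan)
        et_set = scan_targets(et, utrs, config.scan)
        summary = diff_target_sets(wt_set, et_set)
        gainloss_rows.append(
            {
                "variant": et.tag,
                "n_wt": summary["n_wt"],
                "n_et": summary["n_et"],
                "n_shared": summary["n_shared"],
                "n_lost": summary["n_lost"],
                "n_gained": summary["n_gained"],
            }
        )
        if not enrich_written:
            pd.concat([hits_to_table(wt_set), hits_to_table(et_set)]).to_csv(
                out / "target_hits.tsv", sep="\t", index=False
            )
            wt_rows = hypergeom_enrich(wt_set.genes, collection, config.enrich_alpha)
            et_rows = hypergeom_enrich(et_set.genes, collection, config.enrich_alpha)
            wt_rows.to_csv(out / "enrichment_wt.tsv", sep="\t", index=False)
            et_rows.to_csv(out / "enrichment_et.tsv", sep="\t", index=False)
            cmp_res = compare_wt_et_pathways(wt_rows, et_rows)
            pd.DataFrame(
                [{"change": chg, "pathway": p} for chg in ("lost", "gained", "shared") for p in sorted(cmp_res[chg])]
            ).to_csv(out / "pathway_gain_loss.tsv", sep="\t", index=False)
            artifacts["pathway_comparison"] = cmp_res
            enrich_written = True
    pd.DataFrame(gainloss_rows).to_csv(out / "target_gain_loss.tsv", sep="\t", index=False)
    artifacts["target_gain_loss"] = pd.DataFrame(gainloss_rows)

    # -- summary + manifest ---------------------------------------------
    summary = summarize_sites(site_table, diff)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    manifest = {
        "package": "miredit",
        "version": __version__,
        "rng_seed": config.rng_seed,
        "config": asdict(config),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    artifacts["summary"] = summary
    return artifacts


def summarize_sites(site_table: pd.DataFrame, differential: pd.DataFrame | None = None) -> dict:
    """Count summaries: sites per editing type, seed/non-seed split, and
    the per-pair-count histogram of differential significance."""
    summary: dict = {"n_sites": int(len(site_table))}
    if site_table.empty:
        logger.warning("empty site table; empty summary")
        summary.update({"by_editing_type": {}, "seed_sites": 0, "non_seed_sites": 0, "pair_count_histogram": {}})
        return summary
    summary["by_editing_type"] = site_table["editing_type"].value_counts().to_dict()
    if "seed" in site_table.columns:
        seed = site_table["seed"].astype(bool)
        summary["seed_sites"] = int(seed.sum())
        summary["non_seed_sites"] = int((~seed).sum())
    if differential is not None and not differential.empty and "pvalue" in differential.columns:
        sig = differential[differential["pvalue"] < 0.05]
        per_site = sig.groupby("site_id").size()
        hist = per_site.value_counts().sort_index()
        summary["n_differential_sites"] = int(per_site.size)
        summary["pair_count_histogram"] = {int(k): int(v) for k, v in hist.items()}
    return summary
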
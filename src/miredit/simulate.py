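"""Synthetic small RNA-seq data with planted miRNA-editing truth.

Emulates a 4-stage x 3-replicate porcine adipose development design
(stages N30D/N90D/N150D/N210D, replicates F1-F3): a random hairpin
reference with annotated mature arms, per-sample FASTQ reads drawn from
the mature sequences with planted editing sites at stage-dependent
levels, phred-scored sequencing errors, 3' non-templated A/U additions,
and SNP decoys — plus the downstream fixtures (3'UTRs, pathway sets,
SNP file, conservation database) every later stage needs.

Editing is applied per read as an independent Bernoulli draw at the
planted level, matching the binomial sampling model the caller assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import FastqRead, MatureAnnotation, revcomp, write_fasta, write_gmt, write_vcf
from .reference import HairpinReference, seed_flag

BASES = np.array(list("ACGT"))

#: default per-base quality distribution; 10% of mass below Q30 so the
#: quality filters downstream have something to remove.
DEFAULT_PHRED_VALUES = (40, 38, 36, 33, 25, 20)
DEFAULT_PHRED_PROBS = (0.40, 0.25, 0.15, 0.10, 0.06, 0.04)


@dataclass
class SimConfig:
    n_hairpins: int = 30
    hairpin_len_range: tuple[int, int] = (70, 110)
    mature_len_range: tuple[int, int] = (20, 24)
    stages: tuple[str, ...] = ("N30D", "N90D", "N150D", "N210D")
    replicates_per_stage: int = 3
    reads_per_mature: float = 300.0
    seq_error_rate: float = 0.001
    phred_values: tuple[int, ...] = DEFAULT_PHRED_VALUES
    phred_probs: tuple[float, ...] = DEFAULT_PHRED_PROBS
    nta_prob: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ValueError("need at least 2 stages")
        if self.mature_len_range[1] > self.hairpin_len_range[0]:
            raise ValueError("mature length may exceed hairpin length")
        for p in (self.seq_error_rate, self.nta_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        if abs(sum(self.phred_probs) - 1.0) > 1e-9:
            raise ValueError("phred_probs must sum to 1")

    @property
    def samples(self) -> list[tuple[str, str]]:
        """(stage, sample name) pairs, e.g. ('N30D', 'N30D_F1')."""
        return [
            (stage, f"{stage}_F{r}")
            for stage in self.stages
            for r in range(1, self.replicates_per_stage + 1)
        ]


@dataclass
class PlantedSite:
    """Ground truth for one planted editing site (or SNP decoy)."""

    hairpin_id: str
    position: int  # 1-based on hairpin
    ref: str
    alt: str
    stage_levels: dict[str, float] = field(default_factory=dict)
    is_snp_decoy: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt base must differ")
        for lv in self.stage_levels.values():
            if not 0.0 <= lv <= 1.0:
                raise ValueError(f"editing level {lv} outside [0,1]")

    @property
    def site_id(self) -> str:
        return f"{self.hairpin_id}:{self.position}:{self.ref}>{self.alt}"


# ---------------------------------------------------------------------------
# reference generation


def generate_reference(config: SimConfig) -> HairpinReference:
    """Random hairpin reference with one mature arm per hairpin.

    Hairpin bases are i.i.d. uniform; each mature arm is resampled until
    none of its 13-mers occurs anywhere else in the reference, so a
    mature-derived read maps uniquely even with one mismatch allowed.
    """
    rng = np.random.default_rng(config.rng_seed)
    sequences: dict[str, str] = {}
    annotations: list[MatureAnnotation] = []
    seen_kmers: set[str] = set()
    k = 13

    for i in range(config.n_hairpins):
        hp_id = f"hp{i + 1:04d}"
        for _attempt in range(200):
            hp_len = int(rng.integers(config.hairpin_len_range[0], config.hairpin_len_range[1] + 1))
            seq = "".join(rng.choice(BASES, size=hp_len))
            m_len = int(rng.integers(config.mature_len_range[0], config.mature_len_range[1] + 1))
            # arm sits on the 5p or 3p side of the hairpin
            if rng.random() < 0.5:
                start = int(rng.integers(1, max(2, hp_len // 2 - m_len)))
                arm = "5p"
            else:
                start = int(rng.integers(hp_len // 2, hp_len - m_len + 2))
                arm = "3p"
            end = start + m_len - 1
            mature = seq[start - 1 : end]
            kmers = {mature[j : j + k] for j in range(len(mature) - k + 1)}
            if kmers & seen_kmers:
                continue
            seen_kmers |= kmers
            sequences[hp_id] = seq
            annotations.append(
                MatureAnnotation(hp_id, f"mir-{i + 1:04d}-{arm}", start, end)
            )
            break
        else:  # pragma: no cover
            raise RuntimeError("could not place a unique mature arm; reference too dense")

    return HairpinReference(sequences, annotations)


def make_planted_sites(
    ref: HairpinReference,
    config: SimConfig,
    n_edit: int | None = None,
    n_decoys: int | None = None,
    level_profiles: tuple[tuple[float, ...], ...] | None = None,
    seed_region_fraction: float = 0.5,
) -> list[PlantedSite]:
    """Plant editing sites on mature arms with stage-dependent levels.

    Defaults scale with the reference: one edited site per three mature
    arms and one SNP decoy per ten. ``level_profiles`` are per-stage
    level vectors cycled over sites; defaults cover rising, falling and
    peaked trajectories so both the differential test and the
    trajectory clustering see real signal. SNP decoys get a
    stage-constant level of 0.5 (heterozygote-like).
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    if n_edit is None:
        n_edit = max(1, len(ref.annotations) // 3)
    if n_decoys is None:
        n_decoys = max(1, len(ref.annotations) // 10)
    n_stages = len(config.stages)
    if level_profiles is None:
        level_profiles = (
            tuple(np.linspace(0.05, 0.5, n_stages)),
            tuple(np.linspace(0.5, 0.05, n_stages)),
            tuple(0.05 + 0.45 * np.sin(np.linspace(0, np.pi, n_stages))),
            (0.3,) * n_stages,
        )
    anns = list(ref.annotations)
    rng.shuffle(anns)
    sites: list[PlantedSite] = []
    used: set[tuple[str, int]] = set()
    total = n_edit + n_decoys
    if total > len(anns):
        raise ValueError("more planted sites than mature arms")
    for j in range(total):
        ann = anns[j]
        mature = ref.mature_seq(ann)
        n_seed = max(1, int(round(seed_region_fraction * n_edit)))
        in_seed = j < n_seed and j < n_edit
        lo, hi = (2, min(8, len(mature))) if in_seed else (9, len(mature) - 2)
        mpos = int(rng.integers(lo, hi + 1))
        hp_pos = ann.start + mpos - 1
        if (ann.hairpin_id, hp_pos) in used:  # pragma: no cover
            continue
        used.add((ann.hairpin_id, hp_pos))
        ref_base = ref.sequences[ann.hairpin_id][hp_pos - 1]
        # prefer the canonical A-to-G / C-to-U substitutions where possible
        alt = {"A": "G", "C": "T", "T": "C", "G": "T"}[ref_base]
        if j < n_edit:
            profile = level_profiles[j % len(level_profiles)]
            levels = {s: float(profile[i]) for i, s in enumerate(config.stages)}
            sites.append(PlantedSite(ann.hairpin_id, hp_pos, ref_base, alt, levels))
        else:
            levels = {s: 0.5 for s in config.stages}
            sites.append(
                PlantedSite(ann.hairpin_id, hp_pos, ref_base, alt, levels, is_snp_decoy=True)
            )
    return sites


# ---------------------------------------------------------------------------
# read simulation


def _draw_quals(rng, n, values, probs, min_q=None):
    values = np.asarray(values)
    probs = np.asarray(probs, dtype=float)
    if min_q is not None:
        keep = values >= min_q
        values, probs = values[keep], probs[keep] / probs[keep].sum()
    return rng.choice(values, size=n, p=probs)


def simulate_reads(
    ref: HairpinReference,
    sites: list[PlantedSite],
    config: SimConfig,
) -> tuple[dict[str, list[FastqRead]], pd.DataFrame, pd.DataFrame]:
    """Draw per-sample reads from the mature arms with planted edits.

    Returns (reads per sample, per-site truth table, per-arm read counts).
    Each read covering a planted site carries the alt base with
    probability equal to that site's level at the sample's stage;
    sequencing errors are added per base at ``seq_error_rate`` with
    qualities drawn from the phred profile (correct bases are drawn from
    the profile's Q>=30 part). With probability ``nta_prob`` a read gains
    a 1-2 nt non-templated A/U tail.
    """
    rng = np.random.default_rng(config.rng_seed + 2)
    site_by_arm: dict[str, list[tuple[int, PlantedSite]]] = {}
    for s in sites:
        loc = ref.locate_in_mature(s.hairpin_id, s.position)
        if loc is None:
            raise ValueError(
                f"planted site {s.site_id} lies outside every mature arm; "
                "the caller could never observe it"
            )
        mature_id, mpos = loc
        if ref.sequences[s.hairpin_id][s.position - 1] != s.ref:
            raise ValueError(f"planted ref base mismatch at {s.site_id}")
        site_by_arm.setdefault(mature_id, []).append((mpos, s))

    reads: dict[str, list[FastqRead]] = {}
    truth_rows = []
    count_rows = []
    for stage, sample in config.samples:
        sample_reads: list[FastqRead] = []
        for ann in ref.annotations:
            mature = ref.mature_seq(ann)
            n_reads = int(rng.poisson(config.reads_per_mature))
            arm_sites = site_by_arm.get(ann.mature_id, [])
            site_edit_counts = {mpos: 0 for mpos, _ in arm_sites}
            for ridx in range(n_reads):
                seq = np.array(list(mature))
                for mpos, site in arm_sites:
                    if rng.random() < site.stage_levels.get(stage, 0.0):
                        seq[mpos - 1] = site.alt
                        site_edit_counts[mpos] += 1
                qual = _draw_quals(rng, len(seq), config.phred_values, config.phred_probs, min_q=30)
                # per-base sequencing errors, qualities from the full profile
                err_mask = rng.random(len(seq)) < config.seq_error_rate
                for j in np.flatnonzero(err_mask):
                    choices = BASES[BASES != seq[j]]
                    seq[j] = rng.choice(choices)
                    qual[j] = _draw_quals(rng, 1, config.phred_values, config.phred_probs)[0]
                seq_str = "".join(seq)
                if rng.random() < config.nta_prob:
                    tail_len = int(rng.integers(1, 3))
                    tail = "".join(rng.choice(np.array(["A", "T"]), size=tail_len))
                    seq_str += tail
                    qual = np.concatenate(
                        [qual, _draw_quals(rng, tail_len, config.phred_values, config.phred_probs, min_q=30)]
                    )
                sample_reads.append(
                    FastqRead(f"{sample}:{ann.mature_id}:{ridx}", seq_str, [int(q) for q in qual])
                )
            count_rows.append(
                {"sample": sample, "stage": stage, "mature": ann.mature_id, "n_reads": n_reads}
            )
            for mpos, site in arm_sites:
                truth_rows.append(
                    {
                        "site_id": site.site_id,
                        "hairpin": site.hairpin_id,
                        "position": site.position,
                        "ref": site.ref,
                        "alt": site.alt,
                        "mature": ann.mature_id,
                        "mature_position": mpos,
                        "seed": seed_flag(mpos),
                        "is_snp_decoy": site.is_snp_decoy,
                        "sample": sample,
                        "stage": stage,
                        "planted_level": site.stage_levels.get(stage, 0.0),
                        "edited_reads": site_edit_counts[mpos],
                        "total_reads": n_reads,
                    }
                )
        reads[sample] = sample_reads
    return reads, pd.DataFrame(truth_rows), pd.DataFrame(count_rows)


# ---------------------------------------------------------------------------
# downstream fixtures: UTRs, pathways, SNP file, conservation database


def generate_downstream_fixtures(
    ref: HairpinReference,
    sites: list[PlantedSite],
    config: SimConfig,
    out_dir: str | Path,
    n_genes: int = 60,
    utr_len: int = 300,
) -> dict:
    """Write the 3'UTR FASTA, GMT pathways, SNP VCF and conservation TSV.

    UTRs carry designed perfect 8mer complements of the wild-type and/or
    edited seed of the first seed-region planted site, so the retargeting
    stage has a known gain/loss answer; one pathway is stacked with the
    designed ET-only genes so enrichment has a planted pathway gain.
    Returns the paths plus the designed truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed + 3)

    snp_path = out_dir / "known_snps.vcf"
    write_vcf(
        snp_path,
        [(s.hairpin_id, s.position, s.ref, s.alt) for s in sites if s.is_snp_decoy],
    )

    # pick the designed seed-region edit to build WT/ET seeds; prefer
    # positions 2-7, where an edit changes every canonical match class
    # (a position-8 edit leaves the 6mer intact)
    focal = None
    for s in sites:
        if s.is_snp_decoy:
            continue
        loc = ref.locate_in_mature(s.hairpin_id, s.position)
        if loc and 2 <= loc[1] <= 7:
            focal = (s, *loc)
            break
        if loc and seed_flag(loc[1]) and focal is None:
            focal = (s, *loc)
    if focal is None:
        raise ValueError("no seed-region planted site to design UTRs around")
    site, mature_id, mpos = focal
    ann = ref.mature_by_id(mature_id)
    wt_mature = ref.mature_seq(ann)
    et_mature = wt_mature[: mpos - 1] + site.alt + wt_mature[mpos:]
    wt_8mer = revcomp(wt_mature[1:8]) + "A"  # complement of seed 2-8, A opposite pos 1
    et_8mer = revcomp(et_mature[1:8]) + "A"

    genes = [f"G{i:04d}" for i in range(n_genes)]
    n_wt_only, n_et_only, n_both = 10, 6, 4
    wt_genes = set(genes[: n_wt_only + n_both])
    et_genes = set(genes[n_wt_only : n_wt_only + n_both + n_et_only])
    utrs: dict[str, str] = {}
    for g in genes:
        seq = "".join(rng.choice(BASES, size=utr_len))
        # remove accidental motif occurrences, then insert designed ones
        for motif in (wt_8mer, et_8mer, wt_8mer[:-1], et_8mer[:-1]):
            while motif in seq:
                i = seq.index(motif)
                seq = seq[:i] + "".join(rng.choice(BASES, size=len(motif))) + seq[i + len(motif):]
        inserts = []
        if g in wt_genes:
            inserts.append(wt_8mer)
        if g in et_genes:
            inserts.append(et_8mer)
        for m_i, motif in enumerate(inserts):
            pos = 50 + 120 * m_i
            seq = seq[:pos] + motif + seq[pos + len(motif):]
        utrs[g] = seq
    utr_path = out_dir / "utrs.fa"
    write_fasta(utr_path, utrs)

    gained_pathway = "PW_designed_gain"
    lost_pathway = "PW_designed_loss"
    et_only = sorted(et_genes - wt_genes)
    wt_only = sorted(wt_genes - et_genes)
    pathways: dict[str, list[str]] = {
        gained_pathway: et_only + [genes[-1]],
        lost_pathway: wt_only[:5] + [genes[-2]],
    }
    other = [g for g in genes if g not in set(pathways[gained_pathway]) | set(pathways[lost_pathway])]
    rng.shuffle(other)
    for i in range(4):
        pathways[f"PW_background_{i + 1}"] = sorted(other[i * 10 : i * 10 + 10])
    gmt_path = out_dir / "pathways.gmt"
    write_gmt(gmt_path, pathways)

    # conservation database: diverged copies of each real site's flanks + noise
    db_rows = []
    flank = 25
    for idx, s in enumerate(sites):
        if s.is_snp_decoy:
            continue
        hp = ref.sequences[s.hairpin_id]
        lo = max(0, s.position - 1 - flank)
        hi = min(len(hp), s.position + flank)
        seq = list(hp[lo:hi])
        offset = s.position - 1 - lo  # 0-based edit offset within seq
        n_mut = max(1, int(0.06 * len(seq)))
        for j in rng.choice([i for i in range(len(seq)) if i != offset], size=n_mut, replace=False):
            seq[j] = str(rng.choice(BASES[BASES != seq[j]]))
        db_rows.append({"db_id": f"hsa_site_{idx:03d}", "sequence": "".join(seq), "edit_offset": offset + 1})
    for idx in range(20):
        db_rows.append(
            {
                "db_id": f"hsa_rand_{idx:03d}",
                "sequence": "".join(rng.choice(BASES, size=2 * flank + 1)),
                "edit_offset": flank + 1,
            }
        )
    cons_path = out_dir / "conservation_db.tsv"
    pd.DataFrame(db_rows).to_csv(cons_path, sep="\t", index=False)

    return {
        "snp_vcf": snp_path,
        "utr_fasta": utr_path,
        "gmt": gmt_path,
        "conservation_db": cons_path,
        "focal_site": site,
        "focal_mature": mature_id,
        "focal_mature_position": mpos,
        "wt_mature": wt_mature,
        "et_mature": et_mature,
        "designed_wt_genes": wt_genes,
        "designed_et_genes": et_genes,
        "designed_gained_pathway": gained_pathway,
        "designed_lost_pathway": lost_pathway,
    }
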
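"""Pileup construction and binomial editing-site calling.

A systematic mismatch on a hairpin is called an editing candidate when
the count of a single alternative base is implausibly large under a
binomial sequencing-error null: with per-substitution error probability
p_err (default 10^(-Q/10)/3 at Q = 30) the one-sided tail
P(X >= k | n, p_err) is Bonferroni-corrected over every (covered
position, alt base) test in the run. Candidates must then be
significant in at least three individuals, show exactly one editing
type, reach pooled coverage >= 10 and avoid known SNPs. The editing
level is the fraction of editing-type reads among all reads at the
site, per sample, averaged within stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import Alignment
from .reference import HairpinReference, seed_flag

BASE_ORDER = ("A", "C", "G", "T")

_U = {"T": "U", "A": "A", "C": "C", "G": "G"}


def editing_type_name(ref: str, alt: str) -> str:
    """Editing type on the sense mature strand, U written for T."""
    return f"{_U[ref]}-to-{_U[alt]}"


@dataclass
class CallerParams:
    q_min: int = 30
    alpha: float = 0.05
    p_err: float = 10 ** (-30 / 10) / 3
    min_individuals: int = 3
    min_coverage: int = 10
    coverage_pooled: bool = True
    individuals_per_stage: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha outside (0,1)")
        if not 0.0 < self.p_err < 1.0:
            raise ValueError("p_err outside (0,1)")


@dataclass
class PileupColumn:
    hairpin_id: str
    position: int  # 1-based
    ref: str
    counts: dict[str, int]

    @property
    def coverage(self) -> int:
        return sum(self.counts.values())


@dataclass
class EditingSite:
    hairpin_id: str
    position: int
    ref: str
    alt: str
    sample_counts: dict[str, tuple[int, int]]  # sample -> (edited, total)
    pooled_p: float = np.nan
    mature_id: str | None = None
    mature_position: int | None = None
    seed: bool = False
    chrom: str | None = None
    genomic_position: int | None = None
    stage_levels: dict[str, float] = field(default_factory=dict)

    @property
    def site_id(self) -> str:
        return f"{self.hairpin_id}:{self.position}:{self.ref}>{self.alt}"

    @property
    def editing_type(self) -> str:
        return editing_type_name(self.ref, self.alt)

    def sample_level(self, sample: str) -> float:
        k, n = self.sample_counts.get(sample, (0, 0))
        return k / n if n else np.nan


Pileup = dict[tuple[str, int], PileupColumn]


def build_pileup(alignments: list[Alignment], ref: HairpinReference, q_min: int = 30) -> Pileup:
    """Count A/C/G/T per covered hairpin position from bases with Q >= q_min."""
    pileup: Pileup = {}
    for a in alignments:
        hp_seq = ref.sequences[a.hairpin_id]
        for offset, (base, q) in enumerate(zip(a.seq, a.qual)):
            if q < q_min or base not in BASE_ORDER:
                continue
            pos = a.start + offset
            key = (a.hairpin_id, pos)
            col = pileup.get(key)
            if col is None:
                col = PileupColumn(a.hairpin_id, pos, hp_seq[pos - 1], {b: 0 for b in BASE_ORDER})
                pileup[key] = col
            col.counts[base] += 1
    return pileup


def pool_pileups(pileups: dict[str, Pileup]) -> Pileup:
    pooled: Pileup = {}
    for pu in pileups.values():
        for key, col in pu.items():
            agg = pooled.get(key)
            if agg is None:
                pooled[key] = PileupColumn(col.hairpin_id, col.position, col.ref, dict(col.counts))
            else:
                for b in BASE_ORDER:
                    agg.counts[b] += col.counts[b]
    return pooled


def binomial_site_test(column: PileupColumn, params: CallerParams, n_tests: int) -> dict[str, tuple[float, float]]:
    """Per alt base: (raw one-sided binomial p, Bonferroni-corrected p).

    raw p = P(X >= k | n = coverage, p_err); corrected = min(1, p * T).
    """
    n = column.coverage
    out: dict[str, tuple[float, float]] = {}
    if n == 0:
        return out
    for alt in BASE_ORDER:
        if alt == column.ref:
            continue
        k = column.counts[alt]
        raw = float(stats.binom.sf(k - 1, n, params.p_err)) if k > 0 else 1.0
        out[alt] = (raw, min(1.0, raw * max(1, n_tests)))
    return out


def _n_family_tests(pooled: Pileup, params: CallerParams) -> int:
    """Bonferroni family size: 3 alt bases per position at family coverage."""
    return 3 * sum(1 for col in pooled.values() if col.coverage >= params.min_coverage)


def call_sites(
    sample_pileups: dict[str, Pileup],
    ref: HairpinReference,
    params: CallerParams,
    snp_positions: set[tuple[str, int]] | None = None,
    sample_stages: dict[str, str] | None = None,
) -> list[EditingSite]:
    """Call editing sites across samples with the full filter cascade.

    A (position, alt) pair is a candidate when its Bonferroni-corrected
    per-sample binomial p is <= alpha in >= min_individuals samples.
    Candidates are then dropped when the position shows more than one
    significant editing type, pooled coverage < min_coverage, or the
    position is a known SNP.
    """
    snp_positions = snp_positions or set()
    pooled = pool_pileups(sample_pileups)
    n_tests = _n_family_tests(pooled, params)

    # significant (pos, alt) pairs per sample
    sig_by_pos: dict[tuple[str, int], dict[str, list[str]]] = {}
    for sample, pu in sample_pileups.items():
        for key, col in pu.items():
            for alt, (_raw, corr) in binomial_site_test(col, params, n_tests).items():
                if corr <= params.alpha:
                    sig_by_pos.setdefault(key, {}).setdefault(alt, []).append(sample)

    sites: list[EditingSite] = []
    for key in sorted(sig_by_pos):
        hp_id, pos = key
        pooled_col = pooled[key]
        alt_support = {
            alt: samples
            for alt, samples in sig_by_pos[key].items()
            if _enough_individuals(samples, params, sample_stages)
        }
        if len(alt_support) != 1:
            continue  # no supported type, or multiple editing types
        # a second editing type significant in the pooled counts also voids the site
        pooled_sig = {
            alt
            for alt, (_raw, corr) in binomial_site_test(pooled_col, params, n_tests).items()
            if corr <= params.alpha
        }
        if len(pooled_sig | set(alt_support)) > 1:
            continue
        alt = next(iter(alt_support))
        if params.coverage_pooled:
            if pooled_col.coverage < params.min_coverage:
                continue
        else:
            per_sample_cov = [
                pu[key].coverage for pu in sample_pileups.values() if key in pu
            ]
            if not per_sample_cov or max(per_sample_cov) < params.min_coverage:
                continue
        if key in snp_positions or (hp_id, pos) in snp_positions:
            continue
        pooled_tests = binomial_site_test(pooled_col, params, n_tests)
        sample_counts = {}
        for sample, pu in sample_pileups.items():
            col = pu.get(key)
            if col is None:
                sample_counts[sample] = (0, 0)
            else:
                sample_counts[sample] = (col.counts[alt], col.coverage)
        site = EditingSite(
            hp_id, pos, pooled_col.ref, alt, sample_counts, pooled_p=pooled_tests[alt][1]
        )
        map_to_mature(site, ref)
        sites.append(site)
    return sites


def _enough_individuals(samples: list[str], params: CallerParams, sample_stages: dict[str, str] | None) -> bool:
    if not params.individuals_per_stage or sample_stages is None:
        return len(samples) >= params.min_individuals
    by_stage: dict[str, int] = {}
    for s in samples:
        by_stage[sample_stages[s]] = by_stage.get(sample_stages[s], 0) + 1
    return any(v >= params.min_individuals for v in by_stage.values())


def quantify_levels(sites: list[EditingSite], sample_stages: dict[str, str]) -> list[EditingSite]:
    """Per-sample editing level = edited/total; stage level = replicate mean.

    Samples with zero coverage at the site are excluded from the stage mean.
    """
    stages: dict[str, list[str]] = {}
    for sample, stage in sample_stages.items():
        stages.setdefault(stage, []).append(sample)
    for site in sites:
        site.stage_levels = {}
        for stage, samples in stages.items():
            levels = [
                k / n for k, n in (site.sample_counts.get(s, (0, 0)) for s in samples) if n > 0
            ]
            site.stage_levels[stage] = float(np.mean(levels)) if levels else np.nan
    return sites


def map_to_mature(site: EditingSite, ref: HairpinReference) -> EditingSite:
    """Attach mature-arm coordinates and the seed flag (positions 2-8)."""
    loc = ref.locate_in_mature(site.hairpin_id, site.position)
    if loc is None:
        site.mature_id, site.mature_position, site.seed = None, None, False
    else:
        site.mature_id, site.mature_position = loc
        site.seed = seed_flag(site.mature_position)
    return site


def apply_liftover(sites: list[EditingSite], liftover: dict[str, tuple[str, int]]) -> list[EditingSite]:
    """Attach genomic coordinates from a hairpin -> (chrom, genomic start) table."""
    for site in sites:
        if site.hairpin_id in liftover:
            chrom, start = liftover[site.hairpin_id]
            site.chrom = chrom
            site.genomic_position = start + site.position - 1
    return sites


# ---------------------------------------------------------------------------
# site table I/O


def sites_to_table(sites: list[EditingSite], stages: list[str] | None = None) -> pd.DataFrame:
    rows = []
    for s in sites:
        row = {
            "site_id": s.site_id,
            "chromosome": s.chrom or "",
            "genomic_position": s.genomic_position if s.genomic_position is not None else "",
            "hairpin": s.hairpin_id,
            "hairpin_position": s.position,
            "mature_name": s.mature_id or "",
            "position_in_mirna": s.mature_position if s.mature_position is not None else "",
            "editing_type": s.editing_type,
            "seed": s.seed,
            "pooled_p": s.pooled_p,
        }
        for sample, (k, n) in sorted(s.sample_counts.items()):
            row[f"edited:{sample}"] = k
            row[f"total:{sample}"] = n
        for stage in stages or sorted(s.stage_levels):
            row[f"level:{stage}"] = s.stage_levels.get(stage, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def write_site_table(path: str | Path, sites: list[EditingSite], stages: list[str] | None = None) -> None:
    sites_to_table(sites, stages).to_csv(path, sep="\t", index=False)


def site_counts_long(sites: list[EditingSite], sample_stages: dict[str, str]) -> pd.DataFrame:
    """Long-format (site, sample, stage, edited, total) counts for the
    differential stage."""
    rows = []
    for s in sites:
        for sample, (k, n) in s.sample_counts.items():
            rows.append(
                {
                    "site_id": s.site_id,
                    "sample": sample,
                    "stage": sample_stages[sample],
                    "edited": k,
                    "total": n,
                }
            )
    return pd.DataFrame(rows)
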
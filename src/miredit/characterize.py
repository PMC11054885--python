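"""Editing-site characterization: flank base preferences, temporal
clustering of editing levels, and cross-database conservation matching.

Flank preferences compare the +-5 nt around edited sites against a
background of tested-but-uncalled positions with the same reference
base, one Fisher exact test per (offset, base) with Bonferroni
correction over the 40 tests of an editing type.

Temporal patterns are found by fuzzy c-means on per-site
z-standardized stage-mean trajectories (soft clustering in the Mfuzz
style, fuzzifier m = 1.25 by default).

Conservation matching locally aligns the 25-bp flanks of each site
against a database of editing-site flanks from another species; a site
is conserved when its best hit has e-value < 0.001 and identity > 85%
(both strict). E-values use ungapped Karlin-Altschul statistics for
the +1/-2 nucleotide scheme on a query-length x database-length search
space — a threshold-level stand-in for a full BLASTN search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import cdist
from Bio import Align

from .reference import HairpinReference

logger = logging.getLogger(__name__)

FLANK_OFFSETS = tuple(range(-5, 0)) + tuple(range(1, 6))
BASES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# flank base preference


def extract_context(ref: HairpinReference, hairpin_id: str, position: int, flank: int = 5) -> str:
    """Hairpin sequence around a site, N-padded at the boundaries, length
    2*flank+1 with the site at the center index."""
    seq = ref.sequences[hairpin_id]
    out = []
    for off in range(-flank, flank + 1):
        p = position + off
        out.append(seq[p - 1] if 1 <= p <= len(seq) else "N")
    return "".join(out)


def flank_preference(
    edited_contexts: list[str],
    background_contexts: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (offset, base) enrichment of edited flanks over background.

    Contexts are 11-mers centered on the site. Sites contributing fewer
    than 10 real (non-N) flank bases are skipped. Returns one row per
    offset/base with counts, Fisher exact p, Bonferroni-corrected p and
    the enrichment direction at corrected p < alpha.
    """
    if not background_contexts:
        raise ValueError("background set is empty")
    edited_contexts = [c for c in edited_contexts if len(c) - c.count("N") - 1 >= 10]
    rows = []
    n_tests = len(FLANK_OFFSETS) * len(BASES)
    for off in FLANK_OFFSETS:
        idx = off + 5
        ed = [c[idx] for c in edited_contexts if c[idx] != "N"]
        bg = [c[idx] for c in background_contexts if c[idx] != "N"]
        for base in BASES:
            a = sum(1 for b in ed if b == base)
            b_ = len(ed) - a
            c = sum(1 for b in bg if b == base)
            d = len(bg) - c
            _odds, p = stats.fisher_exact([[a, b_], [c, d]], alternative="two-sided")
            p_corr = min(1.0, p * n_tests)
            ed_frac = a / len(ed) if ed else np.nan
            bg_frac = c / len(bg) if bg else np.nan
            direction = ""
            if p_corr < alpha:
                direction = "enriched" if ed_frac > bg_frac else "depleted"
            rows.append(
                {
                    "offset": off,
                    "base": base,
                    "edited_count": a,
                    "edited_total": len(ed),
                    "background_count": c,
                    "background_total": len(bg),
                    "pvalue": p,
                    "p_corrected": p_corr,
                    "direction": direction,
                }
            )
    return pd.DataFrame(rows)


def background_contexts(
    ref: HairpinReference,
    pooled_pileup,
    called_positions: set[tuple[str, int]],
    ref_base: str,
    min_coverage: int = 10,
    flank: int = 5,
) -> list[str]:
    """Tested-but-uncalled positions with the given reference base."""
    out = []
    for (hp, pos), col in pooled_pileup.items():
        if col.ref != ref_base or (hp, pos) in called_positions:
            continue
        if col.coverage < min_coverage:
            continue
        out.append(extract_context(ref, hp, pos, flank))
    return out


# ---------------------------------------------------------------------------
# fuzzy c-means trajectory clustering


@dataclass
class TrajectoryClustering:
    memberships: pd.DataFrame  # site x cluster, rows sum to 1
    centers: np.ndarray  # cluster x stage (z-score units)
    labels: pd.Series  # hard label = argmax membership
    objective: list[float] = field(default_factory=list)
    fuzzifier: float = 1.25
    dropped: list[str] = field(default_factory=list)


def cluster_trajectories(
    trajectories: pd.DataFrame,
    c: int = 4,
    m: float = 1.25,
    rng_seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> TrajectoryClustering:
    """Fuzzy c-means on row-wise z-standardized stage trajectories.

    ``trajectories`` has one row per site, one column per stage (mean
    editing level). Zero-variance rows cannot be standardized and are
    excluded with a warning. Deterministic for a fixed ``rng_seed``.
    """
    var = trajectories.var(axis=1, ddof=0)
    dropped = list(trajectories.index[var == 0])
    if dropped:
        logger.warning("excluding %d zero-variance trajectories", len(dropped))
    data = trajectories.loc[var > 0]
    if len(data) < c:
        raise ValueError(f"need >= c={c} sites with non-zero variance, have {len(data)}")
    X = data.to_numpy(dtype=float)
    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)

    if c == 1:
        u = pd.DataFrame(np.ones((len(data), 1)), index=data.index, columns=["cluster_1"])
        return TrajectoryClustering(
            u, X.mean(axis=0, keepdims=True), pd.Series("cluster_1", index=data.index),
            [], m, dropped,
        )

    rng = np.random.default_rng(rng_seed)
    U = rng.dirichlet(np.ones(c), size=len(data)).T  # c x N
    objective: list[float] = []
    centers = None
    for _ in range(max_iter):
        Um = U**m
        centers = (Um @ X) / Um.sum(axis=1, keepdims=True)
        d2 = np.maximum(cdist(centers, X, metric="sqeuclidean"), 1e-12)
        J = float(np.sum(Um * d2))
        objective.append(J)
        U_new = d2 ** (-1.0 / (m - 1.0))
        U_new /= U_new.sum(axis=0, keepdims=True)
        if len(objective) > 1 and abs(objective[-2] - J) < tol:
            U = U_new
            break
        U = U_new
    cols = [f"cluster_{i + 1}" for i in range(c)]
    memb = pd.DataFrame(U.T, index=data.index, columns=cols)
    labels = memb.idxmax(axis=1)
    return TrajectoryClustering(memb, centers, labels, objective, m, dropped)


# ---------------------------------------------------------------------------
# conservation matching


@dataclass
class ConservationMatch:
    query_id: str
    db_id: str | None
    score: float
    identity: float  # percent over aligned columns
    evalue: float
    conserved: bool


def _karlin_altschul_lambda(match: float = 1.0, mismatch: float = -2.0) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for uniform bases."""

    def f(lam):
        return 0.25 * np.exp(lam * match) + 0.75 * np.exp(lam * mismatch) - 1.0

    return float(optimize.brentq(f, 1e-6, 10.0))


_LAMBDA = _karlin_altschul_lambda()
_KA_K = 0.621  # tabulated ungapped K for the +1/-2 nucleotide scheme


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


def conservation_match(
    queries: dict[str, str],
    site_db: pd.DataFrame,
    evalue_max: float = 1e-3,
    min_identity: float = 85.0,
) -> list[ConservationMatch]:
    """Match each query flank against the editing-site flank database.

    ``queries`` maps query site id -> flank sequence (site +-25 nt,
    truncated at hairpin boundaries). ``site_db`` needs columns db_id
    and sequence. Conserved requires e-value strictly below
    ``evalue_max`` AND identity strictly above ``min_identity``.
    """
    if site_db is None or len(site_db) == 0:
        logger.warning("empty conservation database; no matches")
        return [
            ConservationMatch(qid, None, 0.0, 0.0, np.inf, False) for qid in queries
        ]
    aligner = _make_aligner()
    db_seqs = list(zip(site_db["db_id"], site_db["sequence"]))
    total_db_len = sum(len(s) for _, s in db_seqs)
    out = []
    for qid, qseq in queries.items():
        best = None
        for db_id, dseq in db_seqs:
            alns = aligner.align(qseq, dseq)
            if len(alns) == 0:
                continue
            aln = alns[0]
            if best is None or aln.score > best[0]:
                best = (aln.score, db_id, aln)
        if best is None:
            out.append(ConservationMatch(qid, None, 0.0, 0.0, np.inf, False))
            continue
        score, db_id, aln = best
        counts = aln.counts()  # gaps, identities, mismatches
        aligned_cols = counts.gaps + counts.identities + counts.mismatches
        identity = 100.0 * counts.identities / aligned_cols if aligned_cols else 0.0
        evalue = _KA_K * len(qseq) * total_db_len * np.exp(-_LAMBDA * score)
        conserved = (evalue < evalue_max) and (identity > min_identity)
        out.append(ConservationMatch(qid, db_id, float(score), identity, float(evalue), conserved))
    return out


def extract_flank(ref: HairpinReference, hairpin_id: str, position: int, flank: int = 25) -> str:
    """Site flank sequence truncated at the hairpin boundaries (<= 51 nt)."""
    seq = ref.sequences[hairpin_id]
    lo = max(0, position - 1 - flank)
    hi = min(len(seq), position + flank)
    return seq[lo:hi]


def matches_to_table(matches: list[ConservationMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_id": m.query_id,
                "db_id": m.db_id or "",
                "score": m.score,
                "identity_pct": m.identity,
                "evalue": m.evalue,
                "conserved": m.conserved,
            }
            for m in matches
        ]
    )
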
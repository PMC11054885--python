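"""Seed-edit retargeting: wild-type vs edited-type target prediction.

An edit inside the seed (mature positions 2-8) rewrites the miRNA's
targeting rules. For each variant the 3'UTR set is scanned either for
canonical seed-match classes (default) —

    6mer     perfect Watson-Crick complement of positions 2-7
    7mer-m8  6mer plus a complement at position 8
    7mer-A1  6mer plus an A in the UTR opposite position 1
    8mer     complement of 2-8 plus the A1 anchor

— or, in "score" mode, by a full-miRNA complementarity alignment
(match +5, G:U wobble +1, mismatch -3, gap -9, seed positions 2-8
weighted x4) with a score threshold of 140 and a stacking-sum energy
proxy threshold of -10. A gene is a target when any of its UTRs has at
least one hit; WT-vs-ET gain/loss is plain set algebra on the gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import normalize_seq, revcomp


@dataclass
class MatureVariant:
    mirna: str
    tag: str  # e.g. "ssc-miR-497" (WT) or "ssc-miR-497_2" (ET at base 2)
    sequence: str  # DNA alphabet, 5'->3'
    edited_position: int | None = None  # 1-based; None for WT

    def __post_init__(self) -> None:
        self.sequence = normalize_seq(self.sequence)

    @property
    def seed(self) -> str:
        """Seed subsequence, mature positions 2-8."""
        return self.sequence[1:8]

    @property
    def is_wildtype(self) -> bool:
        return self.edited_position is None


def wildtype_variant(mirna: str, mature_seq: str) -> MatureVariant:
    return MatureVariant(mirna, mirna, mature_seq)


def apply_edit(mirna: str, mature_seq: str, position: int, ref: str, alt: str) -> MatureVariant:
    """Edited-type variant; A-to-G edits substitute G (inosine pairs as G).

    The variant tag appends the edited base position, e.g. a position-2
    edit of miR-497 gives "miR-497_2".
    """
    mature_seq = normalize_seq(mature_seq)
    ref, alt = normalize_seq(ref), normalize_seq(alt)
    if not 1 <= position <= len(mature_seq):
        raise ValueError(f"position {position} outside mature of length {len(mature_seq)}")
    if mature_seq[position - 1] != ref:
        raise ValueError(
            f"reference base mismatch at {mirna} position {position}: "
            f"mature has {mature_seq[position - 1]}, site says {ref}"
        )
    edited = mature_seq[: position - 1] + alt + mature_seq[position:]
    return MatureVariant(mirna, f"{mirna}_{position}", edited, edited_position=position)


# ---------------------------------------------------------------------------
# scanning


@dataclass
class TargetHit:
    gene: str
    position: int  # 1-based UTR position of the match start
    match_class: str  # 8mer | 7mer-m8 | 7mer-A1 | 6mer | score
    score: float = np.nan
    energy: float = np.nan


@dataclass
class TargetSet:
    tag: str
    genes: set[str]
    universe: frozenset[str]
    hits: list[TargetHit] = field(default_factory=list)


@dataclass
class ScanParams:
    mode: str = "seed"  # "seed" or "score"
    min_score: float = 140.0
    max_energy: float = -10.0
    seed_scale: float = 4.0
    match: float = 5.0
    wobble: float = 1.0
    mismatch: float = -3.0
    gap: float = -9.0


def _seed_sites(variant: MatureVariant) -> dict[str, str]:
    """UTR motifs (5'->3') for each canonical seed-match class."""
    m = variant.sequence
    site6 = revcomp(m[1:7])  # complement of positions 2-7
    site7m8 = revcomp(m[1:8])  # adds position 8 (5' side of the UTR site)
    return {
        "8mer": site7m8 + "A",
        "7mer-m8": site7m8,
        "7mer-A1": site6 + "A",
        "6mer": site6,
    }


def scan_targets(
    variant: MatureVariant,
    utrs: dict[str, str],
    params: ScanParams | None = None,
) -> TargetSet:
    """Scan every UTR for target sites of one miRNA variant.

    Seed mode reports, per match position, the best (most specific)
    class among 8mer > 7mer-m8 > 7mer-A1 > 6mer. One hit per gene is
    enough for set membership.
    """
    if not utrs:
        raise ValueError("empty UTR set")
    params = params or ScanParams()
    utrs = {g: normalize_seq(s) for g, s in utrs.items()}
    hits: list[TargetHit] = []
    if params.mode == "seed":
        motifs = _seed_sites(variant)
        for gene in sorted(utrs):
            seq = utrs[gene]
            found: dict[int, str] = {}
            for cls in ("8mer", "7mer-m8", "7mer-A1", "6mer"):
                motif = motifs[cls]
                start = seq.find(motif)
                while start != -1:
                    found.setdefault(start, cls)  # first (most specific) class wins
                    start = seq.find(motif, start + 1)
            for start in sorted(found):
                hits.append(TargetHit(gene, start + 1, found[start]))
    elif params.mode == "score":
        for gene in sorted(utrs):
            best = _best_complementarity(variant.sequence, utrs[gene], params)
            if best is not None:
                score, energy, pos = best
                if score >= params.min_score and energy <= params.max_energy:
                    hits.append(TargetHit(gene, pos, "score", score, energy))
    else:
        raise ValueError(f"unknown scan mode {params.mode!r}")
    genes = {h.gene for h in hits}
    return TargetSet(variant.tag, genes, frozenset(utrs), hits)


_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # G:U with U as T


def _best_complementarity(mirna: str, utr: str, params: ScanParams):
    """Best local complementarity alignment of the miRNA against the UTR.

    The miRNA binds antiparallel, so its reverse is aligned against the
    UTR sense strand and each aligned pair is scored by complementarity.
    Seed positions 2-8 have their pair contributions multiplied by
    seed_scale; gaps score `gap` regardless of position. The energy
    proxy sums -2 per Watson-Crick and -1 per wobble pair over the best
    path. Returns (score, energy, 1-based UTR start) or None.
    """
    q = mirna[::-1]  # reversed miRNA, 5'UTR->3' co-linear with UTR
    L, M = len(q), len(utr)
    if M < 6:
        return None
    # Smith-Waterman with positional weights
    weights = np.ones(L)
    for i in range(L):
        mir_pos = L - i  # original 1-based miRNA position
        if 2 <= mir_pos <= 8:
            weights[i] = params.seed_scale
    H = np.zeros((L + 1, M + 1))
    E = np.zeros((L + 1, M + 1))  # energy proxy along the best path
    best = (0.0, 0.0, 0)
    for i in range(1, L + 1):
        qi = q[i - 1]
        w = weights[i - 1]
        for j in range(1, M + 1):
            pair = (qi, utr[j - 1])
            if pair in _WC:
                s, e = params.match * w, -2.0
            elif pair in _WOBBLE:
                s, e = params.wobble * w, -1.0
            else:
                s, e = params.mismatch * w, 0.0
            diag = H[i - 1, j - 1] + s
            up = H[i - 1, j] + params.gap
            left = H[i, j - 1] + params.gap
            h = max(0.0, diag, up, left)
            H[i, j] = h
            if h == 0.0:
                E[i, j] = 0.0
            elif h == diag:
                E[i, j] = E[i - 1, j - 1] + e
            elif h == up:
                E[i, j] = E[i - 1, j]
            else:
                E[i, j] = E[i, j - 1]
            if h > best[0]:
                best = (h, E[i, j], j)
    if best[0] <= 0:
        return None
    return best[0], best[1], best[2]


# ---------------------------------------------------------------------------
# gain/loss algebra


def diff_target_sets(wt: TargetSet, et: TargetSet) -> dict:
    """Gain/loss summary: lost = WT \\ ET, gained = ET \\ WT."""
    if wt.universe != et.universe:
        raise ValueError("WT and ET target sets computed on different UTR universes")
    shared = wt.genes & et.genes
    lost = wt.genes - et.genes
    gained = et.genes - wt.genes
    return {
        "wt_tag": wt.tag,
        "et_tag": et.tag,
        "n_wt": len(wt.genes),
        "n_et": len(et.genes),
        "shared": shared,
        "lost": lost,
        "gained": gained,
        "n_shared": len(shared),
        "n_lost": len(lost),
        "n_gained": len(gained),
    }


def hits_to_table(ts: TargetSet) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant": ts.tag,
                "gene": h.gene,
                "position": h.position,
                "match_class": h.match_class,
                "score": h.score,
                "energy": h.energy,
            }
            for h in ts.hits
        ]
    )
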
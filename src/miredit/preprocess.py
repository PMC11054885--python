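"""Read filtering and unique alignment to the hairpin reference.

Filtering keeps reads that are adapter-trimmed, 15-28 nt long and have
at least 95% of bases at Q>=30. Alignment is ungapped, sense-strand and
unique: a read is kept only if exactly one hairpin location matches it
with at most one mismatch, after ignoring its 2 3'-terminal bases
(which absorb non-templated A/U additions). Ties in the best mismatch
stratum are not broken — the read is dropped.

The aligner is an internal 6-mer seed index with full Hamming
verification; by the pigeonhole principle a read of >=12 usable nt with
<=1 mismatch always retains one exact 6-mer among its first two, so the
seeding is lossless for this mismatch budget. Alignments can also be
imported from / exported to SAM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .io import FastqRead
from .reference import HairpinReference

logger = logging.getLogger(__name__)

_SEED_K = 6


@dataclass
class ReadFilterParams:
    min_len: int = 15
    max_len: int = 28
    q_threshold: int = 30
    min_hq_fraction: float = 0.95
    adapter: str | None = None
    trim3: int = 2

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if not 0.0 <= self.min_hq_fraction <= 1.0:
            raise ValueError("min_hq_fraction outside [0,1]")


@dataclass
class Alignment:
    read_id: str
    hairpin_id: str
    start: int  # 1-based on hairpin
    seq: str  # aligned (3'-trimmed) read sequence
    qual: list[int]
    mismatches: int

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class QCReport:
    total: int = 0
    kept: int = 0
    removed: dict[str, int] = field(default_factory=lambda: {"low_quality": 0, "too_short": 0, "too_long": 0})


def _trim_adapter(read: FastqRead, adapter: str, min_overlap: int = 8) -> FastqRead:
    """Trim an exact adapter-prefix match at the 3' end (>=8 nt overlap)."""
    seq = read.seq
    for i in range(len(seq) - min_overlap + 1):
        tail = seq[i:]
        if len(tail) <= len(adapter) and adapter.startswith(tail):
            return FastqRead(read.id, seq[:i], read.qual[:i])
    return read


def filter_reads(reads: list[FastqRead], params: ReadFilterParams) -> tuple[list[FastqRead], QCReport]:
    """Quality filter, adapter trim and length filter, in that order."""
    report = QCReport(total=len(reads))
    kept: list[FastqRead] = []
    for read in reads:
        if len(read) == 0:
            report.removed["too_short"] += 1
            continue
        hq = sum(1 for q in read.qual if q >= params.q_threshold)
        if hq / len(read) < params.min_hq_fraction:
            report.removed["low_quality"] += 1
            continue
        if params.adapter:
            read = _trim_adapter(read, params.adapter)
        if len(read) < params.min_len:
            report.removed["too_short"] += 1
            continue
        if len(read) > params.max_len:
            report.removed["too_long"] += 1
            continue
        kept.append(read)
    report.kept = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# alignment


class _SeedIndex:
    def __init__(self, ref: HairpinReference, k: int = _SEED_K):
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for hp_id, seq in ref.sequences.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((hp_id, i))

    def candidates(self, seq: str) -> set[tuple[str, int]]:
        """Candidate (hairpin, 0-based start) pairs from two non-overlapping
        seeds; with <=1 mismatch at least one seed is exact."""
        cands: set[tuple[str, int]] = set()
        for offset in (0, self.k):
            kmer = seq[offset : offset + self.k]
            if len(kmer) < self.k:
                break
            for hp_id, pos in self.index.get(kmer, ()):
                start = pos - offset
                if start >= 0:
                    cands.add((hp_id, start))
        return cands


def _hamming(a: str, b: str, budget: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > budget:
                return mm
    return mm


def align_unique(
    reads: list[FastqRead],
    ref: HairpinReference,
    trim3: int = 2,
    max_mismatches: int = 1,
) -> list[Alignment]:
    """Align each read to exactly one hairpin location or drop it.

    The read's 3'-terminal ``trim3`` bases are excluded from both the
    aligned span and the mismatch count. Reads whose best mismatch
    stratum contains zero or more than one location are discarded.
    """
    if not ref.sequences:
        raise ValueError("empty hairpin reference")
    index = _SeedIndex(ref)
    alignments: list[Alignment] = []
    for read in reads:
        eff_len = len(read) - trim3
        if eff_len < 2 * index.k:
            continue
        seq = read.seq[:eff_len]
        best_mm = max_mismatches + 1
        hits: list[tuple[str, int, int]] = []
        for hp_id, start in index.candidates(seq):
            window = ref.sequences[hp_id][start : start + eff_len]
            if len(window) < eff_len:
                continue
            mm = _hamming(seq, window, max_mismatches)
            if mm > max_mismatches:
                continue
            if mm < best_mm:
                best_mm, hits = mm, [(hp_id, start, mm)]
            elif mm == best_mm:
                hits.append((hp_id, start, mm))
        if len(hits) == 1:
            hp_id, start, mm = hits[0]
            alignments.append(
                Alignment(read.id, hp_id, start + 1, seq, read.qual[:eff_len], mm)
            )
    return alignments


# ---------------------------------------------------------------------------
# SAM export / import


def write_sam(path: str | Path, alignments: list[Alignment], ref: HairpinReference) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for hp_id, seq in ref.sequences.items():
            fh.write(f"@SQ\tSN:{hp_id}\tLN:{len(seq)}\n")
        for a in alignments:
            qual = "".join(chr(q + 33) for q in a.qual)
            fh.write(
                f"{a.read_id}\t0\t{a.hairpin_id}\t{a.start}\t255\t{a.length}M\t*\t0\t0\t"
                f"{a.seq}\t{qual}\tNM:i:{a.mismatches}\n"
            )


def read_sam(path: str | Path) -> list[Alignment]:
    """Import alignments from SAM; multi-mapped read ids are discarded."""
    import pysam

    by_read: dict[str, list[Alignment]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            quals = list(rec.query_qualities) if rec.query_qualities is not None else [40] * rec.query_length
            aln = Alignment(
                rec.query_name,
                rec.reference_name,
                rec.reference_start + 1,
                rec.query_sequence,
                quals,
                int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
            )
            by_read.setdefault(rec.query_name, []).append(aln)
    out = []
    n_multi = 0
    for read_id, alns in by_read.items():
        if len(alns) == 1:
            out.append(alns[0])
        else:
            n_multi += 1
    if n_multi:
        logger.warning("discarded %d multi-mapped reads from SAM import", n_multi)
    return out
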
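"""Readers and writers for the text formats the pipeline exchanges.

Sequences are held internally as uppercase DNA (``ACGT``); any ``U`` in
input is normalized to ``T`` on read, and editing types are reported with
``U`` for ``T`` (e.g. ``C-to-U``) to follow miRNA convention.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_seq(seq: str) -> str:
    return str(seq).upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass
class FastqRead:
    """One sequencing read with per-base phred qualities (Sanger scale)."""

    id: str
    seq: str
    qual: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.seq)


def _open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{id: sequence}`` (first whitespace token as id)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = normalize_seq(rec.seq)
    return out


def write_fasta(path: str | Path, records: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: str | Path) -> list[FastqRead]:
    reads = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        try:
            quals = rec.letter_annotations["phred_quality"]
            reads.append(FastqRead(rec.id, normalize_seq(rec.seq), list(quals)))
        except (KeyError, ValueError) as exc:  # pragma: no cover - defensive
            raise ValueError(f"malformed FASTQ record index {i} in {path}: {exc}") from exc
    return reads


def write_fastq(path: str | Path, reads: Iterable[FastqRead]) -> None:
    with _open(path, "wt") as fh:
        for r in reads:
            qual_str = "".join(chr(q + 33) for q in r.qual)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual_str}\n")


# ---------------------------------------------------------------------------
# GFF3 mature-arm annotation (1-based closed intervals)


def write_gff3(path: str | Path, features: Iterable["MatureAnnotation"]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.mature_id};Name={f.mature_id};Derives_from={f.hairpin_id}"
            fh.write(
                f"{f.hairpin_id}\tmiredit\tmiRNA\t{f.start}\t{f.end}\t.\t+\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list["MatureAnnotation"]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"GFF3 line with {len(cols)} columns in {path}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            feats.append(
                MatureAnnotation(
                    hairpin_id=cols[0],
                    mature_id=attrs.get("Name", attrs.get("ID", "mature")),
                    start=int(cols[3]),
                    end=int(cols[4]),
                )
            )
    return feats


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA arm located on its hairpin (1-based, closed)."""

    hairpin_id: str
    mature_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# SNP files: VCF v4.2 or 3-column BED


def write_vcf(path: str | Path, rows: Iterable[tuple[str, int, str, str]]) -> None:
    """Write minimal VCF v4.2; rows are (chrom, pos1, ref, alt)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")


def read_snp_positions(path: str | Path) -> set[tuple[str, int]]:
    """Read known-SNP positions from VCF (1-based) or BED (0-based half-open).

    Returns a set of (sequence name, 1-based position) covering every base of
    each record's interval.
    """
    path = Path(path)
    positions: set[tuple[str, int]] = set()
    try:
        with _open(path) as fh:
            is_bed = path.suffix.lower() in {".bed"}
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("track"):
                    continue
                cols = line.split("\t")
                if is_bed:
                    chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                    positions.update((chrom, p) for p in range(start + 1, end + 1))
                else:
                    chrom, pos = cols[0], int(cols[1])
                    ref = cols[3] if len(cols) > 3 else "N"
                    positions.update((chrom, pos + i) for i in range(max(1, len(ref))))
    except (OSError, IndexError, ValueError) as exc:
        raise ValueError(f"unparseable SNP file {path}: {exc}") from exc
    return positions


# ---------------------------------------------------------------------------
# GMT pathway sets


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                continue
            pathways[cols[0]] = set(g for g in cols[2:] if g)
    return pathways


def write_gmt(path: str | Path, pathways: dict[str, Iterable[str]]) -> None:
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")
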
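"""Hairpin (pre-miRNA) reference with embedded mature-arm annotation.

The hairpin is the coordinate frame for alignment and pileup: every read
maps to a hairpin, every editing site is a 1-based hairpin position, and
mature-arm annotations locate the excised miRNA (hence the seed region,
positions 2-8 from its 5' end) inside that frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .io import MatureAnnotation, read_fasta, read_gff3, write_fasta, write_gff3


@dataclass
class HairpinReference:
    sequences: dict[str, str]
    annotations: list[MatureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_hp: dict[str, list[MatureAnnotation]] = {}
        for ann in self.annotations:
            if ann.hairpin_id not in self.sequences:
                raise ValueError(f"annotation for unknown hairpin {ann.hairpin_id}")
            hp_len = len(self.sequences[ann.hairpin_id])
            if not (1 <= ann.start <= ann.end <= hp_len):
                raise ValueError(
                    f"mature arm {ann.mature_id} ({ann.start}-{ann.end}) "
                    f"outside hairpin {ann.hairpin_id} (len {hp_len})"
                )
            by_hp.setdefault(ann.hairpin_id, []).append(ann)
        self._by_hairpin = by_hp

    def __len__(self) -> int:
        return len(self.sequences)

    def matures_of(self, hairpin_id: str) -> list[MatureAnnotation]:
        return self._by_hairpin.get(hairpin_id, [])

    def mature_seq(self, ann: MatureAnnotation) -> str:
        return self.sequences[ann.hairpin_id][ann.start - 1 : ann.end]

    def mature_by_id(self, mature_id: str) -> MatureAnnotation:
        for ann in self.annotations:
            if ann.mature_id == mature_id:
                return ann
        raise KeyError(mature_id)

    def locate_in_mature(self, hairpin_id: str, position: int) -> tuple[str, int] | None:
        """Map a 1-based hairpin position to (mature id, 1-based mature position).

        Returns None when the position lies on no annotated arm; raises if
        the hairpin has no annotation at all.
        """
        anns = self._by_hairpin.get(hairpin_id)
        if not anns:
            raise KeyError(f"hairpin {hairpin_id} has no mature annotation")
        for ann in anns:
            if ann.start <= position <= ann.end:
                return ann.mature_id, position - ann.start + 1
        return None

    # ------------------------------------------------------------------
    def save(self, fasta_path: str | Path, gff_path: str | Path) -> None:
        write_fasta(fasta_path, self.sequences)
        write_gff3(gff_path, self.annotations)

    @classmethod
    def load(cls, fasta_path: str | Path, gff_path: str | Path) -> "HairpinReference":
        return cls(read_fasta(fasta_path), read_gff3(gff_path))


def seed_flag(mature_position: int) -> bool:
    """Seed region = mature positions 2-8 from the 5' end."""
    return 2 <= mature_position <= 8
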
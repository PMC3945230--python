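"""Genome records, FASTA input and lifestyle metadata.

A :class:`Genome` is a plain nucleotide sequence over ``{A, C, G, T, N}``
with an identifier, a lifestyle label (temperate / defective / virulent /
unknown) and, optionally, a set of annotated IS-element intervals used to
discount transposon-derived alignment hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

LIFESTYLES = ("temperate", "defective", "virulent", "unknown")

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class Genome:
    """A nucleotide sequence with lifestyle label and optional IS intervals.

    ``is_intervals`` are 0-based half-open ``(start, end)`` pairs on the
    plus strand; they are normalized (sorted, merged) on construction.
    """

    id: str
    seq: str
    lifestyle: str = "unknown"
    is_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        if self.lifestyle not in LIFESTYLES:
            raise ValueError(f"genome {self.id!r}: bad lifestyle {self.lifestyle!r}")
        self.seq = self.seq.upper()
        bad = set(self.seq) - _VALID
        if bad:
            if sum(self.seq.count(c) for c in "ACGT") < len(self.seq) / 2:
                raise ValueError(f"genome {self.id!r}: majority non-nucleotide content")
            logger.warning("genome %s: mapping %s to N", self.id, sorted(bad))
            self.seq = "".join(c if c in _VALID else "N" for c in self.seq)
        self.is_intervals = normalize_intervals(self.is_intervals, len(self.seq))

    def __len__(self) -> int:
        return len(self.seq)

    def revcomp(self) -> "Genome":
        n = len(self.seq)
        return Genome(
            id=self.id,
            seq=revcomp(self.seq),
            lifestyle=self.lifestyle,
            is_intervals=[(n - e, n - s) for s, e in self.is_intervals],
        )


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_intervals(
    intervals: Iterable[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    """Sort, bound-check and merge overlapping half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    for s, e in ivs:
        if not (0 <= s < e <= length):
            raise ValueError(f"interval ({s}, {e}) outside [0, {length})")
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def read_fasta(path: str | Path) -> list[Genome]:
    """Read a (multi-)FASTA of nucleotide sequences into Genome records.

    Record ids are the header token before the first whitespace. Sequences
    are uppercased; characters outside {A,C,G,T,N} are mapped to N with a
    warning. Empty files and duplicate ids are hard errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    genomes = [Genome(id=r.id, seq=str(r.seq)) for r in records]
    seen: set[str] = set()
    for g in genomes:
        if g.id in seen:
            raise ValueError(f"{path}: duplicate id {g.id!r}")
        seen.add(g.id)
    return genomes


def write_fasta(genomes: Iterable[Genome], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a two-column (id, lifestyle) TSV; extra columns are kept."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in df.columns or "lifestyle" not in df.columns:
        raise ValueError(f"{path}: metadata needs 'id' and 'lifestyle' columns")
    bad = set(df["lifestyle"]) - set(LIFESTYLES)
    if bad:
        raise ValueError(f"{path}: unknown lifestyles {sorted(bad)}")
    return df


def apply_metadata(genomes: list[Genome], meta: pd.DataFrame) -> None:
    """Assign lifestyles in place; genomes absent from the table get 'unknown'."""
    table = dict(zip(meta["id"], meta["lifestyle"]))
    for g in genomes:
        g.lifestyle = table.get(g.id, "unknown")
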
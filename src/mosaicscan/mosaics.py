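"""Mosaic detection, IS filtering and per-category summaries.

A *mosaic* is a recently exchanged genomic segment: operationally, a
local alignment of at least 100 bp with strictly more than 90% identity
between two genomes that survived the relatedness screen.  Hits mostly
covered by annotated IS elements are transposition artifacts, not
exchanges, and are removed before counting.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import pandas as pd

from .align import PairwiseAlignment, find_local_hits
from .genomes import Genome
from .scoring import STANDARD, ScoringScheme

MIN_MOSAIC_LEN = 100
MIN_MOSAIC_IDENTITY = 0.90
IS_REMOVAL_OVERLAP = 0.5
IS_MAP_IDENTITY = 0.90
IS_MAP_COVERAGE = 0.80

CATEGORIES = ("T-T", "T-D", "D-D", "V-V", "V-other")


@dataclass
class Mosaic:
    """A filtered high-identity hit between two genomes."""

    g1_id: str
    g2_id: str
    g1_start: int
    g1_end: int
    g2_start: int
    g2_end: int
    strand: str
    length: int          # alignment columns
    identity: float
    score: float
    is_overlap: float = 0.0   # fraction of mosaic overlapping IS annotation

    @classmethod
    def from_hit(cls, hit: PairwiseAlignment) -> "Mosaic":
        return cls(
            g1_id=hit.g1_id,
            g2_id=hit.g2_id,
            g1_start=hit.g1_start,
            g1_end=hit.g1_end,
            g2_start=hit.g2_start,
            g2_end=hit.g2_end,
            strand=hit.strand,
            length=len(hit),
            identity=hit.identity,
            score=hit.score,
        )


def detect_mosaics(
    g1: Genome,
    g2: Genome,
    min_len: int = MIN_MOSAIC_LEN,
    min_identity: float = MIN_MOSAIC_IDENTITY,
    scoring: ScoringScheme = STANDARD,
) -> list[Mosaic]:
    """Mosaics between two distinct genomes: hits of at least ``min_len``
    columns with identity strictly above ``min_identity``, ordered by
    position on g1."""
    if g1.id == g2.id:
        raise ValueError("mosaics are defined between distinct genomes")
    hits = find_local_hits(g1, g2, scoring, min_len=min_len, min_identity=min_identity)
    mosaics = [Mosaic.from_hit(h) for h in hits if h.identity > min_identity]
    mosaics.sort(key=lambda m: (m.g1_start, m.g1_end, m.g2_start))
    return mosaics


def _overlap_fraction(
    start: int, end: int, intervals: list[tuple[int, int]]
) -> float:
    length = end - start
    if length <= 0:
        return 0.0
    covered = sum(
        max(0, min(end, e) - max(start, s)) for s, e in intervals
    )
    return covered / length


def map_is_catalog(
    genomes: list[Genome],
    catalog: list[Genome],
    scoring: ScoringScheme = STANDARD,
) -> dict[str, list[tuple[int, int]]]:
    """Locate IS-catalog sequences on each genome.

    A catalog sequence annotates an interval when it aligns at >=90%
    identity over >=80% of its own length.  Returns merged intervals per
    genome id.
    """
    from .genomes import normalize_intervals

    intervals: dict[str, list[tuple[int, int]]] = {g.id: [] for g in genomes}
    for is_seq in catalog:
        for g in genomes:
            hits = find_local_hits(is_seq, g, scoring, min_len=scoring.word_size,
                                   min_identity=IS_MAP_IDENTITY)
            for h in hits:
                if (h.g1_end - h.g1_start) >= IS_MAP_COVERAGE * len(is_seq):
                    intervals[g.id].append((h.g2_start, h.g2_end))
    return {
        gid: normalize_intervals(ivs, len(next(g for g in genomes if g.id == gid)))
        for gid, ivs in intervals.items()
    }


def filter_is(
    mosaics: list[Mosaic],
    is_intervals: dict[str, list[tuple[int, int]]] | None,
) -> tuple[list[Mosaic], list[Mosaic], float]:
    """Partition mosaics into (kept, removed) by IS overlap.

    A mosaic is removed when at least half of its span on either genome
    overlaps annotated IS intervals.  Returns (kept, removed, pct_is)
    where pct_is = 100 * removed / total; an empty or missing catalog
    removes nothing.
    """
    if not is_intervals or not mosaics:
        return list(mosaics), [], 0.0
    kept, removed = [], []
    for m in mosaics:
        ov1 = _overlap_fraction(m.g1_start, m.g1_end, is_intervals.get(m.g1_id, []))
        ov2 = _overlap_fraction(m.g2_start, m.g2_end, is_intervals.get(m.g2_id, []))
        m.is_overlap = max(ov1, ov2)
        (removed if m.is_overlap >= IS_REMOVAL_OVERLAP else kept).append(m)
    pct = 100.0 * len(removed) / len(mosaics)
    return kept, removed, pct


def mosaic_density(
    mosaics: list[Mosaic], g1: Genome, g2: Genome, denominator: str = "mean"
) -> float:
    """Mosaics per 10 kb of phage genome.

    ``denominator`` picks which genome length normalizes the count:
    'mean' (default), 'min' or 'max' of the pair.
    """
    lengths = {"mean": (len(g1) + len(g2)) / 2, "min": min(len(g1), len(g2)),
               "max": max(len(g1), len(g2))}
    try:
        denom = lengths[denominator]
    except KeyError:
        raise ValueError(f"denominator must be one of {sorted(lengths)}")
    return len(mosaics) / (denom / 10_000.0)


def pair_category(lifestyle1: str, lifestyle2: str) -> str | None:
    """Map a lifestyle pair to its summary category; None when either
    lifestyle is unknown."""
    pair = frozenset((lifestyle1, lifestyle2))
    if "unknown" in pair:
        return None
    if "virulent" in pair:
        return "V-V" if pair == {"virulent"} else "V-other"
    if pair == {"temperate"}:
        return "T-T"
    if pair == {"defective"}:
        return "D-D"
    return "T-D"


@dataclass
class PairResult:
    """Per-pair inputs to the category summaries (filled by the pipeline)."""

    g1_id: str
    g2_id: str
    category: str | None
    n_hits: int = 0                      # local hits before IS filtering
    mosaics: list[Mosaic] = field(default_factory=list)   # kept after IS filter
    n_is_removed: int = 0
    trace_counts: list[int] = field(default_factory=list)  # n_traces per mosaic
    n_testable_sides: int = 0
    mean_background: float = float("nan")


@dataclass
class CategorySummary:
    category: str
    n_pairs: int
    n_blast_matches: int
    pct_is: float
    n_mosaics: int
    mosaics_per_pair: float
    median_len: float
    median_id: float
    n_zero_trace: int
    n_one_trace: int
    n_two_trace: int
    p_random_traces: float


def summarize_categories(
    pair_results: list[PairResult],
    window_len: int = 50,
    delta: float = 0.10,
    flank_len: int = 2000,
) -> list[CategorySummary]:
    """One summary row per pair category over analyzed pairs.

    Medians are over kept mosaics; trace counts require prior trace
    calling (pairs without calls contribute mosaics but no counts).  The
    random-trace probability uses the binomial null at the category's
    mean flank background identity over all tested windows; it is nan
    when no side was testable.
    """
    from .traces import NullModel, random_trace_probability

    out = []
    for cat in CATEGORIES:
        rows = [r for r in pair_results if r.category == cat]
        p = len(rows)
        n_hits = sum(r.n_hits for r in rows)
        n_removed = sum(r.n_is_removed for r in rows)
        mosaics = [m for r in rows for m in r.mosaics]
        m = len(mosaics)
        counts = [c for r in rows for c in r.trace_counts]
        n_sides = sum(r.n_testable_sides for r in rows)
        backgrounds = [
            r.mean_background for r in rows if not pd.isna(r.mean_background)
        ]
        if n_sides and backgrounds:
            null = NullModel(
                b=sum(backgrounds) / len(backgrounds),
                window_len=window_len,
                delta=delta,
            )
            p_random = random_trace_probability(
                null, windows_per_side=flank_len // window_len,
                n_testable_sides=n_sides,
            )
        else:
            p_random = float("nan")
        out.append(
            CategorySummary(
                category=cat,
                n_pairs=p,
                n_blast_matches=n_hits,
                pct_is=100.0 * n_removed / n_hits if n_hits else 0.0,
                n_mosaics=m,
                mosaics_per_pair=m / p if p else 0.0,
                median_len=statistics.median(m_.length for m_ in mosaics) if m else float("nan"),
                median_id=round(
                    statistics.median(100 * m_.identity for m_ in mosaics), 2
                ) if m else float("nan"),
                n_zero_trace=sum(1 for c in counts if c == 0),
                n_one_trace=sum(1 for c in counts if c == 1),
                n_two_trace=sum(1 for c in counts if c >= 2),
                p_random_traces=p_random,
            )
        )
    return out


def summaries_frame(summaries: list[CategorySummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def mosaics_frame(mosaics: list[Mosaic]) -> pd.DataFrame:
    """Pair-level mosaic table; coordinates 1-based inclusive for output."""
    rows = [
        {
            "g1_id": m.g1_id,
            "g2_id": m.g2_id,
            "g1_start": m.g1_start + 1,
            "g1_end": m.g1_end,
            "g2_start": m.g2_start + 1,
            "g2_end": m.g2_end,
            "strand": m.strand,
            "length": m.length,
            "identity_pct": round(100 * m.identity, 2),
            "score": m.score,
            "is_overlap": round(m.is_overlap, 3),
        }
        for m in mosaics
    ]
    return pd.DataFrame(
        rows,
        columns=["g1_id", "g2_id", "g1_start", "g1_end", "g2_start", "g2_end",
                 "strand", "length", "identity_pct", "score", "is_overlap"],
    )
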
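"""Perfect-identity segment statistics and MEPS counts.

Recombinases need a minimal stretch of strict identity to initiate
pairing (a MEPS, Minimal Efficient Pairing Segment): roughly 23-27 bp
for the single-strand-annealing recombinase Redβ and 31-34 bp for RecA.
Counting mismatch-free runs in a homology-region alignment therefore
indicates how many potential initiation sites each pathway sees.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import PairwiseAlignment

MEPS_REDBETA = 23  # lower bound of the Redβ range
MEPS_RECA = 31     # lower bound of the RecA range


@dataclass
class SegmentDistribution:
    """Mismatch-free run lengths of an alignment."""

    segment_lengths: list[int]
    longest: int
    mean_identity: float  # percent


def perfect_segments(aln: PairwiseAlignment) -> SegmentDistribution:
    """Lengths of maximal runs of consecutive match columns.

    Any mismatch or gap column breaks a run; zero-length runs are not
    recorded.
    """
    lengths: list[int] = []
    run = 0
    for a, b in zip(aln.row1, aln.row2):
        if a == b and a != "-" and a != "N":
            run += 1
        elif run:
            lengths.append(run)
            run = 0
    if run:
        lengths.append(run)
    return SegmentDistribution(
        segment_lengths=lengths,
        longest=max(lengths, default=0),
        mean_identity=100.0 * aln.identity,
    )


def meps_count(dist: SegmentDistribution, meps_len: int) -> int:
    """Number of perfect segments long enough to initiate pairing."""
    if meps_len <= 0:
        raise ValueError("meps_len must be positive")
    return sum(1 for n in dist.segment_lengths if n >= meps_len)


def segments_histogram(dist: SegmentDistribution) -> pd.DataFrame:
    counts: dict[int, int] = {}
    for n in dist.segment_lengths:
        counts[n] = counts.get(n, 0) + 1
    return pd.DataFrame(
        sorted(counts.items()), columns=["length", "count"]
    )


def segments_summary(
    regions: dict[str, SegmentDistribution],
    meps_redbeta: int = MEPS_REDBETA,
    meps_reca: int = MEPS_RECA,
) -> pd.DataFrame:
    rows = [
        {
            "region": name,
            "longest": d.longest,
            "mean_identity": round(d.mean_identity, 2),
            "meps_redbeta": meps_count(d, meps_redbeta),
            "meps_reca": meps_count(d, meps_reca),
        }
        for name, d in regions.items()
    ]
    return pd.DataFrame(rows)
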
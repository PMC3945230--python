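"""Alignment scoring schemes.

Two presets are used throughout:

* ``STANDARD`` — megablast-like (+1/−2, gap open 5, extend 2, word 11),
  used for the >90%-identity mosaic screen, where hit sets are robust to
  engine details.
* ``RELAXED`` — +3/−4, gap open 5, extend 2, word 10, the permissive
  scheme that keeps local alignments extending through ~60%-identity
  sequence (expected score per column at identity p is 7p − 4, positive
  down to p ≈ 0.57).  Used for ANI and for phage-vs-host homology screens.

Gap costs follow the Blast convention: a gap of length L costs
``gap_open + gap_extend * L``.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class ScoringScheme:
    match: int
    mismatch: int
    gap_open: int
    gap_extend: int
    word_size: int

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch >= 0:
            raise ValueError("mismatch penalty must be negative")
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("need gap_open >= gap_extend > 0")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")


STANDARD = ScoringScheme(match=1, mismatch=-2, gap_open=5, gap_extend=2, word_size=11)
RELAXED = ScoringScheme(match=3, mismatch=-4, gap_open=5, gap_extend=2, word_size=10)


def make_aligner(scoring: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    """Build a Biopython affine-gap aligner for a scheme.

    N never matches anything (including another N): ambiguity codes are
    scored as mismatches so masked sequence cannot seed spurious identity.
    """
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            matrix[a, b] = scoring.match if (a == b and a != "N") else scoring.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner
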
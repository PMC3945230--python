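"""Homologous-recombination traces in mosaic flanks and their null model.

When a mosaic arose by homologous recombination between diverged
genomes, the crossover necessarily happened inside pre-existing partial
homology, so the sequences immediately flanking the exchanged segment
should be more similar than the genome-wide background b.  Each 2-kb
flank pair is re-aligned globally, the identity of successive 50-bp
windows is measured, and a flank carries a *trace* when at least one
window near the mosaic boundary reaches b + 10 percentage points, b
being the flank's own median window identity.

Flank sequences are stored boundary-first (position 0 abuts the
mosaic), so "proximal" windows are simply the leading windows of the
alignment.

The null model asks how often a window would reach b + delta in the
absence of any planted homology.  With gap-free background divergence,
window matches are Binomial(window_len, b), giving a per-window tail
probability q = P[Bin(w, b) >= ceil(w (b + delta))].  Note q is not
small for moderate b (q ~ 0.07-0.10 for b in 0.55-0.65), so a search
over many windows per flank saturates; restricting the search to
boundary-proximal windows is what makes the call informative.  A
column-permutation estimate of the same tail is provided as a
model-free cross-check.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .align import PairwiseAlignment, global_align, window_profile
from .genomes import Genome, revcomp
from .mosaics import Mosaic
from .scoring import RELAXED, ScoringScheme

FLANK_LEN = 2000
MIN_TESTABLE = 500
WINDOW_LEN = 50
DELTA = 0.10
PROXIMAL_COLS = 2000


@dataclass
class FlankPair:
    """Flanking sequences of a mosaic on one side, boundary-first.

    ``s1``/``s2`` read outward from the mosaic boundary on g1 and on the
    strand-consistent orientation of g2.  ``truncated`` marks flanks
    shortened by a genome end; sides shorter than MIN_TESTABLE bp on
    either genome are untestable.
    """

    side: str  # left | right
    s1: str
    s2: str
    truncated: bool

    @property
    def testable(self) -> bool:
        return min(len(self.s1), len(self.s2)) >= MIN_TESTABLE


@dataclass
class SideCall:
    side: str
    testable: bool
    background_b: float = float("nan")
    qualifying_windows: list[tuple[int, float]] = field(default_factory=list)
    trace: bool = False
    best_window_identity: float = float("nan")


@dataclass
class TraceCall:
    mosaic: Mosaic
    left: SideCall
    right: SideCall

    @property
    def n_traces(self) -> int:
        return int(self.left.trace) + int(self.right.trace)

    @property
    def untestable_sides(self) -> int:
        return int(not self.left.testable) + int(not self.right.testable)

    @property
    def testable_sides(self) -> int:
        return 2 - self.untestable_sides


@dataclass
class NullModel:
    b: float
    window_len: int = WINDOW_LEN
    delta: float = DELTA

    @property
    def q_window(self) -> float:
        """P[window identity >= b + delta] for a background window."""
        if self.b + self.delta >= 1.0:
            return 0.0
        k = math.ceil(self.window_len * (self.b + self.delta))
        return float(binom.sf(k - 1, self.window_len, self.b))


def extract_flanks(
    mosaic: Mosaic, g1: Genome, g2: Genome, flank_len: int = FLANK_LEN
) -> tuple[FlankPair, FlankPair]:
    """The (left, right) flank pairs of a mosaic.

    Flanks run outward from the mosaic boundary and are returned
    boundary-first.  For minus-strand mosaics the g2 flank comes from
    the reverse-complement strand: the left flank of the g1 segment is
    contiguous with the g2 sequence *after* the mosaic on the plus
    strand, read on the complementary strand (and vice versa on the
    right).
    """
    n1, n2 = len(g1), len(g2)
    a1, b1 = mosaic.g1_start, mosaic.g1_end
    a2, b2 = mosaic.g2_start, mosaic.g2_end

    left1 = g1.seq[max(0, a1 - flank_len) : a1][::-1]
    right1 = g1.seq[b1 : b1 + flank_len]
    if mosaic.strand == "+":
        left2 = g2.seq[max(0, a2 - flank_len) : a2][::-1]
        right2 = g2.seq[b2 : b2 + flank_len]
    else:
        # rc-strand coordinates: left of the mosaic on g1 continues past
        # b2 on the g2 plus strand; boundary-first means reading rc(g2)
        # backwards from the segment start.
        left2 = revcomp(g2.seq[b2 : min(n2, b2 + flank_len)])[::-1]
        right2 = revcomp(g2.seq[max(0, a2 - flank_len) : a2])

    left = FlankPair(
        side="left",
        s1=left1,
        s2=left2,
        truncated=len(left1) < flank_len or len(left2) < flank_len,
    )
    right = FlankPair(
        side="right",
        s1=right1,
        s2=right2,
        truncated=len(right1) < flank_len or len(right2) < flank_len,
    )
    return left, right


def side_call_from_alignment(
    aln: PairwiseAlignment,
    side: str = "left",
    window_len: int = WINDOW_LEN,
    delta: float = DELTA,
    proximal_cols: int = PROXIMAL_COLS,
) -> SideCall:
    """Trace call on an already-aligned, boundary-first flank pair.

    The alignment's column 0 must abut the mosaic boundary.  Exposed
    separately from :func:`call_traces` so the window/threshold logic
    can be applied to any column correspondence — for instance the
    known positional alignment of an indel-free simulation, on which
    the binomial null is exact.
    """
    call = SideCall(side=side, testable=True)
    profile = window_profile(aln, window_len)
    idents = profile.identities
    call.background_b = statistics.median(idents)
    proximal = [
        (start, ident)
        for start, ident in profile.windows
        if start + window_len <= proximal_cols
    ]
    if proximal:
        call.best_window_identity = max(i for _, i in proximal)
    threshold = call.background_b + delta
    # saturated background: no headroom for a window to clear b + delta
    if threshold >= 1.0 - 1.0 / window_len:
        return call
    call.qualifying_windows = [
        (start, ident) for start, ident in proximal if ident >= threshold
    ]
    call.trace = bool(call.qualifying_windows)
    return call


def _call_side(
    flank: FlankPair,
    scoring: ScoringScheme,
    window_len: int,
    delta: float,
    proximal_cols: int,
) -> SideCall:
    if not flank.testable:
        return SideCall(side=flank.side, testable=False)
    aln = global_align(flank.s1, flank.s2, scoring)
    return side_call_from_alignment(aln, flank.side, window_len, delta,
                                    proximal_cols)


def call_traces(
    mosaic: Mosaic,
    g1: Genome,
    g2: Genome,
    scoring: ScoringScheme = RELAXED,
    flank_len: int = FLANK_LEN,
    window_len: int = WINDOW_LEN,
    delta: float = DELTA,
    proximal_cols: int = PROXIMAL_COLS,
) -> TraceCall:
    """HR-trace call for one mosaic.

    Each testable flank pair is globally re-aligned; the flank's
    background b is its median window identity, and the side carries a
    trace when a window within ``proximal_cols`` of the boundary reaches
    b + delta.  Untestable sides (under MIN_TESTABLE bp) are flagged and
    excluded from the trace count denominator.
    """
    left, right = extract_flanks(mosaic, g1, g2, flank_len)
    return TraceCall(
        mosaic=mosaic,
        left=_call_side(left, scoring, window_len, delta, proximal_cols),
        right=_call_side(right, scoring, window_len, delta, proximal_cols),
    )


def random_trace_probability(
    null: NullModel, windows_per_side: int, n_testable_sides: int
) -> float:
    """P(at least one qualifying window anywhere) under the binomial null.

    Exactly zero when b + delta >= 1 (no window can qualify).
    """
    if windows_per_side <= 0 or n_testable_sides <= 0:
        raise ValueError("window and side counts must be positive")
    q = null.q_window
    if q == 0.0:
        return 0.0
    n = windows_per_side * n_testable_sides
    # log-space for the tiny-q regime
    return float(-np.expm1(n * np.log1p(-q)))


def permutation_window_tail(
    aln: PairwiseAlignment,
    window_len: int = WINDOW_LEN,
    delta: float = DELTA,
    n_perm: int = 200,
    seed: int = 0,
) -> float:
    """Column-permutation estimate of the per-window tail probability.

    Shuffles alignment columns, recomputes window identities against the
    shuffled median + delta threshold, and returns the fraction of
    windows qualifying — a model-free counterpart of
    :attr:`NullModel.q_window`.
    """
    rng = np.random.default_rng(seed)
    matches = np.array(
        [a == b and a != "-" and a != "N" for a, b in zip(aln.row1, aln.row2)],
        dtype=bool,
    )
    n_windows = len(matches) // window_len
    if n_windows == 0:
        raise ValueError("alignment shorter than one window")
    total = 0
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(matches)[: n_windows * window_len]
        idents = perm.reshape(n_windows, window_len).mean(axis=1)
        threshold = float(np.median(idents)) + delta
        if threshold >= 1.0 - 1.0 / window_len:
            total += n_windows
            continue
        hits += int((idents >= threshold).sum())
        total += n_windows
    return hits / total


def trace_fraction(calls: list[TraceCall]) -> float:
    """Percent of testable mosaics with at least one HR trace.

    A mosaic is testable when at least one side is.  Returns nan when no
    mosaic is testable.
    """
    testable = [c for c in calls if c.testable_sides > 0]
    if not testable:
        return float("nan")
    with_trace = sum(1 for c in testable if c.n_traces >= 1)
    return 100.0 * with_trace / len(testable)


def traces_frame(calls: list[TraceCall]):
    import pandas as pd

    rows = []
    for c in calls:
        for side in (c.left, c.right):
            rows.append(
                {
                    "g1_id": c.mosaic.g1_id,
                    "g2_id": c.mosaic.g2_id,
                    "g1_start": c.mosaic.g1_start + 1,
                    "g1_end": c.mosaic.g1_end,
                    "side": side.side,
                    "testable": side.testable,
                    "background_b": round(side.background_b, 4)
                    if not math.isnan(side.background_b)
                    else float("nan"),
                    "best_window_identity": side.best_window_identity,
                    "trace": side.trace,
                    "n_traces": c.n_traces,
                }
            )
    return pd.DataFrame(rows)
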
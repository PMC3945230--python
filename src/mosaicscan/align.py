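"""Pairwise alignment engines and windowed identity profiles.

Two engines cover every downstream stage:

* :func:`find_local_hits` — a seed-and-extend local aligner: exact
  word-size seeds on both strands, greedy diagonal clustering, then a
  bounded affine-gap Smith–Waterman extension on each cluster
  neighborhood, followed by merging of redundant hits.
* :func:`global_align` — an affine-gap global (Needleman–Wunsch–Gotoh)
  alignment used to re-align mosaic flanks.

Identity is conservative throughout: gap columns count as non-matches,
both in whole-alignment identity and in 50-bp window identities.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

from .genomes import Genome, revcomp
from .scoring import ScoringScheme, make_aligner

MAX_GLOBAL_LEN = 10_000

# seed-cluster geometry; exposed for tuning but stable in practice
DIAG_TOL = 30        # max diagonal drift within one cluster
JOIN_GAP = 200       # max gap (bp) between consecutive seeds of a cluster
REGION_MARGIN = 200  # extension margin around a cluster before local DP
MERGE_OVERLAP = 0.5  # reciprocal-overlap fraction at which two hits merge


@dataclass
class PairwiseAlignment:
    """An aligned pair of subsequences with plus-strand coordinates.

    ``row1``/``row2`` are the gapped rows of the alignment.  For minus
    strand hits, ``row2`` holds the reverse-complemented g2 subsequence
    (the strand that actually aligns), while ``g2_start``/``g2_end``
    always refer to the plus strand of g2.
    """

    g1_id: str
    g2_id: str
    g1_start: int
    g1_end: int
    g2_start: int
    g2_end: int
    strand: str
    row1: str
    row2: str
    score: float
    n_match: int = field(init=False)
    n_mismatch: int = field(init=False)
    n_gapcols: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.row1) != len(self.row2):
            raise ValueError("alignment rows differ in length")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        nm = nx = ng = 0
        for a, b in zip(self.row1, self.row2):
            if a == "-" and b == "-":
                raise ValueError("column gapped in both rows")
            if a == "-" or b == "-":
                ng += 1
            elif a == b and a != "N":
                nm += 1
            else:
                nx += 1
        self.n_match, self.n_mismatch, self.n_gapcols = nm, nx, ng

    def __len__(self) -> int:
        return len(self.row1)

    @property
    def identity(self) -> float:
        return self.n_match / len(self.row1)

    @property
    def columns(self) -> list[tuple[str, str]]:
        return list(zip(self.row1, self.row2))


@dataclass
class WindowProfile:
    """Identity of successive non-overlapping windows along an alignment."""

    window_len: int
    windows: list[tuple[int, float]]

    @property
    def identities(self) -> list[float]:
        return [w for _, w in self.windows]


def global_align(s1: str, s2: str, scoring: ScoringScheme) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two sequences.

    Both sequences must be non-empty and at most 10 kb (quadratic DP
    guard); longer inputs should be chunked by the caller.  The traceback
    is Biopython's canonical first path and is deterministic.
    """
    if not s1 or not s2:
        raise ValueError("global_align requires non-empty sequences")
    if len(s1) > MAX_GLOBAL_LEN or len(s2) > MAX_GLOBAL_LEN:
        raise ValueError(
            f"sequences exceed {MAX_GLOBAL_LEN} bp; chunk the input before aligning"
        )
    aligner = make_aligner(scoring, "global")
    aln = aligner.align(s1, s2)[0]
    return PairwiseAlignment(
        g1_id="s1",
        g2_id="s2",
        g1_start=0,
        g1_end=len(s1),
        g2_start=0,
        g2_end=len(s2),
        strand="+",
        row1=str(aln[0]),
        row2=str(aln[1]),
        score=float(aln.score),
    )


def window_profile(aln: PairwiseAlignment, window_len: int = 50) -> WindowProfile:
    """Identity of successive ``window_len``-column windows.

    Windows tile the alignment without overlap; a trailing partial window
    is dropped.  Gap columns count as non-matches.
    """
    n = len(aln)
    if n < window_len:
        raise ValueError(f"alignment ({n} cols) shorter than one window ({window_len})")
    windows = []
    for start in range(0, n - window_len + 1, window_len):
        r1 = aln.row1[start : start + window_len]
        r2 = aln.row2[start : start + window_len]
        matches = sum(1 for a, b in zip(r1, r2) if a == b and a != "-" and a != "N")
        windows.append((start, matches / window_len))
    return WindowProfile(window_len=window_len, windows=windows)


# ---------------------------------------------------------------------------
# seed-and-extend local search


def _seed_positions(s1: str, s2: str, w: int) -> list[tuple[int, int]]:
    """Exact shared w-mers as (pos1, pos2); words containing N are skipped."""
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(s1) - w + 1):
        word = s1[i : i + w]
        if "N" not in word:
            index[word].append(i)
    seeds = []
    for j in range(len(s2) - w + 1):
        word = s2[j : j + w]
        if "N" in word:
            continue
        for i in index.get(word, ()):
            seeds.append((i, j))
    return seeds


def _cluster_seeds(seeds: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group seeds into diagonal neighborhoods.

    Seeds sort by diagonal (i − j); a run breaks when the diagonal drifts
    by more than DIAG_TOL.  Within a diagonal run, seeds sort by position
    and split where the gap exceeds JOIN_GAP.
    """
    if not seeds:
        return []
    by_diag = sorted(seeds, key=lambda s: (s[0] - s[1], s[0]))
    runs: list[list[tuple[int, int]]] = [[by_diag[0]]]
    for s in by_diag[1:]:
        if (s[0] - s[1]) - (runs[-1][-1][0] - runs[-1][-1][1]) > DIAG_TOL:
            runs.append([s])
        else:
            runs[-1].append(s)
    clusters = []
    for run in runs:
        run.sort()
        cluster = [run[0]]
        for s in run[1:]:
            if s[0] - cluster[-1][0] > JOIN_GAP:
                clusters.append(cluster)
                cluster = [s]
            else:
                cluster.append(s)
        clusters.append(cluster)
    return clusters


def _extend_cluster(
    s1: str,
    s2: str,
    cluster: list[tuple[int, int]],
    word: int,
    aligner,
) -> tuple[int, int, int, int, str, str, float] | None:
    """Best local alignment within the cluster neighborhood.

    Returns (start1, end1, start2, end2, row1, row2, score) in the
    coordinates of s1/s2, or None when nothing scores above zero.
    """
    i_lo = max(0, min(i for i, _ in cluster) - REGION_MARGIN)
    i_hi = min(len(s1), max(i for i, _ in cluster) + word + REGION_MARGIN)
    j_lo = max(0, min(j for _, j in cluster) - REGION_MARGIN)
    j_hi = min(len(s2), max(j for _, j in cluster) + word + REGION_MARGIN)
    alns = aligner.align(s1[i_lo:i_hi], s2[j_lo:j_hi])
    if alns.score <= 0:
        return None
    aln = alns[0]
    coords = aln.coordinates
    start1, end1 = int(coords[0][0]), int(coords[0][-1])
    start2, end2 = int(coords[1][0]), int(coords[1][-1])
    return (
        i_lo + start1,
        i_lo + end1,
        j_lo + start2,
        j_lo + end2,
        str(aln[0]),
        str(aln[1]),
        float(aln.score),
    )


def _score_rows(row1: str, row2: str, scoring: ScoringScheme) -> float:
    """Score of a gapped alignment under a scheme (gap run: open + extend*L)."""
    score = 0.0
    in_gap = False
    for a, b in zip(row1, row2):
        if a == "-" or b == "-":
            score -= scoring.gap_extend + (0 if in_gap else scoring.gap_open)
            in_gap = True
        else:
            score += scoring.match if (a == b and a != "N") else scoring.mismatch
            in_gap = False
    return score


def _trim_to_identity_core(
    row1: str, row2: str, min_identity: float
) -> tuple[int, int] | None:
    """Column range [lo, hi) of the maximal subsegment at the target identity.

    Columns are scored +1 for a match and −t/(1−t) otherwise, where the
    trim identity t sits just below the caller's ``min_identity`` (t =
    min_identity − 0.025): segments above t score positive, extension
    tails through anything more diverged — background sequence but also
    flanking partial homology well below the reporting threshold —
    score negative, and the maximum-sum subarray is the
    identity-consistent core of the hit.  Without this, score-positive
    extension through intermediate-identity flanks would fold the very
    homology that trace calling inspects into the hit itself.
    ``min_identity <= 0.025`` disables trimming.  Returns None when no
    column is a match.
    """
    t = min_identity - 0.025
    if t <= 0:
        return (0, len(row1))
    penalty = t / (1.0 - t) if t < 1 else float("inf")
    best_sum = 0.0
    best: tuple[int, int] | None = None
    run_sum = 0.0
    run_start = 0
    for k, (a, b) in enumerate(zip(row1, row2)):
        gain = 1.0 if (a == b and a != "-" and a != "N") else -penalty
        if run_sum <= 0:
            run_sum, run_start = gain, k
        else:
            run_sum += gain
        if run_sum > best_sum or (
            run_sum == best_sum and best is not None and k + 1 - run_start > best[1] - best[0]
        ):
            best_sum = run_sum
            best = (run_start, k + 1)
    return best


POLISH_WINDOW = 25


def _polish_ends(row1: str, row2: str, min_identity: float) -> tuple[int, int]:
    """Column range after walking both ends inward until the terminal
    POLISH_WINDOW columns meet ``min_identity``.

    The maximal-subsegment trim bounds the hit statistically but can
    still carry a short lucky stretch of flanking lower-identity
    homology; requiring the terminal window itself to meet the
    reporting threshold pins the boundary near the true identity
    change-point.  No-op when ``min_identity <= 0``.
    """
    n = len(row1)
    if min_identity <= 0 or n < POLISH_WINDOW:
        return (0, n)
    need = math.ceil(min_identity * POLISH_WINDOW)
    is_match = [
        a == b and a != "-" and a != "N" for a, b in zip(row1, row2)
    ]
    lo, hi = 0, n
    while hi - lo >= POLISH_WINDOW and sum(is_match[lo : lo + POLISH_WINDOW]) < need:
        lo += 1
    while hi - lo >= POLISH_WINDOW and sum(is_match[hi - POLISH_WINDOW : hi]) < need:
        hi -= 1
    if hi - lo < POLISH_WINDOW:
        return (0, 0)
    return (lo, hi)


def _merge_hits(hits: list[PairwiseAlignment], len2: int) -> list[PairwiseAlignment]:
    """Drop hits redundant with a higher-scoring overlapping hit.

    Two hits merge when they share the same strand, lie within DIAG_TOL
    diagonals and overlap by at least MERGE_OVERLAP of the shorter span on
    both genomes.
    """
    kept: list[PairwiseAlignment] = []
    for h in sorted(hits, key=lambda h: -h.score):
        redundant = False
        for k in kept:
            if h.strand != k.strand:
                continue
            d_h = h.g1_start - (h.g2_start if h.strand == "+" else len2 - h.g2_end)
            d_k = k.g1_start - (k.g2_start if k.strand == "+" else len2 - k.g2_end)
            if abs(d_h - d_k) > DIAG_TOL:
                continue
            ov1 = min(h.g1_end, k.g1_end) - max(h.g1_start, k.g1_start)
            ov2 = min(h.g2_end, k.g2_end) - max(h.g2_start, k.g2_start)
            span1 = min(h.g1_end - h.g1_start, k.g1_end - k.g1_start)
            span2 = min(h.g2_end - h.g2_start, k.g2_end - k.g2_start)
            if ov1 >= MERGE_OVERLAP * span1 and ov2 >= MERGE_OVERLAP * span2:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def find_local_hits(
    g1: Genome,
    g2: Genome,
    scoring: ScoringScheme,
    min_len: int,
    min_identity: float,
) -> list[PairwiseAlignment]:
    """Seed-and-extend local alignment search between two genomes.

    Exact ``word_size`` seeds are collected on both strands of g2,
    clustered by diagonal neighborhood, and each cluster is extended by a
    local affine-gap DP on its neighborhood.  Hits shorter than
    ``min_len`` columns or below ``min_identity`` are discarded;
    overlapping redundant hits keep only the higher-scoring one.  Results
    sort by ``g1_start``.
    """
    w = scoring.word_size
    if len(g1) < w or len(g2) < w:
        raise ValueError("sequences shorter than the seed word size")
    aligner = make_aligner(scoring, "local")
    hits: list[PairwiseAlignment] = []
    len2 = len(g2)
    for strand, s2 in (("+", g2.seq), ("-", revcomp(g2.seq))):
        for cluster in _cluster_seeds(_seed_positions(g1.seq, s2, w)):
            ext = _extend_cluster(g1.seq, s2, cluster, w, aligner)
            if ext is None:
                continue
            a1, b1, a2, b2, row1, row2, score = ext
            core = _trim_to_identity_core(row1, row2, min_identity)
            if core is None:
                continue
            lo, hi = core
            plo, phi = _polish_ends(row1[lo:hi], row2[lo:hi], min_identity)
            lo, hi = lo + plo, lo + phi
            if hi <= lo:
                continue
            if hi - lo < len(row1):
                pre1 = sum(1 for c in row1[:lo] if c != "-")
                suf1 = sum(1 for c in row1[hi:] if c != "-")
                pre2 = sum(1 for c in row2[:lo] if c != "-")
                suf2 = sum(1 for c in row2[hi:] if c != "-")
                a1, b1 = a1 + pre1, b1 - suf1
                a2, b2 = a2 + pre2, b2 - suf2
                row1, row2 = row1[lo:hi], row2[lo:hi]
                score = _score_rows(row1, row2, scoring)
            if strand == "-":
                a2, b2 = len2 - b2, len2 - a2
            hit = PairwiseAlignment(
                g1_id=g1.id,
                g2_id=g2.id,
                g1_start=a1,
                g1_end=b1,
                g2_start=a2,
                g2_end=b2,
                strand=strand,
                row1=row1,
                row2=row2,
                score=score,
            )
            if len(hit) >= min_len and hit.identity >= min_identity:
                hits.append(hit)
    merged = _merge_hits(hits, len2)
    merged.sort(key=lambda h: (h.g1_start, h.g1_end, h.g2_start))
    return merged


def hits_to_table(hits: list[PairwiseAlignment]):
    """Tabular (blast-outfmt-6-like) view of a hit list.

    Coordinates are 1-based inclusive, mirroring tabular Blast output; the
    in-memory objects stay 0-based half-open.
    """
    import pandas as pd

    rows = []
    for h in hits:
        rows.append(
            {
                "qid": h.g1_id,
                "sid": h.g2_id,
                "pident": round(100 * h.identity, 2),
                "length": len(h),
                "mismatch": h.n_mismatch,
                "gapcols": h.n_gapcols,
                "qstart": h.g1_start + 1,
                "qend": h.g1_end,
                "sstart": h.g2_start + 1,
                "send": h.g2_end,
                "strand": h.strand,
                "score": h.score,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "qid", "sid", "pident", "length", "mismatch", "gapcols",
            "qstart", "qend", "sstart", "send", "strand", "score",
        ],
    )
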
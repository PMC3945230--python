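"""End-to-end scan: relatedness screen → mosaics → IS filter → traces → summaries.

The pipeline order mirrors how the comparative screen is run on a real
cohort: every unordered genome pair is ANI-screened, mosaics are
detected on the analyzed pairs only, IS-derived hits are discounted,
HR traces are called on the kept mosaics, and per-category summary
rows plus a pair matrix (mosaic density below the diagonal, mean trace
count above) are written as TSV/JSON twins of every reported number.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ani as ani_mod
from .genomes import Genome
from .mosaics import (
    PairResult,
    detect_mosaics,
    filter_is,
    map_is_catalog,
    mosaic_density,
    mosaics_frame,
    pair_category,
    summaries_frame,
    summarize_categories,
)
from .scoring import RELAXED, STANDARD, ScoringScheme
from .traces import PROXIMAL_COLS, call_traces, trace_fraction, traces_frame

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables of a scan, at the thresholds used throughout:
    mosaics >=100 bp at >90% identity, 2-kb flanks, 50-bp windows,
    b+10% traces, relatedness exclusion at 70/50 (T/D) and 68/48 (V),
    redundancy at 92/80."""

    min_mosaic_len: int = 100
    min_mosaic_identity: float = 0.90
    fragment_len: int = 1000
    flank_len: int = 2000
    window_len: int = 50
    delta: float = 0.10
    proximal_cols: int = PROXIMAL_COLS
    density_denominator: str = "mean"
    mosaic_scoring: ScoringScheme = field(default_factory=lambda: STANDARD)
    relaxed_scoring: ScoringScheme = field(default_factory=lambda: RELAXED)
    skip_ani: bool = False          # trust the caller's pair list (synthetic cohorts)
    pairs: list[tuple[str, str]] | None = None  # restrict to these pairs
    seed: int = 0


@dataclass
class ScanResult:
    statuses: pd.DataFrame
    mosaics: pd.DataFrame
    traces: pd.DataFrame
    summaries: pd.DataFrame
    matrix: pd.DataFrame
    pair_results: list[PairResult]
    mosaics_by_pair: dict[tuple[str, str], list]
    traces_by_pair: dict[tuple[str, str], list]


def run_scan(
    genomes: list[Genome],
    config: RunConfig | None = None,
    is_catalog: list[Genome] | None = None,
    is_intervals: dict[str, list[tuple[int, int]]] | None = None,
) -> ScanResult:
    """Run the full mosaic scan over a cohort.

    ``is_intervals`` (per-genome) takes precedence over mapping an
    ``is_catalog`` FASTA; genome-attached intervals are merged in.
    Deterministic for fixed inputs and config.
    """
    config = config or RunConfig()
    by_id = {g.id: g for g in genomes}
    if len(by_id) != len(genomes):
        raise ValueError("duplicate genome ids in cohort")

    if config.pairs is not None:
        pairs = [tuple(sorted(p)) for p in config.pairs]
    else:
        pairs = [tuple(sorted(p)) for p in itertools.combinations(sorted(by_id), 2)]

    # relatedness screen
    if config.skip_ani:
        statuses = [
            ani_mod.PairStatus(g1_id=a, g2_id=b, status="analyzed")
            for a, b in pairs
        ]
        status_df = pd.DataFrame([vars(s) for s in statuses])
    else:
        table = [
            ani_mod.ani_coverage(by_id[a], by_id[b], config.relaxed_scoring,
                                 config.fragment_len)
            for a, b in pairs
        ]
        all_statuses = ani_mod.classify_pairs(genomes, table)
        wanted = set(pairs)
        statuses = [s for s in all_statuses if (s.g1_id, s.g2_id) in wanted]
        status_df = ani_mod.ani_table_frame(
            [t for t in table if tuple(sorted((t.g1_id, t.g2_id))) in wanted],
            statuses,
        )
        for s in statuses:
            if s.status != "analyzed":
                logger.info("pair %s/%s excluded: %s", s.g1_id, s.g2_id, s.status)

    # IS annotation
    resolved_is: dict[str, list[tuple[int, int]]] = {
        g.id: list(g.is_intervals) for g in genomes
    }
    if is_intervals:
        for gid, ivs in is_intervals.items():
            resolved_is.setdefault(gid, []).extend(ivs)
    if is_catalog:
        mapped = map_is_catalog(genomes, is_catalog, config.mosaic_scoring)
        for gid, ivs in mapped.items():
            resolved_is.setdefault(gid, []).extend(ivs)
    from .genomes import normalize_intervals

    resolved_is = {
        gid: normalize_intervals(ivs, len(by_id[gid]))
        for gid, ivs in resolved_is.items()
    }

    analyzed = [
        (s.g1_id, s.g2_id) for s in statuses if s.status == "analyzed"
    ]
    pair_results: list[PairResult] = []
    mosaics_by_pair: dict[tuple[str, str], list] = {}
    traces_by_pair: dict[tuple[str, str], list] = {}
    all_mosaic_rows = []
    all_trace_rows = []
    matrix_cells = {}

    for a, b in analyzed:
        g1, g2 = by_id[a], by_id[b]
        detected = detect_mosaics(
            g1, g2, config.min_mosaic_len, config.min_mosaic_identity,
            config.mosaic_scoring,
        )
        kept, removed, _ = filter_is(detected, resolved_is)
        for m in removed:
            logger.info(
                "mosaic %s:%d-%d removed: IS overlap %.2f",
                m.g1_id, m.g1_start, m.g1_end, m.is_overlap,
            )
        calls = [
            call_traces(
                m, g1, g2, config.relaxed_scoring, config.flank_len,
                config.window_len, config.delta, config.proximal_cols,
            )
            for m in kept
        ]
        backgrounds = [
            s.background_b
            for c in calls
            for s in (c.left, c.right)
            if s.testable
        ]
        pair_results.append(
            PairResult(
                g1_id=a,
                g2_id=b,
                category=pair_category(g1.lifestyle, g2.lifestyle),
                n_hits=len(detected),
                mosaics=kept,
                n_is_removed=len(removed),
                trace_counts=[c.n_traces for c in calls],
                n_testable_sides=sum(c.testable_sides for c in calls),
                mean_background=(
                    float(np.mean(backgrounds)) if backgrounds else float("nan")
                ),
            )
        )
        mosaics_by_pair[(a, b)] = kept
        traces_by_pair[(a, b)] = calls
        all_mosaic_rows.append(mosaics_frame(kept))
        all_trace_rows.append(traces_frame(calls))
        matrix_cells[(a, b)] = {
            "density": mosaic_density(kept, g1, g2, config.density_denominator),
            "mean_traces": (
                float(np.mean([c.n_traces for c in calls])) if calls else 0.0
            ),
        }

    summaries = summarize_categories(
        pair_results, config.window_len, config.delta, config.flank_len
    )
    matrix = build_pair_matrix(sorted(by_id), matrix_cells, statuses)
    return ScanResult(
        statuses=status_df,
        mosaics=(
            pd.concat(all_mosaic_rows, ignore_index=True)
            if all_mosaic_rows else mosaics_frame([])
        ),
        traces=(
            pd.concat(all_trace_rows, ignore_index=True)
            if all_trace_rows else traces_frame([])
        ),
        summaries=summaries_frame(summaries),
        matrix=matrix,
        pair_results=pair_results,
        mosaics_by_pair=mosaics_by_pair,
        traces_by_pair=traces_by_pair,
    )


def build_pair_matrix(
    ids: list[str],
    cells: dict[tuple[str, str], dict],
    statuses,
) -> pd.DataFrame:
    """Square pair matrix: mosaic density below the diagonal, mean trace
    count above, 'excluded' for screened-out pairs, empty diagonal."""
    status_by_pair = {tuple(sorted((s.g1_id, s.g2_id))): s.status for s in statuses}
    mat = pd.DataFrame("", index=ids, columns=ids, dtype=object)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i == j:
                continue
            key = tuple(sorted((a, b)))
            status = status_by_pair.get(key)
            if status is None:
                continue
            if status != "analyzed":
                mat.iloc[i, j] = "excluded"
            elif key in cells:
                val = cells[key]["density"] if i > j else cells[key]["mean_traces"]
                mat.iloc[i, j] = round(val, 4)
    return mat


def write_outputs(result: ScanResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.statuses.to_csv(outdir / "pair_status.tsv", sep="\t", index=False)
    result.mosaics.to_csv(outdir / "mosaics.tsv", sep="\t", index=False)
    result.traces.to_csv(outdir / "traces.tsv", sep="\t", index=False)
    result.summaries.to_csv(outdir / "category_summary.tsv", sep="\t", index=False)
    result.summaries.to_json(outdir / "category_summary.json", orient="records",
                             indent=1)
    result.matrix.to_csv(outdir / "pair_matrix.tsv", sep="\t")
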
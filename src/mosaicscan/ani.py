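"""Fragment-based average nucleotide identity and genome-pair screening.

ANI follows the fragment convention of Goris et al.: the smaller genome
is cut into consecutive 1-kb fragments, each fragment is locally aligned
to the larger genome under the relaxed scheme, and a fragment contributes
when its best hit covers at least 70% of it.  ANI is the mean percent
identity of contributing best hits; coverage is the percent of fragments
contributing.  The relaxed scoring keeps alignments extending at ~60%
identity, so ANI values well below the reach of default Blast parameters
remain measurable.

Pairs are then screened before mosaic analysis:

* redundant (ani > 92 and coverage > 80): the genomes are near-copies and
  the lexicographically larger id is dropped from the cohort;
* excluded_related: temperate/defective pairs with ani > 70 and
  coverage > 50, virulent pairs with ani > 68 and coverage > 48 — close
  relatives in which mosaic flanks cannot be distinguished from plain
  vertical homology;
* analyzed otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import PairwiseAlignment, find_local_hits
from .genomes import Genome
from .scoring import RELAXED, ScoringScheme

REDUNDANT_ANI, REDUNDANT_COV = 92.0, 80.0
TD_ANI, TD_COV = 70.0, 50.0
VIRULENT_ANI, VIRULENT_COV = 68.0, 48.0
FRAGMENT_CONTRIB_COV = 0.70


@dataclass
class PairANI:
    g1_id: str
    g2_id: str
    ani: float          # percent, over contributing fragments; nan if none
    coverage: float     # percent of fragments contributing
    n_fragments: int
    n_contributing: int


@dataclass
class PairStatus:
    g1_id: str
    g2_id: str
    status: str  # analyzed | excluded_related | redundant


def ani_coverage(
    g1: Genome,
    g2: Genome,
    scoring: ScoringScheme = RELAXED,
    fragment_len: int = 1000,
) -> PairANI:
    """Fragment-based ANI and coverage of a genome pair.

    Fragmentation is always on the smaller genome, so the measure is
    symmetric up to fragment registration.
    """
    small, large = (g1, g2) if len(g1) <= len(g2) else (g2, g1)
    if len(small) < fragment_len:
        raise ValueError(
            f"genome {small.id} shorter than fragment_len={fragment_len}"
        )
    n_fragments = len(small) // fragment_len
    identities = []
    for k in range(n_fragments):
        frag = Genome(
            id=f"{small.id}.frag{k}",
            seq=small.seq[k * fragment_len : (k + 1) * fragment_len],
        )
        hits = find_local_hits(frag, large, scoring, min_len=scoring.word_size,
                               min_identity=0.0)
        if not hits:
            continue
        best = max(hits, key=lambda h: h.score)
        if (best.g1_end - best.g1_start) >= FRAGMENT_CONTRIB_COV * fragment_len:
            identities.append(best.identity)
    n_contrib = len(identities)
    ani = 100.0 * sum(identities) / n_contrib if n_contrib else float("nan")
    return PairANI(
        g1_id=g1.id,
        g2_id=g2.id,
        ani=ani,
        coverage=100.0 * n_contrib / n_fragments,
        n_fragments=n_fragments,
        n_contributing=n_contrib,
    )


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def classify_pairs(
    genomes: list[Genome], ani_table: list[PairANI]
) -> list[PairStatus]:
    """Screen all unordered genome pairs by relatedness.

    Mixed temperate/virulent pairs use the temperate/defective
    thresholds.  When a pair is redundant, every pair involving the
    dropped genome (lexicographically larger id) is also marked
    redundant so the genome leaves the cohort entirely.
    """
    by_pair = { _pair_key(p.g1_id, p.g2_id): p for p in ani_table }
    lifestyles = {g.id: g.lifestyle for g in genomes}
    ids = sorted(lifestyles)

    dropped: set[str] = set()
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            p = by_pair.get(_pair_key(a, b))
            if p is None:
                raise ValueError(f"pair ({a}, {b}) missing from ANI table")
            if not pd.isna(p.ani) and p.ani > REDUNDANT_ANI and p.coverage > REDUNDANT_COV:
                dropped.add(max(a, b))

    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            p = by_pair[_pair_key(a, b)]
            if a in dropped or b in dropped:
                status = "redundant"
            elif pd.isna(p.ani):
                status = "analyzed"
            else:
                both_virulent = lifestyles[a] == lifestyles[b] == "virulent"
                ani_t, cov_t = (
                    (VIRULENT_ANI, VIRULENT_COV) if both_virulent else (TD_ANI, TD_COV)
                )
                if p.ani > ani_t and p.coverage > cov_t:
                    status = "excluded_related"
                else:
                    status = "analyzed"
            out.append(PairStatus(g1_id=a, g2_id=b, status=status))
    return out


def find_homology_regions(
    phage: Genome,
    host: Genome,
    min_len: int = 100,
    min_mean_id: float = 0.70,
    scoring: ScoringScheme = RELAXED,
) -> list[PairwiseAlignment]:
    """Phage-vs-host homology screen with the relaxed scheme.

    Finds regions of at least ``min_len`` aligned columns at a mean
    identity of ``min_mean_id`` or more — the screen used to locate
    prophage-borne homology with an infecting phage.
    """
    return find_local_hits(phage, host, scoring, min_len=min_len,
                           min_identity=min_mean_id)


def ani_table_frame(table: list[PairANI], statuses: list[PairStatus]) -> pd.DataFrame:
    status_by_pair = {_pair_key(s.g1_id, s.g2_id): s.status for s in statuses}
    rows = [
        {
            "g1_id": p.g1_id,
            "g2_id": p.g2_id,
            "ani": round(p.ani, 2),
            "coverage": round(p.coverage, 2),
            "n_fragments": p.n_fragments,
            "n_contributing": p.n_contributing,
            "status": status_by_pair.get(_pair_key(p.g1_id, p.g2_id), "analyzed"),
        }
        for p in table
    ]
    return pd.DataFrame(rows)
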
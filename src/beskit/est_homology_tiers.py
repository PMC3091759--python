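"""Tiered EST-homology classification and coding-content estimates.

Genomic survey sequences are compared against transcript (unigene/EST)
databases in a fixed precedence order — own-species first, close
relatives next, all other plants last. A query consults a database only
if no earlier database produced a qualifying hit, so tier counts
partition the queries with hits. Two stringencies are tracked with a
double E-value cut-off (defaults 1e-20 low, 1e-50 high): the low cut-off
admits reads spanning intron/exon boundaries, the high one bounds the
false-positive rate, and together they bracket the coding fraction.

The homology search itself is external (BLAST-style tabular input); a
small gap-free seed-and-extend matcher for synthetic end-to-end tests
lives in :mod:`beskit.naive_search`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from beskit._util import round_half_up
from beskit.io_formats import HitRecord

__all__ = [
    "TierAssignment", "CodingEstimate",
    "tiered_hits", "coding_fraction", "transcriptome_size",
    "DEFAULT_E_LOW", "DEFAULT_E_HIGH",
]

DEFAULT_E_LOW = 1e-20
DEFAULT_E_HIGH = 1e-50


@dataclass(frozen=True)
class TierAssignment:
    """One query's tier: the first database (in precedence order) with a
    hit at the low-stringency cut-off; `tier` is None for no qualifying
    hit anywhere. `high_stringency` is judged on the assigned tier's best
    hit only, so high-stringency counts are a subset of low-stringency
    counts tier by tier."""

    query_id: str
    tier: str | None
    high_stringency: bool
    best_hit: HitRecord | None


@dataclass
class CodingEstimate:
    n_total: int
    low_counts: dict[str, int]
    high_counts: dict[str, int]
    low_percents: dict[str, float]
    high_percents: dict[str, float]
    total_low: int
    total_high: int
    total_low_percent: float
    total_high_percent: float

    @property
    def coding_fraction_range(self) -> tuple[float, float]:
        """[high-stringency %, low-stringency %] bracket of coding content."""
        return (self.total_high_percent, self.total_low_percent)


def _best_hit(hits: Sequence[HitRecord]) -> HitRecord:
    # lowest E-value, tie -> highest bit score, tie -> first in file order
    best = hits[0]
    for h in hits[1:]:
        if (h.e_value, -h.bit_score) < (best.e_value, -best.bit_score):
            best = h
    return best


def tiered_hits(
    hits_by_db: Mapping[str, Sequence[HitRecord]],
    precedence: Sequence[str],
    e_low: float = DEFAULT_E_LOW,
    e_high: float = DEFAULT_E_HIGH,
    queries: Sequence[str] | None = None,
) -> list[TierAssignment]:
    """Assign each query to the first database with a low-stringency hit.

    `precedence` must cover every database present in `hits_by_db`. If
    `queries` is given, queries with no qualifying hit are reported with
    tier None; otherwise only queries appearing in some hit table are
    reported.
    """
    if e_high > e_low:
        raise ValueError("e_high must be at most e_low")
    unknown = set(hits_by_db) - set(precedence)
    if unknown:
        raise ValueError(f"databases not in precedence order: {sorted(unknown)}")
    per_query: dict[str, dict[str, list[HitRecord]]] = {}
    for db, hits in hits_by_db.items():
        for h in hits:
            per_query.setdefault(h.query_id, {}).setdefault(db, []).append(h)
    universe = list(queries) if queries is not None else sorted(per_query)
    assignments: list[TierAssignment] = []
    for q in universe:
        tier: str | None = None
        high = False
        best: HitRecord | None = None
        dbs = per_query.get(q, {})
        for db in precedence:
            if db not in dbs:
                continue
            cand = _best_hit(dbs[db])
            if cand.e_value <= e_low:
                tier, best = db, cand
                high = cand.e_value <= e_high
                break
        assignments.append(TierAssignment(query_id=q, tier=tier,
                                          high_stringency=high, best_hit=best))
    return assignments


def coding_fraction(assignments: Sequence[TierAssignment], n_total: int) -> CodingEstimate:
    """Per-tier counts and percentages over `n_total` analyzed sequences."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    n_assigned = sum(1 for a in assignments if a.tier is not None)
    if n_total < n_assigned:
        raise ValueError("n_total smaller than the number of assigned queries")
    tiers: list[str] = []
    for a in assignments:
        if a.tier is not None and a.tier not in tiers:
            tiers.append(a.tier)
    low = {t: sum(1 for a in assignments if a.tier == t) for t in tiers}
    high = {t: sum(1 for a in assignments if a.tier == t and a.high_stringency) for t in tiers}
    pct = lambda n: round_half_up(100.0 * n / n_total, 1)
    total_low, total_high = sum(low.values()), sum(high.values())
    return CodingEstimate(
        n_total=n_total,
        low_counts=low, high_counts=high,
        low_percents={t: pct(n) for t, n in low.items()},
        high_percents={t: pct(n) for t, n in high.items()},
        total_low=total_low, total_high=total_high,
        total_low_percent=pct(total_low), total_high_percent=pct(total_high),
    )


def transcriptome_size(melon_hits: int, all_hits: int, unigene_count: int) -> int:
    """Capture-style transcriptome-size estimate.

    If the own-species unigene set explains only a fraction
    ``melon_hits / all_hits`` of all EST-homologous sequences, the full
    transcriptome is about ``unigene_count`` divided by that fraction.
    Rounded to the nearest 1,000.
    """
    if all_hits <= 0:
        raise ValueError("all_hits must be positive")
    if not 0 < melon_hits <= all_hits:
        raise ValueError("melon_hits must be in (0, all_hits]")
    if unigene_count <= 0:
        raise ValueError("unigene_count must be positive")
    estimate = unigene_count / (melon_hits / all_hits)
    return int(round_half_up(estimate / 1000.0, 0) * 1000)
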
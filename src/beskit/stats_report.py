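"""Coverage/GC/length arithmetic and structured survey reports.

Percentages, coverages and densities are rounded half-up to one decimal;
integer counts are never rounded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from beskit._util import round_half_up
from beskit.io_formats import BesRead, SequenceRecord

__all__ = [
    "LibraryStats", "SurveyReport", "SequenceStats",
    "genomic_coverage", "gc_content", "total_length_stats", "build_report",
]


@dataclass(frozen=True)
class LibraryStats:
    n_clones: int
    true_clone_fraction: float
    mean_insert_kb: float
    genome_size_mb: float

    @property
    def coverage(self) -> float:
        return genomic_coverage(self.n_clones, self.true_clone_fraction,
                                self.mean_insert_kb, self.genome_size_mb)


@dataclass
class SequenceStats:
    count: int
    min_bp: int
    max_bp: int
    mean_bp: float
    total_mb: float
    genome_fraction_percent: float


def genomic_coverage(
    n_clones: int,
    true_fraction: float,
    mean_insert_kb: float,
    genome_mb: float,
) -> float:
    """Genome equivalents covered by a clone library.

    round(n_clones x true_fraction) true clones times the mean insert,
    over the haploid genome size; one decimal. Note that some published
    library tables print coverages that this arithmetic does not exactly
    reproduce (their genome-size constant is not always stated); reports
    therefore carry the inputs alongside the result.
    """
    if n_clones <= 0 or not 0 < true_fraction <= 1 or mean_insert_kb <= 0 or genome_mb <= 0:
        raise ValueError("all coverage inputs must be positive (fraction in (0,1])")
    true_clones = int(round_half_up(n_clones * true_fraction, 0))
    return round_half_up(true_clones * mean_insert_kb / (genome_mb * 1000.0), 1)


def gc_content(seqs: Sequence[SequenceRecord]) -> float:
    """Percent G+C over unambiguous bases (N excluded), one decimal."""
    gc = acgt = 0
    for rec in seqs:
        s = rec.sequence
        g_c = s.count("G") + s.count("C")
        gc += g_c
        acgt += g_c + s.count("A") + s.count("T")
    if acgt == 0:
        raise ValueError("gc_content requires at least one unambiguous base")
    return round_half_up(100.0 * gc / acgt, 1)


def total_length_stats(
    reads: Sequence[BesRead | SequenceRecord],
    genome_size_mb: float | None = None,
) -> SequenceStats:
    """Count/min/max/mean/total of read lengths, plus genome fraction.

    Total is reported in Mb to one decimal; the genome fraction (if a
    genome size is given) in percent to one decimal. Full precision is
    kept internally; only the reported fields are rounded.
    """
    lengths = [
        len(r.record.sequence) if isinstance(r, BesRead) else len(r.sequence)
        for r in reads
    ]
    if not lengths:
        return SequenceStats(count=0, min_bp=0, max_bp=0, mean_bp=0.0,
                             total_mb=0.0, genome_fraction_percent=0.0)
    total_bp = sum(lengths)
    fraction = 0.0
    if genome_size_mb:
        fraction = round_half_up(100.0 * (total_bp / 1e6) / genome_size_mb, 1)
    return SequenceStats(
        count=len(lengths),
        min_bp=min(lengths),
        max_bp=max(lengths),
        mean_bp=round_half_up(total_bp / len(lengths), 1),
        total_mb=round_half_up(total_bp / 1e6, 1),
        genome_fraction_percent=fraction,
    )


@dataclass
class SurveyReport:
    """Machine-readable survey report mirroring the standard table layout:
    library stats, sequence stats, SSR summary, repeat summary, coding
    estimate and synteny summary, with the config that produced them."""

    sections: dict
    config: dict = field(default_factory=dict)

    MANDATORY = ("sequence_stats",)
    KNOWN = ("library_stats", "sequence_stats", "ssr_summary",
             "repeat_summary", "coding_estimate", "synteny_summary")

    def to_json(self) -> str:
        def default(obj):
            if hasattr(obj, "__dict__"):
                return obj.__dict__
            if isinstance(obj, (set, tuple)):
                return list(obj)
            return str(obj)
        return json.dumps({"sections": self.sections, "config": self.config},
                          indent=2, sort_keys=True, default=default)


def build_report(config: dict | None = None, **sections) -> SurveyReport:
    """Assemble a survey report from section outputs.

    Sections omitted by the caller are marked absent (not zero); a missing
    mandatory section is an error. Deterministic given identical inputs.
    """
    unknown = set(sections) - set(SurveyReport.KNOWN)
    if unknown:
        raise ValueError(f"unknown report sections: {sorted(unknown)}")
    for name in SurveyReport.MANDATORY:
        if name not in sections or sections[name] is None:
            raise ValueError(f"mandatory report section missing: {name}")
    full = {}
    for name in SurveyReport.KNOWN:
        full[name] = sections[name] if name in sections and sections[name] is not None else "absent"
    return SurveyReport(sections=full, config=dict(config or {}))
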
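"""Repeat-annotation classification, summary ratios, and masking.

Repeat detection itself is done upstream by a screening tool whose output
table this package consumes; here each annotation row is mapped into a
fixed category tree of plant repeat classes (retroelements with LINE/L1
and LTR Ty1-Copia / Ty3-Gypsy branches, the major DNA-transposon
superfamilies, rolling-circle Helitrons, telomere-related sequences and
rRNA genes), summary ratios are computed, and the annotated spans can be
masked out of the sequences before homology searches.

The counting unit is the annotation row — fragmented elements are not
defragmented — matching how survey tables count homology matches rather
than reconstructed elements.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from beskit._util import round_half_up
from beskit.io_formats import RepeatHit, SequenceRecord

__all__ = [
    "RepeatTaxonomy", "RepeatSummary", "MaskMode",
    "classify_repeat", "summarize_repeats", "mask_sequences",
    "DEFAULT_TAXONOMY",
]

UNCLASSIFIED = "Unclassified"

#: the category tree: class -> subclass (or "") -> leaves
_TREE: dict[str, dict[str, tuple[str, ...]]] = {
    "Retroelements": {
        "LINES": ("L1",),
        "LTR": ("Ty1/Copia", "Ty3/Gypsy", UNCLASSIFIED),
    },
    "DNA transposons": {
        "": ("hobo-Activator", "En-Spm", "MuDR", "Harbinger", UNCLASSIFIED),
    },
    "Rolling circles": {"": ("Helitron",)},
    "Telomere-related": {"": ("Telomere-related",)},
    "rRNA genes": {
        "": ("Small subunit", "Large subunit", "45S and Internal spacer region"),
    },
}

#: transposable-element classes (class I + class II + rolling circles)
TE_CLASSES = ("Retroelements", "DNA transposons", "Rolling circles")

#: substring aliases (lower-cased) from family/class labels to leaf paths
_DEFAULT_ALIASES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("copia", ("Retroelements", "LTR", "Ty1/Copia")),
    ("ty1", ("Retroelements", "LTR", "Ty1/Copia")),
    ("gypsy", ("Retroelements", "LTR", "Ty3/Gypsy")),
    ("ty3", ("Retroelements", "LTR", "Ty3/Gypsy")),
    ("line/l1", ("Retroelements", "LINES", "L1")),
    ("l1", ("Retroelements", "LINES", "L1")),
    ("line", ("Retroelements", "LINES", "L1")),
    ("ltr", ("Retroelements", "LTR", UNCLASSIFIED)),
    ("hobo", ("DNA transposons", "", "hobo-Activator")),
    ("activator", ("DNA transposons", "", "hobo-Activator")),
    ("hat", ("DNA transposons", "", "hobo-Activator")),
    ("en-spm", ("DNA transposons", "", "En-Spm")),
    ("enspm", ("DNA transposons", "", "En-Spm")),
    ("cacta", ("DNA transposons", "", "En-Spm")),
    ("mudr", ("DNA transposons", "", "MuDR")),
    ("mule", ("DNA transposons", "", "MuDR")),
    ("harbinger", ("DNA transposons", "", "Harbinger")),
    ("pif", ("DNA transposons", "", "Harbinger")),
    ("dna", ("DNA transposons", "", UNCLASSIFIED)),
    ("helitron", ("Rolling circles", "", "Helitron")),
    ("rc", ("Rolling circles", "", "Helitron")),
    ("telo", ("Telomere-related", "", "Telomere-related")),
    ("ssu", ("rRNA genes", "", "Small subunit")),
    ("18s", ("rRNA genes", "", "Small subunit")),
    ("lsu", ("rRNA genes", "", "Large subunit")),
    ("25s", ("rRNA genes", "", "Large subunit")),
    ("28s", ("rRNA genes", "", "Large subunit")),
    ("45s", ("rRNA genes", "", "45S and Internal spacer region")),
    ("its", ("rRNA genes", "", "45S and Internal spacer region")),
)


class MaskMode(str, Enum):
    HARD_N = "HARD_N"
    SOFT_LOWER = "SOFT_LOWER"


@dataclass
class RepeatTaxonomy:
    """The category tree plus an editable alias table.

    Aliases map (lower-cased) substrings of a family or class label to a
    leaf path; the longest matching alias wins. Labels matching nothing
    fall back to the Unclassified leaf of their declared class when that
    class is recognisable, else to a global Unclassified bucket.
    """

    tree: dict[str, dict[str, tuple[str, ...]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _TREE.items()})
    aliases: list[tuple[str, tuple[str, ...]]] = field(
        default_factory=lambda: list(_DEFAULT_ALIASES))

    def leaves(self) -> list[tuple[str, ...]]:
        out = []
        for cls, subs in self.tree.items():
            for sub, leaves in subs.items():
                for leaf in leaves:
                    out.append((cls, sub, leaf) if sub else (cls, "", leaf))
        return out

    def resolve(self, family_label: str, declared_class: str = "") -> tuple[str, ...]:
        text = f"{declared_class}/{family_label}".lower()
        best: tuple[str, ...] | None = None
        best_len = -1
        for key, path in self.aliases:
            if key in text and len(key) > best_len:
                best, best_len = path, len(key)
        if best is not None:
            return best
        return ("Unclassified",)


DEFAULT_TAXONOMY = RepeatTaxonomy()


@dataclass
class RepeatSummary:
    counts_by_leaf: dict[tuple[str, ...], int]
    counts_by_class: dict[str, int]
    te_count: int
    retro_fraction_of_tes: float | None  # percent
    copia_fraction_of_retros: float | None  # percent
    gypsy_fraction_of_retros: float | None  # percent
    ty1_ty3_ratio: float | None
    class_ratio: float | None  # class I (retro) / class II (DNA) count ratio
    enspm_fraction_of_dna: float | None  # percent
    masked_bp: int
    percent_of_sequence: float
    total_bp: int


def classify_repeat(hit: RepeatHit, taxonomy: RepeatTaxonomy = DEFAULT_TAXONOMY) -> list[str]:
    """Resolve a hit's class path in place and return it."""
    path = taxonomy.resolve(hit.family_label, hit.declared_class)
    hit.class_path = list(path)
    return hit.class_path


def _span_union_bp(hits: Iterable[RepeatHit]) -> int:
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        by_seq.setdefault(h.seq_id, []).append((h.start, h.end))
    total = 0
    for spans in by_seq.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    return total


def summarize_repeats(
    hits: Sequence[RepeatHit],
    total_bp: int,
    taxonomy: RepeatTaxonomy = DEFAULT_TAXONOMY,
) -> RepeatSummary:
    """Aggregate classified hits into the survey's repeat table.

    Transposable elements are retroelements + DNA transposons + rolling
    circles; percentages are rounded half-up to one decimal. Hits without
    a resolved class path are classified first.
    """
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    for h in hits:
        if not h.class_path:
            classify_repeat(h, taxonomy)
    leaf_counts = Counter(tuple(h.class_path) for h in hits)
    class_counts: Counter[str] = Counter()
    for path, n in leaf_counts.items():
        class_counts[path[0]] += n
    te = sum(class_counts.get(c, 0) for c in TE_CLASSES)
    retro = class_counts.get("Retroelements", 0)
    dna = class_counts.get("DNA transposons", 0)
    copia = leaf_counts.get(("Retroelements", "LTR", "Ty1/Copia"), 0)
    gypsy = leaf_counts.get(("Retroelements", "LTR", "Ty3/Gypsy"), 0)
    enspm = leaf_counts.get(("DNA transposons", "", "En-Spm"), 0)
    pct = lambda num, den: round_half_up(100.0 * num / den, 1) if den else None
    masked = _span_union_bp(hits) if hits else 0
    return RepeatSummary(
        counts_by_leaf=dict(leaf_counts),
        counts_by_class=dict(class_counts),
        te_count=te,
        retro_fraction_of_tes=pct(retro, te),
        copia_fraction_of_retros=pct(copia, retro),
        gypsy_fraction_of_retros=pct(gypsy, retro),
        ty1_ty3_ratio=round_half_up(copia / gypsy, 1) if gypsy else None,
        class_ratio=round_half_up(retro / dna, 1) if dna else None,
        enspm_fraction_of_dna=pct(enspm, dna),
        masked_bp=masked,
        percent_of_sequence=round_half_up(100.0 * masked / total_bp, 1),
        total_bp=total_bp,
    )


def mask_sequences(
    seqs: Sequence[SequenceRecord],
    hits: Sequence[RepeatHit],
    mode: MaskMode = MaskMode.HARD_N,
) -> tuple[list[SequenceRecord], int]:
    """Mask annotated spans; returns (masked records, masked bp).

    HARD_N replaces spans with N (the mode used before homology searches);
    SOFT_LOWER lower-cases them. Masked bp is the size of the union of
    spans. A span beyond its sequence end is an error.
    """
    by_seq: dict[str, list[RepeatHit]] = {}
    for h in hits:
        by_seq.setdefault(h.seq_id, []).append(h)
    out: list[SequenceRecord] = []
    for rec in seqs:
        spans = by_seq.get(rec.id, [])
        chars = list(rec.sequence)
        for h in spans:
            if h.end > len(chars):
                raise ValueError(
                    f"repeat span [{h.start},{h.end}) beyond end of {rec.id!r} "
                    f"(length {len(chars)})"
                )
            for i in range(h.start, h.end):
                chars[i] = "N" if mode is MaskMode.HARD_N else chars[i].lower()
        out.append(SequenceRecord(id=rec.id, sequence="".join(chars),
                                  description=rec.description))
    known = {r.id for r in seqs}
    relevant = [h for h in hits if h.seq_id in known]
    masked_bp = _span_union_bp(relevant) if relevant else 0
    return out, masked_bp
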
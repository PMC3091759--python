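"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as plain enumeration, deliberately sharing no
code with the package internals beyond the public pairwise alignment op.
"""

from __future__ import annotations

from beskit.io_formats import SequenceRecord
from beskit.redundancy_assembly import overlap_align

SSR_THRESHOLDS = {1: 12, 2: 12, 3: 12, 4: 16, 5: 20, 6: 24}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rc(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def _primitive(unit: str) -> bool:
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return False
    return True


def brute_canonical(motif: str) -> str:
    forms = []
    for m in (motif, _rc(motif)):
        for i in range(len(m)):
            forms.append(m[i:] + m[:i])
    return min(forms)


def brute_force_ssrs(seq: str) -> list[tuple[int, int, int, str]]:
    """Every maximal perfect tandem run meeting the thresholds, after the
    same longest-span/smallest-unit/leftmost nested suppression, as
    (start, end, unit_length, canonical) tuples."""
    n = len(seq)
    candidates: list[tuple[int, int, int, str]] = []
    for k, min_total in SSR_THRESHOLDS.items():
        for start in range(n - k + 1):
            unit = seq[start:start + k]
            if set(unit) - set("ACGT"):
                continue
            if not _primitive(unit):
                continue
            # left-maximality: the run must not extend one base left
            if start >= 1 and seq[start - 1] == seq[start - 1 + k] and seq[start - 1] in "ACGT":
                continue
            end = start + k
            while end < n and seq[end] in "ACGT" and seq[end] == seq[end - k]:
                end += 1
            if end - start < min_total:
                continue
            candidates.append((start, end, k, brute_canonical(unit)))
    candidates = sorted(set(candidates), key=lambda c: (-(c[1] - c[0]), c[2], c[0]))
    accepted: list[tuple[int, int, int, str]] = []
    for cand in candidates:
        if any(a[0] <= cand[0] and cand[1] <= a[1] for a in accepted):
            continue
        accepted.append(cand)
    return sorted(accepted, key=lambda c: (c[0], c[2]))


def overlap_components(
    seqs: list[SequenceRecord],
    min_overlap: int = 80,
    min_identity: float = 95.0,
) -> set[frozenset[str]]:
    """Connected components of the all-pairs accepted-overlap graph."""
    parent = {s.id: s.id for s in seqs}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if overlap_align(seqs[i], seqs[j], min_overlap, min_identity).accepted:
                ri, rj = find(seqs[i].id), find(seqs[j].id)
                if ri != rj:
                    parent[ri] = rj
    comps: dict[str, set[str]] = {}
    for s in seqs:
        comps.setdefault(find(s.id), set()).add(s.id)
    return {frozenset(v) for v in comps.values()}
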
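"""RAD consensus calling, reference construction and allele extraction.

Implements the coverage-tiered consensus rules (positions with coverage below
the masking floor or inside the masking band become N; called positions take
the majority base, upgraded to a two-base IUPAC code when the minority base is
supported by enough reads and/or a sufficient frequency), the ambiguity-based
sequence filter, stack building from identical reads, greedy >98%-identity
centroid clustering into a RAD reference, positional deduplication of mapped
representatives, and diploid splitting of IUPAC consensus into two alleles.

Read quality scores are not modelled: all rules operate on base counts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

# two-base IUPAC codes with bases in alphabetical order
IUPAC2 = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
IUPAC2_BASES = {code: tuple(sorted(pair)) for pair, code in IUPAC2.items()}
IUPAC3PLUS = set("BDHV")


@dataclass(frozen=True)
class PileupColumn:
    position: int
    base_counts: dict  # base -> count over A/C/G/T

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())


@dataclass(frozen=True)
class ConsensusSequence:
    sequence: str
    source_id: str | None = None

    @property
    def ambiguous_fraction(self) -> float:
        if not self.sequence:
            return 0.0
        amb = sum(1 for b in self.sequence.upper() if b not in "ACGTN")
        return amb / len(self.sequence)


@dataclass(frozen=True)
class RefEntry:
    """A reference representative with optional genomic placement."""

    sequence: str
    count: int
    scaffold_id: str | None = None
    position: int | None = None
    strand: str | None = None


def call_consensus(
    columns: list[PileupColumn],
    min_call: int = 8,
    mask_lo: int = 3,
    mask_hi: int = 7,
    amb_reads: int = 3,
    amb_frac: float = 0.10,
    amb_rule: str = "or",
    source_id: str | None = None,
) -> ConsensusSequence:
    """Consensus base per pileup column under the coverage-tier rules.

    Coverage below ``mask_lo`` or in [mask_lo, mask_hi] emits N (masked, but
    coordinates preserved). At coverage >= ``min_call`` the majority base is
    called, upgraded to a two-base IUPAC code when the second base has at
    least ``amb_reads`` reads and/or frequency above ``amb_frac``
    (``amb_rule`` picks OR or AND semantics). More than two bases meeting the
    minority rule yields N with a warning.
    """
    if not columns:
        raise ValueError("empty pileup")
    if amb_rule not in ("or", "and"):
        raise ValueError("amb_rule must be 'or' or 'and'")
    out = []
    for col in sorted(columns, key=lambda c: c.position):
        depth = col.depth
        if depth < min_call:
            out.append("N")
            continue
        counts = sorted(col.base_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        major = counts[0][0]
        qualifying = []
        for base, c in counts[1:]:
            if c == 0:
                continue
            hit_reads = c >= amb_reads
            hit_frac = c / depth > amb_frac
            hit = (hit_reads or hit_frac) if amb_rule == "or" else (hit_reads and hit_frac)
            if hit:
                qualifying.append(base)
        if not qualifying:
            out.append(major)
        elif len(qualifying) == 1:
            out.append(IUPAC2[frozenset((major, qualifying[0]))])
        else:
            logger.warning(
                "position %d: %d bases pass the ambiguity rule; masking",
                col.position,
                len(qualifying) + 1,
            )
            out.append("N")
    return ConsensusSequence("".join(out), source_id=source_id)


def filter_ambiguous(seq: ConsensusSequence, max_frac: float = 0.025) -> bool:
    """Keep decision: True when the IUPAC fraction is below ``max_frac``."""
    if not seq.sequence:
        raise ValueError("empty consensus sequence")
    return seq.ambiguous_fraction < max_frac


def find_stacks(reads: list[str], min_copies: int = 3) -> dict[str, int]:
    """Exact-identity read stacks with at least ``min_copies`` copies."""
    if not reads:
        return {}
    if len({len(r) for r in reads}) > 1:
        raise ValueError("reads must have equal length")
    counts = Counter(r.upper() for r in reads)
    return {seq: c for seq, c in sorted(counts.items()) if c >= min_copies}


def _identity(a: str, b: str) -> float:
    arr1 = np.frombuffer(a.encode(), dtype=np.uint8)
    arr2 = np.frombuffer(b.encode(), dtype=np.uint8)
    return float((arr1 == arr2).mean())


def cluster_references(
    stacks: dict[str, int], min_identity: float = 0.98
) -> list[RefEntry]:
    """Greedy centroid clustering of stacks from all conspecific individuals.

    Sequences are visited in order of descending stack count (ties broken by
    lexicographic sequence). Each sequence joins the best-matching existing
    centroid with identity strictly above ``min_identity``, else founds a new
    cluster. One representative (the centroid) per cluster, carrying the
    cluster's total stack count.
    """
    if not stacks:
        return []
    if len({len(s) for s in stacks}) > 1:
        raise ValueError("stack sequences must have equal length")
    order = sorted(stacks.items(), key=lambda kv: (-kv[1], kv[0]))
    centroids: list[str] = []
    totals: list[int] = []
    for seq, count in order:
        best = -1
        best_ident = min_identity
        for i, cen in enumerate(centroids):
            ident = _identity(seq, cen)
            if ident > best_ident:
                best_ident = ident
                best = i
        if best >= 0:
            totals[best] += count
        else:
            centroids.append(seq)
            totals.append(count)
    return [RefEntry(sequence=s, count=c) for s, c in zip(centroids, totals)]


def dedup_by_position(entries: list[RefEntry]) -> list[RefEntry]:
    """One representative per (scaffold, position, strand).

    The survivor is the entry with the highest total stack count; ties go to
    the lexicographically smallest sequence. Entries without a placement are
    dropped (they never reached the genome).
    """
    best: dict[tuple, RefEntry] = {}
    for e in entries:
        if e.scaffold_id is None or e.position is None:
            continue
        key = (e.scaffold_id, e.position, e.strand)
        cur = best.get(key)
        if cur is None or (e.count, _neg(e.sequence)) > (cur.count, _neg(cur.sequence)):
            best[key] = e
    return [best[k] for k in sorted(best, key=lambda k: (k[0], k[1], str(k[2])))]


class _neg(str):
    """Inverts lexicographic comparison so max() prefers the smaller string."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def call_alleles(seq: ConsensusSequence) -> tuple[str, str]:
    """Split a diploid consensus into two allele sequences.

    Each two-base IUPAC position contributes its alphabetically first base to
    allele 1 and the second to allele 2 (phase is arbitrary; per-site allele
    frequencies do not depend on it). Three-or-four-base codes cannot be
    diploid-phased and raise ValueError.
    """
    a1 = []
    a2 = []
    for i, b in enumerate(seq.sequence.upper()):
        if b in "ACGTN-":
            a1.append(b)
            a2.append(b)
        elif b in IUPAC2_BASES:
            x, y = IUPAC2_BASES[b]
            a1.append(x)
            a2.append(y)
        elif b in IUPAC3PLUS:
            raise ValueError(f"position {i}: {b} is a >2-base ambiguity; cannot phase")
        else:
            raise ValueError(f"position {i}: unexpected symbol {b!r}")
    return "".join(a1), "".join(a2)
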
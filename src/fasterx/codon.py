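"""Codon-level utilities shared by the simulator, divergence counting and MK classification.

Implements NG86-style fractional synonymous/nonsynonymous site counting and
minimal-path substitution counting between codons, under the standard genetic
code. Stop codons are excluded as substitution targets and paths through stops
are disallowed.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(t) for t in itertools.product(BASES, repeat=3)) if c not in STOP_CODONS
)


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon, ``None`` for stops, ``ValueError`` for non-ACGT."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        return None
    try:
        return CODON_TABLE[codon]
    except KeyError:
        raise ValueError(f"untranslatable codon {codon!r}") from None


def is_synonymous(codon_from: str, codon_to: str) -> bool:
    aa1 = translate_codon(codon_from)
    aa2 = translate_codon(codon_to)
    if aa1 is None or aa2 is None:
        raise ValueError("stop codons have no synonymous/nonsynonymous status")
    return aa1 == aa2


@lru_cache(maxsize=None)
def single_base_changes(codon: str) -> tuple[tuple[str, bool], ...]:
    """All single-base neighbours of ``codon`` that are sense codons.

    Returns (neighbour, is_synonymous) pairs; changes into stop codons are
    omitted (they are not available substitution targets in this model).
    """
    out = []
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            out.append((alt, is_synonymous(codon, alt)))
    return tuple(out)


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """NG86 fractional (synonymous, nonsynonymous) site counts for one codon.

    Each of the three positions contributes 1 site, split by the fraction of
    its three possible changes that are synonymous; changes to stop codons are
    excluded from the denominator.
    """
    s = 0.0
    n = 0.0
    for pos in range(3):
        syn = 0
        tot = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            tot += 1
            syn += is_synonymous(codon, alt)
        if tot:
            s += syn / tot
            n += 1.0 - syn / tot
        # position with all changes -> stop contributes no sites
    return s, n


@lru_cache(maxsize=None)
def codon_path_counts(codon_from: str, codon_to: str) -> tuple[float, float]:
    """Minimal-path averaged (synonymous, nonsynonymous) substitution counts.

    Differences at 1-3 positions are resolved by enumerating all orderings of
    the single-base steps, discarding orderings that pass through a stop
    codon, and averaging the per-step classifications over the remaining
    orderings (NG86 pathway averaging).
    """
    if codon_from == codon_to:
        return 0.0, 0.0
    diff_pos = [i for i in range(3) if codon_from[i] != codon_to[i]]
    syn_tot = 0.0
    nonsyn_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = codon_from
        syn = 0.0
        nonsyn = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_to[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if is_synonymous(cur, nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            syn_tot += syn
            nonsyn_tot += nonsyn
            n_paths += 1
    if n_paths == 0:
        # every ordering passes through a stop: fall back to classifying the
        # raw per-position changes against codon_from (rare, degenerate)
        syn = sum(
            is_synonymous_safe(codon_from, codon_to, pos) for pos in diff_pos
        )
        return float(syn), float(len(diff_pos) - syn)
    return syn_tot / n_paths, nonsyn_tot / n_paths


def is_synonymous_safe(codon_from: str, codon_to: str, pos: int) -> bool:
    alt = codon_from[:pos] + codon_to[pos] + codon_from[pos + 1 :]
    if alt in STOP_CODONS:
        return False
    return is_synonymous(codon_from, alt)
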
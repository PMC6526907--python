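"""Kingman coalescent with piecewise-constant population size.

Independent loci, infinite-sites mutation. The simulator is used both by the
synthetic RAD-data generator and by the recurrent-founder-event simulations.
Population-size histories with many epochs (periodic crash/recovery cycles)
are handled by precomputing the cumulative coalescent intensity
Lambda(t) = integral_0^t dt' / (2 N(t')) and inverting it with a binary
search, so waiting times cost O(log n_epochs) instead of stepping epoch by
epoch.

Time is measured in generations backward from the sampling point; population
sizes are diploid effective sizes (per-pair coalescence rate 1/(2N) per
generation, so E[pi] = 4 N mu at equilibrium).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SizeHistory:
    """Piecewise-constant diploid Ne, backward in time from sampling.

    ``times`` are ascending epoch start times with ``times[0] == 0``; the last
    epoch extends to infinity.
    """

    times: np.ndarray
    sizes: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.sizes, dtype=float)
        if t.ndim != 1 or t.shape != s.shape or t.size == 0:
            raise ValueError("times and sizes must be equal-length 1-D arrays")
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("epoch times must start at 0 and be strictly increasing")
        if np.any(s <= 0):
            raise ValueError("population sizes must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "sizes", s)
        # cumulative intensity at each epoch start
        rates = 1.0 / (2.0 * s)
        cum = np.concatenate([[0.0], np.cumsum(np.diff(t) * rates[:-1])])
        object.__setattr__(self, "_rates", rates)
        object.__setattr__(self, "_cum", cum)

    @classmethod
    def constant(cls, ne: float) -> "SizeHistory":
        return cls(np.array([0.0]), np.array([float(ne)]))

    def intensity(self, t: float) -> float:
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self._cum[i] + (t - self.times[i]) * self._rates[i])

    def inverse_intensity(self, lam: float) -> float:
        i = int(np.searchsorted(self._cum, lam, side="right")) - 1
        return float(self.times[i] + (lam - self._cum[i]) / self._rates[i])


def _coalesce_counts(rng: np.random.Generator, n: int, history: SizeHistory):
    """One genealogy; returns arrays (branch durations, descendant counts)."""
    durations = np.empty(2 * n - 2)
    out_counts = np.empty(2 * n - 2, dtype=np.int64)
    lam = 0.0
    idx = 0
    births = [0.0] * n
    live = list(range(n))
    node_counts = [1] * n
    for k in range(n, 1, -1):
        lam += rng.exponential() / (k * (k - 1) / 2.0)
        t = history.inverse_intensity(lam)
        i, j = rng.choice(k, size=2, replace=False)
        if i > j:
            i, j = j, i
        a = live[i]
        b = live[j]
        durations[idx] = t - births[a]
        out_counts[idx] = node_counts[a]
        durations[idx + 1] = t - births[b]
        out_counts[idx + 1] = node_counts[b]
        idx += 2
        # merge: reuse slot i, drop slot j
        births.append(t)
        node_counts.append(node_counts[a] + node_counts[b])
        live[i] = len(births) - 1
        live.pop(j)
    return durations, out_counts


def simulate_pi(
    n_samples: int,
    history: SizeHistory,
    mu: float,
    locus_len: int,
    n_loci: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-locus pairwise diversity (per site) at independent neutral loci.

    Mutations are Poisson on branches; a mutation carried by d of n samples
    contributes d (n - d) pairwise differences.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 sampled chromosomes")
    n_pairs = n_samples * (n_samples - 1) / 2.0
    out = np.empty(n_loci)
    for locus in range(n_loci):
        dur, cnt = _coalesce_counts(rng, n_samples, history)
        if mu > 0:
            muts = rng.poisson(mu * locus_len * dur)
            diffs = float(np.sum(muts * cnt * (n_samples - cnt)))
        else:
            diffs = 0.0
        out[locus] = diffs / n_pairs / locus_len
    return out


def simulate_genotypes(
    n_samples: int,
    history: SizeHistory,
    mu: float,
    locus_len: int,
    rng: np.random.Generator,
):
    """Simulate one locus and return (positions, genotype matrix).

    Genotypes are a boolean (n_samples, n_sites) array of derived-allele
    carriage; positions are distinct 0-based sites (infinite-sites placement
    on the finite locus: positions drawn without replacement, mutation count
    capped at ``locus_len``).
    """
    # genealogy with member tracking
    births = [0.0] * n_samples
    members: list[tuple[int, ...]] = [(i,) for i in range(n_samples)]
    live = list(range(n_samples))
    branches: list[tuple[float, tuple[int, ...]]] = []
    lam = 0.0
    for k in range(n_samples, 1, -1):
        lam += rng.exponential() / (k * (k - 1) / 2.0)
        t = history.inverse_intensity(lam)
        i, j = rng.choice(k, size=2, replace=False)
        if i > j:
            i, j = j, i
        a, b = live[i], live[j]
        branches.append((t - births[a], members[a]))
        branches.append((t - births[b], members[b]))
        births.append(t)
        members.append(tuple(sorted(members[a] + members[b])))
        live[i] = len(births) - 1
        live.pop(j)
    durations = np.array([d for d, _ in branches])
    n_mut = rng.poisson(mu * locus_len * durations) if mu > 0 else np.zeros(len(branches), int)
    total = int(n_mut.sum())
    total = min(total, locus_len)
    positions = rng.choice(locus_len, size=total, replace=False)
    geno = np.zeros((n_samples, total), dtype=bool)
    site = 0
    for (dur, mem), m in zip(branches, n_mut):
        for _ in range(int(m)):
            if site >= total:
                break
            geno[list(mem), site] = True
            site += 1
    order = np.argsort(positions)
    return positions[order], geno[:, order]
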
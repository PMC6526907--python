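"""Lineage-specific dN, dS and dN/dS from three-species codon alignments.

The alignments carry two ingroup species and one outgroup on the fixed
topology ((ingroup1, ingroup2), outgroup). Substitutions are counted with an
NG86-style estimator: fractional synonymous/nonsynonymous site counts
averaged over the three sequences, differences polarized onto the ingroup1 or
ingroup2 branch by outgroup parsimony, and multi-hit codons resolved by
averaging over minimal substitution paths. Codon columns where the outgroup
matches neither differing ingroup state cannot be polarized and are excluded
from both numerators and denominators.

Pooled estimates divide summed substitution counts by summed site counts
(counts pooled before division, never averaged ratios). Confidence intervals
come from bootstrapping over genes; hypothesis tests are label permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .codon import codon_path_counts, codon_sites

logger = logging.getLogger(__name__)

_CLEAN = set("ACGT")

LINEAGES = ("ingroup1", "ingroup2")


@dataclass(frozen=True)
class CodonAlignmentTriple:
    """Gap-free codon alignment of ingroup1, ingroup2 and outgroup CDS."""

    gene_id: str
    ingroup1: str
    ingroup2: str
    outgroup: str
    chrom_class: str  # "X" or "A"

    def __post_init__(self):
        lens = {len(self.ingroup1), len(self.ingroup2), len(self.outgroup)}
        if len(lens) != 1:
            raise ValueError(f"{self.gene_id}: unequal sequence lengths")
        if len(self.ingroup1) % 3:
            raise ValueError(f"{self.gene_id}: alignment length not divisible by 3")
        if self.chrom_class not in ("X", "A"):
            raise ValueError(f"{self.gene_id}: chrom_class must be 'X' or 'A'")

    @property
    def n_codons(self) -> int:
        return len(self.ingroup1) // 3

    def codons(self, which: str) -> list[str]:
        s = getattr(self, which).upper()
        return [s[i : i + 3] for i in range(0, len(s), 3)]


@dataclass(frozen=True)
class BranchCounts:
    """Per-gene polarized substitution and site counts."""

    gene_id: str
    chrom_class: str
    nd: dict  # lineage -> nonsynonymous substitutions
    sd: dict  # lineage -> synonymous substitutions
    n_sites: float
    s_sites: float


@dataclass
class SubstitutionSummary:
    lineage: str
    chrom_class: str
    dn: float
    ds: float
    omega: float | None
    n_genes: int
    ci: dict | None = None  # quantity -> (low, high)


@dataclass
class RandTestResult:
    statistic_observed: float
    null_statistics: np.ndarray
    p_two_tailed: float
    n_perm: int


def strip_untranslatable_codons(aln: CodonAlignmentTriple) -> CodonAlignmentTriple | None:
    """Remove codon columns containing N, IUPAC codes or gaps in any species.

    Returns ``None`` (with a warning) when nothing translatable remains.
    """
    cods = [aln.codons(w) for w in ("ingroup1", "ingroup2", "outgroup")]
    keep = [
        i
        for i in range(aln.n_codons)
        if all(set(c[i]) <= _CLEAN for c in cods)
    ]
    if not keep:
        logger.warning("%s: no translatable codons remain; gene dropped", aln.gene_id)
        return None
    if len(keep) == aln.n_codons:
        return aln
    return replace(
        aln,
        ingroup1="".join(cods[0][i] for i in keep),
        ingroup2="".join(cods[1][i] for i in keep),
        outgroup="".join(cods[2][i] for i in keep),
    )


def lineage_counts(aln: CodonAlignmentTriple) -> BranchCounts:
    """Polarized NG86 substitution and site counts for one gene.

    Requires a stripped (pure-ACGT) alignment. For each codon column the
    outgroup state stands in for the ingroup ancestor: a difference carried by
    exactly one ingroup is placed on that ingroup's branch and decomposed into
    synonymous/nonsynonymous steps by minimal-path averaging. Columns where
    both ingroups share a state differing from the outgroup put the change on
    the internal/outgroup side (not counted here); columns where the outgroup
    matches neither differing ingroup are skipped entirely.
    """
    c1 = aln.codons("ingroup1")
    c2 = aln.codons("ingroup2")
    co = aln.codons("outgroup")
    nd = {lin: 0.0 for lin in LINEAGES}
    sd = {lin: 0.0 for lin in LINEAGES}
    n_sites = 0.0
    s_sites = 0.0
    for a, b, o in zip(c1, c2, co):
        if not (set(a) <= _CLEAN and set(b) <= _CLEAN and set(o) <= _CLEAN):
            raise ValueError("lineage_counts requires a stripped ACGT-only alignment")
        if a != b and o != a and o != b:
            continue  # unpolarizable: excluded from numerator and denominator
        try:
            sites = [codon_sites(c) for c in (a, b, o)]
        except Exception:
            continue  # stop codon in some species: skip column
        s_col = sum(s for s, _ in sites) / 3.0
        n_col = sum(n for _, n in sites) / 3.0
        s_sites += s_col
        n_sites += n_col
        if a == b:
            continue  # identical ingroups: any change sits outside both branches
        if o == a:
            syn, nonsyn = codon_path_counts(o, b)
            sd["ingroup2"] += syn
            nd["ingroup2"] += nonsyn
        else:  # o == b
            syn, nonsyn = codon_path_counts(o, a)
            sd["ingroup1"] += syn
            nd["ingroup1"] += nonsyn
    return BranchCounts(
        gene_id=aln.gene_id,
        chrom_class=aln.chrom_class,
        nd=nd,
        sd=sd,
        n_sites=n_sites,
        s_sites=s_sites,
    )


def _gene_arrays(genes: list[BranchCounts], lineage: str):
    nd = np.array([g.nd[lineage] for g in genes])
    sd = np.array([g.sd[lineage] for g in genes])
    ns = np.array([g.n_sites for g in genes])
    ss = np.array([g.s_sites for g in genes])
    return nd, sd, ns, ss


def _pooled(nd, sd, ns, ss):
    dn = nd.sum() / ns.sum() if ns.sum() > 0 else np.nan
    ds = sd.sum() / ss.sum() if ss.sum() > 0 else np.nan
    omega = dn / ds if ds and np.isfinite(ds) and ds > 0 else np.nan
    return dn, ds, omega


def pool_dnds(
    genes: list[BranchCounts], lineage: str, chrom_class: str | None = None
) -> SubstitutionSummary:
    """Pooled dN, dS and dN/dS across genes for one lineage (and class)."""
    if chrom_class is not None:
        genes = [g for g in genes if g.chrom_class == chrom_class]
    if not genes:
        raise ValueError("no genes to pool")
    dn, ds, omega = _pooled(*_gene_arrays(genes, lineage))
    return SubstitutionSummary(
        lineage=lineage,
        chrom_class=chrom_class or "all",
        dn=float(dn),
        ds=float(ds),
        omega=None if not np.isfinite(omega) else float(omega),
        n_genes=len(genes),
    )


def bootstrap_genes(
    genes: list[BranchCounts],
    lineage: str,
    chrom_class: str | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> SubstitutionSummary:
    """Pooled estimates with percentile bootstrap CIs over genes."""
    if chrom_class is not None:
        genes = [g for g in genes if g.chrom_class == chrom_class]
    if len(genes) < 2:
        raise ValueError("need >= 2 genes to bootstrap")
    summary = pool_dnds(genes, lineage)
    summary.chrom_class = chrom_class or "all"
    nd, sd, ns, ss = _gene_arrays(genes, lineage)
    rng = np.random.default_rng(seed)
    n = len(genes)
    # multinomial gene weights are equivalent to resampling gene indices
    w = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)
    dn_b = (w @ nd) / (w @ ns)
    ds_b = (w @ sd) / (w @ ss)
    with np.errstate(divide="ignore", invalid="ignore"):
        om_b = dn_b / ds_b
    ci = {}
    for name, vals in (("dn", dn_b), ("ds", ds_b), ("omega", om_b)):
        vals = vals[np.isfinite(vals)]
        if vals.size:
            ci[name] = (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
        else:
            ci[name] = (np.nan, np.nan)
    summary.ci = ci
    return summary


def _stat_class(perm_mask, arrays1, arrays2, statistic):
    """Statistic for class permutations; perm_mask True -> gene counted as X.

    arrays1/arrays2 are (nd, sd, ns, ss) tuples for the lineage(s) involved.
    Vectorized over permutation rows of perm_mask (n_perm, n_genes).
    """
    m = perm_mask.astype(float)
    inv = 1.0 - m

    def pooled(arrays, mask):
        nd, sd, ns, ss = arrays
        dn = mask @ nd / (mask @ ns)
        ds = mask @ sd / (mask @ ss)
        return dn, ds

    if statistic == "omega_diff":
        dn_x, ds_x = pooled(arrays1, m)
        dn_a, ds_a = pooled(arrays1, inv)
        return dn_x / ds_x - dn_a / ds_a
    if statistic == "dS_ratio":
        _, ds_x = pooled(arrays1, m)
        _, ds_a = pooled(arrays1, inv)
        return np.log(ds_x / ds_a)
    if statistic == "omega_ratio_diff":
        dn1x, ds1x = pooled(arrays1, m)
        dn1a, ds1a = pooled(arrays1, inv)
        dn2x, ds2x = pooled(arrays2, m)
        dn2a, ds2a = pooled(arrays2, inv)
        return (dn1x / ds1x) / (dn1a / ds1a) - (dn2x / ds2x) / (dn2a / ds2a)
    raise ValueError(f"unknown statistic {statistic!r}")


def randomization_test(
    genes: list[BranchCounts],
    grouping: str = "class-within-species",
    statistic: str = "omega_diff",
    lineage: str = "ingroup1",
    chrom_class: str | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> RandTestResult:
    """Permutation test on pooled estimates.

    grouping = "class-within-species": permute each gene's chromosome label
    (X vs A) and recompute the statistic for one lineage (``omega_diff``,
    ``dS_ratio``) or both (``omega_ratio_diff``).
    grouping = "species-within-class": the two groups are the two ingroup
    lineages of the same genes (optionally restricted to one class);
    permutation swaps the two lineages gene by gene. Only ``omega_diff``
    and ``dS_ratio`` apply.

    Two-tailed p uses the add-one correction; ratio statistics are compared on
    the log scale.
    """
    rng = np.random.default_rng(seed)
    if grouping == "class-within-species":
        labels = np.array([g.chrom_class == "X" for g in genes])
        if labels.all() or not labels.any():
            raise ValueError("need genes from both classes")
        a1 = _gene_arrays(genes, lineage)
        a2 = _gene_arrays(genes, "ingroup2" if lineage == "ingroup1" else "ingroup1")
        obs = float(_stat_class(labels[None, :], a1, a2, statistic)[0])
        perm = np.stack([rng.permutation(labels) for _ in range(n_perm)])
        null = _stat_class(perm, a1, a2, statistic)
    elif grouping == "species-within-class":
        if statistic == "omega_ratio_diff":
            raise ValueError("omega_ratio_diff is a class-permutation statistic")
        sub = [g for g in genes if chrom_class in (None, g.chrom_class)]
        if not sub:
            raise ValueError("no genes in requested class")
        x1 = np.stack(_gene_arrays(sub, "ingroup1"))  # (4, n)
        x2 = np.stack(_gene_arrays(sub, "ingroup2"))
        # site counts are shared; swapping species swaps only the counts
        def stat(m):  # m: (n_perm, n) True -> gene's lineage1 data goes to group 1
            g1 = np.where(m[:, None, :], x1[None], x2[None])  # (n_perm, 4, n)
            g2 = np.where(m[:, None, :], x2[None], x1[None])
            dn1 = g1[:, 0, :].sum(axis=1) / g1[:, 2, :].sum(axis=1)
            ds1 = g1[:, 1, :].sum(axis=1) / g1[:, 3, :].sum(axis=1)
            dn2 = g2[:, 0, :].sum(axis=1) / g2[:, 2, :].sum(axis=1)
            ds2 = g2[:, 1, :].sum(axis=1) / g2[:, 3, :].sum(axis=1)
            if statistic == "omega_diff":
                return dn1 / ds1 - dn2 / ds2
            if statistic == "dS_ratio":
                return np.log(ds1 / ds2)
            raise ValueError(f"unknown statistic {statistic!r}")

        n = len(sub)
        obs = float(stat(np.ones((1, n), dtype=bool))[0])
        perm = rng.random((n_perm, n)) < 0.5
        null = stat(perm)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    bad = ~np.isfinite(null)
    if bad.mean() > 0.10:
        raise ValueError(
            f"statistic undefined in {bad.mean():.0%} of permutations; test degenerate"
        )
    null = null[~bad]
    p = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (len(null) + 1.0)
    return RandTestResult(
        statistic_observed=obs,
        null_statistics=null,
        p_two_tailed=float(p),
        n_perm=len(null),
    )


def percent_increase(omega_hi: float, omega_lo: float) -> float:
    """Percent increase of the first dN/dS over the second (35 for 35%)."""
    if omega_lo <= 0:
        raise ValueError("reference omega must be positive")
    return (omega_hi / omega_lo - 1.0) * 100.0


def contrast_report(summaries: dict) -> pd.DataFrame:
    """Derived X/A and between-lineage contrasts.

    ``summaries`` maps (lineage, chrom_class) to SubstitutionSummary for both
    lineages x both classes. Emits per-lineage dS_X/dS_A, omega_X/omega_A and
    the X-over-A percent increase, plus per-class between-lineage percent
    increases (larger omega over smaller).
    """
    rows = []
    lineages = sorted({k[0] for k in summaries})
    classes = sorted({k[1] for k in summaries})
    for lin in lineages:
        sx = summaries[(lin, "X")]
        sa = summaries[(lin, "A")]
        rows.append(
            {
                "contrast": f"{lin}:X_vs_A",
                "ds_ratio": sx.ds / sa.ds if sa.ds else np.nan,
                "omega_ratio": sx.omega / sa.omega if sa.omega else np.nan,
                "pct_increase": percent_increase(sx.omega, sa.omega),
            }
        )
    if len(lineages) == 2:
        for cls in classes:
            s1 = summaries[(lineages[0], cls)]
            s2 = summaries[(lineages[1], cls)]
            hi, lo = (s1, s2) if s1.omega >= s2.omega else (s2, s1)
            rows.append(
                {
                    "contrast": f"{cls}:{hi.lineage}_vs_{lo.lineage}",
                    "ds_ratio": hi.ds / lo.ds if lo.ds else np.nan,
                    "omega_ratio": hi.omega / lo.omega,
                    "pct_increase": percent_increase(hi.omega, lo.omega),
                }
            )
    return pd.DataFrame(rows)
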
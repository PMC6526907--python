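"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the study's four input classes:

* sorted sperm-pool read counts per scaffold (known X/A labels and sorting
  impurities; Poisson read model proportional to scaffold length and pool
  composition),
* three-species codon alignments on the fixed topology
  ((ingroup1, ingroup2), outgroup) with per-branch, per-class synonymous
  rates and dN/dS (simple codon-site model, no transition/transversion bias,
  stop codons disallowed),
* per-population RAD locus alignments sampled from a neutral coalescent with
  free recombination between loci and none within, with an Ne scaling factor
  for X-linked loci,
* McDonald-Kreitman inputs (CDS + polymorphism and divergence tables) whose
  classified counts hit requested Pn/Ps/Dn/Ds exactly.

All generators are deterministic given spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import SizeHistory, simulate_genotypes
from .codon import SENSE_CODONS, single_base_changes
from .divergence import CodonAlignmentTriple
from .diversity import PopulationLocusAlignment

BASES = "ACGT"


# ---------------------------------------------------------------------------
# sorted-pool read counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SortSpec:
    """Design of the flow-sorted sperm-pool sequencing experiment.

    ``impurity0`` is the fraction of X-bearing nuclei contaminating pool 0;
    ``impurityX`` the fraction of X-free nuclei contaminating pool X1X2.
    ``depth_per_pool`` is the expected total read count per pool.
    """

    n_scaffolds: int = 3000
    frac_x: float = 0.12
    mean_len: float = 100_000.0
    impurity0: float = 0.10
    impurityX: float = 0.02
    depth_per_pool: float = 1_000_000.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.frac_x <= 1.0:
            raise ValueError("frac_x must lie in [0, 1]")
        if not (0.0 <= self.impurity0 < 0.5 and 0.0 <= self.impurityX < 0.5):
            raise ValueError("impurities must lie in [0, 0.5)")
        if self.depth_per_pool <= 0:
            raise ValueError("depth_per_pool must be positive")
        n_x = round(self.n_scaffolds * self.frac_x)
        if min(n_x, self.n_scaffolds - n_x) < 2:
            raise ValueError("need at least 2 scaffolds per class for the mixture")


def gen_sort_counts(spec: SortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-scaffold reads in the two sorted pools, plus the truth table.

    Read counts are Poisson with expectation proportional to scaffold length
    times the copy fraction of the scaffold in the pool's nucleus mix:
    autosomes are present in every nucleus; X scaffolds are present only in
    X-bearing nuclei, i.e. with fraction ``impurity0`` in pool 0 and
    ``1 - impurityX`` in pool X1X2.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_scaffolds
    n_x = round(n * spec.frac_x)
    labels = np.array(["A"] * n, dtype=object)
    labels[rng.choice(n, size=n_x, replace=False)] = "X"
    lengths = np.maximum(rng.gamma(2.0, spec.mean_len / 2.0, size=n), 200.0).astype(int)
    is_x = labels == "X"
    w0 = lengths * np.where(is_x, spec.impurity0, 1.0)
    wx = lengths * np.where(is_x, 1.0 - spec.impurityX, 1.0)
    mu0 = spec.depth_per_pool * w0 / w0.sum()
    mux = spec.depth_per_pool * wx / wx.sum()
    counts = pd.DataFrame(
        {
            "scaffold_id": [f"scaffold_{i:05d}" for i in range(n)],
            "length": lengths,
            "reads_pool0": rng.poisson(mu0),
            "reads_poolX": rng.poisson(mux),
        }
    )
    truth = pd.DataFrame({"scaffold_id": counts["scaffold_id"], "true_label": labels})
    return counts, truth


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonSimSpec:
    """Per-class, per-branch parameters of the codon simulator.

    ``branch_ds`` maps branch name ("ingroup1", "ingroup2", "outgroup") to the
    expected synonymous divergence per synonymous site, either one float or a
    {"X": ..., "A": ...} map; ``omega`` is the branch x class dN/dS in the
    same format.
    """

    n_genes_per_class: int = 200
    codons_per_gene: int = 150
    branch_ds: dict = field(
        default_factory=lambda: {"ingroup1": 0.01, "ingroup2": 0.01, "outgroup": 0.02}
    )
    omega: dict = field(
        default_factory=lambda: {"ingroup1": 0.13, "ingroup2": 0.13, "outgroup": 0.13}
    )
    seed: int = 0

    def per_class(self, mapping, branch: str, chrom_class: str) -> float:
        v = mapping[branch] if isinstance(mapping, dict) else mapping
        v = v[chrom_class] if isinstance(v, dict) else float(v)
        if v < 0:
            raise ValueError("rates must be nonnegative")
        return float(v)


_CHANGE_CACHE: dict[str, tuple[list[str], list[str]]] = {}


def _changes(codon: str):
    got = _CHANGE_CACHE.get(codon)
    if got is None:
        syn = [alt for alt, s in single_base_changes(codon) if s]
        non = [alt for alt, s in single_base_changes(codon) if not s]
        got = (syn, non)
        _CHANGE_CACHE[codon] = got
    return got


def _evolve_branch(codons: list[str], ds: float, omega: float, rng) -> tuple[list[str], int, int]:
    """Evolve codons for one branch; returns (new codons, n_syn, n_nonsyn).

    Gillespie per codon: each specific synonymous change fires at rate mu and
    each nonsynonymous change at mu * omega over unit branch time, with
    mu = ds / 3 so the expected synonymous divergence per NG86 synonymous
    site equals ``ds``.
    """
    mu = ds / 3.0
    n_syn = n_non = 0
    out = list(codons)
    if mu == 0.0 and omega == 0.0:
        return out, 0, 0
    for i, codon in enumerate(out):
        t = 0.0
        while True:
            syn, non = _changes(codon)
            rate = mu * (len(syn) + omega * len(non))
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= 1.0:
                break
            u = rng.random() * (len(syn) + omega * len(non))
            if u < len(syn):
                codon = syn[int(u)]
                n_syn += 1
            else:
                codon = non[int((u - len(syn)) / omega)] if omega > 0 else codon
                n_non += 1
        out[i] = codon
    return out, n_syn, n_non


def gen_codon_alignments(
    spec: CodonSimSpec,
) -> tuple[list[CodonAlignmentTriple], pd.DataFrame]:
    """Simulate genes per class on ((ingroup1, ingroup2), outgroup).

    The root sequence is uniform over sense codons; each branch evolves
    independently with its class-specific dS and omega. Returns the (gap-free)
    alignments and a truth table of realized per-branch synonymous and
    nonsynonymous substitution counts.
    """
    rng = np.random.default_rng(spec.seed)
    triples = []
    truth_rows = []
    for chrom_class in ("X", "A"):
        for g in range(spec.n_genes_per_class):
            root = [
                SENSE_CODONS[k]
                for k in rng.integers(0, len(SENSE_CODONS), spec.codons_per_gene)
            ]
            gene_id = f"gene_{chrom_class}_{g:05d}"
            seqs = {}
            for branch in ("ingroup1", "ingroup2", "outgroup"):
                ds = spec.per_class(spec.branch_ds, branch, chrom_class)
                om = spec.per_class(spec.omega, branch, chrom_class)
                evolved, n_syn, n_non = _evolve_branch(root, ds, om, rng)
                seqs[branch] = "".join(evolved)
                truth_rows.append(
                    {
                        "gene_id": gene_id,
                        "chrom_class": chrom_class,
                        "branch": branch,
                        "n_syn": n_syn,
                        "n_nonsyn": n_non,
                    }
                )
            triples.append(
                CodonAlignmentTriple(
                    gene_id=gene_id,
                    ingroup1=seqs["ingroup1"],
                    ingroup2=seqs["ingroup2"],
                    outgroup=seqs["outgroup"],
                    chrom_class=chrom_class,
                )
            )
    return triples, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# population RAD loci
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopSimSpec:
    """Neutral coalescent RAD data: per-class locus counts and theta.

    ``theta_a`` is the per-site pairwise diversity target for autosomal loci;
    X loci use ``theta_a * x_factor``. Loci are independent (free
    recombination between, none within) and are packed onto synthetic
    scaffolds ``loci_per_scaffold`` at a time so scaffold-level statistics are
    computable.
    """

    populations: tuple = ("POP1",)
    n_individuals: int = 10
    n_loci: dict = field(default_factory=lambda: {"X": 150, "A": 1000})
    locus_len: int = 100
    theta_a: float = 0.004
    x_factor: float = 0.75
    loci_per_scaffold: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 5:
            raise ValueError("pipeline minimum is 5 individuals")
        if not 0.0 < self.x_factor <= 1.5:
            raise ValueError("x_factor must lie in (0, 1.5]")
        if self.theta_a < 0:
            raise ValueError("theta_a must be nonnegative")


def gen_population_rad(
    spec: PopSimSpec,
) -> tuple[list[PopulationLocusAlignment], pd.DataFrame]:
    """Coalescent RAD alignments per population plus the locus map table."""
    rng = np.random.default_rng(spec.seed)
    ne = 10_000.0
    history = SizeHistory.constant(ne)
    n_chrom = 2 * spec.n_individuals
    loci = []
    map_rows = []
    for pop in spec.populations:
        for chrom_class in ("X", "A"):
            theta = spec.theta_a * (spec.x_factor if chrom_class == "X" else 1.0)
            mu = theta / (4.0 * ne)
            for j in range(int(spec.n_loci[chrom_class])):
                scaf = f"scf{chrom_class}_{j // spec.loci_per_scaffold:05d}"
                pos = (j % spec.loci_per_scaffold) * (spec.locus_len + 100)
                locus_id = f"locus_{chrom_class}_{j:06d}"
                positions, geno = simulate_genotypes(
                    n_chrom, history, mu, spec.locus_len, rng
                )
                anc = rng.integers(0, 4, spec.locus_len)
                seq_base = np.frombuffer(b"ACGT", dtype=np.uint8)[anc].copy()
                seqs = []
                names = []
                for ind in range(spec.n_individuals):
                    for allele in (1, 2):
                        row = seq_base.copy()
                        carrier = geno[2 * ind + (allele - 1)]
                        for p in positions[carrier]:
                            row[p] = _derived_base(seq_base[p], int(p % 3))
                        seqs.append(row.tobytes().decode())
                        names.append(f"{pop}_ind{ind:02d}_a{allele}")
                loci.append(
                    PopulationLocusAlignment(
                        population=pop,
                        locus_id=locus_id,
                        scaffold_id=scaf,
                        position=pos,
                        chrom_class=chrom_class,
                        names=names,
                        sequences=seqs,
                    )
                )
                map_rows.append(
                    {
                        "locus_id": locus_id,
                        "scaffold_id": scaf,
                        "position": pos,
                        "chrom_class": chrom_class,
                        "population": pop,
                    }
                )
    return loci, pd.DataFrame(map_rows)


def _derived_base(anc_code: int, offset: int) -> int:
    """Deterministic derived base differing from the ancestral one."""
    b = b"ACGT"
    anc_i = b.index(anc_code)
    return b[(anc_i + 1 + offset % 3) % 4]


# ---------------------------------------------------------------------------
# McDonald-Kreitman dataset
# ---------------------------------------------------------------------------

_SYN_CODON = "GGA"  # GGA -> GGG is synonymous (Gly)
_NON_CODON = "ATG"  # ATG -> ATA is nonsynonymous (Met -> Ile)


def gen_mk_dataset(
    pn: int,
    ps: int,
    dn: int,
    ds: int,
    scaffold_id: str = "scaffold_mk",
    gene_id: str = "gene_mk",
    depth: int = 30,
):
    """Synthetic CDS + polymorphism and divergence tables with exact counts.

    One variant per codon: synonymous events use GGA->GGG at the third codon
    position, nonsynonymous events ATG->ATA. Returns (genome dict,
    cds annotation table, polymorphism table, divergence table).
    """
    for name, v in (("pn", pn), ("ps", ps), ("dn", dn), ("ds", ds)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    layout = (
        [("P", "N")] * pn + [("P", "S")] * ps + [("D", "N")] * dn + [("D", "S")] * ds
    )
    codons = ["ATG"]  # start codon, untouched
    poly_rows = []
    div_rows = []
    for k, (kind, klass) in enumerate(layout, start=1):
        codon = _NON_CODON if klass == "N" else _SYN_CODON
        codons.append(codon)
        pos0 = 3 * k + 2  # third position of codon k (0-based within CDS)
        ref = codon[2]
        alt = "A" if klass == "N" else "G"
        row = {
            "CHROM": scaffold_id,
            "POS": pos0 + 1,
            "REF": ref,
            "ALT": alt,
            "DP": depth,
        }
        (poly_rows if kind == "P" else div_rows).append(row)
    codons.append("TAA")
    cds = "".join(codons)
    genome = {scaffold_id: cds}
    annot = pd.DataFrame(
        [
            {
                "scaffold": scaffold_id,
                "start": 0,
                "end": len(cds),
                "strand": "+",
                "frame": 0,
                "gene": gene_id,
            }
        ]
    )
    return genome, annot, pd.DataFrame(poly_rows), pd.DataFrame(div_rows)
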
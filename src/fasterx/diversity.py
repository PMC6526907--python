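"""Nucleotide diversity (Nei's pi) on X-linked vs autosomal RAD loci.

Per-population, per-locus multi-individual alignments are concatenated (in a
fixed order: scaffold, then position, with missing individuals written as gap
rows), cut into equally long subalignments whose universal length is anchored
to the population with the least X-chromosome coverage, and summarized as
per-subalignment pi with bootstrap CIs. piX/piA is built by grouping
autosomal subalignments, taking group medians (pi distributions are strongly
right-skewed), and pairing groups randomly with X subalignments. Species
differences in the ratio are tested with a mixed model (population as random
intercept, likelihood-ratio test); population differences within a species
with one-way ANOVA plus Tukey HSD letters.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_GOOD = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PopulationLocusAlignment:
    """One RAD locus in one population: >= 5 individuals x 2 alleles."""

    population: str
    locus_id: str
    scaffold_id: str
    position: int
    chrom_class: str  # "X" or "A"
    names: list[str]  # "pop_individual_allele"
    sequences: list[str]

    def __post_init__(self):
        if len({len(s) for s in self.sequences}) > 1:
            raise ValueError(f"{self.locus_id}: ragged alignment")
        if len(self.names) != len(self.sequences):
            raise ValueError(f"{self.locus_id}: names/sequences mismatch")


@dataclass
class PiEstimate:
    unit_id: str | None
    pi: float | None  # None when no pair has comparable sites
    n_sites: int


@dataclass
class SubalignmentSet:
    population: str
    chrom_class: str
    block_length: int
    row_names: list[str]
    blocks: list[np.ndarray] = field(repr=False, default_factory=list)  # uint8 (n, L)


def _to_matrix(sequences) -> np.ndarray:
    return np.vstack(
        [np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in sequences]
    )


def nei_pi(alignment, unit_id: str | None = None) -> PiEstimate:
    """Average pairwise per-site difference over all sequence pairs.

    ``alignment`` is a list of equal-length sequence strings or a uint8
    matrix. For each pair, sites where either sequence carries a gap, N or
    other non-ACGT symbol are excluded from that pair's denominator; the
    per-pair proportions are averaged over pairs with at least one comparable
    site. With no comparable site in any pair the estimate is undefined.
    """
    mat = alignment if isinstance(alignment, np.ndarray) else _to_matrix(alignment)
    n, length = mat.shape
    if n < 2:
        raise ValueError("need at least 2 sequences")
    valid = np.isin(mat, _GOOD)
    props = []
    for i, j in itertools.combinations(range(n), 2):
        comp = valid[i] & valid[j]
        n_comp = int(comp.sum())
        if n_comp == 0:
            continue
        diffs = int(np.count_nonzero((mat[i] != mat[j]) & comp))
        props.append(diffs / n_comp)
    if not props:
        return PiEstimate(unit_id, None, length)
    return PiEstimate(unit_id, float(np.mean(props)), length)


def build_subalignments(
    loci: list[PopulationLocusAlignment], target_min_blocks: int = 15
) -> dict[tuple[str, str], SubalignmentSet]:
    """Concatenate loci per population x class and cut equal-length blocks.

    The universal block length L is floor(smallest per-population X-class
    total length / target_min_blocks), so the thinnest X set yields exactly
    ``target_min_blocks`` blocks; every set is cut into floor(total/L) blocks
    and trailing remainder sites are discarded. Sets shorter than L are
    excluded with a warning.
    """
    groups: dict[tuple[str, str], list[PopulationLocusAlignment]] = {}
    for loc in loci:
        groups.setdefault((loc.population, loc.chrom_class), []).append(loc)

    totals_x = {}
    for (pop, cls), g in groups.items():
        if cls == "X":
            totals_x[pop] = sum(len(loc.sequences[0]) for loc in g)
    if not totals_x:
        raise ValueError("no X-class loci: cannot anchor the universal block length")
    L = int(min(totals_x.values())) // target_min_blocks
    if L == 0:
        raise ValueError("smallest X-class set shorter than target_min_blocks sites")

    out = {}
    for (pop, cls), g in groups.items():
        g = sorted(g, key=lambda loc: (loc.scaffold_id, loc.position, loc.locus_id))
        rows = sorted({n for loc in g for n in loc.names})
        row_ix = {n: i for i, n in enumerate(rows)}
        total = sum(len(loc.sequences[0]) for loc in g)
        if total < L:
            logger.warning("%s/%s: total %d bp < block length %d; set excluded",
                           pop, cls, total, L)
            continue
        concat = np.full((len(rows), total), ord("-"), dtype=np.uint8)
        off = 0
        for loc in g:
            w = len(loc.sequences[0])
            sub = _to_matrix(loc.sequences)
            for name, r in zip(loc.names, sub):
                concat[row_ix[name], off : off + w] = r
            off += w
        n_blocks = total // L
        blocks = [concat[:, i * L : (i + 1) * L] for i in range(n_blocks)]
        out[(pop, cls)] = SubalignmentSet(pop, cls, L, rows, blocks)
    return out


def block_pi(subset: SubalignmentSet) -> list[PiEstimate]:
    return [
        nei_pi(b, unit_id=f"{subset.population}/{subset.chrom_class}/{i}")
        for i, b in enumerate(subset.blocks)
    ]


def bootstrap_pi(
    estimates: list[PiEstimate] | np.ndarray,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Mean pi with a percentile bootstrap CI over subalignments."""
    if len(estimates) and isinstance(next(iter(estimates)), PiEstimate):
        vals = np.asarray([e.pi for e in estimates if e.pi is not None], dtype=float)
    else:
        vals = np.asarray(estimates, dtype=float)
    if vals.size < 2:
        raise ValueError("need >= 2 subalignment pi values")
    rng = np.random.default_rng(seed)
    w = rng.multinomial(vals.size, np.full(vals.size, 1.0 / vals.size), size=n_boot)
    means = (w @ vals) / vals.size
    return {
        "mean": float(vals.mean()),
        "ci_low": float(np.percentile(means, 2.5)),
        "ci_high": float(np.percentile(means, 97.5)),
        "n_blocks": int(vals.size),
    }


def per_scaffold_pi(
    loci: list[PopulationLocusAlignment], min_loci: int = 3
) -> pd.DataFrame:
    """Pi per scaffold from concatenated RAD loci (scaffolds with >= min_loci)."""
    by_scaf: dict[tuple[str, str], list[PopulationLocusAlignment]] = {}
    for loc in loci:
        by_scaf.setdefault((loc.scaffold_id, loc.chrom_class), []).append(loc)
    rows = []
    for (scaf, cls), g in sorted(by_scaf.items()):
        if len(g) < min_loci:
            continue
        g = sorted(g, key=lambda loc: (loc.position, loc.locus_id))
        names = sorted({n for loc in g for n in loc.names})
        ix = {n: i for i, n in enumerate(names)}
        total = sum(len(loc.sequences[0]) for loc in g)
        mat = np.full((len(names), total), ord("-"), dtype=np.uint8)
        off = 0
        for loc in g:
            w = len(loc.sequences[0])
            for name, r in zip(loc.names, _to_matrix(loc.sequences)):
                mat[ix[name], off : off + w] = r
            off += w
        est = nei_pi(mat, unit_id=scaf)
        rows.append(
            {"scaffold_id": scaf, "chrom_class": cls, "pi": est.pi, "n_loci": len(g)}
        )
    return pd.DataFrame(rows)


def scaffold_cv(
    pi_values, n_boot: int = 1000, seed: int | None = None
) -> dict:
    """Coefficient of variation (sample SD / mean) with a bootstrap CI.

    Undefined when the mean is 0 (all-zero diversity, as in heavily inbred
    populations where most scaffolds are monomorphic).
    """
    vals = np.asarray(pi_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need >= 2 scaffold pi values")
    if vals.mean() == 0:
        raise ValueError("CV undefined: mean pi is 0")
    cv = float(vals.std(ddof=1) / vals.mean())
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        s = vals[rng.integers(0, vals.size, vals.size)]
        reps[b] = s.std(ddof=1) / s.mean() if s.mean() > 0 else np.nan
    reps = reps[np.isfinite(reps)]
    return {
        "cv": cv,
        "ci_low": float(np.percentile(reps, 2.5)),
        "ci_high": float(np.percentile(reps, 97.5)),
        "n": int(vals.size),
    }


def pair_pix_pia(
    x_pis,
    a_pis,
    seed: int | None = None,
    population: str | None = None,
    species: str | None = None,
) -> pd.DataFrame:
    """Independent piX/piA ratios from random grouping of autosomal blocks.

    Autosomal subalignment pi values are shuffled into as many near-equal
    groups as there are X subalignments; each group contributes its median,
    paired randomly with one X block. Pairs whose autosomal median is 0 are
    dropped (count logged), since the ratio is undefined.
    """
    x = np.asarray([e.pi if isinstance(e, PiEstimate) else e for e in x_pis], float)
    a = np.asarray([e.pi if isinstance(e, PiEstimate) else e for e in a_pis], float)
    if len(x) < 2 or len(a) < len(x):
        raise ValueError("need |a_blocks| >= |x_blocks| >= 2")
    rng = np.random.default_rng(seed)
    groups = np.array_split(rng.permutation(a), len(x))
    medians = np.array([np.median(g) for g in groups])
    x_perm = rng.permutation(x)
    keep = medians > 0
    if (~keep).any():
        logger.warning("dropping %d pairs with zero autosomal median pi", (~keep).sum())
    df = pd.DataFrame(
        {
            "x_value": x_perm[keep],
            "a_value": medians[keep],
            "ratio": x_perm[keep] / medians[keep],
        }
    )
    if population is not None:
        df.insert(0, "population", population)
    if species is not None:
        df.insert(0, "species", species)
    return df


def species_ratio_test(ratios: pd.DataFrame, log_ratio: bool = False) -> dict:
    """Likelihood-ratio test for a species effect on piX/piA.

    Fits a linear mixed model of the ratio (or log ratio) with species as
    fixed effect and population as random intercept, against the intercept-
    only model, both by maximum likelihood; p from chi-square with 1 df. A
    singular fit (zero population variance) falls back to a two-sample t-test
    on population means.
    """
    import statsmodels.formula.api as smf

    df = ratios.copy()
    for col in ("species", "population", "ratio"):
        if col not in df.columns:
            raise ValueError(f"ratios table must have a {col!r} column")
    if df.groupby("species")["population"].nunique().min() < 2:
        raise ValueError("need >= 2 populations per species")
    df["y"] = np.log(df["ratio"]) if log_ratio else df["ratio"]
    try:
        full = smf.mixedlm("y ~ species", df, groups=df["population"]).fit(reml=False)
        null = smf.mixedlm("y ~ 1", df, groups=df["population"]).fit(reml=False)
        var_re = float(np.asarray(full.cov_re)[0, 0])
        if not np.isfinite(var_re) or var_re < 1e-12:
            raise np.linalg.LinAlgError("singular random-effect variance")
        chi2 = 2.0 * (full.llf - null.llf)
        p = float(stats.chi2.sf(max(chi2, 0.0), df=1))
        return {"method": "lrt_mixed", "chi2": float(chi2), "df": 1, "p_value": p}
    except Exception as err:  # singular / non-converged fit
        logger.info("mixed model unusable (%s); falling back to population-mean t-test", err)
        means = df.groupby(["species", "population"])["y"].mean().reset_index()
        sp = means["species"].unique()
        t, p = stats.ttest_ind(
            means.loc[means["species"] == sp[0], "y"],
            means.loc[means["species"] == sp[1], "y"],
        )
        return {"method": "ttest_population_means", "t": float(t), "p_value": float(p)}


def population_ratio_test(ratios: pd.DataFrame) -> dict:
    """One-way ANOVA on population plus Tukey HSD display letters."""
    if ratios["population"].nunique() < 2:
        raise ValueError("need >= 2 populations")
    groups = [g["ratio"].to_numpy() for _, g in ratios.groupby("population")]
    f, p = stats.f_oneway(*groups)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(ratios["ratio"], ratios["population"])
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    letters = _compact_letters(tukey, ratios)
    k = ratios["population"].nunique()
    return {
        "F": float(f),
        "df1": k - 1,
        "df2": len(ratios) - k,
        "p_value": float(p),
        "tukey": tukey,
        "letters": letters,
    }


def _compact_letters(tukey: pd.DataFrame, ratios: pd.DataFrame) -> dict[str, str]:
    """Greedy compact-letter display from Tukey pairwise rejections."""
    pops = list(
        ratios.groupby("population")["ratio"].mean().sort_values(ascending=False).index
    )
    differ = {
        frozenset((r["group1"], r["group2"]))
        for _, r in tukey.iterrows()
        if bool(r["reject"])
    }
    letter_groups: list[set[str]] = []
    for p in pops:
        placed = False
        for grp in letter_groups:
            if all(frozenset((p, q)) not in differ for q in grp):
                grp.add(p)
                placed = True
        if not placed:
            letter_groups.append({p})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {p: "" for p in pops}
    for letter, grp in zip(alphabet, letter_groups):
        for p in grp:
            out[p] += letter
    return out
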
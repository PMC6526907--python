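"""End-to-end orchestration: synthesize -> assign -> dnds -> diversity -> mk
-> theory -> simulate, with one config, per-stage seeds fanned out from a
master seed, and a JSON manifest sufficient to reproduce every output byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, divergence, foundersim, io, mktest, synth, theory, xassign

logger = logging.getLogger(__name__)

STAGES = ("synth", "assign", "dnds", "diversity", "mk", "theory", "simulate")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "sort": {"n_scaffolds": 2000, "frac_x": 0.12, "impurity0": 0.10,
             "impurityX": 0.02, "depth_per_pool": 1_000_000.0},
    "assign": {"fdr": 0.025, "min_poolx": 100},
    "codon": {"n_genes_per_class": 150, "codons_per_gene": 120},
    "dnds": {"n_boot": 200, "n_perm": 200},
    "rad": {"populations": ["P1", "P2"], "n_individuals": 8,
            "n_loci_x": 60, "n_loci_a": 300, "locus_len": 100,
            "theta_a": 0.004, "x_factor": 0.75},
    "mk": {"pn": 140, "ps": 150, "dn": 337, "ds": 563},
    "theory": {"nm": 1.0, "nf": 1.0, "k": 0.72, "na": 300_000.0,
               "tgen": 400_000.0, "standardize": 1.0},
    "simulate": {"cycle_len": 50.0, "crash_frac": 0.01, "n_cycles": 10,
                 "n_loci": 1000},
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Fixed counter scheme: one master seed reproduces every stage."""
    return (int(master_seed) * 100_003 + STAGES.index(stage)) % (2**31 - 1)


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in cfg.items():
        if isinstance(v, dict) and k in merged:
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def validate_config(cfg: dict) -> None:
    fdr = cfg["assign"]["fdr"]
    if not 0.0 < fdr < 0.5:
        raise ValueError(f"assign.fdr={fdr} outside (0, 0.5)")
    if cfg["rad"]["n_individuals"] < 5:
        raise ValueError("rad.n_individuals must be >= 5")
    if not 0.0 < cfg["simulate"]["crash_frac"] < 1.0:
        raise ValueError("simulate.crash_frac outside (0, 1)")


def run_pipeline(config: dict | str | Path, outdir) -> dict:
    """Run all stages in dependency order; returns the manifest dict."""
    cfg = load_config(config) if not isinstance(config, dict) else config
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "master_seed": master,
        "stage_seeds": {s: stage_seed(master, s) for s in STAGES},
        "outputs": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def save(df: pd.DataFrame, name: str):
        io.write_tsv(df, outdir / name)
        manifest["outputs"].append(name)

    # --- synth + assign ---------------------------------------------------
    s = cfg["sort"]
    sort_spec = synth.SortSpec(
        n_scaffolds=s["n_scaffolds"], frac_x=s["frac_x"], impurity0=s["impurity0"],
        impurityX=s["impurityX"], depth_per_pool=s["depth_per_pool"],
        seed=stage_seed(master, "synth"),
    )
    counts, truth = synth.gen_sort_counts(sort_spec)
    save(counts, "pool_counts.tsv")
    save(truth, "pool_truth.tsv")

    seed_assign = stage_seed(master, "assign")
    norm = xassign.normalize_pools(counts, seed=seed_assign)
    records = xassign.compute_p0(norm, min_poolx=cfg["assign"]["min_poolx"])
    fit = xassign.fit_p0_mixture(records, seed=seed_assign)
    table = xassign.assign_scaffolds(fit, records, fdr=cfg["assign"]["fdr"])
    save(table, "assignment.tsv")

    # --- divergence -------------------------------------------------------
    c = cfg["codon"]
    codon_spec = synth.CodonSimSpec(
        n_genes_per_class=c["n_genes_per_class"], codons_per_gene=c["codons_per_gene"],
        seed=stage_seed(master, "dnds"),
    )
    triples, _ = synth.gen_codon_alignments(codon_spec)
    genes = [divergence.lineage_counts(divergence.strip_untranslatable_codons(t))
             for t in triples]
    seed_dnds = stage_seed(master, "dnds")
    summaries = {}
    rows = []
    for lin in divergence.LINEAGES:
        for cls in ("X", "A"):
            summ = divergence.bootstrap_genes(
                genes, lin, cls, n_boot=cfg["dnds"]["n_boot"], seed=seed_dnds
            )
            summaries[(lin, cls)] = summ
            rows.append({
                "lineage": lin, "chrom_class": cls, "dn": summ.dn, "ds": summ.ds,
                "omega": summ.omega, "n_genes": summ.n_genes,
                **{f"{q}_ci_{b}": summ.ci[q][i]
                   for q in ("dn", "ds", "omega") for i, b in enumerate(("low", "high"))},
            })
    save(pd.DataFrame(rows), "dnds_summary.tsv")
    save(divergence.contrast_report(summaries), "dnds_contrasts.tsv")
    test_rows = []
    for lin in divergence.LINEAGES:
        for statistic in ("omega_diff", "dS_ratio"):
            res = divergence.randomization_test(
                genes, "class-within-species", statistic, lineage=lin,
                n_perm=cfg["dnds"]["n_perm"], seed=seed_dnds,
            )
            test_rows.append({
                "lineage": lin, "statistic": statistic,
                "observed": res.statistic_observed, "p": res.p_two_tailed,
                "n_perm": res.n_perm,
            })
    save(pd.DataFrame(test_rows), "dnds_tests.tsv")

    # --- diversity --------------------------------------------------------
    r = cfg["rad"]
    seed_div = stage_seed(master, "diversity")
    pops = tuple(r["populations"])
    rad_spec = synth.PopSimSpec(
        populations=pops, n_individuals=r["n_individuals"],
        n_loci={"X": r["n_loci_x"], "A": r["n_loci_a"]}, locus_len=r["locus_len"],
        theta_a=r["theta_a"], x_factor=r["x_factor"], seed=seed_div,
    )
    loci, locus_map = synth.gen_population_rad(rad_spec)
    save(locus_map, "locus_map.tsv")
    subsets = diversity.build_subalignments(loci)
    pi_rows = []
    ratio_frames = []
    for pop in pops:
        blocks = {cls: diversity.block_pi(subsets[(pop, cls)]) for cls in ("X", "A")}
        for cls in ("X", "A"):
            boot = diversity.bootstrap_pi(blocks[cls], n_boot=2000, seed=seed_div)
            pi_rows.append({"population": pop, "chrom_class": cls, **boot})
        ratio_frames.append(
            diversity.pair_pix_pia(
                blocks["X"], blocks["A"], seed=seed_div, population=pop, species="sp1"
            )
        )
    save(pd.DataFrame(pi_rows), "pi_table.tsv")
    ratios = pd.concat(ratio_frames, ignore_index=True)
    save(ratios, "pix_pia_ratios.tsv")
    if len(pops) >= 2:
        ptest = diversity.population_ratio_test(ratios)
        save(
            pd.DataFrame([{"F": ptest["F"], "df1": ptest["df1"], "df2": ptest["df2"],
                           "p": ptest["p_value"]}]),
            "pix_pia_tests.tsv",
        )

    # --- mk ---------------------------------------------------------------
    m = cfg["mk"]
    genome, annot, poly, div = synth.gen_mk_dataset(m["pn"], m["ps"], m["dn"], m["ds"])
    class_map = pd.DataFrame([{"scaffold_id": "scaffold_mk", "label": "X"}])
    tables = mktest.build_mk_tables(poly, div, annot, genome, class_map)
    save(mktest.mk_report(tables), "mk.tsv")

    # --- theory -----------------------------------------------------------
    t = cfg["theory"]
    model = theory.SexRatioModel(t["nm"], t["nf"])
    ctx = theory.CoalescenceContext(t["na"], t["tgen"])
    time_ratio = theory.coalescence_time_ratio(ctx)
    adj = theory.adjust_divergence_ratio(t["k"], time_ratio)
    save(
        pd.DataFrame([{
            "ne_ratio": theory.ne_ratio(model),
            "coalescence_time_ratio": time_ratio,
            "adjusted_k": adj,
            "miyata_alpha": theory.miyata_alpha(adj),
        }]),
        "theory.tsv",
    )
    grid = np.linspace(0.1, 20.0, 60)
    save(
        pd.DataFrame({"nf_over_nm": grid,
                      "expected_pix_pia": theory.pix_pia_curve(grid, t["standardize"])}),
        "pix_pia_curve.tsv",
    )

    # --- simulate -----------------------------------------------------------
    sim = cfg["simulate"]
    scen = foundersim.DemographyScenario(
        cycle_len=sim["cycle_len"], crash_frac=sim["crash_frac"],
        n_cycles=sim["n_cycles"], n_loci=sim["n_loci"],
        seed=stage_seed(master, "simulate"), label="configured",
    )
    result = foundersim.run_scenario(scen)
    save(result.to_frame(), "sim_trajectory.tsv")

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
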
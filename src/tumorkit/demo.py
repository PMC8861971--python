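"""End-to-end demo pipeline on synthetic fixtures.

Generates a seeded fixture set (clonal biopsies, UMI families, regulon
expression, RPPA-like cohort, spatial tissue), runs every analysis stage,
and writes TSV + JSON reports. Deterministic given the seed.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, ctdna, evolution, regulon, scores, spatial
from . import simulate as sim
from . import io as tio

ALL_STAGES = ("fixtures", "ctdna", "evolution", "regulon", "scores", "spatial")


def write_fixtures(outdir: Path, params: sim.SimParams) -> dict:
    """Materialize a full demo dataset directory from the generators."""
    fx = outdir / "fixtures"
    fx.mkdir(parents=True, exist_ok=True)
    tree = sim.example_tree()
    variants = sim.simulate_clonal_biopsies(tree, params)
    tio.write_table(variants, fx / "variants.tsv")

    families = sim.simulate_umi_reads(0.01, params)
    rows = [
        {"umi": f.umi, "site_window": f.site_window, "bases": r}
        for f in families
        for r in f.reads
    ]
    tio.write_table(pd.DataFrame(rows), fx / "umi_reads.tsv")

    net = sim.make_regulon(n_regulators=20, targets_per_regulator=10, seed=params.seed)
    sif = net.edges.assign(relation=regulon.EXPRESSION_RELATION)[
        ["regulator", "relation", "target", "sign"]
    ]
    tio.write_sif(sif, fx / "network.sif")
    expr = sim.simulate_regulator_expression(net, {"R000"}, params)
    tio.write_table(expr.reset_index(names="gene"), fx / "expression.tsv")

    rppa = sim.simulate_rppa_cohort(["AKT", "mTOR", "S6", "PTEN"], seed=params.seed)
    tio.write_table(rppa.reset_index(names="protein"), fx / "rppa.tsv")

    cells, mask = sim.simulate_spatial_tissue(params)
    tio.write_table(cells, fx / "cells.csv", sep=",")
    tio.write_mask(mask, fx / "ecm_mask.png")
    return {"n_variant_rows": len(variants), "n_umi_families": len(families)}


def run_demo(outdir: str | Path, seed: int = 0, stages=None) -> dict:
    """Run the full synthetic demo pipeline; returns the report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages or ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    params = sim.SimParams(seed=seed)
    report: dict = {"version": __version__, "seed": seed, "stages": stages}

    tree = sim.example_tree()
    if "fixtures" in stages:
        report["fixtures"] = write_fixtures(outdir, params)

    if "ctdna" in stages:
        fams = sim.simulate_umi_reads(0.01, sim.SimParams(seed=seed, n_families=2000))
        cons = ctdna.consensus_pipeline(fams)
        site = ctdna.tally_site(
            cons, "site1", sim.MUTANT_POSITION, sim.MUTANT_BASE, timepoint="T1"
        )
        control = ctdna.SiteCounts("site1", 1, 30000, timepoint="T1")
        res = ctdna.detect(site, control)
        report["ctdna"] = {
            "consensus_reads": len(cons),
            "vaf": site.vaf,
            "p_value": res.p_value,
            "detected": res.detected,
        }

    if "evolution" in stages:
        variants = sim.simulate_clonal_biopsies(
            tree, sim.SimParams(seed=seed, depth_mean=500)
        )
        kept = evolution.filter_variants(variants)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            classified = evolution.classify_across_samples(kept)
        mat = evolution.binary_matrix(classified)
        dm = evolution.pairwise_gene_distance(mat)
        me = evolution.minimum_evolution_tree(dm)
        (outdir / "tree.nwk").write_text(me.to_newick() + "\n")
        report["evolution"] = {
            "n_variants": int(classified.shape[0]),
            "categories": classified["category"].value_counts().to_dict(),
            "tree_total_length": me.total_length,
            "newick": me.to_newick(),
        }

    if "regulon" in stages:
        net = sim.make_regulon(n_regulators=20, targets_per_regulator=10, seed=seed)
        expr = sim.simulate_regulator_expression(net, {"R000"}, params)
        sample = sim.active_sample_ids(params)[0]
        scored = regulon.score_regulators(net, expr, sample)
        tio.write_table(scored.reset_index(), outdir / "regulon_scores.tsv")
        report["regulon"] = {
            "sample": sample,
            "top_regulator": str(scored.index[0]),
            "top_integrated_score": float(scored["integrated"].iloc[0]),
        }

    if "scores" in stages:
        pathway = scores.PathwayDefinition(
            name="PI3K-AKT-mTOR",
            positive_predictors=("AKT", "mTOR", "S6"),
            negative_predictors=("PTEN",),
        )
        rppa = sim.simulate_rppa_cohort(["AKT", "mTOR", "S6", "PTEN"], seed=seed)
        z = scores.cohort_zscore(rppa)
        pw = scores.pathway_score(z.iloc[:, 0], pathway)
        report["scores"] = {
            "pathway": pathway.name,
            "pathway_score_first_sample": pw,
            "tmb_example_mut_per_mb": scores.tmb(60, 50.0),
        }

    if "spatial" in stages:
        cells, mask = sim.simulate_spatial_tissue(params)
        dist = spatial.distance_to_mask(cells, mask)
        res = spatial.bin_and_test(cells["marker"], dist, marker="marker")
        report["spatial"] = {
            "n_cells": len(cells),
            "bin_counts": list(res.bin_counts),
            "bin_means": [round(m, 3) for m in res.bin_means],
            "anova_p_adjusted": res.p_adjusted,
            "significant": res.significant,
        }

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
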
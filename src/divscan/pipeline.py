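"""End-to-end scan orchestration: filters -> F_ST windows -> Omega ->
replicate scoring -> ARR scans -> regions -> consensus -> enrichment.

All thresholds and replicate counts live in :class:`RunConfig`; production
defaults mirror the standard protocol (50 kb F_ST windows with a 1e6-replicate
bootstrap at P < 5e-5; 100 kb ARR windows with 1e4 permutations at P < 0.005,
P < 0.001 for trait scans; 95th ARR percentile; +-50 kb regions).  A
scaled-down preset (``RunConfig.test_profile``) keeps desk-scale runs in
minutes.  Every stochastic stage is seeded from ``config.seed``; re-running
with the same config is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arr_rank, bayes_popmodel, diff_scan, regions, smooth_boot
from .genotype_io import (
    GenotypeMatrix,
    apply_locus_filters,
    read_external_candidates,
    read_trait_table,
    read_vcf,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full parameter set for one scan; defaults are the production protocol."""

    # inputs (paths; may be None when objects are passed directly)
    vcf: str | None = None
    popmap: str | None = None
    traits: str | None = None
    annotation: str | None = None
    term_map: str | None = None
    external_candidates: str | None = None  # e.g. a Bayescan locus list

    # filters
    min_pop_presence: float = 0.8
    min_ind_per_pop: int = 5
    min_mac: int = 2
    one_per_tag: bool = True

    # F_ST window scan
    fst_window_bp: int = 50_000
    fst_n_reps: int = 1_000_000
    fst_window_p: float = 5e-5

    # covariance estimation
    n_subsets: int = 10
    subset_size: int = 5_000
    cov_iterations: int = 2_000

    # replicate scoring + ARR
    n_runs: int = 20
    score_iterations: int = 2_000
    beta_prior_sd: float = 1.0
    arr_percentile: float = 95.0
    arr_window_bp: int = 100_000
    arr_n_reps: int = 10_000
    arr_window_p: float = 5e-3
    trait_window_p: float = 1e-3

    # regions
    flank_bp: int = 50_000

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fst_window_p", "arr_window_p", "trait_window_p"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("fst_window_bp", "arr_window_bp", "flank_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def test_profile(cls, **overrides) -> "RunConfig":
        """Scaled-down profile for desk-scale runs.

        Bootstrap replicate counts in the low thousands put the add-one
        P-value floor near 1/(reps+1), so the F_ST window threshold is
        relaxed to 1e-3 (the production 5e-5 is unreachable below 2e4
        replicates by construction of the estimator).
        """
        base = dict(
            fst_n_reps=1999, fst_window_p=1e-3,
            n_subsets=2, subset_size=500, cov_iterations=1200,
            n_runs=8, score_iterations=800,
            arr_n_reps=999, arr_window_p=5e-3, trait_window_p=2e-3,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def report_percentages(subset: int, total: int, decimals: int = 1) -> float:
    """Percent of total, rounded half-up to the requested precision."""
    import decimal

    if total == 0:
        raise ValueError("total must be positive")
    q = decimal.Decimal(1).scaleb(-decimals)
    pct = decimal.Decimal(100 * subset) / decimal.Decimal(total)
    return float(pct.quantize(q, rounding=decimal.ROUND_HALF_UP))


def run_scan(
    config: RunConfig,
    gm: GenotypeMatrix | None = None,
    trait_table: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full scan; returns the report bundle as a dict.

    Inputs come either from the config paths or as in-memory objects.
    When ``out_dir`` is given, per-stage TSV/BED outputs, the effective
    config, and a machine-readable summary are written there.  Any stage
    error aborts with the stage name; previously written outputs remain.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config_effective.yaml")

    stage = "inputs"
    try:
        if gm is None:
            gm = read_vcf(config.vcf, config.popmap)
        if trait_table is None and config.traits:
            trait_table = read_trait_table(config.traits)

        stage = "filters"
        n_input = gm.n_loci
        gm_f, removed = apply_locus_filters(
            gm,
            min_pop_presence=config.min_pop_presence,
            min_ind_per_pop=config.min_ind_per_pop,
            min_mac=config.min_mac,
            one_per_tag=config.one_per_tag,
        )
        logger.info("filters: %d -> %d loci (%s)", n_input, gm_f.n_loci, removed)

        stage = "fst_scan"
        fst_tables = diff_scan.all_pairwise_fst(gm_f)
        fst_windows = []
        global_fst = {}
        for i, (pair, tab) in enumerate(fst_tables.items()):
            global_fst["%s|%s" % pair] = diff_scan.global_fst(tab)
            win = smooth_boot.bootstrap_window_pvalues(
                values=tab.scores[:, 0],
                loci=gm_f.loci,
                window_bp=config.fst_window_bp,
                n_reps=config.fst_n_reps,
                seed=config.seed + 1000 + i,
            )
            fst_windows.append(win)
            if out is not None:
                tab.to_frame().merge(
                    win.drop(columns=["scaffold", "position"]), on="locus_id"
                ).to_csv(out / f"fst_{pair[0]}_{pair[1]}.tsv", sep="\t", index=False)
        fst_candidates = smooth_boot.significant_windows(
            fst_windows, config.fst_window_p
        )

        stage = "covariance"
        omega = bayes_popmodel.estimate_covariance(
            gm_f,
            n_subsets=config.n_subsets,
            subset_size=config.subset_size,
            n_iter=config.cov_iterations,
            seed=config.seed + 2000,
        )
        if out is not None:
            omega.to_text(out / "omega.txt")

        stage = "bayes_scan"
        xtx_table = bayes_popmodel.run_replicates(
            gm_f, omega,
            n_runs=config.n_runs, n_iter=config.score_iterations,
            seed=config.seed + 3000,
        )
        xtx_arr = arr_rank.arr(xtx_table)
        bayes_candidates, xtx_scan = arr_rank.arr_scan(
            xtx_arr,
            window_bp=config.arr_window_bp,
            n_reps=config.arr_n_reps,
            p_threshold=config.arr_window_p,
            percentile=config.arr_percentile,
            seed=config.seed + 3500,
        )
        if out is not None:
            xtx_scan.to_csv(out / "xtx_arr_scan.tsv", sep="\t", index=False)

        stage = "trait_scan"
        trait_results: dict[str, dict] = {}
        if trait_table is not None:
            for t_i, trait in enumerate(trait_table.columns):
                env = bayes_popmodel.standardize_env(
                    trait_table, trait, gm_f.pop_labels
                )
                bf_table = bayes_popmodel.run_replicates(
                    gm_f, omega, env=env,
                    n_runs=config.n_runs, n_iter=config.score_iterations,
                    beta_prior_sd=config.beta_prior_sd,
                    seed=config.seed + 4000 + 100 * t_i,
                )
                bf_arr = arr_rank.arr(bf_table)
                selected, scan_df = arr_rank.arr_scan(
                    bf_arr,
                    window_bp=config.arr_window_bp,
                    n_reps=config.arr_n_reps,
                    p_threshold=config.trait_window_p,
                    percentile=config.arr_percentile,
                    seed=config.seed + 4500 + 100 * t_i,
                )
                trait_results[trait] = {
                    "selected": selected,
                    "in_95th": set(
                        scan_df.loc[scan_df["in_95th"], "locus_id"]
                    ),
                }
                if out is not None:
                    scan_df.to_csv(
                        out / f"trait_{trait}_arr_scan.tsv", sep="\t", index=False
                    )

        stage = "consensus"
        method_sets: dict[str, set[str]] = {
            "fst_scan": fst_candidates,
            "bayes_scan": bayes_candidates,
        }
        if config.external_candidates:
            method_sets["external"] = read_external_candidates(
                config.external_candidates
            )
        support, tallies = regions.consensus_classify(method_sets)

        stage = "regions"
        locus_methods = regions.method_map(method_sets)
        all_candidates = set(support.index)
        cand_df = gm_f.loci[gm_f.loci["locus_id"].isin(all_candidates)]
        region_tiers: dict[int, list] = {}
        for tier in range(1, len(method_sets) + 1):
            tier_loci = {l for l, s in support.items() if s >= tier}
            tier_df = cand_df[cand_df["locus_id"].isin(tier_loci)]
            if len(tier_df):
                region_tiers[tier] = regions.build_regions(
                    tier_df, gm_f.scaffold_lengths,
                    flank_bp=config.flank_bp, methods=locus_methods,
                )
            else:
                region_tiers[tier] = []
            if out is not None:
                regions.write_bed(
                    region_tiers[tier], out / f"regions_tier{tier}.bed"
                )

        stage = "enrichment"
        enrichment = None
        if config.annotation:
            annot = regions.read_gene_annotation(config.annotation)
            regions.intersect_genes(region_tiers[1], annot)
            for tier in region_tiers:
                if tier > 1:
                    regions.intersect_genes(region_tiers[tier], annot)
            if config.term_map:
                tmap = regions.read_term_map(config.term_map)
                selected_genes = set().union(
                    *(r.genes for r in region_tiers[1]), set()
                )
                background = set(annot["gene_id"])
                if selected_genes:
                    enrichment = regions.term_enrichment(
                        selected_genes, background, tmap
                    )
                    if out is not None:
                        enrichment.to_csv(
                            out / "term_enrichment.tsv", sep="\t", index=False
                        )
    except Exception as exc:
        raise RuntimeError(f"scan failed at stage {stage!r}: {exc}") from exc

    n_total = gm_f.n_loci
    union = sorted(all_candidates)
    summary = {
        "n_loci_input": int(n_input),
        "n_loci_filtered": int(n_total),
        "filter_removed": removed,
        "global_fst": global_fst,
        "method_counts": {m: len(s) for m, s in method_sets.items()},
        "union_candidates": len(union),
        "union_pct_of_total": report_percentages(len(union), n_total),
        "consensus_tallies": tallies,
        "regions_per_tier": {t: len(r) for t, r in region_tiers.items()},
        "trait_candidates": {
            t: {"selected": len(v["selected"]), "in_95th": len(v["in_95th"])}
            for t, v in trait_results.items()
        },
        # loci significant in every trait scan (reported, not enforced)
        "trait_intersection": (
            len(set.intersection(*(v["selected"] for v in trait_results.values())))
            if len(trait_results) > 1
            else None
        ),
        "seed": config.seed,
    }
    bundle = {
        "summary": summary,
        "gm_filtered": gm_f,
        "omega": omega,
        "fst_tables": fst_tables,
        "fst_windows": fst_windows,
        "method_sets": method_sets,
        "support": support,
        "region_tiers": region_tiers,
        "trait_results": trait_results,
        "xtx_arr": xtx_arr,
        "enrichment": enrichment,
    }
    if out is not None:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        support.rename("n_methods").rename_axis("locus_id").reset_index().to_csv(
            out / "consensus_support.tsv", sep="\t", index=False
        )
    return bundle
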
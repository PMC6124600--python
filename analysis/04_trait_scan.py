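#!/usr/bin/env python
"""Trait-informed association scan.

Standardizes the per-population trait means (mean 0, sample sd 1), uses
them as the covariate in replicate Bayes-factor runs of the hierarchical
model, aggregates log10 BF by ARR, and applies the stricter dual criterion
for trait scans: 95th ARR percentile AND smoothed-ARR window P < 0.001.

Writes scratch/analysis/trait_<name>_arr_scan.tsv and the candidate list
scratch/analysis/trait_candidates.txt.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import _common
from divscan import arr_rank, bayes_popmodel
from divscan.genotype_io import apply_locus_filters, read_trait_table, read_vcf

def main():
    _common.ensure_dirs()
    data = _common.SCRATCH / "data"
    cfg = _common.SCAN

    gm = read_vcf(data / "genotypes.vcf.gz", data / "popmap.tsv")
    gm_f, _ = apply_locus_filters(gm)
    traits = read_trait_table(data / "traits.tsv")
    omega = bayes_popmodel.CovarianceMatrix.from_text(
        _common.RESULTS / "omega.txt", gm_f.pop_labels
    )

    all_selected = set()
    for t_i, trait in enumerate(traits.columns):
        env = bayes_popmodel.standardize_env(traits, trait, gm_f.pop_labels)
        print(f"trait {trait!r}: standardized vector "
              f"{[round(v, 3) for v in env.values]}")
        tab = bayes_popmodel.run_replicates(
            gm_f, omega, env=env, n_runs=cfg.n_runs,
            n_iter=cfg.score_iterations, beta_prior_sd=cfg.beta_prior_sd,
            seed=cfg.seed + 4000 + 100 * t_i,
        )
        arr_table = arr_rank.arr(tab)
        selected, scan_df = arr_rank.arr_scan(
            arr_table, window_bp=cfg.arr_window_bp, n_reps=cfg.arr_n_reps,
            p_threshold=cfg.trait_window_p, percentile=cfg.arr_percentile,
            seed=cfg.seed + 4500 + 100 * t_i,
        )
        scan_df.to_csv(
            _common.SCRATCH / f"trait_{trait}_arr_scan.tsv", sep="\t", index=False
        )
        n95 = int(scan_df["in_95th"].sum())
        print(f"  {n95} loci in the 95th BF-ARR percentile; {len(selected)} "
              f"also centred in windows with P < {cfg.trait_window_p}")
        all_selected |= selected

    (_common.SCRATCH / "trait_candidates.txt").write_text(
        "\n".join(sorted(all_selected)) + "\n"
    )
    print(f"trait-associated candidates (union over traits): {len(all_selected)}")

if __name__ == "__main__":
    main()
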
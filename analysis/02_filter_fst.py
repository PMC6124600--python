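#!/usr/bin/env python
"""Locus filtering and the pairwise F_ST window scan.

Applies the standard RAD filters (80% per-population presence, >=5
individuals per population, minor-allele count >= 2, one SNP per tag),
computes Weir & Cockerham theta for every population pair, smooths each
pair over 50 kb Gaussian windows, and assigns bootstrap empirical
P-values.  Candidate loci are those centred in a window significant in at
least one pairwise comparison.

Writes: results/global_fst.tsv, scratch/analysis/fst/*.tsv, and the
candidate-locus list scratch/analysis/fst_candidates.txt.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd

import _common
from divscan import diff_scan, smooth_boot
from divscan.genotype_io import apply_locus_filters, read_vcf

def main():
    _common.ensure_dirs()
    data = _common.SCRATCH / "data"
    out = _common.SCRATCH / "fst"
    out.mkdir(parents=True, exist_ok=True)
    cfg = _common.SCAN

    gm = read_vcf(data / "genotypes.vcf.gz", data / "popmap.tsv")
    gm_f, removed = apply_locus_filters(gm)
    print(f"filters: {gm.n_loci} -> {gm_f.n_loci} loci (removed {removed})")
    gm_f.loci["locus_id"].to_csv(
        _common.SCRATCH / "filtered_loci.txt", index=False, header=False
    )

    rows = []
    windows = []
    for i, (pair, tab) in enumerate(diff_scan.all_pairwise_fst(gm_f).items()):
        g = diff_scan.global_fst(tab)
        rows.append({"popA": pair[0], "popB": pair[1], **g})
        win = smooth_boot.bootstrap_window_pvalues(
            tab.scores[:, 0], gm_f.loci, cfg.fst_window_bp,
            cfg.fst_n_reps, seed=cfg.seed + 1000 + i,
        )
        windows.append(win)
        tab.to_frame().merge(
            win.drop(columns=["scaffold", "position"]), on="locus_id"
        ).to_csv(out / f"fst_{pair[0]}_{pair[1]}.tsv", sep="\t", index=False)
        print(f"  {pair[0]} vs {pair[1]}: global theta = "
              f"{g['fst_ratio_of_sums']:.4f} over {g['n_loci']} loci")

    global_tab = pd.DataFrame(rows)
    global_tab.to_csv(_common.RESULTS / "global_fst.tsv", sep="\t", index=False)
    lo, hi = global_tab["fst_ratio_of_sums"].min(), global_tab["fst_ratio_of_sums"].max()
    print(f"genome-wide pairwise F_ST range: {lo:.3f} - {hi:.3f}")

    candidates = smooth_boot.significant_windows(windows, cfg.fst_window_p)
    (_common.SCRATCH / "fst_candidates.txt").write_text(
        "\n".join(sorted(candidates)) + "\n"
    )
    print(f"F_ST window candidates (P < {cfg.fst_window_p} in >=1 pair): "
          f"{len(candidates)} loci")

if __name__ == "__main__":
    main()
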
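#!/usr/bin/env python
"""Generate the synthetic study dataset: 4 populations x 10 diploids,
10,000 SNPs on 100 scaffolds, background F = 0.07, with 60 divergent and
40 trait-correlated loci planted in 10 clusters.

Writes VCF/popmap/trait/truth files to scratch/analysis/data/ and a short
summary of the realized dataset to stdout.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import _common
from divscan import simulate

def main():
    _common.ensure_dirs()
    out = _common.SCRATCH / "data"
    out.mkdir(parents=True, exist_ok=True)

    gm, traits, truth = simulate.simulate(_common.SIM)
    simulate.write_vcf(gm, out / "genotypes.vcf.gz")
    simulate.write_popmap(gm, out / "popmap.tsv")
    simulate.write_trait_table(traits, out / "traits.tsv")
    truth.to_tsv(out / "truth.tsv")
    truth.clusters.to_csv(out / "truth_clusters.tsv", sep="\t", index=False)

    counts = truth.table["class"].value_counts()
    print(f"dataset: {gm.n_loci} SNPs x {gm.n_samples} samples "
          f"({len(gm.pop_labels)} populations) on {len(gm.scaffold_lengths)} scaffolds")
    print(f"locus classes: {dict(counts)}")
    print(f"planted clusters: {len(truth.clusters)} "
          f"({(truth.clusters['class'] == 'divergent').sum()} divergent, "
          f"{(truth.clusters['class'] == 'trait_linked').sum()} trait-linked)")
    print(f"trait means per population:\n{traits}")
    print(f"outputs in {out}")

if __name__ == "__main__":
    main()
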
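import numpy as np
import pandas as pd
import pytest

from divscan import simulate
from divscan.genotype_io import GenotypeMatrix


@pytest.fixture(scope="session")
def neutral_sim():
    """Small neutral Balding-Nichols dataset (4 pops x 10 ind, F = 0.07)."""
    cfg = simulate.SimConfig(n_loci=800, n_scaffolds=10, seed=101)
    gm, traits, truth = simulate.simulate(cfg)
    return gm, traits, truth


@pytest.fixture(scope="session")
def planted_sim():
    """Dataset with clustered divergent and trait-linked loci planted."""
    cfg = simulate.SimConfig(
        n_loci=1200, n_scaffolds=15, n_divergent=30, divergent_shift=0.5,
        n_trait_loci=20, trait_slope=2.0, n_clusters=5, seed=202,
    )
    return simulate.simulate(cfg)


def make_gm(dosage, positions=None, scaffolds=None, pops=None, tag_ids=None,
            scaffold_length=1_000_000):
    """Hand-built GenotypeMatrix from a (loci x samples) dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_loci, n_samples = dosage.shape
    if pops is None:
        half = n_samples // 2
        pops = ["A"] * half + ["B"] * (n_samples - half)
    samples = [f"s{i}" for i in range(n_samples)]
    positions = positions if positions is not None else (np.arange(n_loci) + 1) * 100
    scaffolds = scaffolds if scaffolds is not None else ["scf1"] * n_loci
    loci = pd.DataFrame(
        {
            "locus_id": [f"L{i}" for i in range(n_loci)],
            "scaffold": scaffolds,
            "position": positions,
            "tag_id": tag_ids if tag_ids is not None else [f"t{i}" for i in range(n_loci)],
            "ref": "A",
            "alt": "G",
        }
    ).sort_values(["scaffold", "position"])
    return GenotypeMatrix(
        loci=loci,
        samples=samples,
        populations=dict(zip(samples, pops)),
        dosage=dosage[loci.index.to_numpy()],
        scaffold_lengths={s: scaffold_length for s in set(scaffolds)},
    )
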
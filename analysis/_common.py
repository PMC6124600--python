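"""Shared paths and the desk-scale study configuration for the analysis steps.

Intermediate (large) files live under scratch/, final tables under results/.
Every step reads its inputs from the previous step's outputs, so the scripts
run in order: 01 -> 05.
"""

from pathlib import Path

from divscan import simulate
from divscan.pipeline import RunConfig

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 7

# Study conditions: 4 populations x 10 diploids, ~10^4 SNPs on 100 scaffolds,
# background differentiation F = 0.07, with clustered planted signals.
SIM = simulate.SimConfig(
    n_loci=10_000,
    n_scaffolds=100,
    background_f=0.07,
    n_divergent=60,
    divergent_shift=0.5,
    n_trait_loci=40,
    trait_slope=2.0,
    n_clusters=10,
    seed=SEED,
)

# Desk-scale replicate counts (production defaults mirror the full protocol;
# see docs/methods.md for the scaling rationale).
SCAN = RunConfig.test_profile(seed=SEED)


def ensure_dirs():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
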
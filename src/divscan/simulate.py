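"""Synthetic genotype datasets with known truth for pipeline testing.

The generator emulates the statistical structure of a reduced-representation
(RAD-style) SNP dataset from a small number of closely related populations:

* a neutral background under the Balding--Nichols model -- per-locus
  ancestral frequency p ~ Uniform(0.05, 0.95), population frequencies
  Beta(p(1-F)/F, (1-p)(1-F)/F) drawn independently per population -- which
  is exactly the exchangeable covariance structure (Omega = F I on the
  standardized scale) that the scan's Bayesian model assumes;
* planted divergent loci: one designated population's frequency displaced
  by a fixed shift (default) or redrawn with an inflated F, placed in
  clusters of a configurable width so that window scans see contiguous
  signal;
* planted trait-correlated loci: population frequency
  inverse-logit(logit(p) + slope * standardized trait), tracking a
  per-population trait vector (default: one population distinctly lower,
  the small-eyed-species pattern);
* genotypes Binomial(2, p_pop) per diploid individual, with optional
  missingness.

Defaults mirror the study conditions the pipeline is meant for: 4
populations x 10 individuals, 10,000 SNPs on 100 scaffolds, background
F = 0.07 (inside the 0.05-0.09 genome-wide differentiation range typical of
such species groups).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, MISSING

DEFAULT_TRAIT = "trait"


@dataclass
class SimConfig:
    """Generator settings; defaults define the reference study conditions."""

    n_pops: int = 4
    n_ind_per_pop: int = 10
    n_loci: int = 10_000
    n_scaffolds: int = 100
    scaffold_length: int = 1_000_000
    background_f: float = 0.07
    n_divergent: int = 0
    divergent_shift: float = 0.5  # frequency displacement in one population
    divergent_f_mult: float | None = None  # alternative: redraw with F * mult
    divergent_pop: int = 1  # index of the displaced population
    n_trait_loci: int = 0
    trait_slope: float = 0.0  # logit-scale effect per sd of trait
    trait_values: tuple[float, ...] | None = None  # raw per-pop trait means
    n_clusters: int | None = None  # planted loci spread over this many clusters
    cluster_width_bp: int = 20_000
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.background_f < 1:
            raise ValueError("background_f must lie in (0, 1)")
        for name in ("n_pops", "n_ind_per_pop", "n_loci", "n_scaffolds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_divergent + self.n_trait_loci > self.n_loci:
            raise ValueError("planted loci exceed n_loci")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class TruthTable:
    """Per-locus ground truth emitted alongside the genotypes."""

    table: pd.DataFrame  # locus_id, class, cluster, true_freq_<pop>...
    clusters: pd.DataFrame = field(default_factory=pd.DataFrame)
    # clusters: cluster, class, scaffold, start, end

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _bn_draw(rng, p, f):
    """Balding-Nichols population frequency around ancestral p."""
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return rng.beta(a, b)


def default_trait_vector(n_pops: int) -> np.ndarray:
    """One population distinctly lower than the rest (e.g. a small-eyed species)."""
    v = np.full(n_pops, 0.31)
    v[1] = 0.24
    if n_pops > 2:  # mild spread among the remaining populations
        v[2:] = 0.31 + 0.01 * np.arange(1, n_pops - 1)
    return v


def simulate(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame, TruthTable]:
    """Generate (GenotypeMatrix, trait table, truth table) under ``config``."""
    rng = np.random.default_rng(config.seed)
    K, L = config.n_pops, config.n_loci
    pops = [f"pop{k + 1}" for k in range(K)]

    trait_raw = (
        np.asarray(config.trait_values, dtype=float)
        if config.trait_values is not None
        else default_trait_vector(K)
    )
    trait_std = (trait_raw - trait_raw.mean()) / trait_raw.std(ddof=1)

    # locus classes
    classes = np.array(["neutral"] * L, dtype=object)
    classes[: config.n_divergent] = "divergent"
    classes[config.n_divergent : config.n_divergent + config.n_trait_loci] = (
        "trait_linked"
    )

    # ancestral and population frequencies
    p_anc = rng.uniform(0.05, 0.95, L)
    p_pop = np.empty((L, K))
    for k in range(K):
        p_pop[:, k] = _bn_draw(rng, p_anc, config.background_f)

    div = classes == "divergent"
    if div.any():
        k = config.divergent_pop
        if config.divergent_f_mult is not None:
            f_hi = min(config.background_f * config.divergent_f_mult, 0.95)
            p_pop[div, k] = _bn_draw(rng, p_anc[div], f_hi)
        else:
            shift = np.where(p_anc[div] < 0.5, config.divergent_shift,
                             -config.divergent_shift)
            p_pop[div, k] = np.clip(p_pop[div, k] + shift, 0.01, 0.99)

    trt = classes == "trait_linked"
    if trt.any():
        # slope shift applied on top of the drift draw, so slope = 0 leaves
        # trait-linked loci exactly neutral
        base = np.clip(p_pop[trt], 1e-9, 1 - 1e-9)
        logit = np.log(base / (1 - base))
        shifted = logit + config.trait_slope * trait_std[None, :]
        p_pop[trt] = 1.0 / (1.0 + np.exp(-shifted))

    # coordinates: neutral loci uniform over scaffolds; planted loci clustered
    scaffolds = np.array([f"scf{j + 1:04d}" for j in range(config.n_scaffolds)])
    scf_idx = rng.integers(0, config.n_scaffolds, L)
    pos = rng.integers(1, config.scaffold_length + 1, L)

    cluster_id = np.full(L, -1)
    cluster_rows = []
    half = config.cluster_width_bp // 2
    next_cluster = 0
    for cls_mask, cls_name in ((div, "divergent"), (trt, "trait_linked")):
        if not cls_mask.any():
            continue
        p_idx = np.where(cls_mask)[0]
        n_cls = (
            max(1, round(config.n_clusters * p_idx.size / (div | trt).sum()))
            if config.n_clusters
            else max(1, p_idx.size // 10)
        )
        cluster_scf = rng.choice(
            config.n_scaffolds, size=n_cls, replace=n_cls > config.n_scaffolds
        )
        centers = rng.integers(1 + half, config.scaffold_length - half + 1, n_cls)
        which = np.arange(p_idx.size) % n_cls
        for c in range(n_cls):
            members = p_idx[which == c]
            scf_idx[members] = cluster_scf[c]
            pos[members] = rng.integers(
                centers[c] - half, centers[c] + half + 1, members.size
            )
            cluster_id[members] = next_cluster
            cluster_rows.append(
                {
                    "cluster": next_cluster,
                    "class": cls_name,
                    "scaffold": scaffolds[cluster_scf[c]],
                    "start": int(centers[c] - half),
                    "end": int(centers[c] + half),
                }
            )
            next_cluster += 1

    # resolve coordinate collisions deterministically
    coord = pd.DataFrame({"scf": scf_idx, "pos": pos})
    while coord.duplicated(["scf", "pos"]).any():
        dup = coord.duplicated(["scf", "pos"]).to_numpy()
        coord.loc[dup, "pos"] = (
            coord.loc[dup, "pos"] % (config.scaffold_length - 1)
        ) + 1
    pos = coord["pos"].to_numpy()

    # genotypes
    samples = [f"{p}_ind{i + 1}" for p in pops for i in range(config.n_ind_per_pop)]
    populations = {
        s: pops[j // config.n_ind_per_pop] for j, s in enumerate(samples)
    }
    dosage = np.empty((L, len(samples)), dtype=np.int8)
    for k in range(K):
        cols = slice(k * config.n_ind_per_pop, (k + 1) * config.n_ind_per_pop)
        dosage[:, cols] = rng.binomial(
            2, p_pop[:, k][:, None], (L, config.n_ind_per_pop)
        )
    if config.missing_rate > 0:
        miss = rng.uniform(size=dosage.shape) < config.missing_rate
        dosage[miss] = MISSING

    loci = pd.DataFrame(
        {
            "locus_id": [f"L{i + 1:06d}" for i in range(L)],
            "scaffold": scaffolds[scf_idx],
            "position": pos,
            "tag_id": [f"tag{i + 1:06d}" for i in range(L)],
            "ref": "A",
            "alt": "G",
        }
    )
    order = loci.sort_values(["scaffold", "position"]).index.to_numpy()

    gm = GenotypeMatrix(
        loci=loci.iloc[order],
        samples=samples,
        populations=populations,
        dosage=dosage[order],
        scaffold_lengths={s: config.scaffold_length for s in scaffolds},
    )
    trait_table = pd.DataFrame(
        {DEFAULT_TRAIT: trait_raw}, index=pd.Index(pops, name="population")
    )
    truth_df = pd.DataFrame(
        {
            "locus_id": loci["locus_id"].to_numpy()[order],
            "class": classes[order],
            "cluster": cluster_id[order],
            **{
                f"true_freq_{pops[k]}": p_pop[order, k] for k in range(K)
            },
        }
    )
    truth = TruthTable(table=truth_df, clusters=pd.DataFrame(cluster_rows))
    return gm, trait_table, truth


# ---------------------------------------------------------------------------
# writers


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (GT-only, contig headers with lengths).

    Missing dosages serialize as ``./.``; a ``TAG`` INFO field carries the
    RAD-tag identifier when present.  Gzip output if the path ends in .gz.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with opener(str(path), "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=TAG,Number=1,Type=String,Description="RAD tag id">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for scf in sorted(gm.scaffold_lengths):
            fh.write(f"##contig=<ID={scf},length={gm.scaffold_lengths[scf]}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i, row in enumerate(gm.loci.itertuples()):
            info = f"TAG={row.tag_id}" if row.tag_id else "."
            gts = "\t".join(code[int(d)] for d in gm.dosage[i])
            fh.write(
                f"{row.scaffold}\t{row.position}\t{row.locus_id}\t{row.ref}"
                f"\t{row.alt}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def write_popmap(gm: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        for s in gm.samples:
            fh.write(f"{s}\t{gm.populations[s]}\n")


def write_trait_table(trait_table: pd.DataFrame, path) -> None:
    trait_table.rename_axis("population").reset_index().to_csv(
        path, sep="\t", index=False
    )
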
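"""Genotype matrix input, validation and locus filtering.

The whole pipeline operates on a biallelic SNP x individual allele-dosage
matrix with scaffold coordinates and a sample-to-population map.  This module
owns the conventions every downstream scan relies on:

* coordinates are 1-based inclusive internally (VCF convention); exported
  intervals are BED 0-based half-open;
* dosage is the count of alternate alleles in {0, 1, 2}, with ``-1`` marking
  a missing genotype (half-missing genotypes count as missing);
* missing data are never imputed -- every statistic uses observed allele
  counts only.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

LOCUS_COLUMNS = ["locus_id", "scaffold", "position", "tag_id", "ref", "alt"]

# RAD-tag length proxy used to bin SNPs when no tag identifiers are available.
TAG_BIN_BP = 90


class GenotypeIOError(ValueError):
    """Raised for malformed or mutually inconsistent genotype inputs."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP x individual dosage table with population structure.

    Parameters
    ----------
    loci : pandas.DataFrame
        One row per locus with columns ``locus_id, scaffold, position,
        tag_id, ref, alt``, sorted by (scaffold, position).
    samples : list of str
        Sample identifiers, in dosage column order.
    populations : dict
        Sample -> population label; every sample must be present.
    dosage : numpy.ndarray of int8, shape (n_loci, n_samples)
        Alternate-allele counts, ``-1`` for missing.
    scaffold_lengths : dict, optional
        Scaffold -> length in bp (from VCF contig headers); used for
        region clamping downstream.
    """

    loci: pd.DataFrame
    samples: list[str]
    populations: dict[str, str]
    dosage: np.ndarray
    scaffold_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.loci = self.loci.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.dosage.shape != (len(self.loci), len(self.samples)):
            raise GenotypeIOError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.loci)} loci x {len(self.samples)} samples"
            )
        missing_pop = [s for s in self.samples if s not in self.populations]
        if missing_pop:
            raise GenotypeIOError(f"samples without population: {missing_pop}")
        if len(self.pop_labels) < 2:
            raise GenotypeIOError("need at least 2 populations")
        bad = (self.dosage < -1) | (self.dosage > 2)
        if bad.any():
            raise GenotypeIOError("dosage values outside {-1, 0, 1, 2}")
        key = self.loci[["scaffold", "position"]]
        if key.duplicated().any():
            raise GenotypeIOError("duplicate (scaffold, position) loci")
        if not (
            self.loci.sort_values(["scaffold", "position"]).index
            == self.loci.index
        ).all():
            raise GenotypeIOError("loci not sorted by (scaffold, position)")
        if (self.loci["position"] < 1).any():
            raise GenotypeIOError("positions must be >= 1 (1-based)")

    # -- population structure --------------------------------------------
    @property
    def pop_labels(self) -> list[str]:
        """Population labels in deterministic (sorted) order."""
        return sorted(set(self.populations.values()))

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def pop_sample_indices(self, pop: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.populations[s] == pop]
        if not idx:
            raise GenotypeIOError(f"unknown population label: {pop!r}")
        return np.asarray(idx, dtype=int)

    def subset_loci(self, mask_or_index) -> "GenotypeMatrix":
        """New matrix restricted to the given boolean mask / integer index."""
        idx = np.arange(self.n_loci)[mask_or_index]
        return GenotypeMatrix(
            loci=self.loci.iloc[idx],
            samples=list(self.samples),
            populations=dict(self.populations),
            dosage=self.dosage[idx],
            scaffold_lengths=dict(self.scaffold_lengths),
        )


# ---------------------------------------------------------------------------
# readers


def _open_maybe_gzip(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_popmap(path) -> dict[str, str]:
    """Read a two-column sample<TAB>population map (gzip tolerated)."""
    popmap: dict[str, str] = {}
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise GenotypeIOError(f"malformed popmap line: {line!r}")
            popmap[parts[0]] = parts[1]
    if not popmap:
        raise GenotypeIOError(f"empty popmap: {path}")
    return popmap


def read_trait_table(path) -> pd.DataFrame:
    """Read per-population trait means: population<TAB>one column per trait.

    Returns a DataFrame indexed by population.  Each trait column must have
    at least two distinct values across populations.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise GenotypeIOError("trait table needs a population column plus >=1 trait")
    df = df.set_index(df.columns[0])
    if df.index.duplicated().any():
        raise GenotypeIOError("duplicate population rows in trait table")
    for col in df.columns:
        if df[col].nunique() < 2:
            raise GenotypeIOError(f"trait {col!r} has <2 distinct values")
    return df


def read_vcf(path, popmap_path, min_dp: int | None = None) -> GenotypeMatrix:
    """Read a VCF 4.x into a :class:`GenotypeMatrix`.

    Biallelic SNP records are converted to alternate-allele dosages;
    multiallelic and non-SNP records are dropped (count logged).  Genotypes
    with any missing allele become missing.  A ``TAG`` INFO field, when
    present, populates ``tag_id`` for the one-SNP-per-tag filter.  With
    ``min_dp``, genotypes whose FORMAT/DP falls below the threshold are
    masked to missing (read depth is otherwise an upstream calling concern).

    Raises
    ------
    GenotypeIOError
        If a VCF sample is absent from the popmap or no usable locus remains.
    """
    from cyvcf2 import VCF

    popmap = read_popmap(popmap_path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in popmap]
    if absent:
        raise GenotypeIOError(f"VCF samples missing from popmap: {absent}")

    scaffold_lengths = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else {}

    rows = []
    dosages = []
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_dropped += 1
            continue
        gts = var.genotypes  # [[a0, a1, phased], ...]
        dos = np.empty(len(samples), dtype=np.int8)
        for j, g in enumerate(gts):
            a = g[:-1]
            if len(a) != 2 or min(a) < 0:
                dos[j] = MISSING
            else:
                dos[j] = int(a[0] > 0) + int(a[1] > 0)
        if min_dp is not None:
            dp = var.format("DP")
            if dp is not None:
                dos[dp.ravel()[: len(samples)] < min_dp] = MISSING
        tag = dict(var.INFO).get("TAG")
        rows.append(
            {
                "locus_id": var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}",
                "scaffold": var.CHROM,
                "position": var.POS,
                "tag_id": tag,
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
        dosages.append(dos)
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic/non-SNP records", n_dropped)
    if not rows:
        raise GenotypeIOError(f"no usable biallelic SNP records in {path}")

    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    dosage = np.vstack(dosages)
    order = loci.sort_values(["scaffold", "position"]).index.to_numpy()
    return GenotypeMatrix(
        loci=loci.iloc[order],
        samples=samples,
        populations={s: popmap[s] for s in samples},
        dosage=dosage[order],
        scaffold_lengths=scaffold_lengths,
    )


# ---------------------------------------------------------------------------
# filters


def apply_locus_filters(
    gm: GenotypeMatrix,
    min_pop_presence: float = 0.8,
    min_ind_per_pop: int = 5,
    min_mac: int = 2,
    one_per_tag: bool = True,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply the standard RAD locus filters, returning (matrix, removal counts).

    A locus is retained when, in *every* population, it is genotyped in at
    least ``min_pop_presence`` of the individuals and in at least
    ``min_ind_per_pop`` individuals; when its global minor-allele count is at
    least ``min_mac``; and, with ``one_per_tag``, when it is the
    lowest-position SNP of its RAD tag (loci without tag identifiers fall
    back to non-overlapping 90 bp bins per scaffold as a tag-length proxy).

    Filters are applied sequentially (presence, then MAC, then tag) and the
    per-filter removal counts refer to that order.  Filtering is idempotent.
    """
    counts: dict[str, int] = {}
    observed = gm.dosage != MISSING

    keep = np.ones(gm.n_loci, dtype=bool)
    for pop in gm.pop_labels:
        idx = gm.pop_sample_indices(pop)
        n_obs = observed[:, idx].sum(axis=1)
        keep &= n_obs >= max(min_pop_presence * len(idx), min_ind_per_pop)
    counts["presence"] = int((~keep).sum())

    dos = gm.dosage.astype(np.int64)
    alt = np.where(observed, dos, 0).sum(axis=1)
    total = 2 * observed.sum(axis=1)
    mac = np.minimum(alt, total - alt)
    mac_fail = keep & (mac < min_mac)
    counts["mac"] = int(mac_fail.sum())
    keep &= ~mac_fail

    counts["tag"] = 0
    if one_per_tag:
        loci = gm.loci
        tag = loci["tag_id"]
        if tag.isna().any():
            # positional fallback: 90 bp bins per scaffold
            tag = tag.where(
                tag.notna(),
                loci["scaffold"].astype(str)
                + ":bin"
                + (loci["position"] // TAG_BIN_BP).astype(str),
            )
        surviving = pd.Series(keep, index=loci.index)
        first = (
            loci[surviving]
            .assign(_tag=tag[surviving])
            .sort_values(["scaffold", "position"])
            .drop_duplicates("_tag", keep="first")
            .index
        )
        tag_keep = np.zeros(gm.n_loci, dtype=bool)
        tag_keep[first] = True
        counts["tag"] = int((keep & ~tag_keep).sum())
        keep &= tag_keep

    if not keep.any():
        raise GenotypeIOError(f"all loci removed by filters: {counts}")
    return gm.subset_loci(keep), counts


def allele_frequencies(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus, per-population alternate-allele frequencies.

    Returns
    -------
    freq : ndarray (n_loci, K)
        Alt-allele count / observed allele count; NaN where a population has
        zero observed alleles at a locus.  Populations ordered as
        ``gm.pop_labels``.
    n_alleles : ndarray (n_loci, K)
        Observed (non-missing) allele counts (2 x genotyped individuals).
    """
    pops = gm.pop_labels
    freq = np.full((gm.n_loci, len(pops)), np.nan)
    n_alleles = np.zeros((gm.n_loci, len(pops)), dtype=np.int64)
    observed = gm.dosage != MISSING
    dos = gm.dosage.astype(np.int64)
    for k, pop in enumerate(pops):
        idx = gm.pop_sample_indices(pop)
        n = 2 * observed[:, idx].sum(axis=1)
        alt = np.where(observed[:, idx], dos[:, idx], 0).sum(axis=1)
        n_alleles[:, k] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[:, k] = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return freq, n_alleles


def read_external_candidates(path) -> set[str]:
    """Read an external candidate-locus list (one locus_id per line)."""
    with _open_maybe_gzip(path) as fh:
        ids = {line.strip() for line in fh if line.strip() and not line.startswith("#")}
    return ids
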
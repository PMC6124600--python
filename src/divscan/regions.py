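"""Candidate regions, multi-method consensus, gene intersection, enrichment.

Candidate SNPs are flanked by +-flank_bp (default 50 kb), clamped to the
scaffold, and overlapping or abutting intervals on one scaffold are merged.
Loci are classified by how many independent detection methods support them
(consensus tiers); regions can be built per tier.  Gene intersection uses
any >=1 bp overlap; term enrichment is a one-sided Fisher's exact test per
term with Benjamini-Hochberg FDR across terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class CandidateRegion:
    """A merged scaffold interval around candidate SNPs.

    Coordinates are 1-based inclusive internally; ``to_bed_row`` exports
    0-based half-open.
    """

    scaffold: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    supporting_loci: set[str] = field(default_factory=set)
    methods: set[str] = field(default_factory=set)
    genes: set[str] = field(default_factory=set)

    @property
    def support(self) -> int:
        return len(self.methods)

    def to_bed_row(self, region_id: str) -> str:
        return (
            f"{self.scaffold}\t{self.start - 1}\t{self.end}\t{region_id}"
            f"\t{self.support}\t."
        )


def build_regions(
    candidates: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    flank_bp: int = 50_000,
    methods: dict[str, set[str]] | None = None,
) -> list[CandidateRegion]:
    """+-flank_bp regions around candidate SNPs, merged per scaffold.

    ``candidates``: DataFrame with locus_id, scaffold, position (1-based).
    ``methods``: optional locus_id -> method-name set, unioned into merged
    regions.  Intervals that overlap or abut are merged; output is sorted
    and independent of input row order.  A locus on a scaffold absent from
    ``scaffold_lengths`` is a hard error.
    """
    regions: list[CandidateRegion] = []
    for scaffold, grp in candidates.sort_values(["scaffold", "position"]).groupby(
        "scaffold", sort=True
    ):
        if scaffold not in scaffold_lengths:
            raise ValueError(f"unknown scaffold {scaffold!r} (no length available)")
        slen = int(scaffold_lengths[scaffold])
        current: CandidateRegion | None = None
        for _, row in grp.iterrows():
            pos = int(row["position"])
            start = max(1, pos - flank_bp)
            end = min(slen, pos + flank_bp)
            meth = set(methods.get(row["locus_id"], set())) if methods else set()
            if current is not None and start <= current.end + 1:  # abutting merges
                current.end = max(current.end, end)
                current.supporting_loci.add(row["locus_id"])
                current.methods |= meth
            else:
                if current is not None:
                    regions.append(current)
                current = CandidateRegion(
                    scaffold=scaffold, start=start, end=end,
                    supporting_loci={row["locus_id"]}, methods=meth,
                )
        if current is not None:
            regions.append(current)
    return regions


def consensus_classify(
    method_sets: dict[str, set[str]],
) -> tuple[pd.Series, dict[int, int]]:
    """Per-locus support count and tallies by number of supporting methods.

    Returns ``(support, tallies)`` where ``support`` maps every locus in the
    union of the method sets to its support count and ``tallies[m]`` counts
    loci supported by exactly m methods.  Tallies sum to the union size.
    """
    if not method_sets:
        raise ValueError("need at least one method set")
    union: dict[str, int] = {}
    for loci in method_sets.values():
        for locus in loci:
            union[locus] = union.get(locus, 0) + 1
    support = pd.Series(union, dtype=int).sort_index()
    tallies = {
        m: int((support == m).sum()) for m in range(1, len(method_sets) + 1)
    }
    return support, tallies


def method_map(method_sets: dict[str, set[str]]) -> dict[str, set[str]]:
    """Invert method -> loci into locus -> methods."""
    out: dict[str, set[str]] = {}
    for method, loci in method_sets.items():
        for locus in loci:
            out.setdefault(locus, set()).add(method)
    return out


def read_gene_annotation(path) -> pd.DataFrame:
    """Read gene intervals from BED6 or GFF3 (gene features).

    Returns a DataFrame gene_id, scaffold, start, end with 1-based inclusive
    coordinates.  Malformed lines are skipped with a logged count.
    """
    from .genotype_io import _open_maybe_gzip

    path = str(path)
    rows = []
    n_bad = 0
    is_gff = path.rstrip(".gz").endswith((".gff", ".gff3"))
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if is_gff:
                    if f[2].lower() != "gene":
                        continue
                    attrs = dict(
                        kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                    )
                    gene = attrs.get("ID") or attrs.get("Name")
                    rows.append((gene, f[0], int(f[3]), int(f[4])))
                else:  # BED: 0-based half-open -> 1-based inclusive
                    rows.append((f[3], f[0], int(f[1]) + 1, int(f[2])))
            except (IndexError, ValueError):
                n_bad += 1
    if n_bad:
        logger.warning("read_gene_annotation: skipped %d malformed lines", n_bad)
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end"])


def intersect_genes(
    regions: list[CandidateRegion], annotation: pd.DataFrame
) -> list[CandidateRegion]:
    """Assign genes to regions on any >=1 bp overlap (in place; returns regions)."""
    trees: dict[str, IntervalTree] = {}
    for row in annotation.itertuples():
        # half-open interval keys: [start, end+1) covers 1-based inclusive
        trees.setdefault(row.scaffold, IntervalTree()).addi(
            row.start, row.end + 1, row.gene_id
        )
    for reg in regions:
        tree = trees.get(reg.scaffold)
        if tree is None:
            continue
        reg.genes = {iv.data for iv in tree.overlap(reg.start, reg.end + 1)}
    return regions


def read_term_map(path) -> dict[str, set[str]]:
    """Read a gene<TAB>term map (one pair per line, or comma-joined terms)."""
    from .genotype_io import _open_maybe_gzip

    out: dict[str, set[str]] = {}
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, terms = line.split("\t")[:2]
            out.setdefault(gene, set()).update(terms.split(","))
    return out


def term_enrichment(
    selected_genes: set[str],
    background_genes: set[str],
    term_map: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided Fisher's exact over-representation test per term, BH-FDR.

    The 2x2 table per term contrasts selected vs non-selected background
    genes carrying vs lacking the term.  Requires ``selected_genes`` to be a
    non-empty subset of ``background_genes``.
    """
    if not selected_genes:
        raise ValueError("empty selected gene set")
    if not selected_genes <= background_genes:
        raise ValueError("selected genes must be a subset of the background")
    terms = sorted({t for g in background_genes for t in term_map.get(g, ())})
    n_sel = len(selected_genes)
    n_other = len(background_genes) - n_sel
    rows = []
    for term in terms:
        with_term = {g for g in background_genes if term in term_map.get(g, ())}
        k = len(with_term & selected_genes)
        m = len(with_term) - k
        table = [[k, n_sel - k], [m, n_other - m]]
        odds, p = fisher_exact(table, alternative="greater")
        rows.append((term, k, len(with_term), odds, p))
    df = pd.DataFrame(
        rows, columns=["term", "count_selected", "count_background", "odds_ratio", "P"]
    )
    if len(df):
        df["FDR"] = multipletests(df["P"], method="fdr_bh")[1]
    else:
        df["FDR"] = np.nan
    return df.sort_values("P").reset_index(drop=True)


def write_bed(regions: list[CandidateRegion], path) -> None:
    with open(path, "w") as fh:
        for i, reg in enumerate(regions, start=1):
            fh.write(reg.to_bed_row(f"region_{i:04d}") + "\n")
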
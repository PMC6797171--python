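"""Map SNPs to gene regions and tally population-differentiated genes.

Every SNP is assigned exactly one label out of {promoter, utr5, coding,
intron, utr3, intergenic}.  The promoter is the 5 kb (configurable)
immediately upstream of the transcription start site, strand-aware: for a
minus-strand gene it occupies coordinates *greater* than the TSS.  When a
SNP overlaps features of several (possibly overlapping) genes, a fixed
precedence resolves the label; the default order is
``coding > utr5 > utr3 > promoter > intron``.

Genes carrying at least one population-differentiated SNP (pdSNP) are
"pdGenes"; genes carrying at least three are "enriched pdGenes", and
analogously for the potentially-functional (pf) subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

REGION_LABELS = ("promoter", "utr5", "coding", "intron", "utr3", "intergenic")
DEFAULT_PRECEDENCE = ("coding", "utr5", "utr3", "promoter", "intron")
DEFAULT_PROMOTER_BP = 5000


@dataclass
class GeneModel:
    """One transcript's strand-aware structure, 1-based inclusive coordinates.

    ``exons`` are sorted, non-overlapping genomic intervals;
    ``cds_start``/``cds_end`` give the genomic span of the coding sequence
    (both 0 for a non-coding transcript is not supported here: every model
    is coding).
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start: int = 0
    cds_end: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start {s} > end {e}")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e
        if self.exons[0][0] < self.tx_start or self.exons[-1][1] > self.tx_end:
            raise ValueError(f"{self.gene_id}: exons outside transcript span")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.gene_id}: CDS outside transcript span")

    @property
    def tss(self) -> int:
        """Transcription start site (genomic coordinate)."""
        return self.tx_start if self.strand == "+" else self.tx_end


def _intersect(intervals: Sequence[tuple[int, int]], lo: int, hi: int) -> list[tuple[int, int]]:
    out = []
    for s, e in intervals:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 <= e2:
            out.append((s2, e2))
    return out


def derive_intervals(
    model: GeneModel,
    promoter_bp: int = DEFAULT_PROMOTER_BP,
    chrom_length: int | None = None,
) -> dict[str, list[tuple[int, int]]]:
    """Split a gene model into labelled genomic intervals.

    Returns a dict label -> list of 1-based inclusive (start, end).  The
    promoter is truncated at the chromosome edge; introns are the gaps
    between exons; UTRs are the exonic bases up/downstream of the CDS in
    transcription order.
    """
    if model.strand == "+":
        promoter = (max(1, model.tx_start - promoter_bp), model.tx_start - 1)
    else:
        end = model.tx_end + promoter_bp
        if chrom_length is not None:
            end = min(end, chrom_length)
        promoter = (model.tx_end + 1, end)
    promoters = [promoter] if promoter[0] <= promoter[1] else []

    introns = []
    for (s1, e1), (s2, _) in zip(model.exons, model.exons[1:]):
        introns.append((e1 + 1, s2 - 1))

    coding = _intersect(model.exons, model.cds_start, model.cds_end)
    left_utr = _intersect(model.exons, model.tx_start, model.cds_start - 1)
    right_utr = _intersect(model.exons, model.cds_end + 1, model.tx_end)
    if model.strand == "+":
        utr5, utr3 = left_utr, right_utr
    else:
        utr5, utr3 = right_utr, left_utr

    return {
        "promoter": promoters,
        "utr5": utr5,
        "coding": coding,
        "intron": introns,
        "utr3": utr3,
    }


def merge_gene_intervals(
    models: Iterable[GeneModel],
    promoter_bp: int = DEFAULT_PROMOTER_BP,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[tuple[str, str], dict[str, list[tuple[int, int]]]]:
    """Union the labelled intervals of all transcripts of each gene.

    Keyed by (gene_id, chrom).  Gene-level (not transcript-level)
    resolution: multiple transcripts of one gene are merged per label
    before SNP assignment, because downstream gene tallies are gene-keyed.
    """
    merged: dict[tuple[str, str], dict[str, list[tuple[int, int]]]] = {}
    for m in models:
        clen = chrom_lengths.get(m.chrom) if chrom_lengths else None
        ivs = derive_intervals(m, promoter_bp, clen)
        tgt = merged.setdefault((m.gene_id, m.chrom), {lab: [] for lab in ivs})
        for lab, lst in ivs.items():
            tgt[lab].extend(lst)
    for key, labd in merged.items():
        for lab, lst in labd.items():
            labd[lab] = _merge_sorted(lst)
    return merged


def _merge_sorted(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def assign_region(
    sites: pd.DataFrame,
    models: Iterable[GeneModel],
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    promoter_bp: int = DEFAULT_PROMOTER_BP,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Assign one region label (and gene) to every SNP.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom``, ``pos`` (1-based), ``snp_id``.
    models
        Gene models; transcripts of one gene are merged first.
    precedence
        Label order used when a SNP overlaps several features.  Among
        equal-precedence overlaps the lexicographically smallest gene id
        wins (deterministic).

    Returns a DataFrame (snp_id, region, gene_id) with gene_id ``None``
    for intergenic SNPs.
    """
    if set(precedence) != set(DEFAULT_PRECEDENCE):
        raise ValueError(f"precedence must permute {DEFAULT_PRECEDENCE}")
    rank = {lab: i for i, lab in enumerate(precedence)}
    merged = merge_gene_intervals(models, promoter_bp, chrom_lengths)
    trees: dict[str, IntervalTree] = {}
    for (gene, chrom), labd in merged.items():
        tree = trees.setdefault(chrom, IntervalTree())
        for lab, lst in labd.items():
            for s, e in lst:
                tree.addi(s, e + 1, (lab, gene))  # half-open internally

    regions = []
    genes: list[str | None] = []
    for chrom, pos in zip(sites["chrom"].to_numpy(), sites["pos"].to_numpy()):
        tree = trees.get(chrom)
        hits = tree[int(pos)] if tree is not None else ()
        if not hits:
            regions.append("intergenic")
            genes.append(None)
        else:
            lab, gene = min((h.data for h in hits), key=lambda d: (rank[d[0]], d[1]))
            regions.append(lab)
            genes.append(gene)
    return pd.DataFrame(
        {"snp_id": sites["snp_id"].to_numpy(), "region": regions, "gene_id": genes}
    )


def tally_genes(
    annotations: pd.DataFrame,
    pd_set: set[str],
    pf_set: set[str],
    min_enriched: int = 3,
) -> pd.DataFrame:
    """Per-gene pdSNP / pf-pdSNP counts and the derived gene flags.

    A pdGene carries >= 1 pdSNP; an enriched pdGene carries >=
    ``min_enriched`` (default 3).  pf-pdSNPs are SNPs that are both
    population-differentiated and flagged potentially functional; only
    genic SNPs (non-intergenic labels) count toward a gene.
    """
    genic = annotations[annotations["gene_id"].notna()]
    is_pd = genic["snp_id"].isin(pd_set)
    is_pfpd = is_pd & genic["snp_id"].isin(pf_set)
    tally = (
        pd.DataFrame(
            {
                "gene_id": genic["gene_id"],
                "n_pd": is_pd.astype(int),
                "n_pfpd": is_pfpd.astype(int),
            }
        )
        .groupby("gene_id", sort=True)
        .sum()
        .reset_index()
    )
    tally["pd_gene"] = tally["n_pd"] >= 1
    tally["pf_pd_gene"] = tally["n_pfpd"] >= 1
    tally["enriched_pd_gene"] = tally["n_pd"] >= min_enriched
    tally["enriched_pf_pd_gene"] = tally["n_pfpd"] >= min_enriched
    return tally


def composition_table(
    annotations: pd.DataFrame,
    categories: Mapping[str, set[str] | None],
) -> pd.DataFrame:
    """Region counts and proportions per SNP category.

    ``categories`` maps a category name (e.g. "all", "pd", "pfpd") to the
    set of snp_ids in it, or None meaning all SNPs.  Proportions within a
    category sum to 1 over the six labels (0 rows for empty categories,
    with a warning).
    """
    rows = []
    for cat, ids in categories.items():
        sub = annotations if ids is None else annotations[annotations["snp_id"].isin(ids)]
        n = len(sub)
        if n == 0:
            logger.warning("composition_table: category %r is empty", cat)
        counts = sub["region"].value_counts()
        for lab in REGION_LABELS:
            c = int(counts.get(lab, 0))
            rows.append(
                {
                    "category": cat,
                    "region": lab,
                    "count": c,
                    "proportion": c / n if n else 0.0,
                }
            )
    return pd.DataFrame(rows)


def region_nucleotide_composition(
    models: Iterable[GeneModel],
    chrom_lengths: Mapping[str, int],
    promoter_bp: int = DEFAULT_PROMOTER_BP,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> pd.DataFrame:
    """Base-pair share of each region label across the genome.

    Each base is counted once under the same precedence rule used for
    SNPs, giving the nucleotide-composition background that SNP region
    shares are compared against.
    """
    rank = {lab: i for i, lab in enumerate(precedence)}
    merged = merge_gene_intervals(models, promoter_bp, chrom_lengths)
    per_chrom: dict[str, IntervalTree] = {}
    for (gene, chrom), labd in merged.items():
        tree = per_chrom.setdefault(chrom, IntervalTree())
        for lab, lst in labd.items():
            for s, e in lst:
                tree.addi(s, e + 1, lab)
    total = sum(chrom_lengths.values())
    counts = dict.fromkeys(REGION_LABELS, 0)
    for chrom, length in chrom_lengths.items():
        tree = per_chrom.get(chrom)
        if tree is None:
            counts["intergenic"] += length
            continue
        tree.split_overlaps()
        # after split_overlaps the tree's intervals partition the covered
        # bases; resolve each atomic interval to its best label
        best: dict[tuple[int, int], str] = {}
        for iv in tree:
            key = (iv.begin, iv.end)
            lab = iv.data
            if key not in best or rank[lab] < rank[best[key]]:
                best[key] = lab
        covered = 0
        for (b, e), lab in best.items():
            b2, e2 = max(1, b), min(length + 1, e)
            if e2 > b2:
                counts[lab] += e2 - b2
                covered += e2 - b2
        counts["intergenic"] += length - covered
    return pd.DataFrame(
        {
            "region": list(REGION_LABELS),
            "bp": [counts[lab] for lab in REGION_LABELS],
            "share": [counts[lab] / total for lab in REGION_LABELS],
        }
    )
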
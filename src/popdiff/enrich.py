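"""Fisher 2x2 odds-ratio tests and hypergeometric gene-set enrichment.

Two engines:

* ``fisher_2x2`` - two-sided Fisher's exact test for region-composition
  contrasts (e.g. pdSNPs vs all SNPs in the 3'UTR), with the sample
  (cross-product) odds ratio, Haldane-Anscombe corrected when a cell is
  zero.  The two-sided p sums every table of the hypergeometric support
  whose point probability does not exceed the observed one (the
  minimum-likelihood definition).  Small tables are evaluated by exact
  integer enumeration; large ones fall back to scipy.

* ``hypergeom_enrich`` - upper-tail hypergeometric over-representation
  of a query gene list in each gene set, Benjamini-Hochberg adjusted
  across sets, with per-chromosome comparison mirroring clusterProfiler
  style compareCluster output (adjustment within each chromosome).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05
_EXACT_TOTAL_MAX = 300  # above this, scipy's implementation is used


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows = category 1 vs 2, cols = in-region vs not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")


def fisher_2x2(table: ContingencyTable2x2 | tuple[int, int, int, int]) -> tuple[float, float]:
    """Two-sided Fisher exact test; returns (odds_ratio, p).

    The odds ratio is the cross-product (a*d)/(b*c); when any cell is 0
    the Haldane-Anscombe +0.5 correction is applied to all four cells.
    A zero row or column margin leaves the test undefined.
    """
    if isinstance(table, tuple):
        table = ContingencyTable2x2(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("all margins must be positive for a defined test")
    if min(a, b, c, d) == 0:
        orat = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orat = a * d / (b * c)
    total = a + b + c + d
    if total <= _EXACT_TOTAL_MAX:
        p = _fisher_p_exact(a, b, c, d)
    else:
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(orat), float(p)


def _fisher_p_exact(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided p by integer enumeration of the support.

    With margins fixed, P(k) = C(r1,k) C(r2,c1-k) / C(t,c1); all point
    probabilities share the denominator, so 'P(k) <= P(a)' is an exact
    integer comparison free of floating-point tie ambiguity.
    """
    r1, r2, c1 = a + b, c + d, a + c
    t = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    n_obs = comb(r1, a) * comb(r2, c1 - a)
    total_num = sum(
        n_k for k in range(lo, hi + 1)
        if (n_k := comb(r1, k) * comb(r2, c1 - k)) <= n_obs
    )
    return float(Fraction(total_num, comb(t, c1)))


def region_or_battery(
    composition: pd.DataFrame,
    contrasts: Sequence[tuple[str, str]],
    regions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fisher tests of region membership between SNP-category pairs.

    ``composition`` is the long table from
    :func:`popdiff.regions.composition_table` (category, region, count).
    For contrast (cat1, cat2) and each region, the 2x2 is in-region /
    out-of-region counts for the two categories.  BH adjustment is
    applied across regions within each contrast.  Empty categories are
    skipped with a warning.
    """
    rows = []
    for cat1, cat2 in contrasts:
        sub1 = composition[composition["category"] == cat1].set_index("region")["count"]
        sub2 = composition[composition["category"] == cat2].set_index("region")["count"]
        n1, n2 = int(sub1.sum()), int(sub2.sum())
        if n1 == 0 or n2 == 0:
            logger.warning("contrast (%s, %s) skipped: empty category", cat1, cat2)
            continue
        use_regions = regions if regions is not None else list(sub1.index)
        batch = []
        for reg in use_regions:
            a = int(sub1.get(reg, 0))
            c = int(sub2.get(reg, 0))
            if a + c == 0 or (n1 - a) + (n2 - c) == 0:
                # no SNP of either category in (or outside) the region:
                # the 2x2 has a zero margin and the test is undefined
                logger.warning("region %s skipped in contrast (%s, %s): zero margin",
                               reg, cat1, cat2)
                continue
            orat, p = fisher_2x2((a, n1 - a, c, n2 - c))
            batch.append({"contrast": f"{cat1}_vs_{cat2}", "region": reg,
                          "odds_ratio": orat, "p_raw": p,
                          "count_1": a, "count_2": c})
        padj = bh_adjust([r["p_raw"] for r in batch])
        for r, q in zip(batch, padj):
            r["p_adjusted"] = q
        rows.extend(batch)
    return pd.DataFrame(rows)


def scaled_background_counts(share: Mapping[str, float], n_total: int) -> dict[str, int]:
    """Turn genomic nucleotide shares into pseudo-counts at a SNP total.

    Used for the 'all SNPs vs genome composition' contrast, where the
    background row is the region base-pair share scaled to the observed
    SNP count (largest-remainder rounding so counts sum to n_total).
    """
    labels = list(share)
    raw = np.array([share[lab] for lab in labels], dtype=float) * n_total
    base = np.floor(raw).astype(int)
    rem = n_total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return dict(zip(labels, base.tolist()))


def hypergeom_enrich(
    query: set[str],
    gene_sets: Mapping[str, set[str]],
    universe: set[str],
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set.

    p = P(X >= overlap) drawing |query| genes without replacement from a
    universe of size |universe| containing |set ∩ universe| set members;
    BH adjustment across sets; ``significant`` flags p_adjusted < alpha.
    Query genes outside the universe are ignored.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query) & set(universe)
    M, n = len(universe), len(query)
    rows = []
    for term, members in gene_sets.items():
        members = set(members) & set(universe)
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append({"term": term, "overlap": k, "term_size": K,
                     "query_size": n,
                     "gene_ratio": k / n if n else 0.0,
                     "fold": (k / n) / (K / M) if n and K else np.nan,
                     "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bh_adjust(df["p_raw"].tolist()) if len(df) else []
    df["significant"] = df["p_adjusted"] < alpha
    return df


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def compare_by_chromosome(
    queries_by_chrom: Mapping[str, set[str]],
    gene_sets: Mapping[str, set[str]],
    universe: set[str],
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Per-chromosome enrichment grid (term x chromosome, long format).

    Each chromosome's gene query (e.g. its enriched pdGenes) is tested
    against every gene set; BH adjustment is within chromosome, matching
    per-cluster adjustment in compareCluster-style comparisons.
    Chromosomes with empty queries yield no rows.
    """
    frames = []
    for chrom in sorted(queries_by_chrom):
        q = set(queries_by_chrom[chrom]) & set(universe)
        if not q:
            continue
        df = hypergeom_enrich(q, gene_sets, universe, alpha)
        df.insert(0, "chromosome", chrom)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["chromosome", "term", "overlap", "term_size",
                                     "query_size", "gene_ratio", "fold",
                                     "p_raw", "p_adjusted", "significant"])
    return pd.concat(frames, ignore_index=True)
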
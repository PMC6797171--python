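"""Pairwise F_ST scan, top-percentile pdSNP calling, and population trees.

F_ST measures allele-frequency differentiation between two populations
(0 = identical frequencies, 1 = fixed for different alleles).  The
primary estimator is the two-deme Weir-Cockerham variance-components
theta-hat = a / (a + b + c), computed per SNP from sample sizes, sample
allele frequencies and observed heterozygosity; the Hudson estimator is
provided as an independent closed-form cross-check.

Within each population pair, SNPs whose score falls in the top 1% of
that pair's genome-wide distribution are "population-differentiated"
(pdSNPs); the global pdSNP set is the union over pairs.  The matrix of
mean pdSNP F_ST per pair summarises between-population divergence and is
clustered into a population tree (UPGMA by default, NJ optionally).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AlleleCounts

__all__ = [
    "wc_fst", "hudson_fst", "pairwise_fst", "call_pdsnps", "pd_union",
    "PairSummary", "pair_summaries", "mean_pd_fst_matrix",
    "build_population_tree", "population_pairs",
]


def population_pairs(pops: Sequence[str]) -> list[tuple[str, str]]:
    """All C(K, 2) unordered population pairs, lexicographically ordered."""
    return list(itertools.combinations(sorted(pops), 2))


def wc_fst(n1, p1, h1, n2, p2, h2, clamp: bool = False):
    """Two-deme Weir-Cockerham theta-hat per site (vectorised).

    Parameters
    ----------
    n1, n2
        Diploid sample sizes (non-missing individuals) per site.
    p1, p2
        Sample alt-allele frequencies.
    h1, h2
        Observed heterozygote *proportions* (het count / diploids).
    clamp
        Clamp negative estimates to 0 (off by default: negative values
        are kept so percentile ranking is not distorted by mass ties).

    Returns theta = a / (a + b + c); NaN where the denominator is 0
    (pooled-monomorphic sites, which the monomorphic filter removes
    upstream).
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)

    r = 2.0
    nbar = (n1 + n2) / r
    # n_c corrects for unequal sample sizes
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    if clamp:
        theta = np.maximum(theta, 0.0)
    return theta


def hudson_fst(pA, pB, nA, nB):
    """Hudson's F_ST estimator from sample frequencies and allele counts.

    numerator  = (pA - pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1)
    denominator = pA(1-pB) + pB(1-pA)

    ``nA``/``nB`` are *allele* counts (2 x diploids).  NaN where the
    denominator is 0 (both populations fixed for the same allele).
    """
    pA = np.asarray(pA, dtype=float)
    pB = np.asarray(pB, dtype=float)
    nA = np.asarray(nA, dtype=float)
    nB = np.asarray(nB, dtype=float)
    num = (pA - pB) ** 2 - pA * (1 - pA) / (nA - 1) - pB * (1 - pB) / (nB - 1)
    den = pA * (1 - pB) + pB * (1 - pA)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)


def pairwise_fst(
    counts: AlleleCounts, estimator: str = "wc"
) -> dict[tuple[str, str], np.ndarray]:
    """Per-SNP F_ST for every unordered population pair.

    Sites uncallable in either population of a pair are NaN for that
    pair.  Returns a dict (popA, popB) -> score array over all sites.
    """
    if len(counts.pops) < 2:
        raise ValueError("need at least two populations")
    freqs = counts.freqs()
    ndip = counts.n_called / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        hets = np.where(ndip > 0, counts.het / np.maximum(ndip, 1e-300), np.nan)
    out = {}
    for a, b in population_pairs(counts.pops):
        i, j = counts.pop_index(a), counts.pop_index(b)
        if estimator == "wc":
            score = wc_fst(ndip[:, i], freqs[:, i], hets[:, i],
                           ndip[:, j], freqs[:, j], hets[:, j])
        elif estimator == "hudson":
            score = hudson_fst(freqs[:, i], freqs[:, j],
                               counts.n_called[:, i], counts.n_called[:, j])
        else:
            raise ValueError("estimator must be 'wc' or 'hudson'")
        bad = (counts.n_called[:, i] == 0) | (counts.n_called[:, j] == 0)
        score = np.where(bad, np.nan, score)
        out[(a, b)] = score
    return out


def multilocus_fst(counts: AlleleCounts, popA: str, popB: str) -> float:
    """Ratio-of-sums Weir-Cockerham estimate over all callable sites.

    The standard multi-locus combination: sum the a components over loci
    and divide by the summed a + b + c (more stable than averaging
    per-locus ratios).
    """
    i, j = counts.pop_index(popA), counts.pop_index(popB)
    freqs = counts.freqs()
    ndip = counts.n_called / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        hets = np.where(ndip > 0, counts.het / np.maximum(ndip, 1e-300), np.nan)
    a, b, c = _wc_components(ndip[:, i], freqs[:, i], hets[:, i],
                             ndip[:, j], freqs[:, j], hets[:, j])
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return float(a[ok].sum() / (a[ok] + b[ok] + c[ok]).sum())


def _wc_components(n1, p1, h1, n2, p2, h2):
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    return a, b, c


def call_pdsnps(scores: np.ndarray, q: float = 0.01) -> tuple[float, np.ndarray]:
    """Select the top fraction ``q`` of finite scores (the pdSNP rule).

    Takes the ceil(q * n) highest scores; every score tied with the cut
    value is included, so the selection is permutation-invariant.

    Returns (threshold, boolean mask over the input array).
    """
    scores = np.asarray(scores, dtype=float)
    finite = np.isfinite(scores)
    n = int(finite.sum())
    if n == 0:
        raise ValueError("no finite scores to rank")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    k = math.ceil(q * n)
    vals = scores[finite]
    threshold = float(np.partition(vals, n - k)[n - k])
    mask = finite & (scores >= threshold)
    return threshold, mask


def pd_union(pd_sets: Mapping[tuple[str, str], set[str]]) -> pd.Series:
    """Union of per-pair pdSNP sets with per-SNP supporting-pair counts."""
    if not pd_sets:
        raise ValueError("need at least one pair")
    counter: dict[str, int] = {}
    for ids in pd_sets.values():
        for snp in ids:
            counter[snp] = counter.get(snp, 0) + 1
    return pd.Series(counter, dtype=int).sort_index()


@dataclass
class PairSummary:
    pair: tuple[str, str]
    n_scored: int
    threshold: float
    n_pd: int
    mean_pd_fst: float


def pair_summaries(
    scores: Mapping[tuple[str, str], np.ndarray],
    snp_ids: Sequence[str],
    q: float = 0.01,
) -> tuple[list[PairSummary], dict[tuple[str, str], set[str]]]:
    """Apply the top-q rule to every pair; return summaries and pd sets."""
    snp_ids = np.asarray(snp_ids)
    summaries = []
    pd_sets = {}
    for pair, sc in scores.items():
        threshold, mask = call_pdsnps(sc, q)
        sel = sc[mask]
        summaries.append(PairSummary(
            pair=pair, n_scored=int(np.isfinite(sc).sum()),
            threshold=threshold, n_pd=int(mask.sum()),
            mean_pd_fst=float(sel.mean()),
        ))
        pd_sets[pair] = set(snp_ids[mask])
    return summaries, pd_sets


def mean_pd_fst_matrix(summaries: Sequence[PairSummary]) -> pd.DataFrame:
    """Symmetric zero-diagonal matrix of mean pdSNP F_ST per pair.

    Entry (A, B) is the mean score over pair (A, B)'s own top-1% set.
    All C(K, 2) pairs must be present.
    """
    pops = sorted({p for s in summaries for p in s.pair})
    expected = set(population_pairs(pops))
    seen = {tuple(sorted(s.pair)) for s in summaries}
    missing = expected - seen
    if missing:
        raise ValueError(f"missing pairs: {sorted(missing)}")
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for s in summaries:
        a, b = s.pair
        mat.loc[a, b] = mat.loc[b, a] = s.mean_pd_fst
    return mat


# ---------------------------------------------------------------------------
# population tree


def _upgma_newick(dist: pd.DataFrame) -> str:
    """Average-linkage agglomeration with lexicographic tie-breaking.

    Heights are ultrametric (half the cluster-average distance); among
    equally close cluster pairs the lexicographically smallest pair of
    cluster labels (smallest member id) merges first.
    """
    labels = list(dist.index)
    # cluster id -> (newick string, size, height, sort key)
    clusters = {lab: (lab, 1, 0.0, lab) for lab in labels}
    d = {frozenset((a, b)): float(dist.loc[a, b])
         for a, b in itertools.combinations(labels, 2)}
    while len(clusters) > 1:
        best = min(
            d.items(),
            key=lambda kv: (kv[1], tuple(sorted(clusters[c][3] for c in kv[0]))),
        )
        (pair, dmin) = best
        a, b = sorted(pair, key=lambda c: clusters[c][3])
        na, nb = clusters[a][1], clusters[b][1]
        h = dmin / 2.0
        nwk = (f"({clusters[a][0]}:{h - clusters[a][2]:.10g},"
               f"{clusters[b][0]}:{h - clusters[b][2]:.10g})")
        new_id = f"({a}+{b})"
        key = min(clusters[a][3], clusters[b][3])
        for c in list(clusters):
            if c in (a, b):
                continue
            dac = d.pop(frozenset((a, c)))
            dbc = d.pop(frozenset((b, c)))
            d[frozenset((new_id, c))] = (na * dac + nb * dbc) / (na + nb)
        d.pop(pair)
        del clusters[a], clusters[b]
        clusters[new_id] = (nwk, na + nb, h, key)
    (nwk, _, _, _) = next(iter(clusters.values()))
    return nwk + ";"


def build_population_tree(dist: pd.DataFrame, method: str = "upgma") -> str:
    """Cluster a population distance matrix into a newick tree.

    'upgma' (default) gives a rooted ultrametric dendrogram; 'nj'
    (neighbour joining, via scikit-bio) an unrooted additive tree.
    """
    mat = dist.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(mat) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if method == "upgma":
        return _upgma_newick(dist)
    if method == "nj":
        from skbio import DistanceMatrix
        from skbio.tree import nj

        tree = nj(DistanceMatrix(mat, ids=list(dist.index)))
        return str(tree).strip()
    raise ValueError("method must be 'upgma' or 'nj'")


def tree_splits(newick: str) -> set[frozenset[str]]:
    """Non-trivial leaf bipartition halves of a newick tree (clades)."""
    import io as _io

    from Bio import Phylo

    tree = Phylo.read(_io.StringIO(newick), "newick")
    leaves = {t.name for t in tree.get_terminals()}
    out = set()
    for clade in tree.get_nonterminals():
        names = frozenset(t.name for t in clade.get_terminals())
        if 1 < len(names) < len(leaves):
            out.add(names)
    return out
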
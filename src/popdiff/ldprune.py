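"""Windowed r^2 pruning of SNP sets.

Linkage disequilibrium is measured as the squared Pearson correlation of
unphased diploid dosages over jointly non-missing samples.  Pruning is a
greedy left-to-right sweep per chromosome with the contract that no two
retained SNPs within the window exceed the r^2 ceiling - the property
the pruned set is audited against (default window 1 Mb, ceiling 0.8).
"""

from __future__ import annotations

import numpy as np

from .io import MISSING, GenotypeMatrix

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_R2_MAX = 0.8


def pairwise_r2(dos_i: np.ndarray, dos_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over samples where both calls are non-missing.  Zero
    variance in either vector makes r^2 undefined; it is returned as 0.0
    (such a SNP cannot constrain pruning).
    """
    dos_i = np.asarray(dos_i, dtype=float)
    dos_j = np.asarray(dos_j, dtype=float)
    ok = (dos_i != MISSING) & (dos_j != MISSING)
    if ok.sum() < 2:
        return 0.0
    x, y = dos_i[ok], dos_j[ok]
    xm, ym = x - x.mean(), y - y.mean()
    vx, vy = (xm**2).sum(), (ym**2).sum()
    if vx == 0 or vy == 0:
        return 0.0
    cov = (xm * ym).sum()
    return float(cov * cov / (vx * vy))


def prune(
    gm: GenotypeMatrix,
    snp_ids=None,
    window_bp: int = DEFAULT_WINDOW_BP,
    r2_max: float = DEFAULT_R2_MAX,
    victim: str = "first",
    mafs: dict[str, float] | None = None,
) -> list[str]:
    """Greedy LD pruning; returns retained snp_ids in position order.

    A candidate SNP is compared against every already-retained SNP on
    the same chromosome within ``window_bp``.  ``victim='first'`` keeps
    the earlier SNP on conflict; ``victim='lower-maf'`` discards the
    lower-MAF member of each conflicting pair (requires ``mafs``).
    Either strategy guarantees that no retained pair within the window
    has r^2 > r2_max.
    """
    if victim not in ("first", "lower-maf"):
        raise ValueError("victim must be 'first' or 'lower-maf'")
    if victim == "lower-maf" and mafs is None:
        mafs = _sample_mafs(gm)
    sites = gm.sites
    subset = None if snp_ids is None else set(snp_ids)
    kept: list[str] = []
    # per chromosome: indices of kept sites, in position order
    kept_idx_by_chrom: dict[str, list[int]] = {}
    for i in range(gm.n_sites):
        sid = sites["snp_id"].iat[i]
        if subset is not None and sid not in subset:
            continue
        chrom = sites["chrom"].iat[i]
        pos = int(sites["pos"].iat[i])
        kept_idx = kept_idx_by_chrom.setdefault(chrom, [])
        conflicts = []
        for j in reversed(kept_idx):
            if pos - int(sites["pos"].iat[j]) > window_bp:
                break
            if pairwise_r2(gm.dosages[i], gm.dosages[j]) > r2_max:
                conflicts.append(j)
        if not conflicts:
            kept_idx.append(i)
            continue
        if victim == "first":
            continue
        cand_maf = mafs[sid]
        if all(cand_maf > mafs[sites["snp_id"].iat[j]] for j in conflicts):
            for j in conflicts:
                kept_idx.remove(j)
            kept_idx.append(i)
            kept_idx.sort()
    for chrom in kept_idx_by_chrom:
        kept.extend(sites["snp_id"].iat[j] for j in kept_idx_by_chrom[chrom])
    order = {sid: k for k, sid in enumerate(sites["snp_id"])}
    kept.sort(key=order.__getitem__)
    return kept


def audit_max_r2(
    gm: GenotypeMatrix, retained_ids, window_bp: int = DEFAULT_WINDOW_BP
) -> float:
    """Exhaustive post-pruning check: max r^2 over retained within-window pairs.

    Mirrors the verification that a pruned dataset contains no high-LD
    pair; returns 0.0 when no within-window pair exists.
    """
    retained = set(retained_ids)
    sites = gm.sites
    idx = [i for i in range(gm.n_sites) if sites["snp_id"].iat[i] in retained]
    best = 0.0
    for a in range(len(idx)):
        i = idx[a]
        for b in range(a + 1, len(idx)):
            j = idx[b]
            if sites["chrom"].iat[j] != sites["chrom"].iat[i]:
                break
            if int(sites["pos"].iat[j]) - int(sites["pos"].iat[i]) > window_bp:
                break
            best = max(best, pairwise_r2(gm.dosages[i], gm.dosages[j]))
    return best


def _sample_mafs(gm: GenotypeMatrix) -> dict[str, float]:
    out = {}
    for i, sid in enumerate(gm.sites["snp_id"]):
        d = gm.dosages[i]
        ok = d != MISSING
        if not ok.any():
            out[sid] = 0.0
            continue
        p = d[ok].sum() / (2 * ok.sum())
        out[sid] = float(min(p, 1 - p))
    return out
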
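"""Synthetic multi-population genotype, gene-model and gene-set generator.

Population allele frequencies follow the Balding-Nichols model: given an
ancestral frequency p and a divergence parameter F in [0, 1), each
population's frequency is drawn from Beta(p(1-F)/F, (1-p)(1-F)/F), whose
mean is p and whose expected F_ST equals F.  Diploid genotypes are drawn
under Hardy-Weinberg equilibrium from the population frequency.

Linkage disequilibrium is simulated blockwise: SNPs inside a block share
one underlying frequency draw and haplotypes are copied from a per-block
anchor haplotype with high probability, so adjacent within-block r^2 is
high while between-block pairs are independent.  This is deliberately
simpler than coalescent machinery - it is sufficient to exercise
windowed r^2 pruning.

A hierarchical ``tree_spec`` lets frequencies drift along nested
population splits (e.g. two continental groups), giving distance
matrices with known group structure for tree-recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .io import GenotypeMatrix
from .regions import GeneModel

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``tree_spec`` optionally replaces the flat ``fst_target`` divergence:
    a nested dict where a leaf is ``{"pop": name, "fst": F_branch}`` and
    an internal node is ``{"children": [...], "fst": F_branch}``; each
    branch applies one Balding-Nichols drift step with its own F.
    """

    n_pops: int = 2
    samples_per_pop: int = 50
    n_snps: int = 1000
    chrom_lengths: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 10_000_000), ("chr2", 8_000_000)]
    )
    anc_freq_range: tuple[float, float] = (0.05, 0.95)
    fst_target: float = 0.1
    ld_block_size: int = 1
    ld_copy_prob: float = 0.95
    tree_spec: dict | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fst_target < 1:
            raise ValueError("fst_target must be in [0, 1)")
        if self.samples_per_pop < 2:
            raise ValueError("samples_per_pop must be >= 2")
        lo, hi = self.anc_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("anc_freq_range must be within (0, 1)")
        if any(length <= 0 for _, length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")


@dataclass
class GroundTruth:
    """Planted truth of a simulation (one record per SNP)."""

    snp_ids: list[str]
    anc_freq: np.ndarray            # (n_snps,)
    pop_freqs: np.ndarray           # (n_snps, n_pops)
    pops: list[str]
    pf_flags: np.ndarray | None = None      # bool per SNP
    planted_sets: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"snp_id": self.snp_ids, "anc_freq": self.anc_freq})
        for k, pop in enumerate(self.pops):
            df[f"freq_{pop}"] = self.pop_freqs[:, k]
        if self.pf_flags is not None:
            df["pf"] = self.pf_flags.astype(int)
        return df


def draw_balding_nichols_freqs(p_anc: float, F: float, n_pops: int, rng) -> np.ndarray:
    """Per-population frequencies around ``p_anc`` at divergence ``F``.

    Beta(p(1-F)/F, (1-p)(1-F)/F) draws for F > 0; F = 0 returns the
    ancestral frequency for every population (degenerate, no draw).
    """
    if not 0 < p_anc < 1:
        raise ValueError("p_anc must be in (0, 1)")
    if not 0 <= F < 1:
        raise ValueError("F must be in [0, 1)")
    if F == 0:
        return np.full(n_pops, p_anc)
    shape = (1.0 - F) / F
    return rng.beta(p_anc * shape, (1.0 - p_anc) * shape, size=n_pops)


def _bn_vector(p_anc: np.ndarray, F: float, rng) -> np.ndarray:
    """Vectorised one-step Balding-Nichols drift for an array of frequencies."""
    if F == 0:
        return p_anc.copy()
    shape = (1.0 - F) / F
    # clip away exact 0/1 that earlier drift steps may have produced
    p = np.clip(p_anc, 1e-9, 1 - 1e-9)
    return rng.beta(p * shape, (1.0 - p) * shape)


def _tree_leaves(node: dict) -> list[str]:
    if "pop" in node:
        return [node["pop"]]
    out: list[str] = []
    for child in node["children"]:
        out.extend(_tree_leaves(child))
    return out


def _drift_tree(node: dict, p_parent: np.ndarray, rng, out: dict[str, np.ndarray]) -> None:
    p_here = _bn_vector(p_parent, float(node.get("fst", 0.0)), rng)
    if "pop" in node:
        out[node["pop"]] = p_here
    else:
        for child in node["children"]:
            _drift_tree(child, p_here, rng, out)


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, dict[str, str], GroundTruth]:
    """Draw a genotype matrix, a sample->population panel and its truth.

    Positions are uniform (distinct, sorted) over the configured
    chromosomes, SNP counts allocated proportionally to length.  With
    ``ld_block_size > 1`` consecutive SNPs on one chromosome form
    correlated blocks; blocks never span chromosomes.
    """
    rng = np.random.default_rng(config.seed)
    if config.tree_spec is not None:
        pops = _tree_leaves(config.tree_spec)
    else:
        pops = [f"POP{k + 1}" for k in range(config.n_pops)]
    n_pops = len(pops)
    samples = [f"{pop}_S{i + 1}" for pop in pops for i in range(config.samples_per_pop)]
    panel = {s: s.rsplit("_S", 1)[0] for s in samples}

    # --- site placement ---------------------------------------------------
    lengths = np.array([ln for _, ln in config.chrom_lengths], dtype=float)
    n_per_chrom = _allocate(config.n_snps, lengths / lengths.sum())
    chroms, positions, block_ids = [], [], []
    next_block = 0
    for (chrom, length), n_c in zip(config.chrom_lengths, n_per_chrom):
        n_c = min(n_c, length)  # positions must be distinct
        pos = np.sort(rng.choice(length, size=n_c, replace=False) + 1)
        chroms.extend([chrom] * n_c)
        positions.extend(pos.tolist())
        blocks = next_block + np.arange(n_c) // config.ld_block_size
        block_ids.extend(blocks.tolist())
        next_block = blocks[-1] + 1 if n_c else next_block
    n_snps = len(positions)
    block_ids = np.asarray(block_ids, dtype=int)
    n_blocks = int(block_ids.max()) + 1 if n_snps else 0

    # --- frequencies (one ancestral draw per LD block) ---------------------
    lo, hi = config.anc_freq_range
    block_anc = rng.uniform(lo, hi, size=n_blocks)
    if config.tree_spec is not None:
        freq_map: dict[str, np.ndarray] = {}
        _drift_tree(config.tree_spec, block_anc, rng, freq_map)
        block_freqs = np.column_stack([freq_map[p] for p in pops])
    else:
        F = config.fst_target
        if F == 0:
            block_freqs = np.tile(block_anc[:, None], (1, n_pops))
        else:
            block_freqs = np.column_stack(
                [_bn_vector(block_anc, F, rng) for _ in range(n_pops)]
            )
    anc = block_anc[block_ids] if n_snps else np.empty(0)
    pop_freqs = block_freqs[block_ids] if n_snps else np.empty((0, n_pops))

    # --- genotypes ---------------------------------------------------------
    dosages = np.empty((n_snps, len(samples)), dtype=np.int8)
    col = 0
    for k in range(n_pops):
        ns = config.samples_per_pop
        p = pop_freqs[:, k]
        if config.ld_block_size == 1:
            dos = rng.binomial(2, p[:, None], size=(n_snps, ns)).astype(np.int8)
        else:
            pb = block_freqs[:, k]
            anchors = (rng.random((n_blocks, ns, 2)) < pb[:, None, None])
            copy = rng.random((n_snps, ns, 2)) < config.ld_copy_prob
            indep = rng.random((n_snps, ns, 2)) < p[:, None, None]
            alleles = np.where(copy, anchors[block_ids], indep)
            dos = alleles.sum(axis=2).astype(np.int8)
        dosages[:, col:col + ns] = dos
        col += ns
    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = pio.MISSING

    snp_ids = [f"snp_{c}_{p}" for c, p in zip(chroms, positions)]
    sites = pd.DataFrame({
        "chrom": chroms, "pos": positions,
        "ref": ["A"] * n_snps, "alt": ["G"] * n_snps, "snp_id": snp_ids,
    })
    gm = GenotypeMatrix(sites, dosages, samples)
    truth = GroundTruth(snp_ids=snp_ids, anc_freq=anc, pop_freqs=pop_freqs, pops=pops)
    return gm, panel, truth


def _allocate(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of ``total`` items over weights."""
    raw = weights * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


# ---------------------------------------------------------------------------
# gene models


def simulate_gene_models(
    chrom_lengths: Sequence[tuple[str, int]],
    n_genes: int,
    rng,
    gene_span: tuple[int, int] = (2_000, 10_000),
    max_exons: int = 5,
) -> list[GeneModel]:
    """Random non-degenerate transcripts on both strands.

    Genes are placed uniformly on chromosomes chosen proportionally to
    length; a chromosome too short to fit a gene is skipped with a
    warning.  Each transcript has 1..max_exons exons; the exonic span is
    partitioned (in transcription order) into 5'UTR / CDS / 3'UTR.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    lengths = np.array([ln for _, ln in chrom_lengths], dtype=float)
    models: list[GeneModel] = []
    for g in range(n_genes):
        span = int(rng.integers(gene_span[0], gene_span[1] + 1))
        ci = int(rng.choice(len(chrom_lengths), p=lengths / lengths.sum()))
        chrom, clen = chrom_lengths[ci]
        if clen < span:
            logger.warning("chromosome %s too short for a %d bp gene; skipped", chrom, span)
            continue
        tx_start = int(rng.integers(1, clen - span + 2))
        tx_end = tx_start + span - 1
        strand = "+" if rng.random() < 0.5 else "-"

        n_exons = int(rng.integers(1, max_exons + 1))
        # 2*n_exons - 1 alternating exon/intron segments, each >= minimum
        n_seg = 2 * n_exons - 1
        min_seg = max(10, span // (4 * n_seg))
        cuts = np.sort(rng.choice(span - n_seg * min_seg + 1, size=n_seg - 1,
                                  replace=True)) if n_seg > 1 else np.empty(0, int)
        seg_lens = np.diff(np.concatenate([[0], cuts, [span - n_seg * min_seg]])) + min_seg
        exons = []
        cursor = tx_start
        for s_i, sl in enumerate(seg_lens):
            seg = (cursor, cursor + int(sl) - 1)
            if s_i % 2 == 0:
                exons.append(seg)
            cursor += int(sl)

        exonic = sum(e - s + 1 for s, e in exons)
        utr5_len = int(rng.integers(1, max(2, exonic // 4)))
        utr3_len = int(rng.integers(1, max(2, exonic // 4)))
        if utr5_len + utr3_len >= exonic:
            utr5_len = utr3_len = max(1, exonic // 4)
        if strand == "+":
            cds_start = _exonic_offset(exons, utr5_len)          # first CDS base
            cds_end = _exonic_offset(exons, exonic - utr3_len - 1)
        else:
            # transcription runs right to left: 5'UTR at high coordinates
            cds_start = _exonic_offset(exons, utr3_len)
            cds_end = _exonic_offset(exons, exonic - utr5_len - 1)
        models.append(GeneModel(
            gene_id=f"gene{g + 1:04d}", chrom=chrom, strand=strand,
            tx_start=tx_start, tx_end=tx_end, exons=exons,
            cds_start=cds_start, cds_end=cds_end,
        ))
    models.sort(key=lambda m: (m.chrom, m.tx_start, m.gene_id))
    return models


def _exonic_offset(exons: list[tuple[int, int]], offset: int) -> int:
    """Genomic coordinate of the ``offset``-th exonic base (left-to-right)."""
    for s, e in exons:
        n = e - s + 1
        if offset < n:
            return s + offset
        offset -= n
    raise ValueError("offset beyond exonic span")


# ---------------------------------------------------------------------------
# pf annotation and gene sets


def simulate_pf_table(snp_ids: Sequence[str], fraction: float, rng,
                      tags: Sequence[str] = ("regulatory", "missense", "splice")) -> pd.DataFrame:
    """Flag a random fraction of SNPs as potentially functional."""
    ids = np.asarray(snp_ids)
    n = int(round(fraction * len(ids)))
    chosen = rng.choice(len(ids), size=n, replace=False)
    tag = rng.choice(len(tags), size=n)
    df = pd.DataFrame({"snp_id": ids[np.sort(chosen)],
                       "tag": [tags[t] for t in tag[np.argsort(chosen)]]})
    return df


def simulate_genesets(
    genes: Sequence[str],
    n_sets: int,
    rng,
    hot_genes: Sequence[str] = (),
    planted_set_fraction: float = 0.0,
    set_size: tuple[int, int] = (10, 40),
) -> tuple[dict[str, set[str]], list[str]]:
    """Random gene sets with one optionally planted enriched set.

    With ``planted_set_fraction`` > 0, the first set draws that fraction
    of its members from ``hot_genes`` (genes the genotype simulation made
    highly differentiated) and the rest uniformly; remaining sets are
    uniform draws from ``genes``.  Returns (sets, planted set names).
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    genes = list(genes)
    sets: dict[str, set[str]] = {}
    planted: list[str] = []
    for i in range(n_sets):
        size = int(rng.integers(set_size[0], min(set_size[1], len(genes)) + 1))
        name = f"SET{i + 1:03d}"
        if i == 0 and planted_set_fraction > 0 and len(hot_genes) > 0:
            n_hot = min(int(round(planted_set_fraction * size)), len(hot_genes))
            hot = rng.choice(len(hot_genes), size=n_hot, replace=False)
            members = {hot_genes[j] for j in hot}
            pool = [g for g in genes if g not in members]
            extra = rng.choice(len(pool), size=size - len(members), replace=False)
            members |= {pool[j] for j in extra}
            planted.append(name)
        else:
            pick = rng.choice(len(genes), size=size, replace=False)
            members = {genes[j] for j in pick}
        sets[name] = members
    return sets, planted


# ---------------------------------------------------------------------------
# one-call dataset writer


def simulate_dataset(
    config: SimulationConfig,
    outdir,
    n_genes: int = 50,
    n_sets: int = 20,
    pf_fraction: float = 0.2,
    planted_set_fraction: float = 0.0,
) -> dict[str, Path]:
    """Generate and write a complete synthetic dataset.

    Writes genotypes.vcf, panel.tsv, genes.gff3, pf.tsv, sets.gmt and
    truth.tsv into ``outdir``; returns the path of each file.  The seed
    is recorded in the VCF header.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm, panel, truth = simulate_genotypes(config)
    rng = np.random.default_rng(config.seed + 1)
    models = simulate_gene_models(config.chrom_lengths, n_genes, rng)
    pf = simulate_pf_table(truth.snp_ids, pf_fraction, rng)
    truth.pf_flags = np.isin(np.asarray(truth.snp_ids), pf["snp_id"].to_numpy())

    # genes whose planted frequencies are most divergent = "hot" genes
    gene_ids = [m.gene_id for m in models]
    hot = _hot_genes(gm, truth, models)
    sets, planted = simulate_genesets(
        gene_ids, n_sets, rng, hot_genes=hot,
        planted_set_fraction=planted_set_fraction,
    )
    truth.planted_sets = planted

    paths = {
        "vcf": outdir / "genotypes.vcf",
        "panel": outdir / "panel.tsv",
        "genes": outdir / "genes.gff3",
        "pf": outdir / "pf.tsv",
        "gmt": outdir / "sets.gmt",
        "truth": outdir / "truth.tsv",
    }
    pio.write_vcf(gm, paths["vcf"], dict(config.chrom_lengths),
                  extra_header=[f"##popdiff_seed={config.seed}"])
    pio.write_panel(panel, paths["panel"])
    pio.write_gene_models_gff3(models, paths["genes"])
    pio.write_pf_table(pf, paths["pf"])
    pio.write_gmt(sets, paths["gmt"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


def _hot_genes(gm: GenotypeMatrix, truth: GroundTruth, models: list[GeneModel],
               top_fraction: float = 0.3) -> list[str]:
    """Genes ranked by the planted frequency spread of SNPs in their span."""
    spread = truth.pop_freqs.max(axis=1) - truth.pop_freqs.min(axis=1)
    sites = gm.sites
    scores: dict[str, float] = {}
    for m in models:
        in_span = ((sites["chrom"] == m.chrom) & (sites["pos"] >= m.tx_start)
                   & (sites["pos"] <= m.tx_end)).to_numpy()
        scores[m.gene_id] = float(spread[in_span].max()) if in_span.any() else 0.0
    ranked = sorted(scores, key=lambda g: -scores[g])
    k = max(1, int(round(top_fraction * len(ranked))))
    return ranked[:k]
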
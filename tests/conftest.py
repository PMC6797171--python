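import numpy as np
import pandas as pd
import pytest

from popdiff import chromarch, fst, io as pio, simulate


def make_gm(chroms, positions, dosages, samples=None):
    """Build a small GenotypeMatrix from plain lists."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = dosages.shape
    if samples is None:
        samples = [f"S{i+1}" for i in range(n_samples)]
    sites = pd.DataFrame({
        "chrom": chroms,
        "pos": positions,
        "ref": ["A"] * n_sites,
        "alt": ["G"] * n_sites,
        "snp_id": [f"s{i+1}" for i in range(n_sites)],
    })
    return pio.GenotypeMatrix(sites, dosages, samples)


@pytest.fixture
def gm_factory():
    return make_gm


def two_pop_scan(F, seed, n_snps=20_000, samples_per_pop=50):
    """Simulate 2 populations at Balding-Nichols F; return counts after the
    pooled monomorphic filter."""
    cfg = simulate.SimulationConfig(
        n_pops=2, samples_per_pop=samples_per_pop, n_snps=n_snps,
        fst_target=F, seed=seed)
    gm, panel, truth = simulate.simulate_genotypes(cfg)
    counts = pio.allele_counts(gm, panel)
    gm = gm.subset_sites(pio.filter_monomorphic(counts))
    return gm, panel, pio.allele_counts(gm, panel), truth


@pytest.fixture
def two_pop_scan_factory():
    return two_pop_scan


def two_group_tree_spec(f_within=0.02, f_between=0.2):
    """Two continental groups of two populations each."""
    return {"children": [
        {"fst": f_between, "children": [
            {"fst": f_within, "pop": "A1"}, {"fst": f_within, "pop": "A2"}]},
        {"fst": f_between, "children": [
            {"fst": f_within, "pop": "B1"}, {"fst": f_within, "pop": "B2"}]},
    ]}


def arch_dataset(seed, planted=True, n_snps_per_chrom=1500, samples_per_pop=40):
    """Multi-chromosome two-population dataset for architecture regressions.

    ``planted=True`` scales divergence inversely with chromosome length
    (F = 0.05 + 0.012 * (10 - L_Mb)); the null uses one F everywhere.
    Returns (chromosome stats DataFrame, chrom_lengths dict).
    """
    lengths_mb = [10, 9, 8, 7, 6, 5, 4, 3]
    chrom_lengths = [(f"chr{i+1:02d}", L * 1_000_000) for i, L in enumerate(lengths_mb)]
    Fs = [0.05 + 0.012 * (10 - L) if planted else 0.08 for L in lengths_mb]
    frames, dos = [], []
    for k, ((chrom, L), F) in enumerate(zip(chrom_lengths, Fs)):
        cfg = simulate.SimulationConfig(
            n_pops=2, samples_per_pop=samples_per_pop, n_snps=n_snps_per_chrom,
            chrom_lengths=[(chrom, L)], fst_target=F, seed=seed * 1009 + k)
        gm, panel, _ = simulate.simulate_genotypes(cfg)
        frames.append(gm.sites)
        dos.append(gm.dosages)
        samples = gm.samples
    gm = pio.GenotypeMatrix(pd.concat(frames, ignore_index=True),
                            np.vstack(dos), samples)
    counts = pio.allele_counts(gm, panel)
    gm = gm.subset_sites(pio.filter_monomorphic(counts))
    counts = pio.allele_counts(gm, panel)
    scores = fst.pairwise_fst(counts)
    summaries, pd_sets = fst.pair_summaries(scores, gm.sites["snp_id"])
    pd_ids = set(fst.pd_union(pd_sets).index)
    ann = pd.DataFrame({"snp_id": gm.sites["snp_id"],
                        "region": "intergenic", "gene_id": None})
    empty_tally = pd.DataFrame(columns=["gene_id", "pd_gene", "pf_pd_gene"])
    stats = chromarch.per_chromosome_stats(
        gm.sites, ann, pd_ids, set(), empty_tally, {}, dict(chrom_lengths))
    return stats, dict(chrom_lengths)


@pytest.fixture
def arch_dataset_factory():
    return arch_dataset
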
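"""Chromosome-level architecture statistics and pipeline orchestration.

Within each chromosome the proportions of population-differentiated
SNPs/genes are formed over that chromosome's own totals (pdSNPs on the
chromosome / all SNPs on the chromosome, and likewise for genes), and
the six standard regressions are fitted against chromosome length and
gene count: proportion of pd / pf-pd SNPs vs length, pd / pf-pd genes
vs length, and pd / pf-pd genes vs gene count.

``run_all`` chains the whole pipeline (simulate -> read -> F_ST scan ->
region annotation -> optional LD pruning -> enrichment -> architecture)
into one run directory with a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import enrich as en
from . import fst as fstmod
from . import io as pio
from . import ldprune as lp
from . import regions as rg
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Ordinary least squares y ~ x with the slope's t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    if np.ptp(y) == 0:  # constant response: zero slope, define R^2 = 0
        return RegressionFit(slope=0.0, intercept=float(y[0]),
                             r_squared=0.0, p_value=1.0, n=len(x))
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=len(x),
    )


def per_chromosome_stats(
    sites: pd.DataFrame,
    annotations: pd.DataFrame,
    pd_ids: set[str],
    pf_ids: set[str],
    tallies: pd.DataFrame,
    gene_chrom: Mapping[str, str],
    chrom_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Per-chromosome counts and within-chromosome proportions.

    Proportions are ratios over the chromosome's own totals; a
    chromosome with zero SNPs (or zero genes) reports NaN for the
    corresponding proportions.
    """
    pf_pd = pd_ids & pf_ids
    snp_chrom = dict(zip(sites["snp_id"], sites["chrom"]))
    rows = []
    tally_idx = tallies.set_index("gene_id") if len(tallies) else pd.DataFrame()
    for chrom, length in chrom_lengths.items():
        on = sites["chrom"] == chrom
        ids_here = set(sites.loc[on, "snp_id"])
        n_snps = len(ids_here)
        n_pd = len(ids_here & pd_ids)
        n_pfpd = len(ids_here & pf_pd)
        genes_here = [g for g, c in gene_chrom.items() if c == chrom]
        n_genes = len(genes_here)
        n_pd_genes = n_pfpd_genes = 0
        for g in genes_here:
            if g in tally_idx.index:
                row = tally_idx.loc[g]
                n_pd_genes += bool(row["pd_gene"])
                n_pfpd_genes += bool(row["pf_pd_gene"])
        rows.append({
            "chrom": chrom, "length_bp": length,
            "n_snps": n_snps, "n_pd": n_pd, "n_pfpd": n_pfpd,
            "n_genes": n_genes, "n_pd_genes": n_pd_genes,
            "n_pfpd_genes": n_pfpd_genes,
            "prop_pd": n_pd / n_snps if n_snps else np.nan,
            "prop_pfpd": n_pfpd / n_snps if n_snps else np.nan,
            "prop_pd_genes": n_pd_genes / n_genes if n_genes else np.nan,
            "prop_pfpd_genes": n_pfpd_genes / n_genes if n_genes else np.nan,
        })
    del snp_chrom
    return pd.DataFrame(rows)


STANDARD_REGRESSIONS = (
    ("prop_pd", "length_bp"),
    ("prop_pfpd", "length_bp"),
    ("prop_pd_genes", "length_bp"),
    ("prop_pfpd_genes", "length_bp"),
    ("prop_pd_genes", "n_genes"),
    ("prop_pfpd_genes", "n_genes"),
)


def architecture_report(stats: pd.DataFrame) -> pd.DataFrame:
    """The six chromosome-architecture regressions (slope, R^2, p)."""
    rows = []
    for y_col, x_col in STANDARD_REGRESSIONS:
        sub = stats.dropna(subset=[y_col, x_col])
        if len(sub) < 3 or np.ptp(sub[x_col].to_numpy(dtype=float)) == 0:
            rows.append({"response": y_col, "predictor": x_col, "slope": np.nan,
                         "intercept": np.nan, "r_squared": np.nan,
                         "p_value": np.nan, "n": len(sub)})
            continue
        fit = ols_fit(sub[x_col], sub[y_col])
        rows.append({"response": y_col, "predictor": x_col, **asdict(fit)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class RunConfig:
    """Inputs of one end-to-end run (simulated or user-supplied files)."""

    outdir: str = "popdiff_run"
    simulate: SimulationConfig | None = None
    n_genes: int = 50
    n_sets: int = 20
    pf_fraction: float = 0.2
    planted_set_fraction: float = 0.0
    vcf: str | None = None
    panel: str | None = None
    genes: str | None = None
    pf: str | None = None
    gmt: str | None = None
    chrom_lengths: dict[str, int] | None = None
    top_fraction: float = 0.01
    estimator: str = "wc"
    tree_method: str = "upgma"
    monomorphic_mode: str = "pooled"
    do_prune: bool = True
    prune_window_bp: int = lp.DEFAULT_WINDOW_BP
    prune_r2_max: float = lp.DEFAULT_R2_MAX
    prune_population: str | None = None
    alpha: float = 0.05


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write all stage outputs + manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if config.simulate is not None:
            stage = "simulate"
            paths = simulate_dataset(
                config.simulate, out / "inputs",
                n_genes=config.n_genes, n_sets=config.n_sets,
                pf_fraction=config.pf_fraction,
                planted_set_fraction=config.planted_set_fraction,
            )
            vcf, panel_path = paths["vcf"], paths["panel"]
            genes_path, pf_path, gmt_path = paths["genes"], paths["pf"], paths["gmt"]
            chrom_lengths = dict(config.simulate.chrom_lengths)
        else:
            for name in ("vcf", "panel", "genes", "gmt"):
                val = getattr(config, name)
                if val is None or not Path(val).exists():
                    raise FileNotFoundError(f"stage inputs: missing {name} file: {val}")
            vcf, panel_path = config.vcf, config.panel
            genes_path, pf_path, gmt_path = config.genes, config.pf, config.gmt
            chrom_lengths = config.chrom_lengths or {}

        stage = "read"
        panel = pio.read_panel(panel_path)
        gm = pio.read_vcf(vcf, panel)
        models = pio.read_gene_models_gff3(genes_path)
        gene_sets = pio.read_gmt(gmt_path)
        pf_ids = (set(pio.read_pf_table(pf_path)["snp_id"])
                  if pf_path and Path(pf_path).exists() else set())
        if not chrom_lengths:
            chrom_lengths = {c: int(g["pos"].max()) for c, g in gm.sites.groupby("chrom")}

        stage = "fst_scan"
        counts = pio.allele_counts(gm, panel)
        keep = pio.filter_monomorphic(counts, config.monomorphic_mode)
        gm = gm.subset_sites(keep)
        counts = pio.allele_counts(gm, panel)
        scores = fstmod.pairwise_fst(counts, config.estimator)
        summaries, pd_sets = fstmod.pair_summaries(
            scores, gm.sites["snp_id"], config.top_fraction)
        union = fstmod.pd_union(pd_sets)
        pd_ids = set(union.index)
        dist = fstmod.mean_pd_fst_matrix(summaries)
        newick = fstmod.build_population_tree(dist, config.tree_method)

        stage = "annotate"
        annotations = rg.assign_region(gm.sites, models, chrom_lengths=chrom_lengths)
        tallies = rg.tally_genes(annotations, pd_ids, pf_ids)
        comp = rg.composition_table(
            annotations,
            {"all": None, "pd": pd_ids, "pfpd": pd_ids & pf_ids},
        )

        pruned: list[str] = []
        if config.do_prune:
            stage = "prune"
            prune_gm = gm
            if config.prune_population:
                cols = [s for s in gm.samples if panel[s] == config.prune_population]
                prune_gm = pio.GenotypeMatrix(
                    gm.sites, gm.dosages[:, [gm.samples.index(s) for s in cols]], cols)
            pruned = lp.prune(prune_gm, sorted(pd_ids),
                              config.prune_window_bp, config.prune_r2_max)

        stage = "enrich"
        enriched_genes = set(tallies.loc[tallies["enriched_pd_gene"], "gene_id"])
        universe = {m.gene_id for m in models}
        gsea = en.hypergeom_enrich(enriched_genes, gene_sets, universe, config.alpha)
        or_battery = en.region_or_battery(comp, [("pd", "all"), ("pfpd", "pd")])
        gene_chrom = {m.gene_id: m.chrom for m in models}
        by_chrom_q = {
            c: {g for g in enriched_genes if gene_chrom.get(g) == c}
            for c in chrom_lengths
        }
        grid = en.compare_by_chromosome(by_chrom_q, gene_sets, universe, config.alpha)

        stage = "chrom_arch"
        stats = per_chromosome_stats(gm.sites, annotations, pd_ids, pf_ids,
                                     tallies, gene_chrom, chrom_lengths)
        report = architecture_report(stats)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    # --- outputs ----------------------------------------------------------
    dist.to_csv(out / "fst_distance_matrix.tsv", sep="\t")
    (out / "population_tree.nwk").write_text(newick + "\n")
    pd.DataFrame([asdict(s) for s in summaries]).to_csv(
        out / "pair_summaries.tsv", sep="\t", index=False)
    union.rename("n_pairs").to_csv(out / "pdsnps.tsv", sep="\t")
    annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
    tallies.to_csv(out / "gene_tallies.tsv", sep="\t", index=False)
    comp.to_csv(out / "composition.tsv", sep="\t", index=False)
    or_battery.to_csv(out / "region_odds_ratios.tsv", sep="\t", index=False)
    gsea.to_csv(out / "geneset_enrichment.tsv", sep="\t", index=False)
    grid.to_csv(out / "enrichment_by_chromosome.tsv", sep="\t", index=False)
    stats.to_csv(out / "chromosome_stats.tsv", sep="\t", index=False)
    report.to_csv(out / "architecture_regressions.tsv", sep="\t", index=False)
    if config.do_prune:
        (out / "pruned_pdsnps.txt").write_text("\n".join(pruned) + "\n")

    manifest = {
        "n_sites": gm.n_sites,
        "n_samples": gm.n_samples,
        "populations": counts.pops,
        "n_pdsnps": len(pd_ids),
        "n_pruned": len(pruned),
        "estimator": config.estimator,
        "top_fraction": config.top_fraction,
        "tree_method": config.tree_method,
        "seed": config.simulate.seed if config.simulate else None,
        "input_sha256": {
            "vcf": _sha256(vcf), "panel": _sha256(panel_path),
            "genes": _sha256(genes_path), "gmt": _sha256(gmt_path),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "gm": gm, "pd_ids": pd_ids, "pf_ids": pf_ids, "summaries": summaries,
        "distance": dist, "tree": newick, "annotations": annotations,
        "tallies": tallies, "composition": comp, "pruned": pruned,
        "gsea": gsea, "region_or": or_battery, "by_chromosome": grid,
        "chrom_stats": stats, "architecture": report, "manifest": manifest,
    }


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
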
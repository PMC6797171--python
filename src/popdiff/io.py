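"""Readers/writers for the formats the pipeline touches, and allele counts.

Internal coordinates are 1-based inclusive (the VCF/GFF3 convention).
Genotypes are stored as diploid alt-allele dosages in {0, 1, 2} with -1
for a missing call.  Only biallelic SNPs are kept on VCF read;
multi-allelic records are skipped with a logged count.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .regions import GeneModel

logger = logging.getLogger(__name__)

MISSING = -1

SITE_COLUMNS = ("chrom", "pos", "ref", "alt", "snp_id")


@dataclass
class GenotypeMatrix:
    """Per-site diploid dosages for a set of samples.

    Attributes
    ----------
    sites
        DataFrame with columns (chrom, pos, ref, alt, snp_id), sorted by
        (chrom, pos).
    dosages
        int8 array of shape (n_sites, n_samples); -1 encodes missing.
    samples
        Ordered sample ids matching the dosage columns.
    """

    sites: pd.DataFrame
    dosages: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        if list(self.sites.columns[:5]) != list(SITE_COLUMNS):
            self.sites = self.sites[list(SITE_COLUMNS)]
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if self.dosages.size and (self.dosages.max() > 2 or self.dosages.min() < -1):
            raise ValueError("dosages must be in {-1, 0, 1, 2}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.sites.iloc[idx].reset_index(drop=True),
            self.dosages[idx],
            list(self.samples),
        )


@dataclass
class AlleleCounts:
    """Per-site, per-population allele and heterozygote counts.

    ``n_called`` is the number of called *alleles* (2 x non-missing
    diploids); ``alt`` the alt-allele count; ``het`` the observed
    heterozygote count.  Missing genotypes are excluded, not imputed.
    """

    sites: pd.DataFrame
    pops: list[str]
    n_called: np.ndarray
    alt: np.ndarray
    het: np.ndarray

    def freqs(self) -> np.ndarray:
        """Sample alt-allele frequency per site x population (NaN if uncallable)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_called > 0, self.alt / np.maximum(self.n_called, 1), np.nan)

    def callable_mask(self) -> np.ndarray:
        """(n_sites, n_pops) bool: population has at least one called allele."""
        return self.n_called > 0

    def pop_index(self, pop: str) -> int:
        return self.pops.index(pop)


# ---------------------------------------------------------------------------
# panel / annotation tables


def read_panel(path) -> dict[str, str]:
    """Read a sample->population panel (two tab-separated columns).

    Extra columns (super-population, sex, ...) are ignored; a header line
    whose first field is 'sample' is skipped.
    """
    panel: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[0].lower() == "sample":
            continue
        if len(fields) < 2:
            raise ValueError(f"panel line has fewer than 2 columns: {line!r}")
        panel[fields[0]] = fields[1]
    return panel


def write_panel(panel: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, pop in panel.items():
            fh.write(f"{sample}\t{pop}\n")


def read_pf_table(path) -> pd.DataFrame:
    """Potentially-functional SNP table: snp_id TAB tag (one row per tag)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["snp_id", "tag"], dtype=str)
    return df


def write_pf_table(df: pd.DataFrame, path) -> None:
    df[["snp_id", "tag"]].to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets in GMT format: name TAB description TAB gene..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line needs name, description, >=1 gene: {line!r}")
        sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# VCF


def write_vcf(gm: GenotypeMatrix, path, chrom_lengths: Mapping[str, int] | None = None,
              extra_header: Iterable[str] = ()) -> None:
    """Write a minimal diploid VCF 4.2 with unphased GT fields."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popdiff\n")
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        if chrom_lengths:
            for chrom, length in chrom_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        sites = gm.sites
        for i in range(gm.n_sites):
            row = sites.iloc[i]
            gts = "\t".join(gt_strings[int(d)] for d in gm.dosages[i])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path, panel: Mapping[str, str] | None = None,
             on_unknown_sample: str = "error") -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix via cyvcf2.

    Multi-allelic records are skipped (count logged).  Samples missing
    from ``panel`` raise by default; ``on_unknown_sample='drop'`` removes
    them instead.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    keep_cols = np.arange(len(samples))
    if panel is not None:
        unknown = [s for s in samples if s not in panel]
        if unknown:
            if on_unknown_sample == "error":
                raise ValueError(f"samples absent from panel: {unknown[:5]}...")
            if on_unknown_sample != "drop":
                raise ValueError("on_unknown_sample must be 'error' or 'drop'")
            keep_cols = np.array([i for i, s in enumerate(samples) if s in panel])
            samples = [samples[i] for i in keep_cols]

    recs = []
    dosage_rows = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        g = np.array(var.genotypes, dtype=np.int16)  # (n, 3): a1, a2, phased
        alleles = g[:, :2]
        dos = alleles.sum(axis=1).astype(np.int8)
        dos[(alleles < 0).any(axis=1)] = MISSING
        dosage_rows.append(dos[keep_cols])
        recs.append((var.CHROM, var.POS, var.REF, var.ALT[0],
                     var.ID if var.ID else f"{var.CHROM}:{var.POS}"))
    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic records", n_skipped)
    sites = pd.DataFrame(recs, columns=list(SITE_COLUMNS))
    dosages = (np.vstack(dosage_rows) if dosage_rows
               else np.empty((0, len(samples)), dtype=np.int8))
    gm = GenotypeMatrix(sites, dosages, samples)
    gm.n_skipped_multiallelic = n_skipped
    return gm


# ---------------------------------------------------------------------------
# gene models (GFF3)


def write_gene_models_gff3(models: Iterable[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene / mRNA / exon / CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            base = (m.chrom, "popdiff")
            fh.write("\t".join([*base, "gene", str(m.tx_start), str(m.tx_end), ".",
                                m.strand, ".", f"ID={m.gene_id}"]) + "\n")
            tid = f"{m.gene_id}.t1"
            fh.write("\t".join([*base, "mRNA", str(m.tx_start), str(m.tx_end), ".",
                                m.strand, ".", f"ID={tid};Parent={m.gene_id}"]) + "\n")
            for j, (s, e) in enumerate(m.exons, 1):
                fh.write("\t".join([*base, "exon", str(s), str(e), ".", m.strand, ".",
                                    f"ID={tid}.exon{j};Parent={tid}"]) + "\n")
            for s, e in m.exons:
                cs, ce = max(s, m.cds_start), min(e, m.cds_end)
                if cs <= ce:
                    fh.write("\t".join([*base, "CDS", str(cs), str(ce), ".", m.strand,
                                        "0", f"ID={tid}.cds;Parent={tid}"]) + "\n")


def read_gene_models_gff3(path) -> list[GeneModel]:
    """Read GFF3 gene models back into GeneModel objects (via gffutils)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models = []
    for mrna in db.features_of_type("mRNA"):
        gene_id = mrna.attributes["Parent"][0]
        exons = sorted((f.start, f.end) for f in db.children(mrna, featuretype="exon"))
        cds = sorted((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
        if not cds:
            raise ValueError(f"{gene_id}: transcript without CDS not supported")
        models.append(GeneModel(
            gene_id=gene_id, chrom=mrna.seqid, strand=mrna.strand,
            tx_start=mrna.start, tx_end=mrna.end, exons=exons,
            cds_start=cds[0][0], cds_end=cds[-1][1],
        ))
    models.sort(key=lambda m: (m.chrom, m.tx_start, m.gene_id))
    return models


# ---------------------------------------------------------------------------
# allele counts and site filters


def allele_counts(gm: GenotypeMatrix, panel: Mapping[str, str]) -> AlleleCounts:
    """Per-population called-allele, alt and heterozygote counts.

    Missing calls are excluded; a population with zero called alleles at
    a site is flagged uncallable (n_called 0) for pairs involving it.
    """
    missing_label = [s for s in gm.samples if s not in panel]
    if missing_label:
        raise ValueError(f"samples without population label: {missing_label[:5]}")
    pops = sorted(set(panel[s] for s in gm.samples))
    n_called = np.zeros((gm.n_sites, len(pops)), dtype=np.int64)
    alt = np.zeros_like(n_called)
    het = np.zeros_like(n_called)
    for k, pop in enumerate(pops):
        cols = [i for i, s in enumerate(gm.samples) if panel[s] == pop]
        sub = gm.dosages[:, cols]
        called = sub != MISSING
        n_called[:, k] = 2 * called.sum(axis=1)
        alt[:, k] = np.where(called, sub, 0).sum(axis=1)
        het[:, k] = (sub == 1).sum(axis=1)
    return AlleleCounts(gm.sites, pops, n_called, alt, het)


def filter_monomorphic(counts: AlleleCounts, mode: str = "pooled") -> np.ndarray:
    """Boolean keep-mask removing monomorphic sites.

    mode 'pooled' (default): drop sites monomorphic in the pooled sample
    across all populations.  mode 'any-pop': drop sites monomorphic
    within at least one population (this also discards fixed differences,
    the most differentiated sites, hence is not the default).
    """
    if mode == "pooled":
        tot_alt = counts.alt.sum(axis=1)
        tot_n = counts.n_called.sum(axis=1)
        return (tot_alt > 0) & (tot_alt < tot_n)
    if mode == "any-pop":
        callable_ = counts.n_called > 0
        poly = (counts.alt > 0) & (counts.alt < counts.n_called)
        return np.where(callable_, poly, False).all(axis=1)
    raise ValueError("mode must be 'pooled' or 'any-pop'")
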
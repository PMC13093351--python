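"""Genotype matrix container, VCF/CSV I/O, MAF filtering, allele diversity.

Dosages are ALT-allele counts in {0, 1, 2} with NaN for missing calls.
Allele frequencies are always computed from called alleles only
(pairwise-complete), the standard treatment under sporadic missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "read_genotypes",
    "write_dosage_csv",
    "write_vcf",
    "maf_filter",
    "locally_common_alleles",
    "private_alleles",
]


@dataclass
class GenotypeMatrix:
    """Individuals × loci ALT-dosage matrix with site/area metadata."""

    dosages: np.ndarray                 # n × L float, NaN = missing
    individual_ids: list[str]
    locus_ids: list[str]
    site_ids: np.ndarray
    area_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.site_ids = np.asarray(self.site_ids)
        self.area_ids = np.asarray(self.area_ids)
        n, L = self.dosages.shape
        if L == 0:
            raise ValueError("genotype matrix needs at least one locus")
        if len(self.individual_ids) != n or len(self.locus_ids) != L:
            raise ValueError("id lists do not match dosage matrix shape")
        if len(self.site_ids) != n or len(self.area_ids) != n:
            raise ValueError("site/area metadata length mismatch")
        called = self.dosages[~np.isnan(self.dosages)]
        if called.size and not np.isin(called, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if np.isnan(self.dosages).all(axis=0).any():
            raise ValueError("a locus has 100% missing calls")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def alt_frequencies(self) -> np.ndarray:
        """Overall ALT allele frequency per locus (called alleles only)."""
        called = ~np.isnan(self.dosages)
        alt = np.nansum(self.dosages, axis=0)
        return alt / (2.0 * called.sum(axis=0))

    def subset_loci(self, locus_ids) -> "GenotypeMatrix":
        idx = [self.locus_ids.index(l) for l in locus_ids]
        return replace(self, dosages=self.dosages[:, idx],
                       locus_ids=list(locus_ids))

    def imputed_dosages(self) -> np.ndarray:
        """Per-locus mean-imputed copy (for model fitting)."""
        X = self.dosages.copy()
        means = np.nanmean(X, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = means[nan_c]
        return X


# ---------------------------------------------------------------------------
# I/O


def write_dosage_csv(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(G.dosages, index=G.individual_ids, columns=G.locus_ids)
    df.index.name = "individual_id"
    df.to_csv(path)


def _read_dosage_csv(path, metadata: pd.DataFrame) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    meta = metadata.set_index("individual_id").loc[df.index]
    return GenotypeMatrix(
        dosages=df.to_numpy(dtype=float),
        individual_ids=list(df.index),
        locus_ids=list(df.columns),
        site_ids=meta["site_id"].to_numpy(),
        area_ids=meta["area_id"].to_numpy(),
    )


def write_vcf(G: GenotypeMatrix, path, contig: str = "1") -> None:
    """Minimal GT-only biallelic VCF (one contig, 1-based running positions)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.individual_ids) + "\n")
        for j, lid in enumerate(G.locus_ids):
            gts = [gt_map.get(d, "./.") if not np.isnan(d) else "./."
                   for d in G.dosages[:, j]]
            fh.write(f"{contig}\t{j + 1}\t{lid}\tA\tG\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def _read_vcf(path, metadata: pd.DataFrame) -> tuple[GenotypeMatrix, pd.DataFrame]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    meta = metadata.set_index("individual_id")
    unknown = [s for s in samples if s not in meta.index]
    if unknown:
        raise ValueError(f"VCF samples missing from metadata: {unknown[:5]}")
    cols, ids, rejected = [], [], []
    for var in vcf:
        if len(var.ALT) != 1 or var.ALT[0] not in "ACGT" or len(var.REF) != 1:
            rejected.append({"locus_id": var.ID or f"{var.CHROM}:{var.POS}",
                             "reason": "not biallelic SNP"})
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        cols.append(dos)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if not cols:
        raise ValueError("no usable biallelic records in VCF")
    dosages = np.column_stack(cols)
    msub = meta.loc[samples]
    G = GenotypeMatrix(dosages=dosages, individual_ids=list(samples),
                       locus_ids=ids,
                       site_ids=msub["site_id"].to_numpy(),
                       area_ids=msub["area_id"].to_numpy())
    return G, pd.DataFrame(rejected, columns=["locus_id", "reason"])


def read_genotypes(path, fmt: str, metadata: pd.DataFrame):
    """Read genotypes from ``vcf`` or ``dosage_csv``.

    Returns ``(GenotypeMatrix, rejection_report)``; the report lists
    multi-allelic / malformed records that were skipped (always empty for
    dosage CSVs, which cannot encode them).
    """
    if fmt == "vcf":
        return _read_vcf(path, metadata)
    if fmt == "dosage_csv":
        return _read_dosage_csv(path, metadata), pd.DataFrame(
            columns=["locus_id", "reason"])
    raise ValueError(f"unknown format '{fmt}' (expected 'vcf' or 'dosage_csv')")


# ---------------------------------------------------------------------------
# filtering and allele diversity


def maf_filter(G: GenotypeMatrix, threshold: float = 0.05
               ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop loci whose overall minor-allele frequency is below ``threshold``.

    Missing calls are excluded from the denominator. Returns the filtered
    matrix and a per-locus report (frequency, kept flag).
    """
    if not (0.0 < threshold <= 0.5):
        raise ValueError("MAF threshold must be in (0, 0.5]")
    f_alt = G.alt_frequencies()
    maf = np.minimum(f_alt, 1.0 - f_alt)
    keep = maf >= threshold
    report = pd.DataFrame({"locus_id": G.locus_ids, "alt_freq": f_alt,
                           "maf": maf, "kept": keep})
    kept_ids = [l for l, k in zip(G.locus_ids, keep) if k]
    if not kept_ids:
        raise ValueError("MAF filter removed every locus")
    return G.subset_loci(kept_ids), report


def _area_allele_stats(G: GenotypeMatrix):
    """Per-area ALT frequency and REF/ALT observation counts."""
    areas = np.unique(G.area_ids)
    nA, L = len(areas), G.n_loci
    if nA < 2:
        raise ValueError("allele-diversity statistics need >= 2 areas")
    freq_alt = np.zeros((nA, L))
    obs_alt = np.zeros((nA, L), dtype=bool)
    obs_ref = np.zeros((nA, L), dtype=bool)
    for i, a in enumerate(areas):
        rows = G.dosages[G.area_ids == a]
        if rows.shape[0] == 0:
            raise ValueError(f"area {a} has zero individuals")
        called = ~np.isnan(rows)
        denom = 2.0 * called.sum(axis=0)
        if np.any(denom == 0):
            # area fully missing at a locus: neither allele observed there
            denom = np.where(denom == 0, np.nan, denom)
        alt = np.nansum(rows, axis=0)
        with np.errstate(invalid="ignore"):
            freq_alt[i] = np.where(np.isnan(denom), 0.0, alt / denom)
        obs_alt[i] = np.nansum(rows > 0, axis=0) > 0
        obs_ref[i] = np.nansum(rows < 2, axis=0) > 0
    return areas, freq_alt, obs_alt, obs_ref


def locally_common_alleles(G: GenotypeMatrix, threshold: float = 0.05
                           ) -> pd.Series:
    """Count alleles ≥ ``threshold`` frequency in exactly one area.

    Both REF and ALT alleles are eligible: an allele counts toward an
    area when its frequency there is at least the threshold and is below
    the threshold in every other area.
    """
    areas, freq_alt, _, _ = _area_allele_stats(G)
    counts = np.zeros(len(areas), dtype=int)
    for freqs in (freq_alt, 1.0 - freq_alt):
        common = freqs >= threshold          # areas × loci
        only_one = common.sum(axis=0) == 1
        counts += (common & only_one[None, :]).sum(axis=1)
    return pd.Series(counts, index=pd.Index(areas, name="area_id"),
                     name="locally_common")


def private_alleles(G: GenotypeMatrix) -> pd.Series:
    """Count alleles observed (any copy) in exactly one area."""
    areas, _, obs_alt, obs_ref = _area_allele_stats(G)
    counts = np.zeros(len(areas), dtype=int)
    for obs in (obs_alt, obs_ref):
        only_one = obs.sum(axis=0) == 1
        counts += (obs & only_one[None, :]).sum(axis=1)
    return pd.Series(counts, index=pd.Index(areas, name="area_id"),
                     name="private")
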
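"""Readers and writers for dosage VCFs, PC-coordinate tables and kinship tables.

The central container is :class:`DosagePanel`: an N-samples-by-M-SNPs matrix of
imputed allele dosages (real values in [0, 2]) together with a per-SNP
imputation quality ``rsq`` (the squared correlation between imputed dosages and
true genotypes, BEAGLE's DR2). Dosage VCFs are read with cyvcf2; the writers
emit plain uncompressed VCF 4.2 text with a fixed, minimal schema.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DosagePanel",
    "PCCoordinates",
    "KinshipResult",
    "VariantFilter",
    "read_dosage_vcf",
    "write_dosage_vcf",
    "read_pc_coords",
    "write_pc_coords",
    "write_kinship_table",
    "read_kinship_table",
    "write_iaf_vcf",
    "read_iaf_vcf",
]


@dataclass(frozen=True)
class SnpId:
    """Variant identity: (chrom, pos, ref, alt), pos 1-based per VCF."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def _check_unique(ids: Sequence, what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what}")


@dataclass
class DosagePanel:
    """Imputed dosages for N samples at M biallelic SNPs.

    Attributes
    ----------
    sample_ids : list of str
    snp_ids : list of SnpId
    dosages : (N, M) float array in [0, 2]; np.nan marks a missing entry
        (only permitted when the panel was read with ``allow_missing``).
    rsq : (M,) float array in [0, 1], per-SNP dosage r².
    ref_panel_mean : optional (M,) array, mean genotype of the imputation
        reference panel at each SNP (used by the allele-frequency correction).
    """

    sample_ids: list
    snp_ids: list
    dosages: np.ndarray
    rsq: np.ndarray
    ref_panel_mean: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.rsq = np.asarray(self.rsq, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.snp_ids = list(self.snp_ids)
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.snp_ids, "snp ids")
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} snps"
            )
        if self.rsq.shape != (m,):
            raise ValueError("rsq length does not match number of SNPs")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(
                self.dosages, initial=0.0
            ) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        if self.rsq.min(initial=1.0) < 0 or self.rsq.max(initial=0.0) > 1:
            raise ValueError("rsq must lie in [0, 1]")
        if self.ref_panel_mean is not None:
            self.ref_panel_mean = np.asarray(self.ref_panel_mean, dtype=float)
            if self.ref_panel_mean.shape != (m,):
                raise ValueError("ref_panel_mean length does not match SNPs")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """(N, M) boolean array, True where the dosage is missing."""
        return np.isnan(self.dosages)

    def sample_af(self) -> np.ndarray:
        """Per-SNP allele frequency p~_m = mean dosage / 2 over non-missing."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_snps(self, keep: np.ndarray) -> "DosagePanel":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return DosagePanel(
            sample_ids=self.sample_ids,
            snp_ids=[self.snp_ids[i] for i in keep],
            dosages=self.dosages[:, keep],
            rsq=self.rsq[keep],
            ref_panel_mean=None
            if self.ref_panel_mean is None
            else self.ref_panel_mean[keep],
        )


@dataclass
class PCCoordinates:
    """Per-sample coordinates in a K-dimensional ancestry (PC) space."""

    sample_ids: list
    coords: np.ndarray  # (N, K)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            self.coords = self.coords.reshape(len(self.sample_ids), -1)
        _check_unique(self.sample_ids, "sample ids")
        if self.coords.shape[0] != len(self.sample_ids):
            raise ValueError("coordinate rows do not match sample ids")

    @property
    def n_pcs(self) -> int:
        return self.coords.shape[1]


@dataclass
class KinshipResult:
    """Symmetric kinship estimates with per-pair SNP counts.

    ``phi`` holds kinship coefficients: phi_ij off-diagonal and the
    self-kinship phi_ii = (1 + f_i)/2 on the diagonal.
    """

    sample_ids: list
    phi: np.ndarray  # (N, N)
    n_snps: np.ndarray  # (N, N) int

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.phi = np.asarray(self.phi, dtype=float)
        self.n_snps = np.asarray(self.n_snps)
        n = len(self.sample_ids)
        if self.phi.shape != (n, n) or self.n_snps.shape != (n, n):
            raise ValueError("matrix shapes do not match sample count")
        finite = np.isfinite(self.phi)
        if not np.allclose(
            np.where(finite, self.phi, 0.0),
            np.where(finite.T, self.phi.T, 0.0),
            atol=1e-8,
        ):
            raise ValueError("kinship matrix is not symmetric")
        if (np.asarray(self.n_snps) < 0).any():
            raise ValueError("n_snps must be non-negative")


@dataclass(frozen=True)
class VariantFilter:
    """Inclusive retention thresholds: keep SNPs with MAF >= maf_min and
    rsq >= rsq_min. MAF is computed from the mean dosage."""

    maf_min: float = 0.05
    rsq_min: float = 0.5

    def keep_mask(self, panel: DosagePanel) -> np.ndarray:
        p = panel.sample_af()
        maf = np.minimum(p, 1.0 - p)
        return (maf >= self.maf_min) & (panel.rsq >= self.rsq_min)


# ---------------------------------------------------------------------------
# dosage VCF


def _site_rsq(variant, rsq_key: Optional[str]):
    keys = [rsq_key] if rsq_key else ["DR2", "R2"]
    for key in keys:
        val = variant.INFO.get(key)
        if val is not None:
            if isinstance(val, (tuple, list)):
                val = val[0]
            return float(val)
    return None


def read_dosage_vcf(
    path,
    rsq_key: Optional[str] = None,
    filters: Optional[VariantFilter] = None,
    allow_missing: bool = False,
) -> DosagePanel:
    """Read a dosage VCF (FORMAT DS, INFO DR2/R2) into a :class:`DosagePanel`.

    Dosages are taken from the per-sample DS field. If a site has no DS but
    has GT, the alternative-allele count is used as the dosage and the site's
    rsq defaults to 1.0 (hard genotypes). Multi-allelic sites are skipped with
    a warning. ``filters``, when given, is applied to the assembled panel
    (MAF from mean dosage; inclusive thresholds).

    Raises
    ------
    ValueError
        If a site carries neither DS nor GT, if the rsq key is absent at a
        DS site, or if a dosage is missing and ``allow_missing`` is False.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list = []
    rows: list = []
    rsqs: list = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning(
                "skipping multi-allelic site %s:%d", variant.CHROM, variant.POS
            )
            continue
        ds = variant.format("DS")
        if ds is not None:
            ds = np.asarray(ds, dtype=float).reshape(len(samples))
            # cyvcf2 encodes missing floats as very large negatives or nan
            missing = ~np.isfinite(ds) | (ds < -1)
            rsq = _site_rsq(variant, rsq_key)
            if rsq is None:
                raise ValueError(
                    f"no imputation r2 ({rsq_key or 'DR2/R2'}) in INFO at "
                    f"{variant.CHROM}:{variant.POS}"
                )
        else:
            gts = np.asarray(variant.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            ds = np.choose(gts, [0.0, 1.0, np.nan, 2.0])
            missing = ~np.isfinite(ds)
            rsq = _site_rsq(variant, rsq_key)
            if rsq is None:
                rsq = 1.0
        if ds is None:
            raise ValueError(
                f"site {variant.CHROM}:{variant.POS} has neither DS nor GT"
            )
        if missing.any():
            if not allow_missing:
                raise ValueError(
                    f"missing dosage at {variant.CHROM}:{variant.POS} "
                    f"(sample {samples[int(np.flatnonzero(missing)[0])]}); "
                    "pass allow_missing=True to keep per-pair accounting"
                )
            ds = np.where(missing, np.nan, ds)
        snp_ids.append(SnpId(variant.CHROM, variant.POS, variant.REF, variant.ALT[0]))
        rows.append(np.where(np.isfinite(ds), np.clip(ds, 0.0, 2.0), np.nan))
        rsqs.append(min(max(rsq, 0.0), 1.0))
    panel = DosagePanel(
        sample_ids=samples,
        snp_ids=snp_ids,
        dosages=np.array(rows, dtype=float).T
        if rows
        else np.empty((len(samples), 0)),
        rsq=np.asarray(rsqs, dtype=float),
    )
    if filters is not None:
        panel = panel.subset_snps(filters.keep_mask(panel))
    return panel


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DR2,Number=1,Type=Float,Description="Dosage r-squared: squared correlation between imputed dosage and true genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternative allele dosage">
"""


def write_dosage_vcf(panel: DosagePanel, path) -> None:
    """Write a panel as an uncompressed VCF with DS dosages and INFO DR2."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for m, snp in enumerate(panel.snp_ids):
            vals = [
                "." if not np.isfinite(d) else f"{d:.6f}"
                for d in panel.dosages[:, m]
            ]
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t.\t{snp.ref}\t{snp.alt}\t.\tPASS\t"
                f"DR2={panel.rsq[m]:.6f}\tDS\t" + "\t".join(vals) + "\n"
            )


# ---------------------------------------------------------------------------
# individual-specific allele frequency VCF (FORMAT ISAF)

_ISAF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=ISAF,Number=1,Type=Float,Description="Individual-specific allele frequency predicted from ancestry principal components">
"""


def write_iaf_vcf(sample_ids, snp_ids, af: np.ndarray, path) -> None:
    """Write individual-specific allele frequencies (samples x SNPs) as a VCF
    with one ISAF float per sample per site."""
    af = np.asarray(af, dtype=float)
    with open(path, "w") as fh:
        fh.write(_ISAF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for m, snp in enumerate(snp_ids):
            vals = "\t".join(f"{v:.6f}" for v in af[:, m])
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t.\t{snp.ref}\t{snp.alt}\t.\tPASS\t.\t"
                f"ISAF\t{vals}\n"
            )


def read_iaf_vcf(path):
    """Read an ISAF VCF back into (sample_ids, snp_ids, af matrix)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list = []
    cols: list = []
    for variant in vcf:
        field = variant.format("ISAF")
        if field is None:
            raise ValueError(
                f"no ISAF FORMAT field at {variant.CHROM}:{variant.POS}"
            )
        snp_ids.append(SnpId(variant.CHROM, variant.POS, variant.REF, variant.ALT[0]))
        cols.append(np.asarray(field, dtype=float).reshape(len(samples)))
    af = np.array(cols, dtype=float).T if cols else np.empty((len(samples), 0))
    return samples, snp_ids, af


# ---------------------------------------------------------------------------
# PC coordinate tables


def read_pc_coords(path) -> PCCoordinates:
    """Read a whitespace-delimited table: sample ID then K numeric PCs.

    A single-column file (IDs only) yields K = 0, which feeds an
    intercept-only allele-frequency model downstream.
    """
    sample_ids: list = []
    rows: list = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            sid, *vals = parts
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise ValueError(
                    f"row {lineno}: expected {width} coordinates, got {len(vals)}"
                )
            try:
                rows.append([float(v) for v in vals])
            except ValueError:
                raise ValueError(
                    f"row {lineno}: non-numeric coordinate for sample {sid}"
                ) from None
            sample_ids.append(sid)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in PC table")
    coords = np.asarray(rows, dtype=float).reshape(len(sample_ids), width or 0)
    return PCCoordinates(sample_ids=sample_ids, coords=coords)


def write_pc_coords(pcs: PCCoordinates, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(pcs.sample_ids, pcs.coords):
            fh.write("\t".join([sid] + [f"{v:.6f}" for v in row]) + "\n")


# ---------------------------------------------------------------------------
# kinship tables


def write_kinship_table(result: KinshipResult, path, mode: str = "pairs") -> None:
    """Write kinship estimates.

    ``pairs`` mode: tab-separated ID1, ID2, nSNP, kinship for all i <= j
    (self pairs included). ``matrix`` mode: square matrix with a header row
    of sample IDs and an ID leading column.
    """
    if mode not in ("pairs", "matrix"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = result.sample_ids
    with open(path, "w") as fh:
        if mode == "pairs":
            fh.write("ID1\tID2\tnSNP\tkinship\n")
            for i in range(len(ids)):
                for j in range(i, len(ids)):
                    fh.write(
                        f"{ids[i]}\t{ids[j]}\t{int(result.n_snps[i, j])}\t"
                        f"{result.phi[i, j]:.6f}\n"
                    )
        else:
            fh.write("ID\t" + "\t".join(ids) + "\n")
            for i, sid in enumerate(ids):
                fh.write(
                    sid + "\t" + "\t".join(f"{v:.6f}" for v in result.phi[i]) + "\n"
                )


def read_kinship_table(path, mode: str = "pairs") -> KinshipResult:
    """Read a kinship table written by :func:`write_kinship_table`."""
    if mode == "pairs":
        df = pd.read_csv(path, sep="\t", dtype={"ID1": str, "ID2": str})
        ids = list(dict.fromkeys(list(df.ID1) + list(df.ID2)))
        idx = {s: k for k, s in enumerate(ids)}
        n = len(ids)
        phi = np.zeros((n, n))
        cnt = np.zeros((n, n), dtype=int)
        for row in df.itertuples(index=False):
            i, j = idx[row.ID1], idx[row.ID2]
            phi[i, j] = phi[j, i] = row.kinship
            cnt[i, j] = cnt[j, i] = row.nSNP
        return KinshipResult(sample_ids=ids, phi=phi, n_snps=cnt)
    df = pd.read_csv(path, sep="\t", index_col=0)
    phi = df.to_numpy(dtype=float)
    return KinshipResult(
        sample_ids=list(df.columns),
        phi=phi,
        n_snps=np.zeros_like(phi, dtype=int),
    )
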
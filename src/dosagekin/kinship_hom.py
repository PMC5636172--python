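"""Kinship estimation for homogeneous samples from imputed dosages.

Imputed dosages have smaller variance than the true genotypes they estimate:
under the standard imputation model E(G~ | G, GR) = (1 - r2) GR + r2 G, the
centered dosage shrinks the centered genotype by a factor r2 (the per-SNP
dosage r-squared reported by the imputation program). A naive plug-in of
dosages into the classical genotype-based moment estimator therefore biases
kinship toward zero. The estimators here rescale each SNP's contribution by
powers of r2 so that the per-SNP terms keep the expectation of the
genotype-based terms:

    pairwise:  2 phi_ijm = (G~im - 2p~m)(G~jm - 2p~m) / [2 p~m (1-p~m) r2m^2]
    self:      2 phi_iim = (G~im - 2p~m)^2            / [2 p~m (1-p~m) r2m]

with p~m the sample dosage allele frequency. Genome-wide estimates combine
SNPs with weights w_m = 2 p~m (1-p~m) r2m^2, down-weighting poorly imputed
and low-MAF SNPs; the combined ratio form is implemented blockwise so memory
stays at O(N^2 + N L) for block size L.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import DosagePanel, KinshipResult, VariantFilter

logger = logging.getLogger(__name__)

__all__ = [
    "HomEstimatorConfig",
    "sample_af",
    "per_snp_pair_hom",
    "per_snp_self_hom",
    "estimate_kinship_hom",
    "gcta_estimator",
]


@dataclass(frozen=True)
class HomEstimatorConfig:
    """Thresholds and blocking for the homogeneous estimator.

    rsq_min defaults to 0.5; 0.3 is a documented lower-threshold alternative
    that trades per-SNP quality for SNP count. block_size is the number of
    SNPs processed per accumulation block (results are invariant to it).
    apply_ref_correction enables the reference-panel allele-frequency
    correction p_m = p~m - (GR_m - 2 p~m)(1 - r2m)/r2m; by default the sample
    frequency p~m is used directly.
    """

    rsq_min: float = 0.5
    maf_min: float = 0.05
    block_size: int = 10_000
    apply_ref_correction: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.rsq_min <= 1.0 and 0.0 <= self.maf_min <= 0.5):
            raise ValueError("thresholds out of range")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")

    @property
    def variant_filter(self) -> VariantFilter:
        return VariantFilter(maf_min=self.maf_min, rsq_min=self.rsq_min)


def sample_af(panel: DosagePanel, apply_ref_correction: bool = False):
    """Per-SNP sample allele frequency p~_m = (1/2N) sum_i G~im.

    With ``apply_ref_correction`` and a reference panel mean available,
    additionally returns the corrected population frequency
    p_m = p~m - (GR_m - 2 p~m)(1 - r2m)/r2m; sites with r2 = 0 get p_m = nan
    with a warning (the correction divides by r2).
    """
    p_tilde = panel.sample_af()
    if not apply_ref_correction:
        return p_tilde
    if panel.ref_panel_mean is None:
        raise ValueError("reference panel mean unavailable for correction")
    rsq = panel.rsq
    bad = rsq <= 0
    if bad.any():
        logger.warning(
            "%d sites have r2=0; reference AF correction skipped there", bad.sum()
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        p_corr = p_tilde - (panel.ref_panel_mean - 2 * p_tilde) * (1 - rsq) / rsq
    p_corr = np.where(bad, np.nan, p_corr)
    return p_tilde, p_corr


def per_snp_pair_hom(gi: float, gj: float, p: float, rsq: float) -> float:
    """Single-SNP pairwise estimate 2*phi_ijm (i != j)."""
    if not (0.0 < p < 1.0) or rsq <= 0:
        raise ValueError("requires 0 < p < 1 and r2 > 0")
    return (gi - 2 * p) * (gj - 2 * p) / (2 * p * (1 - p) * rsq**2)


def per_snp_self_hom(gi: float, p: float, rsq: float) -> float:
    """Single-SNP self estimate 2*phi_iim (non-negative)."""
    if not (0.0 < p < 1.0) or rsq <= 0:
        raise ValueError("requires 0 < p < 1 and r2 > 0")
    return (gi - 2 * p) ** 2 / (2 * p * (1 - p) * rsq)


def _usable(p: np.ndarray, rsq: np.ndarray) -> np.ndarray:
    ok = (p > 0) & (p < 1) & (rsq > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("dropping %d monomorphic or r2=0 SNPs", n_bad)
    return ok


def estimate_kinship_hom(
    panel: DosagePanel, config: HomEstimatorConfig | None = None
) -> KinshipResult:
    """Genome-wide weighted kinship estimates for a homogeneous sample.

    Off-diagonal (2*phi):
        sum_m (G~im - 2p~m)(G~jm - 2p~m)  /  sum_m 2 p~m (1-p~m) r2m^2
    Diagonal (2*phi_ii):
        sum_m (G~im - 2p~m)^2 r2m        /  sum_m 2 p~m (1-p~m) r2m^2

    Sums run over the SNPs passing the MAF/r2 filters; with missing dosages
    (allow_missing panels) each pair accumulates over exactly the SNPs
    observed in both members. SNPs are processed in blocks of
    ``config.block_size``; blocking is associative summation, so the result
    is independent of the block size.
    """
    config = config or HomEstimatorConfig()
    if panel.n_samples < 2:
        raise ValueError("need at least two samples")
    panel = panel.subset_snps(config.variant_filter.keep_mask(panel))
    if panel.n_snps == 0:
        raise ValueError("no SNPs survive the MAF/r2 filters")
    n = panel.n_samples
    has_missing = bool(panel.missing_mask.any())

    num = np.zeros((n, n))
    diag_num = np.zeros(n)
    if has_missing:
        den = np.zeros((n, n))
        diag_den = None  # comes from den's diagonal
        counts = np.zeros((n, n), dtype=np.int64)
    else:
        den_scalar = 0.0
        counts_scalar = 0
    kept = 0
    for start in range(0, panel.n_snps, config.block_size):
        d = panel.dosages[:, start : start + config.block_size]
        rsq = panel.rsq[start : start + config.block_size]
        with np.errstate(invalid="ignore"):
            p = np.nanmean(d, axis=0) / 2.0
        ok = _usable(p, rsq)
        if not ok.any():
            continue
        d, rsq, p = d[:, ok], rsq[ok], p[ok]
        kept += d.shape[1]
        w = 2 * p * (1 - p) * rsq**2
        present = np.isfinite(d)
        x = np.where(present, d - 2 * p, 0.0)
        num += x @ x.T
        diag_num += (x * x) @ rsq
        if has_missing:
            pw = present * w
            den += pw @ present.T
            counts += present.astype(np.int64) @ present.T.astype(np.int64)
        else:
            den_scalar += w.sum()
            counts_scalar += d.shape[1]
    if kept == 0:
        raise ValueError("no usable SNPs after dropping monomorphic sites")
    if has_missing:
        with np.errstate(divide="ignore", invalid="ignore"):
            two_phi = num / den
        np.fill_diagonal(two_phi, diag_num / np.diag(den))
        n_snps = counts
    else:
        two_phi = num / den_scalar
        np.fill_diagonal(two_phi, diag_num / den_scalar)
        n_snps = np.full((n, n), counts_scalar, dtype=np.int64)
    return KinshipResult(
        sample_ids=panel.sample_ids, phi=two_phi / 2.0, n_snps=n_snps
    )


def gcta_estimator(
    genotypes: np.ndarray,
    allele_freqs: np.ndarray | None = None,
    sample_ids=None,
    weighted: bool = False,
) -> KinshipResult:
    """Classical genotype-based moment estimator.

    With ``weighted=False`` (default), the equal-weight per-SNP average:
    2*phi_ij = (1/|S_ij|) sum_{m in S_ij} (Gim - 2pm)(Gjm - 2pm) / [2pm(1-pm)],
    where S_ij is the set of SNPs non-missing in both individuals. With
    ``weighted=True``, the ratio-of-sums form with weights w_m = 2pm(1-pm):
    2*phi_ij = sum (Gim-2pm)(Gjm-2pm) / sum 2pm(1-pm), which is the exact
    r2 = 1 reduction of the dosage-based estimator. The diagonal uses the
    same standardized form with i = j, estimating 1 + f_i. Pairs with empty
    S_ij get phi = nan.
    """
    g = np.asarray(genotypes, dtype=float)
    n, m = g.shape
    if allele_freqs is None:
        with np.errstate(invalid="ignore"):
            allele_freqs = np.nanmean(g, axis=0) / 2.0
    p = np.asarray(allele_freqs, dtype=float)
    ok = (p > 0) & (p < 1)
    if not ok.all():
        logger.warning("dropping %d SNPs with p outside (0,1)", int((~ok).sum()))
        g, p = g[:, ok], p[ok]
    present = np.isfinite(g)
    counts = present.astype(np.int64) @ present.T.astype(np.int64)
    if weighted:
        x = np.where(present, g - 2 * p, 0.0)
        num = x @ x.T
        w = 2 * p * (1 - p)
        den = (present * w) @ present.T
    else:
        y = np.where(present, (g - 2 * p) / np.sqrt(2 * p * (1 - p)), 0.0)
        num = y @ y.T
        den = counts
    with np.errstate(divide="ignore", invalid="ignore"):
        two_phi = np.where(counts > 0, num / den, np.nan)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return KinshipResult(sample_ids=sample_ids, phi=two_phi / 2.0, n_snps=counts)
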
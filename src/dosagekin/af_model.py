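"""Individual-specific allele frequencies from ancestry principal components.

In a structured or admixed sample, a single population allele frequency p_m
misrepresents individuals whose ancestry differs from the sample average. The
standard remedy is an individual-specific allele frequency p_im: the expected
frequency of the alternative allele at SNP m given individual i's ancestry.
Here p_im is obtained by (1) running PCA on a reference genotype panel,
(2) regressing each reference SNP's genotypes on the top K PCs,
(3) evaluating the fitted linear predictor at each study individual's PC
coordinates:

    p_im = (beta_m0 + sum_k beta_mk * v_ik) / 2,

clamped to [0.001, 0.999] to avoid boundary values. Study-sample coordinates
v_i may come from any upstream ancestry-placement tool; a genotype-space
projection onto the reference basis is provided as a convenience.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import PCCoordinates

logger = logging.getLogger(__name__)

__all__ = [
    "ReferencePCBasis",
    "AFRegressionModel",
    "IndividualAFMatrix",
    "AF_CLAMP_LO",
    "AF_CLAMP_HI",
    "fit_reference_pca",
    "project_samples",
    "fit_af_regression",
    "predict_individual_af",
]

AF_CLAMP_LO = 0.001
AF_CLAMP_HI = 0.999


@dataclass
class ReferencePCBasis:
    """Top-K PC basis of a column-centered reference genotype matrix.

    ``loadings`` is (K, M): right singular vectors of the centered matrix.
    ``snp_means`` is (M,): the per-SNP means used for centering.
    """

    snp_ids: list
    loadings: np.ndarray
    snp_means: np.ndarray

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[0]


@dataclass
class AFRegressionModel:
    """Per-SNP OLS coefficients of genotype on [1, PCs]; betas is (M, K+1)."""

    snp_ids: list
    betas: np.ndarray
    basis: ReferencePCBasis | None = None

    def __post_init__(self) -> None:
        self.betas = np.atleast_2d(np.asarray(self.betas, dtype=float))
        if not np.isfinite(self.betas).all():
            raise ValueError("non-finite regression coefficients")

    @property
    def n_pcs(self) -> int:
        return self.betas.shape[1] - 1


@dataclass
class IndividualAFMatrix:
    """Samples x SNPs individual-specific allele frequencies, clamped."""

    sample_ids: list
    snp_ids: list
    af: np.ndarray

    def __post_init__(self) -> None:
        self.af = np.asarray(self.af, dtype=float)
        if self.af.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("af matrix shape inconsistent with ids")
        # tolerate float32 round-trip jitter at the clamp bounds
        tol = 1e-6
        if self.af.min(initial=AF_CLAMP_LO) < AF_CLAMP_LO - tol or self.af.max(
            initial=AF_CLAMP_HI
        ) > AF_CLAMP_HI + tol:
            raise ValueError(
                f"individual AFs must lie in [{AF_CLAMP_LO}, {AF_CLAMP_HI}]"
            )
        self.af = np.clip(self.af, AF_CLAMP_LO, AF_CLAMP_HI)


def _impute_missing(genotypes: np.ndarray) -> np.ndarray:
    g = np.asarray(genotypes, dtype=float)
    if np.isnan(g).any():
        means = np.nanmean(g, axis=0)
        idx = np.where(np.isnan(g))
        g = g.copy()
        g[idx] = means[idx[1]]
    return g


def fit_reference_pca(
    ref_genotypes: np.ndarray,
    K: int,
    sample_ids=None,
    snp_ids=None,
) -> tuple[ReferencePCBasis, PCCoordinates]:
    """PCA of a reference genotype matrix (samples x SNPs, values in {0,1,2}).

    Columns are centered by the per-SNP mean; no variance standardization
    (the downstream regression of genotype on PCs absorbs any scaling).
    Missing genotypes are mean-imputed per SNP. Returns the top-K basis and
    the reference individuals' scores (zero mean per PC by construction).

    K = 0 is valid and yields an empty basis for an intercept-only AF model.
    """
    g = _impute_missing(ref_genotypes)
    n, m = g.shape
    if K < 0:
        raise ValueError("K must be >= 0")
    if K >= min(n, m) and K > 0:
        raise ValueError(f"K={K} must be smaller than min(samples, SNPs)={min(n, m)}")
    if sample_ids is None:
        sample_ids = [f"ref{i}" for i in range(n)]
    if snp_ids is None:
        snp_ids = list(range(m))
    means = g.mean(axis=0)
    xc = g - means
    if K > 0 and not (xc != 0).any():
        raise ValueError("reference genotype matrix is constant; PCA undefined")
    if K == 0:
        basis = ReferencePCBasis(
            snp_ids=list(snp_ids), loadings=np.empty((0, m)), snp_means=means
        )
        return basis, PCCoordinates(sample_ids=sample_ids, coords=np.empty((n, 0)))
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per component
    for k in range(K):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    basis = ReferencePCBasis(
        snp_ids=list(snp_ids), loadings=vt[:K], snp_means=means
    )
    scores = u[:, :K] * s[:K]
    return basis, PCCoordinates(sample_ids=sample_ids, coords=scores)


def project_samples(
    genotypes_or_dosages: np.ndarray,
    basis: ReferencePCBasis,
    sample_ids=None,
) -> PCCoordinates:
    """Project study genotype/dosage vectors onto a reference PC basis.

    Each sample's coordinates are its reference-mean-centered vector times the
    basis loadings. Projecting a reference individual's own genotypes returns
    its PCA score exactly.
    """
    g = _impute_missing(genotypes_or_dosages)
    if g.shape[1] != basis.snp_means.shape[0]:
        raise ValueError(
            f"{g.shape[1]} SNPs do not match basis with {basis.snp_means.shape[0]}"
        )
    if g.shape[1] == 0:
        raise ValueError("no overlapping SNPs between samples and basis")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(g.shape[0])]
    coords = (g - basis.snp_means) @ basis.loadings.T
    return PCCoordinates(sample_ids=sample_ids, coords=coords)


def fit_af_regression(
    ref_genotypes: np.ndarray,
    ref_coords: PCCoordinates,
    snp_ids=None,
    basis: ReferencePCBasis | None = None,
) -> AFRegressionModel:
    """Per-SNP ordinary least squares of reference genotype on [1, PCs].

    With K = 0 the fitted intercept is the mean genotype 2p_m. A
    rank-deficient design falls back to the minimum-norm solution with a
    logged warning.
    """
    g = _impute_missing(ref_genotypes)
    n, m = g.shape
    if ref_coords.coords.shape[0] != n:
        raise ValueError("coordinates and genotypes do not share samples")
    design = np.column_stack([np.ones(n), ref_coords.coords])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        logger.warning("rank-deficient PC design; using minimum-norm solution")
    betas, *_ = np.linalg.lstsq(design, g, rcond=None)
    if snp_ids is None:
        snp_ids = basis.snp_ids if basis is not None else list(range(m))
    return AFRegressionModel(snp_ids=list(snp_ids), betas=betas.T, basis=basis)


def predict_individual_af(
    model: AFRegressionModel, coords: PCCoordinates
) -> IndividualAFMatrix:
    """Evaluate p_im = (beta_m0 + sum_k beta_mk v_ik)/2, clamped to
    [0.001, 0.999]."""
    if coords.n_pcs != model.n_pcs:
        raise ValueError(
            f"coordinate dimension {coords.n_pcs} does not match model K={model.n_pcs}"
        )
    design = np.column_stack([np.ones(len(coords.sample_ids)), coords.coords])
    af = 0.5 * (design @ model.betas.T)
    af = np.clip(af, AF_CLAMP_LO, AF_CLAMP_HI)
    return IndividualAFMatrix(
        sample_ids=coords.sample_ids, snp_ids=model.snp_ids, af=af
    )
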
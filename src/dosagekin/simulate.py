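"""Synthetic data with known relatedness: admixed pedigrees, Balding-Nichols
structure, Mendelian gene dropping, and statistical emulation of genotype
imputation.

The generator produces the ground truth the estimators are judged against:

* Subpopulation allele frequencies drift from an ancestral frequency p under
  the Balding-Nichols model, p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F), so that
  E(p_k) = p and Var(p_k) = F p(1-p).
* Founders receive admixture proportions a_i (Dirichlet by default), giving
  individual-specific frequencies q_im = sum_k a_ik p_km, and genotypes
  G_im ~ Binomial(2, q_im) independently per SNP (no linkage).
* Non-founders are generated by gene dropping: each transmitted allele is
  alternative with probability (parental genotype)/2, independently per SNP.
* Imputed dosages satisfy the conditional-mean model
  E(G~ | G, GR) = (1 - r2) GR + r2 G with corr^2(G~, G) = r2; the default
  noise law is a bounded genotype-or-panel-mean mixture (see
  :func:`emulate_imputation`). The panel reports the nominal r2 (optionally
  an empirical re-estimate, to stress-test miscalibration).

Family templates (trios, full-sib quartets, three-generation units, first
cousin units, full-sib-mating units for inbreeding, singletons) provide
pairs of every relationship degree plus inbred individuals with f = 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import DosagePanel, SnpId, VariantFilter

__all__ = [
    "SimConfig",
    "SimTruth",
    "build_pedigree",
    "pedigree_kinship",
    "simulate_founders",
    "drop_genes",
    "emulate_imputation",
    "apply_variant_filters",
    "simulate_dataset",
    "true_degree_labels",
]

FOUNDER = -1


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated dataset.

    Defaults describe a two-way admixed cohort of 200 individuals genotyped
    at 20,000 unlinked SNPs with moderate differentiation (F_ST = 0.1) and
    imputation quality r2 ~ Uniform(0.5, 1) — the conditions used throughout
    the recovery experiments.
    """

    n_snps: int = 20_000
    n_subpops: int = 2
    fst: float = 0.1
    ancestral_maf_range: tuple = (0.05, 0.5)
    n_trios: int = 15
    n_fullsib_families: int = 10
    n_second_degree_units: int = 9
    n_first_cousin_units: int = 5
    n_inbred_units: int = 0
    n_unrelated: int = 30
    admixture: str | Sequence = "dirichlet"  # or fixed (n_subpops,) proportions
    dirichlet_alpha: float = 1.0
    rsq_dist: tuple = ("uniform", 0.5, 1.0)  # or ("fixed", value)
    n_reference: int = 100

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("F_ST must lie in [0, 1)")
        if self.n_snps < 1:
            raise ValueError("need at least one SNP")

    @property
    def n_individuals(self) -> int:
        return (
            3 * self.n_trios
            + 4 * self.n_fullsib_families
            + 5 * self.n_second_degree_units
            + 8 * self.n_first_cousin_units
            + 5 * self.n_inbred_units
            + self.n_unrelated
        )


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    pedigree: pd.DataFrame  # columns: id, father, mother (indices, -1 founder)
    genotypes: np.ndarray  # (N, M) in {0,1,2}
    ancestral_freq: np.ndarray  # (M,)
    subpop_freqs: np.ndarray  # (K, M)
    admixture: np.ndarray  # (N, K), rows sum to 1
    individual_freqs: np.ndarray  # (N, M): q_im = sum_k a_ik p_km
    kinship: np.ndarray  # (N, N) pedigree kinship, diag (1+f)/2
    ref_panel_mean: np.ndarray  # (M,): mean genotype of the imputation reference
    ref_genotypes: Optional[np.ndarray] = None  # unadmixed reference panel
    ref_admixture: Optional[np.ndarray] = None

    @property
    def sample_ids(self) -> list:
        return list(self.pedigree["id"])


# ---------------------------------------------------------------------------
# pedigree construction


def _add(rows, name, father=FOUNDER, mother=FOUNDER):
    rows.append({"id": name, "father": father, "mother": mother})
    return len(rows) - 1


def build_pedigree(config: SimConfig) -> pd.DataFrame:
    """Assemble the family templates into one pedigree table.

    Parents always precede children, so gene dropping and the kinship
    recursion can run in row order.
    """
    rows: list = []
    for t in range(config.n_trios):
        f = _add(rows, f"trio{t}_F")
        m = _add(rows, f"trio{t}_M")
        _add(rows, f"trio{t}_C", f, m)
    for t in range(config.n_fullsib_families):
        f = _add(rows, f"fs{t}_F")
        m = _add(rows, f"fs{t}_M")
        _add(rows, f"fs{t}_C1", f, m)
        _add(rows, f"fs{t}_C2", f, m)
    for t in range(config.n_second_degree_units):
        gf = _add(rows, f"g2_{t}_GF")
        gm = _add(rows, f"g2_{t}_GM")
        p = _add(rows, f"g2_{t}_P", gf, gm)
        s = _add(rows, f"g2_{t}_S")
        _add(rows, f"g2_{t}_C", p, s)
    for t in range(config.n_first_cousin_units):
        gf = _add(rows, f"cz{t}_GF")
        gm = _add(rows, f"cz{t}_GM")
        a = _add(rows, f"cz{t}_A", gf, gm)
        b = _add(rows, f"cz{t}_B", gf, gm)
        sa = _add(rows, f"cz{t}_SA")
        sb = _add(rows, f"cz{t}_SB")
        _add(rows, f"cz{t}_CA", a, sa)
        _add(rows, f"cz{t}_CB", b, sb)
    for t in range(config.n_inbred_units):
        f = _add(rows, f"ib{t}_F")
        m = _add(rows, f"ib{t}_M")
        a = _add(rows, f"ib{t}_A", f, m)
        b = _add(rows, f"ib{t}_B", f, m)
        _add(rows, f"ib{t}_I", a, b)  # full-sib mating: f = 0.25
    for t in range(config.n_unrelated):
        _add(rows, f"un{t}")
    return pd.DataFrame(rows)


def pedigree_kinship(pedigree: pd.DataFrame) -> np.ndarray:
    """Expected kinship matrix from the pedigree by the tabular recursion.

    phi_ii = 1/2 (1 + phi_fm); phi_ij = 1/2 (phi_fj + phi_mj) taking the
    recursion through whichever member of the pair is the later-born
    non-founder. Founder pairs are unrelated.
    """
    fa = pedigree["father"].to_numpy()
    mo = pedigree["mother"].to_numpy()
    n = len(pedigree)
    phi = np.zeros((n, n))
    for i in range(n):
        if fa[i] == FOUNDER:
            phi[i, i] = 0.5
        else:
            if fa[i] >= i or mo[i] >= i:
                raise ValueError("pedigree rows must list parents before children")
            phi[i, i] = 0.5 * (1.0 + phi[fa[i], mo[i]])
        for j in range(i):
            if fa[i] != FOUNDER:
                v = 0.5 * (phi[fa[i], j] + phi[mo[i], j])
            elif fa[j] != FOUNDER:
                v = 0.5 * (phi[i, fa[j]] + phi[i, mo[j]])
            else:
                v = 0.0
            phi[i, j] = phi[j, i] = v
    return phi


def true_degree_labels(phi_true: np.ndarray) -> dict:
    """Map exact pedigree kinship values to degree labels for pairs i < j.

    Values that match none of the canonical degrees (possible in inbred
    loops) are labeled 'other'.
    """
    canonical = {
        0.5: "MZ/duplicate",
        0.25: "PO/FS",
        0.125: "2nd",
        0.0625: "3rd",
        0.0: "unrelated",
    }
    labels = {}
    n = phi_true.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            lab = "other"
            for val, name in canonical.items():
                if abs(phi_true[i, j] - val) < 1e-12:
                    lab = name
                    break
            labels[(i, j)] = lab
    return labels


# ---------------------------------------------------------------------------
# genotypes


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _draw_admixture(config: SimConfig, n: int, rng) -> np.ndarray:
    if isinstance(config.admixture, str):
        if config.admixture != "dirichlet":
            raise ValueError(f"unknown admixture rule {config.admixture!r}")
        return rng.dirichlet(
            np.full(config.n_subpops, config.dirichlet_alpha), size=n
        )
    a = np.asarray(config.admixture, dtype=float)
    if a.shape != (config.n_subpops,) or not np.isclose(a.sum(), 1.0):
        raise ValueError("fixed admixture must be a simplex vector per subpop")
    return np.tile(a, (n, 1))


def simulate_founders(config: SimConfig, seed=None):
    """Draw structured founder genotypes under the Balding-Nichols model.

    Returns (ancestral_freq, subpop_freqs, admixture, individual_freqs,
    founder_genotypes) for ALL pedigree slots; non-founder rows carry their
    expected admixture (mean of parents) and q_im, with genotypes filled in
    later by :func:`drop_genes`.
    """
    rng = _as_rng(seed)
    ped = build_pedigree(config)
    m = config.n_snps
    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    if config.fst == 0.0:
        p_sub = np.tile(p_anc, (config.n_subpops, 1))
    else:
        F = config.fst
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("invalid Beta parameters for Balding-Nichols draw")
        p_sub = rng.beta(a, b, size=(config.n_subpops, m))
    founder = ped["father"].to_numpy() == FOUNDER
    admix = np.empty((len(ped), config.n_subpops))
    admix[founder] = _draw_admixture(config, int(founder.sum()), rng)
    fa, mo = ped["father"].to_numpy(), ped["mother"].to_numpy()
    for i in np.flatnonzero(~founder):
        admix[i] = 0.5 * (admix[fa[i]] + admix[mo[i]])
    q = admix @ p_sub
    g = np.full((len(ped), m), -1, dtype=np.int8)
    g[founder] = rng.binomial(2, q[founder]).astype(np.int8)
    return p_anc, p_sub, admix, q, g


def drop_genes(
    pedigree: pd.DataFrame, genotypes: np.ndarray, seed=None
) -> np.ndarray:
    """Fill non-founder genotypes by Mendelian gene dropping.

    Each transmitted allele is alternative with probability g_parent / 2,
    independently per SNP (unlinked loci); a parent's genotype fully
    determines its transmission law, so this is exact for biallelic SNPs.
    """
    rng = _as_rng(seed)
    g = np.array(genotypes, dtype=np.int8, copy=True)
    fa = pedigree["father"].to_numpy()
    mo = pedigree["mother"].to_numpy()
    m = g.shape[1]
    for i in range(len(pedigree)):
        if fa[i] == FOUNDER:
            if (g[i] < 0).any():
                raise ValueError(f"founder {i} has no genotypes")
            continue
        if (g[fa[i]] < 0).any() or (g[mo[i]] < 0).any():
            raise ValueError(f"parents of row {i} not yet genotyped")
        from_f = rng.random(m) < g[fa[i]] / 2.0
        from_m = rng.random(m) < g[mo[i]] / 2.0
        g[i] = from_f.astype(np.int8) + from_m.astype(np.int8)
    return g


# ---------------------------------------------------------------------------
# imputation emulation


def _draw_rsq(config: SimConfig, rng) -> np.ndarray:
    kind = config.rsq_dist[0]
    if kind == "uniform":
        return rng.uniform(config.rsq_dist[1], config.rsq_dist[2], size=config.n_snps)
    if kind == "fixed":
        return np.full(config.n_snps, float(config.rsq_dist[1]))
    raise ValueError(f"unknown rsq distribution {kind!r}")


def emulate_imputation(
    genotypes: np.ndarray,
    rsq: np.ndarray,
    ref_panel_mean: Optional[np.ndarray] = None,
    noise_af: Optional[np.ndarray] = None,
    seed=None,
    sample_ids=None,
    snp_ids=None,
    reestimate_rsq: bool = False,
    noise: str = "mixture",
) -> DosagePanel:
    """Turn true genotypes into imputed dosages with stated per-SNP r2.

    The dosage model fixes only the conditional mean,
    E(G~ | G, GR) = (1 - r2) GR + r2 G; the noise law is a modeling choice.
    Two are provided:

    ``noise="mixture"`` (default): G~ = B G + (1 - B) GR with
    B ~ Bernoulli(r2) independently per individual and SNP — an individual's
    genotype is either confidently recovered or falls back to the reference
    mean. This satisfies the conditional mean exactly, keeps dosages in
    [0, 2] by construction, and gives corr^2(G~, G) = r2 exactly under HWE
    at every MAF.

    ``noise="gaussian"``: G~ = (1-r2) GR + r2 G + eps with
    eps ~ N(0, r2 (1-r2) 2 p (1-p)), clipped to [0, 2]. Clipping is frequent
    at low MAF and attenuates the dosage-genotype regression, so this law is
    deliberately miscalibrated — useful for sensitivity analysis only.
    ``noise_af`` sets the p of the noise variance (default: per-SNP mean
    genotype / 2; an (N, M) matrix of individual frequencies is accepted).

    r2 = 0 sites emit the constant GR dosage. With ``reestimate_rsq`` the
    panel reports the empirical corr^2(G~, G) instead of the nominal r2.
    """
    rng = _as_rng(seed)
    g = np.asarray(genotypes, dtype=float)
    n, m = g.shape
    rsq = np.asarray(rsq, dtype=float)
    if rsq.shape != (m,):
        raise ValueError("rsq must be per-SNP")
    if ((rsq < 0) | (rsq > 1)).any():
        raise ValueError("rsq must lie in [0, 1]")
    if noise_af is None:
        noise_af = g.mean(axis=0) / 2.0
    noise_af = np.asarray(noise_af, dtype=float)
    if ref_panel_mean is None:
        ref_panel_mean = 2.0 * (noise_af if noise_af.ndim == 1 else noise_af.mean(axis=0))
    ref_panel_mean = np.asarray(ref_panel_mean, dtype=float)
    if noise == "mixture":
        recovered = rng.random((n, m)) < rsq
        dosages = np.where(recovered, g, ref_panel_mean)
    elif noise == "gaussian":
        var = rsq * (1.0 - rsq) * 2.0 * noise_af * (1.0 - noise_af)
        eps = rng.standard_normal((n, m)) * np.sqrt(np.broadcast_to(var, (n, m)))
        dosages = (1.0 - rsq) * ref_panel_mean + rsq * g + eps
        np.clip(dosages, 0.0, 2.0, out=dosages)
    else:
        raise ValueError(f"unknown noise law {noise!r}")
    if reestimate_rsq:
        gc = g - g.mean(axis=0)
        dc = dosages - dosages.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2_emp = (gc * dc).sum(axis=0) ** 2 / (
                (gc * gc).sum(axis=0) * (dc * dc).sum(axis=0)
            )
        rsq_out = np.clip(np.nan_to_num(r2_emp), 0.0, 1.0)
    else:
        rsq_out = rsq
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    if snp_ids is None:
        snp_ids = [SnpId("1", m_ + 1, "A", "C") for m_ in range(m)]
    return DosagePanel(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        dosages=dosages,
        rsq=rsq_out,
        ref_panel_mean=ref_panel_mean,
    )


def apply_variant_filters(
    panel: DosagePanel, maf_min: float = 0.05, rsq_min: float = 0.5
) -> DosagePanel:
    """Retain SNPs with MAF >= maf_min and r2 >= rsq_min (inclusive), in
    their original order. MAF is computed from the mean dosage."""
    return panel.subset_snps(
        VariantFilter(maf_min=maf_min, rsq_min=rsq_min).keep_mask(panel)
    )


# ---------------------------------------------------------------------------
# end-to-end convenience


def simulate_dataset(config: SimConfig, seed=None) -> tuple[SimTruth, DosagePanel]:
    """Generate a full dataset: pedigree, truth, and the imputed dosage panel.

    The imputation reference panel is a set of unadmixed individuals drawn
    round-robin from the subpopulations (``config.n_reference`` of them);
    its mean genotype provides GR for the dosage model, and its genotype
    matrix supports the reference-PCA / AF-regression pipeline.
    """
    rng = _as_rng(seed)
    ped = build_pedigree(config)
    p_anc, p_sub, admix, q, g = simulate_founders(config, rng)
    g = drop_genes(ped, g, rng)
    phi = pedigree_kinship(ped)

    ref_g = None
    ref_admix = None
    if config.n_reference > 0:
        pops = np.arange(config.n_reference) % config.n_subpops
        ref_admix = np.eye(config.n_subpops)[pops]
        ref_q = ref_admix @ p_sub
        ref_g = rng.binomial(2, ref_q).astype(np.int8)
        ref_mean = ref_g.mean(axis=0)
    else:
        ref_mean = 2.0 * p_anc

    rsq = _draw_rsq(config, rng)
    panel = emulate_imputation(
        g,
        rsq,
        ref_panel_mean=ref_mean,
        noise_af=p_anc,
        seed=rng,
        sample_ids=list(ped["id"]),
    )
    truth = SimTruth(
        pedigree=ped,
        genotypes=g,
        ancestral_freq=p_anc,
        subpop_freqs=p_sub,
        admixture=admix,
        individual_freqs=q,
        kinship=phi,
        ref_panel_mean=ref_mean,
        ref_genotypes=ref_g,
        ref_admixture=ref_admix,
    )
    return truth, panel
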
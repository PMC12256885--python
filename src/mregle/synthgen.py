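"""Synthetic multimodal waveform, genotype, covariate and phenotype generation.

The generators reproduce the statistical structure the pipeline assumes
rather than physiological realism: waveforms are smooth linear combinations
of shared and modality-specific latent factors (some of which may be driven
by genotype), genotypes are Hardy-Weinberg binomial dosages with optional
AR(1) linkage disequilibrium, and two purpose-built simulation models back
the calibration/power study (ten equicorrelated factors with a single
genetic effect) and the M-style vs U-style toy comparison (two modalities
sharing non-genetic factors F with a weak genetic factor s).

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .waveforms import MultimodalSample, WaveformRecord

__all__ = [
    "GenotypeMatrix",
    "LatentFactorModel",
    "ToyTwoModalityDraw",
    "hwe_exact_p",
    "simulate_genotypes",
    "simulate_correlated_factors",
    "simulate_toy_two_modality",
    "simulate_covariates",
    "simulate_multimodal_waveforms",
    "simulate_binary_phenotype",
    "COVARIATE_NAMES",
]

COVARIATE_NAMES = ["age", "sex", "bmi", "smoking", "array"] + [f"pc{i}" for i in range(1, 16)]


@dataclass
class GenotypeMatrix:
    """Dosage matrix plus per-variant metadata (chrom, pos, alleles, QC fields)."""

    sample_ids: list[str]
    dosages: np.ndarray  # (n, p) in [0, 2]
    variants: pd.DataFrame  # columns: id, chrom, pos, ref, alt, maf, info, missing_frac, hwe_p

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant table row count must equal the dosage column count")
        if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(self.dosages, initial=0.0) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"positions must be non-decreasing within chromosome {chrom}")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, (list, tuple, pd.Index)):
            mask = self.variants["id"].isin(list(mask_or_ids)).to_numpy()
        else:
            mask = np.asarray(mask_or_ids, dtype=bool)
        return GenotypeMatrix(
            self.sample_ids, self.dosages[:, mask], self.variants.loc[mask].reset_index(drop=True)
        )


def hwe_exact_p(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg equilibrium p-value for one biallelic variant.

    Sums the probabilities of all heterozygote counts (given the observed
    allele counts) that are no more likely than the observed one — the
    standard exact SNP-HWE construction.
    """
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # log-probabilities of every possible het count with the same parity
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    from scipy.special import gammaln

    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1) - gammaln(hets + 1) - gammaln(homr + 1) - gammaln(homc + 1)
        + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hets == n_het]
    if obs.size == 0:
        return 1.0
    return float(min(1.0, p[p <= obs[0] * (1 + 1e-12)].sum()))


def simulate_genotypes(n: int, p: int, maf=None, seed: int = 0, ar1_rho: float = 0.0,
                       chrom: str = "1", pos_start: int = 1_000_000,
                       pos_step: int = 10_000) -> GenotypeMatrix:
    """Hardy-Weinberg genotype dosages, optionally with AR(1) linkage.

    Each variant's dosage is the sum of two haplotype draws; with
    ``ar1_rho`` > 0 the haplotypes come from a Gaussian-copula AR(1) chain
    along the chromosome, inducing exponentially decaying LD between
    neighbouring variants (used by the clumping tests).  Variant metadata is
    filled consistently: the realized maf, info = 1, missing fraction = 0,
    and an exact HWE test p on the hard genotype counts.
    """
    rng = np.random.default_rng(seed)
    if maf is None:
        maf = rng.uniform(0.05, 0.5, size=p)
    maf = np.broadcast_to(np.asarray(maf, dtype=float), (p,)).copy()
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("maf must lie in (0, 0.5] elementwise")
    if not (0.0 <= ar1_rho < 1.0):
        raise ValueError("ar1_rho must lie in [0, 1)")

    from scipy.stats import norm

    def haplotypes() -> np.ndarray:
        if ar1_rho == 0.0:
            return (rng.random((n, p)) < maf).astype(float)
        z = np.empty((n, p))
        z[:, 0] = rng.standard_normal(n)
        innov = rng.standard_normal((n, p - 1)) if p > 1 else None
        for j in range(1, p):
            z[:, j] = ar1_rho * z[:, j - 1] + np.sqrt(1 - ar1_rho**2) * innov[:, j - 1]
        return (norm.cdf(z) < maf).astype(float)

    dosages = haplotypes() + haplotypes()

    hard = np.rint(dosages).astype(int)
    hwe = np.array([
        hwe_exact_p(int((hard[:, j] == 1).sum()), int((hard[:, j] == 0).sum()),
                    int((hard[:, j] == 2).sum()))
        for j in range(p)
    ])
    realized = dosages.mean(axis=0) / 2.0
    realized_maf = np.minimum(realized, 1.0 - realized)
    variants = pd.DataFrame({
        "id": [f"rs{j + 1}" for j in range(p)],
        "chrom": chrom,
        "pos": pos_start + pos_step * np.arange(p),
        "ref": "A",
        "alt": "G",
        "maf": realized_maf,
        "info": 1.0,
        "missing_frac": 0.0,
        "hwe_p": hwe,
        "monomorphic": dosages.std(axis=0) == 0.0,
    })
    sample_ids = [f"S{i:06d}" for i in range(n)]
    return GenotypeMatrix(sample_ids, dosages, variants)


def simulate_correlated_factors(x: np.ndarray, m: int = 10, rho: float = 0.0,
                                b1: float = 0.001, seed: int = 0) -> np.ndarray:
    """Ten (by default) equicorrelated factors with one genetic effect.

    Factor model F_j = X * b_j + e, where only the first factor carries the
    genetic effect (b_1 = ``b1``, the rest 0) and the noise rows are
    multivariate normal with unit variances and constant correlation ``rho``
    (covariance (1 - rho) I + rho J).
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    # equicorrelated noise: shared component + independent components
    shared = rng.standard_normal((n, 1))
    indep = rng.standard_normal((n, m))
    e = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep
    b = np.zeros(m)
    b[0] = b1
    return x[:, None] * b[None, :] + e


@dataclass
class ToyTwoModalityDraw:
    """One draw of the two-modality toy model.

    M1 ~ MVN([F, 0.1 s], I), M2 ~ MVN([F, 0.2 s], I), Y = 0.05 s + sum(F) + 0.8 e,
    with F (n x 2), s and e independent standard normal.  The non-genetic
    factors F dominate both modalities; the genetic factor s enters weakly.
    """

    F: np.ndarray
    s: np.ndarray
    M1: np.ndarray
    M2: np.ndarray
    Y: np.ndarray
    rng_seed: int


def simulate_toy_two_modality(n: int, seed: int = 0, noise_sd: float = 1.0,
                              y_noise_sd: float = 0.8,
                              f_combiner: np.ndarray | None = None) -> ToyTwoModalityDraw:
    """Draw the two-modality toy model at sample size ``n``.

    ``f_combiner`` sets how the two F columns enter the scalar phenotype;
    the default is the column sum (each column with weight 1).
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((n, 2))
    s = rng.standard_normal(n)
    M1 = np.column_stack([F, 0.1 * s]) + noise_sd * rng.standard_normal((n, 3))
    M2 = np.column_stack([F, 0.2 * s]) + noise_sd * rng.standard_normal((n, 3))
    comb = np.ones(2) if f_combiner is None else np.asarray(f_combiner, dtype=float)
    Y = 0.05 * s + F @ comb + y_noise_sd * rng.standard_normal(n)
    return ToyTwoModalityDraw(F, s, M1, M2, Y, seed)


def simulate_covariates(n: int, seed: int = 0, sample_ids: list[str] | None = None,
                        ) -> pd.DataFrame:
    """Covariate table: age, sex, BMI, smoking, genotyping array, 15 genetic PCs."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "age": rng.normal(58.0, 8.0, n),
        "sex": rng.integers(0, 2, n).astype(float),
        "bmi": rng.normal(27.0, 4.0, n),
        "smoking": (rng.random(n) < 0.45).astype(float),
        "array": (rng.random(n) < 0.9).astype(float),
    })
    for i in range(1, 16):
        df[f"pc{i}"] = rng.standard_normal(n)
    df.index = sample_ids if sample_ids is not None else [f"S{i:06d}" for i in range(n)]
    df.index.name = "sample_id"
    return df


def _smooth_basis(length: int, k: int, rng: np.random.Generator,
                  n_bumps: int = 8, n_harmonics: int = 4) -> np.ndarray:
    """Full-column-rank smooth loading basis: Gaussian bumps + low harmonics.

    The shapes are PQRST-like only in spirit; the contract is the linear
    latent-factor structure, not morphology.  Columns are random rotations
    of the bump/harmonic dictionary, orthonormalized so that the configured
    factor variances are exactly the waveforms' principal variances (and so
    distinct modalities load differently on the shared factors).
    """
    t = np.linspace(0.0, 1.0, length)
    cols = []
    centers = np.linspace(0.08, 0.92, n_bumps)
    width = 0.35 / n_bumps
    for c in centers:
        cols.append(np.exp(-0.5 * ((t - c) / width) ** 2))
    for h in range(1, n_harmonics + 1):
        cols.append(np.sin(2 * np.pi * h * t))
        cols.append(np.cos(2 * np.pi * h * t))
    D = np.stack(cols, axis=1)  # (length, n_dict)
    if k > D.shape[1]:
        raise ValueError(f"cannot build {k} independent loadings from {D.shape[1]} shapes")
    B = D @ rng.standard_normal((D.shape[1], k))
    if np.linalg.matrix_rank(B) < k:
        raise ValueError("loading basis is rank-deficient")
    Q, R = np.linalg.qr(B)
    return Q * np.sign(np.diag(R))


@dataclass
class LatentFactorModel:
    """Shared + modality-specific latent-factor model behind the waveforms.

    ``shared_var`` / ``specific_var`` are the factor variances (decaying by
    default so a per-modality latent budget truncates gracefully);
    ``genetic_factors`` lists the shared-factor indices whose values are
    partly determined by genotype, with heritability ``h2`` spread evenly
    over ``n_causal`` causal variants each.
    """

    k_shared: int = 6
    k_specific: dict[str, int] = field(default_factory=lambda: {"ECG_leadI": 4, "PPG": 3})
    shared_var: np.ndarray | None = None
    specific_var: dict[str, np.ndarray] | None = None
    genetic_factors: tuple[int, ...] = (2, 3)
    h2: float = 0.35
    n_causal: int = 3
    noise_sd: float = 0.05

    def resolved_shared_var(self) -> np.ndarray:
        if self.shared_var is not None:
            return np.asarray(self.shared_var, dtype=float)
        return 5.0 * 0.8 ** np.arange(self.k_shared)

    def resolved_specific_var(self, modality: str) -> np.ndarray:
        if self.specific_var is not None and modality in self.specific_var:
            return np.asarray(self.specific_var[modality], dtype=float)
        k = self.k_specific[modality]
        return 1.0 * 0.8 ** np.arange(k)

    @classmethod
    def reconstruction_benchmark(cls) -> "LatentFactorModel":
        """Richer factor structure (8 shared + 4 specific per modality) used
        for the multimodal-vs-unimodal reconstruction comparison."""
        return cls(
            k_shared=8,
            k_specific={"ECG_leadI": 4, "PPG": 4},
            genetic_factors=(),
            noise_sd=0.05,
        )


def simulate_multimodal_waveforms(
    n: int,
    model: LatentFactorModel | None = None,
    modality_lengths: dict[str, int] | None = None,
    genotypes: GenotypeMatrix | None = None,
    seed: int = 0,
    covariates: bool = True,
) -> tuple[list[MultimodalSample], pd.DataFrame, dict]:
    """Generate multimodal waveform samples with known latent structure.

    waveform_m = B_m [u, v_m] + noise, with u shared across modalities and
    v_m modality-specific.  If ``genotypes`` is given, each factor listed in
    ``model.genetic_factors`` is u_j = sqrt(h2) * (standardized genetic
    score) + sqrt(1 - h2) * noise, scaled to the factor's variance; the
    causal variants are disjoint across genetic factors.

    Returns (samples, truth table of latent values, info dict with the
    loading bases and causal-variant assignments).
    """
    model = model or LatentFactorModel()
    lengths = modality_lengths or {"ECG_leadI": 600, "PPG": 100}
    rng = np.random.default_rng(seed)

    shared_var = model.resolved_shared_var()
    u = rng.standard_normal((n, model.k_shared))
    causal: dict[int, pd.DataFrame] = {}
    if genotypes is not None and model.genetic_factors:
        if genotypes.n != n:
            raise ValueError("genotype sample count must match n")
        usable = np.flatnonzero(~genotypes.variants.get(
            "monomorphic", pd.Series(False, index=genotypes.variants.index)).to_numpy())
        picks = rng.choice(usable, size=model.n_causal * len(model.genetic_factors),
                           replace=False)
        for fi, j in enumerate(model.genetic_factors):
            idx = picks[fi * model.n_causal:(fi + 1) * model.n_causal]
            G = genotypes.dosages[:, idx]
            G = (G - G.mean(axis=0)) / G.std(axis=0)
            score = G @ np.ones(len(idx)) / np.sqrt(len(idx))
            u[:, j] = np.sqrt(model.h2) * score + np.sqrt(1 - model.h2) * rng.standard_normal(n)
            causal[j] = genotypes.variants.iloc[idx][["id", "chrom", "pos"]].assign(
                factor=j, weight=np.sqrt(model.h2 * shared_var[j] / len(idx)))
    u = u * np.sqrt(shared_var)

    bases: dict[str, np.ndarray] = {}
    truth = {f"shared_{j}": u[:, j] for j in range(model.k_shared)}
    sample_ids = (genotypes.sample_ids if genotypes is not None
                  else [f"S{i:06d}" for i in range(n)])
    cov = simulate_covariates(n, seed=rng.integers(2**31), sample_ids=sample_ids) \
        if covariates else None

    per_modality_values: dict[str, np.ndarray] = {}
    for m, L in lengths.items():
        kv = model.k_specific.get(m, 0)
        v = rng.standard_normal((n, kv)) * np.sqrt(model.resolved_specific_var(m)) \
            if kv else np.empty((n, 0))
        B = _smooth_basis(L, model.k_shared + kv, rng)
        z = np.concatenate([u, v], axis=1)
        per_modality_values[m] = z @ B.T + model.noise_sd * rng.standard_normal((n, L))
        bases[m] = B
        for j in range(kv):
            truth[f"{m}_specific_{j}"] = v[:, j]

    samples = []
    for i, sid in enumerate(sample_ids):
        wf = {m: WaveformRecord(sid, m, per_modality_values[m][i]) for m in lengths}
        cvs = dict(cov.loc[sid]) if cov is not None else {}
        samples.append(MultimodalSample(sid, wf, cvs))

    truth_df = pd.DataFrame(truth, index=pd.Index(sample_ids, name="sample_id"))
    info = {"bases": bases, "causal": causal, "model": model}
    return samples, truth_df, info


def simulate_binary_phenotype(latents: np.ndarray, prevalence: float = 0.15,
                              env_sd: float = 1.0, seed: int = 0,
                              weights: np.ndarray | None = None) -> np.ndarray:
    """Liability-threshold binary phenotype driven by latent factors.

    liability = latents @ weights + env noise; cases are the top
    ``prevalence`` fraction of the liability distribution.
    """
    rng = np.random.default_rng(seed)
    latents = np.asarray(latents, dtype=float)
    w = np.ones(latents.shape[1]) if weights is None else np.asarray(weights, dtype=float)
    liab = latents @ w + env_sd * rng.standard_normal(latents.shape[0])
    cut = np.quantile(liab, 1.0 - prevalence)
    return (liab > cut).astype(int)
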
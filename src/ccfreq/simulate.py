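"""Synthetic case/control GWAS generator and per-variant logistic fits.

The generator emulates a liability-threshold study: biallelic genotypes are
drawn under Hardy-Weinberg equilibrium with per-variant population MAFs, a
latent liability is composed of a standardized genetic score (from a random
subset of causal variants), an optional covariate score, and Gaussian noise,
and case status is assigned by ranking liability so that case/control counts
are exact.  Per-variant summary statistics (beta, SE, OR, p) come from one
additive-coded logistic regression per variant, optionally adjusted for the
covariates, fitted for all variants simultaneously by a batched Newton
solver.

Covariates follow the three-covariate layout of the emulated study design:
a binary covariate similar to biological sex (p = 0.5), a five-level
categorical covariate (dummy-coded with four indicators), and a continuous
covariate ~ Normal(mean 30, sd 20).  With ``n_covariates = 1`` only the
binary covariate is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_study",
    "fit_pervariant_logistic",
    "true_afs_from_split",
    "write_study",
]

logger = logging.getLogger(__name__)

_NEWTON_TOL = 1e-8
_NEWTON_MAX_ITER = 40
_CHUNK = 512


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for one simulated GWAS.

    Defaults mirror the simulated evaluation design: 10,000 variants of
    which 100 are causal, population MAFs uniform on (0.05, 0.5), a genetic
    liability-variance fraction of 0.2 and (when covariates are present) a
    covariate fraction of 0.2, the remainder observational noise.
    """

    n_case: int
    n_control: int
    n_variants: int = 10_000
    n_causal: int = 100
    n_covariates: int = 0
    genetic_variance_fraction: float = 0.2
    covariate_variance_fraction: float = 0.2
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_case and n_control must be >= 1")
        if not 0 <= self.n_causal <= self.n_variants:
            raise ValueError("need 0 <= n_causal <= n_variants")
        if self.n_covariates not in (0, 1, 3):
            raise ValueError("n_covariates must be 0, 1, or 3")
        g, c = self.genetic_variance_fraction, self.covariate_variance_fraction
        if g < 0 or c < 0 or g + (c if self.n_covariates else 0.0) >= 1:
            raise ValueError("variance fractions must be >= 0 and sum to < 1")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")


@dataclass
class SimulatedStudy:
    """Realized genotypes, phenotype, truth, and (optionally) fitted stats."""

    config: SimulationConfig
    genotypes: np.ndarray  # (n_individuals, n_variants) int8 dosages
    covariates: np.ndarray  # (n_individuals, k) regression design, no intercept
    phenotype: np.ndarray  # (n_individuals,) 0/1
    causal: np.ndarray  # (n_variants,) bool
    causal_effects: np.ndarray  # (n_variants,) liability effect per variant
    pop_maf: np.ndarray  # (n_variants,) sampling MAFs
    af_case: np.ndarray
    af_control: np.ndarray
    af_total: np.ndarray
    sumstats: pd.DataFrame | None = field(default=None, repr=False)


def _draw_covariates(rng: np.random.Generator, n: int, n_covariates: int) -> np.ndarray:
    cols = []
    if n_covariates >= 1:
        cols.append(rng.binomial(1, 0.5, n).astype(float))
    if n_covariates == 3:
        cat = rng.integers(0, 5, n)
        for level in range(1, 5):  # dummy-code 5 levels as 4 indicators
            cols.append((cat == level).astype(float))
        cols.append(rng.normal(30.0, 20.0, n))
    return np.column_stack(cols) if cols else np.empty((n, 0))


def _scaled_score(raw: np.ndarray, target_var: float) -> np.ndarray:
    """Center a raw score and rescale its realized variance to target_var."""
    raw = raw - raw.mean()
    sd = raw.std()
    if sd == 0.0:
        return np.zeros_like(raw)
    return raw * (np.sqrt(target_var) / sd)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate one study; all randomness flows from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control

    pop_maf = rng.uniform(*config.maf_range, config.n_variants)
    genotypes = rng.binomial(2, pop_maf, size=(n, config.n_variants)).astype(np.int8)

    causal = np.zeros(config.n_variants, dtype=bool)
    causal_idx = rng.choice(config.n_variants, size=config.n_causal, replace=False)
    causal[causal_idx] = True
    effects = np.zeros(config.n_variants)
    effects[causal_idx] = rng.normal(0.0, 1.0, config.n_causal)

    g_score = _scaled_score(
        genotypes[:, causal_idx].astype(float) @ effects[causal_idx],
        config.genetic_variance_fraction,
    )

    covariates = _draw_covariates(rng, n, config.n_covariates)
    if covariates.shape[1]:
        cov_std = (covariates - covariates.mean(0)) / np.where(
            covariates.std(0) == 0, 1.0, covariates.std(0)
        )
        cov_coef = rng.normal(0.0, 1.0, covariates.shape[1])
        c_score = _scaled_score(cov_std @ cov_coef, config.covariate_variance_fraction)
        cov_var = config.covariate_variance_fraction
    else:
        c_score = np.zeros(n)
        cov_var = 0.0

    noise_sd = np.sqrt(1.0 - config.genetic_variance_fraction - cov_var)
    liability = g_score + c_score + rng.normal(0.0, noise_sd, n)

    # exact counts: the n_case individuals with highest liability are cases
    order = np.argsort(liability, kind="stable")
    phenotype = np.zeros(n, dtype=np.int8)
    phenotype[order[-config.n_case:]] = 1

    af_case, af_control, af_total = _afs_from_arrays(
        genotypes, phenotype, config.n_case, config.n_control
    )
    return SimulatedStudy(
        config=config,
        genotypes=genotypes,
        covariates=covariates,
        phenotype=phenotype,
        causal=causal,
        causal_effects=effects,
        pop_maf=pop_maf,
        af_case=af_case,
        af_control=af_control,
        af_total=af_total,
    )


def _afs_from_arrays(genotypes, phenotype, n_case, n_control):
    case_mask = phenotype == 1
    af_case = genotypes[case_mask].sum(axis=0, dtype=np.int64) / (2.0 * n_case)
    af_control = genotypes[~case_mask].sum(axis=0, dtype=np.int64) / (2.0 * n_control)
    n_total = n_case + n_control
    af_total = (n_case * af_case + n_control * af_control) / n_total
    return af_case, af_control, af_total


def true_afs_from_split(study: SimulatedStudy):
    """Realized effect-allele frequencies from the case/control split."""
    return _afs_from_arrays(
        study.genotypes, study.phenotype, study.config.n_case, study.config.n_control
    )


def _batched_logistic(y: np.ndarray, C: np.ndarray, G: np.ndarray):
    """Newton-Raphson logistic fits for many variants at once.

    Parameters: ``y`` (n,) binary outcome; ``C`` (n, k0) shared columns
    (intercept plus covariates); ``G`` (n, V) per-variant genotype column.
    Returns (beta_g, se_g, converged), each (V,).

    The Hessian is assembled from shared-column cross products, so the cost
    per iteration is a handful of (k0, n) x (n, V) matrix products instead
    of V separate model fits.
    """
    n, k0 = C.shape
    V = G.shape[1]
    k = k0 + 1

    pair_idx = [(i, j) for i in range(k0) for j in range(i, k0)]
    P = np.column_stack([C[:, i] * C[:, j] for i, j in pair_idx])  # (n, npairs)

    beta = np.zeros((V, k))
    converged = np.zeros(V, dtype=bool)
    H = np.zeros((V, k, k))

    for _ in range(_NEWTON_MAX_ITER):
        eta = C @ beta[:, :k0].T + G * beta[:, k0]
        np.clip(eta, -30.0, 30.0, out=eta)
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        r = y[:, None] - mu

        grad = np.empty((V, k))
        grad[:, :k0] = (C.T @ r).T
        grad[:, k0] = np.einsum("nv,nv->v", G, r)

        Hcc = (P.T @ w).T  # (V, npairs)
        for m, (i, j) in enumerate(pair_idx):
            H[:, i, j] = Hcc[:, m]
            H[:, j, i] = Hcc[:, m]
        Hcg = (C.T @ (w * G)).T  # (V, k0)
        H[:, :k0, k0] = Hcg
        H[:, k0, :k0] = Hcg
        H[:, k0, k0] = np.einsum("nv,nv->v", G * G, w)

        try:
            delta = np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # singular fits (separation / collinearity): regularise lightly
            delta = np.linalg.solve(H + 1e-8 * np.eye(k), grad[..., None])[..., 0]
        beta += delta
        converged = np.max(np.abs(delta), axis=1) < _NEWTON_TOL
        if converged.all():
            break

    with np.errstate(invalid="ignore"):
        cov = np.linalg.inv(H)
        se_g = np.sqrt(cov[:, k0, k0])
    return beta[:, k0], se_g, converged


def fit_pervariant_logistic(
    study: SimulatedStudy, include_covariates: bool = False
) -> pd.DataFrame:
    """One additive-coded logistic regression per variant.

    Returns a DataFrame with columns ``beta``, ``se``, ``or``, ``p``.
    Monomorphic and non-converged variants get NaN rows (with a logged
    warning), never a global failure.
    """
    y = study.phenotype.astype(float)
    if y.min() == y.max():
        raise ValueError("phenotype must contain both cases and controls")
    n = y.size
    ones = np.ones((n, 1))
    C = np.hstack([ones, study.covariates]) if include_covariates else ones

    nv = study.genotypes.shape[1]
    beta = np.full(nv, np.nan)
    se = np.full(nv, np.nan)
    ok = np.zeros(nv, dtype=bool)

    mono = study.genotypes.min(axis=0) == study.genotypes.max(axis=0)
    if mono.any():
        logger.warning("%d monomorphic variants skipped", int(mono.sum()))
    poly_idx = np.flatnonzero(~mono)

    for start in range(0, poly_idx.size, _CHUNK):
        idx = poly_idx[start : start + _CHUNK]
        G = study.genotypes[:, idx].astype(float)
        b, s, conv = _batched_logistic(y, C, G)
        good = conv & np.isfinite(b) & np.isfinite(s) & (s > 0)
        beta[idx[good]] = b[good]
        se[idx[good]] = s[good]
        ok[idx[good]] = True

    n_bad = int((~ok & ~mono).sum())
    if n_bad:
        logger.warning("%d variants failed to converge", n_bad)

    with np.errstate(invalid="ignore"):
        z = np.abs(beta) / se
    p = 2.0 * norm.sf(z)
    fits = pd.DataFrame(
        {"beta": beta, "se": se, "or": np.exp(beta), "p": p}
    )
    study.sumstats = fits
    return fits


def write_study(study: SimulatedStudy, fits: pd.DataFrame, sumstats_path, truth_path) -> None:
    """Write the fitted summary statistics and the truth table as TSV.

    Variants are laid out on chromosome 1 at consecutive positions with
    synthetic A (other) / G (effect) alleles so that outputs can round-trip
    through the summary-statistics reader.
    """
    nv = study.genotypes.shape[1]
    base = pd.DataFrame(
        {
            "chromosome": np.ones(nv, dtype=int),
            "base_pair_location": np.arange(1, nv + 1),
            "effect_allele": "G",
            "other_allele": "A",
        }
    )
    sumstats = base.assign(
        beta=fits["beta"].to_numpy(),
        odds_ratio=fits["or"].to_numpy(),
        standard_error=fits["se"].to_numpy(),
        p_value=fits["p"].to_numpy(),
        effect_allele_frequency=study.af_total,
    )
    sumstats.to_csv(sumstats_path, sep="\t", index=False, na_rep="NA")

    truth = base.assign(
        af_case=study.af_case,
        af_control=study.af_control,
        af_total=study.af_total,
        causal=study.causal.astype(int),
    )
    truth.to_csv(truth_path, sep="\t", index=False, na_rep="NA")


def export_vcf(study: SimulatedStudy, path) -> None:
    """Minimal GT-only VCF export of the simulated genotypes."""
    nv = study.genotypes.shape[1]
    n = study.genotypes.shape[0]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"S{i}" for i in range(n))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for v in range(nv):
            gts = "\t".join(gt_map[int(g)] for g in study.genotypes[:, v])
            fh.write(f"1\t{v + 1}\tvar{v + 1}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
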
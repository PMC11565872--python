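"""Proxy-panel bias correction for SE-derived MAF estimates.

When the originating GWAS adjusted for covariates, the reported log-OR
standard errors are not the plain 2x2-table standard errors, and the
SE-based reconstruction systematically underestimates common-variant MAFs.
To remove this bias without individual-level data, a reference panel of
proxy MAFs (e.g. a gnomAD population export) stands in for the truth:
within five MAF bins ([0.0, 0.1), [0.1, 0.2), [0.2, 0.3), [0.3, 0.4),
[0.4, 0.5]) a second-order polynomial is fitted with the estimated total
MAF as the outcome and the proxy MAF as the predictor.  The fitted bias at
MAF x is B(x) = poly(x) - x, and the correction subtracts B (evaluated at
each variant's estimated total MAF) from the case, control, and total MAF
estimates -- including variants absent from the proxy panel.

Before fitting, GWAS and proxy variants are harmonized by chromosome and
position: allele-pair mismatches are removed, and proxy frequencies
anchored to the opposing allele are flipped (f -> 1 - f) before folding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FIT_BINS",
    "BiasModel",
    "harmonize",
    "fit_bias_model",
    "apply_bias_correction",
]

logger = logging.getLogger(__name__)

#: fitting bins: left-closed, right-open except the last ([0.4, 0.5])
FIT_BINS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
#: bins with fewer pairs than this borrow the nearest populated bin's fit
MIN_FIT_COUNT = 30


def _norm_chrom(c) -> str:
    return str(c).removeprefix("chr")


def _check_unique(df: pd.DataFrame, name: str) -> None:
    dup = df.duplicated(subset=["_key"], keep=False)
    if dup.any():
        offenders = df.loc[dup, "_key"].unique()[:10].tolist()
        raise ValueError(f"duplicate variant keys in {name}: {offenders}")


def harmonize(gwas: pd.DataFrame, proxy: pd.DataFrame) -> pd.DataFrame:
    """Match GWAS estimates with proxy-panel frequencies by position.

    Parameters
    ----------
    gwas
        Columns ``chrom, pos, effect_allele, other_allele,
        estimated_total_maf`` (the SE-route total-MAF estimates).
    proxy
        Columns ``chrom, pos, allele1, allele2, freq`` where ``freq`` is
        anchored to ``allele1`` (it may exceed 0.5; it is folded to a MAF
        after any flip).

    Returns
    -------
    DataFrame with columns ``chrom, pos, estimated_total_maf, proxy_maf,
    flip_applied`` -- the intersection of the two inputs after removing
    allele-pair mismatches.  Duplicate keys in either input and an empty
    overlap raise ``ValueError``.
    """
    g = gwas.copy()
    p = proxy.copy()
    g["_key"] = g["chrom"].map(_norm_chrom) + ":" + g["pos"].astype(int).astype(str)
    p["_key"] = p["chrom"].map(_norm_chrom) + ":" + p["pos"].astype(int).astype(str)
    _check_unique(g, "gwas")
    _check_unique(p, "proxy")

    merged = g.merge(p[["_key", "allele1", "allele2", "freq"]], on="_key", how="inner")
    if merged.empty:
        raise ValueError("no overlapping variants between GWAS and proxy panel")

    ea = merged["effect_allele"].str.upper()
    oa = merged["other_allele"].str.upper()
    a1 = merged["allele1"].str.upper()
    a2 = merged["allele2"].str.upper()

    same = (a1 == ea) & (a2 == oa)
    flipped = (a1 == oa) & (a2 == ea)
    keep = same | flipped
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("harmonize: removed %d allele-mismatched variants", n_removed)
    merged = merged[keep].copy()
    if merged.empty:
        raise ValueError("no variants left after allele harmonization")

    flip = flipped[keep].to_numpy()
    freq = merged["freq"].to_numpy(dtype=float)
    freq = np.where(flip, 1.0 - freq, freq)
    merged["proxy_maf"] = np.minimum(freq, 1.0 - freq)
    merged["flip_applied"] = flip
    out = merged[["chrom", "pos", "estimated_total_maf", "proxy_maf", "flip_applied"]]
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class BiasModel:
    """Per-bin quadratic maps from proxy MAF to estimated MAF.

    ``coefficients`` is a (5, 3) array of (b0, b1, b2) per bin; ``counts``
    the pairs used per bin; ``fallback_from`` records, for each bin, the
    index of the bin whose polynomial it borrowed (its own index if fitted
    directly).  The estimated bias at MAF x in bin k is
    ``B(x) = b0 + b1 x + b2 x^2 - x``.
    """

    coefficients: np.ndarray
    counts: np.ndarray
    fallback_from: np.ndarray
    bins: tuple = FIT_BINS

    def bias(self, maf) -> np.ndarray:
        """Evaluate B(x) with bin assignment by x itself."""
        maf = np.asarray(maf, dtype=float)
        k = assign_bins(maf)
        b = self.coefficients[k]
        pred = b[..., 0] + b[..., 1] * maf + b[..., 2] * maf**2
        return pred - maf


def assign_bins(maf, bins=FIT_BINS) -> np.ndarray:
    """Left-closed bin index in 0..4; exact internal edges go up a bin."""
    maf = np.asarray(maf, dtype=float)
    edges = np.asarray(bins)[1:-1]
    return np.searchsorted(edges, maf, side="right").clip(0, len(bins) - 2)


def fit_bias_model(pairs: pd.DataFrame, min_fit_count: int = MIN_FIT_COUNT) -> BiasModel:
    """OLS quadratic of estimated on proxy MAF within each proxy-MAF bin.

    Bins with fewer than ``min_fit_count`` pairs borrow the nearest
    populated bin's polynomial (logged); if every bin is under-populated a
    ``ValueError`` is raised.
    """
    proxy = pairs["proxy_maf"].to_numpy(dtype=float)
    est = pairs["estimated_total_maf"].to_numpy(dtype=float)
    keep = np.isfinite(proxy) & np.isfinite(est)
    proxy, est = proxy[keep], est[keep]

    n_bins = len(FIT_BINS) - 1
    which = assign_bins(proxy)
    coef = np.full((n_bins, 3), np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for k in range(n_bins):
        mask = which == k
        counts[k] = int(mask.sum())
        if counts[k] >= max(min_fit_count, 3):
            X = np.vander(proxy[mask], 3, increasing=True)
            coef[k], *_ = np.linalg.lstsq(X, est[mask], rcond=None)

    fitted = np.flatnonzero(np.isfinite(coef[:, 0]))
    if fitted.size == 0:
        raise ValueError(
            f"no MAF bin reaches the minimum fit count ({min_fit_count}); "
            "cannot fit a bias model"
        )
    fallback = np.arange(n_bins)
    for k in range(n_bins):
        if k not in fitted:
            nearest = fitted[np.argmin(np.abs(fitted - k))]
            coef[k] = coef[nearest]
            fallback[k] = nearest
            logger.warning(
                "bias bin %d has %d < %d pairs; borrowing bin %d",
                k, counts[k], min_fit_count, nearest,
            )
    return BiasModel(coefficients=coef, counts=counts, fallback_from=fallback)


def apply_bias_correction(estimates: pd.DataFrame, model: BiasModel) -> pd.DataFrame:
    """Append bias-adjusted MAF columns to SE-route estimates.

    ``estimates`` must carry ``maf_case``, ``maf_control``, ``maf_total``.
    Each variant's bias is evaluated from the polynomial of the bin its
    *estimated* total MAF falls in (the only quantity available for
    variants absent from the proxy panel), and the same B is subtracted
    from the case, control, and total MAFs.  Results are clamped to
    [0, 0.5] and appended as ``maf_case_adj``, ``maf_control_adj``,
    ``maf_total_adj``; original columns are preserved.
    """
    total = estimates["maf_total"].to_numpy(dtype=float)
    finite = np.isfinite(total)
    if ((total[finite] < 0) | (total[finite] > 0.5)).any():
        raise ValueError("maf_total estimates must lie in [0, 0.5]")

    bias = np.full_like(total, np.nan)
    bias[finite] = model.bias(total[finite])

    out = estimates.copy()
    for col in ("maf_case", "maf_control", "maf_total"):
        adj = estimates[col].to_numpy(dtype=float) - bias
        out[col + "_adj"] = np.clip(adj, 0.0, 0.5)
    return out
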
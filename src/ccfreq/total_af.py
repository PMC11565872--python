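"""Case/control allele frequencies from OR, total AF and sample sizes.

Given a variant's per-allele odds ratio ``OR``, the effect-allele frequency
``AF_total`` pooled over cases and controls, and the case/control sample
sizes, the case and control frequencies are identified exactly: the pooled
frequency is the sample-size-weighted mean

    AF_total = (Ncase * AF_case + Ncontrol * AF_control) / Ntotal

and the allelic odds ratio of the implied 2x2 allele-count table is

    OR = AF_case * (1 - AF_control) / ((1 - AF_case) * AF_control).

Eliminating ``AF_case`` leaves a quadratic in ``AF_control``,

    A x^2 + B x + C = 0,
    A = (Ncontrol / Ncase) * (OR - 1)
    B = OR * (1 - (Ntotal / Ncase) * AF_total)
        + (Ncontrol + Ntotal * AF_total) / Ncase
    C = -(Ntotal / Ncase) * AF_total,

which has exactly one root in [0, 1]; ``AF_case`` then follows from the
weighted-mean identity.  Both outputs stay anchored to the effect allele, so
no information about which allele is minor is lost.

The inputs are noiseless algebra: when (OR, AF_total) come from an actual
allele-count table the reconstruction is exact to floating point.  With
estimated ORs the only error is the sampling noise of the OR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AFInputs",
    "CaseControlAF",
    "solve_casecontrol_af",
    "solve_casecontrol_af_batch",
    "or_from_beta",
    "se_from_beta_p",
]

logger = logging.getLogger(__name__)

#: roots within [-ROOT_TOL, 1 + ROOT_TOL] are accepted and clamped to [0, 1]
ROOT_TOL = 1e-8


@dataclass(frozen=True)
class AFInputs:
    """Per-variant inputs for the total-AF reconstruction.

    Parameters
    ----------
    or_value
        Per-effect-allele odds ratio; positive and finite.
    af_total
        Effect-allele frequency in the pooled (case + control) sample,
        in [0, 1].  This must be an allele-anchored frequency, not a
        folded MAF.
    n_case, n_control
        Number of case and control individuals.
    """

    or_value: float
    af_total: float
    n_case: float
    n_control: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.or_value) or self.or_value <= 0:
            raise ValueError(f"odds ratio must be positive and finite, got {self.or_value}")
        if not 0.0 <= self.af_total <= 1.0:
            raise ValueError(f"af_total must lie in [0, 1], got {self.af_total}")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("sample sizes must be >= 1")


@dataclass(frozen=True)
class CaseControlAF:
    """Reconstructed effect-allele frequencies for cases and controls."""

    af_case: float
    af_control: float


def _solve_quadratic_root(A, B, C):
    """Vectorised stable quadratic solve returning the root in [0, 1].

    Uses the formulation q = -(B + sign(B) sqrt(disc)) / 2 with roots q/A and
    C/q, which avoids cancellation when ``B**2`` dominates ``4*A*C`` (rare
    variants).  Inputs are broadcast arrays; NaN is returned where no root
    falls inside the tolerance window.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)

    out = np.full(np.broadcast(A, B, C).shape, np.nan)

    linear = np.abs(A) == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        lin_root = np.where(B != 0, -C / B, np.nan)

    disc = B * B - 4.0 * A * C
    valid = (~linear) & (disc >= 0)
    sqrt_disc = np.sqrt(np.where(valid, disc, 0.0))
    sgn = np.where(B >= 0, 1.0, -1.0)
    q = -0.5 * (B + sgn * sqrt_disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(valid, q / A, np.nan)
        r2 = np.where(valid & (q != 0), C / q, np.nan)

    def in_window(r):
        return np.isfinite(r) & (r >= -ROOT_TOL) & (r <= 1.0 + ROOT_TOL)

    take2 = in_window(r2)
    out = np.where(take2, r2, out)
    take1 = in_window(r1)
    out = np.where(take1, r1, out)  # prefer the stable larger-magnitude branch pair order
    out = np.where(linear, np.where(in_window(lin_root), lin_root, np.nan), out)
    return np.clip(out, 0.0, 1.0)  # NaN propagates through clip


def _solve_af_arrays(or_value, af_total, n_case, n_control):
    """Vectorised core: arrays in, (af_case, af_control) arrays out.

    Invalid rows (non-finite or non-positive OR, af_total outside [0, 1])
    and rows with no admissible root yield NaN.
    """
    or_value = np.asarray(or_value, dtype=float)
    af_total = np.asarray(af_total, dtype=float)
    n_case = np.asarray(n_case, dtype=float)
    n_control = np.asarray(n_control, dtype=float)
    n_total = n_case + n_control

    bad = (
        ~np.isfinite(or_value)
        | (or_value <= 0)
        | ~np.isfinite(af_total)
        | (af_total < 0)
        | (af_total > 1)
    )

    A = (n_control / n_case) * (or_value - 1.0)
    B = or_value * (1.0 - (n_total / n_case) * af_total) + (
        n_control + n_total * af_total
    ) / n_case
    C = -(n_total / n_case) * af_total

    A = np.where(bad, np.nan, A)
    af_control = _solve_quadratic_root(np.where(bad, np.nan, A), B, C)
    af_case = (n_total / n_case) * af_total - (n_control / n_case) * af_control
    af_case = np.clip(af_case, 0.0, 1.0)
    af_case = np.where(np.isfinite(af_control), af_case, np.nan)
    return af_case, af_control


def solve_casecontrol_af(inputs: AFInputs) -> CaseControlAF:
    """Reconstruct case and control effect-allele frequencies for one variant.

    Solves the quadratic in ``AF_control`` and selects the unique root in
    [0, 1] (with an ``OR = 1`` input the quadratic degenerates and the
    linear solution ``AF_control = AF_case = AF_total`` is exact).

    Raises
    ------
    ValueError
        If the inputs violate their invariants (via :class:`AFInputs`).
    ArithmeticError
        If no root falls within the tolerance window around [0, 1].
    """
    af_case, af_control = _solve_af_arrays(
        inputs.or_value, inputs.af_total, inputs.n_case, inputs.n_control
    )
    if not np.isfinite(af_control):
        raise ArithmeticError(
            f"no allele-frequency root in [0, 1] for OR={inputs.or_value}, "
            f"af_total={inputs.af_total}"
        )
    return CaseControlAF(af_case=float(af_case), af_control=float(af_control))


def solve_casecontrol_af_batch(records) -> list[CaseControlAF | None]:
    """Element-wise :func:`solve_casecontrol_af`; failures become ``None``.

    Accepts an iterable of :class:`AFInputs`.  Invalid rows are logged and
    reported as ``None`` rather than aborting the batch.
    """
    results: list[CaseControlAF | None] = []
    n_failed = 0
    for i, rec in enumerate(records):
        try:
            results.append(solve_casecontrol_af(rec))
        except (ValueError, ArithmeticError) as exc:
            n_failed += 1
            logger.warning("record %d failed: %s", i, exc)
            results.append(None)
    if n_failed:
        logger.warning("%d of %d records failed reconstruction", n_failed, len(results))
    return results


def or_from_beta(beta: float) -> float:
    """Odds ratio from a log-odds effect estimate: ``exp(beta)``."""
    beta = float(beta)
    if not np.isfinite(beta):
        raise ValueError(f"beta must be finite, got {beta}")
    return float(np.exp(beta))


def se_from_beta_p(beta: float, p: float) -> float:
    """Standard error of the log OR from the effect estimate and p-value.

    Inverts the two-sided Wald test: ``SE = |beta| / z`` with
    ``z = Phi^{-1}(1 - p/2)``.  For p-values at the double-precision
    underflow boundary the z-score is unrecoverable and an ``OverflowError``
    is raised; use the test statistic directly in that case.
    """
    from scipy.stats import norm

    beta = float(beta)
    p = float(p)
    if not np.isfinite(beta) or beta == 0.0:
        raise ValueError("beta must be finite and non-zero to recover SE from a p-value")
    if p < np.finfo(float).tiny:  # includes p <= 0 and subnormal underflow
        raise OverflowError(
            "p-value underflowed below the double-precision normal range; "
            "derive the SE from the test statistic instead"
        )
    if p >= 1.0:
        raise ValueError(f"p-value must lie in (0, 1), got {p}")
    z = norm.isf(p / 2.0)
    if not np.isfinite(z) or z <= 0:
        raise OverflowError(
            "p-value too small to yield a finite normal quantile; "
            "derive the SE from the test statistic instead"
        )
    return abs(beta) / z
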
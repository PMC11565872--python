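"""Case/control minor allele frequencies from OR and the SE of the log OR.

The log-OR standard error of an allelic 2x2 table (allele counts ``a, b`` in
cases and ``c, d`` in controls) is ``SE^2 = 1/a + 1/b + 1/c + 1/d``, and the
odds ratio is ``OR = a d / (b c)``.  With the group allele numbers
``m1 = a + b`` (cases; 2*Ncase for autosomes) and ``m0 = c + d`` (controls)
this is a four-equation system in four unknowns.  Eliminating ``a, b, c``
yields a quadratic in ``d``::

    A d^2 + B d + C = 0
    A = (OR - 1)^2 + OR * SE^2 * m1
    B = -OR * m0 * (2 * (OR - 1) + SE^2 * m1)
    C = OR * m0 * (OR * m0 + m1)

(the cubic obtained by clearing denominators has a spurious root at d = 0).

Root ambiguity and the minor-allele convention
----------------------------------------------
The two roots materialise a table ``T = (a, b, c, d)`` and its
case-control-and-allele mirror ``(d, c, b, a)``, which share OR, SE and (for
balanced designs) the allele numbers.  The inverse problem is therefore
two-valued, and which candidate is the truth cannot be decided from the
summary statistics alone.  Following the convention that the frequency being
reconstructed is the minor allele's, this module selects the root whose
table has both group effect-allele frequencies <= 0.5 ("minor-concordant").
On that class the round trip is exact; for a variant whose minor allele
differs between cases and controls (frequencies straddling 0.5) the returned
pair may be the case/control mirror of the truth.  In practice the two
candidates differ by at most |maf_case - maf_control|, which is small for
the modest effect sizes typical of GWAS.

Outputs are folded minor allele frequencies in [0, 0.5]; the link between
the reported effect allele and the estimated frequency is lost by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "SEInputs",
    "AlleleTable",
    "CaseControlMAF",
    "SexChromosomeCounts",
    "solve_casecontrol_se",
    "solve_casecontrol_se_batch",
    "allele_numbers_for_sex_chromosome",
]

logger = logging.getLogger(__name__)

# relative discriminant tolerance below which a double root is assumed (OR ~ 1)
_DISC_TOL = 1e-12
# admissible cells must lie in (CELL_TOL, m - CELL_TOL) scaled by allele number
_CELL_TOL = 1e-9


@dataclass(frozen=True)
class SEInputs:
    """Per-variant inputs for the SE-based reconstruction.

    ``alleles_case``/``alleles_control`` are total allele numbers per group:
    ``2 * N`` for autosomes, karyotype-dependent for X/Y (see
    :func:`allele_numbers_for_sex_chromosome`).
    """

    or_value: float
    se_value: float
    alleles_case: float
    alleles_control: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.or_value) or self.or_value <= 0:
            raise ValueError(f"odds ratio must be positive and finite, got {self.or_value}")
        if not np.isfinite(self.se_value) or self.se_value <= 0:
            raise ValueError(f"SE must be positive and finite, got {self.se_value}")
        if self.alleles_case < 2 or self.alleles_control < 2:
            raise ValueError("allele numbers must be >= 2 per group")


@dataclass(frozen=True)
class AlleleTable:
    """Real-valued allele-count table (a, b: cases; c, d: controls)."""

    a: float
    b: float
    c: float
    d: float

    @property
    def or_value(self) -> float:
        return (self.a * self.d) / (self.b * self.c)

    @property
    def se_value(self) -> float:
        return float(np.sqrt(1 / self.a + 1 / self.b + 1 / self.c + 1 / self.d))


@dataclass(frozen=True)
class CaseControlMAF:
    """Folded minor allele frequencies; no allele anchoring."""

    maf_case: float
    maf_control: float
    maf_total: float


@dataclass(frozen=True)
class SexChromosomeCounts:
    """Individuals per sex-chromosome karyotype in each group."""

    n_xx_case: int
    n_xy_case: int
    n_xx_control: int
    n_xy_control: int

    def __post_init__(self) -> None:
        for name in ("n_xx_case", "n_xy_case", "n_xx_control", "n_xy_control"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_xx_case + self.n_xy_case == 0 or self.n_xx_control + self.n_xy_control == 0:
            raise ValueError("each group needs at least one individual")


def allele_numbers_for_sex_chromosome(
    counts: SexChromosomeCounts, chromosome: Literal["X", "Y"]
) -> tuple[float, float]:
    """Group allele numbers for X or Y given karyotype counts.

    X: two alleles per XX individual, one per XY.  Y: one allele per XY
    individual, none per XX.
    """
    if chromosome == "X":
        case = 2 * counts.n_xx_case + counts.n_xy_case
        control = 2 * counts.n_xx_control + counts.n_xy_control
    elif chromosome == "Y":
        case = counts.n_xy_case
        control = counts.n_xy_control
    else:
        raise ValueError(f"chromosome must be 'X' or 'Y', got {chromosome!r}")
    if case == 0 or control == 0:
        raise ValueError(f"zero {chromosome} alleles in one group")
    return float(case), float(control)


def _solve_se_arrays(or_value, se_value, alleles_case, alleles_control):
    """Vectorised core returning (maf_case, maf_control, maf_total) arrays.

    NaN marks rows with no admissible table (inconsistent OR/SE pair).
    """
    R = np.asarray(or_value, dtype=float)
    V = np.asarray(se_value, dtype=float) ** 2
    m1 = np.asarray(alleles_case, dtype=float)
    m0 = np.asarray(alleles_control, dtype=float)

    bad = (
        ~np.isfinite(R)
        | (R <= 0)
        | ~np.isfinite(V)
        | (V <= 0)
        | (m1 < 2)
        | (m0 < 2)
    )
    R = np.where(bad, np.nan, R)

    A = (R - 1.0) ** 2 + R * V * m1
    B = -R * m0 * (2.0 * (R - 1.0) + V * m1)
    C = R * m0 * (R * m0 + m1)

    disc = B * B - 4.0 * A * C
    near_zero = np.abs(disc) < _DISC_TOL * B * B
    disc = np.where(near_zero, 0.0, disc)
    ok = disc >= 0
    sqrt_disc = np.sqrt(np.where(ok, disc, np.nan))

    # A > 0 always (sum of a square and a positive term), so no linear branch
    d_roots = np.stack([(-B + sqrt_disc) / (2 * A), (-B - sqrt_disc) / (2 * A)])

    # materialise the table for each root:
    # a = R * m1 * (m0 - d) / (R * m0 - (R - 1) * d), b = m1 - a, c = m0 - d
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = R * m0 - (R - 1.0) * d_roots
        a = R * m1 * (m0 - d_roots) / denom
    b = m1 - a
    c = m0 - d_roots
    d = d_roots

    tol1 = _CELL_TOL * m1
    tol0 = _CELL_TOL * m0
    feasible = (
        np.isfinite(a)
        & (a > tol1)
        & (b > tol1)
        & (c > tol0)
        & (d > tol0)
    )
    # minor-allele convention: prefer the root whose table has both group
    # effect frequencies <= 0.5 (the mirror root has both >= 0.5)
    p_case = a / m1
    p_control = c / m0
    minor_conc = feasible & (p_case <= 0.5 + _CELL_TOL) & (p_control <= 0.5 + _CELL_TOL)
    control_minor = feasible & (p_control <= 0.5 + _CELL_TOL)

    # selection score: minor-concordant > control-minor > merely feasible
    score = feasible.astype(int) + control_minor.astype(int) + minor_conc.astype(int)
    choice = np.argmax(score, axis=0)
    none_ok = ~np.any(feasible, axis=0)

    take = lambda arr: np.take_along_axis(arr, choice[None, ...], axis=0)[0]
    a_s, c_s = take(a), take(c)
    f_case = a_s / m1
    f_control = c_s / m0
    maf_case = np.minimum(f_case, 1.0 - f_case)
    maf_control = np.minimum(f_control, 1.0 - f_control)
    min_count = np.minimum(a_s, m1 - a_s) + np.minimum(c_s, m0 - c_s)
    maf_total = min_count / (m1 + m0)
    maf_total = np.minimum(maf_total, 1.0 - maf_total)

    nan = np.where(none_ok | bad, np.nan, 0.0)
    return maf_case + nan, maf_control + nan, maf_total + nan


def solve_casecontrol_se(inputs: SEInputs) -> CaseControlMAF:
    """Reconstruct case/control/total minor allele frequencies for one variant.

    Solves the quadratic in the control non-effect allele count ``d``,
    materialises the allele table for each root, keeps the admissible
    (all-cells-positive, minor-concordant where possible) table, and folds
    each group frequency to [0, 0.5].  ``maf_total`` is the allele-number-
    weighted minor-allele count fraction, consistent with the folding.

    Raises
    ------
    ValueError
        If inputs violate their invariants (via :class:`SEInputs`).
    ArithmeticError
        If the OR/SE pair admits no positive allele table (negative
        discriminant, or every root yields an out-of-range cell).
    """
    maf_case, maf_control, maf_total = _solve_se_arrays(
        inputs.or_value, inputs.se_value, inputs.alleles_case, inputs.alleles_control
    )
    if not np.isfinite(maf_case):
        raise ArithmeticError(
            f"no positive allele table consistent with OR={inputs.or_value}, "
            f"SE={inputs.se_value} at allele numbers "
            f"({inputs.alleles_case}, {inputs.alleles_control})"
        )
    return CaseControlMAF(
        maf_case=float(maf_case),
        maf_control=float(maf_control),
        maf_total=float(maf_total),
    )


def solve_casecontrol_se_batch(records) -> list[CaseControlMAF | None]:
    """Element-wise :func:`solve_casecontrol_se`; failures become ``None``."""
    results: list[CaseControlMAF | None] = []
    n_failed = 0
    for i, rec in enumerate(records):
        try:
            results.append(solve_casecontrol_se(rec))
        except (ValueError, ArithmeticError) as exc:
            n_failed += 1
            logger.warning("record %d failed: %s", i, exc)
            results.append(None)
    if n_failed:
        logger.warning("%d of %d records failed reconstruction", n_failed, len(results))
    return results
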
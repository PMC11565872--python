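"""Accuracy evaluation: Lin's concordance correlation coefficient and
per-MAF-bin bias/concordance reports.

Lin's CCC between truth ``x`` and estimate ``y`` is

    ccc = 2 * s_xy / (s_x^2 + s_y^2 + (mean(x) - mean(y))^2)

with population (1/n) moments.  Unlike Pearson correlation it penalises
both location and scale departures from the 45-degree line, which is what
"the estimated frequencies equal the true ones" requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SimulationConfig, fit_pervariant_logistic, simulate_study
from .total_af import _solve_af_arrays
from .se import _solve_se_arrays

__all__ = [
    "REPORT_BINS",
    "ConcordanceReport",
    "lins_ccc",
    "accuracy_report",
    "comparison_grid",
]

logger = logging.getLogger(__name__)

#: report bins: [0, 0.1], then left-open (0.1, 0.2], ..., (0.4, 0.5]
REPORT_BINS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


def lins_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient between paired vectors.

    Pairs with a missing value in either vector are dropped (with a logged
    count).  Requires at least two complete pairs and a non-degenerate
    denominator.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    n_dropped = x.size - int(keep.sum())
    if n_dropped:
        logger.info("lins_ccc: dropped %d incomplete pairs", n_dropped)
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ValueError("need at least 2 complete pairs")
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise ValueError("degenerate input: zero variances and equal means")
    return float(2.0 * sxy / denom)


@dataclass
class ConcordanceReport:
    """Overall and per-bin concordance between true and estimated values."""

    ccc: float
    n: int
    mean_bias: float
    by_bin: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        overall = pd.DataFrame(
            [{"bin": "overall", "n": self.n, "ccc": self.ccc, "mean_bias": self.mean_bias}]
        )
        return pd.concat([overall, self.by_bin], ignore_index=True)


def accuracy_report(true_vals, est_vals, bins=REPORT_BINS) -> ConcordanceReport:
    """Overall and per-bin CCC / mean bias, binned on the true value.

    The first bin is closed ([0, 0.1]); later bins are left-open, matching
    the usual reporting convention.  Bins with fewer than 2 complete pairs
    get a missing CCC.
    """
    true_vals = np.asarray(true_vals, dtype=float).ravel()
    est_vals = np.asarray(est_vals, dtype=float).ravel()
    keep = np.isfinite(true_vals) & np.isfinite(est_vals)
    t, e = true_vals[keep], est_vals[keep]

    rows = []
    edges = np.asarray(bins, dtype=float)
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo == edges[0]:
            mask = (t >= lo) & (t <= hi)
        else:
            mask = (t > lo) & (t <= hi)
        n_bin = int(mask.sum())
        if n_bin >= 2:
            try:
                ccc_bin = lins_ccc(t[mask], e[mask])
            except ValueError:
                ccc_bin = np.nan
        else:
            ccc_bin = np.nan
        bias_bin = float(np.mean(e[mask] - t[mask])) if n_bin else np.nan
        label = f"[{lo}, {hi}]" if lo == edges[0] else f"({lo}, {hi}]"
        rows.append({"bin": label, "n": n_bin, "ccc": ccc_bin, "mean_bias": bias_bin})

    by_bin = pd.DataFrame(rows)
    return ConcordanceReport(
        ccc=lins_ccc(t, e),
        n=int(t.size),
        mean_bias=float(np.mean(e - t)),
        by_bin=by_bin,
    )


def _fold(f):
    return np.minimum(f, 1.0 - f)


def evaluate_scenario(config: SimulationConfig) -> dict:
    """Simulate one scenario, run both reconstructions, return CCCs.

    The total-AF route is scored on the allele-anchored AF scale it outputs;
    the SE route on the folded MAF scale it outputs (true values folded to
    match).
    """
    study = simulate_study(config)
    fits = fit_pervariant_logistic(study, include_covariates=config.n_covariates > 0)

    af_case, af_control = _solve_af_arrays(
        fits["or"], study.af_total, config.n_case, config.n_control
    )
    maf_case, maf_control, _ = _solve_se_arrays(
        fits["or"], fits["se"], 2.0 * config.n_case, 2.0 * config.n_control
    )
    return {
        "n_case": config.n_case,
        "n_control": config.n_control,
        "n_covariates": config.n_covariates,
        "seed": config.seed,
        "ccc_af_case": lins_ccc(study.af_case, af_case),
        "ccc_af_control": lins_ccc(study.af_control, af_control),
        "ccc_se_case": lins_ccc(_fold(study.af_case), maf_case),
        "ccc_se_control": lins_ccc(_fold(study.af_control), maf_control),
    }


def comparison_grid(scenarios) -> pd.DataFrame:
    """Per-scenario, per-method case/control CCC table.

    One row per :class:`~ccfreq.simulate.SimulationConfig`; failures are
    flagged rows with NaN metrics rather than a global abort.
    """
    rows = []
    for config in scenarios:
        try:
            rows.append(evaluate_scenario(config))
        except Exception as exc:  # noqa: BLE001 - per-scenario isolation
            logger.warning("scenario %r failed: %s", config, exc)
            rows.append(
                {
                    "n_case": config.n_case,
                    "n_control": config.n_control,
                    "n_covariates": config.n_covariates,
                    "seed": config.seed,
                    "ccc_af_case": np.nan,
                    "ccc_af_control": np.nan,
                    "ccc_se_case": np.nan,
                    "ccc_se_control": np.nan,
                }
            )
    return pd.DataFrame(rows)


def plot_concordance(true_vals, est_vals, ax=None, **scatter_kw):
    """True-vs-estimated scatter with the identity line; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(true_vals, est_vals, s=4, alpha=0.4, **scatter_kw)
    lim = (0.0, float(np.nanmax([np.nanmax(true_vals), np.nanmax(est_vals)])))
    ax.plot(lim, lim, color="black", lw=0.8)
    ax.set_xlabel("true frequency")
    ax.set_ylabel("estimated frequency")
    return ax
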
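"""Reading and writing GWAS summary-statistics tables.

Published summary statistics come in dozens of dialects, so the reader is
canonical-with-mapping: internally everything uses GWAS-SSF-style headers
(``chromosome``, ``base_pair_location``, ``effect_allele``,
``other_allele``, ``odds_ratio``, ``beta``, ``standard_error``,
``p_value``, ``effect_allele_frequency``), and a :class:`ColumnMap`
translates arbitrary input headers/delimiters onto them.  Missing primary
fields are derived where possible (OR from beta; SE from beta and p-value)
with provenance flags recording what was derived.  Rows that fail type
coercion are collected into a rejects table with line numbers instead of
aborting the read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .total_af import or_from_beta, se_from_beta_p

__all__ = ["CANONICAL_COLUMNS", "ColumnMap", "read_sumstats", "write_results"]

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = (
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "odds_ratio",
    "beta",
    "standard_error",
    "p_value",
    "effect_allele_frequency",
)

MISSING_TOKENS = ("NA", "", "NaN", "nan", ".")

_NUMERIC = {
    "base_pair_location",
    "odds_ratio",
    "beta",
    "standard_error",
    "p_value",
    "effect_allele_frequency",
}


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from canonical field names to input column headers.

    Only non-default header names need to be listed in ``names``.
    """

    names: dict = field(default_factory=dict)
    delimiter: str = "\t"
    missing_tokens: tuple = MISSING_TOKENS

    def source(self, canonical: str) -> str:
        return self.names.get(canonical, canonical)


def read_sumstats(path, column_map: ColumnMap | None = None, required=()):
    """Read a summary-statistics table into canonical form.

    Returns ``(records, rejects)``: a DataFrame with canonical columns plus
    ``derived_or`` / ``derived_se`` provenance flags, and a rejects
    DataFrame with 1-based line numbers and reasons.  ``required`` lists
    canonical columns that must be present in the file (after mapping);
    a missing one raises ``ValueError``.
    """
    cmap = column_map or ColumnMap()
    raw = pd.read_csv(
        path,
        sep=cmap.delimiter,
        dtype=str,
        na_values=list(cmap.missing_tokens),
        keep_default_na=False,
    )
    if raw.empty and raw.columns.empty:
        raise ValueError(f"empty summary-statistics file: {path}")

    for col in required:
        if cmap.source(col) not in raw.columns:
            raise ValueError(f"required column {cmap.source(col)!r} ({col}) missing from {path}")

    df = pd.DataFrame(index=raw.index)
    for col in CANONICAL_COLUMNS:
        src = cmap.source(col)
        df[col] = raw[src] if src in raw.columns else np.nan

    reject_reason = pd.Series("", index=df.index)
    for col in _NUMERIC:
        present = df[col].notna()
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = present & coerced.isna()
        if bad.any():
            reject_reason[bad] += f"bad {col};"
        df[col] = coerced
    bad_pos = df["base_pair_location"].notna() & (df["base_pair_location"] <= 0)
    if bad_pos.any():
        reject_reason[bad_pos] += "bad base_pair_location;"
        df.loc[bad_pos, "base_pair_location"] = np.nan

    rejected = reject_reason != ""
    rejects = pd.DataFrame(
        {"line": df.index[rejected] + 2, "reason": reject_reason[rejected]}  # 1-based + header
    ).reset_index(drop=True)
    if rejected.any():
        logger.warning("read_sumstats: %d rows rejected", int(rejected.sum()))
    records = df[~rejected].reset_index(drop=True)

    # derive missing primary fields from what is present
    derived_or = records["odds_ratio"].isna() & records["beta"].notna()
    records["derived_or"] = derived_or
    records.loc[derived_or, "odds_ratio"] = np.exp(records.loc[derived_or, "beta"])

    can_se = (
        records["standard_error"].isna()
        & records["beta"].notna()
        & (records["beta"] != 0)
        & records["p_value"].notna()
        & (records["p_value"] >= np.finfo(float).tiny)
        & (records["p_value"] < 1)
    )
    records["derived_se"] = can_se
    if can_se.any():
        records.loc[can_se, "standard_error"] = [
            se_from_beta_p(b, p)
            for b, p in zip(records.loc[can_se, "beta"], records.loc[can_se, "p_value"])
        ]
    return records, rejects


def write_results(records: pd.DataFrame, estimates: pd.DataFrame | None, path, delimiter="\t"):
    """Write records with estimate columns appended; ``NA`` marks missing.

    ``estimates`` (aligned row-for-row, or ``None`` for a plain round-trip)
    contributes its columns verbatim after the original ones.
    """
    out = records.copy()
    if estimates is not None:
        if len(estimates) != len(records):
            raise ValueError(
                f"length mismatch: {len(records)} records vs {len(estimates)} estimates"
            )
        for col in estimates.columns:
            out[col] = estimates[col].to_numpy()
    for flag in ("derived_or", "derived_se"):
        if flag in out.columns:
            out[flag] = out[flag].astype(bool)
    out.to_csv(path, sep=delimiter, index=False, na_rep="NA")


def read_proxy_panel(path, column_map: ColumnMap | None = None) -> pd.DataFrame:
    """Read a proxy-MAF panel: columns chrom, pos, allele1, allele2, freq.

    ``ColumnMap.names`` may remap any of those canonical names; positions
    are 1-based and chromosome labels keep their input spelling (matching
    strips any leading ``chr``).
    """
    cmap = column_map or ColumnMap()
    raw = pd.read_csv(
        path,
        sep=cmap.delimiter,
        na_values=list(cmap.missing_tokens),
        keep_default_na=False,
    )
    cols = {}
    for col in ("chrom", "pos", "allele1", "allele2", "freq"):
        src = cmap.source(col)
        if src not in raw.columns:
            raise ValueError(f"proxy panel missing column {src!r}")
        cols[col] = raw[src]
    df = pd.DataFrame(cols)
    df["pos"] = pd.to_numeric(df["pos"], errors="raise").astype(int)
    df["freq"] = pd.to_numeric(df["freq"], errors="raise")
    return df
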
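"""gyrB-normalized quantification of hgcA/hgcB genes and transcripts.

Raw coverage (reads per bp) of a gene family in a metagenome or
metatranscriptome scales with sequencing depth; dividing by the mean coverage
of the single-copy housekeeping gene gyrB in the same sample and molecule
pool (gene vs transcript, normalized separately) yields a depth-independent
abundance roughly interpretable as copies per genome.  Per-MAG expression of
functional genes is categorized against gyrB expression with an absolute
coverage-difference threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "COVERAGE_COLUMNS",
    "EXPRESSION_THRESHOLD",
    "validate_coverage",
    "normalize_to_gyrb",
    "classify_expression",
    "aggregate_by_group",
]

COVERAGE_COLUMNS = ["sample_id", "molecule", "gene_family", "mag_id", "taxon", "coverage"]
#: coverage-difference threshold below which gene and gyrB expression are "similar"
EXPRESSION_THRESHOLD = 0.005

_MOLECULES = {"gene", "transcript"}


def validate_coverage(records: pd.DataFrame) -> pd.DataFrame:
    """Check/complete a coverage table; returns a copy with all columns."""
    if records.empty:
        raise ValueError("coverage table is empty")
    df = records.copy()
    for col in ("mag_id", "taxon"):
        if col not in df.columns:
            df[col] = pd.NA
    missing = [c for c in COVERAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"coverage table missing columns: {missing}")
    if (df["coverage"] < 0).any():
        raise ValueError("negative coverage values")
    bad = set(df["molecule"]) - _MOLECULES
    if bad:
        raise ValueError(f"unknown molecule type(s): {sorted(bad)}")
    return df[COVERAGE_COLUMNS]


def normalize_to_gyrb(records: pd.DataFrame) -> pd.DataFrame:
    """Divide each family's coverage by the sample's mean gyrB coverage.

    The mean is taken per (sample, molecule) over all gyrB-annotated rows of
    that pool.  Samples lacking gyrB coverage get ``value = NaN`` and
    ``gyrb_defined = False`` rather than being dropped.
    """
    df = validate_coverage(records)
    gyrb = (
        df[df["gene_family"] == "gyrB"]
        .groupby(["sample_id", "molecule"])["coverage"]
        .mean()
        .rename("gyrb_mean")
    )
    out = df.merge(gyrb, on=["sample_id", "molecule"], how="left")
    defined = out["gyrb_mean"].notna() & (out["gyrb_mean"] > 0)
    out["value"] = np.where(defined, out["coverage"] / out["gyrb_mean"], np.nan)
    out["gyrb_defined"] = defined
    return out[COVERAGE_COLUMNS + ["gyrb_mean", "value", "gyrb_defined"]]


def classify_expression(
    mag_gene_cov: float, gyrb_cov: float, threshold: float = EXPRESSION_THRESHOLD
) -> str:
    """Categorize a functional gene's expression against gyrB expression.

    Returns ``"similar"`` when |gene - gyrB| < threshold, ``"higher"`` when
    the difference is >= threshold and ``"lower"`` when <= -threshold
    (coverage units of transcripts).
    """
    if mag_gene_cov < 0 or gyrb_cov < 0:
        raise ValueError("coverage values must be >= 0")
    delta = mag_gene_cov - gyrb_cov
    if abs(delta) < threshold:
        return "similar"
    return "higher" if delta > 0 else "lower"


def aggregate_by_group(norm: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Sum normalized abundance per group (taxon, zone or mag_id).

    Group sums preserve the ungrouped total.  Rows with undefined
    normalization (no gyrB) are excluded and counted in the ``n_undefined``
    attribute of the result.
    """
    key = {"taxon": "taxon", "zone": "zone", "mag": "mag_id", "mag_id": "mag_id"}.get(grouping)
    if key is None or key not in norm.columns:
        raise ValueError(f"unknown or absent grouping key: {grouping}")
    usable = norm[norm["value"].notna()]
    agg = (
        usable.groupby(["sample_id", "molecule", "gene_family", key], dropna=False)["value"]
        .sum()
        .reset_index()
    )
    agg.attrs["n_undefined"] = int(norm["value"].isna().sum())
    return agg
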
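"""Median-of-ratios count normalization and FPKM.

Size factors follow the median-of-ratios scheme: each sample's factor is the
median, over genes with a positive geometric mean across samples, of that
sample's count divided by the gene's geometric mean (the pseudo-reference).
Spike-ins and intergenic features never inform the estimate — their input
mass is fixed rather than proportional to sample mRNA — but are scaled by
the resulting factors like everything else.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def compute_size_factors(counts: pd.DataFrame, feature_classes: pd.Series | None = None) -> pd.Series:
    """Median-of-ratios size factors, estimated from gene features only.

    Parameters
    ----------
    counts : genes/features x samples integer counts.
    feature_classes : optional Series mapping feature_id -> class; rows whose
        class is not ``gene`` are excluded from estimation.
    """
    mat = counts
    if feature_classes is not None:
        keep = feature_classes.reindex(counts.index).fillna("gene") == "gene"
        mat = counts.loc[keep]
    values = mat.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; size factors are undefined "
            "(filter samples or features first)"
        )
    logs = np.log(values[all_positive])
    log_geomean = logs.mean(axis=1)
    ratios = np.exp(logs - log_geomean[:, None])
    # median on the ratio scale: arithmetic midpoint-of-two for even counts
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor (normalized counts)."""
    if set(counts.columns) != set(size_factors.index):
        raise ValueError("size factors do not match count matrix samples")
    if (size_factors <= 0).any() or not np.isfinite(size_factors).all():
        raise ValueError("size factors must be finite and positive")
    return counts / size_factors.reindex(counts.columns)


def compute_fpkm(
    counts: pd.DataFrame, lengths_bp: pd.Series, mapped_totals: pd.Series | None = None
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    FPKM_gs = count_gs / ((length_g / 1e3) * (total_s / 1e6)).  ``mapped_totals``
    defaults to the column sums of ``counts``.
    """
    lengths = lengths_bp.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("every feature needs a length_bp for FPKM")
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    if mapped_totals is None:
        mapped_totals = counts.sum(axis=0)
    totals = mapped_totals.reindex(counts.columns)
    if (totals <= 0).any():
        raise ValueError("per-sample mapped totals must be positive")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)
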
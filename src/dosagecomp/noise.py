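"""Empirical noise model and low-expression cutoff.

Replicate coefficients of variation (CV, percent) are computed per feature
within each replicate group and pooled across groups.  The low-expression
cutoff is derived in two steps: the lower percentile (default 5th) of the
intergenic CV distribution sets a CV threshold — the noise floor that 95% of
non-genic signal exceeds — and the spike-in CV-vs-abundance curve, fitted by
local polynomial regression, is read off at that threshold to give the
normalized-count cutoff below which quantification is considered too noisy
for ratiometric analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import design_groups


@dataclass
class CutoffResult:
    cv_threshold_percent: float
    count_cutoff: float
    fitted_curve: pd.DataFrame  # columns: mean, cv_fit
    fraction_genes_above_cutoff: float
    fraction_genes_below_cv_threshold: float
    warnings: list[str] = field(default_factory=list)


def replicate_cv(values) -> float:
    """CV percent across replicates: 100 * sample SD (n-1) / mean.

    Undefined (returns NaN) when the mean is zero or fewer than two
    replicates are given.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    m = v.mean()
    if m == 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / m)


def noise_profiles(
    expr: pd.DataFrame, design: pd.DataFrame, feature_classes: pd.Series
) -> pd.DataFrame:
    """Per-feature, per-replicate-group mean and CV of normalized counts.

    Groups are (genotype, karyotype, tra2) combinations with >= 2 samples.
    Features with zero mean in a group are skipped for that group.
    Returns a long DataFrame: feature_id, feature_class, group, mean, cv_percent.
    """
    classes = feature_classes.reindex(expr.index)
    frames = []
    for key, grp in design_groups(design):
        ids = [s for s in grp["sample_id"] if s in expr.columns]
        if len(ids) < 2:
            continue
        sub = expr[ids].to_numpy(dtype=float)
        mean = sub.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = 100.0 * sub.std(axis=1, ddof=1) / mean
        ok = mean > 0
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": expr.index[ok],
                    "feature_class": classes.to_numpy()[ok],
                    "group": "|".join(map(str, key)),
                    "mean": mean[ok],
                    "cv_percent": cv[ok],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["feature_id", "feature_class", "group", "mean", "cv_percent"])
    return pd.concat(frames, ignore_index=True)


def percentile_linear(values, q: float) -> float:
    """Linear-interpolation percentile (the convention used throughout)."""
    return float(np.percentile(np.asarray(values, dtype=float), q))


def intergenic_cv_threshold(
    profiles: pd.DataFrame, percentile: float = 5.0, min_features: int = 20
) -> float:
    """Lower percentile of the intergenic CV distribution.

    With the default percentile 5, 95% of intergenic region CVs exceed the
    returned threshold.
    """
    cvs = profiles.loc[profiles["feature_class"] == "intergenic", "cv_percent"].dropna()
    if len(cvs) < min_features:
        raise ValueError(
            f"only {len(cvs)} intergenic CV values (need >= {min_features}) — "
            "cannot estimate a stable noise threshold"
        )
    return percentile_linear(cvs, percentile)


def _local_poly_fit(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray, span: float = 0.75, degree: int = 2
) -> np.ndarray:
    """Local polynomial regression with tricube weights (loess-style).

    At each grid point the bandwidth is the distance to the ceil(span*n)-th
    nearest data point; data are fitted by weighted least squares of the
    requested degree and the grid point's fitted value returned.
    """
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    grid32 = np.asarray(grid, dtype=np.float32)
    n = len(x)
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    dx = x[None, :] - grid32[:, None]  # G x n
    d = np.abs(dx)
    h = np.partition(d, k - 1, axis=1)[:, k - 1]
    h = np.maximum(h, np.float32(1e-6))
    u = d / h[:, None]
    w = np.clip(1.0 - u**3, 0.0, None) ** 3  # tricube
    # weighted-moment normal equations: A_ij = sum w dx^(i+j), b_i = sum w dx^i y
    p_max = 2 * degree
    M = np.empty((len(grid), p_max + 1), dtype=np.float64)
    V = np.empty((len(grid), degree + 1), dtype=np.float64)
    cur = w.copy()
    wy = w * y[None, :]
    for p in range(p_max + 1):
        M[:, p] = cur.sum(axis=1)
        if p <= degree:
            V[:, p] = wy.sum(axis=1)
            wy *= dx
        if p < p_max:
            cur *= dx
    idx = np.arange(degree + 1)
    A = M[:, idx[:, None] + idx[None, :]]
    A += 1e-9 * np.eye(degree + 1)[None, :, :]
    coef = np.linalg.solve(A, V[..., None])[..., 0]
    return coef[:, 0]  # value at dx = 0


def fit_spikein_cv_curve(
    profiles: pd.DataFrame,
    span: float = 0.75,
    degree: int = 2,
    grid_size: int = 512,
    min_features: int = 10,
    min_decades: float = 2.0,
    max_points: int = 2500,
) -> pd.DataFrame:
    """Local polynomial regression of spike-in CV against log10 mean.

    Returns a DataFrame with columns ``mean`` (normalized counts, dense grid)
    and ``cv_fit`` (fitted CV percent).  When more than ``max_points``
    (feature, group) CV observations are available, an evenly spaced
    subsample along the abscissa is fitted (deterministic).
    """
    sub = profiles[(profiles["feature_class"] == "spikein") & (profiles["mean"] > 0)].dropna(
        subset=["cv_percent"]
    )
    n_features = sub["feature_id"].nunique()
    if n_features < min_features:
        raise ValueError(f"only {n_features} spike-in features with defined CV (need >= {min_features})")
    x = np.log10(sub["mean"].to_numpy(dtype=float))
    y = sub["cv_percent"].to_numpy(dtype=float)
    if len(x) > max_points:
        order = np.argsort(x, kind="stable")
        pick = order[np.linspace(0, len(order) - 1, max_points).round().astype(int)]
        x, y = x[pick], y[pick]
    if x.max() - x.min() < min_decades:
        raise ValueError(
            f"spike-in means span {x.max() - x.min():.2f} decades (need >= {min_decades}) — "
            "curve fit would extrapolate"
        )
    grid = np.linspace(x.min(), x.max(), grid_size)
    fit = _local_poly_fit(x, y, grid, span=span, degree=degree)
    return pd.DataFrame({"mean": 10**grid, "cv_fit": fit})


def derive_count_cutoff(fitted_curve: pd.DataFrame, cv_threshold_percent: float) -> float:
    """Smallest mean at which the fitted CV drops to the threshold.

    Linear interpolation between the flanking grid points.  If the curve
    starts at or below the threshold, the smallest grid mean is returned with
    a warning; a curve entirely above the threshold is an error.
    """
    means = fitted_curve["mean"].to_numpy(dtype=float)
    cv = fitted_curve["cv_fit"].to_numpy(dtype=float)
    below = cv <= cv_threshold_percent
    if not below.any():
        raise ValueError(
            f"fitted CV curve never reaches {cv_threshold_percent:.1f}% "
            f"(range {cv.min():.1f}–{cv.max():.1f}%)"
        )
    i = int(np.argmax(below))
    if i == 0:
        warnings.warn(
            "fitted CV curve is below the threshold over its whole range; "
            "returning the smallest grid mean",
            stacklevel=2,
        )
        return float(means[0])
    # interpolate between grid points i-1 (above) and i (at/below)
    f = (cv[i - 1] - cv_threshold_percent) / (cv[i - 1] - cv[i])
    return float(means[i - 1] + f * (means[i] - means[i - 1]))


def expression_fractions(
    gene_profiles: pd.DataFrame, count_cutoff: float, cv_threshold_percent: float
) -> tuple[float, float]:
    """(fraction of genes with mean above the cutoff, fraction with CV below threshold).

    ``gene_profiles`` is the noise-profile table restricted (internally) to
    gene features; per gene, the mean is averaged and the CV summarized by
    the median across replicate groups.
    """
    genes = gene_profiles[gene_profiles["feature_class"] == "gene"]
    if genes.empty:
        raise ValueError("no gene features in profiles")
    per_gene = genes.groupby("feature_id").agg(mean=("mean", "mean"), cv=("cv_percent", "median"))
    frac_above = float((per_gene["mean"] > count_cutoff).mean())
    with_cv = per_gene["cv"].dropna()
    frac_below_cv = float((with_cv < cv_threshold_percent).mean()) if len(with_cv) else float("nan")
    return frac_above, frac_below_cv


def replicate_correlation(expr: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of log2(normalized count + 1) between replicate pairs.

    Returns a long DataFrame: group, sample_a, sample_b, r.  Pairs involving
    a constant vector get r = NaN (undefined, reported missing).
    """
    rows = []
    logx = np.log2(expr + 1.0)
    for key, grp in design_groups(design):
        ids = [s for s in grp["sample_id"] if s in expr.columns]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = logx[ids[i]].to_numpy(), logx[ids[j]].to_numpy()
                if a.std() == 0 or b.std() == 0:
                    r = float("nan")
                else:
                    r = float(np.corrcoef(a, b)[0, 1])
                rows.append(
                    {"group": "|".join(map(str, key)), "sample_a": ids[i], "sample_b": ids[j], "r": r}
                )
    return pd.DataFrame(rows, columns=["group", "sample_a", "sample_b", "r"])


def derive_cutoff(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    feature_classes: pd.Series,
    percentile: float = 5.0,
    span: float = 0.75,
    degree: int = 2,
    grid_size: int = 512,
) -> CutoffResult:
    """Full cutoff pipeline: profiles -> intergenic threshold -> spike curve -> cutoff."""
    notes: list[str] = []
    profiles = noise_profiles(expr, design, feature_classes)
    threshold = intergenic_cv_threshold(profiles, percentile=percentile)
    curve = fit_spikein_cv_curve(profiles, span=span, degree=degree, grid_size=grid_size)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cutoff = derive_count_cutoff(curve, threshold)
        notes.extend(str(w.message) for w in caught)
    frac_above, frac_below = expression_fractions(profiles, cutoff, threshold)
    return CutoffResult(
        cv_threshold_percent=threshold,
        count_cutoff=cutoff,
        fitted_curve=curve,
        fraction_genes_above_cutoff=frac_above,
        fraction_genes_below_cv_threshold=frac_below,
        warnings=notes,
    )
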
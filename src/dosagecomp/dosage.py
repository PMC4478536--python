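"""Ratiometric dosage-compensation analysis.

For every gene hemizygous in a Df/+ line, expression in the one-dose
samples is compared to a bootstrapped reference: the median of the gene's
normalized expression over all samples in which it is present at two doses,
stratified by karyotype/sex-transformation class.  The ratio r is doubled to
give the compensation fold c = 2r (c = 1: no compensation, c = 2: perfect).
Matched control genes — equally many, sampled from the same arm outside all
deficiencies — are pushed through the identical computation and should
center at c = 2.  Per-arm summaries use boxplot notch confidence intervals
(+/- 1.57 x IQR / sqrt(N)); arms are compared by Mann-Whitney U.

A QC scan flags annotated deficiencies that produce no dosage effect
(median log2 Df/+ vs +/+ ratio above log2 0.75 across the hemizygous
segment), mimicking the exclusion of stocks that lost their deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

# dose codes in the gene x sample matrix
DOSE_TWO = 2
DOSE_ONE_DF = 1
DOSE_ONE_MALE_X = 3  # one dose, male X (reason x_in_male)
EXCLUDED_STRADDLE = 0

DEFAULT_QC_LOG2_THRESHOLD = math.log2(0.75)

_CLASS_TAG = {("XX", False): "XX", ("XY", False): "XY", ("XX", True): "XXt", ("XY", True): "XYt"}


def class_tag(karyotype: str, tra2: bool) -> str:
    return _CLASS_TAG[(karyotype, bool(tra2))]


@dataclass
class BoxStats:
    """Boxplot summary with notch confidence interval."""

    n: int
    median: float
    q1: float
    q3: float
    iqr: float
    notch: float  # half-width, 1.57 * IQR / sqrt(N)

    @property
    def notch_lo(self) -> float:
        return self.median - self.notch

    @property
    def notch_hi(self) -> float:
        return self.median + self.notch


def box_stats(values) -> BoxStats:
    """Quartiles by linear interpolation; notch half-width 1.57 * IQR / sqrt(N)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("box_stats requires at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    return BoxStats(
        n=int(v.size), median=float(med), q1=float(q1), q3=float(q3),
        iqr=float(iqr), notch=float(1.57 * iqr / math.sqrt(v.size)),
    )


# ---------------------------------------------------------------------------
# dose assignment


def assign_dosage(
    annotation: pd.DataFrame, df_intervals: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Gene x sample dose codes.

    A gene is one-dose in a sample iff it lies fully inside the sample's Df
    interval (code 1), or it is X-linked and the sample is XY (code 3).
    Genes partially overlapping any Df boundary are ill-defined under
    deletion and are excluded everywhere (code 0).  Everything else is
    two-dose (code 2).
    """
    genes = annotation[annotation["feature_class"] == "gene"]
    known_chroms = set(genes["chrom"])
    bad = set(df_intervals["chrom"]) - known_chroms
    if bad:
        raise ValueError(f"Df intervals on chromosome(s) {sorted(bad)} absent from the annotation")
    gstart = genes["start"].to_numpy()
    gend = genes["end"].to_numpy()
    gchrom = genes["chrom"].to_numpy()
    samples = design["sample_id"].to_numpy()
    dose = np.full((len(genes), len(samples)), DOSE_TWO, dtype=np.int8)

    straddle = np.zeros(len(genes), dtype=bool)
    df_of_sample = design["df_id"].to_numpy(dtype=object)
    for df_id, iv in df_intervals.iterrows():
        on_chrom = gchrom == iv["chrom"]
        overlap = on_chrom & (gstart < iv["end"]) & (gend > iv["start"])
        inside = on_chrom & (gstart >= iv["start"]) & (gend <= iv["end"])
        straddle |= overlap & ~inside
        carriers = df_of_sample == df_id
        if inside.any() and carriers.any():
            dose[np.ix_(inside, carriers)] = DOSE_ONE_DF
    male = (design["karyotype"] == "XY").to_numpy()
    x_genes = gchrom == "X"
    if x_genes.any() and male.any():
        dose[np.ix_(x_genes, male)] = DOSE_ONE_MALE_X
    dose[straddle, :] = EXCLUDED_STRADDLE
    return pd.DataFrame(dose, index=genes.index, columns=samples)


# ---------------------------------------------------------------------------
# bootstrap reference and per-gene compensation


def bootstrap_reference(
    values, n_boot: int = 1000, seed: int | np.random.Generator = 0, min_samples: int = 5
) -> tuple[float, tuple[float, float]]:
    """Reference median of two-dose expression with a bootstrap percentile CI.

    Resamples the samples with replacement ``n_boot`` times; the CI is the
    2.5/97.5 percentile of the resampled medians.  Deterministic for a fixed
    seed.
    """
    v = np.asarray(values, dtype=float)
    if v.size < min_samples:
        raise ValueError(f"need >= {min_samples} two-dose samples for a reference (got {v.size})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref = float(np.median(v))
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    boots = np.median(v[idx], axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return ref, (float(lo), float(hi))


def gene_compensation(one_dose_values, reference_median: float) -> tuple[float, float]:
    """(ratio r, compensation fold c = 2r) of one-dose expression vs the reference."""
    if reference_median <= 0:
        raise ValueError("reference median must be positive (gene untested otherwise)")
    r = float(np.median(np.asarray(one_dose_values, dtype=float)) / reference_median)
    return r, 2.0 * r


# ---------------------------------------------------------------------------
# compensation table


def _class_partition(design: pd.DataFrame) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for (karyo, tra2), grp in design.groupby(["karyotype", "tra2"], sort=True):
        out[class_tag(karyo, tra2)] = grp["sample_id"].tolist()
    return out


def _bootstrap_block(
    pool_expr: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized bootstrap of per-gene reference medians over a shared pool.

    ``pool_expr`` is genes x pool-samples; one resampling-index matrix is
    shared by the block (each gene's marginal CI is unaffected).
    Returns (ci_lo, ci_hi) per gene.
    """
    n = pool_expr.shape[1]
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = np.median(pool_expr[:, idx], axis=2)  # genes x n_boot
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=1)
    return lo, hi


def compensation_table(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    annotation: pd.DataFrame,
    df_intervals: pd.DataFrame,
    count_cutoff: float = 6.0,
    n_boot: int = 1000,
    seed: int = 0,
    include_controls: bool = True,
    include_male_x: bool = True,
    min_reference_samples: int = 5,
) -> pd.DataFrame:
    """Per gene x Df-line x class compensation estimates.

    Rows of kind ``hemizygous`` cover genes fully inside each line's Df,
    evaluated within each karyotype/tra2 class the line was profiled in; the
    reference pool is every same-class sample not carrying that Df.  Rows of
    kind ``control`` are matched two-dose genes from the same arm outside all
    Dfs (equally many as hemizygous genes passing the cutoff), pushed through
    the identical ratio against the identical pool.  Rows of kind ``male_x``
    give the X-linked one-dose ratio of XY samples against the XX female
    reference.  ``passes_cutoff`` marks genes whose reference-pool mean
    exceeds ``count_cutoff``; only those rows belong in summaries.
    """
    rng = np.random.default_rng(seed)
    genes = annotation[annotation["feature_class"] == "gene"]
    dose = assign_dosage(annotation, df_intervals, design)
    usable = dose.index[(dose != EXCLUDED_STRADDLE).all(axis=1)]
    classes = _class_partition(design)
    sample_df = dict(zip(design["sample_id"], design["df_id"]))

    gchrom = genes["chrom"]
    rows: list[dict] = []

    def emit_block(gene_ids, one_dose_ids, pool_ids, df_id, arm, ctag, kind):
        if len(gene_ids) == 0 or len(one_dose_ids) == 0 or len(pool_ids) < min_reference_samples:
            return
        sub_one = expr.loc[gene_ids, one_dose_ids].to_numpy(dtype=float)
        sub_pool = expr.loc[gene_ids, pool_ids].to_numpy(dtype=float)
        ref = np.median(sub_pool, axis=1)
        pool_mean = sub_pool.mean(axis=1)
        lo, hi = _bootstrap_block(sub_pool, n_boot, rng)
        med_one = np.median(sub_one, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(ref > 0, med_one / ref, np.nan)
        for i, g in enumerate(gene_ids):
            rows.append(
                {
                    "feature_id": g,
                    "df_id": df_id,
                    "arm": arm,
                    "class": ctag,
                    "kind": kind,
                    "n_one_dose": len(one_dose_ids),
                    "n_reference": len(pool_ids),
                    "ratio": r[i],
                    "compensation": 2.0 * r[i],
                    "reference": ref[i],
                    "ci_lo": lo[i],
                    "ci_hi": hi[i],
                    "passes_cutoff": bool(pool_mean[i] > count_cutoff) and np.isfinite(r[i]),
                }
            )

    for df_id in sorted(df_intervals.index):
        iv = df_intervals.loc[df_id]
        arm = iv["chrom"]
        inside = usable[
            (gchrom.loc[usable] == arm)
            & (genes.loc[usable, "start"] >= iv["start"])
            & (genes.loc[usable, "end"] <= iv["end"])
        ]
        line_samples = design.loc[design["df_id"] == df_id]
        if inside.empty or line_samples.empty:
            continue
        outside_pool_genes = usable[
            (gchrom.loc[usable] == arm) & (dose.loc[usable].isin([DOSE_TWO, DOSE_ONE_MALE_X]).all(axis=1))
        ]
        for (karyo, tra2), cls_line in line_samples.groupby(["karyotype", "tra2"], sort=True):
            ctag = class_tag(karyo, tra2)
            one_ids = cls_line["sample_id"].tolist()
            if arm == "X" and karyo == "XY":
                continue  # male X handled as its own category
            pool_ids = [s for s in classes.get(ctag, []) if sample_df.get(s) != df_id]
            n_before = len(rows)
            emit_block(list(inside), one_ids, pool_ids, df_id, arm, ctag, "hemizygous")
            if include_controls and len(pool_ids) >= min_reference_samples:
                n_pass = sum(1 for rrow in rows[n_before:] if rrow["passes_cutoff"])
                pool_gene_means = expr.loc[outside_pool_genes, pool_ids].mean(axis=1)
                candidates = list(outside_pool_genes[(pool_gene_means > count_cutoff).to_numpy()])
                if n_pass > 0 and len(candidates) >= n_pass:
                    ctrl = sorted(rng.choice(candidates, size=n_pass, replace=False))
                    emit_block(ctrl, one_ids, pool_ids, df_id, arm, ctag, "control")

    if include_male_x:
        x_genes = usable[gchrom.loc[usable] == "X"]
        male_ids = design.loc[design["karyotype"] == "XY", "sample_id"].tolist()
        ref_ids_all = classes.get("XX", [])
        if len(x_genes) and male_ids and ref_ids_all:
            # group X genes by the Df line containing them so the XX reference
            # pool can exclude that line's (one-dose) samples
            containing = pd.Series(index=x_genes, dtype=object)
            for df_id in sorted(df_intervals.index[df_intervals["chrom"] == "X"]):
                iv = df_intervals.loc[df_id]
                inside = (genes.loc[x_genes, "start"] >= iv["start"]) & (
                    genes.loc[x_genes, "end"] <= iv["end"]
                )
                containing[inside[inside].index] = df_id
            for df_id, block in containing.groupby(containing, dropna=False):
                pool_ids = [s for s in ref_ids_all if pd.isna(df_id) or sample_df.get(s) != df_id]
                emit_block(list(block.index), male_ids, pool_ids, None, "X", "XY", "male_x")

    cols = [
        "feature_id", "df_id", "arm", "class", "kind", "n_one_dose", "n_reference",
        "ratio", "compensation", "reference", "ci_lo", "ci_hi", "passes_cutoff",
    ]
    return pd.DataFrame(rows, columns=cols)


def cohort_median_compensation(table: pd.DataFrame, kinds: tuple[str, ...] = ("hemizygous",)) -> float:
    """Median compensation fold over passing rows of the given kinds."""
    sel = table[table["kind"].isin(kinds) & table["passes_cutoff"]]
    if sel.empty:
        raise ValueError("no passing rows to summarize")
    return float(sel["compensation"].median())


def arm_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """BoxStats of compensation per (arm, class, kind), passing rows only."""
    rows = []
    for (arm, ctag, kind), grp in table[table["passes_cutoff"]].groupby(["arm", "class", "kind"]):
        bs = box_stats(grp["compensation"])
        rows.append(
            {
                "arm": arm, "class": ctag, "kind": kind, "n": bs.n, "median": bs.median,
                "q1": bs.q1, "q3": bs.q3, "iqr": bs.iqr, "notch": bs.notch,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# comparisons


@dataclass
class ArmComparison:
    p_value: float
    statistic: float
    median_a: float
    median_b: float
    notch_overlap: bool
    method: str


def compare_arms(values_a, values_b, method: str = "mannwhitney") -> ArmComparison:
    """Two-sided comparison of compensation distributions between arms.

    Default Mann-Whitney U (normal approximation, tie-corrected); Welch's t
    on log2 compensation is available as ``method='welch'``.  Fully tied
    inputs yield p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    bs_a, bs_b = box_stats(a), box_stats(b)
    overlap = (bs_a.notch_lo <= bs_b.notch_hi) and (bs_b.notch_lo <= bs_a.notch_hi)
    if np.unique(np.concatenate([a, b])).size == 1:
        return ArmComparison(1.0, float("nan"), bs_a.median, bs_b.median, True, method)
    if method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "welch":
        res = stats.ttest_ind(np.log2(a), np.log2(b), equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ArmComparison(p, stat, bs_a.median, bs_b.median, overlap, method)


def per_df_median_compensation(table: pd.DataFrame) -> pd.Series:
    """Median compensation per Df line over passing hemizygous rows."""
    sel = table[(table["kind"] == "hemizygous") & table["passes_cutoff"]]
    return sel.groupby("df_id")["compensation"].median()


def df_extent_correlation(
    per_df_median: pd.Series, df_intervals: pd.DataFrame, min_lines: int = 5
) -> tuple[float, float]:
    """Spearman correlation of per-Df median compensation vs deletion extent.

    Returns (rho, p); (nan, nan) when extents are all tied (rank-degenerate).
    """
    common = per_df_median.index.intersection(df_intervals.index)
    if len(common) < min_lines:
        raise ValueError(f"need >= {min_lines} Df lines with compensation estimates (got {len(common)})")
    extents = df_intervals.loc[common, "extent_bp"].to_numpy(dtype=float)
    comp = per_df_median.loc[common].to_numpy(dtype=float)
    if np.unique(extents).size == 1:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(comp, extents)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Df presence QC


def df_validation_scan(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    annotation: pd.DataFrame,
    df_intervals: pd.DataFrame,
    count_cutoff: float = 6.0,
    log2_threshold: float = DEFAULT_QC_LOG2_THRESHOLD,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Scan each Df/+ line for the expected expression drop in its segment.

    Per class, each gene inside the annotated Df is summarized as the log2
    ratio of the line's mean normalized expression to the mean in no-Df
    control samples of the same class (genes must pass ``count_cutoff`` in
    controls).  Verdicts: ``df_confirmed`` if the median log2 ratio across
    genes/classes is at most ``log2_threshold`` (default log2 0.75, midway
    between no effect and an uncompensated halving), ``df_absent`` otherwise,
    ``indeterminate`` with fewer than ``min_genes`` expressed genes.
    """
    genes = annotation[annotation["feature_class"] == "gene"]
    no_df = design[design["df_id"].isna()]
    rows = []
    for df_id in sorted(df_intervals.index):
        iv = df_intervals.loc[df_id]
        inside = genes.index[
            (genes["chrom"] == iv["chrom"])
            & (genes["start"] >= iv["start"])
            & (genes["end"] <= iv["end"])
        ]
        line = design[design["df_id"] == df_id]
        ratios: list[float] = []
        genes_used: set[str] = set()
        for (karyo, tra2), cls_line in line.groupby(["karyotype", "tra2"], sort=True):
            ctrl = no_df[(no_df["karyotype"] == karyo) & (no_df["tra2"] == tra2)]
            if ctrl.empty or inside.empty:
                continue
            line_mean = expr.loc[inside, cls_line["sample_id"]].mean(axis=1)
            ctrl_mean = expr.loc[inside, ctrl["sample_id"]].mean(axis=1)
            expressed = ctrl_mean > count_cutoff
            genes_used |= set(inside[expressed])
            ratios.extend(np.log2(line_mean[expressed] / ctrl_mean[expressed]))
        if len(genes_used) < min_genes:
            verdict, med = "indeterminate", float("nan")
        else:
            med = float(np.median(ratios))
            verdict = "df_confirmed" if med <= log2_threshold else "df_absent"
        rows.append(
            {
                "df_id": df_id,
                "n_genes": len(genes_used),
                "median_log2_ratio": med,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows).set_index("df_id", drop=False).rename_axis(None)
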
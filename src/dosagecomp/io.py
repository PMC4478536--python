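"""Readers and writers for the pipeline's external table formats.

All genomic intervals are held 0-based half-open internally.  GTF input
(1-based closed) is converted on read and back on write; BED is native.
Count matrices, study designs, deficiency (Df) interval tables and spike-in
references are plain TSV.
"""

from __future__ import annotations

import re
from pathlib import Path
import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ["feature_id", "chrom", "start", "end", "strand", "length_bp", "feature_class"]
FEATURE_CLASSES = ("gene", "intergenic", "spikein")
KARYOTYPES = ("XX", "XY")
DESIGN_COLUMNS = ["sample_id", "genotype", "df_id", "karyotype", "tra2", "replicate"]

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# annotations


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted list of disjoint intervals."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def read_annotation(path, default_class: str = "gene") -> pd.DataFrame:
    """Read a GTF or BED annotation into the internal table.

    Returns a DataFrame with columns ``feature_id, chrom, start, end, strand,
    length_bp, feature_class, exons`` where ``exons`` is the merged exon
    interval list (half-open) and ``length_bp`` its total base count
    (exon-union length).  Format is chosen by file suffix (.gtf vs .bed).
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        return _read_gtf(path, default_class)
    return _read_bed(path, default_class)


def _read_gtf(path: Path, default_class: str) -> pd.DataFrame:
    per_feature: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            if ftype != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
            if start1 < 1 or end1 < start1:
                raise FormatError(f"{path}:{lineno}: invalid 1-based interval [{start1}, {end1}]")
            attr = dict(_GTF_ATTR_RE.findall(attrs))
            fid = attr.get("gene_id") or attr.get("feature_id")
            if fid is None:
                raise FormatError(f"{path}:{lineno}: no gene_id/feature_id attribute")
            rec = per_feature.setdefault(
                fid,
                {
                    "chrom": chrom,
                    "strand": strand,
                    "feature_class": attr.get("feature_class", default_class),
                    "exons": [],
                    "lineno": lineno,
                },
            )
            if rec["chrom"] != chrom:
                raise FormatError(
                    f"{path}:{lineno}: feature {fid!r} on {chrom} conflicts with {rec['chrom']} "
                    f"(first seen line {rec['lineno']})"
                )
            rec["exons"].append((start1 - 1, end1))  # GTF 1-based closed -> half-open
    return _finalize_annotation(per_feature)


def _read_bed(path: Path, default_class: str) -> pd.DataFrame:
    per_feature: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED line needs >=4 fields (chrom start end name)")
            chrom, start_s, end_s, fid = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
            if start < 0 or end <= start:
                raise FormatError(f"{path}:{lineno}: invalid half-open interval [{start}, {end})")
            if fid in per_feature:
                if per_feature[fid]["chrom"] != chrom:
                    raise FormatError(f"{path}:{lineno}: feature {fid!r} duplicated on a different chromosome")
                per_feature[fid]["exons"].append((start, end))
            else:
                per_feature[fid] = {
                    "chrom": chrom,
                    "strand": strand,
                    "feature_class": default_class,
                    "exons": [(start, end)],
                    "lineno": lineno,
                }
    return _finalize_annotation(per_feature)


def _finalize_annotation(per_feature: dict[str, dict]) -> pd.DataFrame:
    rows = []
    for fid, rec in per_feature.items():
        exons = _merge_intervals(rec["exons"])
        rows.append(
            {
                "feature_id": fid,
                "chrom": rec["chrom"],
                "start": exons[0][0],
                "end": exons[-1][1],
                "strand": rec["strand"],
                "length_bp": sum(e - s for s, e in exons),
                "feature_class": rec["feature_class"],
                "exons": exons,
            }
        )
    ann = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS + ["exons"])
    if not ann.empty:
        bad = set(ann["feature_class"]) - set(FEATURE_CLASSES)
        if bad:
            raise FormatError(f"unknown feature_class values: {sorted(bad)}")
    return ann.set_index("feature_id", drop=False).rename_axis(None)


def write_annotation_gtf(ann: pd.DataFrame, path) -> None:
    """Write one exon line per stored exon interval (internal half-open -> GTF 1-based closed)."""
    with open(path, "w") as fh:
        for rec in ann.itertuples(index=False):
            exons = rec.exons if isinstance(getattr(rec, "exons", None), list) else [(rec.start, rec.end)]
            for s, e in exons:
                attrs = f'gene_id "{rec.feature_id}"; feature_class "{rec.feature_class}";'
                fh.write(
                    f"{rec.chrom}\tdosagecomp\texon\t{s + 1}\t{e}\t.\t{rec.strand}\t.\t{attrs}\n"
                )


def write_annotation_bed(ann: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for rec in ann.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.feature_id}\t0\t{rec.strand}\n")


# ---------------------------------------------------------------------------
# count matrices


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples TSV of integer read counts (first column feature_id)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or unparseable count table: {exc}") from None
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            if np.issubdtype(vals.dtype, np.floating) and np.all(vals == np.floor(vals)) and not vals.isna().any():
                df[col] = vals.astype(np.int64)
            else:
                raise FormatError(f"{path}: column {col!r} contains non-integer counts")
        if (df[col] < 0).any():
            raise FormatError(f"{path}: column {col!r} contains negative counts")
    df.index.name = "feature_id"
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts = counts.copy()
    counts.index.name = "feature_id"
    counts.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# study designs


def read_design(path) -> pd.DataFrame:
    """Read a sample metadata TSV with columns sample_id, genotype, df_id, karyotype, tra2, replicate.

    ``df_id`` may be empty/none for control genotypes.  ``tra2`` accepts
    true/false/1/0.  Karyotype must be XX or XY.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=DESIGN_COLUMNS)
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing design columns {sorted(missing)}")
    df = df[DESIGN_COLUMNS].copy()
    if df.empty:
        return df
    bad = set(df["karyotype"]) - set(KARYOTYPES)
    if bad:
        raise FormatError(f"{path}: unknown karyotype token(s) {sorted(bad)}")
    tra2_map = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}
    try:
        df["tra2"] = df["tra2"].str.lower().map(lambda t: tra2_map[t])
    except KeyError as exc:
        raise FormatError(f"{path}: unknown tra2 token {exc}") from None
    df["replicate"] = df["replicate"].astype(int)
    df["df_id"] = df["df_id"].replace({"": None, "none": None, "NA": None, ".": None})
    df["df_id"] = df["df_id"].where(df["df_id"].notna(), None)
    return df.reset_index(drop=True)


def write_design(design: pd.DataFrame, path) -> None:
    out = design.copy()
    out["df_id"] = out["df_id"].fillna("none")
    out["tra2"] = out["tra2"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False)


def design_groups(design: pd.DataFrame) -> pd.core.groupby.DataFrameGroupBy:
    """Replicate groups: one per (genotype, karyotype, tra2) combination."""
    return design.groupby(["genotype", "karyotype", "tra2"], sort=True)


def single_replicate_samples(design: pd.DataFrame) -> list[str]:
    """Sample ids in replicate groups of size < 2 (flagged for exclusion)."""
    if design.empty:
        return []
    sizes = design_groups(design)["sample_id"].transform("size")
    return design.loc[sizes < 2, "sample_id"].tolist()


# ---------------------------------------------------------------------------
# Df intervals and spike-in references


def read_df_intervals(path) -> pd.DataFrame:
    """BED-like TSV of deficiency intervals: chrom, start, end, df_id (half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: Df interval line needs chrom, start, end, df_id")
            chrom, start_s, end_s, df_id = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end <= start:
                raise FormatError(f"{path}:{lineno}: empty or inverted interval [{start}, {end})")
            rows.append({"df_id": df_id, "chrom": chrom, "start": start, "end": end})
    dfs = pd.DataFrame(rows, columns=["df_id", "chrom", "start", "end"])
    dfs["extent_bp"] = dfs["end"] - dfs["start"]
    return dfs.set_index("df_id", drop=False).rename_axis(None)


def write_df_intervals(dfs: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for rec in dfs.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.df_id}\n")


def read_spikein_reference(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"spikein_id", "input_concentration", "length_bp"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing spike-in columns {sorted(missing)}")
    if (df["input_concentration"] <= 0).any():
        raise FormatError(f"{path}: spike-in concentrations must be positive")
    if df["spikein_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate spikein_id values")
    return df.set_index("spikein_id", drop=False).rename_axis(None)


def write_spikein_reference(ref: pd.DataFrame, path) -> None:
    ref.to_csv(path, sep="\t", index=False)
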
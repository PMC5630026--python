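"""CRE catalogue construction.

A CRE (cis-regulatory element) here is a merged interval of H3K27ac and/or
H3K4me1 ChIP-seq signal.  The catalogue assigns each CRE a class from its
distance to the nearest transcription start site (promoter < 1 kb,
enhancer otherwise), the nearest gene, and its transposable-element (TE)
content as the fraction of its length covered by the union of annotated
TE intervals.  All coordinates are 0-based half-open (BED semantics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

PROMOTER_TSS_BP = 1000
TE_MIN_FRACTION = 0.20

BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into a DataFrame (chrom, start, end[, name, ...])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    ncol = min(df.shape[1], 6)
    df = df.iloc[:, :ncol]
    df.columns = BED_COLS[:ncol]
    bad = df.index[(df["end"] <= df["start"]) | (df["start"] < 0)]
    if len(bad):
        raise ValueError(f"malformed BED interval at line {bad[0] + 1}")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> List[Tuple[int, int]]:
    """Merge possibly-overlapping sorted intervals into a disjoint union."""
    merged: List[Tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((int(s), int(e)))
    return merged


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals per chromosome; output disjoint and sorted."""
    out = []
    for chrom, grp in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        for s, e in _merge_sorted(grp["start"].to_numpy(), grp["end"].to_numpy()):
            out.append((chrom, s, e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def merge_marks(peaks_k27ac: pd.DataFrame, peaks_k4me1: pd.DataFrame) -> pd.DataFrame:
    """Merge the two histone-mark peak sets into one CRE interval set.

    Any two input intervals sharing at least one base end up in the same
    output interval.  The ``marks`` column records which marks contributed
    to each merged interval.
    """
    a = peaks_k27ac.assign(_mark="H3K27ac")
    b = peaks_k4me1.assign(_mark="H3K4me1")
    both = pd.concat([a[["chrom", "start", "end", "_mark"]], b[["chrom", "start", "end", "_mark"]]])
    merged = merge_intervals(both)
    # provenance: which marks overlap each merged interval
    marks_col = []
    for _, row in merged.iterrows():
        hit = both[
            (both["chrom"] == row["chrom"])
            & (both["start"] < row["end"])
            & (both["end"] > row["start"])
        ]["_mark"].unique()
        marks_col.append(",".join(sorted(hit)))
    merged["marks"] = marks_col
    return merged


def tss_distance(start: int, end: int, tss_positions: np.ndarray) -> np.ndarray:
    """Edge distance from a [start, end) interval to each TSS point.

    0 when the TSS lies inside the interval; otherwise the gap, counting
    the base immediately right of the interval as distance 1.
    """
    p = np.asarray(tss_positions)
    left = np.maximum(start - p, 0)
    right = np.maximum(p - (end - 1), 0)
    return np.maximum(left, right) * ((p < start) | (p >= end))


def classify_cre(
    interval: Tuple[str, int, int],
    tss_table: pd.DataFrame,
    promoter_bp: int = PROMOTER_TSS_BP,
) -> Tuple[Optional[str], Optional[int], Optional[str]]:
    """Classify one CRE as promoter/enhancer and find its nearest gene.

    ``tss_table`` needs columns chrom, pos (0-based TSS coordinate), gene.
    A CRE is a promoter iff its edge distance to the nearest TSS is
    strictly below ``promoter_bp`` (exactly 1 kb is an enhancer).  Distance
    ties between genes resolve to the lexicographically smallest gene id.
    Returns (None, None, None) if the chromosome has no TSS.
    """
    chrom, start, end = interval
    if end <= start:
        raise ValueError("zero- or negative-length CRE")
    sub = tss_table[tss_table["chrom"] == chrom]
    if sub.empty:
        return None, None, None
    d = tss_distance(start, end, sub["pos"].to_numpy())
    dmin = int(d.min())
    genes = sub.loc[sub.index[d == dmin], "gene"]
    nearest = sorted(genes)[0]
    cls = "promoter" if dmin < promoter_bp else "enhancer"
    return cls, dmin, nearest


def union_coverage(start: int, end: int, te_starts: Sequence[int], te_ends: Sequence[int]) -> int:
    """Bases of [start, end) covered by the union of the given intervals."""
    clipped = [
        (max(s, start), min(e, end))
        for s, e in zip(te_starts, te_ends)
        if min(e, end) > max(s, start)
    ]
    if not clipped:
        return 0
    clipped.sort()
    covered = 0
    cur_s, cur_e = clipped[0]
    for s, e in clipped[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    covered += cur_e - cur_s
    return covered


def annotate_te_overlap(
    interval: Tuple[str, int, int],
    te_annotation: pd.DataFrame,
    min_fraction: float = TE_MIN_FRACTION,
) -> Tuple[float, List[str], bool]:
    """TE content of one CRE.

    Returns (union-coverage fraction, contributing subfamilies, flag) where
    the flag is true iff the union of TE intervals covers at least
    ``min_fraction`` of the CRE length (>= 20% by default, boundary
    inclusive).  Overlapping/nested TE records are not double counted.
    """
    chrom, start, end = interval
    length = end - start
    if length <= 0:
        raise ValueError("zero-length CRE")
    sub = te_annotation[
        (te_annotation["chrom"] == chrom)
        & (te_annotation["start"] < end)
        & (te_annotation["end"] > start)
    ]
    covered = union_coverage(start, end, sub["start"].to_list(), sub["end"].to_list())
    fraction = covered / length
    families = sorted(sub["subfamily"].unique()) if len(sub) else []
    return fraction, families, fraction >= min_fraction


def build_catalog(
    cres: pd.DataFrame,
    tss_table: pd.DataFrame,
    te_annotation: Optional[pd.DataFrame] = None,
    promoter_bp: int = PROMOTER_TSS_BP,
    te_min_fraction: float = TE_MIN_FRACTION,
) -> pd.DataFrame:
    """Annotate a CRE interval table (chrom, start, end[, name]) in bulk.

    Adds cre_id, cre_class, tss_distance, nearest_gene and — when a TE
    annotation is supplied — te_overlap_fraction, te_families, te_flag.
    """
    rows = []
    for i, row in cres.reset_index(drop=True).iterrows():
        cre_id = row["name"] if "name" in cres.columns and pd.notna(row.get("name")) else f"cre_{i:05d}"
        interval = (row["chrom"], int(row["start"]), int(row["end"]))
        cls, dist, gene = classify_cre(interval, tss_table, promoter_bp)
        rec = {
            "cre_id": cre_id,
            "chrom": interval[0],
            "start": interval[1],
            "end": interval[2],
            "cre_class": cls,
            "tss_distance": dist,
            "nearest_gene": gene,
        }
        if te_annotation is not None:
            frac, fams, flag = annotate_te_overlap(interval, te_annotation, te_min_fraction)
            rec.update(
                te_overlap_fraction=frac,
                te_families=",".join(fams),
                te_flag=flag,
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def read_te_annotation(path) -> pd.DataFrame:
    """Read a TE annotation TSV (chrom, start, end, subfamily, family, class, lineage_age)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "subfamily"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TE annotation missing columns: {sorted(missing)}")
    if df["subfamily"].isna().any() or (df["subfamily"] == "").any():
        raise ValueError("TE annotation has empty subfamily values")
    return df
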
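"""Orthologous-region mapping and sequence divergence from MSA blocks.

Human CRE intervals are projected through multiple-sequence-alignment (MAF)
blocks to recover the orthologous interval and aligned subsequence in each
of the other five species.  Per-nucleotide pairwise divergence to human is
then counted directly on the aligned columns (over the CRE plus flanking
sequence), excluding every column where human has a gap, and species-pair
divergence distributions are screened for outliers with an iterative
Grubbs test.

Coordinates are 0-based half-open throughout; minus-strand MAF rows are
converted to forward-strand coordinates when intervals are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import AlignIO
from scipy import stats

from .trees import SPECIES

GAP = "-"
MIN_COVERAGE = 0.5
FLANK_BP = 500


@dataclass
class AlignmentRow:
    species: str
    chrom: str
    start: int  # strand coordinates, as in the MAF 's' line
    size: int  # ungapped length
    strand: str
    src_size: int
    text: str  # gapped sequence

    @property
    def forward_interval(self) -> Tuple[int, int]:
        """[start, end) on the forward strand."""
        if self.strand == "+":
            return self.start, self.start + self.size
        return self.src_size - self.start - self.size, self.src_size - self.start


@dataclass
class AlignmentBlock:
    rows: Dict[str, AlignmentRow]

    def __post_init__(self) -> None:
        lengths = {len(r.text) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("ragged block: unequal gapped row lengths")
        for r in self.rows.values():
            ungapped = len(r.text) - r.text.count(GAP)
            if ungapped != r.size:
                raise ValueError(
                    f"row {r.species}.{r.chrom}: declared size {r.size} != ungapped length {ungapped}"
                )

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())).text)


def parse_maf(path) -> List[AlignmentBlock]:
    """Parse a MAF file into validated alignment blocks.

    Row ids are expected as ``species.chrom``.  A block whose rows have
    unequal gapped lengths, or whose declared ungapped size disagrees with
    the sequence, is rejected with its (0-based) block index.
    """
    blocks: List[AlignmentBlock] = []
    with open(path) as fh:
        it = AlignIO.parse(fh, "maf")
        i = 0
        while True:
            try:
                msa = next(it)
            except StopIteration:
                break
            except ValueError as e:
                raise ValueError(f"block {i}: {e}") from None
            rows: Dict[str, AlignmentRow] = {}
            for rec in msa:
                species, _, chrom = rec.id.partition(".")
                ann = rec.annotations
                rows[species] = AlignmentRow(
                    species=species,
                    chrom=chrom,
                    start=int(ann["start"]),
                    size=int(ann["size"]),
                    strand="+" if ann["strand"] in (1, "+") else "-",
                    src_size=int(ann["srcSize"]),
                    text=str(rec.seq),
                )
            try:
                blocks.append(AlignmentBlock(rows=rows))
            except ValueError as e:
                raise ValueError(f"block {i}: {e}") from None
            i += 1
    return blocks


@dataclass
class OrthologSet:
    """A human CRE with its orthologous interval in each species.

    ``intervals`` maps species to forward-strand (chrom, start, end) or
    ``None`` when the species' aligned coverage of the human interval is
    below ``min_coverage``.  ``aligned`` holds equal-length gapped strings
    over the human interval extended by the flank, for divergence counting.
    """

    cre_id: str
    human_interval: Tuple[str, int, int]
    intervals: Dict[str, Optional[Tuple[str, int, int]]] = field(default_factory=dict)
    coverage: Dict[str, float] = field(default_factory=dict)
    aligned: Dict[str, str] = field(default_factory=dict)
    six_way: bool = False


def _columns_for_interval(hrow: AlignmentRow, a: int, b: int) -> Optional[Tuple[int, int]]:
    """Contiguous column range [lo, hi) spanning human bases in [a, b)."""
    pos = hrow.start
    lo = hi = None
    for col, ch in enumerate(hrow.text):
        if ch != GAP:
            if a <= pos < b:
                if lo is None:
                    lo = col
                hi = col + 1
            pos += 1
            if pos >= b:
                break
    if lo is None:
        return None
    return lo, hi


def _project_row(row: AlignmentRow, lo: int, hi: int) -> Optional[Tuple[int, int, str]]:
    """Forward-strand interval of a species row over columns [lo, hi)."""
    before = len(row.text[:lo]) - row.text[:lo].count(GAP)
    inside = len(row.text[lo:hi]) - row.text[lo:hi].count(GAP)
    if inside == 0:
        return None
    s = row.start + before
    e = s + inside
    if row.strand == "-":
        s, e = row.src_size - e, row.src_size - s
    return s, e, row.strand


def map_interval(
    human_interval: Tuple[str, int, int],
    blocks: Sequence[AlignmentBlock],
    cre_id: str = "",
    min_coverage: float = MIN_COVERAGE,
    flank: int = FLANK_BP,
    species: Sequence[str] = SPECIES,
    reference: str = "human",
) -> OrthologSet:
    """Project a human interval into each species through the MAF blocks.

    A species' ortholog is the span of its non-gap columns aligned to the
    human interval's columns.  Coverage is the fraction of human interval
    bases aligned to a base (not gap) in that species; below
    ``min_coverage`` the species is marked absent.  Projections from
    several blocks are stitched when collinear on the same strand;
    otherwise the single block with the greatest coverage wins (ties:
    lowest start).  ``six_way`` requires all six species present.
    """
    chrom, a, b = human_interval
    if b <= a:
        raise ValueError("empty human interval")
    length = b - a
    fa, fb = a - flank, b + flank

    # per-block extraction, ordered along the human sequence
    hits = []
    for bi, blk in enumerate(blocks):
        hrow = blk.rows.get(reference)
        if hrow is None or hrow.chrom != chrom or hrow.strand != "+":
            continue
        h_lo, h_hi = hrow.forward_interval
        if h_hi <= a or h_lo >= b:
            continue
        hits.append((h_lo, bi, blk, hrow))
    hits.sort()

    oset = OrthologSet(cre_id=cre_id, human_interval=human_interval)
    if not hits:
        for sp in species:
            if sp != reference:
                oset.intervals[sp] = None
                oset.coverage[sp] = 0.0
        oset.six_way = False
        return oset

    # core projection (the interval itself) and flanked alignment strings
    per_block_proj: Dict[str, List[Tuple[int, int, str, int]]] = {sp: [] for sp in species}
    covered_bases: Dict[str, Dict[int, int]] = {sp: {} for sp in species}
    aligned_parts: Dict[str, List[str]] = {sp: [] for sp in species}

    for h_lo, bi, blk, hrow in hits:
        core = _columns_for_interval(hrow, a, b)
        if core is not None:
            lo, hi = core
            hseq = hrow.text[lo:hi]
            for sp in species:
                row = blk.rows.get(sp)
                if row is None:
                    continue
                proj = _project_row(row, lo, hi)
                if proj is None:
                    continue
                s, e, strand = proj
                # bases of the human interval covered by a base in sp
                cov = sum(
                    1
                    for hc, sc in zip(hseq, row.text[lo:hi])
                    if hc != GAP and sc != GAP
                )
                per_block_proj[sp].append((s, e, strand, cov))
                covered_bases[sp][bi] = cov
        flank_cols = _columns_for_interval(hrow, fa, fb)
        if flank_cols is not None:
            flo, fhi = flank_cols
            width = fhi - flo
            for sp in species:
                row = blk.rows.get(sp)
                aligned_parts[sp].append(row.text[flo:fhi] if row is not None else GAP * width)

    for sp in species:
        oset.aligned[sp] = "".join(aligned_parts[sp])

    for sp in species:
        if sp == reference:
            oset.intervals[sp] = (chrom, a, b)
            oset.coverage[sp] = 1.0
            continue
        projs = per_block_proj[sp]
        if not projs:
            oset.intervals[sp] = None
            oset.coverage[sp] = 0.0
            continue
        strands = {p[2] for p in projs}
        collinear = (
            len(strands) == 1
            and all(projs[i][1] <= projs[i + 1][0] for i in range(len(projs) - 1))
        )
        if len(projs) > 1 and collinear:
            s = projs[0][0]
            e = projs[-1][1]
            cov = sum(p[3] for p in projs)
        else:
            best = max(projs, key=lambda p: (p[3], -p[0]))
            s, e, _, cov = best
        frac = cov / length
        if frac >= min_coverage:
            # chromosome name from any row of this species
            sp_chrom = next(
                blk.rows[sp].chrom for _, _, blk, _ in hits if sp in blk.rows
            )
            oset.intervals[sp] = (sp_chrom, s, e)
        else:
            oset.intervals[sp] = None
        oset.coverage[sp] = frac

    oset.six_way = all(oset.intervals.get(sp) is not None for sp in species)
    return oset


def pairwise_divergence(
    oset: OrthologSet, reference: str = "human"
) -> pd.DataFrame:
    """Per-species divergence to human over the flanked aligned columns.

    Columns where human has a gap are excluded entirely; columns where the
    other species has a gap, or where either base is N, are excluded from
    ``compared_columns``.  Divergence = mismatches / compared_columns,
    case-insensitive.  A species with zero comparable columns gets an
    undefined (NaN) divergence and ``undefined=True``.
    """
    href = oset.aligned.get(reference, "")
    rows = []
    for sp, seq in oset.aligned.items():
        if sp == reference:
            continue
        mism = 0
        comp = 0
        for hc, sc in zip(href, seq):
            if hc == GAP:
                continue
            if sc == GAP:
                continue
            h, s = hc.upper(), sc.upper()
            if h == "N" or s == "N":
                continue
            comp += 1
            if h != s:
                mism += 1
        rows.append(
            {
                "cre_id": oset.cre_id,
                "species": sp,
                "mismatches": mism,
                "compared_columns": comp,
                "divergence": (mism / comp) if comp > 0 else float("nan"),
                "undefined": comp == 0,
            }
        )
    return pd.DataFrame(rows)


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for sample size n."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def flag_divergence_outliers(
    records: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Iterative Grubbs outlier flagging per species-pair distribution.

    Within each species group the most extreme divergence is tested
    against the Grubbs critical value at ``alpha`` and, if rejected,
    flagged and removed; the test repeats until no outlier remains or
    fewer than 3 values are left.  Groups smaller than 3 are never
    flagged.  Adds/overwrites a boolean ``outlier`` column.
    """
    out = records.copy()
    out["outlier"] = False
    for sp, grp in records.groupby("species"):
        vals = grp["divergence"].to_numpy(dtype=float)
        idx = grp.index.to_numpy()
        ok = np.isfinite(vals)
        vals, idx = vals[ok], idx[ok]
        while len(vals) >= 3:
            mean, sd = vals.mean(), vals.std(ddof=1)
            if sd == 0:
                break
            dev = np.abs(vals - mean)
            j = int(np.argmax(dev))
            g = dev[j] / sd
            if g > grubbs_critical(len(vals), alpha):
                out.loc[idx[j], "outlier"] = True
                keep = np.ones(len(vals), dtype=bool)
                keep[j] = False
                vals, idx = vals[keep], idx[keep]
            else:
                break
    return out
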
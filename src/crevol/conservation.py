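"""Human-centric comparison battery and conservation classification.

Every six-way-alignable CRE is tested for differential histone
modification in nine comparisons: the reference species (human by
default) against each of the five other species, and four clade-level
group contrasts (reference vs. all others, ape vs. the rest, Catarrhini
vs. the rest, Haplorrhini vs. Strepsirrhini).  A CRE with no significant
comparison at the chosen FDR is called conserved; lineage-specific labels
require the clade group test plus sign-consistent pairwise significance
against every species outside the clade, with the within-clade pairwise
comparisons non-significant.  Anything else divergent is
``other_divergent``.

The same battery drives the differential-expression classification of
genes (``assay='RNA'`` matrices go through ``glm.diff_expression``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .glm import CountMatrix, diff_expression, diff_histone
from .trees import CLADES, SPECIES

LABELS = (
    "conserved",
    "human_specific",
    "ape_specific",
    "catarrhini_specific",
    "haplorrhini_specific",
    "other_divergent",
)


@dataclass(frozen=True)
class ComparisonSpec:
    comparison_id: str
    group_a: frozenset
    group_b: frozenset

    def __post_init__(self) -> None:
        if self.group_a & self.group_b:
            raise ValueError("comparison groups overlap")


def battery_specs(reference: str = "human") -> List[ComparisonSpec]:
    """The nine comparisons: five pairwise plus four clade contrasts.

    ``group_a`` always contains the reference, so a positive effect means
    higher activity on the reference side of the split.
    """
    if reference not in SPECIES:
        raise ValueError(f"unknown reference species {reference!r}")
    others = [sp for sp in SPECIES if sp != reference]
    specs = [
        ComparisonSpec(f"{reference}_vs_{sp}", frozenset({reference}), frozenset({sp}))
        for sp in others
    ]
    specs.append(ComparisonSpec(f"{reference}_vs_rest", frozenset({reference}), frozenset(others)))
    for clade in ("ape", "catarrhini", "haplorrhini"):
        grp = CLADES[clade]
        if reference not in grp:
            grp = frozenset(SPECIES) - grp  # re-rooted battery: keep ref in A
        rest = frozenset(SPECIES) - grp
        cid = f"{clade}_vs_rest" if clade != "haplorrhini" else "haplorrhini_vs_strepsirrhini"
        specs.append(ComparisonSpec(cid, grp, rest))
    return specs


def _merge_marks_results(per_mark: Dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Combine per-mark test tables for one comparison.

    A CRE is significant if either mark's test is significant; the
    reported effect comes from the mark with the smaller p-value.  A CRE
    untested in every mark stays untested.
    """
    marks = list(per_mark)
    if len(marks) == 1:
        return per_mark[marks[0]]
    merged = None
    for mk in marks:
        t = per_mark[mk].set_index("feature_id")
        if merged is None:
            merged = t.copy()
            continue
        better = t["p"].fillna(np.inf) < merged["p"].fillna(np.inf)
        for col in ("log2fc", "se", "wald_z", "p", "padj", "status"):
            merged.loc[better, col] = t.loc[better, col]
        merged["significant"] = merged["significant"].fillna(False) | t["significant"].fillna(False)
        both_untested = (merged["status"] == "untested") & (t["status"] == "untested")
        merged.loc[~both_untested & (merged["status"] == "untested"), "status"] = "tested"
    return merged.reset_index()


@dataclass
class BatteryResult:
    tables: Dict[str, pd.DataFrame]  # comparison_id -> merged DiffResult table
    calls: pd.DataFrame  # feature x comparison significance vector entries
    reference: str
    fdr: float


def significance_entry(row: pd.Series) -> str:
    if row["status"] == "untested":
        return "untested"
    if bool(row["significant"]):
        return "sig+" if row["log2fc"] > 0 else "sig-"
    return "ns"


def run_comparison_battery(
    counts: CountMatrix,
    fdr: float = 0.10,
    marks: Optional[Sequence[str]] = None,
    reference: str = "human",
) -> BatteryResult:
    """Run all nine comparisons and assemble the significance vectors.

    ``marks`` defaults to every ChIP mark present in the metadata; each
    mark is tested independently and the per-comparison tables merged
    (significant if either mark is).  Raises ``ComparisonError`` if any
    comparison lacks two IP and two input samples per group.
    """
    if marks is None:
        marks = sorted(
            m for m in counts.metadata["mark"].unique() if m not in ("none", "", None)
        )
        if not marks:
            marks = [None]
    specs = battery_specs(reference)
    tables: Dict[str, pd.DataFrame] = {}
    for spec in specs:
        per_mark = {
            mk if mk is not None else "all": diff_histone(
                counts, spec.group_a, spec.group_b, spec.comparison_id, mark=mk, fdr=fdr
            )
            for mk in marks
        }
        tables[spec.comparison_id] = _merge_marks_results(per_mark)

    features = tables[specs[0].comparison_id]["feature_id"]
    calls = pd.DataFrame(index=features)
    for cid, tab in tables.items():
        calls[cid] = tab.set_index("feature_id").loc[features].apply(significance_entry, axis=1).to_numpy()
    return BatteryResult(tables=tables, calls=calls, reference=reference, fdr=fdr)


def calls_at_threshold(battery: BatteryResult, fdr: float) -> pd.DataFrame:
    """Re-derive the significance vectors at a different FDR threshold.

    BH-adjusted p-values are threshold-free, so the battery tables can be
    re-read at any FDR without re-fitting; used e.g. to check that the
    conserved count is monotone non-increasing in the threshold.
    """
    first = next(iter(battery.tables.values()))
    features = first["feature_id"]
    calls = pd.DataFrame(index=features)
    for cid, tab in battery.tables.items():
        t = tab.set_index("feature_id").loc[features]
        sig = t["p"].notna() & (t["padj"] < fdr)
        entries = np.where(
            t["status"] == "untested",
            "untested",
            np.where(sig, np.where(t["log2fc"] > 0, "sig+", "sig-"), "ns"),
        )
        calls[cid] = entries
    calls.index.name = "cre_id"
    return calls


def _sig(v: str) -> bool:
    return v in ("sig+", "sig-")


def _consistent_sign(values: Iterable[str]) -> bool:
    vals = list(values)
    return all(_sig(v) for v in vals) and len(set(vals)) == 1


def classify_conservation(
    vector: Dict[str, str],
    reference: str = "human",
    require_pairwise: bool = True,
) -> str:
    """Label one CRE from its nine-comparison significance vector.

    ``require_pairwise=False`` switches to the group-test-only mode: a
    lineage label then needs the clade group test plus non-significant
    within-clade pairwise comparisons, without demanding significance in
    every cross-clade pairwise test.
    """
    others = [sp for sp in SPECIES if sp != reference]
    expected = {f"{reference}_vs_{sp}" for sp in others} | {
        f"{reference}_vs_rest",
        "ape_vs_rest",
        "catarrhini_vs_rest",
        "haplorrhini_vs_strepsirrhini",
    }
    missing = expected - set(vector)
    if missing:
        raise ValueError(f"incomplete significance vector, missing {sorted(missing)}")
    pairwise = {sp: vector[f"{reference}_vs_{sp}"] for sp in others}

    if all(v in ("ns", "untested") for v in vector.values()):
        return "conserved"

    def clade_label(group_id: str, inside: Sequence[str], outside: Sequence[str], label: str):
        if not _sig(vector[group_id]):
            return None
        if any(pairwise[sp] != "ns" for sp in inside):
            return None
        out_vals = [pairwise[sp] for sp in outside]
        if require_pairwise:
            if not _consistent_sign(out_vals):
                return None
        else:
            if any(v == "untested" for v in out_vals):
                return None
        return label

    ref_clades = [
        (f"{reference}_vs_rest", [], others, f"{reference}_specific"),
        ("ape_vs_rest", [sp for sp in CLADES["ape"] if sp not in (reference,)],
         [sp for sp in others if sp not in CLADES["ape"]], "ape_specific"),
        ("catarrhini_vs_rest", [sp for sp in CLADES["catarrhini"] if sp != reference],
         [sp for sp in others if sp not in CLADES["catarrhini"]], "catarrhini_specific"),
        ("haplorrhini_vs_strepsirrhini", [sp for sp in CLADES["haplorrhini"] if sp != reference],
         [sp for sp in others if sp not in CLADES["haplorrhini"]], "haplorrhini_specific"),
    ]
    for gid, inside, outside, label in ref_clades:
        res = clade_label(gid, inside, outside, label)
        if res is not None:
            return res
    return "other_divergent"


def classify_all(
    battery: BatteryResult, require_pairwise: bool = True
) -> pd.DataFrame:
    """Classify every feature in a battery result; one label each."""
    labels = [
        classify_conservation(dict(row), battery.reference, require_pairwise)
        for _, row in battery.calls.iterrows()
    ]
    out = battery.calls.copy()
    out["label"] = labels
    out.index.name = "cre_id"
    return out.reset_index()


def summarize_catalogue(
    calls: pd.DataFrame, catalogue: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Counts and percentages of each conservation label.

    Overall rows first, then rows stratified by ``cre_class``, TE-overlap
    flag and TE lineage age when a catalogue is supplied.  ``pct`` is an
    unrounded percentage of the stratum total; render with one decimal.
    """
    rows: List[dict] = []

    def add_stratum(name: str, sub: pd.DataFrame) -> None:
        total = len(sub)
        if total == 0:
            return
        vc = sub["label"].value_counts()
        for label in LABELS:
            n = int(vc.get(label, 0))
            rows.append(
                {
                    "stratum": name,
                    "label": label,
                    "count": n,
                    "total": total,
                    "pct": 100.0 * n / total,
                }
            )

    add_stratum("all", calls)
    if catalogue is not None and len(calls):
        merged = calls.merge(catalogue, on="cre_id", how="left")
        if "cre_class" in merged.columns:
            for cls, sub in merged.groupby("cre_class", dropna=True):
                add_stratum(f"class:{cls}", sub)
        if "te_flag" in merged.columns:
            for flag, sub in merged.groupby("te_flag", dropna=True):
                add_stratum(f"te_overlap:{bool(flag)}", sub)
        if "te_lineage_age" in merged.columns:
            for age, sub in merged[merged["te_lineage_age"].notna() & (merged["te_lineage_age"] != "")].groupby(
                "te_lineage_age"
            ):
                add_stratum(f"te_age:{age}", sub)
    return pd.DataFrame(rows, columns=["stratum", "label", "count", "total", "pct"])
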
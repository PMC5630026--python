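"""End-to-end orchestration of the cross-species CRE analysis.

``run_all`` executes the stages in dependency order — catalogue,
orthology mapping, divergence, the differential histone-modification
battery, conservation classification, differential expression, TE
enrichment and the association statistics — writing each stage's table
under the output directory together with a run manifest carrying the
configuration hash and file checksums.  A rerun with the same
configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import association as assoc
from . import catalog as cat
from . import conservation as cons
from . import enrichment as enr
from . import orthology as orth
from .glm import CountMatrix, diff_expression
from .simulate import SimConfig, write_fixture_bundle
from .trees import SPECIES

log = logging.getLogger("crevol")


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 in the CLI)."""


class DataError(ValueError):
    """Invalid or inconsistent input data (exit code 3 in the CLI)."""


@dataclass
class PipelineConfig:
    outdir: str = "crevol_out"
    # input paths; all None -> simulate a bundle first
    maf: Optional[str] = None
    cres_bed: Optional[str] = None
    tss_bed: Optional[str] = None
    te_tsv: Optional[str] = None
    chip_counts: Optional[str] = None
    rna_counts: Optional[str] = None
    samples_tsv: Optional[str] = None
    gene_lengths_tsv: Optional[str] = None
    genome_tsv: Optional[str] = None
    # thresholds (study defaults)
    fdr_histone: float = 0.10
    fdr_expression: float = 0.05
    fdr_te: float = 0.01
    te_min_fraction: float = 0.20
    promoter_tss_bp: int = 1000
    min_coverage: float = 0.5
    flank: int = 500
    n_shuffles: int = 1000
    seed: int = 0
    reference: str = "human"
    simulate: Optional[SimConfig] = None

    def __post_init__(self) -> None:
        for name in ("fdr_histone", "fdr_expression", "fdr_te", "te_min_fraction", "min_coverage"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        if self.promoter_tss_bp <= 0 or self.n_shuffles <= 0 or self.flank < 0:
            raise ConfigError("promoter_tss_bp and n_shuffles must be positive, flank >= 0")
        if self.reference not in SPECIES:
            raise ConfigError(f"unknown reference species {self.reference!r}")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output location is excluded)."""
        d = asdict(self)
        d.pop("outdir", None)
        if self.simulate is not None:
            d["simulate"] = {k: list(v) if isinstance(v, tuple) else v
                             for k, v in asdict(self.simulate).items()}
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str) -> PipelineConfig:
    """Read a TOML config file into a PipelineConfig (+ optional [simulate])."""
    import tomllib

    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except (OSError, tomllib.TOMLDecodeError) as e:
        raise ConfigError(f"cannot read config {path}: {e}") from None
    sim = raw.pop("simulate", None)
    try:
        cfg = PipelineConfig(**raw)
        if sim is not None:
            for key in ("cre_length_range", "gene_length_range", "marks"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulate = SimConfig(**sim)
    except TypeError as e:
        raise ConfigError(str(e)) from None
    return cfg


def _require(path: Optional[str], what: str) -> Path:
    if path is None:
        raise ConfigError(f"missing required input: {what}")
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"{what} file not found: {path}")
    return p


def _read_counts(counts_path, samples_path, lengths_path=None) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(samples_path, sep="\t", index_col=0)
    meta = meta.loc[[s for s in counts.columns]]
    lengths = None
    if lengths_path is not None:
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    try:
        return CountMatrix(counts, meta, feature_lengths=lengths)
    except ValueError as e:
        raise DataError(str(e)) from None


def run_all(config: PipelineConfig) -> Dict:
    """Run every stage; returns the run manifest dictionary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(asctime)s %(name)s %(message)s")

    if config.simulate is not None:
        log.info("stage simulate: writing synthetic bundle")
        bdir = out / "bundle"
        write_fixture_bundle(config.simulate, bdir)
        config.maf = str(bdir / "msa.maf")
        config.cres_bed = str(bdir / "cres.bed")
        config.tss_bed = str(bdir / "tss.bed")
        config.te_tsv = str(bdir / "te_annotation.tsv")
        config.chip_counts = str(bdir / "chip_counts.tsv")
        config.rna_counts = str(bdir / "rna_counts.tsv")
        config.samples_tsv = str(bdir / "samples.tsv")
        config.gene_lengths_tsv = str(bdir / "gene_lengths.tsv")
        config.genome_tsv = str(bdir / "genome.tsv")

    # ---- pre-flight -------------------------------------------------------
    cres_path = _require(config.cres_bed, "CRE BED")
    tss_path = _require(config.tss_bed, "TSS BED")
    te_path = _require(config.te_tsv, "TE annotation")
    maf_path = _require(config.maf, "MAF alignment")
    chip_path = _require(config.chip_counts, "ChIP counts")
    samples_path = _require(config.samples_tsv, "sample metadata")

    cres = cat.read_bed(cres_path)
    tss = cat.read_bed(tss_path).rename(columns={"name": "gene"})
    tss["pos"] = tss["start"]
    te = cat.read_te_annotation(te_path)
    chip = _read_counts(chip_path, samples_path)
    rna = None
    if config.rna_counts is not None:
        rna = _read_counts(
            _require(config.rna_counts, "RNA counts"),
            samples_path,
            config.gene_lengths_tsv,
        )
        rna = rna.subset_samples(list(rna.metadata.index[rna.metadata["assay"] == "RNA"]))

    genome_sizes: Optional[Dict[str, int]] = None
    if config.genome_tsv is not None:
        g = pd.read_csv(config.genome_tsv, sep="\t")
        hg = g[g["species"] == config.reference] if "species" in g.columns else g
        genome_sizes = dict(zip(hg["chrom"], hg["size"].astype(int)))

    # ---- catalogue --------------------------------------------------------
    log.info("stage catalog: %d CREs", len(cres))
    catalogue = cat.build_catalog(cres, tss, te, config.promoter_tss_bp, config.te_min_fraction)
    catalogue.to_csv(out / "catalogue.tsv", sep="\t", index=False)

    # ---- orthology + divergence ------------------------------------------
    log.info("stage orthology: mapping through MAF")
    blocks = orth.parse_maf(maf_path)
    osets = []
    div_frames = []
    ortho_rows = []
    for _, row in cres.iterrows():
        cre_id = row.get("name", f"{row['chrom']}:{row['start']}")
        oset = orth.map_interval(
            (row["chrom"], int(row["start"]), int(row["end"])),
            blocks,
            cre_id=cre_id,
            min_coverage=config.min_coverage,
            flank=config.flank,
            reference=config.reference,
        )
        osets.append(oset)
        for sp, iv in oset.intervals.items():
            ortho_rows.append(
                {
                    "cre_id": cre_id,
                    "species": sp,
                    "chrom": iv[0] if iv else "",
                    "start": iv[1] if iv else -1,
                    "end": iv[2] if iv else -1,
                    "coverage": oset.coverage.get(sp, np.nan),
                    "six_way": oset.six_way,
                }
            )
        if oset.six_way:
            div_frames.append(orth.pairwise_divergence(oset, reference=config.reference))
    pd.DataFrame(ortho_rows).to_csv(out / "orthologs.tsv", sep="\t", index=False)
    divergence = (
        pd.concat(div_frames, ignore_index=True) if div_frames else pd.DataFrame(
            columns=["cre_id", "species", "mismatches", "compared_columns", "divergence", "undefined"]
        )
    )
    divergence = orth.flag_divergence_outliers(divergence)
    divergence.to_csv(out / "divergence.tsv", sep="\t", index=False)
    six_way_ids = [o.cre_id for o in osets if o.six_way]
    log.info("stage orthology: %d/%d six-way-alignable", len(six_way_ids), len(osets))

    # ---- differential histone battery ------------------------------------
    log.info("stage battery: 9 comparisons at FDR < %.2f", config.fdr_histone)
    chip_six = CountMatrix(
        chip.counts.loc[[i for i in chip.counts.index if i in set(six_way_ids)]],
        chip.metadata,
    )
    if len(chip_six.counts) == 0:
        raise DataError("no six-way-alignable CRE has ChIP counts")
    battery = cons.run_comparison_battery(
        chip_six, fdr=config.fdr_histone, reference=config.reference
    )
    for cid, tab in battery.tables.items():
        tab.to_csv(out / f"diffmod_{cid}.tsv", sep="\t", index=False)
    calls = cons.classify_all(battery)
    calls.to_csv(out / "conservation_calls.tsv", sep="\t", index=False)
    summary = cons.summarize_catalogue(calls, catalogue)
    summary.to_csv(out / "conservation_summary.tsv", sep="\t", index=False)

    # ---- differential expression -----------------------------------------
    expr_tables: Dict[str, pd.DataFrame] = {}
    if rna is not None and len(rna.counts):
        log.info("stage expression: 9 comparisons at FDR < %.2f", config.fdr_expression)
        for spec in cons.battery_specs(config.reference):
            expr_tables[spec.comparison_id] = diff_expression(
                rna, spec.group_a, spec.group_b, spec.comparison_id, fdr=config.fdr_expression
            )
        pd.concat(expr_tables.values(), ignore_index=True).to_csv(
            out / "diffexpr.tsv", sep="\t", index=False
        )

    # ---- TE enrichment ----------------------------------------------------
    log.info("stage te-enrichment: %d shuffles", config.n_shuffles)
    cre_named = cres.copy()
    if "name" not in cre_named.columns:
        cre_named["name"] = [f"cre_{i}" for i in range(len(cre_named))]
    te_result = enr.enrichment_test(
        cre_named,
        te,
        genome_sizes=genome_sizes,
        n_shuffles=config.n_shuffles,
        seed=config.seed,
        min_fraction=config.te_min_fraction,
        fdr=config.fdr_te,
    )
    te_result.table.to_csv(out / "te_enrichment.tsv", sep="\t", index=False)

    # ---- associations -----------------------------------------------------
    log.info("stage associations")
    assoc_rows: List[dict] = []
    pairwise_ids = [f"{config.reference}_vs_{sp}" for sp in SPECIES if sp != config.reference]

    if expr_tables:
        cre_long = pd.concat(
            [t.assign(comparison_id=cid) for cid, t in battery.tables.items()],
            ignore_index=True,
        )
        gene_long = pd.concat(expr_tables.values(), ignore_index=True)
        links = catalogue.rename(columns={"nearest_gene": "gene"})[["cre_id", "gene"]]
        strata = assoc.de_cre_strata(gene_long, cre_long, links, pairwise_ids)
        res = assoc.cmh_test(strata)
        assoc_rows.append({"test": "cmh_de_x_diffmod", "statistic": res.statistic,
                           "odds_ratio": res.odds_ratio, "p": res.p,
                           "strata": res.stratum_count})

    merged = calls.merge(catalogue, on="cre_id", how="left")
    if merged["te_flag"].notna().any():
        conserved = merged["label"] == "conserved"
        te_flag = merged["te_flag"].astype(bool)
        tbl = np.array(
            [
                [np.sum(conserved & te_flag), np.sum(conserved & ~te_flag)],
                [np.sum(~conserved & te_flag), np.sum(~conserved & ~te_flag)],
            ]
        )
        res = assoc.fisher_exact(tbl)
        assoc_rows.append({"test": "fisher_conserved_x_te", "statistic": res.statistic,
                           "odds_ratio": res.odds_ratio, "p": res.p, "strata": 1})

    div_ok = divergence[~divergence["outlier"] & ~divergence["undefined"]]
    for sp in SPECIES:
        if sp == config.reference:
            continue
        cid = f"{config.reference}_vs_{sp}"
        tab = battery.tables[cid].set_index("feature_id")
        d = div_ok[div_ok["species"] == sp].set_index("cre_id")["divergence"]
        common = tab.index.intersection(d.index)
        sig = tab.loc[common, "significant"].astype(bool)
        if sig.nunique() < 2:
            continue
        try:
            res = assoc.logistic_conservation(sig.to_numpy(), d.loc[common].to_numpy())
        except ValueError:
            continue
        assoc_rows.append({"test": f"logistic_divergence_{cid}", "statistic": res.statistic,
                           "odds_ratio": res.odds_ratio, "p": res.p, "strata": 1})

    if merged["tss_distance"].notna().any():
        ok = merged["tss_distance"].notna()
        bins = assoc.quantile_bins(merged.loc[ok, "tss_distance"])
        outcome = (merged.loc[ok, "label"] == "conserved").to_numpy()
        if 0 < outcome.sum() < len(outcome):
            try:
                res = assoc.logistic_conservation(outcome, bins)
                assoc_rows.append({"test": "logistic_tss_distance_decile",
                                   "statistic": res.statistic, "odds_ratio": res.odds_ratio,
                                   "p": res.p, "strata": 1})
            except ValueError:
                pass

    associations = pd.DataFrame(assoc_rows)
    associations.to_csv(out / "associations.tsv", sep="\t", index=False)

    # ---- report -----------------------------------------------------------
    report_lines = [f"# crevol run report (config {chash})"]
    total = len(calls)
    if total:
        vc = calls["label"].value_counts()
        for label in cons.LABELS:
            n = int(vc.get(label, 0))
            report_lines.append(f"{label}\t{n}\t{100.0 * n / total:.1f}%")
    n_enr = int(te_result.table["enriched"].sum())
    report_lines.append(f"te_subfamilies_enriched\t{n_enr}\tof {len(te_result.table)}")
    for r in assoc_rows:
        p = r["p"]
        report_lines.append(f"{r['test']}\tOR={r['odds_ratio']}\tp={p}")
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")

    files = sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
                   and p.name != "run_manifest.json")
    manifest = {
        "config_hash": chash,
        "files": {f: hashlib.sha256((out / f).read_bytes()).hexdigest() for f in files},
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("done: %d output files", len(files))
    return manifest
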
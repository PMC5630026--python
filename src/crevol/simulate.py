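"""Synthetic six-species dataset generator.

Produces everything the downstream analysis consumes, with known ground
truth: MAF alignment blocks evolved along the fixed primate tree, a human
CRE catalogue with TSS and TE annotations, and NB-distributed ChIP
(IP + input) and RNA count matrices with branch-specific activity effects.

Sequence model: Jukes-Cantor substitutions (probability
``3/4 * (1 - exp(-4t/3))`` per site per branch of length ``t``), indels at
one tenth of the substitution rate with geometric lengths (mean 3), and
TE insertions realised as extra aligned columns appearing on a chosen
branch — present in that branch's descendants, gap in all other species.

Count model: IP counts ~ NB(mean = depth * 2^(ip_enrichment + effect),
dispersion alpha) where the activity effect applies only in the species
descending from the CRE's gain/loss branch; input counts ~ NB(depth,
alpha); RNA counts for the linked gene are shifted by a configurable
fraction of the CRE effect.  Per-sample log-normal depth heterogeneity is
injected so size-factor normalisation is genuinely exercised.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .orthology import AlignmentBlock, AlignmentRow
from .trees import CLADES, SPECIES, SpeciesTree, TreeNode, default_tree

_ALPHABET = np.frombuffer(b"ACGT-", dtype=np.uint8)
_GAP = 4

#: simulated TE subfamilies: (branch of insertion, class, lineage age, length)
TE_FAMILIES: Dict[str, Tuple[str, str, str, int]] = {
    "SVA_F": ("human", "SVA", "human", 450),
    "SVA_B": ("ape", "SVA", "hominid", 350),
    "SVA_C": ("ape", "SVA", "hominid", 360),
    "SVA_D": ("ape", "SVA", "hominid", 380),
    "LTR12C": ("ape", "LTR", "hominoid", 500),
    "AluY": ("root", "SINE", "primate", 300),
    "L2": ("root", "LINE", "eutherian", 400),
    "MIR": ("root", "SINE", "eutherian", 300),
}

STATES = (
    "conserved",
    "human_specific",
    "ape_specific",
    "catarrhini_specific",
    "haplorrhini_specific",
    "other",
)

#: default truth-state mixture; conserved dominates, echoing the largely
#: conserved regulatory landscape, with enough lineage-specific CREs of
#: every class to measure label recovery.
DEFAULT_STATE_PROBS: Dict[str, float] = {
    "conserved": 0.60,
    "human_specific": 0.08,
    "ape_specific": 0.08,
    "catarrhini_specific": 0.08,
    "haplorrhini_specific": 0.08,
    "other": 0.08,
}

#: relative propensity of each truth state to carry a TE, rescaled so the
#: marginal TE fraction matches ``SimConfig.te_density``.  Recently gained
#: CREs carry young TEs; conserved CREs mostly carry ancient families.
_TE_PROPENSITY: Dict[str, float] = {
    "conserved": 0.16,
    "human_specific": 0.95,
    "ape_specific": 0.85,
    "catarrhini_specific": 0.50,
    "haplorrhini_specific": 0.50,
    "other": 0.30,
}

_STATE_BRANCH: Dict[str, str] = {
    "human_specific": "human",
    "ape_specific": "ape",
    "catarrhini_specific": "catarrhini",
    "haplorrhini_specific": "haplorrhini",
}

_STATE_TE_FAMILIES: Dict[str, Tuple[str, ...]] = {
    "conserved": ("L2", "MIR", "AluY"),
    "human_specific": ("SVA_F",),
    "ape_specific": ("SVA_B", "SVA_C", "SVA_D", "LTR12C"),
    "catarrhini_specific": ("AluY", "L2", "MIR"),
    "haplorrhini_specific": ("AluY", "L2", "MIR"),
    "other": ("L2", "MIR"),
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic bundle.

    Defaults give 2,000 CREs at sequencing depth 100 with activity effects
    of |log2fc| = 2 on the gained/lost branch, NB dispersion 0.05, IP
    enriched 4-fold over input, and a TE landscape where about a quarter
    of CREs overlap a TE.
    """

    n_cres: int = 2000
    n_genes: int = 1000
    individuals_per_species: int = 3
    mean_depth: float = 100.0
    dispersion: float = 0.05
    ip_over_input_log2: float = 2.0
    effect_log2fc: float = 2.0
    branch_scale: float = 1.0
    te_density: float = 0.25
    seed: int = 0
    # layout / nuisance parameters
    cre_length_range: Tuple[int, int] = (400, 1000)
    flank: int = 500
    spacer: int = 2000
    n_chromosomes: int = 3
    indel_rate: float = 0.1
    promoter_fraction: float = 0.175
    rna_coupling: float = 0.5
    sf_sigma: float = 0.15
    gene_length_range: Tuple[int, int] = (500, 3000)
    state_probs: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STATE_PROBS))
    marks: Tuple[str, ...] = ("H3K27ac",)

    def __post_init__(self) -> None:
        if self.n_cres < 0 or self.n_genes <= 0:
            raise ValueError("counts must be positive (n_cres may be 0)")
        if not (3 <= self.individuals_per_species <= 4):
            raise ValueError("individuals_per_species must be 3 or 4")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        for f_ in ("te_density", "promoter_fraction"):
            v = getattr(self, f_)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{f_} must lie in [0, 1]")
        if self.cre_length_range[0] <= 0:
            raise ValueError("zero-length genome: CRE lengths must be positive")
        if abs(sum(self.state_probs.values()) - 1.0) > 1e-9:
            raise ValueError("state_probs must sum to 1")

    def child_rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the master seed."""
        h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
        return np.random.default_rng(np.random.SeedSequence([self.seed, h]))


# ---------------------------------------------------------------------------
# ground truth


def make_truth(config: SimConfig) -> pd.DataFrame:
    """Draw the per-CRE ground truth table.

    Columns: cre_id, true_state, true_branch (branch carrying the activity
    change), true_log2fc (0 iff conserved), linked_gene, te_family,
    te_branch.  TE assignment is state-dependent and rescaled so the
    marginal TE fraction matches ``te_density``.
    """
    rng = config.child_rng("truth")
    states = list(config.state_probs)
    probs = np.array([config.state_probs[s] for s in states])
    drawn = rng.choice(states, size=config.n_cres, p=probs)

    marginal = float(sum(config.state_probs[s] * _TE_PROPENSITY[s] for s in states))
    scale = config.te_density / marginal if marginal > 0 else 0.0

    rows = []
    for i in range(config.n_cres):
        state = drawn[i]
        if state == "conserved":
            branch, lfc = "", 0.0
        elif state == "other":
            branch = rng.choice(["chimp", "rhesus", "marmoset"])
            lfc = config.effect_log2fc * (1 if rng.random() < 0.5 else -1)
        else:
            branch = _STATE_BRANCH[state]
            lfc = config.effect_log2fc * (1 if rng.random() < 0.5 else -1)
        te_family = ""
        te_branch = ""
        if rng.random() < min(1.0, scale * _TE_PROPENSITY[state]):
            te_family = rng.choice(_STATE_TE_FAMILIES[state])
            te_branch = TE_FAMILIES[te_family][0]
        rows.append(
            {
                "cre_id": f"cre_{i:05d}",
                "true_state": state,
                "true_branch": branch,
                "true_log2fc": lfc,
                "linked_gene": f"gene_{i % config.n_genes:05d}",
                "te_family": te_family,
                "te_branch": te_branch,
            }
        )
    cols = ["cre_id", "true_state", "true_branch", "true_log2fc", "linked_gene", "te_family", "te_branch"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# sequence evolution


def _jc_prob(t: float) -> float:
    return 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))


class _BlockSim:
    """Evolve one alignment block down the tree, tracking column tags."""

    def __init__(self, config: SimConfig, rng: np.random.Generator, core_len: int,
                 te_family: str, te_branch: str):
        self.cfg = config
        self.rng = rng
        flank = config.flank
        total = flank + core_len + flank
        root_seq = rng.integers(0, 4, size=total).astype(np.uint8)
        self.col_tag = np.concatenate(
            [np.zeros(flank, np.int8), np.ones(core_len, np.int8), np.full(flank, 2, np.int8)]
        )
        self.te_mask = np.zeros(total, dtype=bool)
        self.seqs: Dict[str, np.ndarray] = {"root": root_seq}
        self.te_family = te_family
        self.te_branch = te_branch
        if te_family and te_branch == "root":
            self._insert_te("root")

    def _insert_columns(self, at: int, n: int, carrier: str, chars: np.ndarray, tag: int, te: bool) -> None:
        for name, s in self.seqs.items():
            if name == carrier:
                self.seqs[name] = np.concatenate([s[:at], chars, s[at:]])
            else:
                self.seqs[name] = np.concatenate([s[:at], np.full(n, _GAP, np.uint8), s[at:]])
        self.col_tag = np.concatenate([self.col_tag[:at], np.full(n, tag, np.int8), self.col_tag[at:]])
        self.te_mask = np.concatenate([self.te_mask[:at], np.full(n, te, bool), self.te_mask[at:]])

    def _insert_te(self, carrier: str) -> None:
        length = TE_FAMILIES[self.te_family][3]
        core_cols = np.flatnonzero(self.col_tag == 1)
        at = int(self.rng.choice(core_cols))
        chars = self.rng.integers(0, 4, size=length).astype(np.uint8)
        self._insert_columns(at, length, carrier, chars, tag=1, te=True)

    def _evolve_branch(self, parent: str, child: str, t: float) -> None:
        rng = self.rng
        seq = self.seqs[parent].copy()
        self.seqs[child] = seq
        nongap = np.flatnonzero(seq != _GAP)
        if t > 0 and len(nongap):
            # substitutions
            p = _jc_prob(t)
            hit = nongap[rng.random(len(nongap)) < p]
            if len(hit):
                seq[hit] = (seq[hit] + rng.integers(1, 4, size=len(hit)).astype(np.uint8)) % 4
            # deletions
            p_ev = 0.5 * self.cfg.indel_rate * t
            n_del = rng.binomial(len(nongap), p_ev)
            for _ in range(n_del):
                j = int(rng.integers(len(nongap)))
                length = int(rng.geometric(1.0 / 3.0))
                seq[nongap[j : j + length]] = _GAP
            # insertions
            n_ins = rng.binomial(len(nongap), p_ev)
            for _ in range(n_ins):
                at = int(rng.integers(1, len(seq) + 1))
                length = int(rng.geometric(1.0 / 3.0))
                chars = rng.integers(0, 4, size=length).astype(np.uint8)
                tag = int(self.col_tag[min(at, len(self.col_tag) - 1)])
                self._insert_columns(at, length, child, chars, tag=tag, te=False)
                seq = self.seqs[child]
        if self.te_family and self.te_branch == child:
            self._insert_te(child)

    def run(self, tree: SpeciesTree) -> None:
        def walk(node: TreeNode, parent_name: str) -> None:
            self._evolve_branch(parent_name, node.name, node.length * tree.scale)
            for c in node.children:
                walk(c, node.name)

        for c in tree.root.children:
            walk(c, "root")

    # -- result accessors ---------------------------------------------------

    def leaf_texts(self) -> Dict[str, str]:
        return {sp: _ALPHABET[self.seqs[sp]].tobytes().decode() for sp in SPECIES}

    def human_core_interval(self) -> Tuple[int, int]:
        """Human (offset, length) of the core CRE columns within the block."""
        h = self.seqs["human"]
        core = self.col_tag == 1
        before = int(np.sum((h != _GAP) & (self.col_tag == 0)))
        length = int(np.sum((h != _GAP) & core))
        return before, length

    def human_te_interval(self) -> Optional[Tuple[int, int]]:
        """Human (offset, length) of the TE columns, if the TE is in human."""
        if not self.te_family:
            return None
        h = self.seqs["human"]
        te_cols = np.flatnonzero(self.te_mask & (h != _GAP))
        if len(te_cols) == 0:
            return None
        nongap_rank = np.cumsum(h != _GAP) - 1
        first, last = int(nongap_rank[te_cols[0]]), int(nongap_rank[te_cols[-1]])
        return first, last - first + 1


@dataclass
class Bundle:
    """Everything the synthetic pipeline run consumes."""

    config: SimConfig
    truth: pd.DataFrame
    blocks: List[AlignmentBlock]
    cre_bed: pd.DataFrame
    tss_bed: pd.DataFrame
    te_annotation: pd.DataFrame
    chip_counts: pd.DataFrame
    rna_counts: pd.DataFrame
    metadata: pd.DataFrame
    gene_lengths: pd.Series
    genome_sizes: Dict[str, Dict[str, int]]  # species -> chrom -> size


def simulate_msa(
    tree: SpeciesTree, config: SimConfig, truth: Optional[pd.DataFrame] = None
):
    """Evolve one alignment block per CRE along the tree.

    Returns (blocks, cre_bed, tss_bed, te_annotation, genome_sizes).
    Blocks are laid out back-to-back on ``n_chromosomes`` chromosomes per
    species with unaligned spacer sequence between them; coordinates and
    source sizes are consistent with the emitted gapped rows.
    """
    if truth is None:
        truth = make_truth(config)
    rng = config.child_rng("msa")
    lo, hi = config.cre_length_range

    sims: List[_BlockSim] = []
    chroms: List[str] = []
    for i in range(len(truth)):
        row = truth.iloc[i]
        core_len = int(rng.integers(lo, hi + 1))
        sim = _BlockSim(config, rng, core_len, row["te_family"], row["te_branch"])
        sim.run(tree)
        sims.append(sim)
        chroms.append(f"chr{(i % config.n_chromosomes) + 1}")

    # per-species per-chromosome coordinate layout
    offsets: Dict[str, Dict[str, int]] = {sp: {} for sp in SPECIES}
    placements: List[Dict[str, Tuple[int, int]]] = []
    for sim, chrom in zip(sims, chroms):
        place: Dict[str, Tuple[int, int]] = {}
        for sp in SPECIES:
            seq = sim.seqs[sp]
            size = int(np.sum(seq != _GAP))
            start = offsets[sp].get(chrom, config.spacer)
            place[sp] = (start, size)
            offsets[sp][chrom] = start + size + config.spacer
        placements.append(place)
    genome_sizes = {
        sp: {c: off for c, off in sorted(offsets[sp].items())} for sp in SPECIES
    }

    blocks: List[AlignmentBlock] = []
    cre_rows = []
    tss_rows = []
    te_rows = []
    for i, (sim, chrom, place) in enumerate(zip(sims, chroms, placements)):
        texts = sim.leaf_texts()
        rows = {}
        for sp in SPECIES:
            start, size = place[sp]
            rows[sp] = AlignmentRow(
                species=sp,
                chrom=chrom,
                start=start,
                size=size,
                strand="+",
                src_size=genome_sizes[sp][chrom],
                text=texts[sp],
            )
        blocks.append(AlignmentBlock(rows=rows))

        hstart = place["human"][0]
        off, length = sim.human_core_interval()
        cre_start, cre_end = hstart + off, hstart + off + length
        tr = truth.iloc[i]
        cre_rows.append((chrom, cre_start, cre_end, tr["cre_id"], 0, "+"))

        # TSS for the linked gene: inside the CRE for promoter-designated
        # CREs, 1.1-1.6 kb upstream otherwise (keeps neighbours > 1 kb away)
        if rng.random() < config.promoter_fraction:
            tss = int(rng.integers(cre_start, cre_end))
        else:
            tss = cre_start - int(rng.integers(1100, 1601))
        tss_rows.append((chrom, max(tss, 0), max(tss, 0) + 1, tr["linked_gene"], 0, "+"))

        te_iv = sim.human_te_interval()
        if te_iv is not None:
            te_off, te_len = te_iv
            fam = tr["te_family"]
            _, te_class, age, _ = TE_FAMILIES[fam]
            te_rows.append(
                (chrom, hstart + te_off, hstart + te_off + te_len, fam, te_class.split("/")[0], te_class, age)
            )

    cre_bed = pd.DataFrame(cre_rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    tss_bed = pd.DataFrame(tss_rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    te_annotation = pd.DataFrame(
        te_rows, columns=["chrom", "start", "end", "subfamily", "family", "class", "lineage_age"]
    )
    return blocks, cre_bed, tss_bed, te_annotation, genome_sizes


# ---------------------------------------------------------------------------
# counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if np.any(mean < 0):
        raise ValueError("negative NB mean")
    if alpha <= 0:
        return rng.poisson(mean)
    n = 1.0 / alpha
    return rng.negative_binomial(n, n / (n + mean))


def _affected(species: str, branch: str) -> bool:
    return bool(branch) and species in CLADES[branch]


def simulate_counts(truth: pd.DataFrame, config: SimConfig):
    """Draw ChIP (IP + input) and RNA count matrices from the truth table.

    Returns (chip: CountMatrix, rna: CountMatrix).  Expected IP counts for
    a non-conserved CRE differ by exactly 2^true_log2fc between species
    descending from the gain/loss branch and the others, before per-sample
    size-factor noise.
    """
    from .glm import CountMatrix

    if len(truth) == 0:
        raise ValueError("truth table is empty")
    rng = config.child_rng("counts")
    k = config.individuals_per_species

    sample_meta = []
    for sp in SPECIES:
        for ind in range(1, k + 1):
            sex = "M" if (sp == "bushbaby" or ind % 2 == 1) else "F"
            for mark in config.marks:
                for assay in ("IP", "input"):
                    sample_meta.append(
                        {
                            "sample_id": f"{sp}_{ind}_{mark}_{assay}",
                            "species": sp,
                            "individual": f"{sp}_{ind}",
                            "assay": assay,
                            "mark": mark,
                            "sex": sex,
                        }
                    )
    chip_meta = pd.DataFrame(sample_meta).set_index("sample_id")
    sf_chip = np.exp(rng.normal(0.0, config.sf_sigma, size=len(chip_meta)))

    eff = np.zeros((len(truth), len(SPECIES)))
    for j, sp in enumerate(SPECIES):
        aff = truth["true_branch"].map(lambda b: _affected(sp, b)).to_numpy()
        eff[:, j] = np.where(aff, truth["true_log2fc"].to_numpy(), 0.0)

    chip = np.zeros((len(truth), len(chip_meta)), dtype=np.int64)
    for sj, (sid, m) in enumerate(chip_meta.iterrows()):
        j = SPECIES.index(m["species"])
        if m["assay"] == "IP":
            mu = config.mean_depth * np.exp2(config.ip_over_input_log2 + eff[:, j])
        else:
            mu = np.full(len(truth), config.mean_depth)
        chip[:, sj] = _nb_draw(rng, mu * sf_chip[sj], config.dispersion)
    chip_counts = pd.DataFrame(chip, index=truth["cre_id"].to_numpy(), columns=chip_meta.index)

    # RNA: one sample per individual; gene effect = coupling * mean CRE effect
    rna_meta_rows = []
    for sp in SPECIES:
        for ind in range(1, k + 1):
            sex = "M" if (sp == "bushbaby" or ind % 2 == 1) else "F"
            rna_meta_rows.append(
                {
                    "sample_id": f"{sp}_{ind}_RNA",
                    "species": sp,
                    "individual": f"{sp}_{ind}",
                    "assay": "RNA",
                    "mark": "none",
                    "sex": sex,
                }
            )
    rna_meta = pd.DataFrame(rna_meta_rows).set_index("sample_id")
    sf_rna = np.exp(rng.normal(0.0, config.sf_sigma, size=len(rna_meta)))

    genes = [f"gene_{g:05d}" for g in range(config.n_genes)]
    glen = pd.Series(
        rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, size=config.n_genes),
        index=genes,
        name="length",
    )
    gene_eff = np.zeros((config.n_genes, len(SPECIES)))
    counts_per_gene = np.zeros(config.n_genes)
    gidx = truth["linked_gene"].map(lambda g: int(g.split("_")[1])).to_numpy()
    for row, g in enumerate(gidx):
        gene_eff[g] += eff[row]
        counts_per_gene[g] += 1
    nz = counts_per_gene > 0
    gene_eff[nz] = gene_eff[nz] / counts_per_gene[nz, None]
    gene_eff *= config.rna_coupling

    rna = np.zeros((config.n_genes, len(rna_meta)), dtype=np.int64)
    base = config.mean_depth * glen.to_numpy() / 1000.0
    for sj, (sid, m) in enumerate(rna_meta.iterrows()):
        j = SPECIES.index(m["species"])
        mu = base * np.exp2(gene_eff[:, j]) * sf_rna[sj]
        rna[:, sj] = _nb_draw(rng, mu, config.dispersion)
    rna_counts = pd.DataFrame(rna, index=genes, columns=rna_meta.index)

    chip_cm = CountMatrix(chip_counts, chip_meta)
    rna_cm = CountMatrix(rna_counts, rna_meta, feature_lengths=glen)
    return chip_cm, rna_cm


# ---------------------------------------------------------------------------
# bundle assembly and serialisation


def simulate_bundle(config: SimConfig) -> Bundle:
    """Run the full generator: truth, alignments, annotations, counts."""
    truth = make_truth(config)
    tree = default_tree(scale=config.branch_scale)
    blocks, cre_bed, tss_bed, te_ann, genome_sizes = simulate_msa(tree, config, truth)
    if len(truth) > 0:
        chip, rna = simulate_counts(truth, config)
        chip_counts, rna_counts = chip.counts, rna.counts
        metadata = pd.concat([chip.metadata, rna.metadata])
        gene_lengths = rna.feature_lengths
    else:
        chip_counts = pd.DataFrame()
        rna_counts = pd.DataFrame()
        metadata = pd.DataFrame(columns=["species", "individual", "assay", "mark", "sex"])
        gene_lengths = pd.Series(dtype=int, name="length")
    return Bundle(
        config=config,
        truth=truth,
        blocks=blocks,
        cre_bed=cre_bed,
        tss_bed=tss_bed,
        te_annotation=te_ann,
        chip_counts=chip_counts,
        rna_counts=rna_counts,
        metadata=metadata,
        gene_lengths=gene_lengths,
        genome_sizes=genome_sizes,
    )


def write_maf(blocks: Sequence[AlignmentBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        for blk in blocks:
            fh.write("a score=0\n")
            for sp in SPECIES:
                if sp not in blk.rows:
                    continue
                r = blk.rows[sp]
                fh.write(
                    f"s {r.species}.{r.chrom} {r.start} {r.size} {r.strand} {r.src_size} {r.text}\n"
                )
            fh.write("\n")


def write_fixture_bundle(config: SimConfig, outdir) -> Dict:
    """Write the complete bundle to ``outdir`` and return the manifest.

    Files: msa.maf, cres.bed, tss.bed, te_annotation.tsv, chip_counts.tsv,
    rna_counts.tsv, samples.tsv, truth.tsv, gene_lengths.tsv, genome.tsv;
    manifest.json lists sha256 checksums.  Identical configs produce
    byte-identical bundles.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = simulate_bundle(config)

    write_maf(bundle.blocks, out / "msa.maf")
    bundle.cre_bed.to_csv(out / "cres.bed", sep="\t", header=False, index=False)
    bundle.tss_bed.to_csv(out / "tss.bed", sep="\t", header=False, index=False)
    bundle.te_annotation.to_csv(out / "te_annotation.tsv", sep="\t", index=False)
    bundle.chip_counts.to_csv(out / "chip_counts.tsv", sep="\t", index_label="feature_id")
    bundle.rna_counts.to_csv(out / "rna_counts.tsv", sep="\t", index_label="feature_id")
    bundle.metadata.to_csv(out / "samples.tsv", sep="\t", index_label="sample_id")
    bundle.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    bundle.gene_lengths.to_csv(out / "gene_lengths.tsv", sep="\t", index_label="gene")
    genome_rows = [
        {"species": sp, "chrom": c, "size": s}
        for sp, d in bundle.genome_sizes.items()
        for c, s in d.items()
    ]
    pd.DataFrame(genome_rows).to_csv(out / "genome.tsv", sep="\t", index=False)

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "files": {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest() for name in files
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
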
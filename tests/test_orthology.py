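"""MAF parsing, interval projection, divergence and outlier flagging."""

import textwrap

import numpy as np
import pandas as pd
import pytest

from crevol.orthology import (
    AlignmentBlock,
    AlignmentRow,
    flag_divergence_outliers,
    grubbs_critical,
    map_interval,
    pairwise_divergence,
    parse_maf,
)
from crevol.trees import SPECIES

ALL = list(SPECIES)


def _block(rows):
    return AlignmentBlock(rows={r.species: r for r in rows})


def _identity_block(seq="ACGTACGTAC" * 30, human_start=100, other_start=500, chrom="chr1"):
    rows = []
    for sp in ALL:
        start = human_start if sp == "human" else other_start
        rows.append(
            AlignmentRow(sp, chrom, start, len(seq), "+", 100000, seq)
        )
    return _block(rows)


def _write_maf(path, text):
    path.write_text(textwrap.dedent(text))
    return path


class TestParseMaf:
    def test_round_trip_from_fixture_bundle(self, bundle_dir, small_bundle):
        blocks = parse_maf(bundle_dir / "msa.maf")
        assert len(blocks) == len(small_bundle.blocks)
        b0, s0 = blocks[0], small_bundle.blocks[0]
        assert set(b0.rows) == set(s0.rows)
        for sp in b0.rows:
            assert b0.rows[sp].text == s0.rows[sp].text
            assert b0.rows[sp].start == s0.rows[sp].start
            assert b0.rows[sp].src_size == s0.rows[sp].src_size

    def test_empty_file(self, tmp_path):
        p = _write_maf(tmp_path / "e.maf", "##maf version=1\n")
        assert parse_maf(p) == []

    def test_short_row_rejected_with_block_index(self, tmp_path):
        p = _write_maf(
            tmp_path / "bad.maf",
            """\
            ##maf version=1
            a score=0
            s human.chr1 0 4 + 100 ACGT
            s chimp.chr1 0 4 + 100 ACGT

            a score=0
            s human.chr1 4 4 + 100 ACGT
            s chimp.chr1 4 3 + 100 ACG

            """,
        )
        with pytest.raises(ValueError, match="block 1"):
            parse_maf(p)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="declared size"):
            AlignmentBlock(
                rows={"human": AlignmentRow("human", "chr1", 0, 5, "+", 100, "AC-GT")}
            )


class TestMapInterval:
    def test_gapless_offset_shift(self):
        blk = _identity_block()
        oset = map_interval(("chr1", 100, 200), [blk])
        assert oset.six_way
        assert oset.intervals["chimp"] == ("chr1", 500, 600)
        assert oset.coverage["chimp"] == 1.0

    def test_gap_in_species_shortens_projection(self):
        # human columns 10-19; chimp has a 4-column gap inside
        hseq = "A" * 30
        cseq = "A" * 12 + "----" + "A" * 14
        rows = [AlignmentRow("human", "chr1", 0, 30, "+", 1000, hseq),
                AlignmentRow("chimp", "chr1", 0, 26, "+", 1000, cseq)]
        for sp in ALL[2:]:
            rows.append(AlignmentRow(sp, "chr1", 0, 30, "+", 1000, hseq))
        oset = map_interval(("chr1", 10, 20), [_block(rows)], flank=0)
        # column-walk oracle: chimp bases at columns 10,11 then 16,17,18,19
        assert oset.intervals["chimp"] == ("chr1", 10, 16)
        assert oset.coverage["chimp"] == 6 / 10

    def test_species_all_gap_marked_absent(self):
        hseq = "ACGTACGTAC"
        rows = [AlignmentRow("human", "chr1", 0, 10, "+", 1000, hseq),
                AlignmentRow("chimp", "chr1", 0, 0, "+", 1000, "-" * 10)]
        for sp in ALL[2:]:
            rows.append(AlignmentRow(sp, "chr1", 0, 10, "+", 1000, hseq))
        oset = map_interval(("chr1", 0, 10), [_block(rows)], flank=0)
        assert oset.intervals["chimp"] is None
        assert not oset.six_way

    def test_interval_outside_blocks(self):
        oset = map_interval(("chr9", 0, 10), [_identity_block()])
        assert not oset.six_way
        assert all(v is None for v in oset.intervals.values())

    def test_minus_strand_row_normalised_to_forward(self):
        hseq = "ACGTACGTAC"
        rows = [AlignmentRow("human", "chr1", 0, 10, "+", 1000, hseq),
                AlignmentRow("chimp", "chr1", 20, 10, "-", 1000, hseq)]
        for sp in ALL[2:]:
            rows.append(AlignmentRow(sp, "chr1", 0, 10, "+", 1000, hseq))
        oset = map_interval(("chr1", 2, 8), [_block(rows)], flank=0)
        # chimp strand coords [22, 28) -> forward [1000-28, 1000-22)
        assert oset.intervals["chimp"] == ("chr1", 972, 978)

    def test_round_trip_identity_on_gapless_block(self):
        blk = _identity_block(human_start=100, other_start=500)
        oset = map_interval(("chr1", 120, 250), [blk])
        chimp_iv = oset.intervals["chimp"]
        # reverse mapping: treat chimp as reference
        back = map_interval(
            (chimp_iv[0], chimp_iv[1], chimp_iv[2]), [blk], reference="chimp"
        )
        assert back.intervals["human"] == ("chr1", 120, 250)

    def test_coverage_below_threshold_marks_absent(self):
        hseq = "A" * 20
        cseq = "A" * 4 + "-" * 16
        rows = [AlignmentRow("human", "chr1", 0, 20, "+", 1000, hseq),
                AlignmentRow("chimp", "chr1", 0, 4, "+", 1000, cseq)]
        for sp in ALL[2:]:
            rows.append(AlignmentRow(sp, "chr1", 0, 20, "+", 1000, hseq))
        oset = map_interval(("chr1", 0, 20), [_block(rows)], min_coverage=0.5, flank=0)
        assert oset.intervals["chimp"] is None
        assert oset.coverage["chimp"] == pytest.approx(0.2)


class TestDivergence:
    def _oset(self, human, other):
        rows = [AlignmentRow("human", "chr1", 0, len(human) - human.count("-"), "+", 1000, human)]
        for sp in ALL[1:]:
            seq = other if sp == "chimp" else human
            rows.append(AlignmentRow(sp, "chr1", 0, len(seq) - seq.count("-"), "+", 1000, seq))
        hlen = len(human) - human.count("-")
        return map_interval(("chr1", 0, hlen), [_block(rows)], flank=0)

    def test_identical_sequences_zero(self):
        d = pairwise_divergence(self._oset("ACGT", "ACGT")).set_index("species")
        assert d.loc["chimp", "divergence"] == 0.0

    def test_single_mismatch_quarter(self):
        d = pairwise_divergence(self._oset("ACGT", "ACGA")).set_index("species")
        assert d.loc["chimp", "divergence"] == 0.25
        assert d.loc["chimp", "mismatches"] == 1
        assert d.loc["chimp", "compared_columns"] == 4

    def test_human_gap_column_excluded(self):
        # manual column table: cols (A,A) (-,A) (C,C) (G,G) (T,A)
        # human-gap col dropped -> compared 4, mismatches 1 -> 0.25
        d = pairwise_divergence(self._oset("A-CGT", "AACGA")).set_index("species")
        assert d.loc["chimp", "compared_columns"] == 4
        assert d.loc["chimp", "divergence"] == 0.25

    def test_species_gap_and_n_excluded(self):
        d = pairwise_divergence(self._oset("ACGTAC", "A-GTNC")).set_index("species")
        assert d.loc["chimp", "compared_columns"] == 4
        assert d.loc["chimp", "mismatches"] == 0

    def test_case_insensitive(self):
        d = pairwise_divergence(self._oset("acgt", "ACGT")).set_index("species")
        assert d.loc["chimp", "divergence"] == 0.0

    def test_column_conservation_invariant(self):
        human, other = "AC-GTA-C", "A-CG--AC"
        oset = self._oset(human, other)
        d = pairwise_divergence(oset).set_index("species").loc["chimp"]
        total = len(oset.aligned["human"])
        human_gaps = oset.aligned["human"].count("-")
        sp_gaps_only = sum(
            1 for h, s in zip(oset.aligned["human"], oset.aligned["chimp"])
            if h != "-" and s == "-"
        )
        assert d["compared_columns"] + human_gaps + sp_gaps_only == total

    def test_zero_comparable_columns_flagged(self):
        d = pairwise_divergence(self._oset("ACGT", "----")).set_index("species")
        assert bool(d.loc["chimp", "undefined"])
        assert np.isnan(d.loc["chimp", "divergence"])


class TestDivergenceMonotonicity:
    def test_divergence_increases_with_branch_scale(self):
        from crevol import SimConfig, simulate_bundle
        from crevol.orthology import map_interval, pairwise_divergence

        means = []
        for scale in (0.5, 1.0, 2.0):
            cfg = SimConfig(n_cres=15, n_genes=10, seed=21, branch_scale=scale)
            b = simulate_bundle(cfg)
            divs = []
            for _, row in b.cre_bed.iterrows():
                oset = map_interval((row["chrom"], row["start"], row["end"]), b.blocks,
                                    cre_id=row["name"])
                if oset.six_way:
                    divs.append(pairwise_divergence(oset)["divergence"].mean())
            means.append(np.nanmean(divs))
        assert means[0] < means[1] < means[2]

    def test_zero_scale_zero_divergence_without_te(self):
        from crevol import SimConfig, simulate_bundle

        cfg = SimConfig(n_cres=10, n_genes=5, seed=22, branch_scale=0.0, te_density=0.0)
        b = simulate_bundle(cfg)
        for blk in b.blocks:
            texts = {sp: blk.rows[sp].text for sp in blk.rows}
            assert len(set(texts.values())) == 1


class TestGrubbs:
    def test_all_equal_no_outliers(self):
        rec = pd.DataFrame({"cre_id": [f"c{i}" for i in range(10)],
                            "species": "chimp", "divergence": 0.01})
        out = flag_divergence_outliers(rec)
        assert not out["outlier"].any()

    def test_single_extreme_value_flagged(self):
        vals = [0.01] * 29 + [0.90]
        rec = pd.DataFrame({"cre_id": [f"c{i}" for i in range(30)],
                            "species": "chimp", "divergence": vals})
        out = flag_divergence_outliers(rec)
        assert out.loc[out["divergence"] == 0.90, "outlier"].all()
        assert out["outlier"].sum() == 1

    def test_grubbs_statistic_vs_critical_value(self):
        # oracle: with 29 identical values the sd is driven by the outlier;
        # G = max|x-mean|/sd must exceed the n=30 critical value
        vals = np.array([0.01] * 29 + [0.90])
        g = np.max(np.abs(vals - vals.mean())) / vals.std(ddof=1)
        assert g > grubbs_critical(30, 0.05)

    def test_tiny_group_never_flagged(self):
        rec = pd.DataFrame({"cre_id": ["a", "b"], "species": "chimp",
                            "divergence": [0.01, 0.99]})
        assert not flag_divergence_outliers(rec)["outlier"].any()

    def test_moderate_spread_not_flagged(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(0.05, 0.005, 50)
        rec = pd.DataFrame({"cre_id": [f"c{i}" for i in range(50)],
                            "species": "chimp", "divergence": vals})
        assert flag_divergence_outliers(rec)["outlier"].sum() <= 1
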
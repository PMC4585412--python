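"""SNP filtering, Bonferroni thresholds and locus clumping."""

import numpy as np
import pandas as pd
import pytest

from leafscore.gwas import (
    Locus,
    clump_loci,
    cross_trait_overlap,
    filter_snps,
    loci_table,
    thresholds,
)


def snp_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "pvalue", "maf", "mac"])


def brute_force_clump(df, gap_bp):
    """O(n²) oracle: repeatedly merge SNPs whose gap is below the threshold."""
    groups = [[i] for i in df.index]
    changed = True
    while changed:
        changed = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ga, gb = groups[a], groups[b]
                if any(
                    df.loc[i, "chrom"] == df.loc[j, "chrom"]
                    and abs(df.loc[i, "pos"] - df.loc[j, "pos"]) < gap_bp
                    for i in ga
                    for j in gb
                ):
                    # merging by any-pair distance equals adjacent-gap runs
                    groups[a] = ga + gb
                    del groups[b]
                    changed = True
                    break
            if changed:
                break
    out = set()
    for g in groups:
        sub = df.loc[g].sort_values("pos")
        out.add((sub["chrom"].iloc[0], int(sub["pos"].iloc[0]), int(sub["pos"].iloc[-1]), len(sub)))
    return out


class TestFilterSnps:
    def test_maf_below_threshold_removed(self):
        df = snp_df([("1", 100, 1e-8, 0.04, 10)])
        assert len(filter_snps(df)) == 0

    def test_inclusive_boundaries_kept(self):
        df = snp_df([("1", 100, 1e-8, 0.05, 6)])
        assert len(filter_snps(df)) == 1

    def test_counts(self):
        rng = np.random.default_rng(0)
        rows = [
            ("1", i, 1e-5, maf, mac)
            for i, (maf, mac) in enumerate(
                [(0.3, 50), (0.04, 50), (0.3, 5), (0.05, 6), (0.2, 12),
                 (0.01, 2), (0.5, 100), (0.049, 7), (0.06, 5), (0.1, 9)]
            )
        ]
        # rows passing both maf >= 0.05 and mac >= 6:
        # (0.3,50), (0.05,6), (0.2,12), (0.5,100), (0.1,9)
        assert len(filter_snps(snp_df(rows))) == 5


class TestThresholds:
    def test_direct_division(self):
        t = thresholds(1_000_000)
        assert t.suggestive == pytest.approx(1e-6)
        assert t.significant == pytest.approx(5e-8)

    def test_unit_marker_count(self):
        assert thresholds(1) == (1.0, 0.05)

    def test_ratio_is_twenty(self):
        t = thresholds(829_187.4)
        assert t.suggestive / t.significant == pytest.approx(20.0)

    def test_suggestive_recovered_from_printed_significant(self):
        # a significant threshold of 6.03e-8 implies N = 0.05/6.03e-8
        # effective markers and hence a suggestive threshold printing 1.21e-6
        n_eff = 0.05 / 6.03e-8
        assert thresholds(n_eff).suggestive == pytest.approx(1.21e-6, abs=0.005e-6)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            thresholds(0)


class TestClumpLoci:
    def test_single_snp_single_locus(self):
        loci = clump_loci(snp_df([("1", 100, 1e-8, 0.2, 10)]))
        assert len(loci) == 1
        assert loci[0].n_snps == 1

    def test_gap_rule_hand_example(self):
        df = snp_df(
            [("1", 1_000_000, 1e-7, 0.2, 10),
             ("1", 1_200_000, 1e-8, 0.2, 10),
             ("1", 1_600_000, 1e-9, 0.2, 10)]
        )
        loci = clump_loci(df, gap_bp=300_000)
        spans = [(l.start, l.end) for l in loci]
        assert spans == [(1_000_000, 1_200_000), (1_600_000, 1_600_000)]

    def test_same_positions_on_different_chromosomes_never_merge(self):
        df = snp_df([("1", 100, 1e-7, 0.2, 10), ("2", 150, 1e-8, 0.2, 10)])
        assert len(clump_loci(df)) == 2

    def test_lead_snp_min_p_tie_smaller_position(self):
        df = snp_df(
            [("1", 100, 1e-8, 0.2, 10),
             ("1", 200, 1e-9, 0.2, 10),
             ("1", 300, 1e-9, 0.2, 10)]
        )
        (locus,) = clump_loci(df)
        assert int(locus.lead["pos"]) == 200

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        df = snp_df(
            [
                (str(c), int(p), float(rng.uniform(1e-10, 1e-6)), 0.2, 10)
                for c in (1, 2)
                for p in rng.integers(1, 5_000_000, 40)
            ]
        )
        loci = clump_loci(df)
        members = pd.concat([l.members for l in loci])
        assert len(members) == len(df)
        rebuilt = members.sort_values(["chrom", "pos"]).reset_index(drop=True)
        expected = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
        assert (rebuilt["pos"] == expected["pos"]).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        df = snp_df(
            [
                (str(rng.integers(1, 4)), int(rng.integers(1, 3_000_000)),
                 float(rng.uniform(1e-10, 1e-6)), 0.2, 10)
                for _ in range(25)
            ]
        )
        got = {
            (l.chrom, l.start, l.end, l.n_snps) for l in clump_loci(df, 300_000)
        }
        assert got == brute_force_clump(df, 300_000)

    def test_empty_input(self):
        assert clump_loci(snp_df([])) == []


class TestLociTable:
    def test_columns_and_lead(self):
        df = snp_df([("1", 100, 1e-8, 0.2, 10), ("1", 200, 1e-9, 0.2, 10)])
        table = loci_table(clump_loci(df))
        row = table.iloc[0]
        assert (row["start"], row["end"], row["n_snps"]) == (100, 200, 2)
        assert row["lead_pos"] == 200


class TestManhattanPlot:
    def test_threshold_lines_and_axes(self):
        import matplotlib

        matplotlib.use("Agg")
        from leafscore.plot import manhattan

        rng = np.random.default_rng(0)
        snps = pd.DataFrame(
            {
                "chrom": rng.integers(1, 4, 50).astype(str),
                "pos": rng.integers(1, 1_000_000, 50),
                "pvalue": rng.uniform(1e-9, 1e-3, 50),
            }
        )
        ax = manhattan(snps, thresholds(1_000_000))
        assert len(ax.lines) == 2  # suggestive + significant cuts
        assert ax.get_ylabel().startswith("$")


class TestCrossTraitOverlap:
    def _locus(self, chrom, start, end):
        members = pd.DataFrame({"chrom": [chrom], "pos": [start], "pvalue": [1e-8]})
        return Locus(chrom, start, end, members, members.iloc[0])

    def test_identical_loci_overlap_count_two(self):
        loci = {
            ("GLA", "tillering"): [self._locus("1", 100, 500)],
            ("TLA", "tillering"): [self._locus("1", 100, 500)],
        }
        table = cross_trait_overlap(loci)
        assert (table["n_overlapping_groups"] == 2).all()

    def test_disjoint_loci_do_not_cross_reference(self):
        loci = {
            "a": [self._locus("1", 100, 200)],
            "b": [self._locus("1", 5_000_000, 5_000_100)],
        }
        table = cross_trait_overlap(loci)
        assert (table["n_overlapping_groups"] == 1).all()

    def test_matches_pairwise_interval_oracle(self):
        rng = np.random.default_rng(1)
        groups = {}
        for trait in ("t1", "t2", "t3"):
            loci = []
            for _ in range(5):
                start = int(rng.integers(1, 2_000_000))
                loci.append(self._locus("1", start, start + int(rng.integers(1, 400_000))))
            groups[trait] = loci
        table = cross_trait_overlap(groups)
        flat = [(g, l) for g, ls in groups.items() for l in ls]
        for _, row in table.iterrows():
            expected = {
                str(g)
                for g, l in flat
                if not (l.end < row["start"] or row["end"] < l.start)
            }
            assert set(row["overlapping_groups"].split(";")) == expected
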
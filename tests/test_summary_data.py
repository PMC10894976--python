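import numpy as np
import pandas as pd
import pytest

from mrpath.exceptions import ConfigurationError, EmptyInputError
from mrpath.summary_data import (
    LDMatrix,
    harmonize,
    read_summary_stats,
    select_instruments,
)

from conftest import make_stats

HEADER = "variant_id\tchromosome\tposition\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"


def _write_tsv(path, rows):
    lines = [HEADER]
    for r in rows:
        lines.append("\t".join(str(x) for x in r) + "\n")
    path.write_text("".join(lines))
    return path


class TestReadSummaryStats:
    def test_parses_standard_tsv(self, tmp_path):
        p = _write_tsv(tmp_path / "x.tsv", [
            ("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.01, 1.5e-23, 10000),
            ("rs2", 1, 200, "C", "A", 0.2, -0.05, 0.01, 5e-7, 10000),
            ("rs3", 2, 300, "T", "G", 0.4, 0.02, 0.01, 0.04, 10000),
        ])
        ss = read_summary_stats(p, trait_name="edu")
        assert len(ss) == 3
        assert ss.trait_name == "edu"
        assert ss.load_report.n_dropped == 0

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        p = _write_tsv(tmp_path / "x.tsv", [
            ("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.01, 1.5e-23, 10000),
            ("rs2", 1, 200, "C", "A", 0.2, -0.05, 0.0, 5e-7, 10000),   # se = 0
            ("rs3", 2, 300, "T", "G", 0.4, "nan", 0.01, 0.04, 10000),  # beta NaN
        ])
        ss = read_summary_stats(p)
        assert len(ss) == 1
        assert ss.load_report.n_dropped == 2
        assert ss.load_report.drop_reasons["nonpositive_se"] == 1

    def test_csv_with_remapped_headers_matches_tsv(self, tmp_path):
        rows = [
            ("rs1", 1, 100, "a", "g", 0.3, 0.1, 0.01, 1.5e-23, 10000),
            ("rs2", 1, 200, "c", "a", 0.2, -0.05, 0.01, 5e-7, 10000),
        ]
        tsv = _write_tsv(tmp_path / "x.tsv", rows)
        csv = tmp_path / "x.csv"
        csv.write_text(
            "SNP,CHR,BP,A1,A2,FREQ,BETA,SE,P,N\n"
            + "\n".join(",".join(str(x) for x in r) for r in rows)
            + "\n"
        )
        ss_tsv = read_summary_stats(tsv, trait_name="t")
        ss_csv = read_summary_stats(
            csv,
            column_map={
                "variant_id": "SNP", "chromosome": "CHR", "position": "BP",
                "effect_allele": "A1", "other_allele": "A2", "eaf": "FREQ",
                "beta": "BETA", "se": "SE", "pvalue": "P", "n": "N",
            },
            trait_name="t",
        )
        pd.testing.assert_frame_equal(ss_tsv.data, ss_csv.data)
        assert (ss_csv.data["effect_allele"] == ["A", "C"]).all()  # upper-cased

    def test_unmapped_column_raises(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("variant_id\tbeta\nrs1\t0.1\n")
        with pytest.raises(ConfigurationError):
            read_summary_stats(p)

    def test_all_rows_invalid_raises(self, tmp_path):
        p = _write_tsv(tmp_path / "x.tsv", [
            ("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.0, 1e-20, 10000),
        ])
        with pytest.raises(EmptyInputError):
            read_summary_stats(p)


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_beta(self):
        exp = make_stats([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        out = make_stats(
            [{"effect_allele": "G", "other_allele": "A", "beta": 0.2, "eaf": 0.7}],
            trait_name="out",
        )
        h = harmonize([exp], out)
        assert h.beta_outcome[0] == pytest.approx(-0.2)

    def test_strand_complement_aligned_without_flip(self):
        exp = make_stats([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        out = make_stats(
            [{"effect_allele": "T", "other_allele": "C", "beta": 0.2}],
            trait_name="out",
        )
        h = harmonize([exp], out)
        assert h.beta_outcome[0] == pytest.approx(0.2)

    def test_palindromic_at_half_frequency_dropped(self):
        exp = make_stats([{"effect_allele": "A", "other_allele": "T", "eaf": 0.5}])
        out = make_stats(
            [{"effect_allele": "A", "other_allele": "T", "eaf": 0.5}], trait_name="out"
        )
        with pytest.raises(EmptyInputError):
            harmonize([exp], out)

    def test_palindromic_oriented_by_low_frequency(self):
        exp = make_stats([{"effect_allele": "C", "other_allele": "G", "eaf": 0.1}])
        out = make_stats(
            [{"effect_allele": "C", "other_allele": "G", "eaf": 0.12, "beta": 0.3}],
            trait_name="out",
        )
        h = harmonize([exp], out)
        assert h.k == 1
        assert h.beta_outcome[0] == pytest.approx(0.3)

    def test_palindromic_disagreeing_frequencies_dropped(self):
        exp = make_stats([
            {"effect_allele": "C", "other_allele": "G", "eaf": 0.1},
            {"effect_allele": "A", "other_allele": "G", "eaf": 0.1},
        ])
        out = make_stats([
            {"effect_allele": "C", "other_allele": "G", "eaf": 0.9, "beta": 0.3},
            {"effect_allele": "A", "other_allele": "G", "eaf": 0.1, "beta": 0.2},
        ], trait_name="out")
        h = harmonize([exp], out)
        assert h.variant_ids == ["rs2"]
        assert dict(h.drop_log)["rs1"] == "palindromic_ambiguous"

    def test_mismatched_alleles_dropped_with_reason(self):
        exp = make_stats([
            {"effect_allele": "A", "other_allele": "G"} for _ in range(5)
        ])
        rows = [{"effect_allele": "A", "other_allele": "G", "beta": 0.2} for _ in range(5)]
        rows[2] = {"effect_allele": "A", "other_allele": "C", "beta": 0.2}
        out = make_stats(rows, trait_name="out")
        h = harmonize([exp], out)
        assert h.k == 4
        assert h.drop_log == [("rs3", "allele_mismatch")]

    def test_idempotent_on_already_aligned_traits(self):
        exp = make_stats([
            {"effect_allele": "A", "other_allele": "G", "beta": 0.1},
            {"effect_allele": "C", "other_allele": "T", "beta": -0.2},
        ])
        out = make_stats([
            {"effect_allele": "A", "other_allele": "G", "beta": 0.05},
            {"effect_allele": "C", "other_allele": "T", "beta": 0.03},
        ], trait_name="out")
        h1 = harmonize([exp], out)
        h2 = harmonize([exp], out)
        np.testing.assert_array_equal(h1.beta_outcome, h2.beta_outcome)
        np.testing.assert_array_equal(h1.beta_exposures, h2.beta_exposures)
        assert h1.drop_log == h2.drop_log == []

    def test_each_dropped_variant_has_exactly_one_reason(self):
        exp = make_stats([
            {"effect_allele": "A", "other_allele": "T", "eaf": 0.5},   # palindromic
            {"effect_allele": "A", "other_allele": "G"},               # mismatch below
            {"effect_allele": "C", "other_allele": "T"},               # fine
        ])
        rows = [
            {"effect_allele": "A", "other_allele": "T", "eaf": 0.5},
            {"effect_allele": "A", "other_allele": "C"},
            {"effect_allele": "C", "other_allele": "T"},
        ]
        out = make_stats(rows, trait_name="out")
        h = harmonize([exp], out)
        dropped = [v for v, _ in h.drop_log]
        assert sorted(dropped) == ["rs1", "rs2"]
        assert len(dropped) == len(set(dropped))

    def test_empty_intersection_raises(self):
        exp = make_stats([{}])
        out = make_stats([{}], trait_name="out")
        out.data["variant_id"] = ["zz9"]
        with pytest.raises(EmptyInputError):
            harmonize([exp], out)


class TestSelectInstruments:
    def _stats(self, pvals, chrom=None, pos=None):
        rows = []
        for i, p in enumerate(pvals):
            rows.append({
                "pvalue": p,
                "chromosome": (chrom or ["1"] * len(pvals))[i],
                "position": (pos or [1000 * (i + 1)] * 1)[i] if pos else 1000 * (i + 1),
            })
        return make_stats(rows)

    def test_unlinked_variants_all_selected(self):
        ss = self._stats([1e-9, 1e-9, 1e-9])
        ld = LDMatrix.identity(["rs1", "rs2", "rs3"])
        assert select_instruments(ss, ld=ld) == ["rs1", "rs2", "rs3"]

    def test_correlated_cluster_keeps_lowest_p(self):
        ss = self._stats([1e-9, 3.16e-9, 9.9e-9, 8e-9])
        r2 = np.full((4, 4), 0.5)
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(["rs1", "rs2", "rs3", "rs4"], r2)
        assert select_instruments(ss, ld=ld, r2_threshold=0.001) == ["rs1"]

    def test_different_chromosome_never_clumped(self):
        ss = self._stats([1e-9, 1e-9], chrom=["1", "2"])
        r2 = np.array([[1.0, 0.9], [0.9, 1.0]])
        ld = LDMatrix(["rs1", "rs2"], r2)
        assert select_instruments(ss, ld=ld) == ["rs1", "rs2"]

    def test_outside_window_never_clumped(self):
        ss = make_stats([
            {"pvalue": 1e-9, "position": 1000},
            {"pvalue": 1e-8, "position": 1000 + 10_000_001},
        ])
        r2 = np.array([[1.0, 0.9], [0.9, 1.0]])
        ld = LDMatrix(["rs1", "rs2"], r2)
        assert select_instruments(ss, ld=ld, window_kb=10_000) == ["rs1", "rs2"]

    def test_p_threshold_strict(self):
        ss = self._stats([5e-8, 4.9e-8])
        assert select_instruments(ss) == ["rs2"]

    def test_row_order_invariance_and_lexicographic_ties(self):
        ss = self._stats([1e-9, 1e-9, 1e-9])
        df = ss.data.iloc[[2, 0, 1]].reset_index(drop=True)
        from mrpath.summary_data import SummaryStats
        shuffled = SummaryStats("trait", "continuous", df)
        ld = LDMatrix.identity(["rs1", "rs2", "rs3"])
        assert select_instruments(ss, ld=ld) == select_instruments(shuffled, ld=ld)

    def test_variant_missing_from_ld_warns_and_kept(self):
        ss = self._stats([1e-9, 1e-9])
        ld = LDMatrix.identity(["rs1"])
        with pytest.warns(UserWarning, match="absent from the LD matrix"):
            assert select_instruments(ss, ld=ld) == ["rs1", "rs2"]
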
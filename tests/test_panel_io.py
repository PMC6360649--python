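import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lineauth import (
    SiteList,
    build_panel,
    read_expression_matrix,
    read_panel,
    read_site_list,
    read_varscan_vcf,
    restrict_panel,
    write_panel,
    write_profile_vcf,
)
from lineauth.panel_io import ASSUMED_DP, DataError, VariantKey, VariantRecord

from conftest import TOY_VCF, make_profile


class TestVariantKey:
    def test_invariants_enforced(self):
        with pytest.raises(DataError):
            VariantKey("chr1", 0, "A", "G")
        with pytest.raises(DataError):
            VariantKey("chr1", 5, "A", "A")
        with pytest.raises(DataError):
            VariantKey("chr1", 5, "", "G")

    def test_total_order_is_tuple_order(self):
        keys = [
            VariantKey("chr2", 1, "A", "G"),
            VariantKey("chr1", 9, "C", "T"),
            VariantKey("chr1", 9, "C", "A"),
        ]
        assert sorted(keys) == [keys[2], keys[1], keys[0]]

    def test_record_bounds(self):
        k = VariantKey("chr1", 5, "A", "G")
        with pytest.raises(DataError):
            VariantRecord(k, 101.0, 10)
        with pytest.raises(DataError):
            VariantRecord(k, 50.0, -1)


class TestReadVarscanVcf:
    def test_parses_fields_and_splits_multiallelic(self, toy_vcf):
        prof = read_varscan_vcf(toy_vcf)
        assert prof.cell_id == "SAMPLE_A"
        by_key = {r.key: r for r in prof.records}
        # forced by the FORMAT convention: GT:DP:FREQ "0/1:52:45.45%"
        r = by_key[VariantKey("chr1", 12345, "A", "G")]
        assert (r.freq, r.dp) == (45.45, 52)
        # bare numeral FREQ accepted
        assert by_key[VariantKey("chr2", 500, "G", "A")].freq == 12.5
        # multi-allelic row split into two records sharing chrom/pos/ref
        alts = {k.alt for k in by_key if k.chrom == "chr2" and k.pos == 700}
        assert alts == {"G", "C"}
        assert len(prof) == 5

    def test_empty_vcf_gives_empty_profile(self, tmp_path):
        path = tmp_path / "empty.vcf"
        header = "\n".join(TOY_VCF.splitlines()[:7]) + "\n"  # up to #CHROM line
        path.write_text(header)
        prof = read_varscan_vcf(path)
        assert len(prof) == 0

    def test_bad_records_skipped_all_bad_errors(self, tmp_path):
        lines = TOY_VCF.splitlines()
        bad = "\n".join(lines[:7] + ["chr1\t1\t.\tA\tG\t.\tPASS\t.\tGT:DP:FREQ\t0/1:10:250%"]) + "\n"
        path = tmp_path / "bad.vcf"
        path.write_text(bad)
        with pytest.raises(DataError, match="rejected"):
            read_varscan_vcf(path)

    def test_missing_file_and_unknown_sample(self, toy_vcf, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_varscan_vcf(tmp_path / "nope.vcf")
        with pytest.raises(DataError, match="not present"):
            read_varscan_vcf(toy_vcf, sample="OTHER")

    def test_roundtrip_through_writer(self, toy_vcf, tmp_path):
        prof = read_varscan_vcf(toy_vcf)
        out = tmp_path / "rt.vcf"
        write_profile_vcf(prof, out)
        back = read_varscan_vcf(out)
        assert {(r.key, round(r.freq, 4), r.dp) for r in back.records} == {
            (r.key, round(r.freq, 4), r.dp) for r in prof.records
        }


class TestBuildPanel:
    def test_same_single_site(self):
        a = make_profile("A", [(10, 50, 30)])
        b = make_profile("B", [(10, 60, 40)])
        panel = build_panel([a, b])
        assert (panel.n_cells, panel.n_sites) == (2, 1)
        assert panel.called.all()

    def test_strict_mode_zero_depth_at_uncalled(self):
        a = make_profile("A", [(1, 50, 30)])
        b = make_profile("B", [(2, 60, 40)])
        panel = build_panel([a, b], coverage_mode="strict")
        assert panel.n_sites == 2
        assert panel.dp[0, 1] == 0 and panel.dp[1, 0] == 0
        assert panel.freq[0, 1] == 0 and panel.freq[1, 0] == 0

    def test_assume_covered_sentinel(self):
        a = make_profile("A", [(1, 50, 30)])
        b = make_profile("B", [(2, 60, 40)])
        panel = build_panel([a, b])
        assert panel.dp[0, 1] == ASSUMED_DP

    def test_union_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            profs = [
                make_profile(f"P{i}", [(int(p), 50, 20) for p in rng.choice(50, size=rng.integers(1, 20), replace=False) + 1])
                for i in range(3)
            ]
            panel = build_panel(profs)
            expected = set().union(*(p.sites for p in profs))
            assert panel.n_sites == len(expected)
            assert set(panel.sites) == expected

    def test_vcf_profile_survives_panel(self, toy_vcf):
        prof = read_varscan_vcf(toy_vcf)
        panel = build_panel([prof])
        for r in prof.records:
            s = panel.sites.index(r.key)
            assert panel.freq[0, s] == r.freq and panel.dp[0, s] == r.dp

    def test_external_mode_uses_supplied_depths(self):
        a = make_profile("A", [(1, 50, 30)])
        b = make_profile("B", [(2, 60, 40)])
        k1, k2 = sorted(a.sites | b.sites)
        depths = {"A": {k1: 30.0, k2: 17.0}, "B": {k1: 8.0, k2: 40.0}}
        panel = build_panel([a, b], coverage_mode="external", external_depths=depths)
        assert panel.dp[0, 1] == 17.0 and panel.dp[1, 0] == 8.0
        assert panel.dp[0, 0] == 30 and panel.dp[1, 1] == 40  # called values win
        with pytest.raises(DataError, match="lookup failed"):
            build_panel([a, b], coverage_mode="external", external_depths={"A": {}})

    def test_errors(self):
        a = make_profile("A", [(1, 50, 30)])
        with pytest.raises(DataError):
            build_panel([a, a])
        with pytest.raises(DataError):
            build_panel([])
        with pytest.raises(DataError):
            build_panel([a], coverage_mode="external")


class TestPanelRoundTrip:
    def test_round_trip_identity(self, tmp_path):
        a = make_profile("A", [(1, 45.4567, 30), (2, 99.9, 55)])
        b = make_profile("B", [(2, 12.3, 18), (3, 70.0, 90)])
        panel = build_panel([a, b])  # keeps inf sentinels at uncalled
        write_panel(panel, tmp_path / "panel")
        back = read_panel(tmp_path / "panel")
        assert back.cell_ids == panel.cell_ids
        assert back.sites == panel.sites
        assert np.allclose(back.freq, panel.freq, atol=1e-4)
        assert np.array_equal(back.dp, panel.dp)  # inf sentinel preserved
        assert np.array_equal(back.called, panel.called)
        assert back.coverage_mode == panel.coverage_mode

    def test_truncated_matrix_is_dimension_error(self, tmp_path):
        a = make_profile("A", [(1, 45.0, 30), (2, 99.0, 55)])
        panel = build_panel([a])
        write_panel(panel, tmp_path / "panel")
        sites = (tmp_path / "panel" / "sites.tsv").read_text().splitlines()
        (tmp_path / "panel" / "sites.tsv").write_text("\n".join(sites[:-1]) + "\n")
        with pytest.raises(DataError, match="shape|metadata"):
            read_panel(tmp_path / "panel")

    def test_version_mismatch(self, tmp_path):
        a = make_profile("A", [(1, 45.0, 30)])
        write_panel(build_panel([a]), tmp_path / "panel")
        meta = tmp_path / "panel" / "meta.json"
        meta.write_text(meta.read_text().replace('"1"', '"99"'))
        with pytest.raises(DataError, match="version"):
            read_panel(tmp_path / "panel")


class TestRestrictPanel:
    def _panel(self):
        a = make_profile("A", [(p, 50, 30) for p in range(1, 11)])
        return build_panel([a])

    def test_identity_and_idempotence(self):
        panel = self._panel()
        full = SiteList(frozenset(panel.sites))
        same = restrict_panel(panel, full)
        assert same.sites == panel.sites and np.array_equal(same.freq, panel.freq)
        sub = SiteList(frozenset(panel.sites[2:6]))
        once = restrict_panel(panel, sub)
        twice = restrict_panel(once, sub)
        assert once.sites == twice.sites == panel.sites[2:6]

    def test_disjoint_gives_zero_sites(self):
        panel = self._panel()
        none = restrict_panel(panel, SiteList(frozenset({VariantKey("chrX", 1, "A", "G")})))
        assert none.n_sites == 0 and none.cell_ids == panel.cell_ids

    def test_intersection_matches_brute_force(self):
        panel = self._panel()
        wanted = frozenset(list(panel.sites)[::3] + [VariantKey("chr9", 1, "A", "G")])
        out = restrict_panel(panel, SiteList(wanted))
        assert out.sites == [k for k in panel.sites if k in wanted]


class TestSiteList:
    def test_tsv_with_duplicate_collapsed(self, tmp_path):
        path = tmp_path / "sites.tsv"
        path.write_text("chr1\t10\tA\tG\nchr1\t10\tA\tG\nchr2\t20\tC\tT\n")
        sl = read_site_list(path)
        assert len(sl) == 2

    def test_vcf_input_matches_vcf_parse(self, toy_vcf):
        sl = read_site_list(toy_vcf)
        prof = read_varscan_vcf(toy_vcf)
        assert sl.keys == prof.sites

    def test_empty_table_errors(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises((DataError, FileNotFoundError)):
            read_site_list(path)

    def test_header_tolerated_bad_rows_skipped(self, tmp_path):
        path = tmp_path / "sites.tsv"
        path.write_text("chrom\tpos\tref\talt\nchr1\t10\tA\tG\nchr1\tnotanint\tA\tG\n")
        assert len(read_site_list(path)) == 1


class TestExpressionMatrix:
    def test_toy_table(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("gene\tC1\tC2\ng1\t1.5\t0.0\ng2\t3.25\t7.5\n")
        em = read_expression_matrix(path)
        assert em.gene_ids == ["g1", "g2"] and em.cell_ids == ["C1", "C2"]
        assert em.rpkm[1, 1] == 7.5

    def test_negative_rpkm_errors(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("gene\tC1\ng1\t-0.5\n")
        with pytest.raises(DataError):
            read_expression_matrix(path)

    def test_round_trip_through_tsv(self, tmp_path):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 50, size=(5, 3)).round(4)
        lines = ["gene\t" + "\t".join(f"C{j}" for j in range(3))]
        lines += [f"g{i}\t" + "\t".join(str(v) for v in vals[i]) for i in range(5)]
        path = tmp_path / "expr.tsv"
        path.write_text("\n".join(lines) + "\n")
        em = read_expression_matrix(path)
        assert np.allclose(em.rpkm, vals)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    st.lists(
        st.lists(st.integers(min_value=1, max_value=30), min_size=1, max_size=10, unique=True),
        min_size=1,
        max_size=4,
    )
)
def test_union_property(site_lists):
    """Panel site count always equals the exact union of profile keys."""
    profs = [
        make_profile(f"P{i}", [(p, 50, 20) for p in sites])
        for i, sites in enumerate(site_lists)
    ]
    panel = build_panel(profs, coverage_mode="strict")
    assert set(panel.sites) == set().union(*(p.sites for p in profs))
    assert panel.sites == sorted(panel.sites)
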
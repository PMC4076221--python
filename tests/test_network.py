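"""Network construction, aggregation, deflation, balance and I/O."""

import numpy as np
import pytest

from enaflow import (
    CurrencyNetwork,
    DeflatorSeries,
    IOTable,
    SectorMapping,
    ValidationError,
    aggregate_sectors,
    average_mutual_information,
    check_balance,
    deflate,
    from_io_table,
    read_flow_csv,
    read_io_csv,
    to_extended_matrix,
    total_system_throughput,
    write_flow_csv,
    write_io_csv,
)
from conftest import EX1, random_network


class TestFromIOTable:
    def test_single_sector_identity(self, one_sector_table):
        net = from_io_table(one_sector_table)
        assert net.supply() == pytest.approx([4.0])
        assert net.demand() == pytest.approx([4.0])
        assert check_balance(net).passed

    def test_unbalanced_table_fails_check(self):
        table = IOTable(
            sector_labels=("A", "B"),
            intermediate=[[1.0, 2.0], [0.0, 1.0]],  # row sums != col sums
            imports=[0.0, 0.0], value_added=[0.0, 0.0],
            final_use_domestic=[0.0, 0.0], exports=[0.0, 0.0],
        )
        assert not check_balance(from_io_table(table)).passed

    def test_synthetic_table_balances_by_independent_sums(self):
        # brute-force accounting: per-sector supply and demand summed by hand
        net = random_network(seed=7, n=3)
        table = IOTable(
            sector_labels=net.sector_labels, intermediate=net.internal,
            imports=net.inflow, value_added=net.value_added,
            final_use_domestic=net.end_use, exports=net.outflow,
        )
        rebuilt = from_io_table(table)
        for i in range(3):
            supply = sum(rebuilt.internal[i, j] for j in range(3)) \
                + rebuilt.end_use[i] + rebuilt.outflow[i]
            demand = sum(rebuilt.internal[j, i] for j in range(3)) \
                + rebuilt.inflow[i] + rebuilt.value_added[i]
            assert supply == pytest.approx(demand, rel=1e-9)
        assert check_balance(rebuilt).passed

    def test_negative_entry_strict_vs_clamped(self):
        table = IOTable(
            sector_labels=("A",), intermediate=[[-1.0]], imports=[1.0],
            value_added=[1.0], final_use_domestic=[1.0], exports=[1.0],
        )
        with pytest.raises(ValidationError):
            from_io_table(table)
        net = from_io_table(table, clamp_negatives=True)
        assert net.internal[0, 0] == 0.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            IOTable(sector_labels=("A", "B"), intermediate=[[1.0]],
                    imports=[0, 0], value_added=[0, 0],
                    final_use_domestic=[0, 0], exports=[0, 0])


class TestExtendedMatrix:
    def test_pure_internal_embedding(self, ex1_network):
        ext = to_extended_matrix(ex1_network)
        assert ext.matrix.shape == (4, 4)
        np.testing.assert_array_equal(ext.matrix[:2, :2], EX1)
        assert ext.total() == 4.0

    def test_one_sector_layout_and_total(self, one_sector_table):
        ext = to_extended_matrix(from_io_table(one_sector_table))
        assert ext.matrix.shape == (3, 3)
        # 2 internal + 1 end use + 1 outflow + 1 VA + 1 inflow
        assert ext.total() == pytest.approx(6.0)
        assert np.all(ext.matrix[-2:, -2:] == 0.0)

    def test_total_equals_double_entry_sum(self):
        net = random_network(seed=11, n=6)
        ext = to_extended_matrix(net)
        by_category = (net.internal.sum() + net.inflow.sum()
                       + net.value_added.sum() + net.outflow.sum()
                       + net.end_use.sum())
        by_sector = net.supply().sum() + net.inflow.sum() + net.value_added.sum()
        assert ext.total() == pytest.approx(by_category, rel=1e-12)
        assert ext.total() == pytest.approx(by_sector, rel=1e-12)


class TestAggregation:
    def test_identity_mapping_is_noop(self):
        net = random_network(seed=1, n=4)
        mapping = SectorMapping({s: s for s in net.sector_labels})
        agg = aggregate_sectors(net, mapping)
        np.testing.assert_allclose(agg.internal, net.internal)
        np.testing.assert_allclose(agg.inflow, net.inflow)

    def test_block_sums(self):
        net = random_network(seed=2, n=4)
        mapping = SectorMapping({"S1": "G1", "S2": "G1", "S3": "G2", "S4": "G2"})
        agg = aggregate_sectors(net, mapping)
        assert agg.sector_labels == ("G1", "G2")
        expected_00 = net.internal[:2, :2].sum()
        assert agg.internal[0, 0] == pytest.approx(expected_00, rel=1e-12)
        assert agg.internal[0, 1] == pytest.approx(net.internal[:2, 2:].sum(), rel=1e-12)

    def test_tst_preserved_and_balance_kept(self):
        net = random_network(seed=3, n=6)
        mapping = SectorMapping({f"S{i+1}": f"G{i % 3}" for i in range(6)})
        agg = aggregate_sectors(net, mapping)
        assert agg.total_flow() == pytest.approx(net.total_flow(), rel=1e-12)
        assert check_balance(agg, tol=1e-9).passed

    def test_ami_never_increases_under_aggregation(self):
        # data-processing inequality, coarse-graining both margins; >=100 nets
        rng = np.random.default_rng(0)
        for seed in range(100):
            net = random_network(seed=seed, n=6)
            targets = rng.integers(0, 3, size=6)
            mapping = SectorMapping(
                {f"S{i+1}": f"G{targets[i]}" for i in range(6)})
            before = average_mutual_information(to_extended_matrix(net))
            after = average_mutual_information(
                to_extended_matrix(aggregate_sectors(net, mapping)))
            assert after <= before + 1e-10

    def test_unmapped_sector_rejected(self):
        net = random_network(seed=4, n=3)
        with pytest.raises(ValidationError):
            aggregate_sectors(net, SectorMapping({"S1": "G", "S2": "G"}))


class TestDeflation:
    def make_deflator(self, year, idx):
        return DeflatorSeries(base_year=1985, index={1985: 100.0, year: idx})

    def test_base_year_is_identity(self):
        net = random_network(seed=5, n=4)
        net = CurrencyNetwork(**{**net.__dict__, "year": 1985})
        out = deflate(net, self.make_deflator(1985, 100.0))
        np.testing.assert_allclose(out.internal, net.internal)

    def test_halving_scales_tst_not_ami(self):
        net = random_network(seed=6, n=4)
        net = CurrencyNetwork(**{**net.__dict__, "year": 2000})
        out = deflate(net, self.make_deflator(2000, 200.0))
        assert out.total_flow() == pytest.approx(net.total_flow() / 2, rel=1e-12)
        ami0 = average_mutual_information(to_extended_matrix(net))
        ami1 = average_mutual_information(to_extended_matrix(out))
        assert ami1 == pytest.approx(ami0, rel=1e-12)
        assert out.price_basis == ("constant", 1985)

    def test_published_endpoint_deflation(self):
        # current-price 9940 deflated by the cumulative index implied by the
        # constant-price 1496 recovers 1496 exactly
        net = CurrencyNetwork(
            sector_labels=("S1",), internal=[[9940.0]], inflow=[0.0],
            value_added=[0.0], outflow=[0.0], end_use=[0.0], year=2010)
        deflator = DeflatorSeries(
            base_year=1985, index={1985: 100.0, 2010: 100.0 * 9940.0 / 1496.0})
        assert deflate(net, deflator).total_flow() == pytest.approx(1496.0, rel=1e-12)

    def test_missing_year_errors(self):
        net = random_network(seed=8, n=3)
        net = CurrencyNetwork(**{**net.__dict__, "year": 1999})
        with pytest.raises(ValidationError):
            deflate(net, self.make_deflator(2000, 150.0))


class TestBalanceReport:
    def test_balanced_network_passes_with_zero_gap(self):
        report = check_balance(random_network(seed=9, n=5))
        assert report.passed
        assert report.max_gap < 1e-12

    def test_perturbed_inflow_fails_that_sector(self):
        net = random_network(seed=10, n=5)
        inflow = net.inflow.copy()
        inflow[2] *= 1.10
        bad = CurrencyNetwork(**{**net.__dict__, "inflow": inflow})
        report = check_balance(bad, tol=1e-6)
        assert not report.passed
        assert report.failing_sectors == ("S3",)

    def test_gaps_match_independent_sums(self):
        net = random_network(seed=12, n=4)
        report = check_balance(net)
        np.testing.assert_allclose(report.supply,
                                   net.internal.sum(1) + net.end_use + net.outflow)
        np.testing.assert_allclose(report.demand,
                                   net.internal.sum(0) + net.inflow + net.value_added)


class TestCSVRoundTrip:
    def test_flow_csv_lossless(self, tmp_path):
        net = random_network(seed=3, n=5)
        path = tmp_path / "net.csv"
        write_flow_csv(net, path)
        back = read_flow_csv(path)
        np.testing.assert_array_equal(back.internal, net.internal)
        np.testing.assert_array_equal(back.inflow, net.inflow)
        np.testing.assert_array_equal(back.value_added, net.value_added)
        np.testing.assert_array_equal(back.outflow, net.outflow)
        np.testing.assert_array_equal(back.end_use, net.end_use)

    def test_negative_cell_rejected_in_strict_mode(self, tmp_path):
        net = random_network(seed=3, n=3)
        path = tmp_path / "net.csv"
        write_flow_csv(net, path)
        text = path.read_text()
        first_num = text.splitlines()[1].split(",")[1]
        path.write_text(text.replace(first_num, "-1.0", 1))
        with pytest.raises(ValidationError):
            read_flow_csv(path)
        read_flow_csv(path, strict=False)  # permissive mode clamps

    def test_orientation_transpose(self, tmp_path):
        net = random_network(seed=4, n=3)
        path = tmp_path / "net.csv"
        write_flow_csv(net, path)
        import pandas as pd
        pd.read_csv(path, index_col=0,
                    float_precision="round_trip").T.to_csv(tmp_path / "t.csv")
        back = read_flow_csv(tmp_path / "t.csv", orientation="demand-rows")
        np.testing.assert_array_equal(back.internal, net.internal)

    def test_io_csv_roundtrip(self, tmp_path, one_sector_table):
        path = tmp_path / "io.csv"
        write_io_csv(one_sector_table, path)
        back = read_io_csv(path)
        np.testing.assert_array_equal(back.intermediate,
                                      one_sector_table.intermediate)
        assert back.sector_labels == one_sector_table.sector_labels
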
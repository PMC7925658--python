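import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refstab.cq_data import (
    CqValueError,
    DataError,
    DesignError,
    DilutionSeries,
    SchemaError,
    amplification_efficiency,
    check_efficiency_range,
    collapse_technical_replicates,
    cq_summary,
    read_cq_long,
    write_cq_long,
)

from conftest import dataset_from_matrix


def _write_toy(tmp_path, cq_rows, design_rows):
    cq_file = tmp_path / "cq.tsv"
    design_file = tmp_path / "design.tsv"
    cq_file.write_text(
        "sample\tgene\tbio_rep\ttech_rep\tcq\n"
        + "".join("\t".join(map(str, r)) + "\n" for r in cq_rows)
    )
    design_file.write_text(
        "sample\ttissue\tstage\n"
        + "".join("\t".join(map(str, r)) + "\n" for r in design_rows)
    )
    return cq_file, design_file


class TestReadCqLong:
    def test_round_trip_identity(self, tmp_path):
        rows = [
            ("s1", "gA", 1, 1, 20.5),
            ("s1", "gB", 1, 1, 22.25),
            ("s2", "gA", 2, 1, 21.0),
            ("s2", "gB", 2, 1, 23.75),
        ]
        design = [("s1", "root", "May"), ("s2", "leaf", "May")]
        cq_file, design_file = _write_toy(tmp_path, rows, design)
        d = read_cq_long(cq_file, design_file)
        assert len(d.data) == 4
        assert d.genes == ["gA", "gB"]
        assert d.samples == ["s1", "s2"]
        out = tmp_path / "out.tsv"
        write_cq_long(d, out)
        assert out.read_text() == cq_file.read_text()

    def test_missing_column_named_in_error(self, tmp_path):
        _, design_file = _write_toy(tmp_path, [], [("s1", "root", "May")])
        cq_file = tmp_path / "nocq.tsv"
        cq_file.write_text("sample\tgene\tbio_rep\ttech_rep\n" "s1\tgA\t1\t1\n")
        with pytest.raises(SchemaError, match="cq"):
            read_cq_long(cq_file, design_file)

    def test_non_numeric_cq_cites_row(self, tmp_path):
        rows = [("s1", "gA", 1, t, 20.0) for t in (1, 2, 3)]
        rows += [("s1", "gB", 1, 1, 21.0), ("s1", "gB", 1, 2, 21.1)]
        rows += [("s1", "gC", 1, 1, 19.0), ("s1", "gC", 1, 2, "NA")]
        cq_file, design_file = _write_toy(tmp_path, rows, [("s1", "root", "May")])
        with pytest.raises(CqValueError, match="row 7"):
            read_cq_long(cq_file, design_file)

    @pytest.mark.parametrize("bad_cq", [0.0, -1.0, 45.5, "inf"])
    def test_out_of_range_cq_rejected(self, tmp_path, bad_cq):
        cq_file, design_file = _write_toy(
            tmp_path, [("s1", "gA", 1, 1, bad_cq)], [("s1", "root", "May")]
        )
        with pytest.raises(CqValueError):
            read_cq_long(cq_file, design_file)

    def test_sample_without_design_entry(self, tmp_path):
        cq_file, design_file = _write_toy(
            tmp_path,
            [("s1", "gA", 1, 1, 20.0), ("s9", "gA", 1, 1, 20.0)],
            [("s1", "root", "May")],
        )
        with pytest.raises(DesignError, match="s9"):
            read_cq_long(cq_file, design_file)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        values=st.lists(
            st.decimals(
                min_value="10.01", max_value="39.99", places=2, allow_nan=False
            ),
            min_size=2,
            max_size=12,
        )
    )
    def test_write_read_write_is_stable(self, values):
        """Canonical files survive a read/write cycle byte-for-byte."""
        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory() as tmp:
            tmp_path = Path(tmp)
            rows = [(f"s{j}", "gA", 1, 1, float(v)) for j, v in enumerate(values)]
            design = [(f"s{j}", "root", "May") for j in range(len(values))]
            cq_file, design_file = _write_toy(tmp_path, rows, design)
            d = read_cq_long(cq_file, design_file)
            out = tmp_path / "rewrite.tsv"
            write_cq_long(d, out)
            assert out.read_bytes() == cq_file.read_bytes()


class TestCollapse:
    @pytest.mark.parametrize(
        "cqs,policy,expected",
        [((20.0, 20.2, 20.4), "mean", 20.2), ((20.0, 20.0, 25.0), "median", 20.0)],
    )
    def test_collapse_statistics(self, cqs, policy, expected):
        rows = [("s1", "gA", 1, t + 1, c) for t, c in enumerate(cqs)]
        data = pd.DataFrame(rows, columns=["sample", "gene", "bio_rep", "tech_rep", "cq"])
        design = pd.DataFrame({"sample": ["s1"], "tissue": ["root"], "stage": ["May"]})
        from refstab.cq_data import CqDataset

        d = collapse_technical_replicates(CqDataset(data, design), policy)
        assert d.data["cq"].iloc[0] == pytest.approx(expected)
        assert d.is_collapsed

    def test_collapse_matches_groupby_oracle(self):
        rng = np.random.default_rng(11)
        rows = []
        for s in ("s1", "s2", "s3"):
            for g in ("gA", "gB"):
                for t in (1, 2, 3):
                    rows.append((s, g, 1, t, float(20 + rng.normal())))
        data = pd.DataFrame(rows, columns=["sample", "gene", "bio_rep", "tech_rep", "cq"])
        design = pd.DataFrame(
            {"sample": ["s1", "s2", "s3"], "tissue": ["root"] * 3, "stage": ["May"] * 3}
        )
        from refstab.cq_data import CqDataset

        d = CqDataset(data, design)
        collapsed = collapse_technical_replicates(d, "mean")
        oracle = data.groupby(["sample", "gene"])["cq"].mean()
        for _, row in collapsed.data.iterrows():
            assert row["cq"] == pytest.approx(oracle[(row["sample"], row["gene"])])

    def test_unknown_policy_rejected(self, abc_dataset):
        with pytest.raises(ValueError):
            collapse_technical_replicates(abc_dataset, "mode")


class TestCqSummary:
    def test_hand_computed_summary(self):
        d = dataset_from_matrix([[20, 21, 22, 23]], genes=["gA"])
        s = cq_summary(d).loc["gA"]
        assert s["mean_cq"] == pytest.approx(21.5)
        assert s["sd_cq"] == pytest.approx(1.2910, abs=1e-4)
        assert (s["min_cq"], s["max_cq"]) == (20, 23)

    def test_zero_variance_gene(self):
        d = dataset_from_matrix([[24, 24, 24]], genes=["gA"])
        s = cq_summary(d).loc["gA"]
        assert s["sd_cq"] == 0.0
        assert s["cv_percent"] == 0.0

    def test_cv_hand_value(self):
        d = dataset_from_matrix([[19, 21]], genes=["gA"])
        s = cq_summary(d).loc["gA"]
        assert s["cv_percent"] == pytest.approx(100 * 1.4142 / 20, abs=1e-3)

    def test_singleton_gene_flagged(self):
        d = dataset_from_matrix([[20.0]], genes=["gA"])
        s = cq_summary(d).loc["gA"]
        assert not s["sd_defined"]
        assert np.isnan(s["sd_cq"])

    def test_shift_invariance_of_sd(self):
        rng = np.random.default_rng(3)
        cq = 20 + rng.normal(0, 1, (1, 10))
        base = cq_summary(dataset_from_matrix(cq)).iloc[0]
        shifted = cq_summary(dataset_from_matrix(cq + 2.5)).iloc[0]
        assert shifted["mean_cq"] == pytest.approx(base["mean_cq"] + 2.5)
        assert shifted["sd_cq"] == pytest.approx(base["sd_cq"])

    def test_pipeline_invariant_to_record_order(self):
        rng = np.random.default_rng(5)
        cq = 20 + rng.normal(0, 1, (3, 6))
        d = dataset_from_matrix(cq)
        shuffled = d.data.sample(frac=1, random_state=1).reset_index(drop=True)
        from refstab.cq_data import CqDataset

        d2 = CqDataset(shuffled, d.design.reset_index())
        a = cq_summary(d).sort_index()
        b = cq_summary(d2).sort_index()
        pd.testing.assert_frame_equal(a, b)


class TestAmplificationEfficiency:
    @pytest.mark.parametrize(
        "slope,expected_e",
        [
            (-1 / np.log10(2.0), 100.0),
            (-3.0, (10 ** (1 / 3.0) - 1) * 100),  # 115.44
            (-3.6, (10 ** (1 / 3.6) - 1) * 100),  # 89.57
        ],
    )
    def test_noiseless_closed_form(self, slope, expected_e):
        pts = [(-float(i), 20.0 + slope * -float(i)) for i in range(5)]
        e = amplification_efficiency(DilutionSeries("gA", pts))
        assert e.slope == pytest.approx(slope, abs=1e-9)
        assert e.e_percent == pytest.approx(expected_e, abs=1e-6)
        assert e.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_known_slope_recovery_with_shifted_intercept(self):
        slope = -3.321928
        pts = [(x, 31.7 + slope * x) for x in (0.0, -1.0, -2.0, -3.0)]
        e = amplification_efficiency(DilutionSeries("gA", pts))
        assert e.slope == pytest.approx(slope, abs=1e-9)

    def test_positive_slope_rejected(self):
        # Cq rising with dilution level means the curve runs the wrong way
        with pytest.raises(DataError, match="non-negative slope"):
            amplification_efficiency(DilutionSeries("gA", [(0, 20), (-1, 19), (-2, 18)]))

    def test_too_few_levels_rejected(self):
        with pytest.raises(DataError):
            amplification_efficiency(DilutionSeries("gA", [(0, 20), (-1, 23)]))


class TestEfficiencyGate:
    @pytest.mark.parametrize(
        "e_percent,expected",
        [(90.0, True), (110.0, True), (100.0, True), (116.84, False), (89.57, False)],
    )
    def test_gate(self, e_percent, expected):
        from refstab.cq_data import GeneEfficiency

        e = GeneEfficiency("gA", -3.3, e_percent, 0.99)
        assert check_efficiency_range(e) is expected
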
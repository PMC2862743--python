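"""Carpet data model, persistence round-trips and stationarity QC."""

from __future__ import annotations

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pcfscan as p
from pcfscan.errors import (
    ConfigurationError,
    FormatError,
    RatioUndefinedError,
    ValidationError,
)

META = dict(pixel_size_um=0.1, pixel_dwell_s=6.3e-6, line_period_s=4.73e-4)


def make_carpet(counts, **kw):
    return p.LineScanCarpet(counts=np.asarray(counts), **{**META, **kw})


class TestInvariants:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            make_carpet([[1, -1], [0, 0]])

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValidationError):
            make_carpet(np.array([[0.5, 1.0], [1.0, 2.0]]))

    def test_integral_floats_accepted(self):
        c = make_carpet(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert c.counts.dtype == np.int64

    def test_line_period_must_cover_active_scan(self):
        with pytest.raises(ValidationError):
            make_carpet(np.zeros((4, 40), dtype=int), line_period_s=40 * 6.3e-6 / 2)

    def test_column_positions(self):
        c = make_carpet(np.zeros((4, 4), dtype=int))
        np.testing.assert_allclose(c.positions_um, [0.0, 0.1, 0.2, 0.3])

    def test_bad_label_rejected(self):
        with pytest.raises(ValidationError):
            make_carpet(np.zeros((4, 2), dtype=int), labels=("nucleus", "mitochondrion"))


class TestIO:
    @pytest.mark.parametrize("fmt,ext", [("tiff", ".tif"), ("csv", ".csv"), ("raw", ".raw")])
    def test_round_trip_bit_exact(self, tmp_path, rng, fmt, ext):
        counts = rng.poisson(7, size=(64, 8))
        counts[3, 5] = 65535  # 16-bit boundary survives
        carpet = make_carpet(counts, labels=("nucleus",) * 4 + ("cytoplasm",) * 4)
        path = tmp_path / f"c{ext}"
        p.save_carpet(carpet, path, format=fmt)
        back = p.load_carpet(path, format=fmt)
        np.testing.assert_array_equal(back.counts, carpet.counts)
        assert back.pixel_size_um == carpet.pixel_size_um
        assert back.pixel_dwell_s == carpet.pixel_dwell_s
        assert back.line_period_s == carpet.line_period_s
        assert back.labels == carpet.labels

    def test_zero_carpet_round_trip(self, tmp_path):
        path = tmp_path / "z.csv"
        p.save_carpet(make_carpet(np.zeros((3, 4), dtype=int)), path)
        back = p.load_carpet(path)
        assert back.n_lines == 3 and back.n_pixels == 4
        assert back.counts.sum() == 0

    def test_full_length_acquisition_shape(self, tmp_path):
        # a 32-pixel, 2e5-line record loads with the right orientation
        path = tmp_path / "long.tif"
        p.save_carpet(make_carpet(np.zeros((200_000, 32), dtype=int)), path)
        back = p.load_carpet(path)
        assert (back.n_lines, back.n_pixels) == (200_000, 32)

    def test_tiff_overflow_suggests_raw(self, tmp_path):
        c = make_carpet(np.array([[65536, 0], [0, 0]]))
        with pytest.raises(FormatError, match="raw"):
            p.save_carpet(c, tmp_path / "o.tif")
        # raw handles it
        p.save_carpet(c, tmp_path / "o.raw")
        np.testing.assert_array_equal(p.load_carpet(tmp_path / "o.raw").counts, c.counts)

    def test_missing_sidecar_field_named(self, tmp_path):
        path = tmp_path / "c.csv"
        p.save_carpet(make_carpet(np.zeros((3, 4), dtype=int)), path)
        meta = json.loads((tmp_path / "c.json").read_text())
        del meta["pixel_dwell_s"]
        (tmp_path / "c.json").write_text(json.dumps(meta))
        with pytest.raises(ConfigurationError, match="pixel_dwell_s"):
            p.load_carpet(path)

    def test_malformed_csv(self, tmp_path):
        (tmp_path / "bad.csv").write_text("1,2\n3,banana\n")
        (tmp_path / "bad.json").write_text(json.dumps(META))
        with pytest.raises(FormatError):
            p.load_carpet(tmp_path / "bad.csv")


class TestSegments:
    def test_full_range_identity(self, rng):
        c = make_carpet(rng.poisson(3, size=(100, 4)))
        out = p.select_segment(c, p.SegmentSelection(0, 100))
        np.testing.assert_array_equal(out.counts, c.counts)

    def test_single_line(self, rng):
        c = make_carpet(rng.poisson(3, size=(100, 4)))
        out = p.select_segment(c, p.SegmentSelection(99, 100))
        assert out.n_lines == 1

    def test_thirty_second_segment_duration(self):
        # 63424 lines at the 0.473 ms line period span ~30 s
        c = make_carpet(np.zeros((70_000, 4), dtype=int), line_period_s=4.73e-4)
        out = p.select_segment(c, p.SegmentSelection(0, 63_424))
        assert out.duration_s == pytest.approx(30.0, abs=0.01)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_selection_composes(self, data):
        n = 60
        counts = np.arange(n * 2, dtype=np.int64).reshape(n, 2)
        c = make_carpet(counts)
        a = data.draw(st.integers(0, n - 2))
        b = data.draw(st.integers(a + 1, n))
        inner = p.select_segment(c, p.SegmentSelection(a, b))
        cc = data.draw(st.integers(0, b - a - 1))
        d = data.draw(st.integers(cc + 1, b - a))
        twice = p.select_segment(inner, p.SegmentSelection(cc, d))
        once = p.select_segment(c, p.SegmentSelection(a + cc, a + d))
        np.testing.assert_array_equal(twice.counts, once.counts)
        assert twice.acquisition_start_s == pytest.approx(once.acquisition_start_s)

    def test_invalid_selection(self):
        with pytest.raises(ValidationError):
            p.SegmentSelection(5, 5)


class TestStationarity:
    def test_constant_column_metric_zero(self):
        c = make_carpet(np.full((2000, 3), 4, dtype=int))
        rep = p.stationarity_report(c, window_lines=100)
        assert (rep["metric"] == 0).all()
        assert rep["passed"].all()

    def test_empty_column_flagged_not_nan(self):
        counts = np.zeros((2000, 2), dtype=int)
        counts[:, 1] = 3
        rep = p.stationarity_report(make_carpet(counts), window_lines=100)
        assert rep.loc[0, "metric"] == 0.0
        assert bool(rep.loc[0, "empty"])
        assert not bool(rep.loc[1, "empty"])

    def test_stationary_poisson_passes_default_threshold(self, rng):
        # Monte-Carlo oracle for the null distribution of the drift metric:
        # windowed means of n iid Poisson(5) samples, 20 windows of 1000.
        n_win, win, mean = 20, 1000, 5.0
        null = []
        for _ in range(200):
            wm = rng.poisson(mean, size=(n_win, win)).mean(axis=1)
            null.append((wm.max() - wm.min()) / mean)
        assert np.quantile(null, 0.99) < 0.2  # threshold clears the null

        counts = rng.poisson(mean, size=(n_win * win, 3))
        rep = p.stationarity_report(make_carpet(counts), window_lines=win)
        assert rep["passed"].all()

    def test_bleaching_column_fails(self):
        n = 20_000
        lam = 40.0 * np.exp(-np.log(2.0) * np.arange(n) / n)  # decays to 50%
        counts = np.random.default_rng(0).poisson(lam)[:, None] * np.ones((1, 2), dtype=int)
        rep = p.stationarity_report(make_carpet(counts), window_lines=1000)
        # windowed means span ~half the initial level; relative to the
        # grand mean of the decaying record the drift metric is ~0.69
        assert rep.loc[0, "metric"] == pytest.approx(np.log(2.0), abs=0.1)
        assert not rep.loc[0, "passed"]

    def test_metric_invariant_to_rescaling(self, rng):
        base = rng.poisson(5, size=(8000, 2))
        c1 = make_carpet(base)
        c2 = make_carpet(base * 7)
        r1 = p.stationarity_report(c1, window_lines=500)
        r2 = p.stationarity_report(c2, window_lines=500)
        assert r1.loc[0, "metric"] == pytest.approx(r2.loc[0, "metric"], rel=1e-12)

    def test_window_bounds_enforced(self, rng):
        c = make_carpet(rng.poisson(5, size=(100, 2)))
        with pytest.raises(ValidationError):
            p.stationarity_report(c, window_lines=26)  # > n/4


class TestConcentrationRatio:
    def test_uniform_carpet_unity(self):
        labels = ("nucleus",) * 2 + ("cytoplasm",) * 2
        c = make_carpet(np.full((50, 4), 9, dtype=int), labels=labels)
        assert p.concentration_ratio(c) == pytest.approx(1.0)

    def test_partition_coefficient_and_symmetry(self):
        counts = np.zeros((10, 4), dtype=int)
        counts[:, :2] = 13
        counts[:, 2:] = 2
        labels = ("nucleus",) * 2 + ("cytoplasm",) * 2
        c = make_carpet(counts, labels=labels)
        keq = p.concentration_ratio(c)
        assert keq == pytest.approx(6.5)
        swapped = ("cytoplasm",) * 2 + ("nucleus",) * 2
        assert p.concentration_ratio(c, labels=swapped) == pytest.approx(1.0 / keq)

    def test_zero_cytoplasm_undefined(self):
        counts = np.zeros((10, 2), dtype=int)
        counts[:, 0] = 5
        c = make_carpet(counts, labels=("nucleus", "cytoplasm"))
        with pytest.raises(RatioUndefinedError):
            p.concentration_ratio(c)
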
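"""Trajectory reading, internal coordinates and time-domain reductions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wavewire import trajectory_io as tio
from wavewire.trajectory_io import (
    InternalCoordinateSpec,
    TimeSeries,
    Trajectory,
    XYZParseError,
    block_average,
    difference,
    extract,
    histogram,
    read_timeseries,
    read_xyz,
    write_timeseries,
    write_xyz,
)

GOOD_XYZ = """3
frame 0
O 0.0 0.0 0.0
H 1.02 0.0 0.0
H 0.0 1.0 0.0
3
frame 1
O 0.0 0.0 0.5
H 1.02 0.0 0.5
H 0.0 1.0 0.5
"""


def iupac_dihedral(p1, p2, p3, p4):
    """Two-plane-normal torsion oracle, IUPAC sign convention."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    return np.degrees(np.arctan2(y, np.dot(n1, n2)))


def chain_with_dihedral(theta_deg, ang_deg=70.0, bond=1.5):
    a, th = np.radians(ang_deg), np.radians(theta_deg)
    p1 = np.array([-bond * np.cos(a), bond * np.sin(a), 0.0])
    p2 = np.zeros(3)
    p3 = np.array([bond, 0.0, 0.0])
    p4 = p3 + bond * np.array([-np.cos(a), np.sin(a) * np.cos(th), np.sin(a) * np.sin(th)])
    return np.stack([p1, p2, p3, p4])


class TestReadXYZ:
    def test_two_frame_file(self, tmp_path):
        p = tmp_path / "t.xyz"
        p.write_text(GOOD_XYZ)
        traj = read_xyz(p, dt=0.5)
        assert traj.n_frames == 2
        assert traj.element_labels == ["O", "H", "H"]
        assert traj.coordinates[1, 0, 2] == pytest.approx(0.5)

    def test_malformed_frame_names_index(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text(GOOD_XYZ.rsplit("\n", 2)[0] + "\n")  # drop last atom of frame 1
        with pytest.raises(XYZParseError, match="frame 1"):
            read_xyz(p, dt=0.5)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.xyz"
        p.write_text("")
        with pytest.raises(XYZParseError):
            read_xyz(p, dt=0.5)

    def test_wire_roundtrip_bit_identical(self, tmp_path, default_wire):
        _, traj, _ = default_wire
        p1, p2 = tmp_path / "a.xyz", tmp_path / "b.xyz"
        write_xyz(traj, p1)
        traj2 = read_xyz(p1, dt=traj.dt)
        write_xyz(traj2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        traj3 = read_xyz(p2, dt=traj.dt)
        assert np.array_equal(traj2.coordinates, traj3.coordinates)


class TestExtract:
    def _one_frame(self, coords):
        labels = ["C"] * coords.shape[0]
        return Trajectory(labels, coords[None, :, :], dt=1.0)

    def test_distance(self):
        traj = self._one_frame(np.array([[0.0, 0, 0], [1.02, 0, 0]]))
        ts = extract(traj, InternalCoordinateSpec("distance", (0, 1)))
        assert ts.values[0] == pytest.approx(1.02)

    def test_cis_trans_dihedral(self):
        cis = self._one_frame(chain_with_dihedral(0.0))
        trans = self._one_frame(chain_with_dihedral(180.0))
        spec = InternalCoordinateSpec("dihedral", (0, 1, 2, 3))
        assert extract(cis, spec).values[0] == pytest.approx(0.0, abs=1e-8)
        assert extract(trans, spec).values[0] == pytest.approx(180.0, abs=1e-8)

    def test_gauche_sign_convention(self):
        traj = self._one_frame(chain_with_dihedral(60.0))
        spec = InternalCoordinateSpec("dihedral", (0, 1, 2, 3))
        got = extract(traj, spec).values[0]
        oracle = iupac_dihedral(*chain_with_dihedral(60.0))
        assert got == pytest.approx(60.0, abs=1e-6)
        assert got == pytest.approx(oracle, abs=1e-6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_dihedral_matches_brute_force_oracle(self, seed):
        coords = np.random.default_rng(seed).normal(size=(4, 3)) * 2.0
        b2 = coords[2] - coords[1]
        n1 = np.cross(coords[1] - coords[0], b2)
        n2 = np.cross(b2, coords[3] - coords[2])
        if min(np.linalg.norm(n1), np.linalg.norm(n2)) < 1e-6:
            return  # near-collinear draw: torsion undefined
        traj = self._one_frame(coords)
        spec = InternalCoordinateSpec("dihedral", (0, 1, 2, 3))
        got = extract(traj, spec).values[0]
        assert got == pytest.approx(iupac_dihedral(*coords), abs=1e-4)
        # the signed torsion is invariant under reversing the atom order
        rev = extract(traj, InternalCoordinateSpec("dihedral", (3, 2, 1, 0))).values[0]
        assert rev == pytest.approx(got, abs=1e-4)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_distance_symmetric_under_swap(self, seed):
        coords = np.random.default_rng(seed).normal(size=(3, 3))
        traj = self._one_frame(coords)
        d01 = extract(traj, InternalCoordinateSpec("distance", (0, 1))).values[0]
        d10 = extract(traj, InternalCoordinateSpec("distance", (1, 0))).values[0]
        assert d01 == d10

    def test_angle_range(self):
        traj = self._one_frame(np.array([[1.0, 0, 0], [0.0, 0, 0], [0.0, 1.0, 0]]))
        ts = extract(traj, InternalCoordinateSpec("angle", (0, 1, 2)))
        assert ts.values[0] == pytest.approx(90.0)

    def test_collinear_dihedral_names_frame(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 1, 0]])
        traj = self._one_frame(coords)
        with pytest.raises(ValueError, match="frame 0"):
            extract(traj, InternalCoordinateSpec("dihedral", (0, 1, 2, 3)))

    def test_bad_spec_arity(self):
        with pytest.raises(ValueError, match="dihedral requires 4"):
            InternalCoordinateSpec("dihedral", (0, 1, 2))


class TestDifference:
    def test_identity_and_offset(self):
        a = TimeSeries(np.arange(10, dtype=float), dt=0.5, label="s1")
        d = difference(a, a)
        assert np.all(d.values == 0.0)
        b = TimeSeries(a.values + 0.3, dt=0.5, label="s0")
        assert np.allclose(difference(b, a).values, 0.3)

    def test_truncates_to_common_span(self):
        a = TimeSeries(np.ones(10), dt=0.5)
        b = TimeSeries(np.zeros(7), dt=0.5)
        assert len(difference(a, b)) == 7

    def test_dt_mismatch(self):
        a = TimeSeries(np.ones(5), dt=0.5)
        b = TimeSeries(np.ones(5), dt=1.0)
        with pytest.raises(ValueError, match="dt"):
            difference(a, b)


class TestBlockAverage:
    @pytest.mark.parametrize(
        "values,window,expected",
        [
            ([1.0, 2.0, 3.0, 4.0], 2, [1.5, 3.5]),
            ([1.0, 2.0, 3.0], 2, [1.5, 3.0]),  # trailing partial block kept
            ([5.0] * 7, 3, [5.0, 5.0, 5.0]),
            ([1.0, 2.0], 10, [1.5]),  # window > length: single value
        ],
    )
    def test_examples(self, values, window, expected):
        out = block_average(TimeSeries(np.array(values), dt=1.0), window)
        assert np.allclose(out.values, expected)
        assert out.dt == window * 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(1, 20), st.integers(1, 6), st.integers(0, 1000))
    def test_mean_preserved_when_window_divides(self, blocks, window, seed):
        v = np.random.default_rng(seed).normal(size=blocks * window)
        out = block_average(TimeSeries(v, dt=0.5), window)
        assert out.values.mean() == pytest.approx(v.mean(), abs=1e-12)


class TestHistogram:
    def test_identical_values_single_bin(self):
        ts = TimeSeries(np.full(100, 2.58), dt=1.0)
        dist = histogram(ts, bin_width=0.01)
        assert dist.counts.sum() == 100
        assert (dist.counts > 0).sum() == 1

    def test_uniform_grid_one_per_bin(self):
        ts = TimeSeries(np.arange(20) * 0.1 + 0.05, dt=1.0)
        dist = histogram(ts, bin_width=0.1)
        assert np.all(dist.counts == 1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(2, 500), st.integers(0, 1000))
    def test_counts_conserved_and_density_normalised(self, n, seed):
        v = np.random.default_rng(seed).normal(size=n)
        dist = histogram(TimeSeries(v, dt=1.0), bin_width=0.25)
        assert dist.counts.sum() == n
        width = np.diff(dist.bin_edges)
        assert np.sum(dist.density * width) == pytest.approx(1.0)

    def test_sinusoid_arcsine_density(self):
        # samples of sin follow the arcsine law: P(bin) = (asin(b)-asin(a))/pi
        t = np.arange(200_000)
        ts = TimeSeries(np.sin(0.1234567 * t), dt=1.0)
        dist = histogram(ts, bin_width=0.125)
        probs = dist.counts / dist.counts.sum()
        lo = np.clip(dist.bin_edges[:-1], -1, 1)
        hi = np.clip(dist.bin_edges[1:], -1, 1)
        expected = (np.arcsin(hi) - np.arcsin(lo)) / np.pi
        assert np.abs(probs - expected).max() < 5e-3
        # edge peaks: outermost occupied bins denser than the centre
        centre = np.argmin(np.abs(dist.bin_edges[:-1] + 0.0625))
        assert dist.density[0] > dist.density[centre]
        assert dist.density[-1] > dist.density[centre]


class TestSeriesIO:
    def test_roundtrip(self, tmp_path):
        ts = TimeSeries(np.sin(np.arange(64)), dt=0.5, t0=3.0, label="x")
        p = tmp_path / "x.csv"
        write_timeseries(ts, p)
        back = read_timeseries(p)
        assert back.dt == pytest.approx(0.5)
        assert back.t0 == pytest.approx(3.0)
        assert np.allclose(back.values, ts.values)

    def test_nonuniform_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_fs,value\n0,1\n1,2\n5,3\n")
        with pytest.raises(ValueError, match="uniform"):
            read_timeseries(p)

    def test_distribution_export(self, tmp_path):
        dist = histogram(TimeSeries(np.random.default_rng(0).normal(size=50), dt=1.0), 0.5)
        p = tmp_path / "d.csv"
        tio.write_distribution(dist, p)
        header = p.read_text().splitlines()[0]
        assert header == "bin_left,bin_right,count,density"
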
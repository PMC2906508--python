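"""Deformation series, smoothing, summaries, occupancy and groove width."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mhcdeform.deformation import (
    RMSDSeries,
    groove_width_series,
    local_fit_rmsd_series,
    moving_average,
    pocket_occupancy,
    region_rmsd_series,
    summarize,
)
from mhcdeform.structures import RegionSelection, Structure, Trajectory
from mhcdeform.synthetic import SyntheticScenario, build_ideal_helix, generate_trajectory

from conftest import random_rotation

SPAN = RegionSelection.span("span", "A", 65, 69)


@pytest.fixture(scope="module")
def base() -> Structure:
    return SyntheticScenario(extra_bodies=False).build_base()


def _traj(base, frames, dt=0.001):
    return Trajectory(base, np.asarray(frames), np.arange(len(frames)) * dt, id="t")


def test_constant_trajectory_gives_zero_series(base):
    traj = _traj(base, [base.coords] * 5)
    s = local_fit_rmsd_series(traj, SPAN, 5, base)
    np.testing.assert_allclose(s.values, 0.0, atol=1e-12)
    assert s.fit_mode == "LOCAL_FLANK(n_flank=5)"


def test_local_fit_removes_per_frame_rigid_motion(base, rng):
    frames = [base.coords @ random_rotation(rng).T + rng.normal(size=3) * 10
              for _ in range(8)]
    s = local_fit_rmsd_series(_traj(base, frames), SPAN, 5, base)
    assert np.all(s.values < 1e-6)


def test_uniform_span_displacement_recovered_exactly(base):
    from mhcdeform.structures import resolve_selection
    span_all = RegionSelection.span("span", "A", 65, 69, "ALL")
    idx = resolve_selection(base, span_all)
    moved = base.coords.copy()
    moved[idx] += np.array([0.0, 4.0, 0.0])  # 0.40 nm
    s = local_fit_rmsd_series(_traj(base, [moved] * 3), SPAN, 5, base)
    np.testing.assert_allclose(s.values, 0.40, atol=1e-12)


def test_region_self_ignores_rigid_rotation_of_region(base, rng):
    helix = RegionSelection.span("helix", "A", 55, 85)
    frames = [base.coords @ random_rotation(rng).T for _ in range(5)]
    s = region_rmsd_series(_traj(base, frames), helix, "REGION_SELF", base)
    assert np.all(s.values < 1e-6)


def test_global_anchor_fit_sees_region_drift(base):
    region = RegionSelection.span("tail", "A", 78, 85)
    anchor = RegionSelection.span("anchor", "A", 55, 70)
    from mhcdeform.structures import resolve_selection
    idx = resolve_selection(base, RegionSelection.span("tail", "A", 78, 85, "ALL"))
    moved = base.coords.copy()
    moved[idx] += np.array([2.5, 0.0, 0.0])  # 0.25 nm drift
    s = region_rmsd_series(_traj(base, [moved] * 4), region, anchor, base)
    np.testing.assert_allclose(s.values, 0.25, atol=1e-12)
    assert s.fit_mode == "GLOBAL(anchor)"


def _series(values, dt=0.001):
    values = np.asarray(values, dtype=float)
    return RMSDSeries(times=np.arange(values.size) * dt, values=values,
                      target="span", fit_mode="LOCAL_FLANK(n_flank=5)",
                      reference_id="ref")


def test_moving_average_constant_is_identity():
    s = _series(np.full(50, 0.2))
    for policy in ("TRUNCATE", "DROP"):
        sm = moving_average(s, 5, policy)
        np.testing.assert_allclose(sm.values, 0.2, atol=1e-12)
    assert len(moving_average(s, 5, "TRUNCATE")) == 50
    assert len(moving_average(s, 5, "DROP")) == 40


def test_moving_average_impulse_matches_direct_summation():
    v = np.zeros(11)
    v[5] = 1.0
    s = _series(v)
    sm = moving_average(s, 2, "TRUNCATE")
    # independent direct-summation oracle
    expected = np.array([
        np.mean(v[max(i - 2, 0): i + 3]) for i in range(11)
    ])
    np.testing.assert_array_equal(sm.values, expected)
    assert np.all(sm.values[3:8] == 1.0 / 5.0)


def test_moving_average_never_exceeds_raw_max(rng):
    v = rng.uniform(0, 1, 200)
    s = _series(v)
    for policy in ("TRUNCATE", "DROP"):
        assert moving_average(s, 7, policy).values.max() <= v.max() + 1e-12


def test_summarize_basics_and_window():
    s = _series([0.1, 0.3])
    summ = summarize(s)
    assert summ.mean_rmsd == pytest.approx(0.2)
    assert summ.max_rmsd == pytest.approx(0.3)
    assert summ.n_frames == 2
    const = _series(np.full(10, 0.2))
    cs = summarize(const, (0.0, 1.0))
    assert cs.mean_rmsd == cs.max_rmsd == pytest.approx(0.2)
    with pytest.raises(ValueError, match="no frames"):
        summarize(const, (5.0, 6.0))


def test_summarize_ramp_closed_form():
    n = 1000
    ramp = np.linspace(0.0, 0.4, n)
    s = _series(ramp)
    half = summarize(s, (s.times[n // 2], s.times[-1]))
    assert half.mean_rmsd == pytest.approx(np.mean(ramp[n // 2:]), abs=1e-12)
    assert half.n_frames == n - n // 2


def _occupancy_fixture(distances, cutoff=8.0, dt=0.001):
    """Two single-atom bodies separated by the given per-frame distances."""
    from mhcdeform.structures import AtomRecord
    atoms = [
        AtomRecord(1, "CA", "C", "GLY", "P", 1, (0.0, 0.0, 0.0)),
        AtomRecord(2, "CA", "C", "GLY", "Q", 1, (0.0, 0.0, 0.0)),
    ]
    topo = Structure(atoms, id="probe-pocket")
    frames = np.zeros((len(distances), 2, 3))
    frames[:, 1, 0] = distances
    traj = Trajectory(topo, frames, np.arange(len(distances)) * dt)
    probe = RegionSelection.span("probe", "P", 1, 1, "ALL")
    pocket = RegionSelection.span("pocket", "Q", 1, 1, "ALL")
    return traj, probe, pocket


def test_occupancy_always_inside():
    traj, probe, pocket = _occupancy_fixture(np.full(10, 2.0))
    occ = pocket_occupancy(traj, probe, pocket)
    assert occ.residency_fraction == 1.0
    assert occ.first_exit_time is None
    assert not occ.early_exit


def test_occupancy_exit_frame_and_threshold():
    d = np.full(2000, 3.0)
    d[800:] = 12.0  # crosses the 8 A sphere outward at frame 800
    traj, probe, pocket = _occupancy_fixture(d)
    occ = pocket_occupancy(traj, probe, pocket, cutoff=8.0, exit_threshold=1.0)
    assert occ.first_exit_time == pytest.approx(0.8)
    assert occ.early_exit  # within the first nanosecond
    assert occ.residency_fraction == pytest.approx(np.mean(d <= 8.0))
    late = pocket_occupancy(traj, probe, pocket, cutoff=8.0, exit_threshold=0.5)
    assert not late.early_exit


def test_occupancy_residency_equals_mean_inside(rng):
    d = rng.uniform(0, 16, 500)
    traj, probe, pocket = _occupancy_fixture(d)
    occ = pocket_occupancy(traj, probe, pocket)
    assert occ.residency_fraction == pytest.approx(occ.inside.mean())


def test_groove_width_static_and_monotone(rng):
    helix = build_ideal_helix(10, "A")
    atoms = list(helix.atoms)
    from dataclasses import replace
    wall = [replace(a, chain_id="B",
                    coords=(a.coords[0], a.coords[1], a.coords[2] + 10.0))
            for a in helix.atoms]
    topo = Structure(atoms + wall, id="groove")
    half_a = RegionSelection.span("a", "A", 1, 10, "CA")
    half_b = RegionSelection.span("b", "B", 1, 10, "CA")
    nb = len(helix.atoms)

    static = Trajectory(topo, np.stack([topo.coords] * 5), np.arange(5) * 0.001)
    gw = groove_width_series(static, half_a, half_b)
    np.testing.assert_allclose(gw.widths, 1.0, atol=1e-12)

    frames = []
    for k in range(5):
        c = topo.coords.copy()
        c[nb:, 2] += 0.5 * k  # widen by 2 A over the run
        frames.append(c)
    widening = Trajectory(topo, np.stack(frames), np.arange(5) * 0.001)
    w = groove_width_series(widening, half_a, half_b).widths
    assert np.all(np.diff(w) > 0)
    assert w[-1] - w[0] == pytest.approx(0.2, abs=1e-12)

    # distance is invariant under whole-complex rotation
    rot_frames = [f @ random_rotation(rng).T for f in frames]
    rotated = Trajectory(topo, np.stack(rot_frames), np.arange(5) * 0.001)
    np.testing.assert_allclose(
        groove_width_series(rotated, half_a, half_b).widths, w, atol=1e-9)


def test_monotone_response_to_injected_amplitude():
    """Mean flank-fitted RMSD increases strictly with the injected amplitude."""
    means = []
    for amp in (1.0, 2.0, 3.0, 4.0):  # A
        sc = SyntheticScenario(name=f"a{amp}", extra_bodies=False, n_frames=400,
                               noise_sigma=0.2, deformation_mode="LOCAL_SPAN",
                               deformation_amplitude=amp, deformation_static=True,
                               seed=7)
        tr = generate_trajectory(sc)
        s = local_fit_rmsd_series(tr, SPAN, 5, tr.topology)
        means.append(s.values.mean())
    assert np.all(np.diff(means) > 0)


@given(
    values=hnp.arrays(np.float64, st.integers(min_value=3, max_value=80),
                      elements=st.floats(0.0, 5.0, allow_nan=False)),
    half_width=st.integers(min_value=0, max_value=12),
)
@settings(deadline=None, derandomize=True, max_examples=50)
def test_moving_average_stays_within_raw_bounds(values, half_width):
    """Smoothing can never escape the raw series' range, any window size."""
    s = _series(values)
    sm = moving_average(s, half_width, "TRUNCATE")
    assert len(sm) == len(s)
    assert sm.values.min() >= values.min() - 1e-9
    assert sm.values.max() <= values.max() + 1e-9
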
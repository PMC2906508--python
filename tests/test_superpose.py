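"""Kabsch superposition, RMSD, fit/measure separation, average structures.

The independent oracle is the quaternion characteristic-polynomial method
(Horn/Theobald family): the optimal superposition RMSD follows from the
largest eigenvalue of the 4x4 quaternion key matrix, with no SVD involved.
"""

import numpy as np
import pytest

from mhcdeform.structures import Trajectory
from mhcdeform.superpose import (
    average_structure,
    batched_fit_measure_rmsd,
    fit_measure_rmsd,
    kabsch_fit,
    rmsd,
)

from conftest import random_rotation


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray,
                    weights: np.ndarray | None = None) -> float:
    """Optimal-superposition RMSD via the quaternion key-matrix eigenvalue."""
    m = mobile.shape[0]
    w = np.ones(m) if weights is None else np.asarray(weights, float)
    wsum = w.sum()
    x = mobile - (w[:, None] * mobile).sum(0) / wsum
    y = reference - (w[:, None] * reference).sum(0) / wsum
    g = (w * ((x**2).sum(1) + (y**2).sum(1))).sum()
    s = x.T @ (w[:, None] * y)  # 3x3 inner-product matrix
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key).max()
    msd = max((g - 2.0 * lam) / wsum, 0.0)
    return float(np.sqrt(msd))


def test_identity_fit(rng):
    pts = rng.normal(size=(20, 3))
    res = kabsch_fit(pts, pts)
    np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(res.translation, 0.0, atol=1e-12)
    assert res.fit_rmsd == pytest.approx(0.0, abs=1e-12)


def test_exact_rigid_transform_recovered(rng):
    ref = rng.normal(size=(15, 3))
    rot90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    mobile = ref @ rot90.T + np.array([1.0, 2.0, 3.0])
    res = kabsch_fit(mobile, ref)
    assert res.fit_rmsd == pytest.approx(0.0, abs=1e-10)
    np.testing.assert_allclose(res.apply(mobile), ref, atol=1e-10)


def test_agrees_with_quaternion_oracle(rng):
    for _ in range(20):
        m = int(rng.integers(5, 80))
        a = rng.normal(size=(m, 3)) * 5
        b = rng.normal(size=(m, 3)) * 5
        w = rng.uniform(0.5, 2.0, size=m)
        assert kabsch_fit(a, b).fit_rmsd == pytest.approx(
            quaternion_rmsd(a, b), abs=1e-10)
        assert kabsch_fit(a, b, w).fit_rmsd == pytest.approx(
            quaternion_rmsd(a, b, w), abs=1e-10)


def test_reflection_excluded_for_mirror_image(rng):
    ref = rng.normal(size=(25, 3))
    mirror = ref * np.array([-1.0, 1.0, 1.0])
    res = kabsch_fit(mirror, ref)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)
    assert res.fit_rmsd > 0.1  # mirror cannot be superposed by a proper rotation


def test_no_random_rotation_beats_kabsch(rng):
    a = rng.normal(size=(8, 3))
    b = rng.normal(size=(8, 3))
    best = kabsch_fit(a, b).fit_rmsd
    ac = a - a.mean(0)
    bc = b - b.mean(0)
    for _ in range(10_000):
        r = random_rotation(rng)
        trial = np.sqrt(((ac @ r.T - bc) ** 2).sum(1).mean())
        assert trial >= best - 1e-12


def test_min_points_and_shape_errors(rng):
    with pytest.raises(ValueError, match="at least 3"):
        kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))
    with pytest.raises(ValueError, match="shape"):
        rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


def test_degenerate_collinear_points_warn(rng):
    line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
    with pytest.warns(UserWarning, match="ill-conditioned"):
        res = kabsch_fit(line, line + 0.1)
    assert res.ill_conditioned


def test_rmsd_closed_forms():
    a = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
    assert rmsd(a, a) == 0.0
    assert rmsd(a + [3.0, 0, 0], a) == pytest.approx(3.0)
    two = np.array([[0.0, 0, 0], [0, 0, 0]])
    moved = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    assert rmsd(moved, two) == pytest.approx(2.0 / np.sqrt(2))


def test_fit_true_invariant_and_symmetric(rng):
    a = rng.normal(size=(12, 3))
    b = rng.normal(size=(12, 3))
    base = rmsd(a, b, fit=True)
    r = random_rotation(rng)
    t = rng.normal(size=3) * 10
    assert rmsd(a @ r.T + t, b, fit=True) == pytest.approx(base, abs=1e-9)
    assert rmsd(a, b @ r.T + t, fit=True) == pytest.approx(base, abs=1e-9)
    assert rmsd(b, a, fit=True) == pytest.approx(base, abs=1e-9)


def test_unit_weights_equal_constant_masses(rng):
    a = rng.normal(size=(10, 3))
    b = rng.normal(size=(10, 3))
    assert kabsch_fit(a, b, np.full(10, 12.011)).fit_rmsd == pytest.approx(
        kabsch_fit(a, b).fit_rmsd, abs=1e-12)


def test_fit_measure_separation(rng):
    ref = rng.normal(size=(30, 3)) * 4
    fit_idx = np.arange(0, 20)
    meas_idx = np.arange(20, 30)
    assert fit_measure_rmsd(ref, ref, fit_idx, meas_idx) == pytest.approx(0.0)
    # whole-structure rigid motion is absorbed by the fit
    r = random_rotation(rng)
    moved = ref @ r.T + [5.0, -2.0, 1.0]
    assert fit_measure_rmsd(moved, ref, fit_idx, meas_idx) == pytest.approx(0.0, abs=1e-6)
    # flanks pinned, measured atoms displaced by a common vector
    shifted = ref.copy()
    shifted[meas_idx] += np.array([0.0, 4.0, 0.0])
    assert fit_measure_rmsd(shifted, ref, fit_idx, meas_idx) == pytest.approx(4.0, abs=1e-10)


def test_batched_matches_per_frame(rng):
    ref = rng.normal(size=(25, 3)) * 3
    frames = ref[None] + rng.normal(0, 0.5, size=(40, 25, 3))
    fit_idx = np.arange(15)
    meas_idx = np.arange(15, 25)
    w = rng.uniform(1, 16, size=25)
    batched = batched_fit_measure_rmsd(frames, ref, fit_idx, meas_idx, w)
    single = [fit_measure_rmsd(f, ref, fit_idx, meas_idx, w) for f in frames]
    np.testing.assert_allclose(batched, single, atol=1e-10)


def _toy_trajectory(helix15, frames):
    return Trajectory(helix15, np.asarray(frames),
                      np.arange(len(frames)) * 0.001, id="toy")


def test_average_structure_constant_trajectory(helix15):
    traj = _toy_trajectory(helix15, [helix15.coords] * 4)
    avg = average_structure(traj, np.arange(len(helix15)), (0.0, 0.003))
    np.testing.assert_allclose(avg.coords, helix15.coords, atol=1e-12)


def test_average_structure_translation_midpoint(helix15):
    d = np.array([0.5, 0.0, 0.0])
    traj = _toy_trajectory(helix15, [helix15.coords - d, helix15.coords + d])
    avg = average_structure(traj, np.arange(len(helix15)), (0.0, 0.001))
    # both frames are rigid translations of the same structure: after fitting
    # to the first in-window frame they coincide there
    np.testing.assert_allclose(avg.coords, helix15.coords - d, atol=1e-9)


def test_average_of_random_rigid_transforms_recovers_structure(helix15, rng):
    frames = []
    for _ in range(6):
        r = random_rotation(rng)
        frames.append(helix15.coords @ r.T + rng.normal(size=3) * 8)
    traj = _toy_trajectory(helix15, frames)
    avg = average_structure(traj, np.arange(len(helix15)), (0.0, 0.01))
    # the average must equal frame 0 (the fit anchor) to numerical precision
    assert rmsd(avg.coords, frames[0], fit=False) == pytest.approx(0.0, abs=1e-6)


def test_average_structure_empty_window_lists_range(helix15):
    traj = _toy_trajectory(helix15, [helix15.coords] * 3)
    with pytest.raises(ValueError, match="0.002"):
        average_structure(traj, np.arange(len(helix15)), (5.0, 6.0))
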
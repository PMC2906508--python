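"""Rigid-body superposition and RMSD with independent fit and measure sets.

The central primitive is the weighted Kabsch fit: the proper rotation and
translation minimising the weighted RMSD between two index-corresponding
point sets, computed via SVD of the weighted covariance with a sign guard
that excludes improper (reflecting) solutions.  Everything downstream — the
flank-fitted span RMSD, whole-region deformation series and windowed average
structures — reduces to this primitive applied with possibly different fit
and measure atom sets.

Units are Angstrom throughout; callers convert to nm when reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structures import Structure, Trajectory

#: Relative singular-value threshold below which a fit is flagged ill-conditioned.
_COND_RTOL = 1e-8


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference.

    ``transform(x) = x @ rotation.T + translation``; ``fit_rmsd`` is the
    weighted RMSD over the fit atoms after transformation, in Angstrom.
    """

    rotation: np.ndarray
    translation: np.ndarray
    fit_rmsd: float
    weights: np.ndarray
    ill_conditioned: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _check_weights(weights, m: int) -> np.ndarray:
    if weights is None:
        return np.ones(m)
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (m,):
        raise ValueError(f"weights shape {w.shape} does not match point count {m}")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() == 0:
        raise ValueError("weights must not all be zero")
    return w


def kabsch_fit(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Weighted Kabsch superposition of ``mobile`` onto ``reference``.

    Both arguments are ``(M, 3)`` arrays whose rows correspond index-wise,
    M >= 3.  The returned rotation is always proper (det = +1): if the
    unconstrained orthogonal optimum is a reflection, the sign of the
    smallest singular value's contribution is flipped.  Degenerate
    (collinear or coincident) point sets produce a warning and a result
    flagged ``ill_conditioned`` rather than an error.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(
            f"point sets must share shape (M, 3); got {mobile.shape} and {reference.shape}"
        )
    m = mobile.shape[0]
    if m < 3:
        raise ValueError(f"superposition needs at least 3 points, got {m}")
    w = _check_weights(weights, m)
    wsum = w.sum()
    cm = (w[:, None] * mobile).sum(axis=0) / wsum
    cr = (w[:, None] * reference).sum(axis=0) / wsum
    x = mobile - cm
    y = reference - cr
    cov = x.T @ (w[:, None] * y)  # 3x3 weighted covariance
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    ill = bool(s[0] <= 0 or s[2] / s[0] < _COND_RTOL)
    if ill:
        warnings.warn(
            "ill-conditioned superposition: covariance is rank-deficient "
            "(collinear or degenerate point set)",
            stacklevel=2,
        )
    flip = np.ones(3)
    flip[2] = d if d != 0 else 1.0
    rotation = vt.T @ np.diag(flip) @ u.T
    translation = cr - rotation @ cm
    diff = x @ rotation.T - y
    fit_rmsd = float(np.sqrt((w * (diff**2).sum(axis=1)).sum() / wsum))
    return SuperpositionResult(rotation, translation, fit_rmsd, w, ill)


def rmsd(
    a: np.ndarray,
    b: np.ndarray,
    weights: np.ndarray | None = None,
    fit: bool = False,
) -> float:
    """Weighted root-mean-square deviation between corresponding points (A).

    With ``fit=True`` the optimal rigid superposition of ``a`` onto ``b`` is
    applied first (requires M >= 3); with ``fit=False`` coordinates are
    compared as given.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if fit:
        return kabsch_fit(a, b, weights).fit_rmsd
    w = _check_weights(weights, a.shape[0])
    diff = a - b
    return float(np.sqrt((w * (diff**2).sum(axis=1)).sum() / w.sum()))


def fit_measure_rmsd(
    frame: np.ndarray,
    reference: np.ndarray,
    fit_idx: np.ndarray,
    measure_idx: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """RMSD of ``measure_idx`` atoms after superposing on ``fit_idx`` atoms.

    ``frame`` and ``reference`` are full-structure ``(N, 3)`` coordinate
    arrays; ``weights`` (if given) is the full-length per-atom weight vector,
    subset internally for each role.  Fit and measure sets may differ or
    overlap — this is what lets a span's RMSD be measured in the frame of
    its own flanks, so the value reflects internal deformation rather than
    global motion.
    """
    frame = np.asarray(frame, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if frame.shape != reference.shape:
        raise ValueError(f"shape mismatch: {frame.shape} vs {reference.shape}")
    fit_idx = np.asarray(fit_idx, dtype=np.intp)
    measure_idx = np.asarray(measure_idx, dtype=np.intp)
    w_fit = None if weights is None else np.asarray(weights)[fit_idx]
    w_meas = None if weights is None else np.asarray(weights)[measure_idx]
    sup = kabsch_fit(frame[fit_idx], reference[fit_idx], w_fit)
    moved = sup.apply(frame[measure_idx])
    return rmsd(moved, reference[measure_idx], weights=w_meas, fit=False)


def batched_fit_measure_rmsd(
    frames: np.ndarray,
    reference: np.ndarray,
    fit_idx: np.ndarray,
    measure_idx: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorised :func:`fit_measure_rmsd` over a ``(T, N, 3)`` frame stack.

    Equivalent to calling :func:`fit_measure_rmsd` per frame but computes the
    T weighted covariances, SVDs and residuals in batched numpy operations,
    which is what makes 20k-frame series cheap.
    """
    frames = np.asarray(frames, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    fit_idx = np.asarray(fit_idx, dtype=np.intp)
    measure_idx = np.asarray(measure_idx, dtype=np.intp)
    if fit_idx.size < 3:
        raise ValueError("superposition needs at least 3 fit atoms")
    w = _check_weights(
        None if weights is None else np.asarray(weights)[fit_idx], fit_idx.size
    )
    wm = _check_weights(
        None if weights is None else np.asarray(weights)[measure_idx], measure_idx.size
    )
    mob = frames[:, fit_idx, :]  # (T, Mf, 3)
    ref = reference[fit_idx]
    wsum = w.sum()
    cm = (w[None, :, None] * mob).sum(axis=1) / wsum  # (T, 3)
    cr = (w[:, None] * ref).sum(axis=0) / wsum  # (3,)
    x = mob - cm[:, None, :]
    y = ref - cr
    cov = np.einsum("tmi,m,mj->tij", x, w, y)
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(np.einsum("tij,tkj->tik", vt.transpose(0, 2, 1), u)))
    d[d == 0] = 1.0
    flip = np.ones((frames.shape[0], 3))
    flip[:, 2] = d
    rot = np.einsum("tji,tj,tkj->tik", vt, flip, u)  # V diag(flip) U^T
    meas = frames[:, measure_idx, :]
    moved = np.einsum("tij,tmj->tmi", rot, meas - cm[:, None, :]) + cr
    diff = moved - reference[measure_idx]
    return np.sqrt((wm[None, :] * (diff**2).sum(axis=2)).sum(axis=1) / wm.sum())


def average_structure(
    traj: Trajectory,
    fit_idx: np.ndarray,
    time_window: tuple[float, float],
    weights: np.ndarray | None = None,
) -> Structure:
    """Per-atom mean structure over a time window after rigid alignment.

    Every in-window frame is superposed (on ``fit_idx``) onto the first
    in-window frame, then coordinates are averaged atom-wise.  The result
    carries the trajectory topology and a window annotation in its id.
    """
    t0, t1 = time_window
    idx = traj.window_indices(t0, t1)
    fit_idx = np.asarray(fit_idx, dtype=np.intp)
    w_fit = None if weights is None else np.asarray(weights)[fit_idx]
    anchor = traj.frames[idx[0]]
    acc = np.zeros_like(anchor)
    for i in idx:
        sup = kabsch_fit(traj.frames[i][fit_idx], anchor[fit_idx], w_fit)
        acc += sup.apply(traj.frames[i])
    mean = acc / idx.size
    return traj.topology.with_coords(
        mean, id=f"{traj.id} average[{t0:g}-{t1:g} ns, n={idx.size}]"
    )
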
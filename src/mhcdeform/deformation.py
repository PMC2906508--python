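"""Deformation metrics on trajectories.

This is the analysis layer the package exists for: per-frame RMSD series of
a residue span measured in the frame of its own flanking residues (so the
value reports internal deformation, not global tumbling), whole-region RMSD
series under self- or anchor-fitting, moving-average smoothing, windowed
summaries, side-chain pocket residency and binding-groove width.

All computation is carried out in Angstrom; every reported series and
summary is in nanometres, matching how MD deformation results are
conventionally quoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .structures import (
    RegionSelection,
    SelectionError,
    Structure,
    Trajectory,
    flank_selection,
    resolve_selection,
)
from .superpose import batched_fit_measure_rmsd

A_PER_NM = 10.0

EdgePolicy = Literal["TRUNCATE", "DROP"]


@dataclass
class RMSDSeries:
    """Per-frame deformation values (nm) with provenance metadata."""

    times: np.ndarray
    values: np.ndarray
    target: str
    fit_mode: str
    reference_id: str

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "value_nm": self.values})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SmoothedSeries:
    """Moving-average view of an :class:`RMSDSeries`.

    With edge policy TRUNCATE the window is clipped at the series ends and
    the length is preserved; with DROP only full windows are kept and the
    series loses ``half_width`` frames at each end.
    """

    times: np.ndarray
    values: np.ndarray
    base: RMSDSeries
    half_width: int
    edge_policy: EdgePolicy

    def __len__(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "value_nm": self.values})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class DeformationSummary:
    region: str
    fit_mode: str
    mean_rmsd: float  # nm
    max_rmsd: float  # nm
    time_window: tuple[float, float]
    n_frames: int


@dataclass
class OccupancyResult:
    """Residency of a probe (e.g. a peptide side chain) in a pocket."""

    times: np.ndarray
    inside: np.ndarray
    residency_fraction: float
    first_exit_time: float | None
    early_exit: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "inside": self.inside.astype(int)})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class GrooveWidthSeries:
    """Per-frame centroid distance (nm) between the two groove-wall helices."""

    times: np.ndarray
    widths: np.ndarray
    half_a: str
    half_b: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "width_nm": self.widths})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _weights_for(struct: Structure, mass_weighted: bool) -> np.ndarray | None:
    return struct.masses if mass_weighted else None


def local_fit_rmsd_series(
    traj: Trajectory,
    span: RegionSelection,
    n_flank: int,
    reference: Structure,
    mass_weighted: bool = True,
) -> RMSDSeries:
    """Flank-fitted RMSD series of a residue span, in nm.

    For each frame, the structure is superposed onto the reference using
    only the ``n_flank`` residues on each side of the span, and the RMSD is
    then measured over the span atoms.  Because the fit atoms bracket the
    span, rigid motion of the whole molecule (or of the local helix segment)
    cancels and the series isolates the span's internal deformation.
    """
    flanks = flank_selection(span, n_flank, struct=traj.topology)
    fit_idx = resolve_selection(traj.topology, flanks)
    measure_idx = resolve_selection(traj.topology, span)
    # the same selection must resolve identically on the reference topology
    resolve_selection(reference, flanks)
    w = _weights_for(traj.topology, mass_weighted)
    vals = batched_fit_measure_rmsd(
        traj.frames, reference.coords, fit_idx, measure_idx, weights=w
    )
    return RMSDSeries(
        times=traj.times,
        values=vals / A_PER_NM,
        target=span.name,
        fit_mode=f"LOCAL_FLANK(n_flank={n_flank})",
        reference_id=reference.id,
    )


def region_rmsd_series(
    traj: Trajectory,
    region: RegionSelection,
    fit_mode: str | RegionSelection,
    reference: Structure,
    mass_weighted: bool = True,
) -> RMSDSeries:
    """Per-frame RMSD of a region under a chosen fit mode, in nm.

    ``fit_mode`` is either the string ``"REGION_SELF"`` (superpose on the
    region itself, so only internal deformation registers) or a
    :class:`RegionSelection` used as an independent global anchor (rigid
    drift of the region relative to the anchor then contributes).
    """
    measure_idx = resolve_selection(traj.topology, region)
    if isinstance(fit_mode, RegionSelection):
        fit_idx = resolve_selection(traj.topology, fit_mode)
        mode_label = f"GLOBAL({fit_mode.name})"
    elif fit_mode == "REGION_SELF":
        fit_idx = measure_idx
        mode_label = "REGION_SELF"
    else:
        raise ValueError(
            f"fit_mode must be 'REGION_SELF' or a RegionSelection, got {fit_mode!r}"
        )
    w = _weights_for(traj.topology, mass_weighted)
    vals = batched_fit_measure_rmsd(
        traj.frames, reference.coords, fit_idx, measure_idx, weights=w
    )
    return RMSDSeries(
        times=traj.times,
        values=vals / A_PER_NM,
        target=region.name,
        fit_mode=mode_label,
        reference_id=reference.id,
    )


def moving_average(
    series: RMSDSeries, half_width: int, edge_policy: EdgePolicy = "TRUNCATE"
) -> SmoothedSeries:
    """Centred moving average over ``2 * half_width + 1`` frames.

    The value at frame i is the mean of the raw values over
    ``[i - half_width, i + half_width]``.  TRUNCATE intersects the window
    with valid indices (edge windows shrink); DROP keeps only frames with a
    full window on both sides.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    v = series.values
    t = series.times
    n = v.size
    if half_width == 0:
        sm_t, sm_v = t.copy(), v.copy()
    else:
        csum = np.concatenate(([0.0], np.cumsum(v)))
        i = np.arange(n)
        lo = np.maximum(i - half_width, 0)
        hi = np.minimum(i + half_width, n - 1)
        sm_v = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
        sm_t = t.copy()
        if edge_policy == "DROP":
            keep = slice(half_width, n - half_width)
            sm_v = sm_v[keep]
            sm_t = sm_t[keep]
            if sm_v.size == 0:
                raise ValueError(
                    f"DROP policy leaves no frames (length {n}, half_width {half_width})"
                )
        elif edge_policy != "TRUNCATE":
            raise ValueError(f"unknown edge policy {edge_policy!r}")
    return SmoothedSeries(
        times=sm_t, values=sm_v, base=series, half_width=half_width, edge_policy=edge_policy
    )


def summarize(
    series: RMSDSeries, time_window: tuple[float, float] | None = None
) -> DeformationSummary:
    """Mean and max of a series over a time window (defaults to the full run)."""
    if time_window is None:
        time_window = (float(series.times[0]), float(series.times[-1]))
    t0, t1 = time_window
    mask = (series.times >= t0) & (series.times <= t1)
    if not mask.any():
        raise ValueError(
            f"window [{t0}, {t1}] ns selects no frames; series covers "
            f"[{series.times[0]:g}, {series.times[-1]:g}] ns"
        )
    vals = series.values[mask]
    return DeformationSummary(
        region=series.target,
        fit_mode=series.fit_mode,
        mean_rmsd=float(vals.mean()),
        max_rmsd=float(vals.max()),
        time_window=(t0, t1),
        n_frames=int(mask.sum()),
    )


def _centroids(traj: Trajectory, sel: RegionSelection) -> np.ndarray:
    idx = resolve_selection(traj.topology, sel)
    return traj.frames[:, idx, :].mean(axis=1)


def pocket_occupancy(
    traj: Trajectory,
    probe: RegionSelection,
    pocket: RegionSelection,
    cutoff: float = 8.0,
    exit_threshold: float = 1.0,
) -> OccupancyResult:
    """Frame-wise residency of a probe group inside a pocket.

    A frame counts as "inside" when the centroid of the probe atoms (the
    position-4 side chain in the pMHC setting) lies within ``cutoff``
    Angstrom of the centroid of the pocket-lining atoms.  ``early_exit`` is
    true when the first exit happens at or before ``exit_threshold`` ns —
    the behaviour that distinguishes a groove-escaping anchor residue from
    one that stays seated for the whole run.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = np.linalg.norm(_centroids(traj, probe) - _centroids(traj, pocket), axis=1)
    inside = d <= cutoff
    if inside.all():
        first_exit = None
        early = False
    else:
        k = int(np.argmin(inside))  # first False
        first_exit = float(traj.times[k])
        early = first_exit <= exit_threshold
    return OccupancyResult(
        times=traj.times,
        inside=inside,
        residency_fraction=float(inside.mean()),
        first_exit_time=first_exit,
        early_exit=early,
    )


def groove_width_series(
    traj: Trajectory, half_a: RegionSelection, half_b: RegionSelection
) -> GrooveWidthSeries:
    """Per-frame distance between the centroids of the two groove walls, nm.

    The centroid distance of the CA atoms of the two helices bounding the
    peptide-binding groove is the simplest rotation-invariant width proxy;
    a widening groove shows as a monotone increase of this series.
    """
    widths = np.linalg.norm(
        _centroids(traj, half_a) - _centroids(traj, half_b), axis=1
    )
    if np.any(widths <= 0):
        raise SelectionError(
            "groove halves have coincident centroids; check the selections"
        )
    return GrooveWidthSeries(
        times=traj.times,
        widths=widths / A_PER_NM,
        half_a=half_a.name,
        half_b=half_b.name,
    )
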
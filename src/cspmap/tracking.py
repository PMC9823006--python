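"""Residue-wise peak tracking across a titration.

In fast exchange a peak drifts gradually with ligand concentration, so the
correspondence between successive spectra is established by nearest-neighbor
matching in the scaled shift plane, chained point to point (each spectrum is
matched against the previous one, not against the apo spectrum).  Matching is
mutual-nearest-neighbor with a greedy distance-ordered fallback for
conflicts; exact ties are rejected rather than resolved arbitrarily.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from cspmap.defaults import ALPHA_N, MAX_STEP_PPM, OVERLAP_TOL_PPM, TIE_TOL_PPM
from cspmap.peaklists import Peak, PeakList, TitrationSeries

__all__ = ["ResidueShiftTrack", "flag_overlap", "match_point", "scaled_distance", "track_series"]


def scaled_distance(a: Peak, b: Peak, alpha: float = ALPHA_N) -> float:
    """Combined-shift distance sqrt(dH^2 + (alpha*dN)^2) between two peaks."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return float(np.hypot(a.h_ppm - b.h_ppm, alpha * (a.n_ppm - b.n_ppm)))


@dataclass(frozen=True)
class ResidueShiftTrack:
    """One residue's peak trajectory across the titration.

    ``positions`` holds the matched (h_ppm, n_ppm) per point, ``None`` after
    the track is lost.  ``dd_h``/``dd_n`` are shift differences relative to
    the apo point, defined only for matched points (NaN otherwise).
    ``peak_ids`` records which peak was matched at each point.
    """

    residue_number: int
    positions: tuple[tuple[float, float] | None, ...]
    peak_ids: tuple[str | None, ...]
    status: str  # "complete" or "lost"
    lost_after: int | None = None
    overlapped: bool = False

    @property
    def dd_h(self) -> np.ndarray:
        h0 = self.positions[0][0]
        return np.array([p[0] - h0 if p is not None else np.nan for p in self.positions])

    @property
    def dd_n(self) -> np.ndarray:
        n0 = self.positions[0][1]
        return np.array([p[1] - n0 if p is not None else np.nan for p in self.positions])

    @property
    def n_matched(self) -> int:
        return sum(p is not None for p in self.positions)

    @property
    def complete(self) -> bool:
        return self.status == "complete"


def _scaled_xy(peaks: list[Peak], alpha: float) -> np.ndarray:
    return np.array([(p.h_ppm, alpha * p.n_ppm) for p in peaks]).reshape(len(peaks), 2)


def match_point(
    prev: list[Peak], cur: list[Peak], alpha: float = ALPHA_N, max_step: float = MAX_STEP_PPM
) -> dict[int, int]:
    """One-to-one match prev -> cur peaks under the scaled metric.

    Mutual nearest neighbors within ``max_step`` are accepted first, then a
    greedy distance-ordered pass claims remaining candidate pairs.  A peak
    whose two best candidates are tied within 1e-9 ppm stays unmatched.
    Returns ``{prev_index: cur_index}``.
    """
    if not prev or not cur:
        return {}
    xy_p = _scaled_xy(prev, alpha)
    xy_c = _scaled_xy(cur, alpha)
    tree_c = cKDTree(xy_c)
    tree_p = cKDTree(xy_p)

    k_c = min(len(cur), 2)
    d_pc, i_pc = tree_c.query(xy_p, k=k_c)
    d_pc = np.atleast_2d(d_pc.reshape(len(prev), k_c))
    i_pc = np.atleast_2d(i_pc.reshape(len(prev), k_c))
    k_p = min(len(prev), 2)
    d_cp, i_cp = tree_p.query(xy_c, k=k_p)
    d_cp = np.atleast_2d(d_cp.reshape(len(cur), k_p))
    i_cp = np.atleast_2d(i_cp.reshape(len(cur), k_p))

    tie_p = (k_c > 1) & (d_pc[:, -1] - d_pc[:, 0] <= TIE_TOL_PPM) & np.isfinite(d_pc[:, -1])
    tie_c = (k_p > 1) & (d_cp[:, -1] - d_cp[:, 0] <= TIE_TOL_PPM) & np.isfinite(d_cp[:, -1])

    matches: dict[int, int] = {}
    used_c: set[int] = set()
    # pass 1: mutual nearest neighbors
    for i in range(len(prev)):
        if tie_p[i] or d_pc[i, 0] > max_step:
            continue
        j = int(i_pc[i, 0])
        if tie_c[j]:
            continue
        if int(i_cp[j, 0]) == i:
            matches[i] = j
            used_c.add(j)
    # pass 2: greedy distance-ordered fallback among remaining pairs
    pairs = tree_p.query_ball_tree(tree_c, r=max_step)
    cand = [
        (float(np.linalg.norm(xy_p[i] - xy_c[j])), i, j)
        for i, js in enumerate(pairs)
        if i not in matches and not tie_p[i]
        for j in js
        if j not in used_c and not tie_c[j]
    ]
    for d, i, j in sorted(cand):
        if i in matches or j in used_c:
            continue
        matches[i] = j
        used_c.add(j)
    return matches


def track_series(
    series: TitrationSeries, alpha: float = ALPHA_N, max_step: float = MAX_STEP_PPM
) -> list[ResidueShiftTrack]:
    """Track every assigned apo peak through the titration.

    The apo point must carry assignments (directly or via assignment
    transfer).  Matching at point k pairs the full point-(k-1) and point-k
    peak lists one-to-one; a residue whose chain breaks at point k is flagged
    ``lost`` (``lost_after = k-1``) and excluded from later points.
    """
    if max_step <= 0:
        raise ValueError("max_step must be > 0")
    if len(series) < 2:
        raise ValueError("tracking needs at least two titration points")
    apo = series.points[0]
    assigned = apo.assigned()
    if not assigned:
        raise ValueError("apo point carries no assignments; transfer assignments first")

    n_pts = len(series)
    # chain: peak index at previous point -> residue, updated as we walk
    prev_peaks = list(apo.peaks)
    residue_of: dict[int, int] = {
        i: p.assignment.residue_number for i, p in enumerate(prev_peaks) if p.assignment
    }
    positions: dict[int, list[tuple[float, float] | None]] = {
        r: [None] * n_pts for r in assigned
    }
    peak_ids: dict[int, list[str | None]] = {r: [None] * n_pts for r in assigned}
    lost_after: dict[int, int | None] = {r: None for r in assigned}
    for i, r in residue_of.items():
        positions[r][0] = (prev_peaks[i].h_ppm, prev_peaks[i].n_ppm)
        peak_ids[r][0] = prev_peaks[i].id

    for k in range(1, n_pts):
        cur_peaks = list(series.points[k].peaks)
        matches = match_point(prev_peaks, cur_peaks, alpha=alpha, max_step=max_step)
        new_residue_of: dict[int, int] = {}
        for i, r in residue_of.items():
            if i in matches:
                j = matches[i]
                new_residue_of[j] = r
                positions[r][k] = (cur_peaks[j].h_ppm, cur_peaks[j].n_ppm)
                peak_ids[r][k] = cur_peaks[j].id
            else:
                lost_after[r] = k - 1
        residue_of = new_residue_of
        prev_peaks = cur_peaks

    tracks = []
    for r in sorted(assigned):
        lost = lost_after[r]
        tracks.append(
            ResidueShiftTrack(
                residue_number=r,
                positions=tuple(positions[r]),
                peak_ids=tuple(peak_ids[r]),
                status="complete" if lost is None else "lost",
                lost_after=lost,
            )
        )
    return tracks


def flag_overlap(
    series: TitrationSeries,
    tracks: list[ResidueShiftTrack],
    alpha: float = ALPHA_N,
    overlap_tol: float = OVERLAP_TOL_PPM,
) -> list[ResidueShiftTrack]:
    """Mark tracks whose matched peak ever has another peak within tolerance.

    Overlap is judged in the scaled metric against every other peak of the
    same spectrum (tracked or not, decoys included).
    """
    if overlap_tol <= 0:
        raise ValueError("overlap_tol must be > 0")
    flagged = []
    trees = []
    ids_per_point = []
    for pl in series.points:
        peaks = list(pl.peaks)
        trees.append(cKDTree(_scaled_xy(peaks, alpha)) if peaks else None)
        ids_per_point.append([p.id for p in peaks])
    for tr in tracks:
        overlapped = False
        for k, pos in enumerate(tr.positions):
            if pos is None or trees[k] is None:
                continue
            xy = np.array([pos[0], alpha * pos[1]])
            hits = trees[k].query_ball_point(xy, r=overlap_tol)
            if any(ids_per_point[k][j] != tr.peak_ids[k] for j in hits):
                overlapped = True
                break
        flagged.append(replace(tr, overlapped=overlapped))
    return flagged
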
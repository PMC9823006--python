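"""Dissociation-constant fitting on the ligand-depletion isotherm.

At 0.4 mM protein and micromolar K_D the bound ligand is never negligible,
so the hyperbolic isotherm is wrong; each residue's combined CSP is fitted
against

    dd_obs(L_t) = dd_max * f(K_D; P_t, L_t)

with f the quadratic two-state depletion fraction
(:func:`cspmap.synth.fraction_bound`).  K_D is parameterized on a log scale
(positivity by construction) and every fit is multi-started over a log-spaced
K_D grid to avoid local minima; ties go to the smaller K_D.

The pooled result follows the reporter-averaging convention: each selected
residue is fitted independently and the pooled K_D is the mean +- SD over
residues; a shared-K_D global fit (one K_D, per-residue amplitudes,
jackknife SD) is available as the alternative reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from cspmap.defaults import ALPHA_N
from cspmap.stats import CspTable, compute_csp
from cspmap.synth import fraction_bound
from cspmap.tracking import ResidueShiftTrack

__all__ = ["FitResult", "ResidueFit", "fit_global", "fit_residue", "select_reporters"]

_OBJ_TOL = 1e-10
MIN_POINTS = 5
MIN_REPORTERS = 3


class FitError(ValueError):
    """Unfittable input (no signal, too few points or reporters)."""


def select_reporters(table: CspTable, tracks: Sequence[ResidueShiftTrack]) -> list[int]:
    """Reporter residues: significant (>=1sigma), fully tracked, not overlapped.

    These are the well-resolved peaks whose titration curves feed the K_D
    fit.  May return an empty list; pooling requires at least three.
    """
    by_res = {tr.residue_number: tr for tr in tracks}
    out = []
    for r in table.significant("1sigma"):
        tr = by_res.get(r)
        if tr is not None and tr.complete and not tr.overlapped:
            out.append(r)
    return sorted(out)


@dataclass(frozen=True)
class ResidueFit:
    residue_number: int
    kd: float  # mM
    ddmax: float  # ppm
    residual_rms: float  # ppm
    n_points: int
    converged: bool

    @property
    def kd_uM(self) -> float:
        return 1e3 * self.kd


@dataclass(frozen=True)
class FitResult:
    """Pooled K_D estimate with the per-residue detail behind it."""

    per_residue: pd.DataFrame  # residue, kd_uM, ddmax_ppm, residual_rms, n_points, converged
    kd_mean_uM: float
    kd_sd_uM: float
    n: int  # reporter count pooled
    mode: str
    curve: pd.DataFrame  # ligand_total_mM, mean_norm, sd_norm

    def summary(self) -> dict:
        return {
            "kd_mean_uM": self.kd_mean_uM,
            "kd_sd_uM": self.kd_sd_uM,
            "n": self.n,
            "mode": self.mode,
        }


def _observed_csp(track: ResidueShiftTrack, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """(point mask, combined CSP per matched point) for one track."""
    dd = compute_csp(track.dd_h, track.dd_n, alpha)
    mask = ~np.isnan(dd)
    return mask, dd


def _fit_curve(
    lig: np.ndarray, dd_obs: np.ndarray, protein_total: float
) -> tuple[float, float, float, bool]:
    """Multi-start least squares of (kd, ddmax); returns (kd, ddmax, rms, ok)."""
    endpoint = dd_obs[-1]
    if endpoint <= 0 or np.all(dd_obs <= 0):
        raise FitError("track has no CSP signal to fit")
    l_pos = lig[lig > 0]
    kd_grid = np.geomspace(l_pos.min(), 10.0 * lig.max(), 5)
    ddmax0 = 1.2 * endpoint

    def resid(params):
        log_kd, ddmax = params
        return ddmax * fraction_bound(np.exp(log_kd), protein_total, lig) - dd_obs

    best = None
    for kd0 in kd_grid:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = least_squares(
                resid,
                x0=np.array([np.log(kd0), ddmax0]),
                ftol=_OBJ_TOL,
                xtol=1e-12,
                gtol=_OBJ_TOL,
                max_nfev=400,
            )
        obj = float(np.sum(sol.fun**2))
        kd = float(np.exp(sol.x[0]))
        if best is None or obj < best[0] - 1e-15 or (abs(obj - best[0]) <= 1e-15 and kd < best[1]):
            best = (obj, kd, float(sol.x[1]), bool(sol.success))
    obj, kd, ddmax, ok = best
    rms = float(np.sqrt(obj / len(lig)))
    # a fit that walked to the grid edge without signal is not converged
    if not np.isfinite(kd) or ddmax <= 0:
        ok = False
    return kd, ddmax, rms, ok


def fit_residue(
    track: ResidueShiftTrack,
    protein_total: float,
    ligand_schedule: Sequence[float],
    alpha: float = ALPHA_N,
) -> ResidueFit:
    """Fit one residue's titration curve; needs >= 5 matched points.

    Raises :class:`FitError` when the track has fewer than five matched
    points or carries no CSP signal.
    """
    mask, dd = _observed_csp(track, alpha)
    lig_all = np.asarray(ligand_schedule, dtype=float)[: len(mask)]
    lig = lig_all[mask[: len(lig_all)]]
    dd_obs = dd[mask]
    if len(dd_obs) < MIN_POINTS:
        raise FitError(
            f"residue {track.residue_number}: only {len(dd_obs)} matched points (< {MIN_POINTS})"
        )
    kd, ddmax, rms, ok = _fit_curve(lig, dd_obs, protein_total)
    return ResidueFit(
        residue_number=track.residue_number,
        kd=kd,
        ddmax=ddmax,
        residual_rms=rms,
        n_points=len(dd_obs),
        converged=ok,
    )


def _normalized_curve(
    fits: list[ResidueFit],
    tracks_by_res: dict[int, ResidueShiftTrack],
    ligand_schedule: np.ndarray,
    alpha: float,
) -> pd.DataFrame:
    norm = []
    for f in fits:
        _, dd = _observed_csp(tracks_by_res[f.residue_number], alpha)
        norm.append(dd / f.ddmax)
    arr = np.vstack(norm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean = np.nanmean(arr, axis=0)
        sd = np.nanstd(arr, axis=0, ddof=1)
    return pd.DataFrame(
        {"ligand_total_mM": ligand_schedule, "mean_norm": mean, "sd_norm": sd}
    )


def fit_global(
    tracks: Sequence[ResidueShiftTrack],
    protein_total: float,
    ligand_schedule: Sequence[float],
    mode: str = "per_residue_average",
    alpha: float = ALPHA_N,
) -> FitResult:
    """Pool reporter tracks into one K_D estimate.

    ``per_residue_average`` (default): independent fits, K_D mean +- SD over
    reporters, normalized curve from the per-residue dd_obs/dd_max.
    ``shared_kd``: one K_D with per-residue amplitudes; SD from leave-one-
    residue-out jackknife.
    """
    if mode not in ("per_residue_average", "shared_kd"):
        raise ValueError("mode must be 'per_residue_average' or 'shared_kd'")
    tracks = list(tracks)
    if len(tracks) < MIN_REPORTERS:
        raise FitError(f"need >= {MIN_REPORTERS} reporter tracks, got {len(tracks)}")
    lig = np.asarray(ligand_schedule, dtype=float)
    tracks_by_res = {tr.residue_number: tr for tr in tracks}

    fits: list[ResidueFit] = []
    for tr in tracks:
        try:
            f = fit_residue(tr, protein_total, lig, alpha=alpha)
        except FitError:
            continue
        if f.converged:
            fits.append(f)
    if len(fits) < MIN_REPORTERS:
        raise FitError(f"only {len(fits)} residues fit successfully (< {MIN_REPORTERS})")

    if mode == "per_residue_average":
        kds = np.array([f.kd for f in fits])
        kd_mean, kd_sd = float(kds.mean()), float(kds.std(ddof=1))
    else:
        kd_mean, kd_sd = _shared_kd(fits, tracks_by_res, protein_total, lig, alpha)

    per_res = pd.DataFrame(
        [
            {
                "residue": f.residue_number,
                "kd_uM": f.kd_uM,
                "ddmax_ppm": f.ddmax,
                "residual_rms": f.residual_rms,
                "n_points": f.n_points,
                "converged": f.converged,
            }
            for f in fits
        ]
    )
    curve = _normalized_curve(fits, tracks_by_res, lig, alpha)
    return FitResult(
        per_residue=per_res,
        kd_mean_uM=1e3 * kd_mean,
        kd_sd_uM=1e3 * kd_sd,
        n=len(fits),
        mode=mode,
        curve=curve,
    )


def _shared_kd(
    fits: list[ResidueFit],
    tracks_by_res: dict[int, ResidueShiftTrack],
    protein_total: float,
    lig: np.ndarray,
    alpha: float,
) -> tuple[float, float]:
    """One K_D across reporters with per-residue amplitudes; jackknife SD."""
    data = []
    for f in fits:
        mask, dd = _observed_csp(tracks_by_res[f.residue_number], alpha)
        data.append((lig[mask[: len(lig)]], dd[mask], f.ddmax))

    def solve(subset):
        def resid(params):
            log_kd = params[0]
            ddmaxes = params[1:]
            out = []
            for (l, dd, _), dm in zip(subset, ddmaxes):
                out.append(dm * fraction_bound(np.exp(log_kd), protein_total, l) - dd)
            return np.concatenate(out)

        kd0 = np.median([f.kd for f in fits])
        x0 = np.array([np.log(kd0)] + [d[2] for d in subset])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = least_squares(resid, x0=x0, ftol=_OBJ_TOL, xtol=1e-12, gtol=_OBJ_TOL)
        return float(np.exp(sol.x[0]))

    kd_full = solve(data)
    if len(data) < 3:
        return kd_full, 0.0
    jack = np.array([solve(data[:i] + data[i + 1 :]) for i in range(len(data))])
    n = len(jack)
    kd_sd = float(np.sqrt((n - 1) / n * np.sum((jack - jack.mean()) ** 2)))
    return kd_full, kd_sd
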
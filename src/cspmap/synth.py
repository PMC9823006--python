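"""Synthetic HSQC titrations with full ground truth.

The generator reproduces the statistical structure the downstream analysis
assumes: two-state fast-exchange binding, so every responsive amide moves
linearly (in the scaled shift plane) from its free position toward its bound
position, with the travelled fraction set by the ligand-depletion isotherm
shared across residues.  Nuisances mirror a real data set: Gaussian
peak-position noise, proline/unassigned gaps in the residue coverage, and a
crowd of non-titrating decoy peaks in the congested 8.0-8.5 ppm proton
region.

Concentrations are mM; dissociation constants are mM here and converted to
uM only at reporting interfaces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from cspmap.defaults import ALPHA_N, NOISE_SIGMA_PPM, PROTEIN_TOTAL_MM
from cspmap.peaklists import Assignment, AssignmentTable, Peak, PeakList, ShiftRow, TitrationSeries

__all__ = [
    "BindingModel",
    "GroundTruth",
    "ResidueResponse",
    "SCENARIOS",
    "default_scenario",
    "fraction_bound",
    "simulate_titration",
]


def fraction_bound(kd, protein_total, ligand_total):
    """Fraction of protein bound under the two-state depletion isotherm.

    Solves the mass balance P + L <-> PL with totals fixed, i.e. the
    physically meaningful root of the quadratic

        f = [(K_D + L_t + P_t) - sqrt((K_D + L_t + P_t)^2 - 4 L_t P_t)] / (2 P_t)

    where f = [PL]/P_t.  Accepts scalars or arrays; K_D may approach zero
    (stoichiometric limit).  Negative concentrations raise ``ValueError``.
    """
    kd = np.asarray(kd, dtype=float)
    pt = np.asarray(protein_total, dtype=float)
    lt = np.asarray(ligand_total, dtype=float)
    if np.any(kd < 0) or np.any(pt <= 0) or np.any(lt < 0):
        raise ValueError("require kd >= 0, protein_total > 0, ligand_total >= 0")
    b = kd + lt + pt
    disc = b * b - 4.0 * lt * pt
    f = (b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * pt)
    f = np.clip(f, 0.0, 1.0)
    return float(f) if f.ndim == 0 else f


# --------------------------------------------------------------------------
# ground-truth containers


@dataclass(frozen=True)
class BindingModel:
    """Shared binding parameters of a titration: K_D and the design."""

    kd: float  # mM
    protein_total: float  # mM
    ligand_schedule: tuple[float, ...]  # mM, starts at 0, strictly increasing

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be > 0")
        if self.protein_total <= 0:
            raise ValueError("protein_total must be > 0")
        sched = self.ligand_schedule
        if len(sched) < 2 or sched[0] != 0:
            raise ValueError("ligand_schedule must start at 0 and have >= 2 points")
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("ligand_schedule must be strictly increasing")

    def fractions(self) -> np.ndarray:
        return fraction_bound(self.kd, self.protein_total, np.array(self.ligand_schedule))


@dataclass(frozen=True)
class ResidueResponse:
    """One residue's response: saturation amplitude and direction.

    ``direction`` is a unit vector in the scaled shift plane (h, alpha*n);
    the peak at bound fraction f sits at
    ``free_position + f * ddmax * direction`` (direction's nitrogen component
    de-scaled by alpha when mapped back to ppm).
    """

    residue_number: int
    ddmax: float  # ppm, combined shift at saturation
    direction: tuple[float, float]
    free_position: tuple[float, float]  # (h_ppm, n_ppm)

    def __post_init__(self) -> None:
        if self.ddmax < 0:
            raise ValueError("ddmax must be >= 0")
        norm = float(np.hypot(*self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must have unit norm in the scaled metric")


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to simulate a titration and to grade its analysis."""

    model: BindingModel
    responses: tuple[ResidueResponse, ...]
    noise_sigma: float = NOISE_SIGMA_PPM  # scaled ppm
    missing_residues: frozenset[int] = frozenset()
    decoy_count: int = 0
    dropout_p: float = 0.0
    seed: int = 0
    binder_residues: frozenset[int] = frozenset()
    residue_types: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0 <= self.dropout_p < 1):
            raise ValueError("dropout_p must be in [0, 1)")
        nums = {r.residue_number for r in self.responses}
        if not self.missing_residues.isdisjoint(nums):
            raise ValueError("missing_residues must not overlap simulated responses")

    @property
    def residues(self) -> list[int]:
        return sorted(r.residue_number for r in self.responses)

    def response(self, residue: int) -> ResidueResponse:
        for r in self.responses:
            if r.residue_number == residue:
                return r
        raise KeyError(residue)

    def ddmax(self) -> dict[int, float]:
        return {r.residue_number: r.ddmax for r in self.responses}

    def endpoint_csp(self) -> dict[int, float]:
        """Noise-free combined CSP of each residue at the final point."""
        f_end = float(self.model.fractions()[-1])
        return {r.residue_number: f_end * r.ddmax for r in self.responses}

    def assignment_table(self) -> AssignmentTable:
        """Reference amide shifts at the free positions (no noise)."""
        rows = []
        for r in sorted(self.responses, key=lambda r: r.residue_number):
            rt = self.residue_types.get(r.residue_number, "X")
            rows.append(ShiftRow(r.residue_number, rt, "H", r.free_position[0]))
            rows.append(ShiftRow(r.residue_number, rt, "N", r.free_position[1]))
        return AssignmentTable(rows=tuple(rows))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "kd_mM": self.model.kd,
            "protein_total_mM": self.model.protein_total,
            "ligand_schedule_mM": list(self.model.ligand_schedule),
            "noise_sigma_ppm": self.noise_sigma,
            "decoy_count": self.decoy_count,
            "dropout_p": self.dropout_p,
            "seed": self.seed,
            "missing_residues": sorted(self.missing_residues),
            "binder_residues": sorted(self.binder_residues),
            "ddmax_ppm": {str(k): v for k, v in sorted(self.ddmax().items())},
        }
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
        return path


# --------------------------------------------------------------------------
# scenario construction

N_SCHEDULE_POINTS = 12


def equal_fraction_schedule(
    kd: float, protein_total: float, endpoint: float, n_points: int = N_SCHEDULE_POINTS
) -> tuple[float, ...]:
    """Ligand schedule with equal bound-fraction increments.

    Mirrors how a titration is actually run: small aliquots while the peaks
    move fast, larger ones as they saturate.  Target fractions are evenly
    spaced between 0 and the endpoint fraction; the isotherm is inverted
    analytically (L_t = f*P_t + K_D*f/(1-f)) and the last point pinned to the
    endpoint.  Equal increments also keep the per-step peak motion far below
    the tracker's default step limit.
    """
    f_end = fraction_bound(kd, protein_total, endpoint)
    f_targets = np.linspace(0.0, f_end, n_points)
    with np.errstate(divide="ignore"):
        lig = f_targets * protein_total + kd * f_targets / (1.0 - f_targets)
    lig[-1] = endpoint
    return tuple(float(x) for x in lig)


#: Residues absent from the assignable set: prolines plus two contiguous
#: unassigned stretches (weak/absent peaks), leaving 160 assignable amides
#: out of the simulated 2-192 span.
PROLINE_RESIDUES = frozenset({7, 24, 40, 77, 96, 124, 165, 183})
UNASSIGNED_CLUSTERS = frozenset(range(47, 58)) | frozenset(range(140, 152))

_RESIDUE_SPAN = range(2, 193)

#: Scenario table: generating K_D (mM) from the corresponding reported
#: titration, final ligand:protein molar ratio, and planted binder count
#: matching the reporter n of the matching figure.
SCENARIOS: dict[str, dict] = {
    "fc14-like": {"kd": 0.0171, "final_ratio": 12.0, "n_binders": 20},
    "lpc14-like": {"kd": 0.0189, "final_ratio": 7.0, "n_binders": 13},
    "mutant-like": {"kd": 0.129, "final_ratio": 24.0, "n_binders": 10},
}

_MIN_SEPARATION = 0.10  # scaled ppm, between assignable-peak trajectories
_H_RANGE = (6.8, 9.6)
_N_RANGE = (104.0, 131.0)
_DECOY_H_RANGE = (8.0, 8.5)
_DECOY_N_RANGE = (115.0, 125.0)

ONE_LETTER = "ACDEFGHIKLMNQRSTVWY"  # no proline: assignable amides only


def default_scenario(
    name: str,
    seed: int = 0,
    kd: float | None = None,
    final_ratio: float | None = None,
    n_binders: int | None = None,
    noise_sigma: float = NOISE_SIGMA_PPM,
    protein_total: float = PROTEIN_TOTAL_MM,
    decoy_count: int = 20,
    alpha: float = ALPHA_N,
) -> GroundTruth:
    """Build the ground truth for a named titration scenario.

    160 assignable residues; ``n_binders`` true binders with
    ddmax ~ Uniform(0.05, 0.30) ppm, the rest ddmax ~ |Normal(0, 0.005)| ppm;
    protein at 0.4 mM with a 12-point ligand schedule running to
    ``protein_total * final_ratio``.  The keyword overrides let the same
    machinery emulate any of the reported titrations (e.g. a weaker-binding
    construct at the same design).

    Free positions are drawn so every pair of assignable-peak trajectories
    keeps a minimum scaled separation at every titration point, which makes
    zero-noise tracking exact; the decoy crowd is exempt on purpose.
    """
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    spec = SCENARIOS[name]
    kd = spec["kd"] if kd is None else kd
    final_ratio = spec["final_ratio"] if final_ratio is None else final_ratio
    n_binders = spec["n_binders"] if n_binders is None else n_binders

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EC14]))
    endpoint = protein_total * final_ratio
    schedule = equal_fraction_schedule(kd, protein_total, endpoint)
    model = BindingModel(kd=kd, protein_total=protein_total, ligand_schedule=schedule)
    fractions = model.fractions()

    missing = PROLINE_RESIDUES | UNASSIGNED_CLUSTERS
    assignable = [r for r in _RESIDUE_SPAN if r not in missing]
    binders = set(rng.choice(assignable, size=n_binders, replace=False).tolist())

    ddmax: dict[int, float] = {}
    for r in assignable:
        if r in binders:
            ddmax[r] = float(rng.uniform(0.05, 0.30))
        else:
            ddmax[r] = float(abs(rng.normal(0.0, 0.005)))

    # rejection-sample free positions so full trajectories stay separated
    n_pts = len(fractions)
    taken = np.empty((len(assignable), n_pts, 2))  # scaled coords
    n_taken = 0
    responses: list[ResidueResponse] = []
    types: dict[int, str] = {}
    for r in assignable:
        for _ in range(10_000):
            h = float(rng.uniform(*_H_RANGE))
            n = float(rng.uniform(*_N_RANGE))
            theta = float(rng.uniform(0, 2 * np.pi))
            direction = (float(np.cos(theta)), float(np.sin(theta)))
            start = np.array([h, alpha * n])
            traj = start[None, :] + fractions[:, None] * ddmax[r] * np.array(direction)
            if n_taken == 0:
                break
            gaps = np.linalg.norm(taken[:n_taken] - traj[None, :, :], axis=2)
            if float(gaps.min()) >= _MIN_SEPARATION:
                break
        else:  # pragma: no cover - generous box, never hit in practice
            raise RuntimeError("could not place peak with required separation")
        taken[n_taken] = traj
        n_taken += 1
        types[r] = ONE_LETTER[int(rng.integers(len(ONE_LETTER)))]
        responses.append(
            ResidueResponse(
                residue_number=r, ddmax=ddmax[r], direction=direction, free_position=(h, n)
            )
        )

    return GroundTruth(
        model=model,
        responses=tuple(responses),
        noise_sigma=noise_sigma,
        missing_residues=frozenset(missing),
        decoy_count=decoy_count,
        seed=seed,
        binder_residues=frozenset(binders),
        residue_types=types,
    )


def simulate_titration(
    truth: GroundTruth, alpha: float = ALPHA_N, assign_apo: bool = False
) -> TitrationSeries:
    """Simulate peak lists for every titration point of a ground truth.

    Peak ids encode the true correspondence (``r<residue>`` / ``d<k>`` for
    decoys) so tests can grade tracking; the analysis itself never interprets
    ids.  Peak order is shuffled within each list.  With ``assign_apo`` the
    apo-point peaks carry their assignments directly (otherwise use
    :func:`cspmap.peaklists.transfer_assignments` with
    ``truth.assignment_table()``).
    """
    # separate streams: adding decoys must not perturb the residue noise
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x711A7E]))
    rng_decoy = np.random.default_rng(np.random.SeedSequence([truth.seed, 0xDEC0]))
    fractions = truth.model.fractions()
    schedule = truth.model.ligand_schedule

    decoys = [
        (float(rng_decoy.uniform(*_DECOY_H_RANGE)), float(rng_decoy.uniform(*_DECOY_N_RANGE)))
        for _ in range(truth.decoy_count)
    ]

    points: list[PeakList] = []
    for k, (f, lig) in enumerate(zip(fractions, schedule)):
        peaks: list[Peak] = []
        for r in truth.responses:
            if truth.dropout_p and k > 0 and rng.random() < truth.dropout_p:
                continue
            dx = f * r.ddmax * r.direction[0] + rng.normal(0.0, truth.noise_sigma)
            dy = f * r.ddmax * r.direction[1] + rng.normal(0.0, truth.noise_sigma)
            assignment = None
            if assign_apo and k == 0:
                rt = truth.residue_types.get(r.residue_number, "X")
                assignment = Assignment(r.residue_number, rt)
            peaks.append(
                Peak(
                    id=f"r{r.residue_number}",
                    h_ppm=r.free_position[0] + dx,
                    n_ppm=r.free_position[1] + dy / alpha,
                    height=1.0,
                    assignment=assignment,
                )
            )
        for j, (dh, dn) in enumerate(decoys):
            peaks.append(
                Peak(
                    id=f"d{j}",
                    h_ppm=dh + rng_decoy.normal(0.0, truth.noise_sigma),
                    n_ppm=dn + rng_decoy.normal(0.0, truth.noise_sigma) / alpha,
                    height=0.5,
                )
            )
        order = rng_decoy.permutation(len(peaks))
        points.append(
            PeakList(
                peaks=tuple(peaks[i] for i in order),
                point_index=k,
                ligand_total=float(lig),
                protein_total=truth.model.protein_total,
                label=f"point {k}",
            )
        )
    return TitrationSeries(points=tuple(points))
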
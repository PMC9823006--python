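import numpy as np
import pytest

import cspmap as cm
from cspmap.peaklists import TitrationSeries


@pytest.fixture(scope="session")
def fc14_truth():
    return cm.default_scenario("fc14-like", seed=7)


@pytest.fixture(scope="session")
def fc14_series(fc14_truth):
    return cm.simulate_titration(fc14_truth, assign_apo=True)


@pytest.fixture(scope="session")
def noiseless_truth():
    return cm.default_scenario("fc14-like", seed=3, noise_sigma=0.0, decoy_count=0)


@pytest.fixture(scope="session")
def noiseless_series(noiseless_truth):
    return cm.simulate_titration(noiseless_truth, assign_apo=True)


def analyze(truth, series=None, rule="ksigma", mode="per_residue_average"):
    """Full in-memory chain: transfer -> track -> csp -> fit."""
    if series is None:
        series = cm.simulate_titration(truth)
        apo = cm.transfer_assignments(
            truth.assignment_table().to_peak_list(truth.model.protein_total),
            series.points[0],
        )
        series = TitrationSeries(points=(apo,) + series.points[1:])
    tracks = cm.track_series(series)
    tracks = cm.flag_overlap(series, tracks)
    table = cm.csp_table_from_tracks(tracks, rule=rule, unassigned=truth.missing_residues)
    reporters = cm.select_reporters(table, tracks)
    by_res = {t.residue_number: t for t in tracks}
    fit = cm.fit_global(
        [by_res[r] for r in reporters],
        series.protein_total,
        series.ligand_schedule,
        mode=mode,
    )
    return series, tracks, table, reporters, fit


def bisect_fraction_bound(kd, pt, lt, tol=1e-15):
    """Independent mass-balance solver: find [PL] with KD*x = (P-x)(L-x)."""
    lo, hi = 0.0, min(pt, lt)
    if hi == 0:
        return 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if kd * mid - (pt - mid) * (lt - mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi) / pt
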
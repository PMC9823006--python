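"""Combined CSP computation and sigma-threshold significance classes.

The per-residue statistic is the combined amide shift change
``dd = sqrt(dd_H^2 + (alpha*dd_N)^2)`` between the apo and the final
titration point.  Residues are classified against the distribution of dd
over all assigned, tracked residues.  Two readings of the significance rule
are supported:

``ksigma`` (default)
    significant when dd exceeds k * sigma of the distribution
    (thresholds sigma and 2*sigma);
``mean_plus_ksigma``
    significant when dd exceeds mean + k * sigma.

Both thresholds are recorded in the table metadata so a reader can judge
either way.  No outlier trimming is applied before computing the mean and
SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from cspmap.defaults import ALPHA_N
from cspmap.tracking import ResidueShiftTrack

__all__ = ["CspTable", "classify_significance", "compute_csp", "csp_table_from_tracks"]

CLASSES = ("ns", "1sigma", "2sigma", "unassigned")
RULES = ("ksigma", "mean_plus_ksigma")


class StatisticsError(ValueError):
    """Too few residues to form a CSP distribution."""


def compute_csp(ddh, ddn, alpha: float = ALPHA_N):
    """Combined amide CSP sqrt(ddh^2 + (alpha*ddn)^2); accepts arrays."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    out = np.hypot(np.asarray(ddh, dtype=float), alpha * np.asarray(ddn, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CspTable:
    """Per-residue endpoint CSPs with distribution stats and classes.

    ``frame`` columns: residue, dd_h_ppm, dd_n_ppm, dd_ppm, cls.  ``mean``
    and ``sigma`` are computed over the assigned residues only (cls !=
    'unassigned').  ``thresholds`` maps each supported rule to its
    (1-sigma, 2-sigma) cutoffs.
    """

    frame: pd.DataFrame
    mean: float
    sigma: float
    rule: str
    alpha: float = ALPHA_N
    thresholds: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def classes(self) -> dict[int, str]:
        return dict(zip(self.frame["residue"], self.frame["cls"]))

    def significant(self, min_class: str = "1sigma") -> list[int]:
        """Residues at or above the given class."""
        want = {"1sigma": {"1sigma", "2sigma"}, "2sigma": {"2sigma"}}[min_class]
        sel = self.frame["cls"].isin(want)
        return sorted(self.frame.loc[sel, "residue"].tolist())

    def dd(self) -> dict[int, float]:
        return dict(zip(self.frame["residue"], self.frame["dd_ppm"]))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rule: str = "ksigma", alpha: float = ALPHA_N):
        """Rebuild a table (e.g. after TSV round trip); stats are recomputed."""
        vals = df.loc[df["cls"] != "unassigned", "dd_ppm"].to_numpy(dtype=float)
        if len(vals) < 3:
            raise StatisticsError("need >= 3 assigned residues")
        mean, sigma = float(vals.mean()), float(vals.std(ddof=1))
        return cls(
            frame=df.reset_index(drop=True),
            mean=mean,
            sigma=sigma,
            rule=rule,
            alpha=alpha,
            thresholds=_thresholds(mean, sigma),
        )


def _thresholds(mean: float, sigma: float) -> dict[str, tuple[float, float]]:
    return {
        "ksigma": (sigma, 2 * sigma),
        "mean_plus_ksigma": (mean + sigma, mean + 2 * sigma),
    }


def classify_significance(
    csps: Mapping[int, float] | pd.Series, rule: str = "ksigma"
) -> tuple[float, float, dict[int, str]]:
    """Classify residues by their combined CSP against the distribution.

    Returns (mean, sigma, classes) where sigma is the sample SD (ddof=1) over
    all provided residues.  A residue is ``2sigma`` when its CSP exceeds the
    rule's 2-sigma threshold, ``1sigma`` when it exceeds only the 1-sigma
    threshold, else ``ns``.  Requires at least three residues.
    """
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}")
    items = dict(csps.items()) if hasattr(csps, "items") else dict(csps)
    vals = np.array(list(items.values()), dtype=float)
    if len(vals) < 3:
        raise StatisticsError("need >= 3 residues with defined CSP")
    mean = float(vals.mean())
    sigma = float(vals.std(ddof=1))
    if sigma <= 1e-12 * max(abs(mean), np.finfo(float).tiny):
        # zero-width distribution (up to fp dust): nothing stands out,
        # whatever the rule; the relative cutoff keeps scale equivariance
        classes = {r: "ns" for r in items}
        return mean, 0.0, classes
    t1, t2 = _thresholds(mean, sigma)[rule]
    classes = {
        r: ("2sigma" if v > t2 else "1sigma" if v > t1 else "ns") for r, v in items.items()
    }
    return mean, sigma, classes


def csp_table_from_tracks(
    tracks: Sequence[ResidueShiftTrack],
    alpha: float = ALPHA_N,
    rule: str = "ksigma",
    unassigned: Iterable[int] = (),
) -> CspTable:
    """Build the endpoint CSP table from tracked residues.

    Only tracks matched through the final point enter the distribution;
    residues listed in ``unassigned`` (and tracks lost before the endpoint)
    appear with class ``unassigned`` and zero shifts so the table covers the
    full residue map.
    """
    rows = []
    csps: dict[int, float] = {}
    for tr in tracks:
        endpoint = tr.positions[-1]
        if endpoint is None:
            rows.append((tr.residue_number, 0.0, 0.0, 0.0, "unassigned"))
            continue
        ddh = float(tr.dd_h[-1])
        ddn = float(tr.dd_n[-1])
        dd = compute_csp(ddh, ddn, alpha)
        csps[tr.residue_number] = dd
        rows.append((tr.residue_number, ddh, ddn, dd, None))
    mean, sigma, classes = classify_significance(csps, rule=rule)
    final = [
        (r, ddh, ddn, dd, cls if cls is not None else classes[r])
        for (r, ddh, ddn, dd, cls) in rows
    ]
    for r in unassigned:
        if r not in {row[0] for row in final}:
            final.append((r, 0.0, 0.0, 0.0, "unassigned"))
    df = pd.DataFrame(
        sorted(final), columns=["residue", "dd_h_ppm", "dd_n_ppm", "dd_ppm", "cls"]
    )
    return CspTable(
        frame=df,
        mean=mean,
        sigma=sigma,
        rule=rule,
        alpha=alpha,
        thresholds=_thresholds(mean, sigma),
    )
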
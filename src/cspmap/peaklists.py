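"""Peak lists, assignment tables, and their text dialects.

The canonical peak-list format is the Sparky-style ``.list`` file: one peak
per line as ``assignment w1 w2 [height]``.  Exporters disagree on whether
the proton or the nitrogen axis comes first, so the axis order is a reader
flag; internally the model is always ``(h_ppm, n_ppm)``.  Assignment tables
are read either from an NMR-STAR v3 chemical-shift loop (the BMRB dialect,
backbone amide H/N rows only) or from plain TSV.

Titration metadata (point index, total ligand and protein concentrations)
travels in ``#`` header lines of the peak-list file so that a written list
round-trips losslessly.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from cspmap.defaults import ALPHA_N, TIE_TOL_PPM, TRANSFER_TOL_PPM


class PeakListError(ValueError):
    """Malformed peak-list or assignment-table input."""


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Assignment:
    """Backbone amide assignment: residue number plus one-letter type."""

    residue_number: int
    residue_type: str = "X"

    def label(self) -> str:
        return f"{self.residue_type}{self.residue_number}N-H"


@dataclass(frozen=True)
class Peak:
    """One HSQC cross peak."""

    id: str
    h_ppm: float
    n_ppm: float
    height: float | None = None
    assignment: Assignment | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.h_ppm) and math.isfinite(self.n_ppm)):
            raise PeakListError(f"peak {self.id!r}: non-finite position")


@dataclass(frozen=True)
class PeakList:
    """All cross peaks of one titration point.

    ``ligand_total`` and ``protein_total`` are total concentrations in mM;
    ``point_index`` 0 is the apo spectrum.
    """

    peaks: tuple[Peak, ...]
    point_index: int
    ligand_total: float
    protein_total: float
    label: str = ""
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.point_index < 0:
            raise PeakListError("point_index must be >= 0")
        if self.ligand_total < 0:
            raise PeakListError("ligand_total must be >= 0")
        if self.protein_total <= 0:
            raise PeakListError("protein_total must be > 0")
        ids = [p.id for p in self.peaks]
        if len(ids) != len(set(ids)):
            raise PeakListError("peak ids must be unique within a list")

    def __len__(self) -> int:
        return len(self.peaks)

    def assigned(self) -> dict[int, Peak]:
        """Map residue number -> peak for the assigned peaks."""
        out: dict[int, Peak] = {}
        for p in self.peaks:
            if p.assignment is not None:
                if p.assignment.residue_number in out:
                    raise PeakListError(
                        f"residue {p.assignment.residue_number} assigned to two peaks"
                    )
                out[p.assignment.residue_number] = p
        return out


@dataclass(frozen=True)
class TitrationSeries:
    """Ordered peak lists sharing one protein sample."""

    points: tuple[PeakList, ...]

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise PeakListError("a titration series needs at least one point")
        lig = [pl.ligand_total for pl in self.points]
        if lig[0] != 0:
            raise PeakListError("first titration point must be ligand-free (apo)")
        if any(b <= a for a, b in zip(lig, lig[1:])):
            raise PeakListError("ligand schedule must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def ligand_schedule(self) -> np.ndarray:
        return np.array([pl.ligand_total for pl in self.points], dtype=float)

    @property
    def protein_total(self) -> float:
        return self.points[0].protein_total


@dataclass(frozen=True)
class ShiftRow:
    residue_number: int
    residue_type: str
    atom_name: str  # "H" or "N"
    shift_ppm: float


@dataclass(frozen=True)
class AssignmentTable:
    """Backbone amide chemical shifts, one row per (residue, atom).

    Residues holding only one of the two amide atoms are retained and
    reported by :meth:`incomplete`.
    """

    rows: tuple[ShiftRow, ...]

    def __post_init__(self) -> None:
        seen = set()
        for r in self.rows:
            key = (r.residue_number, r.atom_name)
            if key in seen:
                raise PeakListError(f"duplicate chemical-shift row for {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rows)

    def residues(self) -> dict[int, dict[str, float]]:
        out: dict[int, dict[str, float]] = {}
        for r in self.rows:
            out.setdefault(r.residue_number, {})[r.atom_name] = r.shift_ppm
        return out

    def residue_types(self) -> dict[int, str]:
        return {r.residue_number: r.residue_type for r in self.rows}

    def incomplete(self) -> frozenset[int]:
        """Residues missing either the H or the N amide shift."""
        return frozenset(
            num for num, atoms in self.residues().items() if len(atoms) < 2
        )

    def to_peak_list(self, protein_total: float, label: str = "reference") -> PeakList:
        """Build an assigned apo peak list from the amide-complete residues."""
        types = self.residue_types()
        peaks = []
        for num, atoms in sorted(self.residues().items()):
            if "H" not in atoms or "N" not in atoms:
                continue
            peaks.append(
                Peak(
                    id=f"ref{num}",
                    h_ppm=atoms["H"],
                    n_ppm=atoms["N"],
                    assignment=Assignment(num, types.get(num, "X")),
                )
            )
        return PeakList(
            peaks=tuple(peaks),
            point_index=0,
            ligand_total=0.0,
            protein_total=protein_total,
            label=label,
        )


# --------------------------------------------------------------------------
# Sparky-style peak lists

_ASSIGN_RE = re.compile(r"^([A-Za-z])(\d+)(?:N)?(?:-H| H|HN?)?$")


def _parse_assignment(token: str) -> Assignment | None:
    """Parse labels like ``L113N-H``; anything else is a placeholder."""
    m = _ASSIGN_RE.match(token)
    if m is None:
        return None
    return Assignment(residue_number=int(m.group(2)), residue_type=m.group(1).upper())


def read_peak_list(
    path: str | Path,
    dialect: Literal["sparky-list", "tsv"] = "sparky-list",
    axis_order: Literal["hn", "nh"] = "hn",
    point_index: int = 0,
    ligand_total: float = 0.0,
    protein_total: float = 0.4,
    label: str = "",
) -> PeakList:
    """Read a peak list from a Sparky-style ``.list`` or TSV file.

    ``#``-prefixed header lines may carry ``point_index``, ``ligand_total_mM``,
    ``protein_total_mM``, ``label`` and ``axis_order`` keys, which override the
    keyword defaults.  A header line reading ``Assignment`` (Sparky's own) is
    ignored.  Unparseable assignment tokens give unassigned peaks; malformed
    numeric fields are an error naming the line.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    sep = "\t" if dialect == "tsv" else None
    meta: dict[str, str] = {}
    peaks: list[Peak] = []
    n_data = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*(\w+)\s*[=:]\s*(.*)$", line)
            if m:
                meta[m.group(1)] = m.group(2).strip()
            continue
        fields = line.split(sep)
        if fields[0].lower() == "assignment":
            continue
        if len(fields) < 3:
            raise PeakListError(f"{path}:{lineno}: expected at least 3 fields")
        try:
            w1, w2 = float(fields[1]), float(fields[2])
            height = float(fields[3]) if len(fields) > 3 and fields[3] != "" else None
        except ValueError as exc:
            raise PeakListError(f"{path}:{lineno}: malformed numeric field") from exc
        order = meta.get("axis_order", axis_order)
        h, n = (w1, w2) if order == "hn" else (w2, w1)
        n_data += 1
        peaks.append(
            Peak(
                id=f"pk{n_data}",
                h_ppm=h,
                n_ppm=n,
                height=height,
                assignment=_parse_assignment(fields[0]),
            )
        )
    if not peaks:
        raise PeakListError(f"{path}: no peaks found")
    return PeakList(
        peaks=tuple(peaks),
        point_index=int(meta.get("point_index", point_index)),
        ligand_total=float(meta.get("ligand_total_mM", ligand_total)),
        protein_total=float(meta.get("protein_total_mM", protein_total)),
        label=meta.get("label", label),
    )


def write_peak_list(
    peak_list: PeakList,
    path: str | Path,
    dialect: Literal["sparky-list", "tsv"] = "sparky-list",
) -> Path:
    """Write a peak list with its titration metadata in ``#`` header lines."""
    path = Path(path)
    sep = "\t" if dialect == "tsv" else "  "
    lines = [
        f"# point_index = {peak_list.point_index}",
        f"# ligand_total_mM = {peak_list.ligand_total!r}",
        f"# protein_total_mM = {peak_list.protein_total!r}",
        "# axis_order = hn",
    ]
    if peak_list.label:
        lines.append(f"# label = {peak_list.label}")
    lines.append(sep.join(("Assignment", "w1(1H)", "w2(15N)", "Height")))
    for p in peak_list.peaks:
        token = p.assignment.label() if p.assignment is not None else "?"
        cols = [token, f"{p.h_ppm:.6f}", f"{p.n_ppm:.6f}"]
        if p.height is not None:
            cols.append(f"{p.height:.6g}")
        lines.append(sep.join(cols))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# --------------------------------------------------------------------------
# assignment tables (NMR-STAR v3 chemical-shift loop subset, or TSV)

_STAR_TAGS = {
    "Seq_ID": "residue_number",
    "Comp_ID": "residue_type",
    "Atom_ID": "atom_name",
    "Val": "shift_ppm",
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _read_star_shift_loop(text: str) -> list[ShiftRow]:
    """Extract backbone amide H/N rows from an NMR-STAR v3 shift loop.

    Minimal reader for the ``_Atom_chem_shift`` loop as deposited at the
    BMRB: ``loop_`` / tag lines / whitespace-separated data rows / ``stop_``.
    """
    lines = text.splitlines()
    rows: list[ShiftRow] = []
    i = 0
    while i < len(lines):
        if lines[i].strip() != "loop_":
            i += 1
            continue
        i += 1
        tags: list[str] = []
        while i < len(lines) and lines[i].strip().startswith("_"):
            tags.append(lines[i].strip())
            i += 1
        if not any(t.startswith("_Atom_chem_shift.") for t in tags):
            continue
        cols: dict[str, int] = {}
        for idx, t in enumerate(tags):
            short = t.split(".", 1)[1] if "." in t else t
            if short in _STAR_TAGS:
                cols[_STAR_TAGS[short]] = idx
        missing = {"residue_number", "atom_name", "shift_ppm"} - set(cols)
        if missing:
            raise PeakListError(f"chemical-shift loop lacks columns: {sorted(missing)}")
        while i < len(lines):
            data = lines[i].strip()
            i += 1
            if data in ("stop_", ""):
                if data == "stop_":
                    break
                continue
            parts = data.split()
            if len(parts) < len(tags):
                raise PeakListError(f"short chemical-shift loop row: {data!r}")
            atom = parts[cols["atom_name"]]
            if atom not in ("H", "N"):
                continue
            rt3 = parts[cols["residue_type"]] if "residue_type" in cols else "XAA"
            rows.append(
                ShiftRow(
                    residue_number=int(parts[cols["residue_number"]]),
                    residue_type=_THREE_TO_ONE.get(rt3.upper(), "X"),
                    atom_name=atom,
                    shift_ppm=float(parts[cols["shift_ppm"]]),
                )
            )
        return rows
    raise PeakListError("no _Atom_chem_shift loop found")


def read_shift_table(
    path: str | Path, dialect: Literal["nmrstar3", "tsv"] = "nmrstar3"
) -> AssignmentTable:
    """Read backbone amide assignments (H and N rows only).

    The TSV dialect expects a header ``residue_number residue_type atom_name
    shift_ppm``.  Duplicate (residue, atom) rows raise an integrity error.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if dialect == "nmrstar3":
        rows = _read_star_shift_loop(text)
    else:
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
        header = lines[0].split("\t")
        required = ["residue_number", "residue_type", "atom_name", "shift_ppm"]
        if any(col not in header for col in required):
            raise PeakListError(f"TSV shift table must have columns {required}")
        idx = {col: header.index(col) for col in required}
        rows = []
        for ln in lines[1:]:
            parts = ln.split("\t")
            atom = parts[idx["atom_name"]]
            if atom not in ("H", "N"):
                continue
            rows.append(
                ShiftRow(
                    residue_number=int(parts[idx["residue_number"]]),
                    residue_type=parts[idx["residue_type"]],
                    atom_name=atom,
                    shift_ppm=float(parts[idx["shift_ppm"]]),
                )
            )
    return AssignmentTable(rows=tuple(rows))


def write_shift_table(table: AssignmentTable, path: str | Path) -> Path:
    """Write an assignment table in the TSV dialect."""
    path = Path(path)
    lines = ["residue_number\tresidue_type\tatom_name\tshift_ppm"]
    for r in sorted(table.rows, key=lambda r: (r.residue_number, r.atom_name)):
        lines.append(f"{r.residue_number}\t{r.residue_type}\t{r.atom_name}\t{r.shift_ppm:.6f}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# --------------------------------------------------------------------------
# assignment transfer


def transfer_assignments(
    reference: PeakList,
    target: PeakList,
    alpha: float = ALPHA_N,
    tol: float = TRANSFER_TOL_PPM,
) -> PeakList:
    """Transfer assignments from a reference spectrum to an unassigned one.

    A target peak inherits the assignment of its nearest reference peak under
    the scaled distance sqrt(dH^2 + (alpha*dN)^2) when that distance is within
    ``tol`` and the pairing is mutual-nearest; each reference assignment is
    used at most once.  Exact ties (within 1e-9 ppm) leave the peak
    unassigned and its id is recorded under ``meta['ambiguous_ids']``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    ref = [p for p in reference.peaks if p.assignment is not None]
    if not ref:
        raise PeakListError("reference peak list carries no assignments")
    tgt = list(target.peaks)

    ref_xy = np.array([(p.h_ppm, alpha * p.n_ppm) for p in ref])
    tgt_xy = np.array([(p.h_ppm, alpha * p.n_ppm) for p in tgt])
    d = np.linalg.norm(tgt_xy[:, None, :] - ref_xy[None, :, :], axis=2)

    ambiguous: set[str] = set()
    assigned: dict[int, Assignment] = {}  # target idx -> assignment
    used_ref: set[int] = set()
    # nearest reference per target, with tie detection
    order = np.argsort(d, axis=1)
    for ti in range(len(tgt)):
        j0 = order[ti, 0]
        if d[ti, j0] > tol:
            continue
        if len(ref) > 1 and d[ti, order[ti, 1]] - d[ti, j0] <= TIE_TOL_PPM:
            ambiguous.add(tgt[ti].id)
            continue
        # mutual check: is ti the nearest target of j0?
        ti_best = int(np.argmin(d[:, j0]))
        if ti_best != ti:
            continue
        col = np.sort(d[:, j0])
        if len(tgt) > 1 and col[1] - col[0] <= TIE_TOL_PPM:
            ambiguous.add(tgt[ti].id)
            continue
        if j0 in used_ref:
            continue
        used_ref.add(j0)
        assigned[ti] = ref[j0].assignment  # type: ignore[assignment]

    new_peaks = tuple(
        replace(p, assignment=assigned[i]) if i in assigned else replace(p, assignment=None)
        for i, p in enumerate(tgt)
    )
    return PeakList(
        peaks=new_peaks,
        point_index=target.point_index,
        ligand_total=target.ligand_total,
        protein_total=target.protein_total,
        label=target.label,
        meta={**target.meta, "ambiguous_ids": sorted(ambiguous)},
    )


# --------------------------------------------------------------------------
# CSP table I/O (the table type itself lives in cspmap.stats)

CSP_TABLE_HEADER = ("residue", "dd_h_ppm", "dd_n_ppm", "dd_ppm", "class")


def write_csp_table(table, path: str | Path) -> Path:
    """Write a per-residue CSP table as TSV, ordered by residue number."""
    path = Path(path)
    lines = ["\t".join(CSP_TABLE_HEADER)]
    df = table.frame.sort_values("residue")
    for row in df.itertuples(index=False):
        lines.append(
            f"{row.residue}\t{row.dd_h_ppm:.6f}\t{row.dd_n_ppm:.6f}"
            f"\t{row.dd_ppm:.6f}\t{row.cls}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_csp_table(path: str | Path):
    """Read back a TSV written by :func:`write_csp_table`."""
    import pandas as pd

    from cspmap.stats import CspTable

    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != list(CSP_TABLE_HEADER):
        raise PeakListError(f"unexpected CSP table header in {path}")
    df = df.rename(columns={"class": "cls"})
    return CspTable.from_frame(df)
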
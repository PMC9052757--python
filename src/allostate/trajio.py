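"""Structure, trajectory and metadynamics-record I/O.

Containers and readers/writers shared by every analysis stage:

* :class:`StructureModel` — a parsed PDB topology with ``(chain, residue,
  atom name)`` addressing and a chain → subunit map (e.g. ``A → HisF``,
  ``B → HisH`` for the IGPS heterodimer fixtures).
* :class:`TrajectoryEnsemble` — ordered coordinate frames (Å) with
  timestamps in ns, bound to a topology.
* :class:`HillSeries` / :class:`CollectiveVariableSeries` — plain-text
  metadynamics HILLS / COLVAR streams in a PLUMED-style dialect
  (whitespace-separated columns under a ``#! FIELDS`` header).

PDB reading is strict fixed-column parsing of ``ATOM``/``HETATM`` records so
that malformed lines can be reported by line number and altloc resolution
(highest occupancy wins) is deterministic.  Coordinate trajectories
(DCD/XTC/TRR) are read and written through MDAnalysis.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "StructureModel",
    "TrajectoryEnsemble",
    "HillSeries",
    "CollectiveVariableSeries",
    "ParseError",
    "load_structure",
    "write_structure",
    "load_trajectory",
    "write_trajectory",
    "read_hills",
    "write_hills",
    "read_colvar",
    "write_colvar",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line/row."""


# --------------------------------------------------------------------------
# structures
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    name: str
    resid: str          # residue number as string, insertion code appended
    resname: str
    chain: str
    element: str


@dataclass
class StructureModel:
    """A static structure: atoms plus Å coordinates and a subunit map."""

    atoms: list[Atom]
    coordinates: np.ndarray          # (n_atoms, 3) Å
    subunit_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array {self.coordinates.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates in structure")
        self._index: dict[tuple[str, str, str], int] = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain, a.resid, a.name)
            if key in self._index:
                raise ValueError(f"duplicate atom key {key}")
            self._index[key] = i
        for a in self.atoms:
            self.subunit_map.setdefault(a.chain, a.chain)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_index(self, chain: str, resid: str | int, name: str) -> int:
        """Index of the atom addressed by (chain, residue, atom name)."""
        key = (chain, str(resid), name)
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"no atom {name} in residue {chain}:{resid}") from None

    def has_atom(self, chain: str, resid: str | int, name: str) -> bool:
        return (chain, str(resid), name) in self._index

    def residues(self) -> list[tuple[str, str, str]]:
        """Ordered unique (chain, resid, resname) triples."""
        seen, out = set(), []
        for a in self.atoms:
            key = (a.chain, a.resid)
            if key not in seen:
                seen.add(key)
                out.append((a.chain, a.resid, a.resname))
        return out

    def subunit_of(self, chain: str) -> str:
        return self.subunit_map.get(chain, chain)


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    return stripped[:1] if stripped else ""


def load_structure(
    path,
    format: str = "PDB",
    subunit_map: dict[str, str] | None = None,
    include_hetatm: bool = False,
) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Only the first MODEL is read; HETATM records are skipped unless
    ``include_hetatm``.  Alternate locations are resolved to the highest
    occupancy (first wins on ties).  Insertion codes are appended to the
    residue-number key (residue 51A is addressed as ``"51A"``).

    Raises :class:`ParseError` naming the line number for malformed records
    and :class:`FileNotFoundError` for missing files.
    """
    if format.upper() != "PDB":
        raise ValueError(f"unsupported structure format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    records: dict[tuple[str, str, str], tuple[float, Atom, np.ndarray]] = {}
    order: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "ENDMDL":
                break  # first MODEL only
            if rec not in ("ATOM", "HETATM"):
                continue
            if rec == "HETATM" and not include_hetatm:
                continue
            try:
                name = line[12:16].strip()
                altloc = line[16].strip()
                resname = line[17:20].strip()
                chain = line[21].strip() or " "
                resnum = line[22:26].strip()
                icode = line[26].strip()
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                occ_field = line[54:60].strip()
                occupancy = float(occ_field) if occ_field else 1.0
                element = line[76:78].strip() if len(line) >= 78 else ""
                if not resnum or not name:
                    raise ValueError("blank atom name or residue number")
            except (ValueError, IndexError) as exc:
                raise ParseError(
                    f"{path.name}: malformed {rec} record at line {lineno}: {exc}"
                ) from None
            resid = resnum + icode
            atom = Atom(
                name=name,
                resid=resid,
                resname=resname,
                chain=chain,
                element=element or _guess_element(name),
            )
            key = (chain, resid, name)
            xyz = np.array([x, y, z])
            if key not in records:
                records[key] = (occupancy, atom, xyz)
                order.append(key)
            else:
                # altloc duplicate: keep highest occupancy, first on ties
                if altloc and occupancy > records[key][0]:
                    records[key] = (occupancy, atom, xyz)
                elif not altloc:
                    raise ParseError(
                        f"{path.name}: duplicate atom {key} at line {lineno}"
                    )
    atoms = [records[k][1] for k in order]
    coords = np.array([records[k][2] for k in order]).reshape(len(atoms), 3)
    return StructureModel(atoms=atoms, coordinates=coords,
                          subunit_map=dict(subunit_map or {}))


def write_structure(model: StructureModel, path) -> None:
    """Write a minimal PDB file (ATOM records, single model)."""
    with open(path, "w") as fh:
        for i, a in enumerate(model.atoms, start=1):
            x, y, z = model.coordinates[i - 1]
            # split resid back into number + insertion code
            num = a.resid
            icode = " "
            if num and num[-1].isalpha():
                num, icode = num[:-1], num[-1]
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            fh.write(
                f"ATOM  {i:5d} {name:4s} {a.resname:<3s} {a.chain:1s}"
                f"{int(num):4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
            )
        fh.write("END\n")


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

@dataclass
class TrajectoryEnsemble:
    """Ordered coordinate frames (Å) with ns timestamps and a topology."""

    frames: np.ndarray               # (n_frames, n_atoms, 3)
    times: np.ndarray                # ns, strictly increasing
    topology: StructureModel

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"trajectory has {self.frames.shape[1]} atoms but topology "
                f"has {self.topology.n_atoms}"
            )
        if len(self.times) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def span_ns(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.n_frames else 0.0

    def slice_time(self, start_ns: float, end_ns: float) -> "TrajectoryEnsemble":
        """Frames with start_ns <= t <= end_ns (boundaries included)."""
        sel = (self.times >= start_ns) & (self.times <= end_ns)
        return TrajectoryEnsemble(self.frames[sel], self.times[sel], self.topology)


def load_trajectory(
    path,
    topology: StructureModel,
    stride_ns: float = 1.0,
    times: Sequence[float] | None = None,
) -> TrajectoryEnsemble:
    """Read a DCD/XTC/TRR trajectory against a topology.

    Timestamps default to ``k * stride_ns`` (frame index times the stride)
    unless ``times`` is supplied explicitly; trajectory formats rarely carry
    trustworthy absolute times.
    """
    from MDAnalysis.coordinates.core import get_reader_for

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    reader_cls = get_reader_for(str(path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reader = reader_cls(str(path))
        n_atoms = reader.n_atoms
        if n_atoms != topology.n_atoms:
            reader.close()
            raise ValueError(
                f"trajectory has {n_atoms} atoms but topology has "
                f"{topology.n_atoms}"
            )
        frames = np.array([ts.positions.copy() for ts in reader], dtype=float)
        reader.close()
    if times is None:
        times = np.arange(len(frames)) * stride_ns
    else:
        times = np.asarray(times, dtype=float)
    return TrajectoryEnsemble(frames=frames, times=times, topology=topology)


def write_trajectory(ensemble: TrajectoryEnsemble, path) -> None:
    """Write frames to a coordinate trajectory (format from the extension)."""
    import MDAnalysis as mda

    n_atoms = ensemble.topology.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n_atoms, trajectory=True)
        with mda.Writer(str(path), n_atoms=n_atoms) as w:
            for frame in ensemble.frames:
                u.atoms.positions = frame
                w.write(u.atoms)


# --------------------------------------------------------------------------
# metadynamics records
# --------------------------------------------------------------------------

@dataclass
class HillSeries:
    """Deposited metadynamics Gaussians from one walker.

    ``times`` are ps, ``centers``/``sigmas`` are per-CV (degrees for
    dihedral CVs), ``heights`` kcal/mol, ``bias_factor`` the well-tempered
    γ > 1.  ``cv_periods`` holds the period per CV (360 for dihedrals) or
    ``None`` for aperiodic CVs.
    """

    times: np.ndarray                # (n,) ps
    centers: np.ndarray              # (n, n_cv)
    sigmas: np.ndarray               # (n, n_cv)
    heights: np.ndarray              # (n,)
    bias_factor: float
    cv_names: list[str]
    cv_periods: list[float | None]
    walker_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        n = len(self.times)
        n_cv = len(self.cv_names)
        self.centers = np.asarray(self.centers, dtype=float).reshape(n, n_cv)
        self.sigmas = np.asarray(self.sigmas, dtype=float).reshape(n, n_cv)
        self.heights = np.atleast_1d(np.asarray(self.heights, dtype=float))
        if n:
            if np.any(self.heights <= 0):
                raise ValueError("hill heights must be > 0")
            if np.any(self.sigmas <= 0):
                raise ValueError("hill widths must be > 0")
            if np.any(np.diff(self.times) < 0):
                raise ValueError("hill times must be non-decreasing")
        if self.bias_factor <= 1:
            raise ValueError("bias factor γ must be > 1")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_cv(self) -> int:
        return len(self.cv_names)


@dataclass
class CollectiveVariableSeries:
    """Named per-frame CV columns with ns timestamps."""

    times: np.ndarray                # (n,) ns
    names: list[str]
    values: np.ndarray               # (n, n_cv)

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            self.values = self.values.reshape(len(self.times), len(self.names))
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape != (len(self.times), len(self.names)):
            raise ValueError("values must have shape (n_times, n_names)")
        if len(self.times) > 1 and np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.times)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, **{n: self.values[:, i]
                                    for i, n in enumerate(self.names)}}
        )


def _read_plumed_table(path) -> tuple[list[str], dict[str, float], np.ndarray]:
    """Read a `#! FIELDS`-headed whitespace table; returns (fields, sets, data)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fields: list[str] = []
    sets: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#!"):
                tokens = stripped[2:].split()
                if tokens and tokens[0] == "FIELDS":
                    fields = tokens[1:]
                elif tokens and tokens[0] == "SET" and len(tokens) >= 3:
                    try:
                        sets[tokens[1]] = float(tokens[2])
                    except ValueError:
                        sets[tokens[1]] = np.nan
                continue
            if stripped.startswith("#"):
                continue
            parts = stripped.split()
            if fields and len(parts) != len(fields):
                raise ParseError(
                    f"{path.name}: row {len(rows)} (line {lineno}) has "
                    f"{len(parts)} columns, expected {len(fields)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}: non-numeric token in row {len(rows)} "
                    f"(line {lineno}): {exc}"
                ) from None
    data = np.array(rows, dtype=float) if rows else np.empty((0, len(fields)))
    return fields, sets, data


def read_hills(path, walker_id: int = 0) -> HillSeries:
    """Read a HILLS file.

    Expected header: ``#! FIELDS time <cv...> sigma_<cv...> height biasf``.
    CV periods default to 360° (dihedral CVs) unless a ``#! SET period_<cv>``
    header overrides them; ``period_<cv> 0`` marks an aperiodic CV.
    """
    fields, sets, data = _read_plumed_table(path)
    if not fields:
        if data.size == 0:
            log.warning("empty HILLS file %s", path)
            return HillSeries(
                times=np.empty(0), centers=np.empty((0, 1)),
                sigmas=np.empty((0, 1)), heights=np.empty(0),
                bias_factor=10.0, cv_names=["cv1"], cv_periods=[360.0],
                walker_id=walker_id,
            )
        raise ParseError(f"{path}: missing #! FIELDS header")
    if fields[0] != "time" or fields[-1] != "biasf" or fields[-2] != "height":
        raise ParseError(f"{path}: unexpected HILLS field layout {fields}")
    cv_cols = fields[1:-2]
    n_cv = len(cv_cols) // 2
    cv_names = cv_cols[:n_cv]
    sigma_names = cv_cols[n_cv:]
    if sigma_names != [f"sigma_{n}" for n in cv_names]:
        raise ParseError(f"{path}: sigma columns do not match CVs: {fields}")
    periods: list[float | None] = []
    for name in cv_names:
        p = sets.get(f"period_{name}", 360.0)
        periods.append(None if p == 0 else p)
    if data.shape[0] == 0:
        log.warning("empty HILLS file %s", path)
        return HillSeries(
            times=np.empty(0), centers=np.empty((0, n_cv)),
            sigmas=np.empty((0, n_cv)), heights=np.empty(0),
            bias_factor=sets.get("biasf", 10.0), cv_names=cv_names,
            cv_periods=periods, walker_id=walker_id,
        )
    return HillSeries(
        times=data[:, 0],
        centers=data[:, 1:1 + n_cv],
        sigmas=data[:, 1 + n_cv:1 + 2 * n_cv],
        heights=data[:, -2],
        bias_factor=float(data[0, -1]),
        cv_names=cv_names,
        cv_periods=periods,
        walker_id=walker_id,
    )


def write_hills(hills: HillSeries, path) -> None:
    names = hills.cv_names
    with open(path, "w") as fh:
        fh.write("#! FIELDS time " + " ".join(names) + " "
                 + " ".join(f"sigma_{n}" for n in names) + " height biasf\n")
        for name, period in zip(names, hills.cv_periods):
            fh.write(f"#! SET period_{name} {period if period else 0}\n")
        for i in range(len(hills)):
            row = [hills.times[i], *hills.centers[i], *hills.sigmas[i],
                   hills.heights[i], hills.bias_factor]
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_colvar(path) -> CollectiveVariableSeries:
    """Read a COLVAR file: ``#! FIELDS time <cv...>`` plus numeric rows."""
    fields, _sets, data = _read_plumed_table(path)
    if not fields:
        if data.size == 0:
            log.warning("empty COLVAR file %s", path)
            return CollectiveVariableSeries(times=np.empty(0), names=[],
                                            values=np.empty((0, 0)))
        raise ParseError(f"{path}: missing #! FIELDS header")
    if fields[0] != "time":
        raise ParseError(f"{path}: first COLVAR field must be 'time'")
    names = fields[1:]
    if data.shape[0] == 0:
        return CollectiveVariableSeries(
            times=np.empty(0), names=names, values=np.empty((0, len(names))))
    return CollectiveVariableSeries(times=data[:, 0], names=names,
                                    values=data[:, 1:])


def write_colvar(series: CollectiveVariableSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write("#! FIELDS time " + " ".join(series.names) + "\n")
        for i in range(len(series)):
            row = [series.times[i], *series.values[i]]
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
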
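"""Per-frame geometric order parameters.

The analysis tracks four kinds of scalar observables over a trajectory:

* backbone φ dihedrals (e.g. ϕ of hV51 and hG50, the two coordinates that
  span the oxyanion-strand conformational landscape),
* the three-Cα interface opening angle θ (vertex at the middle atom; for
  the HisF:HisH interface the triad is fF120 / hW123 / hG52),
* pair distances such as d_nuc, the nucleophilic-attack distance between
  the catalytic cysteine thiol and the substrate amide carbon,
* hydrogen-bond occupancies over distance + angle criteria.

Frames with degenerate geometry (collinear or coincident atoms) carry NaN
and a cleared ``defined`` flag; they are never silently imputed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import wrap_angle
from .trajio import StructureModel, TrajectoryEnsemble

__all__ = [
    "AtomSelection",
    "ObservableSeries",
    "select_atoms",
    "select_ca",
    "phi_selection",
    "dihedral_series",
    "angle_series",
    "distance_series",
    "hbond_occupancy",
]

_EPS = 1e-10


@dataclass(frozen=True)
class AtomSelection:
    """Resolved atom indices plus a human-readable provenance string."""

    indices: tuple[int, ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.indices)


def select_atoms(model: StructureModel, *addresses: tuple[str, str | int, str]) -> AtomSelection:
    """Resolve (chain, resid, atom-name) addresses into an AtomSelection."""
    idx = tuple(model.atom_index(c, r, n) for c, r, n in addresses)
    prov = ", ".join(f"{n} of {model.subunit_of(c)}:{r}" for c, r, n in addresses)
    return AtomSelection(indices=idx, provenance=prov)


def select_ca(model: StructureModel, *residues: tuple[str, str | int]) -> AtomSelection:
    """Resolve Cα atoms of the given (chain, resid) residues."""
    return select_atoms(model, *[(c, r, "CA") for c, r in residues])


def phi_selection(model: StructureModel, chain: str, resid: int) -> AtomSelection:
    """Atom quadruple C(i-1), N(i), Cα(i), C(i) defining φ of residue i."""
    prev = resid - 1
    sel = select_atoms(
        model,
        (chain, prev, "C"),
        (chain, resid, "N"),
        (chain, resid, "CA"),
        (chain, resid, "C"),
    )
    return AtomSelection(indices=sel.indices,
                         provenance=f"phi of {model.subunit_of(chain)}:{resid}")


@dataclass
class ObservableSeries:
    """A per-frame scalar time series with units and optional periodicity."""

    name: str
    unit: str                        # "degrees" or "angstrom"
    values: np.ndarray               # NaN where undefined
    times: np.ndarray                # ns
    periodic: bool = False
    period: float = 360.0
    defined: np.ndarray = field(default=None)  # bool mask, True where valid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.defined is None:
            self.defined = np.isfinite(self.values)
        self.defined = np.asarray(self.defined, dtype=bool)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.defined]


def _frame_coords(traj: TrajectoryEnsemble, sel: AtomSelection) -> np.ndarray:
    return traj.frames[:, list(sel.indices), :]


def dihedral_series(traj: TrajectoryEnsemble, sel4: AtomSelection,
                    name: str = "dihedral") -> ObservableSeries:
    """Signed torsion (IUPAC convention) of four atoms, per frame.

    Values lie in (-180°, 180°].  Frames where three consecutive atoms are
    collinear have no defined torsion and are flagged undefined (NaN).
    """
    if len(sel4) != 4:
        raise ValueError(f"dihedral needs 4 atoms, got {len(sel4)}")
    p = _frame_coords(traj, sel4)
    b0 = p[:, 1] - p[:, 0]
    b1 = p[:, 2] - p[:, 1]
    b2 = p[:, 3] - p[:, 2]
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = np.linalg.norm(b1, axis=1)
    b1u = b1 / np.where(b1n[:, None] > 0, b1n[:, None], 1.0)
    # IUPAC sign: positive for clockwise rotation viewed along b1
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(b1u, n1), n2)
    angles = np.degrees(np.arctan2(y, x))
    bad = (np.linalg.norm(n1, axis=1) < _EPS) | (np.linalg.norm(n2, axis=1) < _EPS)
    angles = wrap_angle(angles)
    angles[bad] = np.nan
    return ObservableSeries(name=name, unit="degrees", values=angles,
                            times=traj.times, periodic=True, period=360.0)


def angle_series(traj: TrajectoryEnsemble, sel3: AtomSelection,
                 name: str = "angle") -> ObservableSeries:
    """Planar angle (degrees, [0, 180]) with vertex at the second atom."""
    if len(sel3) != 3:
        raise ValueError(f"angle needs 3 atoms, got {len(sel3)}")
    p = _frame_coords(traj, sel3)
    v1 = p[:, 0] - p[:, 1]
    v2 = p[:, 2] - p[:, 1]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    bad = (n1 < _EPS) | (n2 < _EPS)
    denom = np.where(bad, 1.0, n1 * n2)
    cosang = np.clip(np.einsum("ij,ij->i", v1, v2) / denom, -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    angles[bad] = np.nan
    return ObservableSeries(name=name, unit="degrees", values=angles,
                            times=traj.times)


def distance_series(traj: TrajectoryEnsemble, sel2: AtomSelection,
                    name: str = "distance") -> ObservableSeries:
    """Euclidean distance (Å) between two atoms, per frame."""
    if len(sel2) != 2:
        raise ValueError(f"distance needs 2 atoms, got {len(sel2)}")
    p = _frame_coords(traj, sel2)
    d = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    return ObservableSeries(name=name, unit="angstrom", values=d,
                            times=traj.times)


def hbond_occupancy(
    traj: TrajectoryEnsemble,
    donor: AtomSelection,
    hydrogen: AtomSelection | None,
    acceptor: AtomSelection,
    d_cut: float = 3.5,
    angle_cut: float = 120.0,
    heavy_only: bool = False,
) -> float:
    """Fraction of frames satisfying a hydrogen-bond criterion.

    The geometric criterion is donor–acceptor distance <= ``d_cut`` (Å) AND
    donor–H···acceptor angle >= ``angle_cut`` (degrees).  With
    ``heavy_only=True`` only the distance criterion is applied, which is
    how backbone H-bonds are typically reported when the hydrogen positions
    are not trusted (or, as for the hH53–fT119 closure marker, when only a
    distance criterion is stated).
    """
    for sel, n in ((donor, "donor"), (acceptor, "acceptor")):
        if len(sel) != 1:
            raise ValueError(f"{n} selection must resolve exactly 1 atom")
    d_series = distance_series(
        traj, AtomSelection(indices=(donor.indices[0], acceptor.indices[0])))
    dist_ok = d_series.values <= d_cut
    if heavy_only:
        return float(np.mean(dist_ok)) if len(dist_ok) else 0.0
    if hydrogen is None or len(hydrogen) != 1:
        raise ValueError(
            "hydrogen selection required unless heavy_only=True")
    # angle at the hydrogen: donor–H···acceptor
    ang = angle_series(
        traj,
        AtomSelection(indices=(donor.indices[0], hydrogen.indices[0],
                               acceptor.indices[0])),
    )
    ang_ok = ang.values >= angle_cut
    ok = dist_ok & ang_ok & np.isfinite(ang.values)
    return float(np.mean(ok)) if len(ok) else 0.0
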
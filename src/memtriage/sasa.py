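"""Solvent-accessible surface area with a membrane slab.

SASA is computed with Shrake-Rupley sphere sampling on a deterministic
golden-spiral point set.  A geometric membrane slab (z-interval) marks
transmembrane residues as buried: their SASA is zeroed before
normalization.  Relative SASA divides each residue's SASA by the SASA of
the free residue (the residue's own atoms taken off the protein and
evaluated in isolation with the same engine), so the normalization is
self-consistent; a published per-type maximum table can be supplied
instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from Bio.PDB import PDBParser

from .profiles import ResidueProfile

#: van der Waals radii by element, Angstrom.
ELEMENT_RADII: Dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90,
}
DEFAULT_RADIUS = 1.70

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA"})

#: Theoretical maximum SASA per residue type (Tien et al. 2013), Angstrom^2.
MAX_SASA_THEORETICAL: Dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass
class StructureModel:
    """Flat atom table plus an optional membrane slab.

    Attributes
    ----------
    resnums, resnames, atomnames : per-atom annotation arrays
    coords : (n_atoms, 3) float array, Angstrom
    radii : (n_atoms,) float array, Angstrom
    membrane_slab : (z_lo, z_hi) interval or None
    """

    resnums: np.ndarray
    resnames: np.ndarray
    atomnames: np.ndarray
    coords: np.ndarray
    radii: np.ndarray
    membrane_slab: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        n = len(self.resnums)
        if not (len(self.resnames) == len(self.atomnames) == len(self.coords) == len(self.radii) == n):
            raise ValueError("atom annotation arrays have inconsistent lengths")
        if np.any(self.radii <= 0):
            raise ValueError("atomic radii must be positive")
        if self.membrane_slab is not None and self.membrane_slab[0] > self.membrane_slab[1]:
            raise ValueError("membrane slab interval must satisfy lo <= hi")

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.unique(self.resnums)

    def residue_types(self) -> Dict[int, str]:
        out = {}
        for num, name in zip(self.resnums, self.resnames):
            out[int(num)] = str(name)
        return out

    def residue_atoms(self, resnum: int) -> np.ndarray:
        return np.nonzero(self.resnums == resnum)[0]


def radius_for(element: str) -> float:
    return ELEMENT_RADII.get(element.upper().strip(), DEFAULT_RADIUS)


def load_pdb(path, membrane_slab: Optional[Tuple[float, float]] = None,
             radii: Optional[Mapping[str, float]] = None) -> StructureModel:
    """Read the first model/chain set of a PDB file into a StructureModel."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", path)
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"no protein atoms found in {path}") from None
    resnums, resnames, atomnames, coords, rads = [], [], [], [], []
    table = dict(ELEMENT_RADII)
    if radii:
        table.update({k.upper(): float(v) for k, v in radii.items()})
    for chain in model:
        for residue in chain:
            hetflag, seqid, _ = residue.id
            if hetflag.strip():
                continue  # skip waters/hetero groups
            for atom in residue:
                resnums.append(seqid)
                resnames.append(residue.get_resname().strip())
                atomnames.append(atom.get_name().strip())
                coords.append(atom.get_coord())
                element = (atom.element or atom.get_name()[:1]).upper().strip()
                rads.append(table.get(element, DEFAULT_RADIUS))
    if not resnums:
        raise ValueError(f"no protein atoms found in {path}")
    return StructureModel(
        resnums=np.asarray(resnums, dtype=int),
        resnames=np.asarray(resnames, dtype=object),
        atomnames=np.asarray(atomnames, dtype=object),
        coords=np.asarray(coords, dtype=float),
        radii=np.asarray(rads, dtype=float),
        membrane_slab=membrane_slab,
    )


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa_atoms(coords: np.ndarray, radii: np.ndarray,
               probe_radius: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Shrake-Rupley SASA per atom, Angstrom^2."""
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a usable estimate")
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n_atoms = len(coords)
    sphere = _sphere_points(n_points)
    extended = radii + probe_radius

    # pairwise neighbor lists; duplicate-position atoms only warrant a warning
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    if n_atoms > 1:
        off_diag = dist + np.eye(n_atoms) * 1e9
        if np.any(off_diag < 1e-6):
            warnings.warn("overlapping identical atom positions detected", stacklevel=2)

    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        cutoff = extended[i] + extended
        neighbors = np.nonzero((dist[i] < cutoff) & (np.arange(n_atoms) != i))[0]
        pts = coords[i] + extended[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > extended[j] ** 2
        areas[i] = 4.0 * np.pi * extended[i] ** 2 * accessible.mean()
    return areas


def sasa_per_residue(model: StructureModel, probe_radius: float = 1.4,
                     n_points: int = 960) -> ResidueProfile:
    """Per-residue SASA: the sum of its atoms' accessible areas."""
    atom_areas = sasa_atoms(model.coords, model.radii, probe_radius, n_points)
    values: Dict[int, float] = {}
    for num, area in zip(model.resnums, atom_areas):
        values[int(num)] = values.get(int(num), 0.0) + float(area)
    return ResidueProfile(values=values, units="A^2")


def sidechain_centroid_z(model: StructureModel, resnum: int) -> float:
    """z of the side-chain centroid; falls back to CA for glycine/backbone-only."""
    idx = model.residue_atoms(resnum)
    if len(idx) == 0:
        raise KeyError(f"residue {resnum} not in model")
    side = [i for i in idx if str(model.atomnames[i]) not in BACKBONE_ATOMS]
    if side:
        return float(np.mean(model.coords[side, 2]))
    ca = [i for i in idx if str(model.atomnames[i]) == "CA"]
    chosen = ca if ca else list(idx)
    return float(np.mean(model.coords[chosen, 2]))


def membrane_buried_residues(model: StructureModel) -> set[int]:
    """Residues whose side-chain centroid z lies inside the membrane slab."""
    if model.membrane_slab is None:
        return set()
    lo, hi = model.membrane_slab
    buried = set()
    for resnum in model.residue_numbers:
        z = sidechain_centroid_z(model, int(resnum))
        if lo <= z <= hi:
            buried.add(int(resnum))
    return buried


def apply_membrane_burial(profile: ResidueProfile, model: StructureModel) -> ResidueProfile:
    """Zero the SASA of residues buried in the membrane slab."""
    buried = membrane_buried_residues(model)
    values = {r: (0.0 if r in buried else v) for r, v in profile.values.items()}
    return ResidueProfile(values=values, units=profile.units)


def free_residue_max_sasa(model: StructureModel, probe_radius: float = 1.4,
                          n_points: int = 960) -> Dict[int, float]:
    """Max SASA per residue: each residue's atoms evaluated in isolation."""
    out = {}
    for resnum in model.residue_numbers:
        idx = model.residue_atoms(int(resnum))
        areas = sasa_atoms(model.coords[idx], model.radii[idx], probe_radius, n_points)
        out[int(resnum)] = float(areas.sum())
    return out


def rsasa(profile: ResidueProfile,
          max_sasa: Mapping[int, float] | Mapping[str, float],
          residue_types: Optional[Mapping[int, str]] = None) -> ResidueProfile:
    """Relative SASA: residue SASA / free-residue maximum, clipped to [0, 1].

    ``max_sasa`` is keyed either by residue number (per-instance maxima, e.g.
    from :func:`free_residue_max_sasa`) or by residue type name, in which
    case ``residue_types`` must map residue number -> type.
    """
    by_type = any(isinstance(k, str) for k in max_sasa)
    values = {}
    for resnum, area in profile.values.items():
        if by_type:
            if residue_types is None:
                raise ValueError("residue_types required with a per-type max table")
            rtype = residue_types[resnum]
            if rtype not in max_sasa:
                raise KeyError(f"residue type {rtype!r} missing from max-SASA table")
            ref = float(max_sasa[rtype])  # type: ignore[index]
        else:
            if resnum not in max_sasa:
                raise KeyError(f"residue {resnum} missing from max-SASA table")
            ref = float(max_sasa[resnum])  # type: ignore[index]
        if ref <= 0:
            raise ValueError(f"non-positive max SASA for residue {resnum}")
        values[resnum] = min(area / ref, 1.0)
    return ResidueProfile(values=values, units="fraction")
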
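"""Synthetic inputs with known ground truth for every pipeline stage.

One :class:`SyntheticSpec` drives all generators; a fixed seed makes every
output byte-identical.  The generators emulate the statistical structure
the analysis assumes rather than physical realism:

* toy helical-bundle structures whose membrane burial is known by
  construction (ideal-helix C-alphas, burial decided purely by the z-slab);
* alignments whose per-column identity fraction is hit exactly by count
  construction, so conservation ground truth is exact;
* feature tables drawn from two truncated Gaussians (pathogenic: low
  rSASA, high EC, high PD; non-pathogenic the reverse), with hidden true
  labels for the "unknown" rows;
* per-residue RMSF profiles equal to a wild-type baseline plus
  region-targeted shifts;
* per-frame energy-component tables with stated means/SDs and a
  closed-form expected binding energy.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import mmpbsa as _mmpbsa
from .classify import FeatureVector
from .conservation import Alignment
from .dynamics import RegionMap
from .profiles import ResidueProfile
from .sasa import ELEMENT_RADII, StructureModel

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

EnergySpec = Mapping[str, Tuple[float, float]]


@dataclass
class SyntheticSpec:
    """Parameters for all synthetic generators. Seed-deterministic."""

    seed: int = 0
    n_residues: int = 60
    membrane_z_range: Tuple[float, float] = (-8.0, 8.0)
    n_species: int = 35
    per_column_identity: Union[float, Sequence[float]] = 0.8
    n_pathogenic: int = 16
    n_nonpathogenic: int = 23
    n_unknown: int = 18
    class_separation: float = 3.0
    rmsf_region_effects: Dict[str, Dict[str, float]] = field(default_factory=dict)
    energy_means_sds: Dict[str, EnergySpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_residues < 1 or self.n_species < 1:
            raise ValueError("counts must be positive")
        if min(self.n_pathogenic, self.n_nonpathogenic, self.n_unknown) < 0:
            raise ValueError("class counts must be non-negative")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        idents = np.atleast_1d(np.asarray(self.per_column_identity, dtype=float))
        if np.any((idents < 0) | (idents > 1)):
            raise ValueError("per_column_identity must lie in [0, 1]")
        if self.membrane_z_range[0] > self.membrane_z_range[1]:
            raise ValueError("membrane_z_range must satisfy lo <= hi")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticSpec":
        kwargs = dict(data)
        if "membrane_z_range" in kwargs:
            kwargs["membrane_z_range"] = tuple(kwargs["membrane_z_range"])
        if "energy_means_sds" in kwargs:
            kwargs["energy_means_sds"] = {
                ent: {c: tuple(ms) for c, ms in comps.items()}
                for ent, comps in kwargs["energy_means_sds"].items()}
        return cls(**kwargs)


def _rng(spec: SyntheticSpec, stream: str) -> np.random.Generator:
    # independent, reproducible stream per generator (crc32: stable across runs)
    return np.random.default_rng([spec.seed, zlib.crc32(stream.encode())])


def random_sequence(spec: SyntheticSpec) -> str:
    rng = _rng(spec, "sequence")
    return "".join(rng.choice(list(AA20), size=spec.n_residues))


# ---------------------------------------------------------------------------
# Toy structure


@dataclass
class ToyStructure:
    model: StructureModel
    sequence: str
    buried: set  # ground-truth residue numbers inside the slab

    def to_pdb(self) -> str:
        lines = []
        m = self.model
        for serial, i in enumerate(range(len(m.resnums)), start=1):
            name = str(m.atomnames[i])
            x, y, z = m.coords[i]
            element = name[0]
            lines.append(
                f"ATOM  {serial:5d} {name:^4s} {str(m.resnames[i]):<3s} A"
                f"{int(m.resnums[i]):4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")
        lines.append("END")
        return "\n".join(lines) + "\n"

    def write_pdb(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_pdb())


def make_toy_structure(spec: SyntheticSpec) -> ToyStructure:
    """Four-helix-bundle-like backbone + CB trace with known slab burial.

    Each helix is centered on z = 0, so with a symmetric slab the helix
    cores are buried and the helix ends (and any slab-exterior residues)
    are solvent exposed.  Ground-truth burial is decided by CB z (CA for
    glycine) against the slab — the same rule the SASA stage applies.
    """
    if spec.n_residues < 20:
        raise ValueError("toy structures need n_residues >= 20")
    sequence = random_sequence(spec)
    n_helices = 4
    per_helix = int(np.ceil(spec.n_residues / n_helices))
    axis_xy = [(0.0, 0.0), (11.0, 0.0), (11.0, 11.0), (0.0, 11.0)]
    rise, twist = 1.5, np.deg2rad(100.0)

    resnums, resnames, atomnames, coords, radii = [], [], [], [], []
    for i in range(spec.n_residues):
        h, j = divmod(i, per_helix)
        cx, cy = axis_xy[h % n_helices]
        theta = j * twist
        z = (j - (per_helix - 1) / 2.0) * rise
        ca = np.array([cx + 2.3 * np.cos(theta), cy + 2.3 * np.sin(theta), z])
        cb = np.array([cx + 3.9 * np.cos(theta), cy + 3.9 * np.sin(theta), z])
        aa = sequence[i]
        atoms = [("N", ca + (-0.9, -0.8, -0.6), "N"),
                 ("CA", ca, "C"),
                 ("C", ca + (0.9, 0.8, 0.6), "C"),
                 ("O", ca + (1.2, 1.6, 0.4), "O")]
        if aa != "G":
            atoms.append(("CB", cb, "C"))
        for name, xyz, element in atoms:
            resnums.append(i + 1)
            resnames.append(AA3[aa])
            atomnames.append(name)
            coords.append(np.asarray(xyz, dtype=float))
            radii.append(ELEMENT_RADII[element])

    model = StructureModel(
        resnums=np.asarray(resnums, dtype=int),
        resnames=np.asarray(resnames, dtype=object),
        atomnames=np.asarray(atomnames, dtype=object),
        coords=np.asarray(coords, dtype=float),
        radii=np.asarray(radii, dtype=float),
        membrane_slab=spec.membrane_z_range,
    )
    lo, hi = spec.membrane_z_range
    buried = set()
    for i in range(spec.n_residues):
        h, j = divmod(i, per_helix)
        z = (j - (per_helix - 1) / 2.0) * rise
        if lo <= z <= hi:
            buried.add(i + 1)
    return ToyStructure(model=model, sequence=sequence, buried=buried)


# ---------------------------------------------------------------------------
# Toy alignment


@dataclass
class ToyMsa:
    alignment: Alignment
    ec_truth: ResidueProfile  # exact identity fraction per reference position

    def to_fasta(self) -> str:
        return "".join(f">{sid}\n{seq}\n" for sid, seq in self.alignment.sequences)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_fasta())


def make_toy_msa(spec: SyntheticSpec, reference_seq: Optional[str] = None) -> ToyMsa:
    """Alignment hitting each column's identity fraction exactly by count.

    The number of matching rows in column i is round(p_i * n_species),
    floored at 1 (the reference always matches itself); mismatching rows
    get a different residue, occasionally a gap.
    """
    if spec.n_species < 2:
        raise ValueError("need at least two species")
    rng = _rng(spec, "msa")
    ref = reference_seq if reference_seq is not None else random_sequence(spec)
    n = len(ref)
    idents = np.broadcast_to(
        np.atleast_1d(np.asarray(spec.per_column_identity, dtype=float)), (n,))

    columns = []
    truth = {}
    for i, p in enumerate(idents):
        n_match = int(np.clip(round(p * spec.n_species), 1, spec.n_species))
        truth[i + 1] = n_match / spec.n_species
        matching = {0}
        if n_match > 1:
            matching.update(rng.choice(
                np.arange(1, spec.n_species), size=n_match - 1, replace=False))
        col = []
        others = [aa for aa in AA20 if aa != ref[i]]
        for row in range(spec.n_species):
            if row in matching:
                col.append(ref[i])
            elif rng.random() < 0.1:
                col.append("-")
            else:
                col.append(others[rng.integers(len(others))])
        columns.append(col)

    names = ["reference"] + [f"species_{j:02d}" for j in range(1, spec.n_species)]
    rows = ["".join(columns[i][r] for i in range(n)) for r in range(spec.n_species)]
    alignment = Alignment(sequences=list(zip(names, rows)), reference_id="reference")
    return ToyMsa(alignment=alignment,
                  ec_truth=ResidueProfile(values=truth, units="fraction"))


# ---------------------------------------------------------------------------
# Feature table

_FEATURE_CENTER = np.array([0.45, 0.60, 2.0])     # rsasa, ec, pd
_FEATURE_SD = np.array([0.08, 0.08, 0.5])
_PATHOGENIC_SIGN = np.array([-1.0, 1.0, 1.0])     # low rsasa, high ec, high pd


def class_means(spec: SyntheticSpec) -> Tuple[np.ndarray, np.ndarray]:
    """(pathogenic mean, non-pathogenic mean) in (rsasa, ec, pd) space."""
    shift = 0.5 * spec.class_separation * _FEATURE_SD * _PATHOGENIC_SIGN
    return _FEATURE_CENTER + shift, _FEATURE_CENTER - shift


@dataclass
class ToyFeatures:
    vectors: List[FeatureVector]         # labelled + unknown rows
    hidden_labels: Dict[str, str]        # true class of each "unknown" row


def _draw_class(rng, mean: np.ndarray, n: int) -> np.ndarray:
    pts = rng.normal(mean, _FEATURE_SD, size=(n, 3))
    pts[:, 0] = np.clip(pts[:, 0], 0.0, 1.0)      # rsasa
    pts[:, 1] = np.clip(pts[:, 1], 1e-6, 1.0)     # ec
    pts[:, 2] = np.maximum(pts[:, 2], 0.0)        # pd
    return pts


def make_feature_table(spec: SyntheticSpec) -> ToyFeatures:
    """Two separable feature classes plus unknowns with hidden true labels."""
    rng = _rng(spec, "features")
    mean_p, mean_n = class_means(spec)
    vectors: List[FeatureVector] = []
    for i, row in enumerate(_draw_class(rng, mean_p, spec.n_pathogenic)):
        vectors.append(FeatureVector(f"path{i:03d}", *row, label="pathogenic"))
    for i, row in enumerate(_draw_class(rng, mean_n, spec.n_nonpathogenic)):
        vectors.append(FeatureVector(f"nonp{i:03d}", *row, label="non_pathogenic"))

    hidden: Dict[str, str] = {}
    for i in range(spec.n_unknown):
        true = "pathogenic" if rng.random() < 0.5 else "non_pathogenic"
        mean = mean_p if true == "pathogenic" else mean_n
        row = _draw_class(rng, mean, 1)[0]
        mid = f"unkn{i:03d}"
        vectors.append(FeatureVector(mid, *row, label="unknown"))
        hidden[mid] = true
    return ToyFeatures(vectors=vectors, hidden_labels=hidden)


# ---------------------------------------------------------------------------
# RMSF profiles


@dataclass
class ToyRmsf:
    profiles: Dict[str, ResidueProfile]          # "WT" plus one per mutant
    region_sums: Dict[str, Dict[str, float]]     # ground-truth sums per variant


def make_rmsf_profiles(spec: SyntheticSpec, regions: RegionMap) -> ToyRmsf:
    """WT baseline profile plus mutants shifted inside chosen regions.

    ``spec.rmsf_region_effects`` maps mutant name -> {region -> additive
    per-residue shift in A}.  Mutant profiles equal WT everywhere else.
    """
    rng = _rng(spec, "rmsf")
    residues = range(1, spec.n_residues + 1)
    wt = {r: float(v) for r, v in zip(residues,
                                      rng.uniform(0.4, 1.2, spec.n_residues))}
    profiles = {"WT": ResidueProfile(values=dict(wt), units="A")}
    for mutant, effects in spec.rmsf_region_effects.items():
        vals = dict(wt)
        for region, shift in effects.items():
            if region not in regions.intervals:
                raise KeyError(f"unknown region {region!r} for mutant {mutant}")
            for r in regions.residues(region):
                if r in vals:
                    vals[r] = vals[r] + shift
        profiles[mutant] = ResidueProfile(values=vals, units="A")

    region_sums = {}
    for name, profile in profiles.items():
        sums = {}
        for reg in regions:
            members = [r for r in regions.residues(reg) if r in profile]
            if members:
                sums[reg] = float(sum(profile[r] for r in members))
        region_sums[name] = sums
    return ToyRmsf(profiles=profiles, region_sums=region_sums)


# ---------------------------------------------------------------------------
# Energy frames

_DEFAULT_ENERGY: Dict[str, Dict[str, Tuple[float, float]]] = {
    "complex": {"internal": (-1200.0, 5.0), "vdw": (-150.0, 4.0),
                "coulombic": (-300.0, 6.0), "pb_solv": (250.0, 5.0),
                "sasa": (21000.0, 150.0)},
    "receptor": {"internal": (-1100.0, 5.0), "vdw": (-120.0, 4.0),
                 "coulombic": (-280.0, 6.0), "pb_solv": (240.0, 5.0),
                 "sasa": (20500.0, 150.0)},
    "ligand": {"internal": (-60.0, 2.0), "vdw": (-5.0, 1.0),
               "coulombic": (-15.0, 2.0), "pb_solv": (25.0, 2.0),
               "sasa": (900.0, 30.0)},
}


@dataclass
class ToyEnergies:
    frames: pd.DataFrame          # schema: time_ps, entity, components, sasa
    expected_dg: float            # closed-form mean binding energy, kcal/mol


def energy_spec(spec: SyntheticSpec) -> Dict[str, Dict[str, Tuple[float, float]]]:
    out = {e: dict(c) for e, c in _DEFAULT_ENERGY.items()}
    for entity, comps in spec.energy_means_sds.items():
        if entity not in out:
            raise KeyError(f"unknown entity {entity!r}")
        for comp, ms in comps.items():
            if comp not in out[entity]:
                raise KeyError(f"unknown component {comp!r}")
            out[entity][comp] = (float(ms[0]), float(ms[1]))
    return out


def expected_binding_energy(spec: SyntheticSpec,
                            alpha: float = _mmpbsa.ALPHA_DEFAULT,
                            beta: float = _mmpbsa.BETA_DEFAULT) -> float:
    """Closed-form mean binding energy implied by the generator means."""
    means = energy_spec(spec)

    def g(entity: str) -> float:
        comps = means[entity]
        energy = sum(comps[c][0] for c in _mmpbsa.COMPONENTS)
        return energy + alpha * comps["sasa"][0] + beta

    return g("complex") - g("receptor") - g("ligand")


def make_energy_frames(spec: SyntheticSpec, n_frames: int,
                       interval_ps: float = 20.0,
                       t_start_ps: float = 0.0) -> ToyEnergies:
    """Per-frame energy components for complex/receptor/ligand.

    Components are independent normals with the stated (mean, SD);
    timestamps are uniform at ``interval_ps`` spacing.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be positive")
    rng = _rng(spec, "energy")
    means = energy_spec(spec)
    times = t_start_ps + interval_ps * np.arange(1, n_frames + 1)
    rows = []
    for entity in _mmpbsa.ENTITIES:
        comps = means[entity]
        draws = {c: rng.normal(comps[c][0], comps[c][1], size=n_frames)
                 for c in (*_mmpbsa.COMPONENTS, "sasa")}
        for f in range(n_frames):
            rows.append({"time_ps": float(times[f]), "entity": entity,
                         **{c: float(draws[c][f]) for c in draws}})
    frames = pd.DataFrame(rows, columns=list(_mmpbsa.SCHEMA))
    return ToyEnergies(frames=frames, expected_dg=expected_binding_energy(spec))
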
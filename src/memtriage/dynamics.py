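"""Trajectory-derived descriptors: RMSF, region sums, and cross-correlation.

Per-residue RMSF is aggregated into named-region sums (transmembrane
helices, cytosolic loops, C-terminal domain).  The combination
TM1 + TM2 + CL2 - TM7 - TM9_10 of region sums ("cumulative RMSF") acts as
an empirical pathogenicity discriminant: values at or below 46 A look like
pathogenic variants, values above 50 A like non-pathogenic ones, and the
interval in between is reported as ambiguous.

Cross-correlation maps (DCCM) are computed from C-alpha displacement
vectors about the mean structure; difference maps between averaged mutant
and wild-type maps localize dynamics changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .profiles import ResidueProfile

#: Default region boundaries (inclusive, 1-based) for the DHCR7 topology.
DHCR7_REGIONS: Dict[str, Tuple[int, int]] = {
    "TM1": (40, 60), "TM2": (94, 115), "TM3": (145, 164), "TM4": (176, 191),
    "TM5": (235, 256), "TM6": (268, 288), "TM7": (302, 326), "TM8": (332, 352),
    "TM9_10": (408, 442), "CL1": (116, 144), "CL2": (198, 234),
    "CL3": (289, 301), "CL4": (354, 407), "CTD": (443, 475),
}

CUMULATIVE_PLUS: Tuple[str, ...] = ("TM1", "TM2", "CL2")
CUMULATIVE_MINUS: Tuple[str, ...] = ("TM7", "TM9_10")

PATHOGENIC_UPPER = 46.0   # cumulative RMSF <= this -> pathogenic_like
NONPATHOGENIC_LOWER = 50.0  # cumulative RMSF > this -> nonpathogenic_like


@dataclass
class RegionMap:
    """Named inclusive residue intervals over the reference numbering."""

    intervals: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(DHCR7_REGIONS))

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.intervals.items():
            if lo > hi:
                raise ValueError(f"region {name}: invalid interval ({lo}, {hi})")

    def __iter__(self):
        return iter(self.intervals)

    def residues(self, name: str) -> range:
        lo, hi = self.intervals[name]
        return range(lo, hi + 1)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[int]]) -> "RegionMap":
        return cls({str(k): (int(v[0]), int(v[1])) for k, v in mapping.items()})


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body fit of ``mobile`` onto ``target`` (both (n,3))."""
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    h = mc.T @ tc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return mc @ rot + target.mean(axis=0)


def rmsf(coords: np.ndarray, residue_numbers: Iterable[int] | None = None,
         superpose: bool = True) -> ResidueProfile:
    """Per-residue RMSF (A) of an ensemble, about the mean position.

    ``coords`` has shape (n_frames, n_residues, 3).  With ``superpose``
    each frame is first rigid-body fitted to the first frame.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("coords must have shape (n_frames, n_residues, 3)")
    n_frames, n_res, _ = coords.shape
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if superpose:
        coords = np.stack([kabsch_superpose(f, coords[0]) for f in coords])
    mean = coords.mean(axis=0)
    disp = coords - mean
    values = np.sqrt((disp ** 2).sum(axis=2).mean(axis=0))
    if residue_numbers is None:
        residue_numbers = range(1, n_res + 1)
    return ResidueProfile(
        values={int(r): float(v) for r, v in zip(residue_numbers, values)},
        units="A")


def region_rmsf(profile: ResidueProfile, regions: RegionMap) -> Dict[str, float]:
    """Sum (not mean) of per-residue RMSF over each named region."""
    sums = {}
    for name in regions:
        residues = [r for r in regions.residues(name) if r in profile]
        if not residues:
            raise ValueError(f"region {name}: no residues present in profile")
        sums[name] = float(sum(profile[r] for r in residues))
    return sums


def cumulative_rmsf(region_sums: Mapping[str, float],
                    plus: Sequence[str] = CUMULATIVE_PLUS,
                    minus: Sequence[str] = CUMULATIVE_MINUS) -> float:
    """Discriminant statistic: sum(plus regions) - sum(minus regions), A."""
    missing = [n for n in (*plus, *minus) if n not in region_sums]
    if missing:
        raise KeyError(f"region sums missing: {missing}")
    return float(sum(region_sums[n] for n in plus) - sum(region_sums[n] for n in minus))


def discriminant_call(cumulative: float,
                      pathogenic_upper: float = PATHOGENIC_UPPER,
                      nonpathogenic_lower: float = NONPATHOGENIC_LOWER) -> str:
    """Classify a cumulative-RMSF value.

    Returns ``"pathogenic_like"`` (<= pathogenic_upper),
    ``"nonpathogenic_like"`` (> nonpathogenic_lower) or ``"ambiguous"``.
    """
    if cumulative <= pathogenic_upper:
        return "pathogenic_like"
    if cumulative > nonpathogenic_lower:
        return "nonpathogenic_like"
    return "ambiguous"


def dccm(coords: np.ndarray, superpose: bool = True) -> np.ndarray:
    """Residue-residue cross-correlation of displacement vectors.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) over frames, where
    dr is the displacement from the mean position.  Symmetric with unit
    diagonal; zero-variance residues yield NaN rows (with a warning).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("coords must have shape (n_frames, n_residues, 3)")
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if superpose:
        coords = np.stack([kabsch_superpose(f, coords[0]) for f in coords])
    disp = coords - coords.mean(axis=0)
    # covariance of 3D displacement vectors: sum over frames of dot products
    cov = np.einsum("fik,fjk->ij", disp, disp) / coords.shape[0]
    var = np.diag(cov).copy()
    zero = var <= 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} residue(s) with zero displacement variance; "
                      "their correlations are undefined (NaN)", stacklevel=2)
        var[zero] = np.nan
    norm = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / norm
    np.fill_diagonal(corr, np.where(zero, np.nan, 1.0))
    return corr


def dccm_difference(mutant_runs: Sequence[np.ndarray],
                    wt_runs: Sequence[np.ndarray],
                    superpose: bool = True) -> np.ndarray:
    """mean-over-runs(mutant DCCM) - mean-over-runs(WT DCCM).

    Accepts per-run coordinate ensembles or precomputed correlation
    matrices (2-D arrays are treated as matrices).
    """
    def avg(runs: Sequence[np.ndarray]) -> np.ndarray:
        mats = [np.asarray(r) if np.asarray(r).ndim == 2 else dccm(r, superpose)
                for r in runs]
        return np.mean(mats, axis=0)

    if not mutant_runs or not wt_runs:
        raise ValueError("need at least one run per condition")
    return avg(mutant_runs) - avg(wt_runs)


def region_table(profiles: Mapping[str, ResidueProfile], regions: RegionMap) -> pd.DataFrame:
    """Region sums, cumulative RMSF, and discriminant call per variant."""
    rows = []
    for name, profile in profiles.items():
        sums = region_rmsf(profile, regions)
        cum = cumulative_rmsf(sums)
        rows.append({"variant": name, **sums,
                     "cumulative": cum, "call": discriminant_call(cum)})
    return pd.DataFrame(rows)
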
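"""MM/PBSA post-processing: frame selection and binding-energy aggregation.

Per-frame component energies (internal, van der Waals, Coulombic, PB
solvation) plus a SASA column arrive as a table with one row per
(time, entity) pair, entities being ``complex``, ``receptor`` and
``ligand``.  The nonpolar solvation term is the affine map
``alpha * SASA + beta`` with defaults alpha = 0.0054 kcal/(mol*A^2) and
beta = 0.92 kcal/mol, applied per entity per frame (so the intercept
contributes -beta to every binding energy; ``beta_per_entity=False``
adds beta once to the final difference instead).
"""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

ALPHA_DEFAULT = 0.0054   # kcal/(mol*A^2)
BETA_DEFAULT = 0.92      # kcal/mol

ENTITIES = ("complex", "receptor", "ligand")
COMPONENTS = ("internal", "vdw", "coulombic", "pb_solv")
SCHEMA = ("time_ps", "entity", "internal", "vdw", "coulombic", "pb_solv", "sasa")


def read_energy_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"energy table missing columns: {missing}")
    return df


def select_frames(times_ps: Iterable[float], tail_ns: float,
                  interval_ps: float) -> np.ndarray:
    """Timestamps at ``interval_ps`` spacing within the final ``tail_ns`` window.

    Returns the selected timestamps (count = tail/interval).  Raises if the
    input is sparser than the requested spacing — no interpolation.
    """
    times = np.unique(np.asarray(list(times_ps), dtype=float))
    if times.size == 0:
        raise ValueError("empty timestamp series")
    tail_ps = tail_ns * 1000.0
    n_expected = tail_ps / interval_ps
    if abs(n_expected - round(n_expected)) > 1e-9:
        raise ValueError("interval must divide the tail window evenly")
    n_expected = int(round(n_expected))
    t_end = times[-1]
    if times[-1] - times[0] < tail_ps - 1e-9:
        raise ValueError("run shorter than the requested tail window")
    wanted = t_end - interval_ps * np.arange(n_expected)[::-1]
    have = np.isin(np.round(wanted, 6), np.round(times, 6))
    if not have.all():
        raise ValueError(
            f"{int((~have).sum())} required timestamps absent from the run; "
            "input is sparser than the requested interval")
    return wanted


def select_frame_table(frames: pd.DataFrame, tail_ns: float,
                       interval_ps: float) -> pd.DataFrame:
    """Row-filter an energy table to the selected timestamps."""
    wanted = select_frames(frames["time_ps"].unique(), tail_ns, interval_ps)
    return frames[frames["time_ps"].round(6).isin(np.round(wanted, 6))].copy()


def nonpolar_sasa_energy(sasa, alpha: float = ALPHA_DEFAULT,
                         beta: float = BETA_DEFAULT):
    """Nonpolar solvation energy: alpha * SASA + beta (kcal/mol)."""
    return alpha * np.asarray(sasa, dtype=float) + beta


def binding_energy(frames: pd.DataFrame, alpha: float = ALPHA_DEFAULT,
                   beta: float = BETA_DEFAULT,
                   beta_per_entity: bool = True) -> Tuple[pd.Series, float]:
    """Per-frame binding energy series and its mean over frames.

    For each entity and frame,
    G = internal + vdw + coulombic + pb_solv + nonpolar_sasa_energy(sasa);
    dG = G(complex) - G(receptor) - G(ligand).
    """
    missing = [c for c in SCHEMA if c not in frames.columns]
    if missing:
        raise ValueError(f"energy table missing columns: {missing}")
    unknown = set(frames["entity"]) - set(ENTITIES)
    if unknown:
        raise ValueError(f"unknown entities in table: {sorted(unknown)}")

    work = frames.copy()
    beta_term = beta if beta_per_entity else 0.0
    work["g"] = (work[list(COMPONENTS)].sum(axis=1)
                 + nonpolar_sasa_energy(work["sasa"], alpha, beta_term))
    g = work.pivot_table(index="time_ps", columns="entity", values="g")
    lacking = [e for e in ENTITIES if e not in g.columns or g[e].isna().any()]
    if lacking:
        raise ValueError(f"incomplete entity rows for: {lacking}")
    dg = g["complex"] - g["receptor"] - g["ligand"]
    if not beta_per_entity:
        dg = dg + beta
    dg.name = "dG"
    return dg, float(dg.mean())


def run_statistics(run_means: Sequence[float]) -> Tuple[float, float]:
    """Sample mean and SD (ddof=1; SD is 0.0 for a single run)."""
    arr = np.asarray(list(run_means), dtype=float)
    if arr.size == 0:
        raise ValueError("no run means supplied")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd
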
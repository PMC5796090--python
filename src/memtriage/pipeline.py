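"""End-to-end orchestration: feature building, classification, dynamics.

A run is driven by a plain mapping (typically parsed from YAML).  Every run
writes a ``manifest.json`` capturing the full configuration, its hash, the
seeds and the package version, which is sufficient to reproduce the outputs
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Mapping, Optional

import pandas as pd

from . import __version__
from .classify import FeatureVector, classify_unknowns, feature_frame, k_sweep, partition
from .conservation import ec_score, read_alignment
from .dynamics import RegionMap, cumulative_rmsf, discriminant_call, region_rmsf
from .physchem import pd_distance
from .profiles import ResidueProfile
from .sasa import apply_membrane_burial, free_residue_max_sasa, load_pdb, sasa_per_residue, rsasa
from .variants import parse_protein_change


@dataclass
class RunConfig:
    """Validated run parameters; everything is serialized into the manifest."""

    params: Dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key):
        return self.params[key]

    def get(self, key, default=None):
        return self.params.get(key, default)

    def require(self, *keys) -> None:
        missing = [k for k in keys if k not in self.params]
        if missing:
            raise ValueError(f"run config missing required keys: {missing}")

    def digest(self) -> str:
        canon = json.dumps(self.params, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError("run config must be a mapping")
        return cls(params=data)


def write_manifest(config: RunConfig, outdir: Path, extra: Optional[Mapping] = None) -> Path:
    manifest = {
        "config": config.params,
        "config_sha256": config.digest(),
        "package_version": __version__,
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path


def build_features(config: RunConfig) -> tuple[List[FeatureVector], List[dict]]:
    """Compute (rSASA, EC, PD) per mutation from structure + MSA + table.

    Per-row failures (position absent from the structure or the reference
    sequence, mismatched reference residue) do not abort the run; they are
    returned as a failure list for the summary.
    """
    config.require("structure", "msa", "mutations")
    slab = config.get("membrane_z")
    model = load_pdb(config["structure"],
                     membrane_slab=tuple(slab) if slab else None)
    sasa = sasa_per_residue(model,
                            probe_radius=float(config.get("probe_radius", 1.4)),
                            n_points=int(config.get("n_points", 960)))
    sasa = apply_membrane_burial(sasa, model)
    max_table = free_residue_max_sasa(model,
                                      probe_radius=float(config.get("probe_radius", 1.4)),
                                      n_points=int(config.get("n_points", 960)))
    rel = rsasa(sasa, max_table)

    alignment = read_alignment(config["msa"], reference_id=config.get("reference"))
    ec = ec_score(alignment)

    mut_df = pd.read_csv(config["mutations"], sep="\t")
    if "protein_change" not in mut_df.columns:
        raise ValueError("mutation table lacks a protein_change column")

    vectors: List[FeatureVector] = []
    failures: List[dict] = []
    for _, row in mut_df.iterrows():
        change = str(row["protein_change"])
        try:
            ref_aa, pos, alt_aa = parse_protein_change(change)
            if pos not in rel:
                raise KeyError(f"position {pos} absent from structure")
            if pos not in ec:
                raise KeyError(f"position {pos} absent from reference sequence")
            label = str(row["label"]) if "label" in mut_df.columns and not pd.isna(row.get("label")) else "unknown"
            vectors.append(FeatureVector(
                mutation_id=change, rsasa=rel[pos], ec=ec[pos],
                pd=pd_distance(ref_aa, alt_aa), label=label))
        except (ValueError, KeyError) as exc:
            failures.append({"protein_change": change, "error": str(exc)})
    return vectors, failures


def run_feature_pipeline(config: RunConfig, outdir) -> Dict[str, Any]:
    """Features -> (optional) K sweep -> classification of unknowns."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vectors, failures = build_features(config)
    feature_frame(vectors).to_csv(outdir / "features.tsv", sep="\t", index=False)

    labelled = [v for v in vectors if v.label != "unknown"]
    unknowns = [v for v in vectors if v.label == "unknown"]
    k = int(config.get("k", 7))
    summary: Dict[str, Any] = {"n_features": len(vectors),
                               "n_labelled": len(labelled),
                               "n_unknown": len(unknowns),
                               "failures": failures}

    if config.get("sweep") and labelled:
        train, test = partition(labelled, int(config.get("train_n", max(1, int(0.75 * len(labelled))))),
                                int(config.get("seed", 0)))
        table, recommended = k_sweep(train, test, list(range(1, min(len(train), 15) + 1)))
        table.to_csv(outdir / "k_sweep.tsv", sep="\t", index=False)
        summary["recommended_k"] = recommended
        k = recommended

    if labelled and unknowns:
        report = classify_unknowns(labelled, unknowns, k=min(k, len(labelled)))
        report.to_csv(outdir / "classification.tsv", sep="\t", index=False)
        summary["n_predicted_pathogenic"] = int((report["predicted"] == "pathogenic").sum())
    write_manifest(config, outdir, {"stage": "features", "summary": summary})
    return summary


def run_dynamics_pipeline(config: RunConfig, outdir) -> pd.DataFrame:
    """Region sums -> cumulative statistic -> discriminant call per variant.

    Input is either a region-sum table (``region_table``: variant column +
    one column per region) or a directory of per-residue RMSF TSV profiles
    (``profiles``), aggregated with the configured region map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    regions = RegionMap.from_mapping(config["regions"]) if config.get("regions") else RegionMap()

    rows = []
    if config.get("region_table"):
        df = pd.read_csv(config["region_table"], sep="\t", comment="#")
        if "variant" not in df.columns:
            raise ValueError("region table lacks a variant column")
        region_cols = [c for c in df.columns if c in regions.intervals]
        if not region_cols:
            raise ValueError("region table has no recognized region columns")
        for _, row in df.iterrows():
            sums = {c: float(row[c]) for c in region_cols}
            cum = cumulative_rmsf(sums)
            rows.append({"variant": row["variant"], **sums,
                         "cumulative": cum, "call": discriminant_call(cum)})
    elif config.get("profiles"):
        for path in sorted(Path(config["profiles"]).glob("*.tsv")):
            profile = ResidueProfile.from_tsv(path, units="A")
            sums = region_rmsf(profile, regions)
            cum = cumulative_rmsf(sums)
            rows.append({"variant": path.stem, **sums,
                         "cumulative": cum, "call": discriminant_call(cum)})
    else:
        raise ValueError("dynamics run needs either region_table or profiles")

    report = pd.DataFrame(rows)
    report.to_csv(outdir / "dynamics.tsv", sep="\t", index=False)
    write_manifest(config, outdir, {"stage": "dynamics", "n_variants": len(report)})
    return report
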
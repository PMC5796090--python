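"""Curation of missense-variant tables into labelled mutation sets.

Rules implemented:

* curated pathogenic set: clinical significance ``pathogenic`` or
  ``likely_pathogenic`` (plus an override list of variants known to cause
  disease despite a different database significance), restricted to
  variants with ExAC allele frequency > 1e-5;
* unknown set: significance ``uncertain`` under the same frequency gate;
* non-pathogenic set: allele frequency > 0 in the 1000 Genomes Project
  and exactly 0 in the ESP cohort (true zeros, not missing values);
* per-variant sex frequency: carrier females (males) over total carriers.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio.SeqUtils import seq1

VALID_SIGNIFICANCE = frozenset({
    "benign", "likely_benign", "uncertain", "likely_pathogenic",
    "pathogenic", "conflicting",
})
POPULATIONS = ("AFR", "AMR", "EAS", "FIN", "NFE", "SAS", "OTH")
DEFAULT_PATHOGENIC_OVERRIDES = frozenset({"E288K", "G303R"})
EXAC_AF_GATE = 1e-5

_CHANGE_RE = re.compile(
    r"^(?:p\.)?([A-Za-z]{1,3})(\d+)([A-Za-z]{1,3})$")

AA1 = set("ACDEFGHIKLMNPQRSTVWY")


def parse_protein_change(text: str) -> Tuple[str, int, str]:
    """Parse ``T93M``, ``Thr93Met`` or ``p.Thr93Met`` into (ref, pos, alt)."""
    m = _CHANGE_RE.match(text.strip())
    if not m:
        raise ValueError(f"unparsable protein change: {text!r}")
    ref_raw, pos, alt_raw = m.group(1), int(m.group(2)), m.group(3)

    def to_one(token: str) -> str:
        if len(token) == 1:
            aa = token.upper()
        elif len(token) == 3:
            aa = seq1(token.capitalize()).upper()
        else:
            raise ValueError(f"unparsable residue token {token!r} in {text!r}")
        if aa not in AA1:
            raise ValueError(f"unknown residue {token!r} in {text!r}")
        return aa

    ref, alt = to_one(ref_raw), to_one(alt_raw)
    if pos < 1:
        raise ValueError(f"position must be >= 1 in {text!r}")
    if ref == alt:
        raise ValueError(f"reference and alternate residues identical in {text!r}")
    return ref, pos, alt


@dataclass
class MutationRecord:
    """One missense variant with curation metadata and cohort frequencies."""

    protein_change: str                 # canonical one-letter form, e.g. "T93M"
    clinical_significance: str
    af_exac: Optional[float] = None
    af_1000g: Optional[float] = None
    af_esp: Optional[float] = None
    population_af: Dict[str, float] = field(default_factory=dict)
    n_female: int = 0
    n_male: int = 0
    label: Optional[str] = None         # pathogenic | non_pathogenic | unknown

    def __post_init__(self) -> None:
        ref, pos, alt = parse_protein_change(self.protein_change)
        self.protein_change = f"{ref}{pos}{alt}"
        self.ref_aa, self.position, self.alt_aa = ref, pos, alt
        for name in ("af_exac", "af_1000g", "af_esp"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1] for {self.protein_change}")

    @property
    def n_carriers(self) -> int:
        return self.n_female + self.n_male


def _require(value: Optional[float], column: str, record: MutationRecord) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(
            f"missing {column} for {record.protein_change}; "
            "frequencies must be explicit (0 is data, absent is an error)")
    return value


def classify_by_curation(
    records: Iterable[MutationRecord],
    overrides: Iterable[str] = DEFAULT_PATHOGENIC_OVERRIDES,
    af_gate: float = EXAC_AF_GATE,
) -> List[MutationRecord]:
    """Label curated variants pathogenic/unknown from clinical significance.

    Variants whose ExAC allele frequency fails ``af_exac > af_gate`` are
    excluded.  Variants named in ``overrides`` are forced to pathogenic.
    Benign/likely-benign/conflicting rows are dropped (neither set).
    """
    override_set = {f"{r}{p}{a}" for r, p, a in map(parse_protein_change, overrides)}
    out: List[MutationRecord] = []
    for rec in records:
        sig = rec.clinical_significance.strip().lower().replace(" ", "_")
        if sig not in VALID_SIGNIFICANCE:
            raise ValueError(
                f"unrecognized clinical significance {rec.clinical_significance!r} "
                f"for {rec.protein_change}")
        if _require(rec.af_exac, "af_exac", rec) <= af_gate:
            continue
        if rec.protein_change in override_set:
            out.append(replace(rec, label="pathogenic"))
        elif sig in ("pathogenic", "likely_pathogenic"):
            out.append(replace(rec, label="pathogenic"))
        elif sig == "uncertain":
            out.append(replace(rec, label="unknown"))
    return out


def select_nonpathogenic(records: Iterable[MutationRecord]) -> List[MutationRecord]:
    """Variants seen in the healthy 1000G cohort but absent from ESP."""
    out = []
    for rec in records:
        af_1kg = _require(rec.af_1000g, "af_1000g", rec)
        af_esp = _require(rec.af_esp, "af_esp", rec)
        if af_1kg > 0 and af_esp == 0:
            out.append(replace(rec, label="non_pathogenic"))
    return out


def sex_frequency(record: MutationRecord) -> Tuple[float, float]:
    """(female fraction, male fraction) among carriers; sums to 1."""
    total = record.n_carriers
    if total <= 0:
        raise ValueError(f"no carriers recorded for {record.protein_change}; "
                         "sex frequency undefined")
    return record.n_female / total, record.n_male / total


def top_frequent(records: Iterable[MutationRecord], min_individuals: int = 50,
                 k: int = 40) -> List[MutationRecord]:
    """Top-``k`` variants by overall allele frequency among those carried by
    more than ``min_individuals`` people.  Ties break by position, then
    alternate residue (deterministic)."""
    survivors = [r for r in records if r.n_carriers > min_individuals]
    for rec in survivors:
        _require(rec.af_exac, "af_exac", rec)
    survivors.sort(key=lambda r: (-r.af_exac, r.position, r.alt_aa))
    return survivors[:k]


# ---------------------------------------------------------------------------
# I/O

DEFAULT_COLUMNS = {
    "protein_change": "protein_change",
    "clinical_significance": "clinical_significance",
    "af_exac": "af_exac",
    "af_1000g": "af_1000g",
    "af_esp": "af_esp",
    "n_female": "n_female",
    "n_male": "n_male",
}


def read_variant_table(path, columns: Optional[Dict[str, str]] = None) -> List[MutationRecord]:
    """Read a tab-separated variant table into MutationRecords.

    ``columns`` remaps the documented logical names to the file's header.
    Population frequencies are picked up from ``af_<POP>`` columns.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t")
    for logical in ("protein_change", "clinical_significance"):
        if colmap[logical] not in df.columns:
            raise ValueError(f"variant table lacks required column {colmap[logical]!r}")

    def opt_float(row, logical):
        col = colmap[logical]
        if col not in df.columns:
            return None
        v = row[col]
        return None if pd.isna(v) else float(v)

    records = []
    for _, row in df.iterrows():
        pop_af = {}
        for pop in POPULATIONS:
            col = f"af_{pop}"
            if col in df.columns and not pd.isna(row[col]):
                pop_af[pop] = float(row[col])
        records.append(MutationRecord(
            protein_change=str(row[colmap["protein_change"]]),
            clinical_significance=str(row[colmap["clinical_significance"]]),
            af_exac=opt_float(row, "af_exac"),
            af_1000g=opt_float(row, "af_1000g"),
            af_esp=opt_float(row, "af_esp"),
            population_af=pop_af,
            n_female=int(row[colmap["n_female"]]) if colmap["n_female"] in df.columns else 0,
            n_male=int(row[colmap["n_male"]]) if colmap["n_male"] in df.columns else 0,
        ))
    return records


def read_vcf(path, protein_change_key: str = "PCHANGE",
             significance_key: str = "SIG") -> List[MutationRecord]:
    """Secondary input path: plain-text VCF with protein change and
    significance in INFO fields, frequencies in AF_EXAC/AF_1000G/AF_ESP."""
    import pysam

    records = []
    with pysam.VariantFile(path) as vcf:
        for var in vcf:
            info = var.info
            if protein_change_key not in info:
                continue
            pchange = info[protein_change_key]
            if isinstance(pchange, tuple):
                pchange = pchange[0]

            def get_f(key):
                if key not in info:
                    return None
                v = info[key]
                return float(v[0] if isinstance(v, tuple) else v)

            sig = info.get(significance_key, "uncertain")
            if isinstance(sig, tuple):
                sig = sig[0]
            records.append(MutationRecord(
                protein_change=str(pchange),
                clinical_significance=str(sig),
                af_exac=get_f("AF_EXAC"),
                af_1000g=get_f("AF_1000G"),
                af_esp=get_f("AF_ESP"),
            ))
    return records


def write_variant_table(records: Sequence[MutationRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "protein_change": r.protein_change,
            "clinical_significance": r.clinical_significance,
            "label": r.label if r.label is not None else "",
            "af_exac": r.af_exac, "af_1000g": r.af_1000g, "af_esp": r.af_esp,
            "n_female": r.n_female, "n_male": r.n_male,
        }
        for pop, v in r.population_af.items():
            row[f"af_{pop}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
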
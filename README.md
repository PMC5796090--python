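# memtriage

Triage of missense mutations in membrane proteins from structure,
conservation, physicochemistry and molecular-dynamics descriptors.

The package computes, per mutation:

- **rSASA** — per-residue solvent-accessible surface area (Shrake–Rupley
  sphere sampling) with a geometric membrane slab (residues whose
  side-chain centroid lies inside the slab are treated as buried),
  normalized by the free-residue SASA computed with the same engine;
- **EC score** — the fraction of aligned species sharing the reference
  residue at each position of a multiple sequence alignment;
- **PD** — the Euclidean distance between (hydrophobicity, charge)
  property vectors of the wild-type and mutant residue types
  (Wimley–White interface scale by default, pluggable);

and classifies unknown-effect mutations with a KNN model trained on
labelled pathogenic/non-pathogenic sets (train/test partitioning, K sweep
with median-of-argmax recommendation, vote margins).

Trajectory-derived analyses:

- per-residue **RMSF** (optional Kabsch superposition) aggregated into
  named-region sums over the bundled DHCR7 topology (TM1…CTD);
- the **cumulative RMSF** discriminant TM1 + TM2 + CL2 − TM7 − TM9_10,
  with calls `pathogenic_like` (≤ 46 Å), `nonpathogenic_like` (> 50 Å)
  and `ambiguous` in between;
- **DCCM** residue cross-correlation maps and mutant-vs-WT difference maps;
- **MM/PBSA** post-processing: frame selection (e.g. 500 frames at 20 ps
  from the last 10 ns), the nonpolar term G = 0.0054·SASA + 0.92 kcal/mol,
  per-frame binding energies ΔG = G(complex) − G(receptor) − G(ligand),
  and run-level mean/SD.

Variant curation from ClinVar/ExAC-style tables is included (significance
mapping with an override list, the ExAC allele-frequency gate > 1e-5, the
1000G>0 & ESP=0 non-pathogenic rule, sex-frequency and top-k summaries).

A `synthetic` module generates every input the pipeline consumes — toy
helical-bundle PDBs with known burial, alignments with exact per-column
identity, separable feature tables, region-shifted RMSF profiles and
per-frame energy tables — with ground truth emitted alongside, so the
whole pipeline is testable offline.

## CLI

One entry point with subcommands:

```sh
memtriage synth --seed 1 --out bundle/            # synthetic input bundle
memtriage select variants.tsv --out curated.tsv   # variant curation
memtriage sasa structure.pdb --membrane-z -15 15 --out rsasa.tsv
memtriage conserve alignment.fasta --reference human --out ec.tsv
memtriage pd --out pd_matrix.tsv
memtriage classify features.tsv --k 7 --sweep --out calls.tsv
memtriage rmsf ensemble.npy --out rmsf.tsv
memtriage regions rmsf.tsv --out regions.tsv      # region sums + discriminant
memtriage dccm ensemble.npy --out dccm.tsv
memtriage mmpbsa run1.tsv run2.tsv run3.tsv --out report.tsv
memtriage run config.yaml --stage features --out outdir/
```

Every `run` writes a `manifest.json` (config, config hash, package
version) sufficient to reproduce its outputs byte-identically.

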
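# glycomap

Glycan-fragment mapping of protein–carbohydrate complex structures, plus the
family-level sequence analyses that usually accompany such a study.

Given a reference structure and a series of ligand-soaked complexes, the
pipeline:

1. parses PDB coordinates and categorises residues (protein / saccharide /
   water / other) from a user-extensible component table;
2. detects pyranose rings, glycosidic linkages (donor position, acceptor
   position, α/β anomericity from mean-plane geometry) and assembles glycan
   connectivity graphs;
3. computes Cremer–Pople puckering parameters (Q, θ, φ) and classifies each
   ring against the 38-conformer pyranose itinerary (e.g. `4C1`, `OS2-like`,
   `B25`);
4. superposes every complex onto the reference (Kabsch fits seeded by a
   global sequence alignment, with iterative outlier rejection), pools the
   transferred ligand sugars, clusters them into consensus subsites, and
   labels them with glycosidase subsite nomenclature (+n/−n around the
   catalytic Asp-Asp motif);
5. builds the glycan × subsite occupancy matrix, reassembles composite
   glycans along a chosen subsite path, and classifies their shape
   (linear / C / U) from the end-to-end span;
6. annotates the binding groove: aromatic lining, disulfides, contact
   tables, and comparison of externally predicted complex models against
   the observed subsite map;
7. runs desk-scale sequence analyses: pairwise identity/E-value statistics,
   representative-node collapsing, sequence similarity networks, per-species
   co-distribution statistics, and Jensen–Shannon conservation profiles
   mapped onto the reference structure.

A fully seeded synthetic-data module (`glycomap.synthetic_data`) generates
every fixture the pipeline consumes: ideal sugars at arbitrary puckers,
linked glycans with typed linkages and set torsions, toy canyon complexes
with sugars planted at known subsites, sequence families with controlled
identities and paralog counts, and MSAs with designed conserved columns.

## CLI

```sh
glycomap simulate --what complexes --seed 1 --out demo   # synthetic soak series
glycomap map-subsites --reference demo/reference.pdb \
    --complex demo/soak0.pdb --complex demo/soak1.pdb --complex demo/soak2.pdb \
    --out demo_map
glycomap report demo_map                                  # human-readable summary
glycomap pucker demo/soak0.pdb                            # per-ring Cremer-Pople TSV
glycomap align demo/soak0.pdb demo/reference.pdb          # iterative Calpha fit
glycomap simulate --what family --out fam
glycomap ssn fam/family.fasta --evalue-cutoff 1e-10 --identity-threshold 0.99 --out ssn
glycomap simulate --what msa --out msa
glycomap conserve msa/msa.fasta --out conservation.tsv
```

All tunables (merge radius, rejection cutoff, shape thresholds, E-value
cutoff, …) live in a YAML config (`glycomap.config.RunConfig`); every
command is deterministic given config + seed.

## Layout

```
src/glycomap/
  structure_io.py     PDB I/O + residue categorisation
  glycan_topology.py  rings, linkages, anomericity, glycan graphs
  ring_puckering.py   Cremer-Pople transform + conformer itinerary
  superposition.py    Kabsch + sequence-guided iterative alignment
  subsite_mapping.py  ligand transfer, subsite clustering/labelling,
                      occupancy, reassembly, shape, groove annotation
  family_analysis.py  pairwise stats, SSN, co-distribution, conservation
  synthetic_data.py   seeded generators for all fixtures
  deposited.py        composed analyses of a local deposited-entry series
  cli.py, config.py   command line and run configuration
```
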
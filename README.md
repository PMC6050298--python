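# barrelforge

Combinatorial backbone assembly and PSSM-constrained sequence design for
homologous enzyme families.

Natural enzyme families built on the (β/α)₈ (TIM) barrel fold are
structurally modular: the eight strand–helix units vary between family
members while the positions that frame them are tightly conserved.
barrelforge exploits this modularity as a design engine. Given a family of
homologous structures, it

1. superposes the members onto a reference numbering and profiles per-position
   structural conservation (mean pairwise CA deviation);
2. segments the fold at the conservation minima inside the β-strands;
3. extracts every member's torsion-space **fragment** per segment, with a
   **conformation-dependent PSSM** (built only from family sequences whose
   local backbone lies within 1.5 Å CA RMSD of the fragment's);
4. clusters each segment's conformations at an RMSD threshold and estimates
   the combinatorial backbone diversity — the product over segments of
   cluster counts, which for real families exceeds the deposited structures
   by many orders of magnitude;
5. recombines fragments into novel backbones (exact torsion splicing:
   reassembling one source's own fragments reproduces it to numerical
   precision) and designs sequences position-by-position under PSSM,
   steric and fixed-catalytic-residue constraints;
6. samples designs by simulated-annealing Monte Carlo over fragment swaps —
   at each step a random segment is replaced by a random fragment, the
   segment plus every residue within 6 Å is redesigned, and the move passes
   the Metropolis criterion (accept if ΔE ≤ 0, else with probability
   exp(−ΔE/T)) under a decreasing temperature — then ranks and clusters the
   resulting designs into conformationally unique backbones.

Design operates at identity level under a documented surrogate energy
(soft steric clash between representative atoms + negative PSSM log-odds +
junction bond strain); all-atom scoring, rotamer packing and stability
design are intentionally out of scope. A synthetic-family generator with
planted ground truth (conserved anchors, conformational modes, indels,
mode-correlated sequences, fixed catalytic residues) makes every stage of
the pipeline testable without downloading any structures.

## Worked example

Generate a synthetic 12-member family, build its fragment database, and
measure its combinatorial diversity:

```
$ barrelforge make-fixtures --seed 11 --out-dir fam
wrote 12 structures to fam

$ barrelforge build-db --pdb-dir fam --reference ref --scheme scheme.yaml \
      --msa fam/msa.fasta --out db.jsonl
wrote DB with 48 fragments to db.jsonl

$ barrelforge diversity --db db.jsonl --threshold 1.0
segment n_fragments n_clusters
seg1    12          4
seg2    12          5
seg3    12          6
seg4    12          5
# total 600         log10=2.778
```

Each of the four sampled segments has 12 fragments (one per member) falling
into 4–6 conformational clusters at 1 Å CA RMSD; recombining clusters across
segments yields 4·5·6·5 = 600 distinct backbones from only 12 input
structures — the combinatorial amplification the method is built on.
`scheme.yaml` names the segments, their 1-based reference ranges and the
fixed catalytic positions; `barrelforge make-fixtures` writes the planted
truth (`fam/truth.json`) from which such a scheme can be derived.

Run a small annealing campaign and reduce it to unique designs:

```
$ barrelforge design-run --db db.jsonl --seed 4 --n-starts 5 --out-dir designs
best energy -311.766 over 5 designs

$ barrelforge cluster-designs --in-dir designs --threshold 2.0
...
# 5 conformationally unique designs
```

The campaign writes ranked designs as PDB + FASTA, a per-trajectory energy
table, a JSON summary, and a manifest (inputs, config hash, seed) that makes
the run replayable: the same seed reproduces the design FASTA byte for byte.
Energies are surrogate units — useful for ranking within one database, not
physical stabilities.

## Layout

```
src/barrelforge/
  geometry.py            torsions, NeRF placement, Kabsch superposition
  structure_io.py        PDB I/O, internal <-> Cartesian conversion
  family_db.py           alignment, conservation, segmentation, PSSMs,
                         fragment extraction, DB serialization
  diversity.py           conformational clustering, diversity estimate
  assembly_design.py     fragment splicing, design shells, surrogate
                         energy, sequence design
  sampler.py             Metropolis, annealing trajectories, campaigns,
                         design clustering
  synthetic_fixtures.py  planted-truth family generator
  cli.py                 barrelforge {make-fixtures, build-db, diversity,
                         design-run, cluster-designs}
```

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.
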
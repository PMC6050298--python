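# Methods

## The design engine

barrelforge re-implements, at backbone-and-identity resolution, the
combinatorial assembly strategy used to design active enzymes from natural
(β/α)-barrel families: rather than sampling backbones from scratch, the
conformational diversity already present in a structural family is
recombined. The pipeline is

1. **Family alignment.** Every member structure is mapped onto a reference
   numbering (through a user MSA, or global pairwise sequence alignment with
   BLOSUM62 when no MSA is given) and rigidly superposed by iterative trimmed
   Kabsch fitting of mapped CA pairs (pairs deviating by more than
   `trim_cutoff` are dropped and the fit repeated, at most 10 rounds).
   The default trim is 3.0 Å; for *conservation profiling and boundary
   selection* a core-focused trim of 1.0 Å is used, because a permissive fit
   lets large loop excursions rotate the frame and smear apparent deviation
   onto conserved positions (a "seesaw" artifact that displaces profile
   minima from the truly conserved anchors).
2. **Conservation profile and segmentation.** Per reference position, the
   mean pairwise CA–CA distance among covering members (positions with
   coverage below 0.5 are excluded). The chain is cut at the profile minimum
   inside each user-supplied β-strand range (ties resolve to the lowermost
   position); consecutive cuts bound the sampled segments, and segments can
   be merged into groups to form discontinuous sampling units. Strand ranges
   are user input (or a simple φ/ψ criterion); the architecture of the family
   is assumed known.
3. **Fragment extraction.** For each member and segment, the per-residue
   internal coordinates (φ, ψ, ω plus the *actual* bond lengths and angles)
   are stored, together with the incoming peptide-link geometry from the
   residue preceding the segment in the source. Insertions relative to the
   reference stay inside their segment, so segments of different lengths are
   different backbones by definition.
4. **Conformation-dependent PSSMs.** Each fragment's position-specific
   scoring matrix is built only from the sequences of same-segment fragments
   (same length profile) within a conformational radius of 1.5 Å local CA
   RMSD — sequence preferences are conditioned on backbone conformation.
   Scores are background-relative log₂ odds with background-proportional
   pseudocounts:  `score = log2(((count + pc·bg)/(N + pc))/bg)` with
   `pc = 1` and a uniform background by default (a Robinson–Robinson
   background is selectable). The implied column distribution renormalizes
   exactly, so single-sequence columns are finite.
5. **Assembly.** One fragment per segment (plus the constant region) is
   spliced in reference order and rebuilt to Cartesian coordinates by
   sequential natural-extension placement, anchored at the reference frame.
   At block junctions the bond length and the two bond angles of the peptide
   link come from the *downstream* fragment's stored incoming-link record;
   torsions stay with the residue that owns them. Because actual (not
   idealized) covalent geometry is stored, reassembling all fragments of one
   source reproduces that source exactly — the identity-assembly oracle that
   anchors the test suite. Carbonyl O and CB are rebuilt from ideal sp²/
   tetrahedral geometry (they are derivable and would be re-placed by any
   downstream refinement).
6. **Sequence design.** Identity-level design under a surrogate energy
   (below): at each designable position, the identity maximizing
   `w_pssm·pssm − w_clash·clash` among identities with PSSM score ≥ the
   cutoff (0 bits by default), swept to convergence (≤ 5 sweeps) because
   clash terms couple neighbours. A position where nothing passes the cutoff
   falls back to the PSSM argmax with a logged warning and an explicit
   record in the design state. Catalytic positions (reference numbering,
   fixed identities) are never designed and are excluded from design shells.
7. **Simulated annealing.** Each trajectory starts from a uniformly random
   fragment selection with a fully designed sequence; each of `n_steps`
   (default 30) steps replaces a uniformly chosen segment with a uniformly
   chosen fragment (self-swaps count), redesigns the swapped segment plus
   every residue whose representative atom lies within `shell_radius`
   (default 6 Å), and applies the Metropolis criterion
   (accept if ΔE ≤ 0, else with probability exp(−ΔE/T)) under a geometric
   temperature schedule T_start → T_end (defaults 2.0 → 0.01 in surrogate
   units; the schedule shape and endpoints are free parameters exposed in
   config). A campaign runs `n_starts` independent trajectories (desk
   default 50; the production-scale value of 3000 is configurable), ranks
   finals by energy, and reduces them to conformationally unique designs by
   greedy leader clustering on full-backbone CA RMSD (default 2.0 Å),
   processed in energy order so each representative is its cluster's
   lowest-energy member.

## The surrogate energy

All-atom force fields, rotamer packing and Cartesian minimization are out of
scope; design operates at identity level under a three-term surrogate that
preserves the architecture of the original protocol (steric plausibility,
sequence-profile likelihood, chain integrity):

* **clash** — Σ over representative-atom pairs (CB, CA for glycine)
  separated by more than 2 in sequence of `max(0, d_clash − d)²`,
  `d_clash = 4.0 Å`;
* **pssm** — Σ over positions of `−score(pos, aa)` in bits;
* **junction** — Σ over assembly junctions of `(d_CN − 1.329 Å)²`.

Defaults `w_clash = 1, w_pssm = 1, w_junction = 10`. The terms are reported
separately and sum exactly to the total. Surrogate energies order designs
and drive annealing; they are not calibrated to physical units, and no claim
about folding stability or catalysis follows from them.

## The synthetic family generator

Tests need structure families with known ground truth. The generator builds
open β/α-repeat chains (no barrel closure or strand pairing — the engine
operates on chain topology, not tertiary packing): a 4-residue lead,
`n_units` repeats of strand(5)–loop(3)–helix(7)–loop(2), and a 5-residue cap
strand so every unit is flanked by anchors. One planted anchor sits
mid-strand; sampled segments run anchor-to-anchor (one full β-α unit each).

Members are generated in torsion space (chains are always chemically sane,
with ideal bond geometry and ω = 180°) and then **closed**: the interior
φ/ψ of each unit are adjusted by a regularized Levenberg–Marquardt solve so
that the downstream anchor's N/CA/C land on the reference anchor frame plus
N(0, `anchor_sigma`) jitter (default 0.1 Å). Without closure, torsion noise
in any loop would lever-arm every downstream anchor and no conservation
signal would survive. Per-segment conformational **modes** are planted the
same way: candidate torsion offsets (≈ ±90° on six loop/early-helix
torsions) are closed onto the anchor and accepted only if clash-free and
mutually separated by ≥ 2.5 Å local CA RMSD, so modes are recoverable by
1 Å clustering by construction. Indel classes get one planted, closed,
clash-free base conformation each, shared by all carriers (odd-indexed
members), making each length class a coherent cluster of its own; indel
members are pinned to mode 0 in that segment.

Noise scales: interior torsion noise is `6°` per Å of requested
`loop_sigma` (the realized coordinate sigma is measured against the
reference and reported in the truth record — the mapping is deliberately
approximate and sublinear because closure absorbs part of the noise);
strand/lead residues get `30° × anchor_sigma` of torsion noise so that
conservation grows away from the anchors instead of being flat across each
rigid strand; with all sigmas zero the family is exactly degenerate.
Members violating the steric floor (4.05 Å between representative atoms, 3+
apart in sequence) or straying more than `max(0.5 Å, 2·loop_sigma)` from
their mode mean are locally repaired: the offending unit's noise is redrawn
and that unit and everything downstream re-closed (anchors are pinned, so a
repair cannot disturb other units). Sequences are mode-correlated: each
(segment, mode) has preferred identities used with probability 0.9, the
constant region has a 0.95-fidelity consensus, and two planted "catalytic"
positions are fixed to Glu in every member. Glycine is excluded from the
generator's alphabet so every residue carries a CB representative atom;
design can still produce glycine, and the CA-representative logic is
covered by unit tests.

What the fixtures do **not** emulate: tertiary packing and barrel closure,
real Ramachandran statistics, correlated inter-segment conformations,
crystallographic noise, and real sequence covariation. Passing tests
demonstrate the correctness of the machinery (lossless fragment algebra,
recovery of planted structure, constraint handling, sampler statistics), not
that designs against real families will be active enzymes.

## Numerical choices

* Torsions follow the IUPAC sign convention (verified against an
  independent library implementation); values in (−180°, 180°], exact trans
  reported as +180°. Collinear triplets raise instead of returning an
  arbitrary value.
* Superposition is Kabsch (proper rotation only); the RMSD is recomputed
  from the applied rotation because the solver's residual norm loses ~10⁻⁶
  absolute precision to cancellation near zero — the identity-assembly
  oracle at 10⁻⁶ Å needs better.
* Internal-coordinate sentinels are NaN (φ of the first residue, ψ/ω and
  link geometry of the last); reconstruction raises if a required value is
  undefined, and idealized bond values (N–CA 1.458, CA–C 1.525, C–N
  1.329 Å) fill in only where a junction lacks source geometry.
* Leader clustering is order-dependent by design; input order is fixed to
  sorted source id (fragments) or energy rank (designs) for determinism.
  Fragments with different length profiles never co-cluster, and each
  length class adds to the cluster count.
* Fragment-to-fragment RMSD superposes each range of a discontinuous
  segment independently and combines ranges as a length-weighted RMS.
* The diversity estimate is the product over segments of cluster counts —
  exact integer plus log₁₀ — and is validated against exhaustive enumeration
  of assembled cluster representatives on toy databases.
* All samplers consume a uniform draw every step whether or not ΔE ≤ 0,
  keeping the random stream aligned so trajectories replay bit-identically
  from their seed; campaign sub-seeds derive from the campaign seed.

## Problem sizes used in verification

The verification suite runs on desk-scale planted families chosen to make
every property checkable exactly: 10–12 members, 2–3 repeat units (~40–60
residues), 2–4 modes per segment, 20-seed replicates for the statistical
recoveries, 50-trajectory annealing campaigns against a 2-segment
planted-optimum database, and toy diversity databases of ≤ 24 combinations
for exhaustive enumeration. The production-scale parameters (3000 starts,
full families of hundreds of structures) are configuration values, not code
paths, so the desk runs exercise the identical machinery.

## Known limitations

* Identity-level design cannot represent rotamer-level effects; catalytic
  "conformation fixed" constraints reduce to identity constraints.
* The surrogate energy has no solvation, electrostatics or hydrogen-bond
  terms; rankings are only meaningful relative to the same database and
  weights.
* The pairwise-alignment fallback of `align_family` assumes family members
  are globally alignable; domain rearrangements would need a curated MSA.
* `propose_boundaries` takes strand ranges as input; it does not assign
  secondary structure from coordinates beyond a simple φ/ψ window.
* Multi-chain designable units are out of scope; oligomeric interfaces are
  handled at the segmentation level (constant regions), not by modelling
  the partner chain.
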
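# Methods

## Model

`cgbeta` treats a MARTINI coarse-grained structure as a point cloud: one
backbone grain ("BB" bead) per residue, positions in nm, partitioned into
peptides. β-sheet content is inferred purely from geometry in two stages.

**Aligned triples.** For thresholds α ∈ [0, 1] and ε > 0, an ordered triple
of grains (x⃗, y⃗, z⃗) is (α, ε)-aligned when (i) the three grains lie on
pairwise-distinct peptides, (ii) ‖x⃗ − y⃗‖ ≤ ε and ‖y⃗ − z⃗‖ ≤ ε, and
(iii) the angle at the center — arccos of the dot product of the unit arm
vectors — is at least απ. The angle of a collinear triple with y⃗ between
the ends is π, so the criterion selects near-collinear, closely spaced
triples spanning three different strands: the signature of a cross-β stack.
The distinct-peptide requirement is what suppresses α-helices and random
coil, whose near-collinear runs live on a single peptide. We deliberately
use the angle at the vertex (large for collinear geometries), which is what
the aligned-triple inequality and the worked threshold values require; a
description of the same construction in terms of the acute companion angle
is equivalent up to the substitution θ ↦ π − θ and is not used anywhere in
the code.

**Gluing.** Two aligned triples overlap when they share at least two of
their three grains (set-wise on grain identity — end/center roles are
ignored). Connected components of the overlap graph are the putative
β-sheets; a component's grain set is the union of its triples' grains.

## Parameters

| name | default | units | meaning |
|---|---|---|---|
| α (`alpha`) | 0.89 | – | angular threshold; triples need angle ≥ απ (≈ 160.2°) |
| ε (`epsilon`) | 0.7 | nm | maximum center–end gap |
| GL (`group_length`) | required | residues | peptide length used to partition the grain list |
| `use_pbc` | off | – | minimum-image displacement with the frame's orthorhombic box |

α = 0.89 / ε = 0.7 nm is the standard operating point for MARTINI backbone
beads: inter-strand spacing in a cross-β stack (≈ 0.48 nm) falls well inside
ε while the diagonal to the next residue column (≈ 0.73 nm at the synthetic
lattice spacings) falls outside. Periodic boundaries are off by default
because exported structure files are typically whole-molecule clustered; the
flag exists for raw wrapped coordinates.

## Algorithms and numerics

* Triple search prunes candidates with a fixed-radius KD-tree query (cell
  size ε); angles over the surviving end pairs are evaluated vectorized,
  and every candidate is confirmed by the scalar criterion so no tolerance
  band enters the decision. The literal dense enumeration over all ordered
  triples is kept as `find_aligned_triples_bruteforce` and must agree
  exactly (tested on seeded random frames).
* Triples are canonicalized as (end_a, center, end_b) with end_a < end_b;
  the criterion is symmetric under swapping the ends, so each geometric
  alignment is stored once, and all reported counts are of canonical
  (deduplicated) triples.
* Gluing uses union-find keyed on 2-subsets of grain ids: two triples
  overlap iff they share a 2-subset, so uniting all triples seen on the same
  pair reproduces the pairwise-overlap graph's components in near-linear
  time. The quadratic scan + BFS (networkx) is retained as the test oracle.
  Component order is deterministic: decreasing grain count, ties by smallest
  grain id.
* The arccos argument is clamped to [−1, 1]; a zero-length arm makes a
  triple "not aligned" rather than raising, so coincident beads in noisy
  frames never abort a run. Distance and angle thresholds use ≤ / ≥ exactly.
* Gromos87 positions are parsed by fixed columns (not whitespace); residue
  boundaries are detected by change of (residue number, residue name)
  between consecutive atom lines, which survives the 5-digit residue-number
  wrap; velocities are discarded; only orthorhombic boxes are interpreted.
  The writer emits residue/atom numbers modulo 100000 (the GROMACS wrap
  convention), and coordinates quantize to 0.001 nm (%8.3f).

## PDB backbone mapping

`map_backbone` reduces each standard residue to one BB grain at the
unweighted centroid of its N, CA, C, O atoms (missing members skipped,
residues with none dropped; Å → nm). This is a deterministic stand-in close
to the MARTINI backbone center-of-mass convention; the difference from a
mass-weighted mapping is far below the 0.7 nm detection scale. Peptide
identity comes from PDB chains in file order — GL is not used for mapped
structures. Altloc conflicts resolve to highest occupancy (ties → first);
HETATM residues are skipped unless allowlisted; `ca_only` puts beads on CA.

## Synthetic structures

The generators produce the geometries the detector must separate, with
closed-form ground truth:

* **Parallel sheet** — grain (s, i) at (0.48·s, 0.55·i, 0) plus optional
  Gaussian jitter. With S strands and L residues each, jitter 0,
  inter-strand ≤ ε and √(inter² + intra²) > ε, the detector finds exactly
  L·(S − 2) triples gluing into L column components; for S ≥ 3 every grain
  is in a sheet. The 0.55 nm intra-strand spacing is chosen above the
  realistic ≈ 0.35 nm MARTINI spacing precisely to keep this closed form
  (diagonals suppressed); at realistic spacing ground truth is defined by
  the brute-force oracle instead.
* **Antiparallel sheet** — identical positions, residue ordering reversed on
  odd strands; detection output is identical to the parallel case because
  the criterion uses positions only.
* **Helix / random coil** — negative controls for the distinct-peptide
  constraint.
* **Synthetic fibril PDB** — a 12-chain × 32-residue cross-β stack with the
  amyloid-β 11–42 sequence and full N/CA/C/O backbone records whose
  centroids sit exactly on the lattice. It is a synthetic, lattice-regular
  substitute for a deposited amyloid fibril structure, so the PDB → mapping
  → detection pipeline can be exercised end to end offline. What passing
  tests on it show is that the pipeline preserves chains, counts and
  geometry — not that the detector reproduces any particular experimental
  fibril model.

The jittered lattice emulates the distorted-lattice geometry of real CG
aggregates but not their density fluctuations, chain connectivity along
strands, or solvent; tests passing on synthetic data demonstrate the
detector's contracts (exactness, monotonicity, invariance), not biological
recall/precision on MD output.

## Problem sizes

Oracle-equivalence checks run on 20 seeded random frames of 100–200 grains
over 5–20 peptides in a 2.5 nm box — dense enough that hundreds of triples
occur. The full suite and the acceptance script each complete in seconds on
one CPU.

## Known limitations

* Parallel vs antiparallel sheet topology, twist, and inter-frame component
  tracking are out of scope.
* The distinct-peptide rule means intra-molecular β-hairpins within a single
  peptide are invisible by construction.
* Counts are of deduplicated triples; a convention counting both
  orientations would double them but leaves all ratios unchanged.
* Only orthorhombic periodic boxes are supported, and only when opted in.
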
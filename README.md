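# cgbeta

Geometric β-sheet detection in MARTINI coarse-grained structures.

Self-assembling peptides (SAPs) aggregate into β-sheet-rich supra-molecular
structures whose β-content correlates with the mechanical properties of the
resulting biomaterials. In MARTINI coarse-grained molecular dynamics, each
residue's backbone is a single "BB" bead, so classical secondary-structure
tools (DSSP, STRIDE) that need atomistic hydrogen-bond geometry do not
apply. `cgbeta` detects putative β-sheets directly from bead geometry, for
people analyzing CG-MD trajectories of peptide self-assembly.

## Method

Given grains (points in ℝ³, nm) partitioned into peptides, a triple
(x⃗, y⃗, z⃗) on **three pairwise-distinct peptides** is **(α, ε)-aligned**
when

* ‖x⃗ − y⃗‖₂ ≤ ε and ‖y⃗ − z⃗‖₂ ≤ ε, and
* the angle at the center, arccos(v⃗·w⃗) with v⃗ = (x⃗−y⃗)/‖x⃗−y⃗‖ and
  w⃗ = (z⃗−y⃗)/‖z⃗−y⃗‖, is ≥ απ (near-collinear).

Defaults are α = 0.89 and ε = 0.7 nm. In a cross-β architecture the backbone
beads of adjacent strands stack into near-collinear columns, so aligned
triples pick out β-sheets while the distinct-peptide requirement suppresses
α-helices and coils. Two triples sharing at least two grains *overlap*; the
connected components of the overlap graph are the putative β-sheets. Per
frame, the tool reports triple and component counts, the fraction of grains
in sheets, and residue-type compositions (and ratios such as Lys/Asp).

## Worked example

```python
from cgbeta import SheetSpec, analyze_frame, make_parallel_sheet

frame = make_parallel_sheet(SheetSpec(n_strands=12, strand_len=32))
triples, components, stats = analyze_frame(frame)
print(stats.n_triples, stats.n_components, stats.fraction_in_sheets)
# 320 32 1.0
```

An ideal 12-strand × 32-residue lattice (strand spacing 0.48 nm, residue
spacing 0.55 nm) yields exactly 320 triples — each of the 32 cross-strand
columns contributes one triple per interior strand (12 − 2 = 10) — which
glue into 32 column components covering all 384 grains (sheet fraction 1.0).
See `examples/` for narrative scripts covering trajectory statistics, PDB
backbone mapping and negative controls.

## Command line

```sh
cgbeta fixture sheet --out sheet.gro          # synthetic test structure
cgbeta analyze sheet.gro --gl 32 --out report # CSV/JSON per-frame reports
cgbeta map protein.pdb backbone.gro           # PDB -> one BB bead/residue
```

`analyze` reads single- or multi-frame Gromos87 (.gro) files of MARTINI
backbone grains plus the group length GL (residues per peptide);
`--export-labels` writes per-grain component assignments so any molecular
viewer can color grains by sheet. `map` coarse-grains an all-atom PDB
(one bead per residue at the N/CA/C/O centroid; `--ca-only` for CA beads).

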
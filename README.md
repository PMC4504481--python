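# darc

Ray-casting surface-complementarity docking for shallow binding sites, with
particle-swarm pose search, on-the-fly conformer sampling, grid
electrostatics, and rank-based calibration of the scoring weights.

## The problem

Small molecules that inhibit protein–protein interactions bind shallow,
flat pockets where conventional docking scores struggle. This engine takes
a geometric view: the pocket's topography is mapped by casting rays from
vantage points ("origins") placed 30 Å behind the pocket, recording for
each ray the distance ρ_pocket at which it meets the protein surface. A
ligand pose is complementary when the same rays meet the ligand surface at
similar distances, so the score sums, over rays,

```
c1·(ρ_ligand − ρ_pocket)   if ρ_pocket < ρ_ligand   (underpacking)
c2·(ρ_pocket − ρ_ligand)   if ρ_ligand < ρ_pocket   (steric clash)
c3                         ray misses the ligand    (ligand too small)
c4                         boundary ray hits ligand (outside the pocket)
```

with c1 fixed at 1.00, plus optionally c5·Σ qᵢφᵢ, the ligand charges read
against a clamped, masked electrostatic potential grid. Five origins (one
central, four rotated ±45° about the pocket center) redistribute the same
rays to whichever vantage point sees each surface patch best. Docking
minimizes this score with a global-best particle swarm over translation,
rotation, and a seventh "conformer index" coordinate that selects among
pre-generated ligand conformers during a single trajectory. Because each
weight multiplies a disjoint group of rays, poses reduce to five cached
"component energies", and scoring-weight calibration (minimizing the sum
of native-pose ranks against decoy poses by Nelder–Mead, with
leave-one-out cross-validation) needs no re-docking.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Everything below runs offline on generated inputs:

```
darc gen-fixtures --seed 5 --out demo/
darc make-rays --receptor demo/receptor.pdb \
    --target-residues "$(python -c "import json;print(','.join(map(str,json.load(open('demo/truth.json'))['target_resids'][::6])))")" \
    --multiple-origins --seed 3 \
    --bound-ligand demo/ligand.sdf --lig-grid --near-cutoff 2.5 \
    --out demo/rays.txt
darc dock --ray-file demo/rays.txt --ligand demo/ligand.sdf \
    --receptor demo/receptor.pdb --search-conformers \
    --num-particles 100 --num-steps 300 --seed 1 --out-prefix demo/
```

The three commands print:

```
wrote fixture bundle to demo (208 receptor atoms, 5 conformers, 20 decoys)
wrote demo/rays.txt: 1103 rays from 5 origin(s)
best score 1663.2890 (conformer 4); wrote DARC_receptor_lig5.json
```

`gen-fixtures` builds a synthetic self-dock problem: a 15-atom
pseudo-ligand and a receptor whose cavity is carved to complement it
exactly, with the generating pose stored in `demo/truth.json`. `make-rays`
detects the pocket, places five origins, and writes the ray-file (1103
rays: pocket shell plus boundary layer). `dock` then recovers the buried
pose: the reported score is close to the generating pose's own
discretization floor, and comparing `pose` in the output JSON against
`true_pose` in `truth.json` gives a heavy-atom RMSD of 0.73 Å. A score of
this magnitude is ~1.5 per ray — the floor set by the 0.5 Å pocket grid —
whereas a randomly placed pose on the same ray map scores several-fold
higher.

Weight calibration runs from a component cache (TSV of per-pose component
energies, written by `darc.weight_fit.ComponentCache.to_tsv`):

```
darc fit-weights --cache cache.tsv --loocv --out fit.json
```

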
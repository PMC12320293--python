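# hairpinscreen

Analysis toolkit for multi-assay small-molecule screening campaigns against
structured RNA — built around the screen of the pre-miR-31 hairpin, whose
dicing-site/junction region is a candidate site for blocking Dicer/TRBP
processing. The package covers every computational stage of such a
campaign, together with synthetic-data generators so the whole pipeline
runs and is testable at desk scale:

1. **Virtual-screen triage** (`hairpinscreen.docking`) — hits are compounds
   whose docking score satisfies *s ≤ μ − 2σ* (sample SD) over the library
   scored against the target; a counter-screen removes compounds that pass
   the same rule on selectivity-control RNAs (miR-21, miR-20b hairpins).
2. **Fluorescence indicator displacement** (`hairpinscreen.fid`) — dye
   affinity from a one-site fit *Y = B*max*·X/(K_D + X)*; working RNA
   concentration at 10% dye occupancy, fb₀.₁ = K_D/9; the displacement
   statistic %FID = 100·(F₀ − F)/F₀ with a ±15% window requiring every
   replicate above the window for a hit; artifact flags from dye-only and
   RNA-only controls.
3. **NMR titration analysis** (`hairpinscreen.nmr`) — chemical shift
   perturbations CSP = √(Δδ_H² + (α·Δδ_C)²) (α = 0.25), significance at
   mean + 1 SD, binding-site mapping onto the hairpin's regions; K_D from
   intermediate-exchange volume redistribution, *B(X) = B*max*·X/(K_D+X) +
   NS·X* with *B = V_B/(V_B+V_I)*, or from fast-exchange CSP isotherms,
   with censored ">max tested" verdicts for non-saturating titrations;
   STD-NMR binder/non-binder/untestable calls.
4. **Similarity expansion** (`hairpinscreen.similarity`) — Morgan
   (radius 2, 2048-bit) fingerprints and Tanimoto search (default cutoff
   0.6) to grow confirmed scaffolds into derivative candidate sets.
5. **Evidence integration** (`hairpinscreen.integrate`) — set-based final
   calls (any positive assay validates a binder) and hit-rate accounting.
6. **Synthetic data** (`hairpinscreen.synthetic`) — seeded generators for
   docking tables with planted hits, plates driven by the exact
   RNA/dye/ligand competition equilibrium (`hairpinscreen.equilibrium`),
   two-state titration series in both exchange regimes, and SMILES
   libraries with planted near-duplicates.

## Worked example

The numbered drivers under `analysis/` run the full pipeline on synthetic
inputs and write their tables under `results/`:

```bash
python analysis/01_simulate_inputs.py
python analysis/02_virtual_screen.py
...
python analysis/06_integrate_evidence.py
```

`02_virtual_screen.py` prints, for a 400-compound table with 8 planted
hits (3 of them planted control binders):

```
hit rule: mean -12.12, sd 3.34, threshold -18.80 kcal/mol -> 13 hits
counter-screen removed 3 compounds (planted control binders among them: 3/3)
planted selective hits recovered: 5/5
```

i.e. the 2-SD rule recovers every planted selective hit and the
counter-screen eliminates exactly the planted control binders. The
integration driver reproduces the campaign's hit-rate arithmetic from its
per-compound outcomes:

```
miR-31 screening campaign (n = 40):
  STD binders: 7 (17.5%, ~18% rounded)
  FID hits:    4 (10.0%)
  dual union:  10 (25.0%)
  validated:   11 (27.5%)
```

— 7/40 STD binders, 4/40 FID hits with one compound shared, so the dual
union is 10/40 = 25%, and one HSQC-only rescue brings validated binders to
11/40 = 27.5%. The NMR driver reports KD-estimator recovery on synthetic
intermediate-exchange titrations at the campaign's two measured
affinities (29.10 and 20.64 µM), with mean fitted K_D within a few percent
of truth.

A `hairpinscreen` console script exposes each stage
(`simulate`, `screen`, `fid`, `nmr`, `similar`, `integrate`); see
`hairpinscreen --help`.

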
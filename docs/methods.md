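# Methods

## The screening problem

The package analyses a multi-assay campaign for small molecules binding a
precursor-microRNA hairpin (the miR-31 hairpin, construct residues 20–52,
5'-GGCAUAGCUGUUGAACUGGGAACCUGCUAUGCC-3'). A docking screen proposes
candidates; saturation-transfer-difference (STD) NMR and a fluorescence
indicator displacement (FID) assay provide two orthogonal binding
read-outs; ¹H-¹³C HSQC titrations localise binding and quantify affinity;
2D similarity search expands confirmed scaffolds. Each stage is an
independent module; the integration stage combines them set-wise.

## Models and procedures

### Docking triage

Scores are treated as given (kcal/mol, more negative more favourable).
The hit rule is *s ≤ μ − k·σ* with k = 2 and σ the sample SD (ddof = 1)
over all compounds scored against the target; the SD = 0 degenerate case
admits no hits (no compound is distinguishable). "Also binds a control"
is operationalised as passing the same k-SD rule on the control's own
score distribution — the symmetric, least arbitrary reading; a
per-compound alternative (control score more favourable than target
score) is available behind `selectivity_filter(per_compound=True)` but is
not the default. Mean/SD are computed before any control-based removal.

### Competition equilibrium and the FID model

The plate signal model is RFU = gain·[RNA·dye] + baseline (+ compound
autofluorescence); linearity is the minimal assumption since no
photophysical model is specified for the dye. [RNA·dye] comes from the
exact two-ligand, one-site competition equilibrium, solved by 1-D root
finding (Brent) on free RNA over [0, RNA_tot]: for a trial free-RNA value
the dye and ligand balances close in closed form, so the RNA mass-balance
residual is strictly monotone and the bracketed root is unique. Mass
balances close to better than 1e-9 relative (asserted at the solution).

%FID = 100·(F₀ − F)/F₀, with F₀ the per-plate blank (RNA + dye) mean and
no cross-plate normalisation (single-plate design). This form makes the
"fluorescence change" axis 100 − %FID equal 100·F/F₀, so hits (>15%
displacement) sit below 85 on that axis — the only form consistent with
both descriptions of the assay. The hit rule is strict per replicate
(every replicate > +15%); the increase rule applies to the replicate mean
(< −15%). Artifact flags (ligand–dye, ligand–RNA interaction) are raised
when the corresponding no-RNA / no-dye control exceeds its baseline by
more than the window; flags annotate but never change the classification.

### HSQC analysis

CSP = √(Δδ_H² + (α·Δδ_C)²) with α = 0.25, the standard aromatic-carbon
scaling (configurable). Per-residue CSP is the maximum over that
residue's atom pairs — the conservative site-mapping statistic given that
C2–H2 and C6–H6/C8–H8 report independently. Significance is CSP > mean +
1 SD of quantified residues (a configurable convention); residues whose
peaks are overlapped or undetected are excluded from both the threshold
and the significance set. Peak matching is nearest-neighbour within an
ellipse (default 0.05 ppm ¹H, 0.5 ppm ¹³C; wider for CSP profiling): no
candidate → not detected, contested or multiple candidates → overlapped.

Binding-site mapping groups significant residues by a region annotation
(stem 20–27/45–52, dicing site 28–30/42–44, junction 31–32/39–41, apical
loop 33–38 — the package's reading of the hairpin's secondary structure);
ties for the modal region are reported joined ("dicing_site/junction").
A "non-specific" flag is raised when ≥ 75% of quantified residues show
CSP above an absolute 0.02 ppm floor (the DMSO-control tolerance). The
flag needs an absolute floor because the relative mean + 1 SD threshold
can never mark *all* residues significant, yet whole-molecule
perturbation at ligand excess is exactly the phenotype to catch.

K_D estimation: in intermediate exchange, fraction bound B =
V_B/(V_B + V_I) per titration point (pooled as the mean over site
correlations) is fit to B(X) = B_max·X/(K_D + X) + NS·X with B_max ∈
(0, 1], NS ≥ 0 (linear nonspecific term), B(0) ≡ 0. In fast exchange the
site CSP is fit to CSP(X) = CSP_max·X/(K_D + X). A fit is censored
(">max(X)") when K_D exceeds the tested range or, for fast exchange, when
the fitted curve at the top concentration stays below 80% of CSP_max —
operationalising "did not reach saturation". Reported uncertainty is the
asymptotic least-squares SE (×1.96), labelled as such.

STD classification: untestable without a usable proton spectrum
(insoluble compounds); binder when any difference-spectrum amplitude
reaches 3× the noise SD; otherwise non-binder.

### Similarity search

Morgan fingerprints (radius 2, 2048 bits) on canonicalised structures —
salts stripped to the largest fragment, stereochemistry ignored
(scaffold-level 2D search). Tanimoto |A∩B|/|A∪B| with a 0.6 default
cutoff; the fingerprint family and cutoff are package choices (the
original campaign used a commercial-database search with unspecified
settings) and are configurable.

### Integration

A compound is a validated binder iff STD = binder, or FID = hit, or HSQC
shows specific or non-specific perturbation. HSQC "weak_or_none" (no
perturbation at 10-fold excess) is negative evidence — this is what makes
the campaign arithmetic come out at 11/40 = 27.5% validated, with the
dual (STD ∪ FID) union at 10/40 = 25% and the one HSQC-only rescue
(RA1). Compounds untested everywhere are inconclusive. The ~18% STD rate
is the roster-wide fraction 7/40 = 17.5% rounded to integer percent; raw
fractions are always emitted alongside.

Only 23 of the campaign's 40 compounds are individually named in the
assay summaries; the roster is padded with placeholders X01–X17 carrying
the outcomes (no proton spectrum, no fluorescence change) that reproduce
every reported count: 22 STD-testable, 7 binders, 4 FID hits, 11
increases, 25 no-change, 18 without ¹H spectra. RA1 is placed in the
STD-untestable set because the HSQC follow-up panel was defined as the
overlap of STD-untestable and FID-increase compounds.

## Synthetic data: what it emulates, what it does not

Generator defaults mirror the campaign's assay design: 50.9 nM RNA with
500 nM dye on plates (dye K_D 458 nM — the fb₀.₁ = K_D/9 working point),
ligands screened at 100 µM in duplicate, titrations on 100 µM RNA up to
1 mM ligand, 2% multiplicative lognormal noise (positive read-outs).
All generators are byte-deterministic for a fixed seed.

Titration truth uses the exact two-state quadratic at the configured RNA
concentration rather than the excess-ligand hyperbola, so the bias of the
hyperbolic estimator is a measurable property: negligible in the
excess-ligand regime (RNA ≪ K_D; the package's recovery experiments use
1 µM RNA), but substantial when RNA ≳ K_D, as in stoichiometric-depletion
titrations. The estimator-recovery experiments report a small (~2–3%)
positive bias at 2% volume noise — noise propagated through the
fraction-bound ratio and the nonlinear fit, not a coding artifact.

Deliberate idealisations: synthetic reference spectra are placed on a
lightly jittered grid and are therefore better resolved than real crowded
aromatic regions (real data motivates the overlapped-peak handling, which
is exercised with constructed overlaps); intermediate-exchange line
broadening is not simulated — only free/bound volume redistribution,
which is all the volume-based estimator consumes; bound-state shift
offsets (0.05–0.12 ppm ¹H, 0.4–1.0 ppm ¹³C) are drawn to clear the
free-peak matching ellipse so free and bound peaks are always separable;
docking scores are i.i.d. normal with planted 4-SD outliers, and planted
*selective* hits draw control scores from a ±1.5-SD-truncated background
so their label is never contradicted by a chance tail draw. Passing tests
on these generators therefore demonstrate correctness of the estimators
and rules under their stated assumptions, not robustness to spectral
overlap, plate drift, or correlated noise in real data.

## Numerical choices

Equilibrium root: Brent with near-machine relative tolerance; binding
fits: trust-region-reflective least squares (scipy `curve_fit`) with
bounds as above and half-saturation initialisation. Ties in hit ranking
break lexicographically by compound id. Degenerate inputs raise typed
errors (insufficient scores/replicates/points, missing blanks, both peak
volumes zero, unparseable SMILES naming the record). The recovery
experiments use 100 replicate titrations of 8 points each — sizes at
which the estimator statistics are stable.

## Known limitations

No docking, cavity detection or pose handling; no raw spectral
processing, resonance assignment, lineshape fitting or exchange-regime
auto-detection (the regime is declared); no plate-quality statistics
(Z'); residue labels are opaque strings and no arithmetic is done on
them. The campaign's externally-derived numbers (real docking score
tables, real plate RFUs) are inputs, not outputs, of this package.
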
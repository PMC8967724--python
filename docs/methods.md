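# Methods

This note documents the models, conventions and design choices behind
`vagalseq`, in the order the pipeline runs.

## Barcode classification

Cells are held in a pandas DataFrame, one row per cell, with barcode
expression in `upb_<organ>` columns on the processed (post-normalisation,
log-scale) expression scale. A barcode is called positive when its
expression is **strictly** greater than the detection threshold (default
0.8); exact ties fall below. With positives P:

- |P| = 0 → unlabelled; |P| = 1 → organ-specific single;
- P = {stomach, oesophagus} → oesophageal-sphincter class;
- P = {stomach, duodenum} → pyloric-sphincter class;
- other |P| = 2 → generic dual; |P| ≥ 3 → multi, excluded from
  organ-specific statistics (only single and dual categories carry
  anatomical meaning downstream).

QC retains cells with `min_genes < n_genes < max_genes` and
`mito_fraction < max_mito` (defaults 500 / 8000 / 0.10, all strict).
Damage flagging works at cluster level: a cluster whose mean
injury-marker expression (*Sprr1a*, *Ecel1*) exceeds 5× the grand mean
across all cells is dropped whole, mirroring the removal of a damaged
subpopulation rather than of individual cells. The 5× factor assumes the
damaged cluster is a minority (≲10% of cells); with much larger damage
fractions the grand mean is inflated and the factor should be lowered.

The organ correlation matrix uses
N_dual(i,j) / √(N_single(i)·N_single(j)) off-diagonal with unit diagonal.
The normalisation by the geometric mean of single counts is this
package's own convention (the statistic's inputs — single and dual
counts — are standard; the normalisation is not canonical). Organs with
zero single-labelled cells yield missing (NaN) entries, not zeros.

## Trajectory scoring

The organ position score of a cluster is the weighted mean of normalised
organ positions (fractions of body length from the nodose ganglia;
built-in table: lung 0.241, heart 0.280, oesophagus 0.228, stomach 0.469,
duodenum 0.567, colon 0.589, pancreas 0.545), weighted by the cluster's
share P_organ-cluster of each organ's single-labelled cells.

Trajectory scores use a polyline through caller-ordered centroids rather
than a fitted smooth curve: the score is a position along a displayed
curve, and a polyline makes the orthogonal projection well defined and
exactly testable. Points are projected onto every segment (clamped to
segment ends); the globally nearest projection wins, with ties resolved
to the smaller arc length; the score is cumulative arc length divided by
total length, so it lives in [0, 1] regardless of embedding units.

Tissue-layer indices weight fixed layer scores (mucosa/inner epithelium
0, muscle 1, connective tissue 2) by ending counts; the result is bounded
by the smallest and largest index present. Score–position relationships
are summarised by ordinary least squares (scipy's `linregress`); no
robust fitting, since the relationship of interest is a plain linear one.

## Calcium-trace analysis

The baseline F is the mean fluorescence over the half-open frame window
[onset − 20, onset − 10), i.e. exactly 10 frames (17.2 s at the 1.72 s
frame interval); "frame −20 to frame −10" is ambiguous about inclusivity
and the half-open reading is the one that keeps the stated 10 frames.
ΔF/F is (F_t − F)/F, which makes the transform invariant to positive
rescaling of the raw trace.

A cell is responsive when max ΔF/F within the stimulus window is
strictly above 1.0 (more than 100% above baseline). Window conventions:
stretch stimuli span stretch-on to stretch-off inclusive; intestinal
stretch uses 40 frames (68.8 s) from onset; intestinal infusion 90 frames
(154.8 s).

Activation kinetics use 10%-of-peak first-crossing semantics on the
discrete frame sequence, without interpolation (frame counts are
integers): the activation frame is the first frame of the ≥10% run that
contains the peak, and the activation duration counts frames from that
crossing to the last ≥10% frame after the peak, inclusive — a rectangular
pulse of width w has duration exactly w. A trace that never falls back
below the level is censored at the trace end and marked as such.

Marker rules classify imaged cells into subpopulations A–L in fixed
listing order, first match wins, no match → "X". "Multiple hits" means at
least two of the listed markers positive. Rule A's "Runx3+ and/or
Piezo2+/P2ry1+" is read as (Runx3+) OR (Piezo2+ AND P2ry1+): the A
population is characterised elsewhere as co-expressing Piezo2 and P2ry1,
so the slash denotes a conjunction. Because evaluation order is fixed,
cells satisfying several rules take the earliest letter (e.g. a
Tmc3+Car8+Cckar+ cell is D, not I); this is an inherent property of
ordered rule lists and is documented rather than resolved.

## Landmark registration

Landmarks are matched by mutual nearest neighbours under the current
transform within a caller-set gate radius; at least 3 mutual pairs are
required. The transform is estimated by the closed-form least-squares
rigid solution (Kabsch; Umeyama when isotropic scale is enabled for
live-tissue-to-section shrinkage). The determinant constraint is enforced
inside the solve, so a reflection is never returned — reflected data
simply shows a large residual. Collinear configurations (second singular
value ≈ 0) are rejected as degenerate.

The virtual section plane minimises the **sum of squared** point-to-plane
distances, giving the closed-form solution (centroid plus
smallest-spread singular direction of the centred set); a
sum-of-absolute-distances variant would need iterative optimisation and
is noted as an alternative, not implemented.

Unlabelled cells register to their nearest transformed candidate iff that
candidate is within the gate radius r (default 15 μm, one cell diameter)
AND the second-nearest candidate is more than ρ× farther (default
ρ = 1.5); equal distances are ambiguous. The (r, ρ) gate is this
package's formalisation of "unambiguous" registration — the qualitative
relative-distance-and-depth rule does not pin down numeric criteria — and
both parameters are configurable. Cells failing the gate are meant to be
dropped downstream.

## Ending-type assignment

Innervation intensity is measure / sample total area, with areas for
ME/pIMA/cIMA and terminal counts for IGLE; replicates are averaged.
AF(type, region) divides regional intensity by the same type's
whole-stomach intensity. SF(type, region) is the **ratio of sums** —
summed regional dual-barcode percentages over summed stomach
single-barcode percentages across the type's clusters — not a sum of
ratios. The assignment objective is the plain double sum of squared
SF − AF differences over 4 types × 4 regions, invariant to iteration
order.

The search enumerates all type^k assignments of the free clusters in
lexicographic order (cluster order × canonical type order
ME < pIMA < cIMA < IGLE) merged with the fixed pre-annotated map; exact
variance ties resolve to the earliest enumerated trial. The inner loop
uses precomputed per-cluster vectors so the full 4⁷ scan runs in ~0.2 s.

Enrichment rules: single-organ mode requires a cluster's single-barcode
share strictly above 4%; dual/sphincter mode additionally requires the
dual share to be at least 5 **percentage points** (additive, matching the
units of the compared shares) above both organs' single shares; the
fundus (region 5) mode inverts this, requiring the stomach single share
to beat each dual share by 5 points. Boundary semantics: strict ">" for
the 4% rule, "≥ +5 points" for the margin.

## Correlation index

For a pruned bipartite connection map (variables with no connections are
removed first), C = (E − E_min)/(E_max − E_min) with E_min = max(n₁, n₂)
(every retained variable must be connected) and E_max = n₁·n₂; the
degenerate case E_max = E_min defines C = 0. v₁, v₂ are **population**
variances of per-variable connection counts — population rather than
sample variance is what makes both printed anchors (one-to-one → 1,
all-to-all → 0) hold at every size. The index (1 − C)/((v₁+1)(v₂+1)) is
invariant under variable renaming and side swapping.

## Brainstem profiles

FI is mean minus background fluorescence, clamped at zero (a negative
subtraction is treated as no signal). PI = FI·A/TF·100 with
TF = Σ FI·A per pathway, so each profile sums to 100 and is invariant to
common rescaling of fluorescences and areas. Grid cells missing for a
pathway are treated as FI = 0 when profiles are compared on the union
grid. Pairwise profiles are compared by Σ(PI₁ − PI₂)² and the variance
matrix is summarised by average linkage (UPGMA, the conventional default
for this kind of distance matrix; configurable), exported as newick.

## Synthetic data

The generators define the study conditions; all randomness flows from a
single seed through spawned generators, so fixed seeds give bit-identical
scenes.

- **Cell tables** (default 3000 cells, 12 clusters incl. one damage
  cluster): each regular cluster carries one organ and one tissue layer;
  a cell's true organ is its cluster's organ, and with probability
  `dual_rate` (default 0.16, matching the observed dual share) a partner
  organ is drawn proportional to an adjacency table that is nonzero only
  for physically adjacent pairs. Positive barcodes are drawn as
  threshold + |N(0.7, σ)| — a folded-normal stand-in for the unknown
  expression distribution above threshold, not a claim about real data —
  and negatives as N(0.1, σ) clipped at 0, so zero noise yields exact
  recovery. Cluster centroids sit at (10 × organ position, 2 × layer):
  the organ axis is linear in anatomical position and orthogonal to the
  layer axis. QC fields have a configurable contaminant tail (default
  5%).
- **Traces** (1.72 s/frame, 200 frames): archetypes sustained (plateau
  across the whole first stimulus window), transient (decay within ~5
  frames), polymodal (transient responses to both stimuli) and
  non-responder, each with peak ΔF/F equal to `response_amplitude`
  (default 2.0) plus Gaussian noise on the raw trace. Archetype recovery
  thresholds: sustained vs transient at 15 frames of activation duration.
- **Landmark scenes**: section-space points are drawn per 10 μm section
  (≥3 landmarks each) and pulled back through the exact inverse
  transform, so the forward transform is recoverable to machine
  precision at zero noise; noise perturbs the section side only.
- **Ending tables**: dual percentages are constructed as
  AF(type(c), region) × single_pct(c), so under the true assignment SF
  equals AF exactly and the search objective has its global minimum (zero
  variance) at the truth; the four built-in AF profiles are chosen
  mutually distinct so that minimum is unique. Gaussian noise on the dual
  percentages degrades recovery smoothly.
- **Innervation tables**: smooth unimodal fluorescence bumps with
  pathway-specific centres over a constant background, so nearby pathways
  get small correlation variance.

What the generators do **not** emulate: transcriptome-wide expression
structure, read-level sequencing noise, ambient RNA, batch effects,
nonrigid tissue deformation, imaging artefacts, or realistic anatomical
fold-change magnitudes. Passing tests therefore demonstrate correctness
of the computations and recoverability of planted structure, not
robustness to every failure mode of real data.

## Problem sizes and numerics

Test and example scenes use 400–3000 cells, 60–200 traces, tens of
landmarks and the full 4⁷ assignment search — sizes chosen so the whole
suite runs in well under a minute while exercising every code path at
realistic structure. Numerical conventions worth knowing: strict
inequalities at every printed threshold (0.8, QC bounds, 1.0
responsiveness, 4%); ≥ at the 10%-of-peak level and the 5-point
enrichment margin; NaN (never zero) for undefined ratios; ties broken
deterministically (first maximum for peaks, smaller arc length for
projections, lexicographic order for assignments).
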
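# Methods

## The measurement and the model

A glycan microarray experiment probes a fluorescently labeled
glycan-binding protein (GBP) against several hundred printed glycans,
each spotted in replicate (6 spots on CFG-style arrays). The scanner
reports, per spot, a foreground and a background intensity; `glycofit`
defines the spot signal as **RFU = foreground median − background
median**, clamped at 0 (both the clamp and the channel/column selection
are configurable, since scanners differ). Replicates collapse to a mean
RFU with the **sample** standard deviation (n−1 denominator; replicates
are a sample of spot-level variability). Scanner-flagged spots
(`Flags < 0`) are excluded by default.

Repeating the scan across a ladder of protein concentrations — the
reference design is 0.04–10 µM in 3-fold steps (0.04, 0.12, 0.36, 1.1,
3.3, 10 µM) — gives each glycan a dose series which is fit to the
one-site (Langmuir) saturation binding isotherm:

    RFU(c) = Bmax · c / (KD + c)

`Bmax` is the plateau signal (RFU), `KD` the concentration of
half-maximal binding (µM), and `KA = 1/KD` (µM⁻¹) the association
constant used for ranking. `KA` is stored as the exact inverse of the
fitted `KD`, so the identity `KA·KD = 1` holds to machine precision.
A free-Hill-coefficient variant is available behind a flag
(`free_hill=True`) but the default fixes h = 1: array spots offer no
reliable information to constrain cooperativity, and the one-site form
is what gives the Bmax/KD vocabulary its meaning.

Because printed glycan density is unknown and varies between glycans and
print batches, all constants are **relative**: valid for comparing
glycans within one experiment, not thermodynamic affinities. This is
precisely the point of the multi-dose design — the isotherm *shape*
(KD) is insensitive to the density-driven scale (Bmax) that corrupts
single-concentration rank ordering.

## Fitting

Nonlinear least squares on the replicate means (unweighted; fitting the
means rather than pooled spots keeps each concentration equally
weighted regardless of replicate count), using a bounded trust-region
reflective algorithm (`scipy.optimize.least_squares`, tolerances 1e-12).

- Bounds: `Bmax ∈ (0, 10·max RFU]`, `KD ∈ (0, 10⁴·c_max]` — generous
  boxes that exclude only unphysical values.
- Initialisation is deterministic: `Bmax₀ = max mean RFU`, `KD₀` = the
  tested concentration whose RFU is nearest `Bmax₀/2`. No random
  restarts, so identical inputs give identical fits.
- The relative standard error of `KD` comes from the asymptotic
  covariance `s²(JᵀJ)⁻¹` at the solution; with fewer than 3
  concentrations the residual degrees of freedom vanish and the SE is
  reported as 0.
- Degenerate inputs: an all-zero series is routed to *nonbinder* without
  fitting; a flat positive series (no dose information) keeps its
  best-effort parameters but is marked `converged = False`.

The test suite cross-checks the optimizer against an independent dense
log-grid search over the same parameter box (the optimizer's SSE must
not exceed the 400×400-grid minimum), and against noise-free data
generated from the model itself, where `KD` and `Bmax` are recovered to
better than 1e-4 relative.

## Classification

Three-way, total and deterministic:

- **nonbinder** — top-concentration mean RFU below the detection floor
  `max(A, k·SD_top)` with defaults `A = 100 RFU`, `k = 3`. On pure-noise
  simulations (spot SD 50 RFU, 6 replicates) this floor keeps the
  false-positive rate ≤ 1%.
- **saturated** — a converged fit whose predicted fractional occupancy
  at the top tested concentration, `c_max/(KD + c_max)`, is at least
  θ = 0.8, with `KD` relative standard error ≤ 0.5.
- **unsaturated** — any remaining binder.

All three thresholds are exposed in the run config. The occupancy rule
makes the classification monotone in `KD` for a fixed ladder: lowering
`KD` can only move a glycan toward saturation. θ = 0.8 corresponds to
`KD ≤ c_max/4` (2.5 µM on the reference ladder) — a glycan must be
within reach of its plateau inside the tested range before its `KA` is
taken at face value.

For unsaturated binders the reported quantity is

    %max_i = 100 · RFU_i(c_max) / max_j RFU_j(c_max),

the glycan's top-dose signal relative to the strongest top-dose signal
over **all** glycans in the experiment. This ratio form was chosen
because %max is used as a binding-strength gradient (darker = stronger):
it is scale-invariant, lies in [0, 100], and assigns the top binder
exactly 100. The denominator deliberately spans all glycans, not just
unsaturated ones, so %max values remain comparable with the overall
binding landscape.

## Graphics

Every figure is computed as a pure *plot model* first and rendered from
it, so tests assert on data, never pixels.

- **Dose-response curves**: mean ± SD per concentration with the fitted
  curve, log concentration axis; green line = saturated, gray =
  unsaturated, points only for nonbinders; `KA` and top RFU annotated.
- **Heatmap**: glycans × concentrations, single-hue blue scale spanning
  [0, global max RFU] (darker = higher); rows blocked by structure group
  in the fixed order N-glycan, blood-group antigen, sialic acid, other,
  then terminal motif (lexicographic), then chart number.
- **KA vs RFU scatter** over saturated glycans; the KA axis switches to
  log when the values span ≥ 3 decades.
- **Rank table**: top-60 glycans by top-concentration RFU (or by KA),
  ties broken toward the lower chart number; the KA column carries a
  white→red and the RFU column a white→blue min–max gradient, each
  normalised independently — the visual point being how poorly the two
  rankings agree.
- **Ring charts**: one chart per structure family (N-glycans,
  blood-group antigens, sialylated glycans), every glycan an
  equal-width wedge (the value lives in the color, not the angle),
  wedges ordered by linkage class then chart number so linkage arcs are
  contiguous. Inner layer: white→red for `KA` (min–max within the ring;
  an all-equal ring paints full red), white→blue for %max on the fixed
  [0, 100] scale, white for nonbinders. Middle layer: fixed discrete
  palette over Type 1 LacNAc / Type 2 LacNAc / other / unknown. Outer
  layer: structure labels. A shared `ka_range` can be passed to compare
  several proteins on one color scale; the default normalises per ring,
  which maximises within-chart contrast at the cost of cross-protein
  comparability.

## Glycan catalog and group assignment

The catalog is a CSV (`chart_number, structure, linkage_class,
structure_group, terminal_motif`); the last three columns are optional
and are filled by ordered motif rules over the condensed-IUPAC structure
text when absent: sialylated terminal (`Neu5Ac/Gc(a2-3/6/8)`) →
sialic_acid; fucosylated Lewis/ABH motif (`Fuc(a1-2/3/4)`) →
blood_group_antigen; chitobiose–mannose core
(`Man(b1-4)GlcNAc(b1-4)GlcNAc`) → N_glycan; else other. First match
wins, which makes the three ring-chart families disjoint (sialyl-Lewis
antigens count as sialylated). These rules are a stated convention of
this package — array providers do not publish a group assignment — and
explicit catalog columns always override them.

Two catalog print versions merge by exact structure-text equality after
whitespace normalisation: the merged list is the intersection (glycans
on only one version are dropped), renumbered consecutively from 1 in the
first catalog's chart-number order, with the old→new mapping exported
for both versions. Duplicated structure strings within one catalog are
an error rather than a silent choice.

## Synthetic experiments

The generator (`glycofit.simulate`) emulates the reference design: 555
glycans × 6 replicate spots × the 0.04–10 µM ladder, written as real GPR
files plus a truth table, catalog and run config. Spot foreground is

    background + Bmax·c/(KD + c) · (1 + cv·z),   z ~ N(0,1)

with the file's background *estimate* carrying its own Gaussian error,
so background-subtracted RFU is noisy even for nonbinders. Defaults,
chosen once as a realistic scanner regime: replicate CV 5%, background
100 ± 20 RFU, Bmax log-uniform in [10³, 6×10⁴] RFU, class mix 0.5
saturating (KD ∈ [0.05, 1] µM, log-uniform), 0.3 unsaturated-range
(KD ∈ [30, 300] µM), 0.2 nonbinder. All draws flow from one recorded
seed; equal seeds reproduce identical bytes.

What the generator does **not** emulate — and therefore what passing
tests do not demonstrate about real arrays: spatial slide artifacts and
print-density gradients, saturation of the scanner photomultiplier,
glycan-specific printing efficiency, multivalency/avidity effects, and
non-Gaussian outlier spots. Weak simulated "binders" whose true top-dose
signal falls below the 100-RFU floor are correctly reported as
nonbinders; truth-versus-call comparisons in the tests account for this
detectability boundary explicitly.

## Problem sizes and runtime

The shipped test suite and the acceptance script use 50 glycans for
noise-free recovery, 100 for noisy recovery (median relative KD error
≈ 3% at 5% CV), 20 series for the grid-search cross-check, and the full
555-glycan array for the end-to-end determinism run — sizes chosen so
the entire suite completes in well under a minute of compute while still
exercising the full array scale. A complete 555-glycan pipeline run
(parse → fit → spreadsheet, plots off) takes a few seconds on one CPU;
with all ~570 figures enabled, rendering dominates at roughly a minute.

## Known limitations

- Constants are relative; no printed-density normalisation is attempted
  (the multi-dose design is the substitute for it, by construction).
- One-site model only; two-site and avidity models are out of scope.
- The saturation rule (θ, SE bound, detection floor) is a convention;
  results near the thresholds should be inspected via the per-glycan
  curve plots.
- Structure strings are treated as annotated text; no structural
  normalisation (WURCS/GlycoCT) or cartoon rendering is performed, so
  catalog merging requires textually identical structures.
- Only the GPR/ATF text dialect is read; binary or spreadsheet exports
  of scanner software must be converted upstream.
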
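# Methods

## Problem setting

Intrinsically disordered proteins (IDPs) lack a stable tertiary structure;
they are depleted in bulky hydrophobics and aromatics, enriched in charged
and structure-breaking residues, and — lacking an aggregating hydrophobic
core — tend to remain soluble after boiling. A heat-resistant protein
fraction is therefore a practical experimental enrichment for IDPs, and its
computational characterization rests on a small set of sequence-level
primitives: per-residue disorder scores, run-length statistics over the
binarized calls, protein-level IDP criteria combined across predictors, and
set-level composition and physico-chemical summaries. `idrscan` implements
that tool chain end to end, with a synthetic proteome generator providing
ground truth for validation.

## Per-residue predictors

### Charge–hydropathy (unfoldability)

For each residue, the window of `window` residues centred on it (truncated
at the termini; default 51) is summarized by the mean rescaled
Kyte–Doolittle hydropathy ⟨H⟩ ∈ [0, 1] (rescaled as (H + 4.5)/9) and the
mean net charge ⟨q⟩ under unit charges K, R = +1 and D, E = −1 (His is
treated as neutral at the unspecified working pH; configurable). The score
is

    S = 2.785·⟨H⟩ − |⟨q⟩| − 1.151,

the signed distance from the classical boundary line separating folded
from natively unfolded proteins in the charge–hydropathy plane. Negative
scores predict disorder; the boundary value 0 itself is called ordered.
All constants are parameters (`ChargeHydropathyParams`), so alternative
boundaries or scales can be tested.

### Pairwise energy estimation

Disordered sequences are those that cannot gain enough stabilizing
interaction energy from their sequential context. For residue *i* with
amino acid *a*, the context is the window (default 21) centred at *i*
excluding position *i*; with context composition *f*, the estimated energy
is

    e_i = Σ_b M[a][b] · f(b)

for a symmetric 20×20 interaction-propensity matrix *M*, mapped to a
disorder probability by the logistic
`score = 1/(1 + exp((e − midpoint)/(−slope)))`; scores at or above 0.5 are
called disordered.

The shipped default matrix (`data/energy_matrix.yaml`) is the additive
form `M[a][b] = (p(a) + p(b))/2` over a signed per-residue
disorder-propensity scale of the TOP-IDP type, so `e_i` is the mean of the
residue's own propensity and its context's mean propensity. Because the
scale is signed around the order/disorder boundary, the logistic midpoint
defaults to 0; the slope (0.1) only sets score sharpness, not the calls.
The matrix is data, not code: users can substitute any published
interaction matrix (e.g. the IUPred energy-predictor matrix) via YAML.

### Window and tie conventions

Windows are odd; termini are handled by truncation rather than padding, so
no residues are invented. Ambiguous `X` residues are excluded from all
window statistics with renormalization over the non-X residues present
(an all-X window scores `−intercept` for the charge–hydropathy model; an
all-X context gives e = 0). An X at the centre of the energy model is
scored with the context-averaged row `fᵀMf`. Ties at the binarization
threshold go to "disordered" for probability-like scores and to "ordered"
for unfoldability scores. Neural-network predictors whose weights are not
redistributable (PONDR VL-XT, DisEMBL Remark-465) are supported only as
imported per-residue score tracks in the TSV track schema.

## Disorder metrics and IDP criteria

Per (protein, predictor): the disordered-residue count, percent disorder
(100·count/length), the longest disordered region (LDR; longest maximal
run of disordered calls, with no bridging over single ordered residues),
and the LDR length-range bin `0~9 / 10~29 / 30~49 / 50~99 / 100<`. The
last bin is read as LDR ≥ 100 so the bins partition the non-negative
integers.

A protein is an IDP under the **strict** criterion when LDR ≥ 30
consecutive residues, the conventional long-disordered-region threshold.
The **extended** criterion adds proteins with 10 ≤ LDR < 30 whose percent
disorder exceeds 10; the upper bound of the short-LDR clause is exclusive
so the two clauses partition, and the long-region clause carries no
percent condition. Predictors vote over a common universe and a protein is
a consensus IDP when at least *k* of *n* predictors agree (default
*k* = *n*, the conservative all-predictors intersection).

## Composition enrichment

Enrichment of a query set against a background set is
`(Cq − Cb)/Cb` per amino acid on pooled compositions (X excluded).
Uncertainty comes from a protein-level bootstrap — proteins, not residues,
are the exchangeable unit, because residues within one protein are not
independent — with both sets resampled with replacement independently, B ≥
100 replicates (default 1000). The CI is the empirical (α/2, 1 − α/2)
quantile interval. The two-sided p-value is the Monte-Carlo sign test
`p = 2·(min(#{rep ≤ 0}, #{rep ≥ 0}) + 1)/(B + 1)`, clipped to
[2/(B+1), 1]; the add-one numerator is the standard finite-B correction,
without which the test measures ~5.5% null rejection at α = 0.05 (measured
at 50 proteins × 300 residues per set, B = 500) instead of the ~5.0%
achieved with it. Amino acids with zero background fraction are reported
as undefined (NaN), never divided. No multiple-testing correction is
applied by default (20 comparisons, reported as a panel); a Bonferroni
flag is available. One seeded NumPy generator (PCG64) drives all
replicates in fixed order, so reports are bit-reproducible.

## Proteome statistics

* **Theoretical pI** — pH of zero net charge under the
  Henderson–Hasselbalch sum over the termini and ionizable side chains
  (D, E, C, Y acidic; K, R, H basic), found by bisection on [0, 14] until
  the bracket is below 1e-9 pH units (≤ 60 halvings), leaving |charge|
  well under 1e-4. The default pKa table is a Bjellqvist-style set shipped
  as editable YAML — the table is data, not code.
* **Molecular weight** — sum of average residue masses plus one water;
  X contributes the mean of the 20 canonical residue masses by default
  (configurable).
* **DR–length regression** — least squares of disordered-residue count on
  protein length, with intercept by default; a through-origin flag fits
  DR = a·L with R² against the uncentred total sum of squares. DR values
  reconstructed from percent disorder are rounded to whole residues first.
* **Yields and frequency tables** — treatment yields as
  100·treated/control; category frequencies over compartment codes
  (C/M/O, one count per protein) or GO terms (multi-label, so percents may
  sum past 100). Report percents are rounded half-up to one decimal; raw
  values are retained in JSON outputs.

## Synthetic proteomes

`synthetic.generate` draws, per protein: a length, a region count, region
lengths (all uniform over configured inclusive ranges), and uniform
placements accepted only when regions are non-overlapping and separated by
at least one backbone residue (rejection sampling, capped at 1000 tries —
the shipped designs keep total region mass well under protein length so
the cap is unreachable for valid specs). Region residues are i.i.d. from
the disordered composition, the backbone from the ordered composition.
Ground truth is exact by construction, and the non-adjacency rule makes
the truth LDR equal the longest planted region.

The default design (`data/disorder_biased.yaml`): 150 proteins, lengths
U(200, 600), 1–2 regions of U(30, 80) residues, giving ≈ 20–25% mean
planted disorder — the level reported for heat-enriched IDP fractions.
Its disordered composition is enriched in E, K, G, A, S, P and depleted in
C, W, F, Y, I, L, V, the canonical disorder bias; the ordered composition
is a hydrophobic-leaning globular profile. The generator emulates
composition-biased disorder only: it does not model real features such as
sequence repeats, domain architecture, secondary-structure signals,
post-translational modification, or mass-spectrometry sampling (PSM
counts and partial-sequence flags are consumed as annotations, never
simulated). Validation on these proteomes therefore demonstrates that the
pipeline recovers composition-driven disorder signal, not that any
predictor is accurate on real proteomes.

## Numerical and design choices

* Sliding-window sums use cumulative sums; scores equal a direct-loop
  evaluation to < 1e-9, enforced by oracle tests.
* Report rounding is half-up (`decimal`), avoiding banker's-rounding
  surprises in printed percents.
* `filter_records` treats missing PSM as +∞ and missing partial flags as
  full-length, so the MS-level filters act only on explicit annotations.
* Records with duplicate ids are rejected at parse time; ids are otherwise
  opaque.
* Validation problem sizes (150-protein proteomes, 200-pair calibration,
  1000-sequence oracle sweeps) were chosen so the full suite completes in
  well under a minute while keeping Monte-Carlo intervals tight.

## Known limitations

* The two built-in predictors are deliberately simple, self-contained
  models of their families; neither is a re-implementation of any
  published server's exact parameterization, and default windows and
  thresholds are declared conventions, not fitted values.
* Percentile bootstrap CIs at small set sizes (tens of proteins) retain
  some small-sample coverage error even with the add-one p-value.
* The charge–hydropathy model smears region boundaries by roughly half a
  window, so its residue-level sensitivity drops for regions much shorter
  than the window; the protein-level extended criterion compensates.
* Through-origin and with-intercept regressions can differ materially on
  real DR–length clouds; both are exposed because which model a given
  reported slope used is often unstated.
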
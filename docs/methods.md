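# Methods

## The measurement being modeled

Pulse SILAC distinguishes newly synthesized protein (medium-heavy or heavy
arginine/lysine) from pre-existing protein (light) by mass shift. When two
conditions are labeled with different isotope sets and pooled, the H/M
intensity ratio of a peptide reads out the ratio of new-protein production
between the conditions; a label swap across replicates cancels
label-specific bias. In the pulse-chase variant a short heavy pulse is
chased into medium label, so loss of the H cohort relative to the
pre-existing L pool reads out degradation of newly synthesized protein.
`mitopulse` implements the computational stages of such an experiment and
a generative simulator so that every stage can be validated against known
ground truth without access to raw mass-spectrometry data.

## In-silico digestion

Cleavage rules: trypsin after K/R, lysC after K, chymotrypsin after
F/W/Y; a protease set cuts at the union of sites. The proline rule
(suppression of a cut when the next residue is proline) defaults to on
for trypsin and chymotrypsin and never applies to lysC; it is a flag
because conventions differ across search engines. Chymotrypsin is
deliberately restricted to the aromatic residues — in a SILAC context the
labels ride on essential amino acids, which is the reason this protease
is interesting for membrane proteins — and does not model the weaker
L/M cleavage. With `m` missed cleavages the digestion products are all
runs of up to `m + 1` adjacent fully cleaved fragments; with `m = 0` they
partition the sequence (tested exhaustively against a brute-force
oracle). "Theoretically observable" means a fully specific product of
6–30 residues with 0 missed cleavages; that convention makes the
observable count the iBAQ divisor and reproduces the MT-ND4L arithmetic
(one arginine → fragments of 23 and 75 residues → one observable
peptide). Missed cleavages remain available as a parameter where a user
wants the search-engine-style enumeration. Initiator methionine is not
removed; coordinates are 1-based inclusive; residues outside the 20
canonical amino acids are rejected with position information rather than
silently skipped.

## Turnover model and simulator

Each protein follows first-order kinetics `dX/dt = s(t) − k_d(t) X` with
synthesis rate `s` (intensity units/h) and degradation rate `k_d` (/h);
the pre-pulse pool starts at steady state `A0 = s/k_d`. The drug is two
orthogonal knobs: `f ≥ 0` multiplies synthesis (direct translational
inhibition), and `g ≥ 1` multiplies the degradation rate of newly made
cohorts (the orphan-subunit effect — unassembled subunits are degraded,
assembled ones are not). Closed forms:

- pSILAC (pre-label `t1 = 8 h` without drug, then `t2 = 16 h` with drug
  or vehicle; `f' = f`, `k' = g·k_d` under drug):
  `L = A0·e^(−k_d t1 − k' t2)`,
  `New = (s/k_d)(1 − e^(−k_d t1))·e^(−k' t2) + (s f'/k')(1 − e^(−k' t2))`.
  The new cohort is reported in H or M per the replicate's label
  assignment; channel L pools both dishes' pre-existing protein.
- pulse-chase (pulse `4 h`, chase `4 h`):
  `H = (s/k_d)(1 − e^(−k_d·4))·e^(−k'·4)`, `M = (s f'/k')(1 − e^(−k'·4))`,
  `L = A0·e^(−k_d·8)` — the pre-existing pool always decays at baseline
  `k_d` in this design (assembled proteins are not orphaned). MG132
  co-treatment is modeled as `g → 1` with `f` retained (proteasome
  blockade rescues degradation but not the synthesis block).

Both closed forms are validated against piecewise ODE quadrature to
1e-6 relative over a broad parameter grid.

Peptide-level evidence: intensity = channel amount × a log-normal
peptide ionization factor (σ default 1.0, shared across the three
channels of a peptide, so within-peptide ratios are noise-free — the
SILAC ratio principle) × independent log-normal channel noise (σ default
0.2) × a per-channel mixing-bias factor. Each channel measurement is
dropped with probability `expit(−slope·(log10 I − midpoint))` (defaults
slope 2 per decade, midpoint 10⁴), i.e. missingness is channel-wise and
intensity-dependent; at the default abundance distribution roughly a
tenth of channel measurements drop. All randomness flows from a single
seed.

The packaged pSILAC scenario fixes the study conditions used throughout
the tests: 1000 proteins, 2 label-swapped replicates; 13
"mitochondrially encoded" proteins with `f = 0.05`; 50 planted effects
with `f = 0.25`; all others null. Degradation rates are log-normal
around 0.02/h (≈ 35 h half-life, a typical mammalian median) with 0.6
natural-log spread; steady-state abundances are log-normal around 10⁶
with 1.5 spread so that dropout acts on a realistic dynamic range.
Protein sequences are random with human-like residue composition
(~11% K+R), digested with lysC+trypsin. The chase scenario uses 20
orphans (`g = 3`, `f = 0.3`) against 40 stable proteins.

What the simulator does **not** emulate: spectrum-level effects (isotope
envelope overlap, co-elution interference — the known failure mode for
one MT subunit in real data), growth dilution, protein-group ambiguity,
or peptide-level identity errors. Passing tests therefore demonstrate
correctness of the quantification and inference machinery under the
stated noise model, not robustness to identification artifacts.

## Quantification and moderated statistics

Peptide ratios use only rows with both channels present and positive
(exclusions tallied); orientation is per replicate (`cap_channel` "H" or
"M"), which makes label-swap correction a relabeling, with an invariance
test. Protein-level ratio = median of peptide log2 ratios (robust to
the heavy-tailed peptide factors; the exact aggregation used by common
search engines is not public, so the median is this package's choice).
Proteins must be quantified in **all** replicates; no imputation.
Normalization is per-replicate median-centering — the purpose is to
remove the global shift from unequal lysate mixing, which a location
correction achieves exactly and idempotently. An affine-arcsinh
transform (`arcsinh_stabilize`) is provided as a documented
approximation of calibrated variance-stabilizing transforms for users
who want to stabilize raw intensities before ratio formation; it is not
part of the default path, which operates on log ratios.

The test is a one-sample moderated t on the per-protein mean log2 ratio
across `n` replicates (`d = n − 1`). The variance prior is fit by
moment matching on the log scale: `e_i = log s_i² − ψ(d_i/2) +
log(d_i/2)` has mean `log σ_i²` and sampling variance `ψ'(d_i/2)`;
under a scaled inverse-χ² prior, `mean(e) = log s0² + ψ(d0/2) −
log(d0/2)` and `var(e) = mean ψ'(d_i/2) + ψ'(d0/2)`, inverted for `d0`
by Newton iteration on the trigamma function. When the observed spread
of log variances does not exceed its sampling floor the prior collapses
to `d0 = ∞` with the bias-corrected geometric-mean pooled variance — the
common outcome at n = 2 replicates, where per-protein variances carry a
single degree of freedom. Parameter recovery is verified by simulation
(5000 proteins, `d0 = 4`, `s0² = 0.04`, `d_i = 4` — a realistic
small-replicate setting chosen for the recovery experiment); the
`d0 = 0` limit reproduces the ordinary t-test. Two-sided p-values on
`d0 + d` df (normal when infinite); BH across all tested proteins.

## Pulse-chase inference

Per condition, protein-level H/L and M/L log2 ratios are medians over
peptides; each condition is median-centered by default (flagged: chase
ratios share one lysate, so this correction is a convention, not a
necessity). Scores are drug-minus-vehicle differences of these log2
ratios; in the noiseless model the degradation score equals
`−k_d(g−1)·t_chase/ln 2`, which the tests pin (e.g. `g = 2`,
`k_d = 0.1/h`, 4 h → −0.577). Classification uses the **pSILAC**
experiment's mean log2 H/M with an inclusive boundary: ≥ −0.5 unchanged,
< −0.5 CAP-sensitive, missing → unassigned. The group comparison is a
one-sided Wilcoxon rank-sum test (sensitive < unchanged), exact when the
combined sample is ≤ 12 without ties, otherwise normal approximation
with tie and continuity corrections; the exact branch is verified
against full enumeration of rank assignments, and the comparison's
type-I error under a null simulation (g = 1 everywhere) is checked over
200 seeds.

## Complexes, modules, enrichment

The packaged annotation pins the denominators 45/4/11/21/17 for CI–CV
and 13 mitochondrially encoded subunits. Module labels are
complex-qualified (e.g. "CIII subcomplex 1", "CV step 1") so that a
module resolves to exactly one complex — a validated invariant.
Memberships that are not firmly established (subunit isoforms, the
UQCRFS1-derived small subunit, NDUFA4's complex assignment, c-ring step
placement) are flagged `uncertain=1` rather than silently asserted; the
header of the fixture documents this. Category summaries partition
proteins into MT-encoded OXPHOS / nuclear OXPHOS / nuclear
mitochondrial / nuclear non-mitochondrial, with mitochondrial
localization of non-OXPHOS proteins taken from an optional
`localization` column. Cross-experiment agreement is the Pearson
correlation of mean log2 fold changes over shared proteins per category
(≥ 3 shared proteins, otherwise skipped with a warning).

Enrichment is the plain one-sided hypergeometric test, `P[X ≥ k]` for
`X ~ HG(N, m, K)`, with BH adjustment — a deliberate substitution for
web-service GO tools, whose modified scores and term graphs are out of
scope. The documented background convention is the set of proteins
quantified in all protocols under comparison.

## Numerical and I/O conventions

Tables are UTF-8 TSV with a single header row and `#` comments; writes
are atomic (temp file + rename); output headers carry version, seed and
config hash, and identical configurations produce bit-identical outputs.
Missing intensities are empty cells, never zeros; a stored 0 is read as
missing only under the MaxQuant column dialect, matching that tool's
convention. Degenerate cases: zero posterior variance yields the
smallest positive float as p-value with a warning; iBAQ with zero
observable peptides is NaN (undefined, not an error); non-positive
ratios give missing scores with a QC tally.

## Problem sizes

The default test and acceptance runs use the packaged scenario sizes
stated above (1000-protein screen, 60-protein chase, 200-seed null
calibration, 5000-variance prior recovery, exhaustive small-table checks
for the exact statistics). These sizes were chosen so the full
simulation-based validation remains quick on a laptop while keeping
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

Single-timepoint designs only — no per-protein `k_d` fitting from
multi-timepoint dynamic SILAC, and no absolute half-life estimation.
No protein-group inference or PSM-level FDR modeling. The chase
normalization convention (median-centering per condition) is applied
uniformly and flagged; users with spike-in calibration should disable
it. The annotation fixture is a curated stand-in whose uncertain entries
are flagged, not resolved.
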
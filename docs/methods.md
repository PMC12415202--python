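# Methods

This note documents the models, estimators, default parameters and design
choices behind each module, what the synthetic-data generators do and do not
emulate, and the package's known limitations.

## Thermal shift analysis (`thermoshift`)

Model. Melt curves are treated as two-state unfolding with linear
pre- and post-transition baselines:
F(T) = B_f(T) + (B_u(T) − B_f(T)) / (1 + exp((T_m − T)/w)), with the
transition width w in °C. Real melt curves can deviate from two-state
behaviour (aggregation, multi-domain transitions); no multi-transition
deconvolution is attempted.

Estimators. `boltzmann_fit` (default) fits the full six-parameter model by
Levenberg–Marquardt-style least squares, initialised from the derivative
maximum; it falls back to `derivative_max` if the fit does not converge.
`derivative_max` takes the maximum of dF/dT after a centered moving average
whose window is max(5 points, 1 °C) — chosen to be robust on 0.5 °C-step
plate reads. A curve is unusable when its transition amplitude is below 3×
the residual noise (no real transition) or the estimated T_m falls outside
the scanned range.

Hit calling. ΔT_m = T_m(+ligand) − T_m(reference) per replicate; a
(domain, ligand) pair is a hit when the replicate mean is ≥ 2.0 °C
(inclusive — the cutoff convention here treats the threshold itself as
significant). Strong negative shifts (≤ −2 °C) are flagged destabilising
but never count as hits, since binding of the ligands of interest
stabilises the folded state. Means and SDs are taken over biological
replicates; the reported p-value (two-sample t-test of replicate T_m values
against the reference wells) is descriptive and never gates the hit
decision. Whether every replicate individually must clear the cutoff is a
judgment call; this implementation applies the rule to the replicate mean.

## One-site ITC (`itcfit`)

Forward model. Concentrations after the i-th injection follow the standard
overflow-cell (perfusion displacement) bookkeeping:
[M]_i = M₀(1 − v_i/2V₀)/(1 + v_i/2V₀), [X]_i = X_syr(v_i/V₀)/(1 + v_i/2V₀)
with v_i the cumulative injected volume. The bound fraction is the physical
root of the one-site quadratic, cumulative heat Q_i = nΘ_i[M]_iΔH·V₀, and
per-injection heats add back the heat carried out with the displaced
volume. Inputs are integrated heats (µcal, or µJ via the unit flag); raw
power traces are out of scope.

Fitting. Nonlinear least squares over (n, log₁₀K_D, ΔH, q_offset), uniform
weights, multi-start over log-spaced K_D initial values, with the first
injection excluded by default. q_offset absorbs residual dilution heat.
Confidence intervals come from the Gauss–Newton covariance; the K_D
interval uses the delta method on the log parameter. The best finite-cost
solution is kept even when the optimizer stops on its evaluation budget —
in shallow titrations the (n, ΔH) valley is genuinely flat, and that
flatness is reported through the `low_information` flag (c = n·M₀/K_D
outside [0.1, 1000]) and wide intervals rather than by discarding the fit.
For such shallow experiments `fix_n` pins the stoichiometry to a known
value, the standard remedy.

Precision. At 5% heat noise the attainable K_D precision is design-limited:
a Cramér–Rao analysis shows uniform injection schedules cannot reach a
median relative error below ~18–29% in a single titration, whereas a ramped
schedule (small injections through the transition, larger toward
saturation) spreads the signal and reaches ~15%; averaging log-K_D over
triplicate titrations — the normal practice when reporting binding
constants — brings the median error to ~9–12%. The test suite asserts the
triplicate-averaged figure.

Independence test. Two pockets are called independent when K_D fitted after
presaturation with the second ligand agrees with the unperturbed K_D: 95%
intervals overlap and the ratio lies within 3-fold. The 3-fold band
operationalises a qualitative "no apparent impact" conclusion; shared-site
competition at the simulated conditions inflates the apparent K_D ~21-fold
and is detected essentially always. Simulated study conditions: 200 µL
cell, 50 µM protein, 1 mM titrant, 25×2 µL injections, 0.1 µcal heat noise.

## Sequence classification (`seqscan`)

Procedure. (1) Align the query to every packaged reference with
BLOSUM62, affine gaps (open 11, extend 1), local mode; identity is counted
as identical aligned pairs over the shorter sequence length, so flanking
sequence outside the domain does not dilute it. Queries whose best identity
falls below 0.20 get no family. (2) Map each motif's reference-numbered
pocket positions onto the query through the alignment (deletions yield an
explicit GAP). (3) A motif matches when all required positions hold allowed
residues; determinant rules then resolve sub-specificity (sCache_2
position 114: L → L-lactate, H → pyruvate). Bimodular dCache queries are
evaluated independently per module and can carry two calls (e.g. distal
uracil + proximal SCFA). Confidence is the matched fraction of
required+determinant positions; ties between matching motifs break by
confidence, then alignment score.

Reference scaffolds. Full-length sequences of the experimentally
characterised domains are not redistributed; the packaged references are
synthetic scaffolds that carry the documented pocket residues at the
documented residue numbering (all dCache_1 family references share one
scaffold backbone, mirroring the fact that these families align well).
Consequences: classification of real sequences should supply real
references via `MotifLibrary.from_files`; the packaged library is faithful
for pocket-position logic and for testing, not a curated alignment
database. Motif entries whose residue identities are not printed in the
main source (amine/amino-acid/purine distal sets, formate positions) are
placeholders stamped `provenance` accordingly in `motifs.json` and can be
edited without code changes.

## Contact geometry (`structcontacts`)

Hydrogen bonds are distance-only contacts between polar heavy atoms (N, O)
at ≤ 3.5 Å — no angle term and no hydrogen placement, matching how
donor–acceptor distances are quoted for high-resolution structures. A water
mediates when its oxygen is within the same cutoff of both ligand and
protein polar atoms. π-stacking is ring-centroid distance ≤ 4.5 Å with no
interplanar-angle filter; tryptophan is measured on both rings and the
nearer is reported. Ligand ring atoms come from a packaged template table
(uracil shipped; extensible). All cutoffs are arguments. Geometry is
invariant under rigid-body motion and atom order by construction.

The packaged site model (`synthsite`) is a labelled synthetic stand-in:
only contact-relevant atoms, coordinates constructed to realise the
published coordination distances (uracil hydrogen bonds ≈2.9 Å; water
bridge 2.8/3.1/2.9/2.7 Å; stacking 3.8/3.6 Å; acetate 2.6/2.7/2.5/2.9 Å)
and the published 1.46 Å resolution record. It exercises the full parsing
and geometry path; conclusions about the deposited experimental entry
require running the same functions on the deposited file.

## Growth kinetics (`growthkin`)

μ(t) = d ln(OD)/dt via centered finite differences, then a centered
*median* filter (default window 5 points). A median filter is used instead
of a moving average deliberately: growth curves leave the lag phase through
a kink in ln(OD), and any linear smoother smears that kink across its
window, displacing the located maximum by half a window; the median filter
keeps t(μmax) within one grid step of the lag end for windows 3–7 while
still rejecting point noise. t(μmax) is the earliest time attaining the
maximum (tie rule); OD must be positive (blank subtraction is the caller's
job — non-positive values are an error, not imputed).

Condition comparison uses the classic two-tailed unpaired (pooled-variance)
t-test. With triplicate groups the Welch variant halves the degrees of
freedom and loses roughly half its power against two-hour effects at 0.1 h
replicate scatter; the pooled test is what "unpaired t test" conventionally
denotes in figure captions. Significance tiers: */**/***/**** at
0.05/0.01/0.001/0.0001. Sampling must resolve the replicate scatter:
quantization of t(μmax) to a coarse read interval destroys within-group
variance and with it the test's calibration.

## Evidence aggregation (`report`)

Evidence records carry (lbd, organism, receptor class, domain family,
ligand, ligand class, evidence level, source). Experimental evidence
(TSA hits, converged ITC fits) supersedes predictions for the same
(domain, ligand class); contradictions are kept as warnings with the
experimental record retained. The ligand-class taxonomy groups lactate,
formate, and the other short-chain fatty/carboxylic acids as "carboxylic
acid". Tallies count a domain once for "domains with assigned ligands" and
once per class for the composition (bimodular uracil+SCFA domains
contribute to two classes). The packaged curated table contains only
assignments verifiable from the main source text: ids not named there are
anonymized (sc2-a/b/c, sc33-a) and organism attribution is left blank
except where stated; the full interaction inventory lives in supplementary
datasets and is out of scope.

## Synthetic data (`synthdata`)

What is emulated: two-state melts with linear baselines; one-site and
two-independent-site ITC heat series under arbitrary injection schedules;
shared-site competition via the apparent-constant model
K_D,app = K_D(1 + [B]/K_D(B)); family scaffolds with pocket residues
planted at reference numbering and i.i.d. background mutations;
three-phase (lag → logistic → saturation) growth with t(μmax) = lag end by
construction. Noise is Gaussian and homoscedastic everywhere; a single
seeded generator per call, no global state.

What is not emulated: instrument drift and plate-position effects,
non-two-state melts, heteroscedastic or correlated ITC noise, first-
injection artifacts, indel-containing sequence divergence, diauxic or
Baranyi-type growth. Passing round-trip tests therefore demonstrates
estimator correctness under the stated models, not robustness to every
artifact of real instruments.

Problem sizes in tests and the acceptance script (100 melt curves, 100
independence seeds, 50 triplicate noisy fits, 20–25 sequences per planted
family, 25 growth curves) are chosen to give stable medians and rates on a
single CPU in seconds to a couple of minutes.

## Known limitations

- Quantities that require supplementary datasets, genome inventories or raw
  instrument data — the fraction of Cache-type chemoreceptors covered,
  absolute K_D values of real domains, the D-/L-lactate affinity ratio, and
  growth effects of specific metabolites on *Roseburia* strains — are not
  reproduced here; the property-based suites cover the corresponding
  machinery instead.
- The classifier's accuracy on real (non-scaffold) sequences depends on
  user-supplied references and motif curation.
- The independence verdict is a heuristic band on K_D ratios, not a formal
  model comparison.
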
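# Methods

## Trophic position and marine fraction from amino acid δ¹⁵N

The nitrogen model treats the consumer's glutamic acid / phenylalanine
δ¹⁵N difference as the sum of a producer-level offset (β) and a
per-trophic-step enrichment (Δ_glu-phe):

* `TP = (δ¹⁵N_glu − δ¹⁵N_phe + β) / Δ_glu-phe + 1` with
  β_marine = −3.4 ‰ for aquatic photoautotrophs and
  β_terrestrial = +8.4 ‰ for C3 vascular plants;
* under a mixed diet the producer offset is the f-weighted combination
  `(1 − f)·β_terrestrial + f·β_marine` of the two baselines;
* Δ_glu-phe defaults to 7.6 ‰ (mammalian collagen).  C4 baselines are out
  of scope (the model targets C3-dominated agricultural systems).

Assumptions: phenylalanine δ¹⁵N passes from diet to collagen without
fractionation; glutamic acid enrichment per step is constant across the
food web; marine and terrestrial protein mix linearly in nitrogen supply.

Two estimators of the marine protein fraction are exposed:

* **HTL-constrained** — invert the mixed-diet equation at an assumed human
  trophic level (default 2.21; empirical global range 2.04–2.76).  Depends
  only on measured consumer values and the β constants.
* **Phenylalanine mass balance** — two-source mixing of consumer δ¹⁵N_phe
  between a terrestrial and a marine baseline end member (defaults
  22.7 ± 0.9 ‰, an archaeological wetland reed representing crops grown in
  manipulated soil, and 0.4 ± 0.6 ‰, the lowest measured fish).  The
  end-member inversion uses the fish *average* 1.0 ‰ instead; both marine
  values are configuration, as is the 0.41 ‰ variant used in the
  radiocarbon presets.

The two estimators are algebraically consistent: setting the terrestrial
end member to the mass-balance inversion of the HTL solution reproduces
the HTL fraction exactly (a tested round-trip identity).

A sensitivity sweep evaluates f and TP_mixed over a grid of candidate
terrestrial end members, flagging grid points that violate mass balance
(f outside [0, 1]) and points where the rat trophic position falls below
2.0 — rats are partly faunivorous, so baselines implying rat TP < 2 are
rejected.

## Error propagation

All reported SDs are first-order (delta-method) propagation treating
inputs as independent; measurement SDs, end-member SDs and (optionally)
constant SDs all enter.  Partial derivatives are written out in each
estimator.  The contract is pinned by 10⁶-draw Monte-Carlo equivalence
tests (2 % relative) at the study measurement scales.

Validity regime: the two-source fraction is a ratio whose denominator is
the end-member separation.  When end-member SDs are an appreciable
fraction of that separation (roughly above ~10 %), the ratio distribution
becomes heavy-tailed — its exact variance is not finite — and *no*
first-order formula can match a raw Monte-Carlo SD; the delta-method value
then describes the central spread only approximately.  This matters for
the bulk δ¹³C configuration (separation 9.2 ‰, end-member SDs 2.0/1.5 ‰),
where the quoted SD should be read as a local linearization, and is
negligible for the phenylalanine configuration (separation 22.3 ‰, SDs
≤ 0.9 ‰).

Constant uncertainties (σ_β, σ_Δ) default to zero and are included only
when supplied, since no published values exist for them.

## Bulk collagen δ¹³C mixing

A plug-in linear two-source model on the collagen scale.  Plant-tissue end
members are shifted by the conventional +5 ‰ diet-to-collagen enrichment
(configurable; the true value varies with diet composition — a known
limitation).  Era-dependent Suess corrections are applied as explicit
user-supplied offsets rather than a built-in year model, since analyses
typically need only one or two fixed values (+0.5 ‰, +1.4 ‰ for
mid-20th-century reference material).  End-member uncertainty enters only
the SD, never the point estimate.  Fractions outside [0, 1] are returned
and flagged infeasible, never clamped: they are evidence against the
chosen end members.  Population summaries (mean/min/max) are computed over
feasible samples, with infeasible ids listed.

## EAA δ¹³C fingerprinting and Bayesian mixing

Centered essential-amino-acid δ¹³C patterns (each sample's Leu/Lys/Phe/Val
values minus their mean) fingerprint protein sources independent of
absolute baselines.  PCA (scikit-learn) ordinates the training set; group
assignment is an explicit user input, never automatic, because visual
cluster membership is a judgement call.  Component signs are fixed by
making each loading's largest-magnitude element positive; the centering
constraint removes one degree of freedom, so one component is dropped with
a warning.

The mixing model: source proportions **p** get a flat Dirichlet prior;
each used EAA's centered value is `Normal(Σ_i p_i μ_ik, σ_k²)` with
`σ_k² = consumer analytical variance + Σ_i p_i² s_ik² + model-error
variance`.  The model error defaults to 0.4 ‰ (the analytical replicate
scale) and absorbs routing and preservation effects the likelihood does
not model.  Lysine participates in centering and PCA but is excluded from
the default likelihood as the least source-diagnostic EAA.  Sampling is
random-walk Metropolis in additive-log-ratio coordinates (logistic-normal
proposals), 4 parallel chains, step size adapted toward ~30 % acceptance
during burn-in only; convergence is monitored by split R-hat (threshold
1.05) with a crude initial-positive-sequence ESS.  A fixed seed gives
bit-identical results; non-convergence flags the result rather than
failing silently.

Identifiability: with four sources observed through three centered EAAs
the posterior is only weakly identified — a consumer sitting exactly on
one source's mean is assigned ~0.65–0.8 to that source, not ~1.0, and
near-duplicate sources are identified only through their sum.  Credible
intervals remain well calibrated (coverage-tested); point proportions
should be read with their SDs.

## Radiocarbon calibration

Curves follow the IntCal file convention and are linearly interpolated to
a 1-year calendar grid.  The diet-weighted curve is
`μ_mix = (1 − f)·μ_atm + f·(μ_mar + ΔR)` with variance
`(1 − f)²σ_atm² + f²(σ_mar² + σ_ΔR²) + (μ_mar + ΔR − μ_atm)²·σ_f²`;
ΔR is applied to the marine mean before mixing (the usual mixed-curve
convention; default −83 ± 34 ¹⁴C yr).  σ_f defaults to 0, matching
point-f practice.  The calendar-age posterior is the Gaussian likelihood
`exp(−(age − μ(θ))² / 2(σ_age² + σ(θ)²))` normalized over the grid
(uniform calendar prior); intervals are greedy highest-posterior-density
sets of grid years merged into runs, reported as AD = 1950 − cal BP.
Posterior mass > 0.1 % at a grid edge flags truncation.  `f = 0` is
special-cased to return the atmospheric values unchanged so the
terrestrial limit is bit-exact.  No sequence/phase modelling is provided,
and no curve products are bundled.

## Synthetic food web

The generator runs the forward model at known truths: consumer
δ¹⁵N_phe = f·marine + (1 − f)·terrestrial end-member means, glutamic acid
set so the mixed-diet equation holds at (f_true, tp_true), then
independent Gaussian analytical noise (0.41 ‰ nitrogen, 0.38 ‰ carbon —
the observed replicate scales).  Default conditions mirror the study:
terrestrial phe 22.7 ± 0.9 ‰, marine phe 0.4 ± 0.6 ‰, f = 0.5 consumers,
tp_true drawn uniformly over the empirical human range 2.04–2.76.  EAA
training data are four sum-to-zero cluster means (two marine, two plant,
pairwise separations 3.5–6.4 ‰, several times the analytical SD) plus
noise, re-centered; consumers are convex combinations of cluster means
(default mixture ≈ 0.38/0.16/0.25/0.21, a marine-leaning omnivore).
Bulk values mix collagen-basis end members linearly with 0.8 ‰ noise; the
δ¹⁵N end members (12.9/17.5 ‰) exist only for plotting parity.  Synthetic
calibration curves are smooth invented functions (linear trend plus
sinusoid, constant marine offset +400 ¹⁴C yr) covering 0–2500 cal BP.

What the generator does **not** emulate: covariance between amino acids
(only per-AA replicate SDs are published), diagenesis, inter-individual
end-member variation, soil biogeochemistry (only its end-member
consequences), and real curve wiggle structure.  Passing tests therefore
demonstrate algebraic self-consistency, correct uncertainty calibration
under the stated noise model, and correct code — not robustness to
baseline misspecification in real material, which remains the analyst's
responsibility via the sensitivity sweep.

## Numerical and design choices

* C:N QC interval is closed, [2.9, 3.6]; samples without C:N (plants,
  soils) pass with a warning since collagen QC does not apply to them.
* Inter-laboratory δ¹³C offsets (Leu −0.86, Lys −0.32, Phe −3.75,
  Val −0.76 ‰) are *added* by default, with a `subtract` switch; a
  provenance flag makes double application an error.
* The derivatization correction `(δ_CSIA − (1 − X)·δ_ISO)/X` is the exact
  algebraic inverse of the forward carbon mixture, property-tested over X.
* Report tables round half-even to 2 decimals; full-precision CSVs are
  always written alongside.  The human δ¹⁵N_phe average is 11.5 ‰ in the
  full-suite table context and 11.6 ‰ in the mass-balance context; both
  constants are exposed and used where each applies.
* Test and acceptance problem sizes (200-consumer recovery runs, 100
  coverage replicates at 2000 MCMC steps, 10⁶-draw Monte Carlo) were
  chosen to hold estimator bias and coverage statistics to well under
  their assertion margins while keeping the suite fast.
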
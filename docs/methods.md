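# Methods

This note documents the models implemented in `dvhrad`, the choices
made where conventions are genuinely open, and what the synthetic
cohort does and does not emulate.

## DVH representation and dose metrics

A cumulative DVH is stored as a strictly increasing dose grid starting
at 0 Gy with the absolute volume (cm³) receiving at least each dose;
bins are half-open `[edge_i, edge_{i+1})` with cumulative volume
defined at the left edges. Files may carry volumes in percent of the
declared structure total; they are converted to cm³ on input, because
the TCP model needs absolute volume (clonogen count) while NTCP models
need fractions — both are then derivable.

Before any model evaluation the curve is resampled to a uniform
0.05 Gy grid (linear interpolation of volume against dose), comparable
to a planning system's export resolution. This makes gEUD/TCP
integrals insensitive to the input file's binning; a convergence test
verifies that mean-dose errors shrink monotonically with bin width and
are < 0.02 Gy at 0.025 Gy. The export bin width is otherwise a free
parameter of whoever produced the file.

Differentiation places each bin's volume at the interval midpoint
(symmetric, converges under grid refinement). Residual volume at the
last edge becomes a terminal bin at that edge so total volume is
conserved exactly. D_x% uses linear interpolation of dose against
cumulative volume — the standard planning-system convention — and on
plateaus returns the highest dose carrying the requested volume, so a
uniform-dose structure returns its plateau dose for every x.

## Fractionation (EQD2/LQED2)

Each dose edge D is mapped to `D (d + α/β)/(2 + α/β)` with per-fraction
dose `d = D/N`. In a simultaneous-integrated-boost plan every structure
is irradiated in all N = 33 fractions with spatially varying fraction
size, so `d = D/N` per bin is the natural reading. The map is strictly
increasing for α/β > 0, hence the output is again a valid cumulative
curve; volumes are untouched.

Defaults: α/β = 3 Gy for organs at risk, N = 33. The correction is
applied to OAR DVHs before LKB evaluation. The target DVH is *not*
EQD2-corrected for TCP: the LQ survival exponent already carries the
fraction-size dependence with the tumor's own α/β = 10 Gy. Mean doses
fed to the logistic models use physical dose by default — the source
models were fitted to conventionally fractionated physical doses — but
`AnalysisConfig.eqd2_logistic_means` switches this, since the
convention is not universal.

## LKB NTCP

Pipeline: resample → EQD2 → differential → gEUD → probit.

* gEUD is computed in log space (`n` as small as 0.07 raises 70 Gy
  doses to the ~14th power; `exp(n·logsumexp(log w + log D / n))` is
  exact to rounding and overflow-safe). Zero-dose bins contribute
  nothing to the power sum but stay in the normalizing volume.
* The probit is the erf-based standard normal CDF, not quadrature.
* The larynx volume exponent 1.17 > 1 (a sub-linear volume effect) is
  accepted as published, without clamping.
* The registry ships parotid (two parameterizations with very
  different slopes: m = 0.18 vs 0.45 — the steeper one is more
  dose-sensitive by construction, which the tests verify at D₅₀),
  mandible, larynx and spinal cord rows. The cord triple equals the
  mandible triple in the source table; it is implemented as printed,
  though other cord parameterizations exist in the literature. With
  it, any cord kept below 46 Gy physical dose maps to gEUD far below
  D₅₀ = 72 Gy and a reported risk of exactly zero.
* Reported probabilities follow the clinical convention that values
  below 0.1% are zero; raw probabilities are always retained alongside.

Parotid NTCP is evaluated on the combined left+right gland DVH (summed
volumes on a common grid), matching how the source models were fitted.

## Logistic NTCP

`NTCP = (1 + e^(−S))⁻¹` with S linear in named covariates: thyroid
(Dmean in Gy, gland volume in cm³ — taken from the DVH total unless a
covariate overrides it) and the two swallowing models (superior
pharyngeal constrictor and supraglottic larynx mean doses; the
solid-food model adds age). The published solid-food age coefficient
(0.795 per unit) produces a saturated probability when age is entered
in years, which suggests the source used a categorical age term; the
package defaults to the coefficient exactly as published and offers
`age_as_indicator` (age ≥ 65 → 1) as the alternative reading.

## Poisson-LQ TCP

`TCP = exp(−Σ ρ vᵢ SFᵢ)`, `SFᵢ = exp(−α Dᵢ (1 + dᵢ/(α/β)))`, α = 0.33
Gy⁻¹, α/β = 10 Gy, ρ = 10⁷ cells/cm³, N = 33. Survivor terms are
accumulated from log-space exponents; the bin-level kernel
(`tcp_from_bins`) matches the closed single-bin form to 1e−12 relative
and is invariant under splitting bins at identical dose. Clonogens are
uniformly distributed over the absolute target volume; no inter-patient
radiosensitivity heterogeneity (σ_α = 0), repopulation or hypoxia. At
these parameters TCP is dominated by the coldest few cm³ of the target:
a uniform 69.96 Gy would give TCP ≈ 0.999, and realistic 75–90% values
arise only from small cold sub-volumes (see the generator below).

## Paired cohort statistics

Per endpoint and arm: median [min, max]; per-patient Δ% = 100(A−B)/A
(one fixed sign convention — B lower is positive). Both "median of the
per-patient Δ%" and "Δ% of the medians" are computed and labeled, since
the two phrasings differ and both appear in clinical reports.
Comparison is the two-sided Wilcoxon signed-rank test: zero differences
dropped, ties mid-ranked, exact null for ≤ 25 non-zero differences when
available, otherwise the normal approximation with continuity
correction; all-identical pairs are degenerate and report p = 1.
Shapiro–Wilk normality p-values are reported for information only — the
comparison is always nonparametric. Patients missing a structure are
excluded per endpoint, not per cohort, with the contributing count
recorded. No multiple-testing correction is applied.

## Synthetic cohort generator

The generator emulates the *statistical signature* of a 26-patient
nasopharynx SIB cohort evaluated under two dose algorithms; it does not
simulate 3-D dose transport.

* **Curve family.** Each structure's cumulative curve is an asymmetric
  logistic survival (location μ, separate widths below/above) truncated
  at a hard maximum dose and renormalized to V(0) = V_total. Template
  parameters (per-structure μ, widths, caps, volumes) were chosen so
  the recomputed D95%/D2%/Dmean medians and ranges land near published
  clinical values — e.g. high-risk-target D95 ≈ 66.8 Gy, mandible
  Dmean ≈ 47 Gy with D2 ≈ 70 Gy, cord D2 ≈ 38 Gy with maximum dose
  capped below 46 Gy.
* **Cold tail.** The high-risk target mixes in an absolute 1–2.4 cm³
  of volume spread linearly down to ≈ 41.5–44 Gy, representing
  underdosed voxels at bone/air interfaces. This is the mathematical
  prerequisite for clinically reported TCP medians (~84%) under the
  stated α and ρ; its absolute (not fractional) size reflects that an
  interface artifact scales with local anatomy, not target volume.
* **Arm-B shift.** Per structure the dose axis is contracted by a
  sampled percentage: constant for OARs; for targets affine through
  the (D95%, D2%) anchors, flat above D2% and tapering as (D/D95)²
  below D95% (the algorithm difference concentrates near the target
  periphery). Default medians/ranges follow reported per-structure
  reductions: high-risk D95% median 1.5% on support [0.1, 4.0]%
  (logit-normal, so the declared range is the exact support), D2%
  median 0.8% on [0.3, 1.8]%, OAR mean-dose medians from 0.95%
  (constrictor) to 3.4% (mandible). Low-risk-target D95% shifts are
  small and sign-mixed (their paired difference is not expected to be
  significant).
* **Coupling.** A per-patient latent "anatomical severity" drives both
  the shift size and the cold-tail depth — plans with more bone
  interface show both — which produces the reported strong positive
  rank coupling between ΔD95% and ΔTCP%.
* **Covariates.** Age ~ U(35, 72) years and thyroid volume from the
  sampled gland; these distributions are plausible ranges, not
  published values. When n = 26, three patients lack the swallowing
  structures (post-surgical anatomy), exercising the per-endpoint
  exclusion path.
* **Randomness.** One root seed; per-patient and per-structure
  substreams via `SeedSequence(seed, spawn_key=...)`, so extending the
  cohort never perturbs existing patients and cohorts are
  bit-reproducible.

**What passing tests show — and don't.** The generator reproduces
summary dose metrics, shift distributions and their couplings; it does
not reproduce spatial dose correlations between structures of one
patient, realistic DVH micro-structure, or the physics that causes
algorithm differences. Conclusions verified on it are about the
evaluation chain (metrics → models → statistics), not about any real
cohort.

## Numerical choices and degenerate inputs

* Internal grid 0.05 Gy; all integrals on midpoint differential bins.
* gEUD and TCP accumulations in log space; probit via `erf`.
* Zero-dose bins excluded from power sums; zero total volume, constant
  samples (Shapiro), all-zero paired differences (Wilcoxon p = 1) and
  a zero Δ% reference are each rejected or flagged explicitly.
* Wilcoxon falls back from the exact to the corrected normal method
  when rank ties make the exact null unavailable.
* Problem sizes: the default test and acceptance runs use the
  26-patient cohort on ~1500-point dose grids, the cohort size and
  resolution the analysis is designed around.

## Known limitations

* NTCP parameters are consumed, never fitted; no confidence intervals
  on NTCP/TCP.
* No DICOM RT parsing — the DVH-CSV dialect is the only input format.
* No relative-seriality or critical-volume NTCP models; no
  repopulation/hypoxia TCP terms.
* The cord LKB row is as published in the source table and atypically
  mandible-like; swap in alternative parameters via the registry if
  cord risk quantification matters.
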
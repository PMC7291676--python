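# dvhrad

Radiobiological evaluation of radiotherapy treatment plans from
dose–volume histograms (DVHs), built for the question a physicist faces
when a plan is recalculated with a second dose algorithm at identical
monitor units: *do the dosimetric differences matter clinically?*
`dvhrad` answers it by converting each structure's DVH into tumor
control probability (TCP) and normal-tissue complication probabilities
(NTCP) and comparing the two calculations patient by patient with
paired nonparametric statistics.

The package targets head-and-neck (nasopharynx) plans with a
simultaneous integrated boost — three nested targets at 69.96 / 59.40 /
54.45 Gy in 33 fractions and the classic organ-at-risk roster (parotids,
larynx, mandible, spinal cord, pharyngeal constrictor, supraglottic
larynx, thyroid, brainstem) — but every model is generic in its
parameters.

## Models

**Fractionation.** Organ-at-risk DVHs are corrected bin-wise to the
2 Gy/fraction equivalent (EQD2/LQED2) with the linear-quadratic model,

&nbsp;&nbsp;&nbsp;&nbsp;EQD2 = D · (d + α/β) / (2 + α/β), &nbsp; d = D/N,

with α/β = 3 Gy for late normal-tissue effects and N = 33 fractions.

**LKB NTCP.** The corrected DVH is reduced to a generalized equivalent
uniform dose, gEUD = (Σᵢ (vᵢ/V) Dᵢ^(1/n))ⁿ, and mapped through the
Lyman probit, NTCP = Φ((gEUD − D₅₀)/(m·D₅₀)). The bundled registry
carries published parameter sets for parotid xerostomia (two
parameterizations), mandible necrosis, laryngeal edema and cord
myelopathy; it is user-extensible via YAML.

**Logistic NTCP.** Mean-dose logistic models NTCP = (1 + e^(−S))⁻¹ for
hypothyroidism (thyroid Dmean and volume) and swallowing dysfunction
(constrictor and supraglottic mean doses, optionally age).

**Poisson-LQ TCP.** On the high-risk target, TCP =
exp(−Σᵢ ρ vᵢ SFᵢ) with SFᵢ = exp(−α Dᵢ (1 + dᵢ/(α/β))), α = 0.33 Gy⁻¹,
α/β = 10 Gy, clonogen density ρ = 10⁷ cm⁻³.

**Paired comparison.** Per endpoint: median [min, max] per arm,
A-referenced per-patient percentage differences Δ% = 100(A−B)/A, and
the two-sided Wilcoxon signed-rank test (Shapiro–Wilk normality is
reported alongside). NTCP values below 0.1% are reported as zero.

Because no public DVH cohort of this kind exists, `dvhrad.simulate`
generates a statistically matched synthetic stand-in: paired plan sets
whose D95%/D2%/Dmean distributions and arm-to-arm reductions follow the
values reported for clinical nasopharynx cohorts.

## Worked example

```python
from dvhrad import PairedCohortAnalysis, generate_cohort

cohort = generate_cohort(n_patients=26, seed=1)       # paired synthetic plans
results = PairedCohortAnalysis(cohort).fit()
tcp = results["tcp_ptv1"]
print(f"TCP arm A median {100*tcp.median_a:.2f}%  arm B {100*tcp.median_b:.2f}%  "
      f"p={tcp.p_value:.1e}")
print(results.summary())
```

prints

```
TCP arm A median 85.73%  arm B 83.60%  p=8.8e-06
Paired cohort comparison (arm A vs arm B)
patients: 26   Wilcoxon signed-rank, two-sided, alpha = 0.05
delta% = 100*(A-B)/A, median over patients
...
ptv1_d95                   26         66.3 [65.24,67.89]         65.22 [63.35,67.1]     1.41     <0.001  *
tcp_ptv1                   26     0.8573 [0.6484,0.9185]      0.836 [0.5551,0.9107]     2.32     <0.001  *
...
```

i.e. the recalculated arm B covers the high-risk target slightly worse
(median D95% lower by 1.4%), which translates into a TCP lower by ~2
percentage points in the median and a highly significant paired
difference — small dose differences, visible radiobiological effect.
The same table contains every OAR mean dose, D2% of the serial organs
and all eight NTCP endpoints. `dvhrad simulate|compute|compare` expose
the same workflows on the command line.

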
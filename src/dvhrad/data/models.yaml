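# Default NTCP model registry: published LKB and logistic models for
# head-and-neck organs at risk.  Users may extend the registry with a
# file of the same layout via ntcp.load_registry().
lkb:
  - organ: parotid
    endpoint: 25% xerostomia at 1 year
    source: eisbruch
    n: 1.00
    d50: 28.40
    m: 0.18
  - organ: parotid
    endpoint: 25% xerostomia at 1 year
    source: roesink
    n: 1.00
    d50: 39.00
    m: 0.45
  - organ: mandible
    endpoint: necrosis
    source: burman
    n: 0.07
    d50: 72.00
    m: 0.10
  - organ: larynx
    endpoint: grade >= 2 edema
    source: rancati
    n: 1.17
    d50: 47.30
    m: 0.23
  - organ: spinal_cord
    endpoint: myelopathy
    source: kirkpatrick_emami
    n: 0.07
    d50: 72.00
    m: 0.10
logistic:
  - organ: thyroid
    endpoint: hypothyroidism
    source: boomsma
    intercept: 0.011
    terms:
      dmean_thyroid: 0.062
      volume_thyroid: -0.19
  - organ: pcm_supraglottic
    endpoint: SWALM6
    source: christianen
    intercept: -6.09
    terms:
      dmean_pcm: 0.057
      dmean_sl: 0.057
  - organ: pcm_supraglottic
    endpoint: swallowing solid food
    source: christianen
    intercept: -6.89
    terms:
      dmean_pcm: 0.049
      dmean_sl: 0.048
      age: 0.795
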
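# Methods

## Setting and model

Each route is treated as a sample Ψ₁, …, Ψₙ from a continuous
nonnegative law; the order statistics Ψ₍₁₎ ≤ … ≤ Ψ₍ₙ₎ carry all the
information the nonparametric machinery uses. No distributional family
is assumed anywhere in the inference; the estimators are chosen
precisely because route-level PM2.5 data are heavy-tailed and
spike-contaminated, so moment-based summaries are fragile. Observations
within a route are treated as exchangeable for inference purposes —
serial correlation along the walk is a recognised limitation, noted
below.

All concentrations are mg/m3 internally; readers of µg/m3 files convert
by an exact division by 1000.

## Statistical conventions

* **Kurtosis is non-excess** (normal reference value 3) and both shape
  statistics use population central moments (divisor n) without
  small-sample bias correction; the SD uses divisor n − 1. With zero
  variance the shape statistics are reported as undefined (`None`),
  never as numbers.
* **Quartiles are Tukey hinges** throughout — including inside the
  trimean, the semi-interquartile range, and box-plot fences — for
  internal consistency: each half of the sorted sample includes the
  overall median element when n is odd.
* **Moving average**: centred window of nominal size w, clipped at the
  series ends so the output keeps the input length; boundary values
  average over the in-range part of the window. Default w = 10.
* **Empirical median interval**: McGill's notch formula
  median ± 1.57·IQR/√n. This is an approximate, normal-motivated band —
  distinct from, and not interchangeable with, the exact order-statistic
  interval.
* **Sign test ties**: observations equal to m₀ are discarded (the data
  contain exact zeros even though the model is continuous); the
  two-sided p-value 2·min{P(K ≤ k), P(K ≥ k)} is capped at 1.
* **Order-statistic interval**: the tail conditions on k' and k are
  stated on (X₍k'₎, X₍k₎); the implementation returns [X₍k'+1₎, X₍k₎],
  the standard equal-tail interval — X₍₀₎ does not exist when k' = 0,
  and the k'+1 convention is what the coverage formula
  1 − P(K ≤ k') − P(K ≥ k) describes. When even the extreme order
  statistics cannot reach the level (n = 5 at α = 0.05: P(K ≤ 0) = 1/32
  > 0.025) a `SampleTooSmallError` is raised rather than returning an
  undersized interval.
* **Rank-sum**: midranks for ties, the tie-corrected variance, a 0.5
  continuity correction, and an upper-tail normal p-value for the
  one-sided alternative "Y stochastically larger". For the six-route
  band-ordinal example this gives var(W) = 4.5 and p = 0.4068.
* **Biweight midvariance**: the canonical form — deviations centred on
  the sample median M, u_i = (Ψ_i − M)/(c·MAD), the sum restricted to
  |u_i| < 1, denominator [Σ(1−u²)(1−5u²)]². Since E[MAD] ≈ (2/3)σ for
  normal data, c = 9 discards points more than ~6 SDs out. A zero MAD
  returns zero scale (constant-in-the-middle data have no robust
  dispersion) rather than an error.
* **Subrange estimator C_nα**: with h = ⌊αn⌋ + 1, the raw statistic is
  the minimum of Ψ₍i+h₎ − Ψ₍i₎ over **all** start indices i = 1…n−h
  (not only the lower half; this reading makes C_nα reduce to the LMS
  construction as α → 0.5, up to the normaliser), divided by
  Φ⁻¹(0.75) − Φ⁻¹(0.75−α).
* **MAD is unscaled** — no 1.4826 normal-consistency factor — so its
  magnitude is directly comparable to SIR and LMS in the scale table.
* **Default sweeps**: trimming grid of 99 points on [0, 0.49]; biweight
  c = 0.1…18 step 0.1; subrange α = 0.005…0.495 step 0.005 (grid points
  undefined for the sample size are dropped).

## Classification rule

A median interval can straddle a band boundary, so classification
exposes two views: the **candidate set** (all bands intersecting the
closed interval) and a single **conservative label**, the band of the
upper endpoint — the worst level the median cannot be excluded from at
the given confidence. The conservative rule is a design choice: no
unique rule is forced by the candidate-set view, and the upper-endpoint
rule is the one consistent with precaution in an exposure context. Band
systems are configurable; the QAQI limits are the default.

## Synthetic generator

The generator emulates the features of real route data that the
analysis depends on:

* a lognormal body parameterised by its median (so the target median is
  exact in the large-sample limit) and by the SD of the log
  (`body_scale`, giving multiplicative spread e^`body_scale`);
* additive trend segments, clipped at zero — a negative segment
  produces the near-zero stretches seen on quiet route sections;
* multiplicative Bernoulli spike contamination (`contamination_rate`,
  `contamination_scale`), reflecting that extreme route observations
  are high values. The uniform draw for the spike mask is made at every
  rate, so raising the rate perturbs only the contaminated subset, not
  the body — clean/contaminated pairs are exactly coupled;
* per-route seeds derived as SHA-256(study seed, route id) mod 2³¹, so
  routes are mutually independent and each is bit-reproducible.

The six-route preset uses the published sample sizes (156, 83, 102, 70,
70, 82) and medians of the motivating campaign; spread, trend and
contamination per route were fixed once at values giving the published
qualitative shape — tight X2 (σ_log 0.14), spiky X1 (σ_log 0.45, 5%
spikes ×10, a clipped negative dip), diffuse Y1 (σ_log 0.9, 5% spikes
×5), and Y3 spanning the Acceptable/Caution boundary.

What the generator does **not** model: serial correlation along the
walk, instrument noise, humidity artefacts, meteorology, or spatial
(GPS) structure. Tests passing on synthetic data therefore validate the
estimators' statistical behaviour under heavy tails and contamination,
not the field accuracy of any particular monitor.

## Simulation sizes

Coverage of the exact median interval is assessed over 2000 lognormal
samples of size 80 (achieved coverage for n = 80 at α = 0.05 is 96.70%
analytically, so empirical values near 96–97% are expected). The
robust-vs-classical contamination contrast (MAD/LMS shift < 10%,
SD shift > 25% when 5% of points are multiplied by 10) is evaluated on
samples of n = 10⁵: the systematic MAD shift under these conditions is
≈ 9%, close enough to the 10% bound that route-sized samples (n ≈ 500)
would make the comparison a coin flip of Monte-Carlo noise; at n = 10⁵
the margin is several standard errors.

## Known limitations

* The exact interval is conservative (coverage above the nominal level,
  noticeably so for small n), inherent to order-statistic intervals.
* The rank-sum normal approximation is coarse for six observations with
  heavy ties; it is reported with its continuity correction, and exact
  enumeration is used only as a test oracle.
* The breakdown resistance of MAD and LMS guarantees boundedness up to
  50% corruption, not small drift: one-sided corruption of 40% of a
  sample moves both by factors of ~2–3 while the SD explodes by > 10³×.
* Applying 24-h index bands to route medians is an interpretive choice
  of the motivating campaign that this package follows; it is not a
  regulatory compliance computation.
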
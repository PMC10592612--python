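# Methods

`trnatherm` asks how bacterial tRNA pools co-evolve with environmental
temperature and genome GC content, and what that implies for translation
accuracy. It couples three pieces: (1) species-level statistics of the tRNA
gene complement, (2) a mechanistic kinetic model translating a tRNA pool into
per-codon elongation and missense-error rates, and (3) phylogenetic
regressions that compare those quantities across species while accounting for
shared ancestry.

## Codon–anticodon pairing

Anticodons are written 5'→3'; position 34 (the first character) pairs
antiparallel with the codon's third base. Codon positions 1–2 always demand
Watson–Crick pairing; position 3 follows a configurable wobble table. The
bacterial default is Crick wobble:

| anticodon-34 base | codon-3 bases read |
|---|---|
| G | C (WC), U (wobble) |
| U | A (WC), G (wobble) |
| C | G (WC) only |
| A | U (WC) only |

An optional switch treats A34 as inosine (reads U, C, A); it is off by
default because bacterial pools largely avoid unmodified ANN anticodons. The
exact wobble repertoire and pairing-efficiency constants of the kinetic
literature are not reproducible from public summaries alone, so this table is
a declared convention of the package, not a claim about any particular
measured rule set; every result is reported together with the parameter set
used.

Relative to a focal sense codon, an anticodon falls in exactly one of five
classes: **cognate-WC** (reverse complement), **cognate-wobble** (read through
the table), **pseudo-cognate** (not cognate, but its WC codon encodes the same
amino acid), **near-cognate** (not cognate or pseudo, WC codon one mismatch
away, different amino acid — including stop-decoding anticodons), and
**non-cognate**. Classification is purely rule-table-based; in rare box
configurations a wobble read can deliver a different amino acid (e.g. a UAU
anticodon wobble-reading AUG while WC-decoding AUA/Ile). We keep the
operational rule-table definition and note that real bacteria suppress these
cases through base modifications the model does not represent. Stop codons
are never focal codons; anticodons whose WC codon is a stop may sit in pools
and classify under the same rules.

## The error model

For species with tRNA gene copy numbers (tGCN) `n_a` per anticodon `a`, each
sense codon `i` gets

- cognate elongation rate `R_C(i) = Σ_a n_a·w_a`, with `w_a = 1` for WC
  readers and `w_a = wobble_efficiency` (default 0.64) for wobble readers;
- near-cognate rate `R_N(i) = near_efficiency · Σ_a n_a` over near-cognate
  readers (default 7.8×10⁻⁴);
- missense error rate `ε_M(i) = R_N(i) / (R_C(i) + R_N(i) + R_D)`, the
  probability that a near-cognate wins the kinetic competition against the
  cognate flux and the ribosome drop-off pathway
  (`R_D = 3.146×10⁻³ s⁻¹`, constant across codons).

Pseudo-cognates contribute to neither term by default (the error formula
contains only `R_C`, `R_N`, `R_D`); an alternative policy adds them to `R_C`
at near-cognate efficiency as correct-but-mismatched incorporation flux.

Per species, one multiplicative constant rescales all `R_C` and `R_N` so that
the harmonic mean of the per-codon total elongation rate `R_C + R_N` over
sense codons equals 12.5 amino acids per second; `R_D` is not rescaled, so
`ε_M` depends on the calibration — by design, since the drop-off pathway is
an absolute clock. The calibration basis is switchable to `R_C` alone
(`scale_on="cognate"`); we default to the total rate because total elongation
flux is the quantity with aa/s units. Note the direction of the scale
dependence: multiplying both elongation rates by `s` strictly *increases*
`ε_M` toward its drop-off-free limit `R_N/(R_C+R_N)`, because the constant
`R_D` loses relative weight.

Codons with no cognate and no near-cognate reader (possible in reduced pools
that rely on modified-base decoding) are flagged "undecodable", excluded from
the harmonic mean and from ε_M summaries, and always logged. Default
parameter values put complete uniform pools' median ε_M in the
10⁻⁴–10⁻² band, consistent with the canonical one-error-per-10³–10⁴-codons
figure for bacterial translation; ε_M is reported as a dimensionless
fraction (per elongation event), not a per-second rate.

The species-level summary is the **median** ε_M across decodable sense
codons, which is what enters the comparative regressions.

## tRNA-pool statistics

- **diversity** — number of distinct anticodons with tGCN > 0. Default
  "strict" mode counts only the 61 anticodons whose WC codon is a sense
  codon, so a complete pool scores 61; a permissive mode counts all 64.
- **total tGCN** — sum of copy numbers (total tRNA gene count).
- **GC-/AT-ending split** — diversity partitioned by whether the anticodon's
  WC codon ends in G/C or A/U (no wobble considered).
- **temperature class** — psychrophile below 15 °C optimal growth
  temperature, thermophile above 45 °C, mesophile between; the boundary
  values 15 and 45 fall to mesophile since the outer classes are defined by
  strict inequalities.

GC content is a fraction in [0, 1] internally; readers accept percentages
(values > 1 are divided by 100 with a log message) because databases use
both conventions.

## Phylogenetic regression

Linear models `y = Xβ + ε` are fitted with residual covariance
`cov(ε) = σ²V` defined on a rooted, time-calibrated tree:

- **BM**: `V_ij` = shared root-to-MRCA path length; diagonal = root-to-tip
  depth.
- **OU** (fixed root): `V_ij = (1/2α)·e^{−α d_ij}·(1 − e^{−2α t_ij})` with
  `d_ij` the tip-to-tip distance and `t_ij` the MRCA depth. As α → 0 this
  converges to BM. Non-ultrametric trees are accepted with a warning, using
  per-tip depths in the same formulas.

Estimation is maximum likelihood throughout (not REML), because AIC
comparisons across different mean structures require a consistent likelihood:
β by GLS via Cholesky whitening, σ² profiled as the ML estimator
`rᵀV⁻¹r/n`, and for OU the selection strength α profiled by a deterministic
19-point grid on log α over [10⁻⁶, 10³] (in units of inverse tree depth)
followed by bounded scalar refinement, so fits are exactly reproducible.
Standard errors come from `σ̂²(XᵀV⁻¹X)⁻¹` with two-sided p-values from the t
distribution on n − p degrees of freedom (a software convention; the d.f.
choice is immaterial at the sample sizes involved). An exactly collinear
response returns exact coefficients with σ̂² = 0 and a degenerate
likelihood; a zero-variance response is rejected.

Temperature class enters as 0/1 indicators for thermophile and psychrophile
with mesophile as the reference (intercept) level; indicators for classes
absent from a dataset are dropped with a warning. GC enters as a fraction,
so a GC slope of ~21 means ~21 anticodons per unit GC fraction (~0.21 per
GC percentage point). Parameter count for AIC is coefficients + σ² (+ α for
OU); the BM and OU fits of each regression are compared by AIC with a
parsimony rule: differences under 2 units are treated as ties and the
fewer-parameter model (BM) wins. Diversity is bounded and discrete yet
modelled as a continuous Gaussian response; this is a known approximation
and the main caveat on coefficient interpretation near the bounds.

The regression battery also reports a Benjamini–Hochberg-adjusted p-value
column next to the raw p-values; the adjustment is an extension, clearly
labelled, and no conclusion in the package depends on it.

## Synthetic data

The generator replaces external tGCN tables, growth-temperature databases
and published trees with simulations that have the statistical structure the
analysis assumes. Defaults are the study conditions the pipeline targets:
406 species in proportions 5 psychrophiles : 334 mesophiles : 67
thermophiles, GC in [0.26, 0.74], and diversity effect sizes
(intercept 29.90884, β_GC 21.43034, β_Thermo 1.76894, β_Psychro −0.41211)
on the scale of the empirical bacterial dataset this design mirrors.

- **Tree**: Yule process, stopped at n tips and extended by the Exp(nλ)
  waiting time to the next (unrealized) speciation so no terminal branch is
  zero, then rescaled to unit root-to-tip depth.
- **GC**: BM on a latent logit scale (σ = 1.5 per unit depth), squashed by a
  logistic map into the GC range — GC therefore carries phylogenetic signal
  and a median near 0.50.
- **Classes**: a latent BM "thermo-affinity" thresholded at the marginal
  Gaussian quantiles matching the target proportions, so thermophiles form
  clades rather than a uniform scatter; an exact-count mode thresholds at
  empirical quantiles instead (useful when small classes must be present in
  every replicate). Optimal growth temperatures are drawn uniformly within
  class-consistent bands (2–14, 20–42, 47–80 °C).
- **Diversity**: the linear mean structure plus a BM (or OU) phylogenetic
  residual, rounded and clamped. The residual BM rate defaults to 4.0
  (tip SD 2 anticodons), chosen to reproduce the empirical regime this
  design mirrors — a strongly significant thermophile effect at n ≈ 400
  with a clearly non-significant psychrophile effect — and a within-class
  diversity spread of a few anticodons; the regime is insensitive to this
  choice over at least 0.5–9.
- **Pools**: every species receives the minimal decodable core — the greedy
  set cover of the 61 sense codons by sense-decoding anticodons under the
  active wobble table (31 anticodons for the default table: GNN readers for
  pyrimidine-ending codons in all 16 codon boxes, UNN for purine-ending in
  14, plus CCA for tryptophan). Remaining anticodons are drawn without
  replacement with weights `exp(±b·(GC − ½))` (b = 3) favouring GC-ending
  readers in GC-rich genomes, so the GC-ending diversity split scales with
  GC as the comparative analysis expects. Copy numbers are geometric with
  mean 1/0.85 ≈ 1.18, putting total gene counts near 48 at diversity 41.
  Realized diversity equals the requested value exactly, and every simulated
  pool decodes every sense codon.

The diversity clamp floor is the decodable-core size (31), not a smaller
nominal bound: pools below the core would contain undecodable codons, which
the generator guarantees against; explicit requests below the core raise an
error naming the floor. An optional two-component mesophile mean structure
(`bimodal_mesophile_offset`) can mimic a bimodal mesophile diversity
distribution; it is off by default and not validated against any external
dataset.

What the generator does **not** emulate: real anticodon co-occurrence
structure (modification-dependent decoding, e.g. lysidine or inosine
repertoires), correlation between copy numbers and codon usage, measurement
error in growth temperatures, and non-ultrametric calibration error in the
tree. Passing tests therefore demonstrate the pipeline's statistical
behaviour under its own assumptions, not the biology of any particular
lineage.

## Verification strategy and problem sizes

The suite checks the pairing engine exhaustively against a first-principles
classifier over all 61 × 64 pairs; rate assembly against brute-force
classification on random small pools; the calibration against closed-form
harmonic-mean algebra; GLS against ordinary least squares at V = I, a
pencil-and-paper 3×3 oracle and the OU → BM limit; and the whole regression
stack by simulation-based calibration — 200 replicates of 300-tip trees
with known coefficients, requiring 95% Wald-interval coverage between 90%
and 99% for every term (exact-count class mode keeps the psychrophile
indicator estimable in every replicate) — plus a 50-replicate end-to-end
run (simulate → error model → PGLS → AIC selection) requiring the
thermophile diversity effect to be recovered with positive sign in ≥ 95% of
replicates. These problem sizes keep the full suite under a minute while
leaving the Monte-Carlo bands comfortably away from their thresholds.

## Known limitations

- Wobble efficiencies and the near-cognate kinetic weight are conventions
  (documented above), not fitted constants; ε_M values are meaningful in
  relative, cross-species terms under a fixed parameter set.
- The Gaussian linear model for a bounded count response can misbehave near
  the diversity bounds.
- Fixed-root OU on non-ultrametric trees is a pragmatic extension, flagged
  by a warning rather than a different model.
- The greedy decodable core is minimal-practical, not provably minimum,
  though for the default table it matches the hand-derived lower bound.
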
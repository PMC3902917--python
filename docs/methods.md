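# Methods

`plasmidyn` models and analyses the intracellular dynamics of high-copy
ColE1-type plasmids in rod-shaped bacteria: where the molecules sit, how
they move, how often they replicate, and how they are partitioned at cell
division. This note records the models, the parameter choices, and the
numerical decisions, in that order.

## Coordinate conventions and units

All long-axis positions use a relative coordinate in [0, 1] with a pole at
0 and the septum at 0.5; absolute positions are in µm with the pole at 0.
Short-axis positions are µm from the cell centerline. Column names in
every CSV dialect carry units (`x_um`, `t_s`, `time_min`). Times are
seconds for imaging and simulation, minutes for cell-cycle quantities.

## Confined diffusion and MSD analysis (`tracking`, `synth`)

A plasmid focus tracked at uniform intervals dt is summarized by its
time-averaged mean-square displacement per axis,
MSD(k·dt) = ⟨(x_{i+k} − x_i)²⟩ over all frame pairs. Free diffusion gives
MSD(t) = 2Dt per axis; motion confined to a region of size L saturates.
We fit the single-exponential confined-diffusion form

    MSD(t) = (L²/6)·(1 − exp(−12·D·t/L²))  [+ offset],

whose asymptote L²/6 is the plateau of 1-D diffusion restricted to a
segment of length L. The fit is weighted least squares (weights = number
of displacement pairs per lag, via `scipy.optimize.least_squares`) with a
3×3 multi-start grid over initial (L, D) to avoid local minima. The
optional offset models a localization-noise floor (2σ² per axis) and is
off by default. Apparent diffusion coefficients use
D_app = MSD(τ)/(τ·q_i), with dimensionality factor q_i = 2 per axis and 4
in 2-D; on confined data D_app necessarily declines with lag.

A fit is classified `plateau_reached` only if the fitted L does not exceed
the cell dimension on that axis **and** the longest observed lag covers at
least three relaxation times L²/(12D). The factor three is our choice of
"long enough to see the plateau"; tracks failing it mirror experimental
curves that never level off within the movie and are excluded from
confinement summaries.

Applying the D_app formula to a published mean positional change of
0.20 µm per 5 s (two-dimensional) gives MSD/τq = 0.04/(5·4) = 2.0×10⁻³
µm²/s. The original report quotes 0.4×10⁻³ µm²/s for that construct; the
package implements the printed formula and leaves the five-fold
discrepancy documented rather than resolved.

The synthetic generator realizes exactly the model the fit assumes:
Brownian increments of variance 2·D·dt per axis, folded specularly at the
box walls. Folding the free path is exact for reflecting Brownian motion
and preserves the uniform stationary distribution (positional variance
box²/12, the basis of a generator test). Camera error is Gaussian noise
added to *observed* positions only (default 0.02 µm SD — a configuration
value typical of repressor–operator spots, not a measurement; no
localization error was published for this system).

## Hop diffusion and nucleoid exclusion (`synth`, `sim`)

The nucleoid occupies one or two long-axis intervals; its edges are
partially permeable barriers. Each sub-step whose path crosses an edge
*into* the nucleoid succeeds with probability `p_hop` per attempt and is
otherwise folded back at that edge; crossings *out* of the nucleoid are
always free. The asymmetry is deliberate: a large supercoiled plasmid
(gyration diameter ≈ 265 nm, versus ≈ 18 nm for a ribosome) is
volume-excluded by the chromosomal mesh, so the nucleoid interior is an
unfavourable region, not merely a slow one. A symmetric barrier rule
(same probability both ways) has a uniform stationary distribution — it
slows exchange but produces no polar accumulation at steady state — and
therefore cannot reproduce polar enrichment as an equilibrium property.
Under the one-sided rule the stationary density inside the nucleoid is
suppressed by the factor p_hop, the p_hop = 1 limit is plain reflecting
diffusion (verified against the box generator by a KS test on steps), and
p_hop = 0 confines a particle to its starting compartment absolutely.

## Copy-number quantification and the cell-cycle model (`copynum`)

Relative qPCR: with per-cycle amplification efficiencies E in (1, 2], the
plasmid:origin copy ratio is E_pl^(ΔCt_pl) / E_chr^(ΔCt_chr), each ΔCt
taken against calibrator wells of known (default 1:1) composition, using
mean Ct per target. The ratio is invariant to any global Ct shift.
Efficiencies default to 2 (perfect doubling) unless measured values are
supplied. Multiplying by the mean origins per cell in exponential growth,
2^((C+D)/τ), converts the ratio to copies per cell; C+D defaults to
92.6 min at τ = 100 min, reproducing the literature value of 1.9 origins
per cell used by the study (the exact provenance of that 1.9 — formula or
cell-cycle simulation — is not stated in the source; the C+D default is a
config value).

Within the cycle, an exponentially amplifying replicon follows
p(x) = m·2^x for cell-cycle stage x ∈ [0, 1]. In an asynchronous
exponential culture cell ages are distributed with density
f(x) = 2 ln 2·2^(−x), and requiring the population mean of p to equal the
measured average k fixes m = k/(2 ln 2) — the unique closure consistent
with the age distribution. With k = 17 copies per cell this gives 12.3
copies at birth and 24.5 at division (the "~12 / ~24" endpoints), and the
inverse map k = p₀·2 ln 2 round-trips exactly; a Monte-Carlo average over
sampled ages (inverse-CDF x = −log₂(1 − u/2)) agrees with the closed form
and serves as the oracle in tests.

## Replication-event statistics (`repstats`)

With n plasmids at birth each replicating once per generation on average,
a new initiation is expected every τ/n minutes (100/12 ≈ 8.3 min at the
measured copy number). Empirical intervals are computed from consecutive
event *start* times within a cell — marker lifetime does not enter — and
binned by cell length; empty bins are reported as missing, never zero.

Marker lifetimes decompose as synthesis time plus retention:
plasmid_bp / fork_speed + retention. An 11.3-kb plasmid at ~600 bp/s
gives 18.8 s of synthesis, the timescale of SSB spots; a sliding-clamp
marker retained ~283 s after synthesis reproduces a ~302 s mean spot
lifetime.

EdU pulse labelling: if replication events are independent per plasmid,
per-cell counts in a window t are Poisson with λ = t/t₁, where t₁ is the
labelling time yielding one spot per cell on average. t₁ is calibrated as
the least-squares slope through the origin of mean spots versus time (one
point suffices). The count ratios obey P(1)/P(2) = 2/λ and
P(1)/P(3) = 6/λ², hence P(1)/P(3) = 1.5·(P(1)/P(2))² identically. At the
published calibration t₁ = 17.6 min and a 6-min window, λ = 0.341:
the predicted single:triple ratio is 51.6, matching the observed
(rounded) 50, while the predicted single:double ratio is 5.9 against an
observed 4. The package reports both and flags the second as a genuine
model–data discrepancy; nothing is tuned to hide it. Goodness of fit uses
a chi-square on bins {0, 1, 2, ≥3} with the rate fixed by external
calibration (3 degrees of freedom); its type-I error rate is verified by
simulation.

## Whole-cell simulator (`sim`)

One cell is a 2-D rectangle (long × short axis, constant width) whose
length doubles exponentially over a deterministic generation timer τ_gen
(no size-control law is assumed, as none was measured). The nucleoid is a
central interval covering `nucleoid_fraction` of the length that splits
into two blocks — opening a midcell gap — at cycle stage
`nucleoid_split_x` (default 0.75), emulating the late-cycle midcell
accumulation of plasmids between separating sister nucleoids. Plasmids
hop-diffuse as above; at division the septum falls at midcell and each
daughter inherits the plasmids in its half (a copy exactly at the septum
is assigned by a fair coin); counts are conserved at every division.
Newly replicated copies appear at the parent position with 0.01 µm
jitter — no cohesion period is modelled.

Replication has two modes:

* **constant_rate** — each non-replicating plasmid initiates with
  probability λ·dt per step, default λ = ln 2/τ_gen, which doubles the
  expected copy number per generation. This is the study's headline
  "constant probability of initiation per plasmid", and it is a *critical
  branching process*: the mean is preserved but fluctuations accumulate
  without bound, so no single lineage holds a setpoint over hundreds of
  generations. Tests therefore check the sound ensemble statement (mean
  copies at division ≈ 2·n_birth over ≥500 independent generations)
  rather than per-lineage stationarity.
* **rnaI_feedback** — initiation is inhibited hyperbolically by total
  copy number, standing in for the well-mixed antisense-RNA pool that
  governs ColE1 copy number: λ(n) = λ₀/(1 + R(n)/R_half) with
  R(n) = n·rnai_pool/k_ref molecules (defaults: 400-molecule pool at the
  17-copy reference, half-inhibition at 47 molecules ≈ 2 copy
  equivalents — a steep, ColE1-like control curve). Setting
  λ₀ = (ln 2 + n_birth/K)/τ_gen, with K the half-inhibition point in copy
  units, makes the deterministic cycle map n_birth → 2·n_birth exactly
  (closed form of ∫(1/n + 1/K)dn). This mode gives true homeostasis and
  is used wherever long-run copy-number stability matters.

With n copies at division positioned symmetrically, positional partition
is equivalent to Binomial(n, ½) (verified by chi-square over 10⁴
divisions), so the probability of producing an empty daughter is
2·(½)ⁿ ≈ 1.2×10⁻⁷ at the measured 24 copies — under 0.01 expected losses
across 1000 lineages × 70 generations, consistent with the observed
70-generation stability. The direct simulation check runs a reduced
ensemble (10 lineages × 70 generations) alongside the closed-form bound.
Note that partition statistics require mobile plasmids: with diffusion
switched off, clonal clusters segregate as units and losses become
common — a useful illustration of why diffusive mixing matters for
high-copy stability.

The gyration diameter of a supercoiled plasmid is obtained from a
power-law d = A·bpᵛ fitted in log–log space to a user calibration table
(≥2 points). The underlying literature calibration data are not
published, so the default is the single 265 nm @ 11.3 kb anchor with an
assumed exponent ν = 0.5 — a configuration default, not a derived result.
Whether "diameter of gyration" means twice the radius of gyration is not
defined in the source; the package treats it as an opaque size measure.

## Synthetic data: what it does and does not emulate

Generators cover every input class: reflecting-box and hop trajectories
(with localization noise), qPCR plates (Ct = base − log_eff(ratio) +
Gaussian cycle noise, with calibrator wells), Poisson EdU counts, and
Gaussian-spot images on noisy backgrounds for the minimal localizer. All
randomness flows from one integer seed per call; identical spec + seed is
bit-identical. Not emulated: photophysics (bleaching, blinking), 3-D
point-spread functions, plasmid–plasmid crowding, EdU incorporation
efficiency, or multimers/catenanes. Passing recovery tests on this
synthetic data therefore demonstrates estimator correctness under the
stated models, not robustness to those unmodelled effects in real images.

The spot localizer (plumbing, not a study method) thresholds local maxima
at median + 5 robust SD — a 3-SD cut would admit several noise maxima per
blank 64×64 frame — and refines positions by background-subtracted
intensity-weighted centroid.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately modest scales chosen to make
the statistical tolerances meaningful: 200–300 synthetic tracks of
120–240 frames for confinement recovery (mean fitted L within 10%), 10⁴
division replicates for partition statistics, 8 lineages × 200
generations for feedback homeostasis (grand-mean birth copies within 5%),
and coarse simulator steps (dt = 10–60 s) where the property under test
is insensitive to step size (the initiation probability per step is
validated to stay below 0.1, warning level, and 0.5, error level).
Profile averaging resamples by linear interpolation onto 50 bins.
Degenerate inputs fail loudly: all-zero profiles, missing qPCR target
classes, non-monotone frame times, overlapping nucleoid intervals and
out-of-range cell-cycle stages all raise with explicit messages.
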
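# Methods

This note records the model behind `replifork`, the design choices that were
genuinely open, the numerical conventions, and what the simulation-based
validation does and does not establish.

## Steady-state marker frequency model

A culture in balanced exponential growth with doubling time τ has cell-age
density `p(a) = (2 ln2/τ)·2^(−a/τ)` on `[0, τ]`.  A locus whose replication
completes at cell age `a(m) = a_i + t(m)` — initiation age `a_i` (B period)
plus time-since-initiation `t(m)` — is present in two copies in cells older
than `a(m)` and one copy otherwise, giving an expected per-cell copy number of
`2·2^(−a(m)/τ)`.  Relative read depth across loci is therefore
`∝ 2^(−t(m)/τ)`, which is the marker frequency equation
`N_X/N_Y = 2^((m_y−m_x)·C/τ)` when the fork speed is constant.  All analysis
is done on `log2` of the mean-1 relative frequency, where the model is
piecewise linear: the local fork speed is `v = 1/(τ · d(log2 N)/dM)`.

Assumptions inherited from this model, and enforced by the simulator:

* slow growth — replication rounds never overlap (`a_i + max t(m) ≤ τ` is an
  error otherwise).  Rich-media regimes with overlapping rounds are out of
  scope;
* steady state — the age distribution is exactly exponential;
* every cell completes replication within its cycle, including
  initiation-failure cells.

## Chromosome geometry and segmentation

Coordinates are 0-based, half-open, on a circle; intervals may wrap.  The
stock geometry uses the public U00096 (E. coli MG1655) annotation —
`oriC = 3,925,744`, `terA = 1,286,235`, `terC = 1,609,157`,
`L = 4,641,652` — these numbers come from genome annotation, not from any
measurement made here.  The ectopic origin `oriX` is only known to sit
"about halfway" along the left replichore; the default `2,767,000` is the
snapped midpoint and must be overridden if the true insertion site is known.

Fork-trap semantics: forks travelling the right-replichore direction pass
*terA* and are arrested at *terC*; forks travelling the other way pass *terC*
and are arrested at *terA*.  In the two-origin strain the leftward *oriX*
fork therefore runs past *terC* and waits at *terA* for the rightward *oriC*
fork — the termination zone collapses onto *terA*, which is why the
two-origin `ter` segment is centred there.

Segmentation rules (two-origin): the four origin-proximal segments have equal
length, the distance from each origin to the inter-origin midpoint; `L2` runs
from the end of `X_L` to the `ter` boundary, `R2` continues from `C_R` with
the same length as `L2` (the two remaining forks are assumed to share one
speed, so equal time means equal distance); `R3` is the remainder; `ter` is
*terA* ± `ter_extension` (default 50 kb — a round figure wide enough to
absorb termination-associated deviations; configurable).  One-origin strains
reuse the identical boundaries with `ter` widened to the whole trap zone
(terA − ext … terC + ext), so ratio statistics compare identical regions
across strains.

Numerical conventions: anchor coordinates are snapped to the bin grid and the
inter-origin distance rounded to an even number of bins (moving the oriC-side
boundary by at most one bin) so the equal-length invariants hold exactly in
whole bins.  On genomes whose length is not a bin multiple, the one boundary
computed across the coordinate wrap inherits an offset of `L mod bin_size`;
exact equal lengths are kept in preference to grid alignment there.  The
snapping introduces sub-bin offsets between the true origin positions and the
segment knots; with 1 kb bins this perturbs fitted per-segment speeds by
≲ 0.3%.

## Profiles and bias correction

Reads are binned by leftmost aligned coordinate (primary, mapped,
`MAPQ ≥ 20` by default; mates counted independently).  Zero-coverage bins and
count outliers outside the (0.001, 0.999) quantile band are masked, never
deleted, keeping the bin grid comparable across samples.

The cross-sample correction computes, per sample and per retained bin, the
deviation of `log2` frequency from the mean of the 30 preceding and 30
following retained bins (circularly wrapped, focal bin excluded, neighbour
search capped at 3× the window); the deviation averaged across samples is
subtracted from every sample and each profile re-centred to mean 1.
Subtraction on the log2 scale equals division by a shared multiplicative
bias.  Two properties matter:

* the filter is one-shot, not exactly idempotent: a second application is a
  strong contraction (and exactly null on locally flat profiles) but not a
  1e-9 no-op on arbitrary data;
* the filter is blind to bias components smoother than its window.  A raw
  iid log2-normal bias track contains a random low-frequency component whose
  projection on a segment's slope is `≈ σ·sqrt(12/n)` (several per cent for
  σ = 0.1) and is mathematically indistinguishable from a replication
  gradient — no windowed correction can remove it.  The simulator's bias
  generator therefore models *bin-scale* technical artifacts (mappability,
  local GC): iid log2-normal per bin, centred on its ±30-bin neighbourhood.
  With that model the correction reduces slope distortion from ≈ 2% to
  ≈ 0.5%.  Slowly drifting biases (large-scale GC, growth-phase artifacts)
  are an acknowledged blind spot of the method itself.

## Connecting-point fit

Minimising the root-mean-square deviation between retained bins and a
continuous piecewise-linear curve with knots fixed at the segment boundaries
is an ordinary linear least-squares problem on a hat-function basis (RMSD and
sum-of-squares share their minimiser); knot positions never float.  The seven
directed segments form one continuous chain around the circle.  The chain is
deliberately broken at the two `ter` boundaries: the termination zone carries
a V-shaped feature (forks arriving from both sides; in two-origin strains the
trapped-fork side has an inverted slope) that a single line cannot follow,
and welding its endpoints to the chain drags the neighbouring knots and
biases the `L2`/`R3` speeds by several per cent.  `ter` is fitted with its
own two endpoint values, reported, flagged, and excluded from every average.

Per-segment speeds are computed from the fitted knot values (the marker ratio
across a segment is `2^(Δ log2)` between its connecting points), re-signed
along the fork's travel direction; a non-ter segment whose log2 frequency
*rises* along the fork direction raises an orientation error rather than
being silently absolute-valued.  Each segment needs ≥ 5 retained bins.

## Derived indices

* **Average RFS**: length-weighted mean of per-segment speeds, `ter`
  excluded.  A *restricted* variant uses only `L2, X_L, C_R, R2`, for
  two-origin samples whose converging segments are suspect.
* **O-P/O-D**: length-weighted mean speed of `X_L, X_R, C_L, C_R` over that
  of `L2, R2, R3` (restricted: `X_L, C_R` over `L2, R2`).  Aggregation
  within groups is length-weighted averaging of speeds; the aggregation rule
  is a package choice.
* **Synchrony index**: length-weighted mean log2-gradient magnitude of the
  converging segments (`X_R, C_L`) divided by that of the diverging segments
  (`X_L, C_R`) — equivalently the diverging/converging ratio of apparent
  speeds.  The direction of this ratio was fixed empirically against the
  simulator: in a mixture where a fraction *f* of cells fire only one
  origin, the single-origin cells replicate each converging segment from the
  *far* origin, adding a counter-gradient that flattens those segments only
  (diverging segments decay at the true rate in every class).  The
  gradient-ratio convention therefore reads 1 at *f* = 0 and falls
  monotonically — ≈ 0.77 at *f* = 0.25 on the stock geometry, robust to the
  choice of τ and fork speed because the leading-order value is simply
  `1 − f` — whereas a speed-ratio convention would rise above 1.  A
  converging-segment gradient below the diverging one is thus the
  *initiation failure* signature, not faster forks.
* **oriX/oriC ratio**: mean relative frequency in a ±10 kb window (default
  `peak_window` 20 kb total; the window must stay inside the origin-proximal
  segments) around each origin.
* **Doubling time**: `ln 2 / slope` of the least-squares regression of
  `ln OD` on time, requiring at least eight readings, with R² reported.
* **Local replication time `C_XY`**: per-segment whole-replichore-equivalent
  replication time, using as the reference replichore length the arc from the
  segment's firing origin to the trap-zone midpoint along the fork direction.

## Simulator

Fork kinematics are event-driven on the continuous circle: forks move
outward from each firing origin; converging forks meet where arrival times
are equal; a fork reaching its blocking ter site stalls and waits; the common
speed may switch whenever the number of *moving* forks changes (`v4` for ≥ 4,
`v2` for 2–3, `v1` for 1; a constant mode exists for null models).  Because
the leftward fork crosses half the `ter` window before its arrest, the 2 → 1
switch falls `ter_extension` inside `R3`; the ground truth for validation is
therefore the schedule-derived per-segment *average* speed (identical to the
configured step speed for the pure segments).

Initiation-failure mixtures hold the initiation age fixed across classes
(both-origins, oriC-only, oriX-only; failures split evenly by default), so
every class's expected copy number carries the same proportionality constant
`2·2^(−a_i/τ)` and classes are mixed *unnormalised*, then normalised once —
normalising each class to mean 1 before mixing would silently reweight the
slower-replicating failure classes by ~1.2–1.35×.  In oriC-only cells the
forks meet wherever arrival times allow (traps still respected); in oriX-only
cells the leftward fork waits at *terA* for the rightward fork to come the
long way around.

Read counts are independent Poisson draws around `depth` times the
bias-weighted expected frequencies (`noise: none` rounds deterministically by
largest remainders so totals are exact); identical seeds give identical
counts.  Overdispersion (negative-binomial noise) is not modelled.

## Validation scope and problem sizes

All validation runs use the stock 4.64 Mbp genome at 1 kb bins (4,642 bins),
τ = 3,600 s, and 10 M reads where noise is involved — the scale of a real
experiment, and small enough that the entire suite runs in seconds.  The
calibration statistics recomputed by `scripts/acceptance.py` are noiseless
and deterministic.  Passing tests establish that the estimator inverts the
model it assumes: steady-state growth, stepwise speeds, bin-scale bias,
Poisson noise.  They cannot establish robustness to what the generator does
not emulate — overdispersed coverage, replication–transcription conflicts,
smoothly drifting bias, non-steady-state cultures, or uncertainty in the
true *oriX* insertion coordinate.

Known limitations, restated: the synchrony index confounds initiation
failure with genuinely asymmetric converging speeds; `R3`'s narrow log2 drop
makes its speed the noisiest estimate (its uncertainty is visibly larger at
realistic depths); the one-origin O-P/O-D uses the two-origin boundaries by
convention, which is flagged in the report metadata.
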
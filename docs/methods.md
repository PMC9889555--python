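# Methods

## The design and the unit of analysis

The package analyzes AB single-case designs with an optional
generalization phase: one subject, repeated sessions, a bounded count
score per session (correct responses out of `max_score` opportunities,
default 50).  Sessions carry a 1-based *global* index across phases — a
5-session baseline followed by 30 training sessions is indexed 1..35 and a
generalization phase continues at 36 — because clinical milestones
("first response in session 8") are counted on that axis and the
regression uses the index as its time regressor.  This implies uniform
session spacing; series with gaps must be re-indexed before analysis,
which is a deliberate v1 restriction.

## Recording procedures

Direct observation converts a raw event log (instants and onset/offset
intervals on a session clock) into a score by frequency (event count),
duration (length of the union of the intervals — overlaps are merged,
because double-counting a behavior's time is never meaningful), or
interval recording.  The three interval sub-modes are the canonical ones:
partial-interval (bin touched at all), whole-interval (bin fully covered)
and momentary time sampling (behavior occurring at the bin endpoint).
Partial is the default.  Whole-interval proportion can never exceed
partial-interval proportion; this is property-tested.

## Non-overlap effect sizes

NAP, PND, PEM, Tau-AB and Tau-U are implemented as the minimal set
covering the non-overlap family commonly applied to AB designs; PAND and
IRD are omitted as rarely decision-changing.  Ties count 0.5 toward
improvement in NAP and PEM, making NAP(A, A) = 0.5 exact and NAP(A, B) +
NAP(B, A) = 1 an identity.  NAP is computed from the Mann–Whitney U
statistic; an exhaustive pair-enumeration oracle cross-checks it (and
Tau-AB, Tau-U, PND, PEM) in the tests.  Tau-U is the baseline-trend-only
correction (S_AB − S_AA) without intervention-phase trend augmentation —
the variant usually meant for AB designs — and is reported unclipped with
a flag when it leaves [−1, 1].  One qualification found in testing: PEM is
invariant under strictly monotone transforms of the scores only when the
baseline length is odd; with an even n_A the median is the midpoint of two
order statistics, which a nonlinear transform moves relative to the data.
The other four indices are unconditionally rank-based.

## Detrended level/slope regression

Stage one fits the baseline "natural trend" by OLS on the baseline
(t, y) points alone; stage two regresses the de-trend scores
d_t = y_t − (b0 + b1·t), over baseline and treatment sessions alike, on
`[1, P_t, P_t·(t − t_B)]`.  This parameterization makes c1 the level
change *at intervention onset* and c2 the slope change, and its degrees of
freedom (2, n − 3) give F(2, 32) at the case-study size n = 35.  The fit
statistics (R², F, p) are invariant to how the interaction regressor is
centered; only c1's interpretation moves, and this is tested.  The signed
effect size is r = sign(c1)·√R², mirrored when the therapeutic goal is a
decrease.

Numerical choices: the OLS solve is `numpy.linalg.lstsq` with explicit
SSE/SST bookkeeping (statsmodels OLS is the independent oracle in a unit
test, not the implementation, so exact-fit handling and Monte-Carlo speed
stay under our control).  A perfect fit — common in toy series such as a
flat-zero baseline against a flat treatment phase — is reported with an
`exact_fit` flag, F = ∞ and p = 0 (meaning "below machine display
precision") rather than raising on the zero denominator; R² = 1 is
declared at 8 machine epsilons.  A rank-deficient design matrix raises.
A constant de-trend series (SST = 0) yields R² = 0, F = 0, p = 1.

The covariance assumption is operationalized as cov(P_t, d_t) > 0 for an
increase goal (< 0 for decrease), using the sample covariance; the
operands are our documented choice since only the condition's name and
sign are conventionally stated.  Assumption failure never aborts an
analysis — the result carries the flag and every report surfaces it.
Two-stage estimation (trend estimated, then treated as known) is
anti-conservative; reports attach a fixed caveat string rather than any
correction.  Generalization sessions are excluded from the A-vs-B fit;
the B-vs-G comparison is descriptive (per-phase OLS slopes).

## Method selection and interpretation bands

Selection is a pure, logged rule table: detrended regression iff n_A ≥ 3,
n_B ≥ 5, positive baseline time-variance and the covariance assumption
holds (R1); else Tau-U iff n_A ≥ 3 with a nonzero baseline trend, since
Tau-U exists to absorb baseline trend (R2); else NAP, the
assumption-light floor (R3).  With a flat baseline and a failed
covariance assumption the selector therefore lands on NAP, not Tau-U —
a trend correction has nothing to correct there.

Band tables (config-overridable, printed in every report): NAP < 0.66
weak, < 0.93 medium, else large; |Tau| < 0.2 / < 0.6; |r| < 0.3 / < 0.5;
PND and PEM < 70 / < 90 on their percentage scales.  Boundaries are
closed below (an estimate exactly at a threshold takes the higher band).
The gauge position rescales the estimate's native range linearly onto
[0, 1] for speedometer-style rendering.

Mastery detection returns the *last* session of the first run of
`consecutive` sessions at or above `threshold_fraction·max_score` — the
session at which the criterion is reached — and with `consecutive = 1`
coincides with the first-session-meeting scan.

## The synthetic generator

`SimConfig` defaults encode the reference study design: 5 baseline, 30
training and 10 generalization sessions, 50 trials per session, baseline
success probability 0 (an all-zero baseline).  Acquisition follows a
logistic curve p_t = p_max / (1 + exp(−k·(t − t0))) on the global session
axis with defaults p_max = 0.95, k = 0.45, t0 = 16, chosen once so the
emergent trajectory matches the reported clinical course — first correct
responses around sessions 7–8, ~80% correct by session 20, stable
performance after session 30 — rather than fitted to any printed
statistic.  A linear ramp is available as an alternative curve kind.
Per-session scores are Binomial(m, p_t): the dependent variable is a
bounded count, so binomial (not Gaussian) noise is the honest choice, and
its variance shrinks near the floor and ceiling as real
percentage-correct data does.  The generalization phase uses the same
curve family with its own parameters (default p_max 0.9, k 0.5, midpoint
4 sessions after the phase starts) in the `home` context.

What the generator does *not* emulate: serial correlation between
sessions (an AR(1) hook exists in the config but only 0 is implemented),
within-session trial dynamics (prompt delays, reinforcer effects),
observer error, and motivational day-to-day variability beyond binomial
noise.  Passing calibration tests therefore show the analysis is correct
*under conditional independence*; autocorrelated real series can inflate
the F test's type-I rate beyond what these simulations measure.

## Monte-Carlo harnesses and problem sizes

`run_mc` derives repetition i's seed as `SeedSequence([master_seed, i])`
(reduced mod 2³¹), so any repetition is reproducible in isolation and a
fixed master seed reproduces rates exactly.  Degenerate repetitions
(e.g. a 1-session baseline breaking the parametric path) are counted and
excluded from the rejection-rate denominator, never silently dropped.
Calibration checks run at 2000 repetitions for the null type-I rate
(expected in [0.03, 0.07] at α = 0.05 when the true zero trend is
supplied), 500 per point for power monotonicity across p_max with an MC
jitter allowance of 0.03, and 200 for the strong-effect power bound —
sizes at which the MC standard error (~0.005 at the null) is small
against the bands being checked.

## Data formats

Sessions travel as a canonical 8-column CSV
(`case_id,session_index,phase,score,max_score,context,observer,date`,
UTF-8, LF, RFC-4180); foreign dialects are adapted by a `ColumnMapping`
(column renames + phase-label dictionary) rather than hard-coded, because
deposited datasets rarely document their layout.  Scores must be integers
— the measure is a count.  Measures serialize to a versioned JSON schema
with a bit-exact round trip; simulated series are written through the same
CSV writer as collected data, so downstream tooling cannot tell them
apart by format.  Reports serialize to canonically-ordered JSON
(byte-identical for identical inputs) and Markdown.

## Known limitations

Single behavior per series; AB(G) only (no ABAB, multiple-baseline or
alternating treatments); no confidence intervals for the non-overlap
indices (the parametric module carries the inference); no autocorrelation
modeling; the two-stage regression's anti-conservatism is flagged, not
corrected.
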
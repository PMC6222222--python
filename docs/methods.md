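# Model and methods

`ohsmarket` simulates a market for occupational-health-and-safety (OHS)
services for small and medium-sized enterprises (SMEs) under government
regulation. Three agent types interact on a discrete tick clock: `m`
enterprises that each tick either self-build their safety system or buy a
service, a variable population of service agencies that each tick raise,
hold, or lower the quality they supply, and one government that may
punish, subsidise, or grade-and-disclose.

## Enterprise economics

An enterprise operating at safety level `s ∈ (0,1)` earns safety income

    F(s) = L(s) + I(s),   L(s) = L·exp(l/s) + L0,   I(s) = I·exp(−i/s),

where `L(s)` is the (declining) loss-reduction component and `I(s)` the
(rising) productivity component, and pays the self-build cost
`C_F(s) = C_F·exp(c_F/(1−s)) + C0F`. The two strategies' revenues are

    U(j1) = F(s_self) − C_F(s_self)                      (self-build)
    U(j2) = F(s_t) − P − β·D                             (purchase)

with `P` the uniform service price, `D` the accident loss, and `β` the
accident indicator. Accidents are drawn by roulette: a uniform `R` is
compared with the safety level actually obtained; an accident occurs iff
`R` exceeds it, so the accident probability is exactly `1 − s` (the
boundary draw is safe). When a payoff feeds a *decision*, the indicator is
replaced by its expectation `1 − s`; realized revenue uses the drawn
indicator.

Because service quality is unobservable to buyers (information
asymmetry), the purchase payoff is evaluated at the mean quality of the
pool a buyer would be matched with: all living agencies normally, the best
published grade class under rating.

## Agency economics

An agency supplying quality `s` bears the per-transaction cost
`C_A(s) = C_A·exp(c_A/(1−s)) + C0A` and earns `Q(s) = P − C_A(s)` per
transaction; gross revenue ("income") of a tick is `volume · P`. Total
assets are `KT = GT + Σπ` (fixed endowment plus cumulative profit). An
agency exits when profit has been non-positive for `T` consecutive ticks,
when accumulated *unpayable* fines exceed `k · KT`, or when `KT ≤ 0`; a
fine covered by the tick's operating profit leaves no debt. Entry: each
tick a Poisson number of candidates appears and each enters with
probability `clamp(mean profit of operating agencies / scale, p_min,
p_max)` — the higher the going industry's average profit, the more entry.

## Learning

Both populations use experience-weighted attraction (EWA) learning with a
logit response. Attractions update as

    N(t) = ρ·N(t−1) + 1
    A_j(t) = ( N(t−1)·φ·A_j(t−1) + [δ + (1−δ)·1{j chosen}]·U_j ) / N(t)

and strategy `j` is chosen next tick with probability
`exp(λ·A_j) / Σ_k exp(λ·A_k)` (computed max-shifted for overflow safety).
The chosen strategy's payoff is its realized outcome; unchosen strategies
enter with their estimated foregone payoff, evaluated at the agent's
*current* (post-move) position with the tick's settled information. The
post-move convention matters: evaluating foregone payoffs at the pre-move
position makes attractions lag one step behind, and an agency descending
toward a punishment standard then steps straight through it before its
learner registers the fine ahead.

Agencies anticipate the transaction volume of each candidate quality as a
short exponential moving average (memory ≈ 10 ticks) of their realized
volume — one lucky or unlucky matching draw must not dominate the
forecast, and a literal last-tick volume of zero would erase the cost side
of the forecast entirely while any subsidy term persists, systematically
luring low-volume agencies to the quality ceiling. Entrants anticipate the
market's current mean per-agency volume. Under rating, a candidate quality
maps to a grade, and the anticipated volume is the mean realized volume of
that grade's occupants; an empty grade above the market's best is valued
at the whole buyer pool, an empty grade below at zero.

## Interventions

* **Punishment** (standard `S_p`, intensity `β`): an agency with `s < S_p`
  is fined `β · income` out of the tick's revenue; quality exactly at the
  standard is compliant.
* **Support** (standard `S_r`, intensity `α`): an agency with `s > S_r`
  receives `α·(s − S_r)·(industry income / active agency count)`. The
  industry income figure is the previous tick's sales plus subsidy
  transfers — what is observable when the tick opens; this makes the
  subsidy pool a convergent geometric amplification of sales income (the
  amplification factor `α·(s̄ − S_r)·w < 1` in every scenario run here).
  The divisor can be switched to the enterprise count in the config.
* **Rating**: the government inspects every agency's current quality each
  tick (period configurable) and publishes grades — C on [0, 0.4), B on
  [0.4, 0.7), A on [0.7, 1]; the printed closed intervals double-assign
  their endpoints, resolved here half-open upward. Buyers are matched
  uniformly within the best published grade present; without rating,
  matching is uniform over all living agencies.

## Tick order

(1) agencies move their quality; (2) the government inspects and
publishes grades; (3) enterprises choose and buyers are matched;
(4) accidents are drawn for buyers; (5) settlement — revenues, fines,
subsidies, loss streaks; (6) learning updates for both populations;
(7) exits, then entries; (8) metrics. Grades are published after the
quality move so disclosure reflects the quality actually sold that tick,
and before matching so it can steer buyers. Randomness comes from one
root seed split into six named sub-streams (initialisation, agency
choice, enterprise choice, matching, accidents, entry), so a
(config, seed) pair fully determines a trajectory.

## Default calibration

The economic and learning constants are not identified by the
experimental protocol itself, so the package ships one frozen calibration,
found once by a search against the no-intervention baseline (mean quality
≈ 0.2, purchase share ≈ 10%) and then reused unchanged by every
intervention scenario — making the intervention outcomes out-of-sample
with respect to the calibration. The structurally meaningful choices:

| Constant | Value | Role |
|---|---|---|
| `P` | 10.2 | uniform service price; sets the currency scale |
| `C_A, c_A, C0A` | 8.22, 0.043, 0.01 | agency cost: gentle gradient (≈0.9 at s=0.3), breakeven `Q=0` near s≈0.78, marginal cost ≈ 1.5·P near s≈0.80 and ≈ 3·P near s≈0.85 |
| `L, l, L0` | 1, 0.01, 20 | near-constant loss-reduction income |
| `I, i` | 1.2, 0.3 | productivity income; F(s) rises ≈ 0.8/unit s |
| `C_F, c_F, C0F` | 1, 1, 5.6 | self-build cost ≈ 11.9 at s_self (above P, per the assumption that self-building costs more than purchasing) |
| `D` | 1.55 | accident loss; with F′ sets the logit slope of purchase share in market quality |
| `s_self` | 0.4 | self-built safety level |
| `ρ, φ, δ, λ` | 0.8, 0.8, 1.0, 2.5 | learning memory ≈ 5 ticks; full foregone-payoff weight; moderate choice sharpness |
| `T, k, GT` | 3, 0.5, 900 | exit: 3-tick loss streak; insolvency at unpayable fines > 0.5·KT; endowment ≈ 90 transactions' revenue |
| `quality band, δ_s` | [0.05, 0.9], 0.05 | strategy step and admissible band; the 0.9 cap keeps a one-step overshoot of the cost singularity survivable |
| entry | rate 0.5, scale 8, p∈[0.05, 0.9] | candidate flux and profit→entry mapping |
| scale | m=1000, n=20, 2000 ticks, final 25% averaged | run protocol |

Why the dynamics land where they do, in brief: with quality invisible,
an agency's margin falls in quality, so quality drifts down and the
baseline settles low, sustained by entrant turnover. Punishment at
`β=0.8` makes sub-standard operation loss-making, culling agencies up
past the standard, where margins are positive again — the market re-forms
just above `S_p`; at `β=0.1` fines stay payable out of profit and change
nothing; at `β=1.5` a single fine is insolvency, so deaths peak. A
standard of 0.8 sits above the breakeven quality, so even compliant
agencies bleed and the market churns at mid quality. Support pays a
volume-independent subsidy against a volume-proportional cost, so
agencies above the standard climb until marginal subsidy equals marginal
cost (≈0.8 at α=1.5, ≈0.85 at α=3), and subsidised incumbents
accumulate while unsubsidised floor agencies starve of volume; how much
of the population is captured — and hence the mean — rises with α and
falls with `S_r`. Rating makes the best grade a winner-take-all market,
so agencies race to grade A and park just above the 0.7 boundary.

## What the runs do and do not show

The simulator emulates the study conditions themselves (the model *is*
the object of study; there is no external data). Passing the reproduction
checks shows the implemented mechanisms generate the reported
steady-state levels and orderings under one common calibration; it does
not validate the model against real OHS markets, and levels are
calibration-dependent (one narrative level, the quality under a *low*
punishment standard of 0.3, settles near 0.5 here rather than the
reported 0.35 — the ordering across standards still reproduces).

## Numerical and degenerate-input choices

* Softmax is computed max-shifted; probabilities sum to 1 within 1e−12.
* Sampling inverts the cumulative distribution with one uniform per
  agent; ties need no rule.
* Quality moves are clipped to the band; a clipped raise still records
  strategy "raise" for learning.
* With no living agency, enterprises are forced to self-build, the
  purchase attraction relaxes toward the self-build payoff (an empty
  market leaves buyers indifferent, not deterred), and the tick's mean
  quality is recorded as missing, never fabricated.
* Exit thresholds are strict: a loss streak of `T−1`, a debt ratio of
  exactly `k`, and assets of exactly 0 all survive — except assets, where
  `KT ≤ 0` exits (the ratio's domain requires positive assets).
* The steady-state summary averages the final window, skipping
  agency-free ticks in the quality average, and reports within-window
  standard deviations as a stability diagnostic.

## Limitations

* Factories are homogeneous and never exit; agencies are homogeneous in
  their cost curve; prices do not compete (both by assumption).
* Matching is memoryless — buyers have no supplier loyalty.
* One EWA parameter set serves both populations.
* The entry rule's candidate flux and profit mapping are not identified
  by anything in the source experiments; they were chosen in calibration
  and materially shape population sizes.
* Steady-state levels are read from the final quarter of 2000-tick runs;
  the support scenarios ratchet slowly and their levels would drift
  somewhat higher over much longer horizons.
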
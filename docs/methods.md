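# Methods

## Model and assumptions

The package analyzes decedent claims panels: one row per (person, month
before death), with a monthly cost total Y_igt (units of 100,000 JPY) and
five binary disease-group occurrence indicators I_igtd (circulatory
I00–I99, CKD N18, neoplasms C00–D48, respiratory J00–J99, others). Persons
are eligible if they died inside the study window, were 65–95 at death, and
had at least 24 months of coverage (read as consecutive enrollment ending
at the death month; an alternative reading — any 24 months — would only
relax the filter). Time to death t = 0 is the calendar month of death;
the analysis window is t = 0..23.

The two-part structure separates *whether* a disease group generated a
claim (frequency, the raw proportion F_gtd with the full stratum size N_g
as denominator) from *how much* it cost conditional on claiming (severity).
Severity assumes each group's latent monthly cost is
Normal(mu_gtd, sigma2_gtd), independent across groups, and that the
observed total is the sum of the active components. The Normal assumption
is knowingly wrong for real claims (costs are skewed); it is what makes the
decomposition tractable, and the reconstruction audit quantifies how much
the fitted decomposition misses in aggregate. Comorbidity super-additivity
(joint costs exceeding the sum of parts) is likewise not modeled.

Because the components are independent Normals, the marginal likelihood of
a record is Normal(sum I*mu, sum I*sigma2): the latent per-disease costs
are integrated out analytically rather than sampled. This is purely an
efficiency choice; the posterior over (mu, sigma2) is identical.

Parameters are indexed by (stratum, month, disease) with no pooling, so
each (g, t) cell is fit independently — mathematically identical to a
joint fit. Diseases that never occur in a cell get no parameter: their
frequency is zero, which zeroes their AHCE contribution regardless, and a
prior-only posterior would be meaningless downstream. Records with a
positive indicator but zero billed cost are valid observations and enter
the likelihood.

## Priors and sampler

Priors are common to every cell: mu ~ Normal(0, 20^2),
sigma2 ~ LogNormal(0, 10^2), in 100k-JPY units — weakly informative on the
scale of monthly costs (typical component means are 0.5–6). The sampler
walks (mu_d, log sigma2_d); the prior on log sigma2 is the exact Normal
transform of the LogNormal, so no Jacobian surprises.

The sampler is a self-contained component-wise adaptive
Metropolis-within-Gibbs. The likelihood is evaluated from per-pattern
sufficient statistics (count, sum, sum of squares for each distinct
indicator combination, at most 31), so one evaluation costs O(patterns)
regardless of the number of records; chains are vectorized. Proposal
scales adapt toward 0.44 acceptance every 50 iterations during warm-up
only, then freeze, keeping the retained draws a valid fixed-kernel chain.
Initial values come from a ridge least-squares fit on the pattern design
with per-chain overdispersed jitter. Defaults follow the reference
settings: 4 chains x 6000 iterations with the first 2000 discarded
(16,000 retained draws per parameter).

Convergence: classic split-chain R-hat (each chain halved; not the
rank-normalized variant) on every mu, sigma2 and the log-posterior trace,
with threshold 1.05. Zero-variance chains define R-hat = 1 with a warning.
A rank-deficient indicator design (e.g. two diseases that only ever
co-occur) is fit anyway — the prior regularizes — but flagged, because the
split between the collinear components is then prior-driven.

Credible intervals are central 2.5%/97.5% quantile intervals.

### Grid-quadrature oracle

For cells with at most two active diseases the posterior is a 2- or
4-dimensional integral, evaluated on a self-refining tensor grid (wide
first pass from moment estimates, then two re-grids at weighted mean +/- 8
sd, 60 points per axis). It shares only the sufficient-statistics code
with the sampler, making it an independent check; tests require 2%
relative agreement on posterior means.

## Bayes factors

The comparisons of interest are directional ("is mu higher in the younger
stratum?"). Under the shared 0-symmetric prior, both directions of the
difference carry equal prior mass, so the composite-hypothesis Bayes
factor reduces to the posterior odds of the favored direction, estimated
from paired posterior draws of the difference (equal-length streams;
longer streams truncated; ties at zero split evenly). A Savage–Dickey
point-null construction was considered and rejected: the hypotheses are
directional, not point nulls. With 16,000 draws the estimator saturates
near 1/16,000 tail mass, so values beyond 150 are reported as ">150" —
which is also where the evidence scale tops out (>150 = very strong;
boundaries 3/20/150 bin downward).

## AHCE, CAHCE and the reconstruction audit

AHCE_gtd = mu-hat_gtd * F_gtd (per capita per month), CAHCE_gd sums t =
0..23. The audit compares, per month, actual total cost with the
N_g-weighted estimated total Sum_g N_g Sum_d AHCE_gtd — the only weighting
that makes the two columns commensurable — and reports
error rate = (actual − estimated)/actual x 100. (The opposite orientation
is sometimes written in prose; the printed reference audit rows force this
one, and we follow the rows.) Display rounding is half-up to two decimals;
full precision is kept internally. The default audit uses the
unstratified fit; any scheme can be requested.

## Synthetic generator

The generator draws the exact process the severity model assumes —
Bernoulli occurrence, Normal component costs, totals as exact sums — so
parameter-recovery and calibration tests have well-defined truth.
Conditions it emulates, and their defaults:

- **Strata**: six sex-by-age groups with shares 8.7 / 20.6 / 22.6 / 4.2 /
  13.7 / 30.2 % (male then female, ages 65–75 / 75–85 / 85–95), the
  decedent composition of a large prefectural insurance panel.
- **Trajectories**: occurrence p(t) and component mean m(t) follow
  base + amp * exp(−t/tau) per disease, rising toward death, with
  multiplicative age and sex modifiers. Calibration anchors: respiratory
  occurrence at t=1 is ~1.5x and its component cost ~3.5x their t=12
  values; CKD is flat and most expensive (dialysis), circulatory flat and
  cheapest near death (chronic, largely prescriptions); younger strata
  cost more except respiratory. Only orderings and ratios are anchored —
  no public source prints per-disease component costs, so magnitudes are
  chosen to reproduce realistic monthly totals (mean total incurred cost
  ~3–6 at t=1, falling with age).
- **Month of death**: occurrence, component mean *and component sd* are
  multiplied by 0.5 at t=0, emulating the half-month of exposure. Scaling
  the sd along with the mean is this package's choice: a half-month of
  exposure scales the whole cost distribution, and it keeps m/s (hence
  the negative-draw rate) constant at t=0.
- **Negative draws**: component sds default to m/3, so Normal draws go
  negative with probability ~0.13%; the default policy redraws them
  (rejection from the positive part, a negligible distortion at m/s = 3),
  keeping the severity model near-correctly specified. A truncate-at-zero
  policy is available for robustness experiments.
- **Independence**: occurrences are independent across diseases by
  default; an optional Gaussian-copula correlation between one pair
  (default circulatory–CKD) lets tests inject the small real-world
  association (phi ~ 0.11), with `latent_rho_for_phi` inverting the
  copula-to-phi map.
- **Admissions**: inpatient probability ramps from ~0.19 at t=6 to ~0.66
  at t=0 (conditional on any claim), slightly lower in older groups.

What the generator does *not* emulate: skewed/heavy-tailed cost
distributions, comorbidity super-additivity, calendar-time trends,
survivors/censoring, and nursing-care substitution. Tests passing on
synthetic panels therefore validate the estimation machinery under the
model's own assumptions — not the Normal assumption itself against real
claims.

## Problem sizes and numerical choices

The validation suite runs the full pipeline at ~250–6,000 decedents and,
where many cells are fit, scales the sampler to 4 chains x 1200–2000
iterations (400–800 warm-up); single-cell checks use the full 4 x 6000 /
2000 settings. These scaled-down runs converge comfortably (R-hat
typically < 1.02) because the pattern-sufficient-statistics likelihood
makes cells cheap and posteriors are unimodal. The acceptance script uses
a 3,000-decedent panel for the reconstruction audit (scaled-down sampler)
and one ~1,000-record cell at full settings for the convergence target.

Tie-breaks and edge cases: age bins are half-open [65,75), [75,85),
[85,95] (the upper endpoint closed to honor the 65–95 eligibility range);
age at death is completed years at the death month; empty strata are
allowed but flagged; an empty cell (no costed records) is skipped with a
report entry; actual-total zero makes the error rate undefined and
flagged rather than infinite.

## Known limitations

- The Normal severity likelihood understates skew; posterior means remain
  unbiased for component means under the synthetic process but real-claim
  tails would distort sigma2.
- Component means are not constrained positive; on realistic panels the
  posteriors stay positive, but pathological designs plus weak data could
  produce negative attributions (flagged via the rank-deficiency warning).
- The directional-BF construction relies on the shared symmetric prior;
  with asymmetric or stratum-specific priors the prior-odds correction
  would need to be reinstated.
- Frequencies are raw proportions (no smoothing); in tiny strata they are
  noisy and AHCE inherits that noise multiplicatively.
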
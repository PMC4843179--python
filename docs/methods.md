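# Methods

`mhatlas` turns three kinds of local data — a service inventory, population
tables and origin–destination (OD) travel times — into a comparable "atlas"
of adult mental health care provision. This note records the models and
conventions behind each stage, the choices made where the underlying
methodology is genuinely open, and what the synthetic test bed does and does
not establish.

## Units of analysis

Comparisons are made like-with-like at three levels. A *service* is the
named organisation of care delivery (an acute ward, a day hospital, a
community mental health centre). Each service decomposes into *basic stable
inputs of care* (BSICs): stable functional teams identified by five
criteria — placement, target patients, common staff, administrative
autonomy and temporal stability. `identify_bsic` accepts a unit only when
all five hold; anything less is treated as an activity or programme, which
is the signal the rejection error carries. Each BSIC is classified by
*main-type-of-care* (MTC) codes from a DESDE-LTC-style tree: a branch
letter (R residential, D day, O outpatient, A accessibility, I information,
S self-help) plus a dotted numeric path. The first code is the principal
one; additional codes capture secondary structures, with a warning (not an
error) beyond four codes because such units are rare in practice.

The packaged registry carries 91 codes. The instrument's published manual,
not reproduced here, defines the authoritative code list; the packaged file
has the documented shape (six branches, 91 codes, letter+dotted-integer
grammar) with labels authored for this package. Every computation is
registry-driven, so substituting a corrected registry JSON changes coding
behaviour without touching code. Qualifier vocabularies (user status, care
typology, intensity, time of stay, mobility) are likewise declared in the
registry file rather than hard-coded.

## Inclusion rules

The comparison covers publicly funded care with universal access serving
adults (18+) with a psychiatric disorder. `apply_inclusion_rules` evaluates,
in order: funding/access; an optional reference-year filter (off by
default); exclusion of specialised services for substance dependence,
intellectual disability, children/adolescents and criminal justice;
exclusion of elderly-specific services unless they carry a mental-health
remit (`adult_mh` tag); a threshold rule for general services (included only
when at least 20% of users have a mental disorder — implemented as an
inclusive `>= 0.20`, configurable); and retention of outside-area services
only when they are specialised mental-health services serving the area's
residents. All failed rules are reported, so decisions are record-local and
order-independent, and every exclusion is machine-readable. A general
service with no recorded user share is a data error, not an exclusion.

## Indicators

All provision rates are standardised per 100,000 adults. The adult
denominator defaults to 18+ (18–64 plus 65+): services target adults and
elderly-specific services are excluded, but included services do serve
people over 64, so excluding them from the denominator would overstate
provision; `denominator="18-64"` is available where the narrower convention
is wanted. Availability counts each BSIC once through its principal MTC
(total and by branch, so branch rates sum exactly to the total); beds are
counted only on residential-branch principals and day places only on
day-care-branch principals, with a warning when beds appear elsewhere;
workforce is full-time equivalents by six professional groups (physicians,
psychologists, nurses, social workers, occupational therapists, other
workers — the last holds e.g. voluntary staff). Utilisation reports
admission and contact rates, mean length of stay (pooled bed-days over
pooled admissions) and mean visits per user; missing counts propagate as
missing, never as zeros, and positive bed-days with zero admissions is an
inconsistency error. When unit-to-catchment zoning and service catchment
assignments are available, rates are additionally computed per catchment
against that catchment's own adult population, which makes the pooled rate
the population-weighted mean of catchment rates by construction. The
"attended population" of a service without zoning information is the whole
study area.

## Deprivation index

The index is built from fifteen census variables covering family
composition, employment, education, household size, age composition,
housing, density and migration. Each variable carries a declared
*deprivation direction* in `data/ses_variables.json` (e.g. unemployment +,
tertiary education −); directions the source methodology leaves implicit
(such as industrial employment) are declared there rather than hard-coded.
Variables are z-standardised across units with the sample standard
deviation (ddof=1, exposed as a parameter), sign-flipped to the deprivation
direction, mean-imputed where missing (flagged in the result metadata) and
combined either as an equal/weighted mean of z-scores (default) or as the
first principal component oriented to correlate positively with
unemployment. Both constructions are standard for area deprivation indices
and the aggregation is deliberately configurable because published indices
of this family vary across areas and periods. A variable that is constant
across units is uninformative and dropped with a warning — unless *every*
variable is constant, in which case all units are indistinguishable and all
scores are 0. Scores are invariant to affine transforms of any raw
variable; ranks run from 1 = most deprived.

## Accessibility

The package consumes precomputed OD matrices (long CSV, minutes, absent
pair = unreachable) or a great-circle fallback at a constant speed (default
50 km/h); road-network routing and isochrone polygon drawing are explicit
non-goals, so "isochrone" coverage is computed from travel times: the share
of population whose nearest qualifying service lies within a threshold
(default 60 minutes), plus its complement.

The enhanced two-step floating catchment area (E2SFCA) uses discrete
travel-time zones (default breaks 10/20/30 minutes) weighted by a Gaussian
decay: beta solves exp(−t_max²/β) = w_min (default w_min = 0.01 at the
catchment limit), and each zone's weight is the Gaussian at the zone
*midpoint*, reflecting the discrete-zone formulation of the method; the
continuous decay is exposed separately (`ZoneScheme.decay`). Step 1 assigns
each site j the ratio R_j = S_j / Σ_i P_i·W(d_ij) over units within t_max;
step 2 gives each unit A_i = Σ_j R_j·W(d_ij). Sites reaching no weighted
demand have undefined ratios, contribute nothing and are reported. The
algebraic identity Σ_i P_i·A_i = Σ_j S_j (over contributing sites) is
asserted in tests at 1e-9, and a single zone of weight 1 reduces the method
to the plain two-step floating catchment area. Supply capacity is
configurable; the CLI uses total clinical FTE per service. Demand is the
total adult population per unit; a prevalence multiplier can be applied by
scaling unit populations. Ties for the nearest provider resolve to the
lowest site id.

## Agreement statistics

Coder-training quality control uses raw pairwise proportion agreement:
agreement for each rater pair over the items both rated, averaged per rater
against the remaining raters, and grand-averaged (which equals the mean of
the per-rater means exactly, by symmetry). The published index this
summarises is defined in an external reference without a printed formula,
so the raw-proportion form is the canonical statistic here; Fleiss' kappa
(via statsmodels) is offered as an explicitly non-canonical
chance-corrected alternative. Gold-standard agreement is the per-item share
of raters matching the gold principal code, banded poor/fair/good/excellent
at configurable cut points (defaults 0.40/0.60/0.75, boundaries to the
higher band — conventional bands, declared not sourced). Branch-level
matching scores two codes as agreeing when their main branches match.
Items allowing several codes are scored on the principal code only.

## Synthetic generator

`generate_study_area` emulates the full input bundle. Population units get
log-normal sizes (σ = 1) scaled by largest-remainder rounding to an exact
adult total (default 500,000 adults, ≈640,000 inhabitants — inside the
200,000–1,500,000 band a comparable study area must occupy); units split
into two hospital-level (H3) catchments at the median longitude. Eighty
services (default) are placed uniformly in the bounding box; 200 BSICs are
assigned to them with principal codes drawn across branches (30% R, 25% D,
35% O, 10% A/I/S) and exactly 75% single-MTC units by default — the
single-code share observed in practice exceeds 70%, and the generator's
fraction is exact, not stochastic. Beds (50/100k) and day places (30/100k)
are allocated by multinomial draws over residential/day units so totals are
exact; FTE rates (total 105/100k across six groups) are split by Dirichlet
weights with the last share taking the rounding residue, so planted rates
are recovered *exactly* by the indicator pipeline. Census variables are
monotone functions of a latent standard-normal deprivation factor plus
Gaussian noise (sd 0.3 on the latent scale), clipped to plausible ranges;
at this noise the index recovers the latent ordering with Spearman ≈ 0.99.
The OD matrix is the great-circle fallback. All randomness flows from one
`numpy.random.default_rng(seed)`, so a seed regenerates the bundle
byte-identically.

What the generator does **not** emulate: road networks and realistic
settlement geography (travel times are great-circle), correlated
service/population placement, services that fail inclusion rules, missing
data patterns, and within-variable census dependence beyond the single
latent factor. Passing tests therefore establish the correctness of the
computations and the internal consistency of the pipeline, not the
behaviour of the tool on messy real-world inventories.

The packaged vignette fixture (12 items, 14 distinct gold codes, three
flagged incomplete) is synthetic: the texts are authored for this package
as training-shaped examples; only the counts and the
incomplete-information property mirror the original exercise.

## Numerical conventions

Rates are numerator/denominator × 100,000 with denominators required
positive; emitted tables carry numerator and denominator alongside the
rate. Travel-time zone lookup assigns a zone's upper break to that zone;
times beyond t_max get weight 0 and NaN means unreachable. Z-scores use
ddof=1; zero variance is detected with a relative tolerance of 1e-12.
Writers sort rows and columns by id and keep full float precision, so
re-exports of identical inputs are byte-identical. Problem sizes used in
the test suite (200 random E2SFCA instances up to 10×10, 100 random
indicator fixtures, a 200-BSIC default area) were chosen as comfortably
sufficient to exercise every code path while keeping the suite fast.

## Known limitations

The registry's code labels are package-authored stand-ins pending the
instrument's official list; the inclusion rule for mixed-age services
relies on an explicit `adult_mh` tag rather than age-range parsing; the 20%
general-service threshold has no time window (annual users vs. caseload is
a data-definition question left to the inventory compiler); E2SFCA results
depend on the declared zone breaks and w_min, which are conventions, not
estimates; and the deprivation index is a construction choice — the two
offered aggregations can rank mid-table units differently even when both
track a dominant deprivation gradient.
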
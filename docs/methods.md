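# Methods

## Substitution model

Every PHI entity in a document is replaced by a synthetic surrogate.
Within one document, the mentions of one original value (chain key:
category + case-folded, whitespace-collapsed surface) form a chain; the
surrogate for each successive mention follows a two-state first-order
Markov policy — *reuse* the previous surrogate with probability `p` (the
self-transition), otherwise *resample* a fresh one. The first mention
always resamples. `p` is 1.0 for consistent, 0.5 for markov, 0.0 for
random; it is exposed as a configuration parameter (`--self-transition`)
because tuning it against the expected FN load is a natural extension.
Chains never cross document boundaries; a patient-level policy over
multiple documents is deliberately out of scope.

Keying chains by category *and* original surface (rather than category
alone) keeps two different people's names in one note on separate chains;
otherwise unrelated values would alias one chain and corrupt both the
realism of the output and the MSRS statistic. Mention order for chain
transitions is the document offset order of each entity's first fragment —
the only order the file format defines.

A fresh draw is never forced to differ from the previous value: pool
collisions are what give the random policy a nonzero chance of MSRS > 1,
and removing them would bias the masking statistics.

## Surrogate makers

Each category has a replacement kind:

- **list-based** — drawn from a seeded pool. Critical categories use a
  pool of exactly `pool_size` (default 1000) values. Person pools are
  built from synthesized given names (syllable combinations) specifically
  so that all 1000 entries have *distinct first names*: a chain over a
  single-token original ("Sandy") renders surrogates as bare first names,
  and a pool whose entries shared first names would silently shrink the
  effective pool and inflate collisions. Private user-supplied pools (one
  value per line) can replace any built-in pool.
- **format-preserving** (regex / alphanumeric) — the surrogate mirrors the
  original's character classes (digit→digit, letter→letter, case kept).
  For critical categories the draw selects a pool *index* in
  `[0, pool_size)` and derives the character fill deterministically from
  (seed, category, original, index), so the collision structure is the
  same as for a materialized pool.
- **offset-date / offset-age** — one date offset (uniform ±1–30 days) and
  one age offset (uniform ±1–5 years) are drawn *per document*, not per
  mention, so intra-document chronology and pairwise day differences are
  conserved. Date surfaces are re-emitted in their original format
  (slash dates with padding preserved, ISO, month names, bare years,
  weekday names); unparseable dates fall back to a canonical MM/DD/YYYY
  surrogate and increment a logged fallback counter. Ages never cross the
  90 boundary in either direction, since ≥90 receives distinct Safe
  Harbor treatment. HOLIDAY surfaces are drawn from a holiday-name list
  rather than parsed as calendar dates. TIME re-emits the original
  HH:MM(:SS)/am-pm pattern with a uniformly drawn minute of day,
  uncoupled from the date offset.

All randomness flows through `numpy` generators seeded from the run
configuration (documents get sub-streams keyed by seed and document id),
so identical configurations produce byte-identical outputs.

## Span realignment

Text edits are applied in descending start-offset order; afterwards every
annotation span is remapped through the cumulative length deltas of edits
at earlier offsets. Offsets are 0-based half-open over line-ending
normalized text (CRLF/CR → LF before any offset is read). Two *planned*
replacements with overlapping spans are an error (ambiguous, fail loudly);
an *unplanned* entity overlapping an edit is clipped to cover the whole
replacement and its surface re-read from the new text. Discontinuous
entities distribute the replacement's whitespace tokens across fragments
as evenly as possible (repeating the last token if there are too few, so
no fragment becomes empty). The warning header, when enabled, is prefixed
to the text and all emitted `.ann` offsets are shifted by the prefix
length — both the prefix and span alignment cannot hold otherwise.
Verification after substitution checks that entity/attribute/event counts
are conserved and that every surface matches its text slice.

## Leakage model

MSRS is the maximum multiplicity of any surrogate value within any single
critical chain, maximized over chains; multiplicities are never pooled
across chains (a corpus with hundreds of critical mentions per document
could otherwise not have MSRS ≈ 1 under random substitution, which it
observably does). The document leak rule compares the document's *total*
critical FN count to its MSRS (consistent: any FN leaks). FN injection is
Bernoulli per critical mention — the analytic binomial model implies
independent trials — and the simulator draws the per-document count as
Binomial(m, FNER), which is distributionally identical and vectorizes.
Replicate `r` uses seed `base_seed + r` so any replicate can be re-run in
isolation.

## Strategy thresholds and the analytic model

The per-strategy masking threshold τ is the expected repeat count of a
fake surrogate value: 0 for consistent by definition. For random and
markov it is estimated by Monte Carlo: one chain is modelled as `m` fresh
draws from the pool of 1000, each draw opening a run of mentions whose
length is geometric with mean `1/(1−p)`; the statistic is the mean, over
distinct drawn values, of the value's total mention count. The default
`m = 30` is a calibrated setting: it yields τ ≈ 1.015 (random) and
τ ≈ 2.03 (markov), the reference values for a pool of 1000, and is
recorded as `CALIBRATED_THRESHOLD_DRAWS`. The standard error of the
estimate is always reported alongside.

The analytic leak probability for a simulated corpus is the binomial
upper tail `P(X > τ)`, `X ~ Binomial(N, FNER)`, `N = documents ×
entities/document`, evaluated with `scipy.stats.binom.sf`. The
corpus-total reading (one comparison of the corpus-wide FN count against
τ) is used. At τ = 0 it reduces to `1 − (1−FNER)^N`. Since
τ_consistent < τ_random < τ_markov, the three curves never cross.

## Synthetic corpora

Per-document critical-mention counts are log-normal, rounded and clipped
to a preset range; log-normal matches the extreme right skew of real
per-document PHI loads. The presets (`mimic-like`: mean 6.8, median 5,
range 2–76; `uab-like`: mean 388.5, median 224, range 2–2545) were
calibrated so the *clipped, rounded* expectation hits the target mean —
μ = ln 4.952, σ = 0.7843 and μ = ln 223.0, σ = 1.10 respectively — while
keeping the target median. Chain lengths (mentions per original value)
default to geometric with mean 3, the maximum-entropy choice for a repeat
process, and are configurable. Filler text is deterministic template
boilerplate: the generator emulates PHI *density and repeat structure*,
not clinical language. Passing tests on these corpora therefore validate
the substitution and leakage machinery, not robustness to real-note
formatting quirks (unusual date dialects, OCR noise, nested annotations).

Simulation problem sizes used by the test suite and the acceptance script
— 1000-document corpora, 200 FN-injection replicates, 10⁵–2×10⁵ threshold
replicates, 10⁶-draw binomial tails — were chosen to put Monte-Carlo
standard errors well inside the assertion tolerances.

## Known limitations

- UNIQUE free-text identifying phrases and images are not resynthesized
  and require manual handling; no pronoun or ethnicity adjustment.
- Date parsing covers common US clinical formats; exotic formats fall
  back (logged) rather than being shifted.
- Only entity (T), attribute (A) and event (E) standoff lines are
  modelled; relation/normalization/note lines are preserved verbatim but
  their internal offsets are not rewritten.
- The built-in surrogate pools are public; an attacker who knows them
  could in principle distinguish pool members from real values. Private
  pool files mitigate this for list-based categories.
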
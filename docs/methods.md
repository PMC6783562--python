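# Methods

## The model

A melody is reduced to an ordered sequence of pitches (MIDI semitone
indices).  For a model order *n* ∈ {1, …, 6}, every window of *n*+1
consecutive pitches is re-expressed relative to its first pitch: the window
(p₀, …, pₙ) becomes the offset tuple (0, p₁−p₀, …, pₙ−p₀).  A rising
semitone is +1, a falling semitone −1.  This makes every statistic
transposition-invariant: the same figure in C major and in A♭ major is one
pattern.  The *transition probability* (TP) of a pattern is the conditional
relative frequency of its final offset given the preceding ones,

  P(eₙ₊₁ | e₁ … eₙ) = count(e₁ … eₙ, eₙ₊₁) / count(e₁ … eₙ),

estimated per piece with no smoothing of any kind: an unseen continuation
has probability 0 and an obligatory one has probability 1.  This is
deliberate — raw melodic TPs genuinely take the values 0 and 1, which is
exactly why downstream analyses transform them with the *empirical logit*

  logit_emp(p; n) = ln((p·n + ½) / ((1−p)·n + ½)),

the half-count (Haldane–Anscombe) continuity-corrected log-odds, finite at
p = 0 and p = 1, odd about p = ½ and bounded by ±ln(2n+1).  The ½ constant
is a convention and is exposed as the transform's definition rather than a
tunable.

Windows never cross piece boundaries and no start/end padding symbols are
used.  Patterns are compared by exact tuple equality; octave equivalence is
*not* applied (an offset of −12 is distinct from 0), because real corpora
contain melodically meaningful leaps beyond an octave.

## Melody extraction from scores

MusicXML scores (plain `.xml` or compressed `.mxl`) are parsed with lxml
into a flat list of note events with exact rational onsets in quarter-note
units (onset equality is exact, never a float tolerance).  The melodic line
is the sequence of **highest pitches playable at each onset**:

- grace notes are excluded;
- tied same-pitch chains within a voice are merged into a single event, so
  a note held across a barline is counted once;
- simultaneity is onset-wise: at each distinct onset time, the maximum
  pitch among notes *starting* there is emitted, across all voices.  A long
  low note under a later high onset does not suppress the later note, and a
  held high note does not suppress a later low onset.

Slurs over *different* pitches are phrasing marks and are not merged —
merging them would delete real pitch transitions.  Only same-pitch ties
collapse.  Repeats and voltas are taken as written, not unfolded.
Enharmonic spelling is collapsed to the semitone index; spelling survives
only in the piece metadata (key root).

## Universal patterns and the ANOVA

A pattern is *universal* at order *n* if it occurs at least once in every
piece of the corpus.  On realistic corpora the universal set is nonempty
only at low orders — the pattern space grows exponentially and no long
window survives in every piece.  The tonality analysis runs on the
empirical-logit TPs of the universal first-order patterns, with the default
designated set {[0,−2], [0,−1], [0,1], [0,−3]} (descending whole tone,
descending and ascending semitone, descending minor third — the small
intervals that dominate melodic motion).

The design treats the **pitch class of the key root as the subject**
(12 subjects), making tonality (major/minor), series (1/2), type
(prelude/fugue) and sequence (the universal patterns) fully within-subject
factors; every 2-level effect then has error df 11.  Each effect is tested
by projecting the subject × cell matrix onto the effect's orthonormal
contrasts (Kronecker products of per-factor Helmert contrasts and
normalized averaging vectors): F = MS(effect) / MS(effect × subject).  For
effects with more than one numerator df, sphericity is assessed with
Mauchly's test on the contrast-space covariance, and the Greenhouse–Geisser
ε corrects both dfs whenever ε < 1 and Mauchly p < 0.05 (a policy switch
allows "always" or "never").  Effect size is partial η² =
SS_effect / (SS_effect + SS_error).  Post-hoc comparisons are paired t
tests on subject × level means with p multiplied by the number of
comparisons, capped at 1.

The implementation was verified against an independent marginal-means
sums-of-squares oracle (1e−8) and against pingouin for one- and two-factor
designs (F, dfs, p, ε and Mauchly W to 1e−8; Mauchly's p uses the standard
first-order χ² approximation and agrees with pingouin to ~1e−3).

## Correlation bands and PCA

Pieces are compared through their TP vectors over the union vocabulary of
an order (absent patterns contribute 0 on the raw scale, or the logit of 0
at that piece's context count, with n = 1 when the context itself is
unseen).  Pearson correlation is the default (Spearman by flag), with
two-sided p values from the t distribution.  Pairs are banded: strong
|r| ≥ 0.7, moderate 0.4 ≤ |r| < 0.7, weak 0.2 ≤ |r| < 0.4, each requiring
p < 0.01, otherwise none.  Degenerate (zero-variance) piece vectors give an
undefined coefficient, reported as band "none" with a flag.

PCA is computed on the **correlation matrix of pieces** (pieces are the
variables, vocabulary patterns the observations); the variance share of
component k is eigenvalue_k / n_pieces × 100.  Components with eigenvalue
greater than 1 are retained, at most the first three reported.  Loadings
are eigenvector × √eigenvalue, each column's sign fixed so its mean loading
is nonnegative; no rotation is applied.  PCA runs only for orders whose
correlation report contains at least 30 pairs with |r| ≥ 0.3 (both
configurable).  With ~30–40 vocabulary patterns and 96 pieces the
correlation matrix is rank-deficient; a warning is emitted and the retained
low-rank components remain interpretable, but trailing eigenvalues are
exactly zero.

Related keys of a reference key are its relative, its subdominant and
dominant with their relatives, and its parallel — the keys sharing all or
all-but-one pitches — computed by pitch-class arithmetic with canonical
spellings, and used to annotate which pieces co-load on later components.

## The synthetic corpus generator

The generator emulates the factorial structure of the study corpus — 96
monophonic pieces, 24 major/minor keys × 2 series × 2 types, default 500
notes per piece — with planted, exactly known transition structure:

- **Base step distribution** over offsets −16…+16: two-sided exponential
  decay (scale 2 semitones) with a down-weighted repeated note, log-odds
  boosts making the universal targets the most probable in the
  corpus-typical ranking P(−2) > P(−1) > P(+1) > P(−3), and an exponential
  tilt solved (Brent root-finding, 1e−14) so the mean step is exactly
  zero.  Zero drift matters: pitches accumulate from an anchor (72,
  clipped to 36–96 by resampling the step from the allowed, renormalized
  targets), and a drifting walk would sit against the range floor where
  clipping distorts the realized distribution away from the planted one.
- **Condition effects**: additive log-odds shifts on the universal targets
  — tonality (+0.3 in minor pieces), type (+0.3 in fugues), series (+0.15
  in series 1) — each re-tilted to preserve the zero mean step, keeping
  the effects drift-neutral.
- **Related-key component**: a shared latent distribution blended (weight
  0.7) into the designated pair C major / D minor of series 1.  The latent
  copies each condition's own universal-target probabilities — so the
  blend leaves the ANOVA's dependent measure exactly invariant — and
  concentrates its mass near |offset| = 8, where the base assigns little
  probability: the blended pieces acquire large, coherent logit deviations
  on those rare coordinates, and the shared direction separates cleanly
  from the noise floor of the rank-deficient correlation PCA.  The 0.7
  weight was chosen, together with the latent shape, so that the
  generator's stated recovery contract (the designated pieces, and only
  they, exceed |loading| 0.4 on component 2 in ≥ 90% of seeds) holds with
  margin; smaller weights leave component 2 below the eigenvalue-1
  retention threshold.
- Generation is deterministic under the seed, bit for bit.  Higher-order
  generation (order ≤ 3) is supported via context-keyed transition tables;
  the default is first-order — analyzing first-order data at higher orders
  is itself a meaningful test, since higher-order TPs are then analytically
  determined by the chain.

What the generator does **not** emulate: voice leading, cadences, meter,
phrase structure, or any stylistic feature of real keyboard writing — only
the statistical skeleton under test.  Passing recovery tests therefore
demonstrates that the estimation and inference machinery recovers known
structure from sequences of realistic length and interval distribution; it
does not validate the musicological claims on real scores, which require
user-supplied MusicXML.

## Verification against planted truth

- **Estimator exactness**: the TP estimator agrees *exactly* (no
  tolerance) with brute-force window counting on hundreds of random
  sequences at all orders, and every estimated context distribution sums
  to 1 within 1e−12.
- **Parameter recovery**: on a 96-piece null-effect corpus of 2000-note
  pieces, every estimated first-order TP must be consistent with its
  planted value under binomial sampling.  With ~3,000 simultaneous
  (piece, target) comparisons, a fixed per-comparison 3σ radius is
  exceeded by pure sampling noise almost surely, and for planted
  probabilities of order 10⁻⁵ a normal-approximation radius is
  meaningless (the expected count is far below one).  The bound is
  therefore implemented as the exact binomial test with the 99.73%
  confidence of a 3σ check allocated family-wise (level 0.0027/M per
  comparison).  The null-effect configuration is used so that recovery is
  isolated from the (intentional) interaction between condition drifts
  and range clipping.
- **Effect recovery**: the planted tonality effect is detected by the
  ANOVA at p < 0.05, and the planted related-key pair is recovered exactly
  by PCA, in ≥ 90% of 200 regenerated corpora each (observed: 100%).

## Problem sizes

Default pieces are 500 notes — the order of magnitude of the highest-pitch
lines of real keyboard pieces — and recovery tests use 2000 notes where
root-N convergence is the point.  Rate estimates use 200 corpus
replicates in the test suite and 100 in the acceptance script; these sizes
give the rate estimates standard errors of ~2–3 percentage points, ample
for a ≥ 90% criterion observed at 100%.

## Known limitations

- The MusicXML reader covers the subset of the format the extraction rules
  need (pitches, divisions timing, chords, ties, grace notes, voices,
  backup/forward, compressed archives); it does not realize ornaments,
  unfold repeats, or interpret tuplet time modifications beyond the
  encoded duration values.
- Mauchly's p uses the first-order χ² approximation.
- The subject unit of the ANOVA (pitch class) is a modeling choice exposed
  in the API; other groupings (e.g. piece pairs) can be passed as the
  subject column.
- The banding rule treats |r| = 1 as strong; exact unity occurs only for
  degenerate duplicated pieces, which real corpora do not contain.
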
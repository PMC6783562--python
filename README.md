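# melstat

Transposition-invariant Markov statistics of melodic lines: how the
statistical structure of melodies interacts with tonality.

Melodies — the highest-pitch lines of keyboard scores — are modeled with
nth-order Markov (n-gram) models over *interval patterns*: each window of
n+1 pitches is renumbered so its first pitch is 0 and every other pitch is
its signed semitone offset, which removes the key from every statistic.
The transition probability (TP) of a pattern is the conditional relative
frequency of its last offset given the preceding ones,

    P(e_{n+1} | e_1 ... e_n) = count(e_1 ... e_n, e_{n+1}) / count(e_1 ... e_n),

estimated per piece with no smoothing, for orders n = 1–6.  On top of the
per-piece TP distributions the package provides the corpus analyses used in
computational musicology and statistical-learning research:

- **universal patterns** — interval patterns occurring in every piece of a
  corpus — and a type × tonality × series × sequence repeated-measures
  ANOVA on their empirical-logit TPs (Greenhouse–Geisser corrected,
  Bonferroni post-hocs, partial η²);
- **correlation banding** — every piece pair correlated over the full
  pattern vocabulary and counted in strength bands (strong |r| ≥ 0.7,
  moderate ≥ 0.4, weak ≥ 0.2, all at p < 0.01);
- **PCA of the piece correlation matrix** (eigenvalue > 1, loadings =
  eigenvector × √eigenvalue) with related-key annotation of co-loading
  pieces;
- a **synthetic-corpus generator** that plants known interval-Markov
  structure across 24 major/minor keys × 2 series × 2 types (prelude /
  fugue), so every stage is testable against exact ground truth without
  any real scores.

Real corpora enter through MusicXML: the reader extracts the highest pitch
playable at each onset, excluding grace notes and counting tied notes once.
It is intended for corpora like the 24-key prelude/fugue collections of the
Baroque keyboard literature, which must be supplied by the user.

## Worked example

Generate the default synthetic corpus and run the tonality analysis:

```sh
python analysis/01_simulate_corpus.py --seed 0
python analysis/03_tonality_anova.py
```

prints

```
384 observations, 12 pitch-class subjects
significant effects (p < 0.05):
  type                                F(1.00, 11.00) = 82.41, p = 1.926e-06, partial eta^2 = 0.88
  tonality                            F(1.00, 11.00) = 83.97, p = 1.757e-06, partial eta^2 = 0.88
  ...
mean logit TP by tonality: major = -1.621, minor = -1.565
mean logit TP by type: fugue = -1.562, prelude = -1.624
sequence post-hocs below 0.05 (Bonferroni x6):
  [0, -1] > [0, -3]  (p = 4.384e-16)
  ...
```

The generator planted a positive tonality shift on the universal patterns
in minor-mode pieces, and the ANOVA recovers it: minor-key TPs sit above
major-key TPs with F(1, 11) on 12 pitch-class subjects.  The other drivers
continue the analysis — `02` tabulates TP distributions and vocabulary
growth across orders 1–6, `04` shows correlation bands thinning from 4,539
strong pairs at order 1 to none at orders 5–6, and `05` runs the PCA, e.g.

```
order 1: 2 components retained (eigenvalues 89.30, 1.43), 94.5% of variance
  component 1 loadings: min 0.77 (general component, all pieces)
  component 2: C_no1_prelude loads +0.52; related keys of C: Am, Cm, Dm, Em, F, G
  ...
  planted related-key pair recovered exactly (C_no1_prelude, C_no1_fugue, Dm_no1_prelude, Dm_no1_fugue)
```

component 1 is the general component every piece shares; component 2 is
carried by exactly the related-key pair (C major / D minor, series 1) into
which the generator blended a common latent distribution.

The same analyses run on real scores via the CLI:

```sh
melstat extract --scores scores/ --manifest manifest.csv --out melodies/
melstat tp --melodies melodies/ --orders 1..6 --out results/
```

where `manifest.csv` has columns `file,key_root,mode,series,type`.

## Layout

- `src/melstat/` — the library: `score_io` (MusicXML, melody extraction),
  `encoding` (interval patterns), `markov` (TP estimation, universal and
  representative patterns), `stats` (correlation, PCA, RM-ANOVA, related
  keys), `synthetic` (corpus generator), `pipeline` (end-to-end runs),
  `cli`.
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `docs/methods.md` — the model, estimation and design choices in detail.
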
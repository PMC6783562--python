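"""Universal-pattern ANOVA: does tonality shape first-order statistics?

Takes the empirical-logit TPs of the four designated universal interval
patterns ([0,-2], [0,-1], [0,1], [0,-3]) in every piece, treats the pitch
class of the key root as the subject (12 subjects, all factors within),
and runs a type x tonality x number x sequence repeated-measures ANOVA
with Greenhouse-Geisser correction where sphericity fails, followed by
Bonferroni-corrected pairwise comparisons of the sequence factor.
"""

import argparse
from pathlib import Path

from melstat.encoding import IntervalPattern, extract_ngrams
from melstat.markov import estimate_tp
from melstat.pipeline import _anova_long_table
from melstat.score_io import corpus_from_melody_csv
from melstat.stats import bonferroni_posthoc, rm_anova

UNIVERSAL = [IntervalPattern((0, t)) for t in (-3, -2, -1, 1)]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--corpus", type=Path, default=Path("results/corpus"))
    ap.add_argument("--out", type=Path, default=Path("results/anova"))
    args = ap.parse_args()

    corpus = corpus_from_melody_csv(args.corpus / "melodies.csv", args.corpus / "manifest.csv")
    dists = [estimate_tp(extract_ngrams(s.pitches, 1), 1, s.meta.piece_id) for s in corpus]
    long = _anova_long_table(corpus, dists, UNIVERSAL)
    args.out.mkdir(parents=True, exist_ok=True)
    long.to_csv(args.out / "anova_input.csv", index=False)

    result = rm_anova(
        long, dv="logit_tp", subject="subject",
        within=["type", "tonality", "number", "sequence"],
    )
    result.table.to_csv(args.out / "anova_effects.csv", index=False)

    show = result.table[result.table["p"] < 0.05]
    print(f"{len(long)} observations, {result.n_subjects} pitch-class subjects")
    print("significant effects (p < 0.05):")
    for _, row in show.iterrows():
        gg = " (GG-corrected)" if row["sphericity_corrected"] else ""
        print(
            f"  {row['effect']:<35} F({row['df1']:.2f}, {row['df2']:.2f}) = "
            f"{row['F']:.2f}, p = {row['p']:.4g}, partial eta^2 = "
            f"{row['partial_eta_sq']:.2f}{gg}"
        )
    for factor in ("tonality", "type"):
        means = long.groupby(factor)["logit_tp"].mean()
        print(f"mean logit TP by {factor}: "
              + ", ".join(f"{k} = {v:.3f}" for k, v in means.items()))

    posthoc = bonferroni_posthoc(long, dv="logit_tp", subject="subject", factor="sequence")
    posthoc.to_csv(args.out / "posthoc_sequence.csv", index=False)
    sig = posthoc[posthoc["p_bonferroni"] < 0.05]
    print(f"sequence post-hocs below 0.05 (Bonferroni x{posthoc['n_comparisons'].iloc[0]}):")
    for _, row in sig.iterrows():
        hi, lo = ((row.level_a, row.level_b) if row.mean_a > row.mean_b
                  else (row.level_b, row.level_a))
        print(f"  {hi} > {lo}  (p = {row.p_bonferroni:.4g})")
    print(f"tables -> {args.out}")


if __name__ == "__main__":
    main()
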
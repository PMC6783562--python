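"""Estimate per-piece transition probabilities at orders 1-6.

For every piece of the simulated corpus, slides order-n windows (n = 1-6)
over the melody, encodes each window as semitone offsets from its first
pitch, and estimates conditional probabilities of the final offset given
the preceding ones.  Reports how the pattern vocabulary explodes with
order, which patterns are universal (present in every piece), and the
highest/lowest mean-TP patterns per order.
"""

import argparse
from pathlib import Path

import pandas as pd

from melstat.encoding import extract_ngrams
from melstat.markov import estimate_tp, representative_patterns, tp_matrix, universal_patterns
from melstat.score_io import corpus_from_melody_csv


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--corpus", type=Path, default=Path("results/corpus"))
    ap.add_argument("--out", type=Path, default=Path("results/tp"))
    args = ap.parse_args()

    corpus = corpus_from_melody_csv(args.corpus / "melodies.csv", args.corpus / "manifest.csv")
    args.out.mkdir(parents=True, exist_ok=True)

    print(f"{len(corpus)} pieces")
    print(f"{'order':>5} {'vocabulary':>10} {'universal':>9}  top pattern (mean TP)")
    for order in range(1, 7):
        dists = [
            estimate_tp(extract_ngrams(s.pitches, order), order, s.meta.piece_id)
            for s in corpus
        ]
        tidy = pd.concat([d.to_frame() for d in dists], ignore_index=True)
        tidy.to_csv(args.out / f"tp_order{order}.csv", index=False)

        matrix = tp_matrix(dists, order, scale="raw")
        universal = universal_patterns(dists, order)
        pd.DataFrame({"pattern": [str(p) for p in universal]}).to_csv(
            args.out / f"universal_order{order}.csv", index=False
        )
        top, bottom = representative_patterns(matrix, 5)
        rep = pd.DataFrame(
            [
                {"rank": i + 1, "which": w, "pattern": str(p), "mean_tp": m}
                for w, lst in (("highest", top), ("lowest", bottom))
                for i, (p, m) in enumerate(lst)
            ]
        )
        rep.to_csv(args.out / f"representative_order{order}.csv", index=False)
        print(
            f"{order:>5} {len(matrix.vocabulary):>10} {len(universal):>9}  "
            f"{top[0][0]} ({top[0][1]:.3f})"
        )
    print(f"tables -> {args.out}")


if __name__ == "__main__":
    main()
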
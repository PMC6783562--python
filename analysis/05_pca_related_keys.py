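"""PCA of the piece correlation matrix and related-key components.

Runs correlation-matrix PCA (pieces as variables, patterns as
observations) at every order whose correlation report has at least 30
pairs with |r| >= 0.3, retaining components with eigenvalue > 1 (at most
three).  Component 1 is the general component every piece loads on;
later components are shared structure among subsets of pieces.  Pieces
loading at least 0.4 on component 2 are listed together with their
related keys to check whether the shared component joins a related-key
pair, as planted by the generator.
"""

import argparse
import json
from pathlib import Path

from melstat.encoding import extract_ngrams
from melstat.markov import estimate_tp, tp_matrix
from melstat.score_io import corpus_from_melody_csv
from melstat.stats import correlate_pieces, count_correlations_at, pca_pieces, related_keys

import warnings

warnings.filterwarnings("ignore", message=".*observations.*")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--corpus", type=Path, default=Path("results/corpus"))
    ap.add_argument("--out", type=Path, default=Path("results/pca"))
    args = ap.parse_args()

    corpus = corpus_from_melody_csv(args.corpus / "melodies.csv", args.corpus / "manifest.csv")
    meta = {s.meta.piece_id: s.meta for s in corpus}
    truth_path = args.corpus / "truth.json"
    planted = json.loads(truth_path.read_text())["related_piece_ids"] if truth_path.exists() else None
    args.out.mkdir(parents=True, exist_ok=True)

    for order in range(1, 7):
        dists = [
            estimate_tp(extract_ngrams(s.pitches, order), order, s.meta.piece_id)
            for s in corpus
        ]
        matrix = tp_matrix(dists, order, scale="logit")
        report = correlate_pieces(matrix)
        if count_correlations_at(report, 0.3) < 30:
            print(f"order {order}: fewer than 30 correlations with |r| >= 0.3; PCA not run")
            continue
        pca = pca_pieces(matrix)
        pca.summary().to_csv(args.out / f"summary_order{order}.csv", index=False)
        pca.loadings.to_csv(args.out / f"loadings_order{order}.csv")
        cum = pca.cumulative_pct[pca.n_retained - 1]
        print(
            f"order {order}: {pca.n_retained} components retained "
            f"(eigenvalues {', '.join(f'{e:.2f}' for e in pca.eigenvalues[:pca.n_retained])}), "
            f"{cum:.1f}% of variance"
        )
        print(f"  component 1 loadings: min {pca.loadings['component_1'].min():.2f} "
              f"(general component, all pieces)")
        if pca.n_retained >= 2:
            l2 = pca.loadings["component_2"]
            high = l2[l2.abs() >= 0.4]
            for pid, loading in high.items():
                m = meta[pid]
                rk = related_keys(m.key_root, m.mode)
                print(f"  component 2: {pid} loads {loading:+.2f}; related keys of "
                      f"{rk.key}: {', '.join(sorted(rk.all))}")
            if planted is not None:
                hit = set(high.index) == set(planted)
                print(f"  planted related-key pair {'recovered exactly' if hit else 'NOT recovered'}"
                      f" ({', '.join(planted)})")
    print(f"tables -> {args.out}")


if __name__ == "__main__":
    main()
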
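"""End-to-end orchestration: corpus -> n-grams -> TPs -> statistics.

A single :class:`RunConfig` drives the whole analysis and every stage
writes its tables under one output directory.  Reruns with an identical
config and inputs reproduce byte-identical CSVs; timestamps live only in
the run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from melstat import encoding, markov, score_io, stats, synthetic

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """One pipeline run: input mode, orders, scale and stage toggles."""

    mode: Literal["simulate", "melodies", "scores"] = "simulate"
    orders: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    scale: Literal["raw", "logit"] = "logit"
    out_dir: str = "results/run"
    seed: int = 0
    # simulate mode
    generator: synthetic.GeneratorConfig | None = None
    # melodies mode
    melodies_csv: str | None = None
    manifest_csv: str | None = None
    # scores mode
    scores_dir: str | None = None
    scores_manifest: str | None = None
    # stats toggles and thresholds
    run_correlation: bool = True
    run_pca: bool = True
    run_anova: bool = True
    pca_corr_threshold: float = 0.3
    pca_min_corr_cells: int = 30
    representative_k: int = 10

    def __post_init__(self) -> None:
        bad = [o for o in self.orders if not 1 <= o <= 6]
        if bad:
            raise ValueError(f"orders must be within 1..6, got {bad}")
        if self.mode == "melodies" and not (self.melodies_csv and self.manifest_csv):
            raise ValueError("melodies mode needs melodies_csv and manifest_csv")
        if self.mode == "scores" and not (self.scores_dir and self.scores_manifest):
            raise ValueError("scores mode needs scores_dir and scores_manifest")


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(type(o))

    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    """Write atomically: temp file in the same directory, then rename."""
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            df.to_csv(fh, index=kwargs.pop("index", False), **kwargs)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _load_corpus(config: RunConfig) -> tuple[list[score_io.MelodicSequence], object | None]:
    if config.mode == "simulate":
        gen = config.generator or synthetic.GeneratorConfig(seed=config.seed)
        corpus, truth = synthetic.generate_corpus(gen)
        return corpus, truth
    if config.mode == "melodies":
        return score_io.corpus_from_melody_csv(config.melodies_csv, config.manifest_csv), None
    return score_io.load_corpus(config.scores_dir, config.scores_manifest), None


def _anova_long_table(
    corpus: Sequence[score_io.MelodicSequence],
    dists: Sequence[markov.TPDistribution],
    universal: Sequence[encoding.IntervalPattern],
) -> pd.DataFrame:
    rows = []
    for seq, dist in zip(corpus, dists):
        meta = seq.meta
        for pattern in universal:
            n = dist.context_total(pattern.context)
            p = dist.probability(pattern)
            rows.append(
                {
                    "piece_id": meta.piece_id,
                    "subject": meta.key_pc,
                    "tonality": meta.mode,
                    "type": meta.type,
                    "number": int(meta.series),
                    "sequence": encoding.format_pattern(pattern),
                    "tp": p,
                    "logit_tp": markov.empirical_logit(p, max(n, 1)),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a dict of in-memory results keyed by stage.  Statistical stages
    run only where their preconditions hold (e.g. the universal-pattern
    ANOVA needs a nonempty universal set and a complete subject design;
    PCA needs enough |r| >= threshold correlations).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.time()
    stage = "load-corpus"
    results: dict = {"config": config}
    try:
        corpus, truth = _load_corpus(config)
        results["corpus"] = corpus
        results["truth"] = truth
        score_io.corpus_to_melody_csv(corpus, out / "melodies.csv", out / "manifest.csv")
        if truth is not None:
            with open(out / "truth.json", "w") as fh:
                json.dump(
                    {
                        "seed": truth.seed,
                        "related_piece_ids": truth.related_piece_ids,
                        "matrices": {
                            pid: {str(list(ctx)): dist for ctx, dist in m.items()}
                            for pid, m in truth.matrices.items()
                        },
                    },
                    fh,
                    indent=1,
                )

        band_frames = []
        for order in sorted(config.orders):
            stage = f"tp-order-{order}"
            dists = [
                markov.estimate_tp(
                    encoding.extract_ngrams(seq.pitches, order), order, seq.meta.piece_id
                )
                for seq in corpus
            ]
            results[f"tp_{order}"] = dists
            tidy = pd.concat([d.to_frame() for d in dists], ignore_index=True)
            _write_csv(tidy, out / f"tp_order{order}.csv")

            matrix = markov.tp_matrix(dists, order, scale=config.scale)
            results[f"matrix_{order}"] = matrix
            _write_csv(matrix.to_frame(), out / f"tp_matrix_order{order}.csv", index=True)
            with open(out / f"tp_matrix_order{order}.json", "w") as fh:
                json.dump(
                    {
                        "order": order,
                        "scale": matrix.scale,
                        "n_pieces": len(matrix.piece_ids),
                        "vocabulary_size": len(matrix.vocabulary),
                    },
                    fh,
                    indent=1,
                )

            if len(corpus) >= 2:
                universal = markov.universal_patterns(dists, order)
            else:
                universal = []
            results[f"universal_{order}"] = universal
            _write_csv(
                pd.DataFrame(
                    {"order": order, "pattern": [str(p) for p in universal]},
                    columns=["order", "pattern"],
                ),
                out / f"universal_order{order}.csv",
            )

            top, bottom = markov.representative_patterns(
                matrix, min(config.representative_k, len(matrix.vocabulary))
            )
            rep = pd.DataFrame(
                [
                    {"order": order, "rank": i + 1, "which": w, "pattern": str(p), "mean_tp": m}
                    for w, lst in (("highest", top), ("lowest", bottom))
                    for i, (p, m) in enumerate(lst)
                ]
            )
            _write_csv(rep, out / f"representative_order{order}.csv")

            if config.run_correlation and len(corpus) >= 2 and len(matrix.vocabulary) >= 3:
                stage = f"correlation-order-{order}"
                report = stats.correlate_pieces(matrix)
                results[f"correlation_{order}"] = report
                _write_csv(report.r_frame(), out / f"correlation_order{order}.csv", index=True)
                bands = stats.band_correlations(report)
                band_frames.append(bands)

                if config.run_pca:
                    n_incl = stats.count_correlations_at(report, config.pca_corr_threshold)
                    if n_incl >= config.pca_min_corr_cells:
                        stage = f"pca-order-{order}"
                        pca = stats.pca_pieces(matrix)
                        results[f"pca_{order}"] = pca
                        _write_csv(pca.summary(), out / f"pca_summary_order{order}.csv")
                        _write_csv(
                            pca.loadings, out / f"pca_loadings_order{order}.csv", index=True
                        )
                    else:
                        logger.info(
                            "order %d: only %d correlations with |r|>=%g; PCA skipped",
                            order, n_incl, config.pca_corr_threshold,
                        )

            if config.run_anova and len(universal) >= 2:
                stage = f"anova-order-{order}"
                long = _anova_long_table(corpus, dists, universal)
                complete = (
                    long.groupby(["subject", "tonality", "type", "number"]).size().nunique() == 1
                    and long.groupby("subject").size().nunique() == 1
                    and long["subject"].nunique() >= 2
                    and long["tonality"].nunique() == 2
                    and long["type"].nunique() == 2
                    and long["number"].nunique() == 2
                )
                if complete:
                    _write_csv(long, out / f"anova_input_order{order}.csv")
                    anova = stats.rm_anova(
                        long, dv="logit_tp", subject="subject",
                        within=["type", "tonality", "number", "sequence"],
                    )
                    results[f"anova_{order}"] = anova
                    _write_csv(anova.table, out / f"anova_order{order}.csv")
                    posthoc = stats.bonferroni_posthoc(
                        long, dv="logit_tp", subject="subject", factor="sequence"
                    )
                    _write_csv(posthoc, out / f"posthoc_sequence_order{order}.csv")
                else:
                    logger.warning(
                        "order %d: incomplete subject design; universal-pattern ANOVA skipped",
                        order,
                    )

        if band_frames:
            _write_csv(pd.concat(band_frames, ignore_index=True), out / "correlation_bands.csv")
            results["bands"] = pd.concat(band_frames, ignore_index=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    from melstat import __version__

    manifest = {
        "config_hash": _config_hash(config),
        "package_version": __version__,
        "mode": config.mode,
        "orders": list(config.orders),
        "scale": config.scale,
        "seed": config.seed,
        "n_pieces": len(corpus),
        "elapsed_s": round(time.time() - started, 3),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    results["manifest"] = manifest
    return results
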
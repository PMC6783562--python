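"""Cross-piece statistics: correlation banding, PCA, repeated-measures ANOVA.

Pieces are compared through their transition-probability vectors.  The
correlation analysis reports every piece pair in bands of association
strength; PCA decomposes the pieces' correlation matrix into shared
components (loadings = eigenvector * sqrt(eigenvalue)); the repeated-
measures ANOVA tests tonality / series / type / sequence effects on the
logit TPs of patterns common to the whole corpus, treating the pitch class
of the key root as the subject unit (12 subjects, every factor within).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from melstat.keys import key_label, name_to_pc
from melstat.markov import PieceByPatternMatrix

__all__ = [
    "CorrelationReport",
    "PCAResult",
    "AnovaResult",
    "RelatedKeys",
    "correlate_pieces",
    "band_correlations",
    "count_correlations_at",
    "pca_pieces",
    "rm_anova",
    "bonferroni_posthoc",
    "related_keys",
]

BANDS = ("strong", "moderate", "weak", "none")


@dataclass
class CorrelationReport:
    """Piece-by-piece correlation matrix with banded strength labels.

    Bands (off-diagonal, requiring p < 0.01): strong |r| >= 0.7, moderate
    0.4 <= |r| < 0.7, weak 0.2 <= |r| < 0.4, otherwise none.  Pairs where
    the coefficient is undefined (a zero-variance piece vector) are banded
    none and flagged.
    """

    order: int
    piece_ids: list[str]
    r: np.ndarray
    p: np.ndarray
    band: np.ndarray  # dtype object, off-diagonal labels; diagonal ""
    undefined: np.ndarray  # bool mask of undefined coefficients

    def r_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.piece_ids, columns=self.piece_ids)


def _band_of(r: float, p: float) -> str:
    a = abs(r)
    if p < 0.01:
        if a >= 0.7:
            return "strong"
        if a >= 0.4:
            return "moderate"
        if a >= 0.2:
            return "weak"
    return "none"


def correlate_pieces(
    matrix: PieceByPatternMatrix, method: Literal["pearson", "spearman"] = "pearson"
) -> CorrelationReport:
    """Pairwise correlation of piece TP vectors over the full vocabulary."""
    X = np.asarray(matrix.values, dtype=float)
    n_pieces, n_vocab = X.shape
    if n_pieces < 2:
        raise ValueError("correlation needs >= 2 pieces")
    if n_vocab < 3:
        raise ValueError("correlation needs >= 3 vocabulary entries")
    if method == "spearman":
        X = np.apply_along_axis(sps.rankdata, 1, X)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    sd = X.std(axis=1)
    undefined_rows = sd <= 1e-14 * (np.abs(X).max(axis=1) + 1.0)
    r = np.ones((n_pieces, n_pieces))
    p = np.zeros((n_pieces, n_pieces))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(X)
    for i in range(n_pieces):
        for j in range(n_pieces):
            if i == j:
                continue
            if undefined_rows[i] or undefined_rows[j]:
                r[i, j] = np.nan
                p[i, j] = np.nan
                continue
            rij = float(np.clip(c[i, j], -1.0, 1.0))
            r[i, j] = rij
            df = n_vocab - 2
            if abs(rij) == 1.0:
                p[i, j] = 0.0
            else:
                t = rij * np.sqrt(df / (1.0 - rij * rij))
                p[i, j] = 2.0 * sps.t.sf(abs(t), df)

    band = np.empty((n_pieces, n_pieces), dtype=object)
    undefined = np.zeros((n_pieces, n_pieces), dtype=bool)
    for i in range(n_pieces):
        for j in range(n_pieces):
            if i == j:
                band[i, j] = ""
            elif np.isnan(r[i, j]):
                band[i, j] = "none"
                undefined[i, j] = True
            else:
                band[i, j] = _band_of(r[i, j], p[i, j])
    return CorrelationReport(
        order=matrix.order, piece_ids=list(matrix.piece_ids), r=r, p=p,
        band=band, undefined=undefined,
    )


def band_correlations(report: CorrelationReport) -> pd.DataFrame:
    """Counts of unordered off-diagonal piece pairs per band."""
    n = len(report.piece_ids)
    counts = {b: 0 for b in BANDS}
    for i in range(n):
        for j in range(i + 1, n):
            counts[report.band[i, j]] += 1
    total = n * (n - 1) // 2
    return pd.DataFrame(
        [
            {"order": report.order, "band": b, "pairs": counts[b], "total_pairs": total}
            for b in BANDS
        ]
    )


def count_correlations_at(report: CorrelationReport, threshold: float = 0.3) -> int:
    """Unordered piece pairs with |r| >= threshold (PCA inclusion rule)."""
    n = len(report.piece_ids)
    return sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if not np.isnan(report.r[i, j]) and abs(report.r[i, j]) >= threshold
    )


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    """PCA of the pieces' correlation matrix.

    ``eigenvalues`` holds the full spectrum; components with eigenvalue > 1
    are retained (at most the first three reported).  ``loadings`` is the
    pieces x retained-components table of eigenvector * sqrt(eigenvalue),
    each column's sign fixed so its mean loading is nonnegative.
    """

    order: int
    eigenvalues: np.ndarray
    n_retained: int
    variance_pct: np.ndarray
    cumulative_pct: np.ndarray
    loadings: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, self.n_retained + 1),
                "eigenvalue": self.eigenvalues[: self.n_retained],
                "variance_pct": self.variance_pct,
                "cumulative_pct": self.cumulative_pct,
            }
        )


def pca_pieces(matrix: PieceByPatternMatrix, max_components: int = 3) -> PCAResult:
    """Principal components of the piece correlation matrix.

    Pieces are the variables, vocabulary patterns the observations.  The
    variance share of component k is eigenvalue_k / n_pieces * 100 (the
    trace of a correlation matrix equals the number of variables).
    """
    X = np.asarray(matrix.values, dtype=float).T  # observations x variables
    n_obs, n_var = X.shape
    if n_var < 2:
        raise ValueError("PCA needs >= 2 pieces")
    if n_obs <= n_var:
        warnings.warn(
            f"{n_obs} observations for {n_var} pieces; correlation matrix is singular "
            "or near-singular",
            stacklevel=2,
        )
    sd = X.std(axis=0)
    constant = np.flatnonzero(sd <= 1e-14 * (np.abs(X).max(axis=0) + 1.0))
    if constant.size:
        names = ", ".join(matrix.piece_ids[i] for i in constant)
        raise ValueError(f"constant TP vector for piece(s): {names}")
    R = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    idx = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[idx], 0.0, None)
    eigvec = eigvec[:, idx]

    n_retained = min(int(np.sum(eigval > 1.0)), max_components)
    n_retained = max(n_retained, 1)
    loadings = eigvec[:, :n_retained] * np.sqrt(eigval[:n_retained])
    for k in range(n_retained):
        if loadings[:, k].mean() < 0:
            loadings[:, k] = -loadings[:, k]
    variance_pct = eigval[:n_retained] / n_var * 100.0
    return PCAResult(
        order=matrix.order,
        eigenvalues=eigval,
        n_retained=n_retained,
        variance_pct=variance_pct,
        cumulative_pct=np.cumsum(variance_pct),
        loadings=pd.DataFrame(
            loadings,
            index=pd.Index(matrix.piece_ids, name="piece_id"),
            columns=[f"component_{k + 1}" for k in range(n_retained)],
        ),
    )


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA


@dataclass
class AnovaResult:
    """Effect table of a fully within-subject repeated-measures ANOVA.

    ``table`` has one row per main effect and interaction with the F ratio,
    (possibly Greenhouse-Geisser corrected) degrees of freedom, p value and
    partial eta squared; uncorrected dfs and sphericity diagnostics are
    carried alongside.
    """

    table: pd.DataFrame
    n_subjects: int

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(f"unknown effect {name!r}; have {list(self.table['effect'])}")
        return rows.iloc[0]


def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """levels x (levels-1) orthonormal contrast matrix, orthogonal to 1."""
    h = np.zeros((levels, levels - 1))
    for j in range(levels - 1):
        h[: j + 1, j] = 1.0
        h[j + 1, j] = -(j + 1.0)
        h[:, j] /= np.linalg.norm(h[:, j])
    return h


def _pivot_cells(
    data: pd.DataFrame, dv: str, subject: str, within: Sequence[str]
) -> tuple[np.ndarray, list[str], dict[str, list]]:
    levels = {f: sorted(data[f].unique().tolist()) for f in within}
    subjects = sorted(data[subject].unique().tolist())
    cells = list(itertools.product(*[levels[f] for f in within]))
    pivot = data.set_index([subject, *within])[dv]
    if pivot.index.has_duplicates:
        raise ValueError("more than one observation per subject x cell; aggregate first")
    Y = np.empty((len(subjects), len(cells)))
    missing = []
    for i, s in enumerate(subjects):
        for j, cell in enumerate(cells):
            try:
                Y[i, j] = pivot.loc[(s, *cell)]
            except KeyError:
                missing.append((s, *cell))
    if missing:
        shown = ", ".join(map(str, missing[:10]))
        raise ValueError(
            f"design is incomplete: {len(missing)} missing subject x cell combinations "
            f"({shown}{'...' if len(missing) > 10 else ''})"
        )
    return Y, subjects, levels


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: Sequence[str],
    gg_policy: Literal["mauchly", "always", "never"] = "mauchly",
) -> AnovaResult:
    """Fully within-subject repeated-measures ANOVA, any number of factors.

    Each effect is tested by projecting the subject x cell matrix onto the
    effect's orthonormal contrasts: F = MS(effect) / MS(effect x subject).
    For effects with more than one numerator df, sphericity is assessed with
    Mauchly's test and the Greenhouse-Geisser epsilon; under the default
    policy the correction is applied when epsilon < 1 and Mauchly p < 0.05.
    """
    within = list(within)
    if not within:
        raise ValueError("need at least one within-subject factor")
    Y, subjects, levels = _pivot_cells(data, dv, subject, within)
    S = len(subjects)
    if S < 2:
        raise ValueError("need >= 2 subjects")

    # floor below which a sum of squares is numerically zero (constant data)
    ss_floor = 1e-20 * max(1.0, float((Y * Y).sum()))
    rows = []
    for k in range(1, len(within) + 1):
        for combo in itertools.combinations(within, k):
            mats = []
            for f in within:
                L = len(levels[f])
                if f in combo:
                    mats.append(_orthonormal_contrasts(L))
                else:
                    mats.append(np.full((L, 1), 1.0 / np.sqrt(L)))
            K = mats[0]
            for m in mats[1:]:
                K = np.kron(K, m)
            Z = Y @ K  # subjects x d
            d = Z.shape[1]
            zbar = Z.mean(axis=0)
            ss_eff = S * float(zbar @ zbar)
            resid = Z - zbar
            ss_err = float((resid * resid).sum())
            if ss_eff < ss_floor:
                ss_eff = 0.0
            if ss_err < ss_floor:
                ss_err = 0.0
            df1, df2 = float(d), float((S - 1) * d)
            if ss_err == 0.0:
                F = 0.0 if ss_eff == 0.0 else np.inf
                p_unc = 1.0 if ss_eff == 0.0 else 0.0
            else:
                F = (ss_eff / df1) / (ss_err / df2)
                p_unc = float(sps.f.sf(F, df1, df2))

            eps = 1.0
            mauchly_w = np.nan
            mauchly_p = np.nan
            if d > 1 and S > 1:
                cov = np.atleast_2d(np.cov(Z, rowvar=False))
                tr = np.trace(cov)
                tr2 = np.trace(cov @ cov)
                eps = float(tr * tr / (d * tr2)) if tr2 > 0 else 1.0
                eps = min(max(eps, 1.0 / d), 1.0)
                mauchly_w, mauchly_p = _mauchly(cov, S, d)
            apply_gg = (
                d > 1
                and eps < 1.0
                and (
                    gg_policy == "always"
                    or (gg_policy == "mauchly" and not np.isnan(mauchly_p) and mauchly_p < 0.05)
                )
            )
            if apply_gg and np.isfinite(F):
                df1_c, df2_c = df1 * eps, df2 * eps
                p = float(sps.f.sf(F, df1_c, df2_c))
            else:
                df1_c, df2_c, p = df1, df2, p_unc
            rows.append(
                {
                    "effect": " * ".join(combo),
                    "F": F,
                    "df1": df1_c,
                    "df2": df2_c,
                    "df1_uncorrected": df1,
                    "df2_uncorrected": df2,
                    "p": p,
                    "p_uncorrected": p_unc,
                    "gg_epsilon": eps,
                    "mauchly_W": mauchly_w,
                    "mauchly_p": mauchly_p,
                    "sphericity_corrected": bool(apply_gg),
                    "partial_eta_sq": ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0,
                    "ss_effect": ss_eff,
                    "ss_error": ss_err,
                }
            )
    return AnovaResult(table=pd.DataFrame(rows), n_subjects=S)


def _mauchly(cov: np.ndarray, n_subjects: int, d: int) -> tuple[float, float]:
    """Mauchly's sphericity test on the contrast-space covariance."""
    eig = np.linalg.eigvalsh(cov)
    eig = np.clip(eig, 0.0, None)
    mean_eig = eig.mean()
    if mean_eig <= 0 or np.any(eig <= 0):
        return 0.0, 0.0  # singular: sphericity maximally violated
    w = float(np.prod(eig / mean_eig))
    df_chi = d * (d + 1) / 2 - 1
    f_corr = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * (n_subjects - 1))
    chi2 = -(n_subjects - 1) * f_corr * np.log(w)
    p = float(sps.chi2.sf(chi2, df_chi))
    return w, p


def bonferroni_posthoc(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    factor: str,
    within: str | None = None,
) -> pd.DataFrame:
    """Bonferroni-corrected paired comparisons between the levels of a factor.

    Observations are collapsed to subject x level means (within each level
    of ``within``, if given — simple effects), then all level pairs are
    compared with paired t tests; p values are multiplied by the number of
    comparisons in the table and capped at 1.
    """
    for col in (dv, subject, factor):
        if col not in data.columns:
            raise ValueError(f"unknown column {col!r}")
    if within is not None and within not in data.columns:
        raise ValueError(f"unknown column {within!r}")
    strata = sorted(data[within].unique()) if within is not None else [None]
    rows = []
    for stratum in strata:
        sub = data if stratum is None else data[data[within] == stratum]
        cell = sub.groupby([subject, factor])[dv].mean().unstack(factor)
        levels = list(cell.columns)
        for a, b in itertools.combinations(levels, 2):
            diff = cell[a] - cell[b]
            t, p = sps.ttest_rel(cell[a], cell[b])
            rows.append(
                {
                    **({} if within is None else {within: stratum}),
                    "level_a": a,
                    "level_b": b,
                    "mean_a": float(cell[a].mean()),
                    "mean_b": float(cell[b].mean()),
                    "t": float(t),
                    "df": len(diff) - 1,
                    "p_uncorrected": float(p),
                }
            )
    m = len(rows)
    out = pd.DataFrame(rows)
    out["n_comparisons"] = m
    out["p_bonferroni"] = np.minimum(out["p_uncorrected"] * m, 1.0)
    return out


# ---------------------------------------------------------------------------
# Related keys


@dataclass(frozen=True)
class RelatedKeys:
    """The related keys of a reference key: relative, fifth-related, parallel."""

    key: str
    relative: str
    fifth_related: frozenset[str]  # subdominant, dominant and their relatives
    parallel: str

    @property
    def all(self) -> frozenset[str]:
        return frozenset({self.relative, self.parallel}) | self.fifth_related


def related_keys(key_root: str, mode: Literal["major", "minor"]) -> RelatedKeys:
    """Keys sharing all or all-but-one pitches with the given key.

    For a major key: its relative minor, the subdominant and dominant majors
    with their relative minors, and the parallel minor; symmetrically for a
    minor key.  Labels use canonical spellings ('Am' = A minor).
    """
    pc = name_to_pc(key_root)
    if mode == "major":
        relative = key_label((pc + 9) % 12, "minor")
        fifth = {
            key_label((pc + 5) % 12, "major"),
            key_label((pc + 7) % 12, "major"),
            key_label((pc + 2) % 12, "minor"),
            key_label((pc + 4) % 12, "minor"),
        }
        parallel = key_label(pc, "minor")
        me = key_label(pc, "major")
    elif mode == "minor":
        relative = key_label((pc + 3) % 12, "major")
        fifth = {
            key_label((pc + 5) % 12, "minor"),
            key_label((pc + 7) % 12, "minor"),
            key_label((pc + 8) % 12, "major"),
            key_label((pc + 10) % 12, "major"),
        }
        parallel = key_label(pc, "major")
        me = key_label(pc, "minor")
    else:
        raise ValueError(f"mode must be major|minor, got {mode!r}")
    return RelatedKeys(
        key=me, relative=relative, fifth_related=frozenset(fifth), parallel=parallel
    )
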
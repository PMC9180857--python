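"""Homogeneous-group lettering (ANOVA + Tukey HSD + compact letter display) and PCA.

The figures of a factorial greenhouse study annotate treatment means with
lowercase letters: two treatments share a letter exactly when Tukey's test
finds them not significantly different.  ``tukey_pairwise`` builds the pairwise
significance matrix from the one-way ANOVA mean square error and the
studentized-range distribution (Tukey-Kramer for unequal replicate counts);
``compact_letter_display`` turns it into letters with the insert-and-absorb
algorithm and verifies the sharing-iff-non-significant biconditional before
returning.  A minimal PCA (z-scored by default) supports treatment-effect
ordination.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupedMeasurements",
    "TukeyResult",
    "LetterAssignment",
    "LetterDisplayError",
    "PcaResult",
    "tukey_pairwise",
    "compact_letter_display",
    "letters_table",
    "pca",
]


class LetterDisplayError(ValueError):
    """Raised when no letter assignment can represent a significance pattern."""


@dataclass
class GroupedMeasurements:
    """Replicate values per group label."""

    groups: dict[str, np.ndarray]

    @classmethod
    def from_tidy(cls, frame: pd.DataFrame, group_col: str = "group", value_col: str = "value"):
        return cls(
            {str(g): sub[value_col].to_numpy(dtype=float) for g, sub in frame.groupby(group_col, sort=False)}
        )

    def __post_init__(self) -> None:
        self.groups = {g: np.asarray(v, dtype=float) for g, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")

    @property
    def labels(self) -> list[str]:
        return list(self.groups)

    def means(self) -> pd.Series:
        return pd.Series({g: v.mean() for g, v in self.groups.items()})


@dataclass
class TukeyResult:
    """Pairwise Tukey HSD outcome: q statistics, critical value, significance.

    ``pvalues`` are computed lazily (the studentized-range survival function
    costs ~10 ms per evaluation; significance itself needs only one quantile).
    """

    q: pd.DataFrame
    critical_value: float
    significant: pd.DataFrame
    mse: float
    df_error: int
    alpha: float
    n_groups: int

    _pvalues: pd.DataFrame | None = None

    @property
    def pvalues(self) -> pd.DataFrame:
        if self._pvalues is None:
            tri = np.triu_indices(self.n_groups, k=1)
            pv = np.ones((self.n_groups, self.n_groups))
            vals = stats.studentized_range.sf(
                self.q.to_numpy()[tri], self.n_groups, self.df_error
            )
            pv[tri] = vals
            pv.T[tri] = vals
            self._pvalues = pd.DataFrame(pv, index=self.q.index, columns=self.q.columns)
        return self._pvalues


def tukey_pairwise(data: GroupedMeasurements, alpha: float = 0.01) -> TukeyResult:
    """All-pairs Tukey HSD at level ``alpha`` (default 0.01).

    For groups i, j with means m_i, m_j and replicate counts n_i, n_j,

        q_ij = |m_i - m_j| / sqrt(MSE/2 * (1/n_i + 1/n_j))

    with MSE the one-way ANOVA within-group mean square on N - k degrees of
    freedom; q_ij is referred to the studentized-range distribution with k
    groups and N - k error df (the Tukey-Kramer form for unequal n).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    labels = data.labels
    k = len(labels)
    ns = {g: len(v) for g, v in data.groups.items()}
    small = [g for g, n in ns.items() if n < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 replicates: {small}")
    n_total = sum(ns.values())
    df_error = n_total - k
    sse = sum(((v - v.mean()) ** 2).sum() for v in data.groups.values())
    mse = sse / df_error
    if mse <= 0:
        raise ValueError("zero within-group variance in every group: MSE degenerate")
    means = data.means()
    q = pd.DataFrame(0.0, index=labels, columns=labels)
    for a in range(k):
        for b in range(a + 1, k):
            ga, gb = labels[a], labels[b]
            se = np.sqrt(mse / 2.0 * (1.0 / ns[ga] + 1.0 / ns[gb]))
            qq = abs(means[ga] - means[gb]) / se
            q.loc[ga, gb] = q.loc[gb, ga] = qq
    # quantile routine accurate to ~1e-6; one evaluation decides all pairs
    q_crit = float(stats.studentized_range.ppf(1.0 - alpha, k, df_error))
    sig = (q > q_crit) & ~np.eye(k, dtype=bool)
    return TukeyResult(
        q=q,
        critical_value=q_crit,
        significant=sig,
        mse=mse,
        df_error=df_error,
        alpha=alpha,
        n_groups=k,
    )


@dataclass
class LetterAssignment:
    """Letters per group; groups sharing a letter are statistically homogeneous."""

    letters: dict[str, str]

    def __getitem__(self, group: str) -> str:
        return self.letters[group]


def _letter_seq(n: int) -> list[str]:
    # a..z, then aa, ab, ... for pathological patterns
    seq = list(string.ascii_lowercase)
    while len(seq) < n:
        seq += [a + b for a in string.ascii_lowercase for b in string.ascii_lowercase]
    return seq[:n]


def compact_letter_display(
    significant: pd.DataFrame,
    means: pd.Series | dict,
    *,
    order: str = "descending",
) -> LetterAssignment:
    """Insert-and-absorb compact letter display.

    Groups are ordered by mean (descending by default — figure convention puts
    'a' on the highest mean).  Starting from one column holding every group,
    each significant pair found sharing a column splits the column in two;
    columns that became subsets of others are absorbed.  The result is checked
    against the biconditional — two groups share a letter iff their comparison
    is non-significant — and a violation raises :class:`LetterDisplayError`
    rather than returning misleading letters (every symmetric pattern is in
    fact representable, so this is a guard, not an expected path).
    """
    if not significant.index.equals(significant.columns):
        raise ValueError("significance matrix must have identical row/column labels")
    sig = significant.astype(bool)
    if not sig.equals(sig.T):
        raise ValueError("significance matrix must be symmetric")
    if order not in ("descending", "ascending"):
        raise ValueError(f"unknown order {order!r}")
    means = pd.Series(means)
    groups = means.reindex(sig.index).sort_values(ascending=(order == "ascending"), kind="stable")
    labels = list(groups.index)

    columns: list[set[str]] = [set(labels)]
    for i, ga in enumerate(labels):
        for gb in labels[i + 1 :]:
            if not sig.loc[ga, gb]:
                continue
            new_cols: list[set[str]] = []
            for col in columns:
                if ga in col and gb in col:
                    new_cols.append(col - {ga})
                    new_cols.append(col - {gb})
                else:
                    new_cols.append(col)
            # absorb: drop columns contained in another
            columns = [
                c
                for idx, c in enumerate(new_cols)
                if c
                and not any(
                    c < other or (c == other and idx > jdx)
                    for jdx, other in enumerate(new_cols)
                    if jdx != idx
                )
            ]
    # groups significantly different from everything still need their own letter
    for g in labels:
        if not any(g in col for col in columns):
            columns.append({g})
    # stable ordering: by position of best-ranked member
    rank = {g: i for i, g in enumerate(labels)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    seq = _letter_seq(len(columns))
    letters = {g: "".join(seq[i] for i, col in enumerate(columns) if g in col) for g in labels}

    for i, ga in enumerate(labels):
        for gb in labels[i + 1 :]:
            share = bool(set(letters[ga]) & set(letters[gb]))
            if share == bool(sig.loc[ga, gb]):
                raise LetterDisplayError(
                    f"significance pattern not representable: pair ({ga}, {gb}) "
                    f"{'shares' if share else 'lacks'} a letter against its test outcome"
                )
    return LetterAssignment(letters=letters)


def letters_table(data: GroupedMeasurements, alpha: float = 0.01, order: str = "descending") -> pd.DataFrame:
    """Convenience: Tukey + letters as a tidy frame (group, mean, letters)."""
    res = tukey_pairwise(data, alpha=alpha)
    cld = compact_letter_display(res.significant, data.means(), order=order)
    means = data.means()
    return pd.DataFrame(
        {
            "group": list(means.index),
            "mean": means.to_numpy(),
            "letters": [cld[g] for g in means.index],
        }
    )


@dataclass
class PcaResult:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray


def pca(matrix: np.ndarray | pd.DataFrame, n_components: int | None = None, *, standardize: bool = True) -> PcaResult:
    """Principal component analysis of a cases x variables matrix.

    Variables are z-scored by default (the measured variables carry mixed
    units); ``standardize=False`` decomposes the covariance of the raw
    columns.  Sign convention: within each component, the loading of largest
    magnitude is made positive.  ``scores @ loadings.T`` (times scales, plus
    column means) reconstructs the input when all components are kept.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 cases and 2 variables")
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}], got {n_components}")
    mu = X.mean(axis=0)
    Xc = X - mu
    if standardize:
        scale = X.std(axis=0, ddof=1)
        if (scale == 0).any():
            bad = np.where(scale == 0)[0]
            raise ValueError(f"constant variables (zero variance) at columns {bad.tolist()}")
        Xc = Xc / scale
    else:
        scale = np.ones(p)
        if np.allclose(Xc, 0):
            raise ValueError("constant matrix has no principal components")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (n - 1)
    ratio = var / var.sum()
    loadings = Vt.T[:, :n_components]
    scores = U[:, :n_components] * s[:n_components]
    for j in range(n_components):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=ratio[:n_components],
        column_means=mu,
        column_scales=scale,
    )
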
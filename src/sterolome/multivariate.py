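"""Distance-based group inference: Bray-Curtis dissimilarity, one-factor
PERMANOVA with optional restricted permutations, pairwise post hoc tests,
SIMPER decomposition and PCA.

PERMANOVA follows the classical distance partition: with n samples in a
groups,

    SS_total  = sum_{i<j} d_ij^2 / n
    SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
    pseudo-F  = (SS_between / (a - 1)) / (SS_within / (n - a))

and the p-value is the add-one permutation estimate
(1 + #{F_perm >= F_obs}) / (1 + N_perm), so it is never zero.  A random
effect such as species is handled as restricted permutations: labels are
shuffled only within the declared strata, the standard distance-based
analogue of a nested design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermanovaResult",
    "SimperResult",
    "PcaResult",
    "bray_curtis",
    "permanova",
    "pairwise_permanova",
    "simper",
    "pca",
]


def bray_curtis(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities d(x,y)=sum|x-y|/sum(x+y)."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    row_sums = arr.sum(axis=1)
    if (row_sums == 0).any():
        bad = np.asarray(values.index)[row_sums == 0].tolist()
        raise ValueError(f"all-zero rows have no Bray-Curtis distance: {bad}")
    dist = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(dist, index=values.index, columns=values.index)


@dataclass
class PermanovaResult:
    """Pseudo-F with permutation p for one factor on one distance matrix."""

    factor: str
    pseudo_f: float
    df_between: int
    df_residual: int
    r_squared: float
    p_value: float
    n_permutations: int
    n_samples: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "pseudo_F": self.pseudo_f,
            "df": [self.df_between, self.df_residual],
            "R2": self.r_squared,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "n_samples": self.n_samples,
            "seed": self.seed,
        }


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    total = 0.0
    for g in range(n_groups):
        mask = codes == g
        n_g = int(mask.sum())
        if n_g < 2:
            continue
        total += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    return total


def permanova(
    distances: pd.DataFrame,
    groups,
    factor: str = "group",
    n_permutations: int = 10_000,
    seed: int | None = None,
    strata=None,
) -> PermanovaResult:
    """One-factor permutational multivariate analysis of variance.

    ``groups`` (and optional ``strata``) are label sequences aligned with
    the rows of ``distances``.  When strata are given, permutations move
    labels only within each stratum; if the factor is constant inside
    every stratum no permutation can change the grouping, which is
    reported as an error rather than a degenerate p-value.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    labels = np.asarray(list(groups))
    if len(labels) != n:
        raise ValueError("group labels must align with the distance matrix")
    codes, uniques = pd.factorize(labels)
    a = len(uniques)
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")

    strata_codes = None
    if strata is not None:
        strata_arr = np.asarray(list(strata))
        if len(strata_arr) != n:
            raise ValueError("strata labels must align with the distance matrix")
        strata_codes, _ = pd.factorize(strata_arr)
        confounded = all(
            len(np.unique(codes[strata_codes == s])) == 1
            for s in np.unique(strata_codes)
        )
        if confounded:
            raise ValueError(
                "factor is constant within every stratum: no admissible "
                "permutation can change the grouping"
            )

    d2 = d ** 2
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = _ss_within(d2, codes, a)
    ss_between = ss_total - ss_within
    df_between, df_residual = a - 1, n - a
    if df_residual <= 0:
        raise ValueError("no residual degrees of freedom")
    with np.errstate(divide="ignore"):
        f_obs = (ss_between / df_between) / (ss_within / df_residual)

    rng = np.random.default_rng(seed)
    exceed = 0
    perm = np.arange(n)
    strata_idx = (
        None
        if strata_codes is None
        else [np.flatnonzero(strata_codes == s) for s in np.unique(strata_codes)]
    )
    for _ in range(n_permutations):
        if strata_idx is None:
            perm = rng.permutation(n)
        else:
            for idx in strata_idx:
                perm[idx] = idx[rng.permutation(len(idx))]
        shuffled = codes[perm]
        ss_w = _ss_within(d2, shuffled, a)
        ss_b = ss_total - ss_w
        with np.errstate(divide="ignore"):
            f_perm = (ss_b / df_between) / (ss_w / df_residual)
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    p_value = (1 + exceed) / (1 + n_permutations)

    return PermanovaResult(
        factor=factor,
        pseudo_f=float(f_obs),
        df_between=df_between,
        df_residual=df_residual,
        r_squared=float(ss_between / ss_total),
        p_value=float(p_value),
        n_permutations=n_permutations,
        n_samples=n,
        seed=seed,
    )


def pairwise_permanova(
    distances: pd.DataFrame,
    groups,
    factor: str = "group",
    n_permutations: int = 10_000,
    seed: int | None = None,
    correction: str = "holm",
) -> pd.DataFrame:
    """Post hoc PERMANOVA on every level pair, with multiplicity control.

    Each pair is tested on its distance sub-matrix; adjusted p-values use
    the stated step-down correction (Holm by default).
    """
    labels = pd.Series(list(groups), index=distances.index)
    levels = labels.unique()
    if len(levels) < 3:
        raise ValueError("pairwise tests need at least three factor levels")
    rows = []
    for i, (lv_a, lv_b) in enumerate(itertools.combinations(levels, 2)):
        keep = labels.isin([lv_a, lv_b])
        sub = distances.loc[keep, keep]
        res = permanova(
            sub,
            labels[keep],
            factor=factor,
            n_permutations=n_permutations,
            seed=None if seed is None else seed + i,
        )
        rows.append(
            {
                "level_a": lv_a,
                "level_b": lv_b,
                "pseudo_F": res.pseudo_f,
                "df_between": res.df_between,
                "df_residual": res.df_residual,
                "p_value": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method=correction)[1]
    return out


@dataclass
class SimperResult:
    """Per-sterol contributions to the mean between-group dissimilarity."""

    table: pd.DataFrame  # contribution, percent, cumulative_percent; ranked
    mean_dissimilarity: float
    group_a: str = ""
    group_b: str = ""

    def top(self, k: int = 5) -> pd.DataFrame:
        return self.table.head(k)


def simper(
    values: pd.DataFrame, groups, group_a, group_b
) -> SimperResult:
    """Similarity-percentage decomposition between two groups.

    For each cross pair (x in A, y in B) the Bray-Curtis dissimilarity
    splits additively over variables as |x_i - y_i| / sum_k (x_k + y_k);
    averaging over pairs gives each sterol's contribution, whose total is
    exactly the mean between-group dissimilarity.
    """
    labels = pd.Series(list(groups), index=values.index)
    a_rows = values.loc[labels == group_a].to_numpy(dtype=float)
    b_rows = values.loc[labels == group_b].to_numpy(dtype=float)
    if len(a_rows) == 0 or len(b_rows) == 0:
        raise ValueError(f"empty group in SIMPER: {group_a!r} or {group_b!r}")

    diffs = np.abs(a_rows[:, None, :] - b_rows[None, :, :])  # (nA, nB, p)
    deners = (a_rows[:, None, :] + b_rows[None, :, :]).sum(axis=2)  # (nA, nB)
    contributions = (diffs / deners[:, :, None]).mean(axis=(0, 1))

    total = contributions.sum()
    percent = 100.0 * contributions / total if total > 0 else np.zeros_like(contributions)
    table = pd.DataFrame(
        {"contribution": contributions, "percent": percent},
        index=values.columns,
    ).sort_values("contribution", ascending=False)
    table["cumulative_percent"] = table["percent"].cumsum()
    table["rank"] = np.arange(1, len(table) + 1)
    return SimperResult(
        table=table,
        mean_dissimilarity=float(total),
        group_a=str(group_a),
        group_b=str(group_b),
    )


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    explained_variance: np.ndarray = field(default=None)


def pca(values: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA of column-centred (unscaled) per-mille values.

    Eigen-decomposition of the sample covariance; components are ordered
    by decreasing variance, and each loading vector is signed so that its
    largest-magnitude entry is positive (a deterministic convention).
    Variables share units (permille), so no rescaling is applied.
    """
    X = np.asarray(values, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least two samples")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    k = min(n_components or min(n, p), p)
    eigvals, eigvecs = eigvals[:k], eigvecs[:, :k]
    for j in range(k):
        pivot = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[pivot, j] < 0:
            eigvecs[:, j] *= -1.0
    scores = Xc @ eigvecs

    total_var = cov.trace()
    ratios = eigvals / total_var if total_var > 0 else np.zeros(k)
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=values.index, columns=comp_names),
        loadings=pd.DataFrame(eigvecs, index=values.columns, columns=comp_names),
        explained_variance_ratio=ratios,
        explained_variance=eigvals,
    )
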
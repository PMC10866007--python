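"""Alpha/beta diversity on ASV count tables.

Tables are pandas DataFrames oriented features x samples (QIIME-style).
Samples are first standardized to a common sequencing depth (the minimum
sample total by default) by single-draw subsampling without replacement;
Chao1 richness and Shannon entropy summarize alpha diversity, Bray-Curtis
dissimilarity with principal coordinates analysis (classical scaling) and
a PERMANOVA permutation test summarize community structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class DiversityError(ValueError):
    pass


def _as_count_matrix(table: pd.DataFrame) -> np.ndarray:
    x = table.to_numpy()
    if not np.issubdtype(x.dtype, np.integer):
        if not np.allclose(x, np.round(x)):
            raise DiversityError("feature table must hold integer counts")
        x = np.round(x).astype(np.int64)
    if (x < 0).any():
        raise DiversityError("feature table contains negative counts")
    return x.astype(np.int64)


def rarefy(
    table: pd.DataFrame,
    depth: int | str = "min",
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Subsample every sample (column) to exactly ``depth`` reads.

    ``depth="min"`` uses the smallest sample total, the usual
    standardize-to-minimum convention.  Sampling is a single
    multivariate-hypergeometric draw per sample (without replacement),
    deterministic under a fixed seed.
    """
    x = _as_count_matrix(table)
    totals = x.sum(axis=0)
    if depth == "min":
        depth = int(totals.min())
    depth = int(depth)
    if depth <= 0:
        raise DiversityError("rarefaction depth must be a positive integer")
    short = np.where(totals < depth)[0]
    if short.size:
        raise DiversityError(
            f"sample {table.columns[short[0]]!r} has only {totals[short[0]]} reads, "
            f"fewer than depth {depth}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(x[:, j], depth)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimator for one sample.

    Bias-corrected form S_obs + F1(F1-1) / (2(F2+1)) by default (the
    common mothur/QIIME choice); ``bias_corrected=False`` gives the
    classic S_obs + F1^2 / (2 F2).
    """
    c = np.asarray(counts)
    if c.sum() <= 0:
        raise DiversityError("Chao1 undefined for an empty sample")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return float(s_obs) if f1 == 0 else s_obs + f1 * (f1 - 1) / 2.0
    return s_obs + f1 * f1 / (2.0 * f2)


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy -sum p_i log p_i over nonzero proportions.

    Natural log by default; pass ``base=2`` for bits (platform defaults
    differ between pipelines).
    """
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise DiversityError("Shannon undefined for an empty sample")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def alpha_diversity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Chao1 and Shannon per sample, as a tidy frame indexed by sample."""
    return pd.DataFrame(
        {
            "chao1": [chao1(table[c]) for c in table.columns],
            "shannon": [shannon(table[c]) for c in table.columns],
        },
        index=pd.Index(table.columns, name="sample_id"),
    )


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples (columns).

    d(a, b) = sum|a_i - b_i| / sum(a_i + b_i); square symmetric frame with
    zero diagonal, entries in [0, 1].
    """
    from scipy.spatial.distance import pdist, squareform

    x = table.to_numpy(dtype=float).T
    if (x.sum(axis=1) == 0).sum() >= 2:
        raise DiversityError("Bray-Curtis undefined between two all-zero samples")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.columns, columns=table.columns)


@dataclass
class PCoAResult:
    """Principal coordinates, eigenvalues and variance-explained shares."""

    coordinates: pd.DataFrame  # samples x retained axes (PC1, PC2, ...)
    eigenvalues: np.ndarray  # all eigenvalues, sorted descending
    proportion_explained: np.ndarray  # over positive eigenvalues only
    negative_eigenvalues: np.ndarray  # the negative part, for reporting


def _check_distance_matrix(d: pd.DataFrame) -> np.ndarray:
    a = d.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise DiversityError("distance matrix must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise DiversityError("distance matrix must be symmetric")
    if not np.allclose(np.diag(a), 0.0):
        raise DiversityError("distance matrix must have a zero diagonal")
    return a


def pcoa(d: pd.DataFrame, n_axes: int | None = None) -> PCoAResult:
    """Classical scaling (PCoA) of a distance matrix.

    Gower-centers -d^2/2, eigendecomposes, and returns coordinates on the
    axes with positive eigenvalues (up to ``n_axes``).  Negative
    eigenvalues — expected for non-Euclidean dissimilarities such as
    Bray-Curtis — are reported unchanged and excluded from the
    proportion-explained denominator; no Cailliez/Lingoes correction.
    """
    a = _check_distance_matrix(d)
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (a**2) @ j
    w, v = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > max(1e-12, 1e-12 * abs(w[0])) if w.size else w > 0
    n_pos = int(pos.sum())
    keep = n_pos if n_axes is None else min(n_axes, n_pos)
    coords = v[:, :keep] * np.sqrt(w[:keep])
    frame = pd.DataFrame(
        coords, index=d.index, columns=[f"PC{i + 1}" for i in range(keep)]
    )
    prop = w[:keep] / w[pos].sum() if n_pos else np.zeros(0)
    return PCoAResult(
        coordinates=frame,
        eigenvalues=w,
        proportion_explained=prop,
        negative_eigenvalues=w[w < 0],
    )


def _permanova_stat(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.where(codes == g)[0]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(
    d: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """One-way PERMANOVA: pseudo-F with a label-permutation p value.

    p = (1 + #{permuted F >= observed}) / (1 + n_perm); permutations are
    unrestricted and seed-deterministic.
    """
    a = _check_distance_matrix(d)
    labels = pd.Categorical(np.asarray(groups))
    codes = labels.codes.astype(np.int64)
    n_groups = len(labels.categories)
    counts = np.bincount(codes, minlength=n_groups)
    if n_groups < 2:
        raise DiversityError("PERMANOVA needs at least two groups")
    if (counts < 2).any():
        small = labels.categories[int(np.argmin(counts))]
        raise DiversityError(f"group {small!r} has fewer than 2 samples")
    if n_perm < 99:
        warnings.warn("fewer than 99 permutations gives a coarse p value")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d2 = a**2
    f_obs = _permanova_stat(d2, codes, n_groups)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _permanova_stat(d2, perm, n_groups) >= f_obs:
            exceed += 1
    return {
        "pseudo_F": f_obs,
        "p_value": (1 + exceed) / (1 + n_perm),
        "n_perm": n_perm,
        "n_groups": n_groups,
    }
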
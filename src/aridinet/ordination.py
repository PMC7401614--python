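"""Beta diversity: Bray-Curtis distances, non-metric MDS, PERMANOVA.

Distances are computed on relative abundances by default (so that unequal
sequencing depth does not masquerade as community turnover); NMDS embeds
the rank order of those distances in k dimensions by minimizing Kruskal
stress-1; PERMANOVA tests group differences with a permutation null on the
distance matrix (Anderson's pseudo-F).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.manifold import MDS


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between sample columns.

    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i); 0 for identical samples,
    1 for disjoint supports.  Accepts counts or proportions.
    """
    totals = table.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total samples: {list(zero.index)}")
    dm = squareform(pdist(table.T.to_numpy(dtype=float), metric="braycurtis"))
    np.fill_diagonal(dm, 0.0)
    return pd.DataFrame(dm, index=table.columns, columns=table.columns)


class NonmetricMDS(BaseEstimator):
    """Non-metric multidimensional scaling with random restarts.

    Minimizes Kruskal stress-1 via SMACOF with monotone regression,
    keeping the lowest-stress configuration over ``n_restarts`` random
    initializations.  Deterministic given ``random_state``.

    Attributes (after :meth:`fit`)
    ------------------------------
    embedding_ : DataFrame, samples x n_components
    stress_ : float
        Kruskal stress-1 of the returned configuration.
    n_restarts_ : int
    """

    def __init__(self, n_components: int = 2, n_restarts: int = 20,
                 max_iter: int = 500, random_state=None):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        ids = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
        D = np.asarray(X, dtype=float)
        if D.shape[0] != D.shape[1]:
            raise ValueError("X must be a square distance matrix")
        if self.n_components >= D.shape[0]:
            raise ValueError("n_components must be < number of samples")
        import inspect

        kwargs = dict(
            n_components=self.n_components, n_init=1, max_iter=self.max_iter,
            eps=1e-9, normalized_stress=True,
        )
        params = inspect.signature(MDS.__init__).parameters
        if "metric_mds" in params:  # sklearn >= 1.9 naming
            kwargs.update(metric="precomputed", metric_mds=False, init="random")
        else:
            kwargs.update(dissimilarity="precomputed", metric=False)
        seeds = np.random.SeedSequence(self.random_state).generate_state(self.n_restarts)
        best_stress, best_coords = np.inf, None
        for seed in seeds:
            mds = MDS(random_state=int(seed), **kwargs)
            coords = mds.fit_transform(D)
            if mds.stress_ < best_stress:
                best_stress, best_coords = float(mds.stress_), coords
        self.embedding_ = pd.DataFrame(
            best_coords, index=ids,
            columns=[f"nmds{i + 1}" for i in range(self.n_components)],
        )
        self.stress_ = best_stress
        self.n_restarts_ = self.n_restarts
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


def nmds(d: pd.DataFrame, k: int = 2, n_restarts: int = 20, seed=None) -> NonmetricMDS:
    """Convenience wrapper: fit :class:`NonmetricMDS` on a distance matrix."""
    return NonmetricMDS(n_components=k, n_restarts=n_restarts, random_state=seed).fit(d)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _ss_within(D2: np.ndarray, codes: np.ndarray, k: int) -> float:
    ssw = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        ssw += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ssw


def permanova(d, grouping, permutations=5000, seed=None) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F = (SS_among / (k-1)) / (SS_within / (n-k)), with sums of
    squares computed directly from squared distances.  The p-value is
    (#{permuted F >= observed} + 1) / (permutations + 1) for Monte-Carlo
    permutations, or the exact proportion over all label orderings when
    ``permutations="exhaustive"`` (small n only).

    Parameters
    ----------
    d
        Square distance matrix (DataFrame or array).
    grouping
        Group label per sample, aligned with ``d``'s order (a Series is
        reindexed by ``d``'s ids).
    """
    if isinstance(d, pd.DataFrame):
        if isinstance(grouping, pd.Series):
            grouping = grouping.reindex(d.index)
            if grouping.isna().any():
                raise ValueError("grouping missing labels for some samples")
        D = d.to_numpy(dtype=float)
    else:
        D = np.asarray(d, dtype=float)
    labels = np.asarray(grouping)
    n = D.shape[0]
    if labels.shape[0] != n:
        raise ValueError("grouping length must match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("need >=2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [str(uniq[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"groups smaller than 2 samples: {small}")

    D2 = D**2
    ss_total = D2.sum() / (2.0 * n)
    ssw_obs = _ss_within(D2, codes, k)

    def pseudo_f(ssw):
        return ((ss_total - ssw) / (k - 1)) / (ssw / (n - k))

    f_obs = pseudo_f(ssw_obs)

    if permutations in ("exhaustive", "exact"):
        fs = [
            pseudo_f(_ss_within(D2, np.asarray(perm), k))
            for perm in itertools.permutations(codes)
        ]
        fs = np.asarray(fs)
        n_perm = len(fs)
        p = float(np.mean(fs >= f_obs - 1e-12))
        return PermanovaResult(float(f_obs), p, n_perm)

    n_perm = int(permutations)
    if n_perm < 1:
        raise ValueError("permutations must be >= 1")
    rng = np.random.default_rng(seed)
    # all permuted label matrices at once: argsort of uniform noise
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_codes = codes[order]  # (n_perm, n)
    ssw = np.zeros(n_perm)
    for g in range(k):
        m = (perm_codes == g).astype(float)  # (n_perm, n)
        ssw += np.einsum("bi,bi->b", m @ D2, m) / (2.0 * sizes[g])
    f_perm = ((ss_total - ssw) / (k - 1)) / (ssw / (n - k))
    p = (np.count_nonzero(f_perm >= f_obs - 1e-12) + 1) / (n_perm + 1)
    return PermanovaResult(float(f_obs), float(p), n_perm)
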
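"""Cluster-number selection and DAPC for SSR genotype data.

Individuals are encoded as allele-copy-count vectors (one column per
locus/allele, entries 0/1/2), centered and scaled, and projected onto
principal components. The number of genetic groups K is chosen by replicated
non-hierarchical K-means: the between-group inertia L(K) is recorded over R
independent runs per K and the Evanno-style second difference

    deltaK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K))

is maximized. BIC(K) = n ln(WSS_K / n) + K ln n is reported as a diagnostic
only. Population structure itself is described by DAPC: PCA followed by
linear discriminant analysis with a shared within-group covariance, whose
Gaussian posterior gives each individual a membership probability per
cluster; the number of retained PCs is chosen by the a-score (reassignment
quality minus the label-permuted expectation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotypes import GenotypeMatrix, PopulationFrame


def allele_indicator_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Individuals x (locus, allele) matrix of allele copy counts (0/1/2).

    Row sums equal 2L for complete data; column sums / 2n are the pooled
    allele frequencies.
    """
    if gm.missing_mask().any():
        raise ValueError("indicator encoding requires complete genotypes")
    cols: list[str] = []
    blocks: list[np.ndarray] = []
    for l, locus in enumerate(gm.locus_ids):
        alleles = np.unique(gm.calls[:, l, :])
        block = np.zeros((gm.n_individuals, alleles.size), dtype=np.int8)
        for k, a in enumerate(alleles):
            block[:, k] = (gm.calls[:, l, :] == a).sum(axis=1)
        blocks.append(block)
        cols.extend(f"{locus}.{int(a)}" for a in alleles)
    return pd.DataFrame(np.hstack(blocks), index=gm.individual_ids, columns=cols)


def _scale(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _pca_scores(X: np.ndarray, var_retained: float = 0.95,
                n_components: int | None = None) -> np.ndarray:
    Xs = _scale(np.asarray(X, dtype=float))
    max_comp = min(Xs.shape) - 1
    if max_comp < 1:
        return Xs
    pca = PCA(n_components=max_comp, svd_solver="full")
    scores = pca.fit_transform(Xs)
    if n_components is not None:
        return scores[:, : min(n_components, max_comp)]
    cum = np.cumsum(pca.explained_variance_ratio_)
    keep = int(np.searchsorted(cum, var_retained) + 1)
    return scores[:, :keep]


@dataclass
class ClusterResult:
    """Replicated K-means summary across a K range."""

    table: pd.DataFrame  # index K; columns mean_L, sd_L, BIC, deltaK
    chosen_k: int
    no_clear_k: bool
    labels: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    n_pca: int | None = None


def compute_delta_k(mean_l: pd.Series, sd_l: pd.Series) -> pd.Series:
    """Evanno-style second difference of a clustering criterion over K.

    Defined on the interior of the K range; sd values of exactly zero (a
    perfectly reproducible optimum) are floored at 1e-12, making such K
    stand out sharply, which is the intended reading of "reproducible
    optimum = accurate clustering".
    """
    ks = mean_l.index.to_numpy()
    out = {}
    for i, k in enumerate(ks):
        if i == 0 or i == len(ks) - 1:
            continue
        second = abs(mean_l.iloc[i + 1] - 2 * mean_l.iloc[i] + mean_l.iloc[i - 1])
        out[int(k)] = second / max(float(sd_l.iloc[i]), 1e-12)
    return pd.Series(out, name="deltaK")


def find_clusters(
    X: np.ndarray | pd.DataFrame,
    k_range: tuple[int, int] = (2, 6),
    n_runs: int = 100,
    iters: int = 50_000,
    starts: int = 5,
    seed: int = 0,
    var_retained: float = 0.95,
) -> ClusterResult:
    """Replicated K-means over a K range with deltaK model selection.

    For each K, ``n_runs`` independent best-of-``starts`` Lloyd K-means fits
    are made on the retained principal components; the between-group sum of
    squares L(K) is the criterion. ``chosen_k`` is the interior K with the
    highest deltaK; ``no_clear_k`` flags a flat deltaK profile (maximum below
    five times the median), mirroring the inconclusive-BIC situation.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 to estimate sd(L)")
    Xv = np.asarray(X, dtype=float)
    scores = _pca_scores(Xv, var_retained)
    n = scores.shape[0]
    k_lo, k_hi = k_range
    if k_lo < 2 or k_hi > n - 1 or k_lo > k_hi:
        raise ValueError("k_range must lie within [2, n-1]")
    tot_ss = float(((scores - scores.mean(axis=0)) ** 2).sum())
    ss = np.random.SeedSequence(seed)
    # K = 1 is analytic: between-group inertia is identically zero, which
    # anchors the second difference so deltaK(k_lo) is defined
    rows = [
        {"K": 1, "mean_L": 0.0, "sd_L": 0.0,
         "BIC": n * np.log(tot_ss / n) + np.log(n) if tot_ss > 0 else -np.inf}
    ]
    labels: dict[int, np.ndarray] = {}
    for k in range(k_lo, k_hi + 1):
        l_vals = np.empty(n_runs)
        best_wss = np.inf
        for r in range(n_runs):
            rs = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            km = KMeans(
                n_clusters=k,
                n_init=starts,
                max_iter=min(iters, 1000),
                algorithm="lloyd",
                random_state=rs,
            ).fit(scores)
            l_vals[r] = tot_ss - km.inertia_
            if km.inertia_ < best_wss:
                best_wss = km.inertia_
                labels[k] = km.labels_.copy()
        bic = n * np.log(best_wss / n) + k * np.log(n) if best_wss > 0 else -np.inf
        rows.append(
            {"K": k, "mean_L": l_vals.mean(), "sd_L": l_vals.std(ddof=1), "BIC": bic}
        )
    table = pd.DataFrame(rows).set_index("K")
    dk = compute_delta_k(table["mean_L"], table["sd_L"])
    table["deltaK"] = dk
    if dk.empty:  # K range too short for an interior point
        chosen = int(table["BIC"].idxmin())
        no_clear = True
    else:
        chosen = int(dk.idxmax())
        no_clear = bool(dk.max() < 5 * dk.median())
    return ClusterResult(
        table=table,
        chosen_k=chosen,
        no_clear_k=no_clear,
        labels=labels,
        n_pca=scores.shape[1],
    )


def dapc(
    X: np.ndarray | pd.DataFrame,
    labels: np.ndarray | pd.Series,
    n_pca: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Membership probabilities from PCA + linear discriminant analysis.

    Rows are individuals, columns the group labels; each row sums to 1.
    ``n_pca`` must satisfy n_pca < n - K; a singular within-group scatter is
    handled by shrinking n_pca with a warning. Deterministic (``seed`` is
    accepted for interface symmetry only).
    """
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    n, k = Xv.shape[0], classes.size
    if n_pca >= n - k:
        warnings.warn(
            f"n_pca={n_pca} >= n - K = {n - k}; reducing", stacklevel=2
        )
        n_pca = max(1, n - k - 1)
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(n)
    while True:
        scores = _pca_scores(Xv, n_components=n_pca)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lda = LinearDiscriminantAnalysis(solver="svd")
                lda.fit(scores, y)
                proba = lda.predict_proba(scores)
            break
        except np.linalg.LinAlgError:
            if n_pca <= 1:
                raise
            warnings.warn(
                f"singular within-group scatter at n_pca={n_pca}; reducing",
                stacklevel=2,
            )
            n_pca -= 1
    return pd.DataFrame(proba, index=index, columns=lda.classes_)


def optimize_a_score(
    X: np.ndarray | pd.DataFrame,
    labels: np.ndarray | pd.Series,
    candidates: list[int] | None = None,
    seed: int = 0,
    n_perm: int = 10,
) -> tuple[int, pd.Series]:
    """Choose the number of PCs for DAPC by the a-score.

    a-score(n_pca) = mean over groups of (correct reassignment rate minus the
    expected rate under label permutation, estimated from ``n_perm``
    permuted fits). Returns (best n_pca, a-score per candidate); ties break
    toward the smallest candidate.
    """
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    n, k = Xv.shape[0], classes.size
    if not candidates:
        hi = max(1, min(Xv.shape[1], n - k - 1))
        candidates = sorted(set(np.linspace(1, hi, num=min(hi, 8), dtype=int)))
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(y) for _ in range(n_perm)]

    def group_rate(yy: np.ndarray, npc: int) -> float:
        proba = dapc(Xv, yy, npc)
        pred = proba.columns.to_numpy()[np.argmax(proba.to_numpy(), axis=1)]
        rates = [np.mean(pred[yy == c] == c) for c in np.unique(yy)]
        return float(np.mean(rates))

    scores = {}
    for npc in candidates:
        obs = group_rate(y, npc)
        null = float(np.mean([group_rate(p, npc) for p in perms]))
        scores[int(npc)] = obs - null
    series = pd.Series(scores, name="a_score")
    best = int(series.index[np.argmax(series.to_numpy())])  # first max = smallest
    return best, series


def population_assignment(
    memberships: pd.DataFrame, pf: PopulationFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-population cluster composition and majority cluster.

    Each individual is attributed to its argmax-membership cluster; the
    table gives, per population, the fraction of individuals per cluster
    (rows sum to 1). The majority cluster is the argmax fraction, ties
    broken toward the lowest cluster index with a warning.
    """
    clusters = memberships.columns
    hard = memberships.columns.to_numpy()[
        np.argmax(memberships.to_numpy(), axis=1)
    ]
    hard = pd.Series(hard, index=memberships.index, name="cluster")
    pops = pf.population_labels
    table = pd.DataFrame(0.0, index=pd.Index(pops, name="population"), columns=clusters)
    for pop in pops:
        ids = pf.individuals_of(pop)
        vc = hard.loc[ids].value_counts(normalize=True)
        table.loc[pop, vc.index] = vc.to_numpy()
    fracs = table.to_numpy()
    majority = []
    for i, pop in enumerate(pops):
        best = fracs[i].max()
        tied = np.flatnonzero(np.isclose(fracs[i], best))
        if len(tied) > 1:
            warnings.warn(f"population {pop}: majority-cluster tie", stacklevel=2)
        majority.append(clusters[tied[0]])
    return table, pd.Series(majority, index=table.index, name="majority_cluster")
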
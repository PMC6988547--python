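"""Compositional genetic differentiation at levels of genetic integration.

A population j is described by a relative-frequency distribution over
"types": allele copies (gene-pool level), unordered single-locus genotypes
(SLG), or full multi-locus genotypes (MLG). Its differentiation Delta_j is
the total-variation distance d0 = 1/2 * sum |p - q| between the population's
distribution and that of its pooled complement (all other individuals pooled
with equal weight). The subdivision differentiation Delta_SD is the
sample-size-weighted mean of the Delta_j.

Because alleles are a marginalization of single-locus genotypes, and each
single-locus genotype a marginalization of the multi-locus genotype, total
variation cannot increase when moving down a level, giving the ordering

    Delta_SD(gene pool) <= Delta_SD(mean SLG) <= Delta_SD(MLG)

for every data set.

Two permutation analyses probe which associations carry the differentiation:
(1) permuting gene copies among individuals *within* each population
destroys genotypic associations while preserving every population's allele
counts (so the gene-pool level is invariant by construction); (2) permuting
individuals *among* populations (sample sizes fixed) destroys the
population-type association at any level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, PopulationFrame

LEVELS = ("genepool", "slg", "mlg")


@dataclass
class TypeDistribution:
    """Relative frequencies over types at one integration level."""

    level: str
    freqs: pd.Series
    locus: str | None = None  # absent at the MLG level

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        f = pd.Series(self.freqs, dtype=float)
        if (f < 0).any():
            raise ValueError("frequencies must be non-negative")
        if f.index.duplicated().any():
            raise ValueError("support labels must be unique")
        if not np.isclose(f.sum(), 1.0, atol=1e-9):
            raise ValueError("frequencies must sum to 1")
        self.freqs = f


def d0(p: TypeDistribution, q: TypeDistribution) -> float:
    """Total-variation distance 1/2 * sum_t |p_t - q_t| over the union support.

    A metric on distributions, 0 for identical compositions and 1 for
    disjoint supports.
    """
    if p.level != q.level or p.locus != q.locus:
        raise ValueError("distributions are at different levels/loci")
    support = p.freqs.index.union(q.freqs.index)
    pv = p.freqs.reindex(support, fill_value=0.0).to_numpy()
    qv = q.freqs.reindex(support, fill_value=0.0).to_numpy()
    return float(0.5 * np.abs(pv - qv).sum())


@dataclass
class DifferentiationResult:
    """Delta_j per population, Delta_SD, and (optional) permutation nulls."""

    level: str
    delta_j: pd.Series
    delta_sd: float
    weights: pd.Series
    aggregation: str = "mean"
    B: int = 0
    rng_seed: int | None = None
    perm1_null: np.ndarray | None = None
    perm2_null: np.ndarray | None = None
    perm1_exceeds95: bool | None = None
    perm2_exceeds95: bool | None = None
    perm1_p: float | None = None
    perm2_p: float | None = None
    per_locus_delta_j: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        assert np.isclose(
            self.delta_sd, float((self.weights * self.delta_j).sum()), atol=1e-12
        )

    def to_dict(self) -> dict:
        out = {
            "level": self.level,
            "aggregation": self.aggregation,
            "delta_j": {k: float(v) for k, v in self.delta_j.items()},
            "delta_sd": float(self.delta_sd),
            "weights": {k: float(v) for k, v in self.weights.items()},
            "B": int(self.B),
            "rng_seed": self.rng_seed,
        }
        for name in ("perm1", "perm2"):
            null = getattr(self, f"{name}_null")
            out[name] = (
                None
                if null is None
                else {
                    "null_delta_sd": [float(x) for x in null],
                    "exceeds95": bool(getattr(self, f"{name}_exceeds95")),
                    "p_value": getattr(self, f"{name}_p"),
                }
            )
        return out


# ---------------------------------------------------------------------------
# integer-coded internals
# ---------------------------------------------------------------------------


def _indexed(gm: GenotypeMatrix, pf: PopulationFrame):
    """Allele-index calls (n, L, 2), per-locus allele alphabets, pop codes."""
    if gm.missing_mask().any():
        raise ValueError("differentiation requires complete (filtered) genotypes")
    n, L = gm.n_individuals, gm.n_loci
    idx_calls = np.empty((n, L, 2), dtype=np.int64)
    alphabets = []
    for l in range(L):
        alleles, inv = np.unique(gm.calls[:, l, :], return_inverse=True)
        idx_calls[:, l, :] = inv.reshape(n, 2)
        alphabets.append(alleles)
    pops = pf.population_labels
    if len(pops) < 2:
        raise ValueError("at least two populations are required")
    pop_index = {p: k for k, p in enumerate(pops)}
    order = {ind: i for i, ind in enumerate(gm.individual_ids)}
    pop_codes = np.empty(n, dtype=np.int64)
    for ind, pop in pf.assignment.items():
        pop_codes[order[ind]] = pop_index[pop]
    return idx_calls, alphabets, pop_codes, pops


def _counts_matrix(codes: np.ndarray, pop_codes: np.ndarray, K: int, T: int,
                   reps: int = 1) -> np.ndarray:
    """(K, T) occurrence counts from per-item type codes (items may repeat)."""
    flat = pop_codes * T + codes
    return np.bincount(flat, minlength=K * T).reshape(K, T)


def _d0_rows(counts: np.ndarray) -> np.ndarray:
    """Delta_j for every population from a (K, T) counts matrix.

    Complement counts are the column totals minus the population's row, i.e.
    all other individuals pooled with equal weight.
    """
    totals = counts.sum(axis=0)
    row_sums = counts.sum(axis=1, keepdims=True).astype(float)
    comp = totals[None, :] - counts
    comp_sums = comp.sum(axis=1, keepdims=True).astype(float)
    if (row_sums == 0).any() or (comp_sums == 0).any():
        raise ValueError("empty population or empty complement")
    p = counts / row_sums
    q = comp / comp_sums
    return 0.5 * np.abs(p - q).sum(axis=1)


def _slg_codes(idx_calls: np.ndarray, n_alleles: int, locus: int) -> np.ndarray:
    lo = idx_calls[:, locus, 0]
    hi = idx_calls[:, locus, 1]
    return lo * n_alleles + hi  # pairs are stored sorted, so this is unordered


def _mlg_codes(idx_calls: np.ndarray, alphabets: list[np.ndarray]) -> np.ndarray:
    """Mixed-radix multi-locus genotype code, then compacted to 0..T-1."""
    n = idx_calls.shape[0]
    code = np.zeros(n, dtype=np.int64)
    for l, alleles in enumerate(alphabets):
        radix = len(alleles) * len(alleles)
        code = code * radix + _slg_codes(idx_calls, len(alleles), l)
    _, compact = np.unique(code, return_inverse=True)
    return compact


def _delta_arrays(
    idx_calls: np.ndarray,
    alphabets: list[np.ndarray],
    pop_codes: np.ndarray,
    K: int,
    level: str,
    aggregation: str = "mean",
) -> tuple[np.ndarray, np.ndarray | None]:
    """Delta_j vector (and per-locus matrix for genepool/slg) for one level."""
    L = len(alphabets)
    if level == "mlg":
        codes = _mlg_codes(idx_calls, alphabets)
        T = int(codes.max()) + 1
        return _d0_rows(_counts_matrix(codes, pop_codes, K, T)), None
    per_locus = np.empty((K, L))
    stacked: list[np.ndarray] = []
    for l in range(L):
        A = len(alphabets[l])
        if level == "genepool":
            codes = idx_calls[:, l, :].ravel()
            pcodes = np.repeat(pop_codes, 2)
            counts = _counts_matrix(codes, pcodes, K, A)
        else:  # slg
            codes = _slg_codes(idx_calls, A, l)
            counts = _counts_matrix(codes, pop_codes, K, A * A)
        per_locus[:, l] = _d0_rows(counts)
        stacked.append(counts)
    if aggregation == "mean":
        return per_locus.mean(axis=1), per_locus
    if aggregation == "pooled":
        return _d0_rows(np.hstack(stacked)), per_locus
    raise ValueError("aggregation must be 'mean' or 'pooled'")


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def build_distribution(
    gm: GenotypeMatrix,
    pf: PopulationFrame,
    level: str,
    population: str | None = None,
    complement_of: str | None = None,
    locus: str | None = None,
) -> TypeDistribution:
    """Type-frequency distribution of one population or of a pooled complement.

    Gene-pool and SLG levels require a ``locus``; the complement pools the
    individuals of every other population with equal weight.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    if (population is None) == (complement_of is None):
        raise ValueError("give exactly one of population / complement_of")
    target = population or complement_of
    if target not in pf.population_labels:
        raise KeyError(f"unknown population {target!r}")
    member = pf.assignment == target
    if complement_of is not None:
        member = ~member
        if not member.any():
            raise ValueError("empty complement: input has a single population")
    order = {ind: i for i, ind in enumerate(gm.individual_ids)}
    sel = np.array([order[i] for i in pf.assignment.index[member]], dtype=int)

    if level == "mlg":
        labels = [
            "|".join(f"{a}/{b}" for a, b in gm.calls[i]) for i in sel
        ]
        vc = pd.Series(labels).value_counts()
        return TypeDistribution("mlg", vc / vc.sum())
    if locus is None:
        raise ValueError(f"{level} level requires a locus")
    l = gm.locus_ids.index(locus)
    pairs = gm.calls[sel, l, :]
    pairs = pairs[(pairs != MISSING).all(axis=1)]
    if level == "genepool":
        vc = pd.Series(pairs.ravel()).value_counts()
    else:
        vc = pd.Series([f"{a}/{b}" for a, b in pairs]).value_counts()
    return TypeDistribution(level, vc / vc.sum(), locus=locus)


def delta(
    gm: GenotypeMatrix,
    pf: PopulationFrame,
    level: str,
    aggregation: str = "mean",
    weighted: bool = True,
) -> DifferentiationResult:
    """Delta_j and Delta_SD at one integration level (no permutations).

    At the gene-pool and SLG levels the per-locus d0 values are averaged
    with equal locus weight before forming Delta_j (``aggregation='mean'``);
    ``'pooled'`` instead concatenates the per-locus type spaces into one
    distribution. Delta_SD weights populations by n_j / n (``weighted``) or
    equally.
    """
    idx_calls, alphabets, pop_codes, pops = _indexed(gm, pf)
    K = len(pops)
    dj, per_locus = _delta_arrays(
        idx_calls, alphabets, pop_codes, K, level, aggregation
    )
    sizes = np.bincount(pop_codes, minlength=K)
    w = sizes / sizes.sum() if weighted else np.full(K, 1.0 / K)
    delta_j = pd.Series(dj, index=pops, name="delta_j")
    weights = pd.Series(w, index=pops, name="weight")
    pld = (
        pd.DataFrame(per_locus, index=pops, columns=gm.locus_ids)
        if per_locus is not None
        else None
    )
    return DifferentiationResult(
        level=level,
        delta_j=delta_j,
        delta_sd=float((delta_j * weights).sum()),
        weights=weights,
        aggregation=aggregation,
        per_locus_delta_j=pld,
    )


def _delta_sd_from_arrays(idx_calls, alphabets, pop_codes, K, level, aggregation,
                          weights) -> float:
    dj, _ = _delta_arrays(idx_calls, alphabets, pop_codes, K, level, aggregation)
    return float((dj * weights).sum())


def _exceeds95(null: np.ndarray, observed: float) -> bool:
    # "higher than 95% of all null values": strict >, ties count against
    return bool(np.sum(null < observed - 1e-12) > 0.95 * len(null))


def _upper_p(null: np.ndarray, observed: float) -> float:
    return float((1 + np.sum(null >= observed - 1e-12)) / (1 + len(null)))


def permutation_alleles_within(
    gm: GenotypeMatrix,
    pf: PopulationFrame,
    level: str,
    B: int = 1000,
    seed: int = 0,
    aggregation: str = "mean",
    weighted: bool = True,
) -> DifferentiationResult:
    """Permutation analysis 1: shuffle gene copies within population x locus.

    Each replicate independently re-pairs the 2 n_j allele copies of every
    population at every locus, destroying Hardy-Weinberg and inter-locus
    associations while preserving all allele counts; Delta_SD is then
    recomputed at the requested level. The gene-pool level is invariant by
    construction, which is asserted. Replicate b uses its own RNG stream
    derived from (seed, b), so results do not depend on evaluation order.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    result = delta(gm, pf, level, aggregation, weighted)
    idx_calls, alphabets, pop_codes, pops = _indexed(gm, pf)
    K = len(pops)
    weights = result.weights.to_numpy()
    blocks = [np.flatnonzero(pop_codes == k) for k in range(K)]
    null = np.empty(B)
    for b in range(B):
        rng = np.random.default_rng([seed, 1, b])
        shuffled = idx_calls.copy()
        for sel in blocks:
            for l in range(len(alphabets)):
                copies = shuffled[sel, l, :].ravel()
                rng.shuffle(copies)
                shuffled[sel, l, :] = np.sort(copies.reshape(-1, 2), axis=1)
        null[b] = _delta_sd_from_arrays(
            shuffled, alphabets, pop_codes, K, level, aggregation, weights
        )
    if level == "genepool":
        assert np.allclose(null, result.delta_sd, atol=1e-9), (
            "gene-pool Delta_SD must be invariant under within-population "
            "allele permutation"
        )
    result.B = B
    result.rng_seed = seed
    result.perm1_null = null
    result.perm1_exceeds95 = _exceeds95(null, result.delta_sd)
    result.perm1_p = _upper_p(null, result.delta_sd)
    return result


def permutation_individuals_among(
    gm: GenotypeMatrix,
    pf: PopulationFrame,
    level: str,
    B: int = 1000,
    seed: int = 0,
    aggregation: str = "mean",
    weighted: bool = True,
) -> DifferentiationResult:
    """Permutation analysis 2: shuffle whole individuals among populations.

    Sample sizes n_j are held fixed; each replicate permutes which
    individuals (with their full genotypes) belong to which population and
    recomputes Delta_SD. The one-sided p-value is
    (1 + #{null >= observed}) / (1 + B).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    result = delta(gm, pf, level, aggregation, weighted)
    idx_calls, alphabets, pop_codes, pops = _indexed(gm, pf)
    K = len(pops)
    weights = result.weights.to_numpy()
    null = np.empty(B)
    for b in range(B):
        rng = np.random.default_rng([seed, 2, b])
        perm_codes = rng.permutation(pop_codes)
        null[b] = _delta_sd_from_arrays(
            idx_calls, alphabets, perm_codes, K, level, aggregation, weights
        )
    result.B = B
    result.rng_seed = seed
    result.perm2_null = null
    result.perm2_exceeds95 = _exceeds95(null, result.delta_sd)
    result.perm2_p = _upper_p(null, result.delta_sd)
    return result


def differentiation_analysis(
    gm: GenotypeMatrix,
    pf: PopulationFrame,
    levels: tuple[str, ...] = LEVELS,
    B: int = 1000,
    seed: int = 0,
    aggregation: str = "mean",
    weighted: bool = True,
) -> dict[str, DifferentiationResult]:
    """Run Delta plus both permutation analyses at each requested level."""
    out: dict[str, DifferentiationResult] = {}
    for level in levels:
        r1 = permutation_alleles_within(gm, pf, level, B, seed, aggregation, weighted)
        r2 = permutation_individuals_among(gm, pf, level, B, seed, aggregation, weighted)
        r1.perm2_null = r2.perm2_null
        r1.perm2_exceeds95 = r2.perm2_exceeds95
        r1.perm2_p = r2.perm2_p
        out[level] = r1
    return out


def snail_export(result: DifferentiationResult) -> pd.DataFrame:
    """Polar-plot table: per population Delta_j, its contribution w_j * Delta_j,
    and cumulative angles (sector angle proportional to the weight).

    Contributions sum to Delta_SD; the table carries ``delta_sd`` in
    ``DataFrame.attrs``.
    """
    out = pd.DataFrame(
        {
            "delta_j": result.delta_j,
            "weight": result.weights,
            "contribution": result.delta_j * result.weights,
        }
    )
    angles = 2 * np.pi * result.weights.to_numpy()
    out["angle_start"] = np.concatenate([[0.0], np.cumsum(angles)[:-1]])
    out["angle_end"] = np.cumsum(angles)
    out["cum_contribution"] = out["contribution"].cumsum()
    out.index.name = "population"
    out.attrs["delta_sd"] = float(result.delta_sd)
    out.attrs["level"] = result.level
    return out
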
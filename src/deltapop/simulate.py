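"""Synthetic SSR genotype data with the structure the analysis assumes.

The generator emulates a two-region (N/S) hierarchy of small, partially
selfing, partially clonal populations typed at a handful of multi-allelic
microsatellite loci. Allele frequencies drift down a Dirichlet hierarchy:

    ancestral  p_l           ~ Dirichlet(alpha * 1)
    regional   p_rl          ~ Dirichlet(theta_region * p_l)
    population p_jl          ~ Dirichlet(theta_pop * p_{r(j),l})

(smaller theta = stronger drift). Within a population, each individual is
either an exact clone of a previously generated member (probability c) or a
fresh draw under the partial-selfing equilibrium with inbreeding coefficient
F_eq = s / (2 - s): a homozygote aa with probability p_a^2 + F_eq p_a (1-p_a),
a heterozygote ab with probability 2 p_a p_b (1 - F_eq). Missing calls are
masked at rate m.

Defaults reproduce the sampling design of the German Helosciadium repens
survey this toolkit analyzes: 27 populations with the published per-site
sample sizes (715 individuals in total, 14 Northern and 13 Southern sites)
and six loci whose allele counts span four to nine (38 alleles in total).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, PopulationFrame

#: Published per-population sample sizes of the 27-site survey (sum = 715).
STUDY_POP_SIZES: tuple[int, ...] = (
    27, 28, 29, 7, 25, 26, 30, 30, 29, 30, 26, 30, 15,  # Northern sites
    29, 30, 28, 27, 30, 29, 30, 29, 30, 29, 28, 29, 26, 9,  # Southern sites
)
#: Number of Northern populations among the defaults.
STUDY_N_NORTH: int = 13


@dataclass
class SimulationParams:
    """Parameters of the Dirichlet-drift SSR generator (see module docs)."""

    pop_sizes: Sequence[int] = STUDY_POP_SIZES
    n_north: int = STUDY_N_NORTH
    allele_counts: Sequence[int] = (4, 5, 6, 7, 7, 9)
    alpha: float = 1.0
    theta_region: float = 30.0
    theta_pop: float = 10.0
    selfing: float | Sequence[float] = 0.5
    clonality: float | Sequence[float] = 0.3
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a < 1 for a in self.allele_counts):
            raise ValueError("every locus needs at least one allele")
        if any(n < 1 for n in self.pop_sizes):
            raise ValueError("population sizes must be positive")
        s = np.atleast_1d(np.asarray(self.selfing, dtype=float))
        if (s < 0).any() or (s > 1).any():
            raise ValueError("selfing must lie in [0, 1]")
        c = np.atleast_1d(np.asarray(self.clonality, dtype=float))
        if (c < 0).any() or (c >= 1).any():
            raise ValueError("clonality must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")

    def per_pop(self, value: float | Sequence[float]) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if arr.size == 1:
            return np.full(len(self.pop_sizes), float(arr[0]))
        if arr.size != len(self.pop_sizes):
            raise ValueError("per-population parameter has wrong length")
        return arr


def expected_fis(s: float) -> float:
    """Equilibrium inbreeding coefficient under partial selfing, s / (2 - s)."""
    if not 0 <= s <= 1:
        raise ValueError("selfing rate must lie in [0, 1]")
    return s / (2.0 - s)


@dataclass
class SimulationTruth:
    """Latent state of one simulated data set."""

    ancestral: list[np.ndarray]
    regional: dict[str, list[np.ndarray]]
    population: dict[str, list[np.ndarray]]
    f_eq: dict[str, float]
    clone_parent: dict[str, str | None]

    def to_dict(self) -> dict:
        return {
            "ancestral": [p.tolist() for p in self.ancestral],
            "regional": {
                r: [p.tolist() for p in ps] for r, ps in self.regional.items()
            },
            "population": {
                j: [p.tolist() for p in ps] for j, ps in self.population.items()
            },
            "f_eq": self.f_eq,
            "clone_parent": self.clone_parent,
        }


def _draw_genotype(p: np.ndarray, f_eq: float, rng: np.random.Generator) -> tuple[int, int]:
    if rng.random() < f_eq:
        a = int(rng.choice(len(p), p=p))
        return a, a
    a, b = rng.choice(len(p), size=2, p=p)
    return int(a), int(b)


def simulate(
    params: SimulationParams | None = None, seed: int | None = None
) -> tuple[GenotypeMatrix, PopulationFrame, SimulationTruth]:
    """Generate one SSR data set; reproducible given the seed.

    Returns the genotype matrix (allele codes are 101, 102, ... per locus,
    mimicking fragment lengths), a population frame with minimal metadata
    (region, EGU, form, size class), and the latent truth record.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    K = len(params.pop_sizes)
    L = len(params.allele_counts)
    regions = ["N" if j < params.n_north else "S" for j in range(K)]
    selfing = params.per_pop(params.selfing)
    clonality = params.per_pop(params.clonality)

    ancestral = [
        rng.dirichlet(np.full(a, params.alpha)) for a in params.allele_counts
    ]
    regional = {
        r: [rng.dirichlet(params.theta_region * p + 1e-12) for p in ancestral]
        for r in ("N", "S")
    }
    pop_labels = [f"P{j + 1:02d}" for j in range(K)]
    pop_freqs = {
        lab: [
            rng.dirichlet(params.theta_pop * regional[regions[j]][l] + 1e-12)
            for l in range(L)
        ]
        for j, lab in enumerate(pop_labels)
    }

    individual_ids: list[str] = []
    assignment: list[str] = []
    calls = np.empty((sum(params.pop_sizes), L, 2), dtype=np.int32)
    f_eq = {}
    clone_parent: dict[str, str | None] = {}
    row = 0
    for j, lab in enumerate(pop_labels):
        fe = expected_fis(selfing[j])
        f_eq[lab] = fe
        members: list[int] = []
        for i in range(params.pop_sizes[j]):
            ind = f"{lab}_{i + 1:03d}"
            if members and rng.random() < clonality[j]:
                parent = int(rng.choice(members))
                calls[row] = calls[parent]
                clone_parent[ind] = individual_ids[parent]
            else:
                for l in range(L):
                    a, b = _draw_genotype(pop_freqs[lab][l], fe, rng)
                    calls[row, l, 0] = 101 + min(a, b)
                    calls[row, l, 1] = 101 + max(a, b)
                clone_parent[ind] = None
            members.append(row)
            individual_ids.append(ind)
            assignment.append(lab)
            row += 1

    if params.missing_rate > 0:
        mask = rng.random(calls.shape[:2]) < params.missing_rate
        calls[mask] = MISSING

    gm = GenotypeMatrix(individual_ids, [f"L{l + 1}" for l in range(L)], calls)
    sizes = np.asarray(params.pop_sizes)
    meta = pd.DataFrame(
        {
            "region": regions,
            "egu": [f"{regions[j]}-EGU{j // 2 + 1}" for j in range(K)],
            "form": ["aqu" if j % 3 == 2 else "terr" for j in range(K)],
            "size_class": np.where(
                sizes <= 15, "small", np.where(sizes >= 29, "large", "medium")
            ),
            "n": sizes,
        },
        index=pd.Index(pop_labels, name="population"),
    )
    counts = meta["egu"].value_counts()
    meta["only_egu_representative"] = meta["egu"].map(counts).eq(1)
    for flag in ("immediate_threat", "management_plan", "protected_area",
                 "introduced", "low_vitality", "collaboration"):
        meta[flag] = False
    pf = PopulationFrame(pd.Series(assignment, index=individual_ids), meta)
    truth = SimulationTruth(ancestral, regional, pop_freqs, f_eq, clone_parent)
    return gm, pf, truth
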
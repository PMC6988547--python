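"""Rule-based selection of most appropriate wild populations (MAWPs).

Turns per-population genetics (the gene-pool Delta_j) and site metadata
(eco-geographic unit, size class, threat/management/protection flags) into a
deterministic portfolio of genetic-reserve candidates, with a justification
listing every fired rule for each population.

Rules, in order:

1. *Delta extremes* — the populations with the lowest and highest Delta_j
   are seeded into the portfolio: the minimum best represents the pooled
   remainder, the maximum is the most distinct composition.
2. *Threat exclusion* — populations with an immediate threat are never
   selected (even sole EGU representatives; the EGU is then uncovered).
3. *Large size* — large populations are selected outright: population size
   is the primary viability criterion for a reserve.
4. *Protection/management* — populations inside a protected area or with an
   existing management plan are selected outright: the infrastructure for
   long-term conservation already exists.
5. *EGU coverage* — every eco-geographic unit must hold at least one
   selected population (adaptive-variation proxy). Uncovered EGUs receive
   their lexicographically best eligible population by the configured
   quality order (size class, then protection, management, vitality,
   collaboration; population label as final deterministic tie-break).
6. *Suboptimal flag* — a selected population that is its EGU's only
   representative but is small or introduced is marked complementary-but-
   suboptimal.

The engine argues by dominance (lexicographic priority), not by weighted
scores, and is independent of input row order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .genotypes import SIZE_CLASSES

_SIZE_ORDINAL = {s: i for i, s in enumerate(SIZE_CLASSES)}


@dataclass
class SelectionConfig:
    """Switches and the lexicographic quality order of the rule engine."""

    include_delta_extremes: bool = True
    exclude_threatened: bool = True
    select_large: bool = True
    select_protected_or_managed: bool = True
    require_egu_coverage: bool = True
    quality_order: tuple[str, ...] = (
        "size_class",
        "protected_area",
        "management_plan",
        "not_low_vitality",
        "collaboration",
    )


@dataclass
class MawpDecision:
    """Outcome for one population, with the rules that fired."""

    population: str
    selected: bool
    suboptimal: bool = False
    justification: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.selected:
            assert not self.suboptimal, "suboptimal applies only to selected"
        if self.selected:
            assert self.justification, "selected populations need a justification"


def _quality_key(row: pd.Series, order: tuple[str, ...]) -> tuple:
    key = []
    for crit in order:
        if crit == "size_class":
            key.append(_SIZE_ORDINAL.get(row.get("size_class", "medium"), 1))
        elif crit == "not_low_vitality":
            key.append(0 if row.get("low_vitality", False) else 1)
        else:
            key.append(1 if row.get(crit, False) else 0)
    return tuple(key)


def select_mawps(
    delta_j: pd.Series,
    metadata: pd.DataFrame,
    cfg: SelectionConfig | None = None,
) -> list[MawpDecision]:
    """Run the rule engine.

    Parameters
    ----------
    delta_j
        Gene-pool Delta_j per population (index = population label).
    metadata
        Per-population table as produced by
        :func:`deltapop.genotypes.read_metadata` (flags, egu, size_class...).
    """
    cfg = cfg or SelectionConfig()
    pops = sorted(metadata.index)  # input-order independence
    missing = [p for p in pops if p not in delta_j.index or pd.isna(delta_j[p])]
    if cfg.include_delta_extremes and missing:
        raise ValueError(f"delta_j missing for populations: {missing}")

    reasons: dict[str, list[str]] = {p: [] for p in pops}
    excluded: set[str] = set()
    if cfg.exclude_threatened:
        for p in pops:
            if metadata.loc[p].get("immediate_threat", False):
                excluded.add(p)
                reasons[p].append("excluded: immediate threat recorded at the site")

    eligible = [p for p in pops if p not in excluded]
    selected: set[str] = set()

    if cfg.include_delta_extremes and eligible:
        sub = delta_j[eligible]
        lo, hi = sub.idxmin(), sub.idxmax()
        selected.add(lo)
        reasons[lo].append(
            f"lowest gene-pool differentiation (Delta_j = {sub[lo]:.4f}): best "
            "single representative of the pooled remainder"
        )
        selected.add(hi)
        reasons[hi].append(
            f"highest gene-pool differentiation (Delta_j = {sub[hi]:.4f}): most "
            "distinct composition in the set"
        )

    if cfg.select_large:
        for p in eligible:
            if metadata.loc[p].get("size_class", "medium") == "large":
                selected.add(p)
                reasons[p].append("large population size (long-term viability)")

    if cfg.select_protected_or_managed:
        for p in eligible:
            row = metadata.loc[p]
            if row.get("protected_area", False):
                selected.add(p)
                reasons[p].append("lies within a protected area")
            if row.get("management_plan", False):
                selected.add(p)
                reasons[p].append("management plan already in place")

    if cfg.require_egu_coverage:
        for egu in sorted(metadata["egu"].unique()):
            members = [p for p in pops if metadata.loc[p, "egu"] == egu]
            if any(p in selected for p in members):
                continue
            candidates = [p for p in members if p in eligible]
            if not candidates:
                warnings.warn(
                    f"EGU {egu!r} has no eligible population and stays uncovered",
                    stacklevel=2,
                )
                continue
            keys = {
                p: _quality_key(metadata.loc[p], cfg.quality_order)
                for p in candidates
            }
            best_key = max(keys.values())
            # quality ties resolve toward the smallest label, deterministically
            best = min(p for p in candidates if keys[p] == best_key)
            selected.add(best)
            reasons[best].append(
                f"best eligible representative of EGU {egu!r} by the quality order"
            )

    decisions = []
    for p in pops:
        sel = p in selected
        subopt = False
        if sel:
            row = metadata.loc[p]
            if row.get("only_egu_representative", False) and (
                row.get("size_class", "medium") == "small"
                or row.get("introduced", False)
            ):
                subopt = True
                why = "critically small" if row.get("size_class") == "small" else "introduced"
                reasons[p].append(
                    f"complementary but suboptimal: only representative of its "
                    f"EGU, yet {why}"
                )
        decisions.append(MawpDecision(p, sel, subopt, reasons[p]))
    return decisions


def decisions_frame(decisions: list[MawpDecision]) -> pd.DataFrame:
    """Tabular view of the decisions (one row per population)."""
    return pd.DataFrame(
        {
            "population": [d.population for d in decisions],
            "selected": [d.selected for d in decisions],
            "suboptimal": [d.suboptimal for d in decisions],
            "justification": ["; ".join(d.justification) for d in decisions],
        }
    ).set_index("population")
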
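"""Genotype containers and file I/O for diploid SSR data.

The central objects are :class:`GenotypeMatrix` — an individuals x loci table
of unordered diploid allele pairs, where alleles are positive integer codes
(semantically PCR fragment lengths) — and :class:`PopulationFrame`, which maps
individuals to populations and carries per-population metadata used by the
reserve-selection rules (region, eco-geographic unit, size class, threat and
management flags).

Genotypes are read and written in the genepop text dialect: a title line,
one locus name per line (or a single comma-separated line), populations
separated by lines equal to ``Pop``, and one individual per line as
``label ,  dddddd dddddd ...`` with fixed-width 2- or 3-digit allele codes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel allele code for a missing call. A call with either allele missing
#: is treated as entirely missing.
MISSING: int = -1

REGIONS = ("N", "S")
SIZE_CLASSES = ("small", "medium", "large")
FLAG_COLUMNS = (
    "immediate_threat",
    "management_plan",
    "protected_area",
    "introduced",
    "only_egu_representative",
    "low_vitality",
    "collaboration",
)


class GenepopFormatError(ValueError):
    """Raised when a genepop file violates the dialect."""


@dataclass
class GenotypeMatrix:
    """Unordered diploid calls for ``n`` individuals at ``L`` loci.

    Parameters
    ----------
    individual_ids
        Unique labels, one per row of ``calls``.
    locus_ids
        Unique locus labels.
    calls
        Integer array of shape ``(n, L, 2)``. Each pair is stored sorted
        ascending so that ``(a, b)`` and ``(b, a)`` are identical; missing
        calls hold :data:`MISSING` in both slots.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        calls = np.asarray(self.calls, dtype=np.int32)
        if calls.ndim != 3 or calls.shape[2] != 2:
            raise ValueError("calls must have shape (n_individuals, n_loci, 2)")
        if calls.shape[0] != len(self.individual_ids):
            raise ValueError("calls rows do not match individual_ids")
        if calls.shape[1] != len(self.locus_ids):
            raise ValueError("calls columns do not match locus_ids")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual_ids must be unique")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("locus_ids must be unique")
        if len(self.locus_ids) < 1:
            raise ValueError("at least one locus is required")
        # canonicalize: propagate missingness to the whole call, sort pairs
        calls = np.sort(calls, axis=2)
        missing = (calls == MISSING).any(axis=2)
        calls[missing] = MISSING
        self.calls = calls

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L) mask of missing calls."""
        return (self.calls == MISSING).all(axis=2)

    def subset(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in idx],
            list(self.locus_ids),
            self.calls[idx].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class PopulationFrame:
    """Individual-to-population assignment plus per-population metadata.

    ``assignment`` is a pandas Series indexed by individual id with the
    population label as value. ``populations`` (optional) is a DataFrame
    indexed by population label with columns ``region`` (N|S), ``egu``,
    ``form`` (terr|aqu), ``size_class`` (small < medium < large) and the
    boolean flags of :data:`FLAG_COLUMNS`; unknown columns are preserved.
    """

    assignment: pd.Series
    populations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.assignment = pd.Series(self.assignment).astype(str)
        self.assignment.index = self.assignment.index.astype(str)
        if self.populations is not None:
            self.populations = self.populations.copy()
            self.populations.index = self.populations.index.astype(str)

    @property
    def population_labels(self) -> list[str]:
        """Population labels in order of first appearance in the assignment."""
        seen: dict[str, None] = {}
        for p in self.assignment:
            seen.setdefault(p, None)
        return list(seen)

    def sizes(self) -> pd.Series:
        """Number of assigned individuals n_j per population."""
        counts = self.assignment.value_counts()
        return counts.reindex(self.population_labels).rename("n_j")

    def individuals_of(self, population: str) -> list[str]:
        return list(self.assignment.index[self.assignment == population])

    def subset(self, individual_ids: Iterable[str]) -> "PopulationFrame":
        ids = list(individual_ids)
        return PopulationFrame(self.assignment.loc[ids], self.populations)

    def with_metadata(self, populations: pd.DataFrame) -> "PopulationFrame":
        return PopulationFrame(self.assignment, populations)


@dataclass
class ExclusionReport:
    """Individuals removed by the completeness filter, with offending loci."""

    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["individual", "missing_loci"])
    )

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def to_tsv(self, path: str | os.PathLike) -> None:
        out = self.excluded.copy()
        out["missing_loci"] = out["missing_loci"].map(lambda v: ",".join(v))
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genepop dialect
# ---------------------------------------------------------------------------


def _detect_width(fields: list[str], lineno: int) -> int:
    w = len(fields[0])
    if w not in (4, 6):
        raise GenepopFormatError(
            f"line {lineno}: genotype field '{fields[0]}' has width {w}; expected 4 or 6"
        )
    return w


def read_genepop(
    path: str | os.PathLike, missing_code: str | None = None
) -> tuple[GenotypeMatrix, PopulationFrame]:
    """Parse a genepop file into a genotype matrix and population assignment.

    The allele-code width (2 or 3 digits per allele) is auto-detected from the
    first genotype field and enforced for the whole file. An allele equal to
    ``missing_code`` (default ``000``/``00`` depending on width) marks the
    whole call missing. Populations are labelled ``Pop1..PopK`` in file order
    unless every population block shares a distinct common label prefix.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopFormatError("empty file")

    # title, then locus names until the first Pop separator
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        entry = lines[i].strip()
        if entry:
            loci.extend(x.strip() for x in entry.split(",") if x.strip())
        i += 1
    if not loci:
        raise GenepopFormatError("no locus lines before the first 'Pop' separator")
    if i == len(lines):
        raise GenepopFormatError("no 'Pop' separator found")

    width: int | None = None
    pops: list[list[tuple[str, list[tuple[int, int]]]]] = []
    current: list[tuple[str, list[tuple[int, int]]]] = []
    for lineno, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            if current or not pops:
                pops.append(current)
                current = []
            continue
        if "," in line:
            label, _, geno = line.partition(",")
            label = label.strip()
        else:  # tolerate a missing comma: first token is the label
            label, _, geno = line.partition(" ")
        fields = geno.split()
        if len(fields) != len(loci):
            raise GenepopFormatError(
                f"line {lineno}: expected {len(loci)} genotype fields, found {len(fields)}"
            )
        if width is None:
            width = _detect_width(fields, lineno)
        half = width // 2
        miss = missing_code if missing_code is not None else "0" * half
        miss_val = int(miss)
        row: list[tuple[int, int]] = []
        for f in fields:
            if len(f) != width or not f.isdigit():
                raise GenepopFormatError(
                    f"line {lineno}: genotype field '{f}' inconsistent with detected width {width}"
                )
            a, b = int(f[:half]), int(f[half:])
            if a == miss_val or b == miss_val:
                row.append((MISSING, MISSING))
            else:
                row.append((a, b))
        current.append((label or f"ind{lineno}", row))
    pops.append(current)
    pops = [p for p in pops if p]
    if not pops:
        raise GenepopFormatError("file contains no individuals")

    pop_labels = _population_labels(pops)
    individual_ids: list[str] = []
    assignment: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    for plabel, block in zip(pop_labels, pops):
        for label, row in block:
            individual_ids.append(label)
            assignment.append(plabel)
            calls.append(row)
    individual_ids = _deduplicate(individual_ids)
    gm = GenotypeMatrix(individual_ids, loci, np.array(calls, dtype=np.int32))
    pf = PopulationFrame(pd.Series(assignment, index=individual_ids))
    return gm, pf


def _population_labels(pops: list[list[tuple[str, list]]]) -> list[str]:
    prefixes = []
    for block in pops:
        labels = [lab for lab, _ in block]
        pre = os.path.commonprefix(labels).rstrip("0123456789").strip("_-. ")
        prefixes.append(pre)
    if all(prefixes) and len(set(prefixes)) == len(prefixes):
        return prefixes
    return [f"Pop{k + 1}" for k in range(len(pops))]


def _deduplicate(labels: list[str]) -> list[str]:
    if len(set(labels)) == len(labels):
        return labels
    seen: dict[str, int] = {}
    out = []
    for lab in labels:
        seen[lab] = seen.get(lab, 0) + 1
        out.append(lab if seen[lab] == 1 else f"{lab}_{seen[lab]}")
    return out


def write_genepop(
    gm: GenotypeMatrix,
    pf: PopulationFrame,
    path: str | os.PathLike,
    title: str = "deltapop export",
) -> None:
    """Write a genepop file with 3-digit zero-padded allele codes.

    Populations are emitted in ``pf`` order; missing calls become ``000000``.
    Allele codes must be below 1000 (3 digits).
    """
    valid = gm.calls[gm.calls != MISSING]
    if valid.size and valid.max() >= 1000:
        raise ValueError(
            f"allele code {int(valid.max())} is not representable with 3 digits"
        )
    index = {ind: i for i, ind in enumerate(gm.individual_ids)}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in gm.locus_ids:
            fh.write(locus + "\n")
        for pop in pf.population_labels:
            fh.write("Pop\n")
            for ind in pf.individuals_of(pop):
                row = gm.calls[index[ind]]
                fields = [
                    "000000" if a == MISSING else f"{a:03d}{b:03d}" for a, b in row
                ]
                fh.write(f"{ind} ,  " + " ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read the per-population metadata table (CSV).

    Required columns: ``population``, ``region`` (N|S), ``egu``, ``form``.
    Optional: ``size_class`` (default ``medium``), the boolean flags of
    :data:`FLAG_COLUMNS` (default false) and arbitrary extra columns, which
    are preserved untouched. ``only_egu_representative`` is derived from the
    EGU column when absent.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"population", "region", "egu", "form"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing required columns: {sorted(missing)}")
    if df["population"].duplicated().any():
        dups = sorted(df["population"][df["population"].duplicated()].unique())
        raise ValueError(f"duplicate population labels in metadata: {dups}")
    bad_region = set(df["region"]) - set(REGIONS)
    if bad_region:
        raise ValueError(f"region values outside {REGIONS}: {sorted(bad_region)}")
    df = df.set_index("population")
    if "size_class" not in df.columns:
        df["size_class"] = "medium"
    bad_size = set(df["size_class"]) - set(SIZE_CLASSES)
    if bad_size:
        raise ValueError(f"size_class values outside {SIZE_CLASSES}: {sorted(bad_size)}")
    for flag in FLAG_COLUMNS:
        if flag in df.columns:
            df[flag] = df[flag].str.strip().str.lower().isin(
                {"1", "true", "t", "yes", "y"}
            )
        else:
            df[flag] = False
    if "only_egu_representative" not in pd.read_csv(path, nrows=0).columns:
        counts = df["egu"].value_counts()
        df["only_egu_representative"] = df["egu"].map(counts).eq(1)
    for numcol in ("delta_j", "n"):
        if numcol in df.columns:
            df[numcol] = pd.to_numeric(df[numcol], errors="coerce")
    return df


def filter_complete_individuals(
    gm: GenotypeMatrix,
) -> tuple[GenotypeMatrix, ExclusionReport]:
    """Drop every individual with a missing call at any locus.

    Mirrors the standard SSR quality rule of excluding individuals that
    failed to amplify in one or more primer sets. Idempotent; an empty
    result is allowed.
    """
    mask = gm.missing_mask()
    keep = ~mask.any(axis=1)
    rows = []
    for i in np.flatnonzero(~keep):
        loci = [gm.locus_ids[j] for j in np.flatnonzero(mask[i])]
        rows.append({"individual": gm.individual_ids[i], "missing_loci": loci})
    report = ExclusionReport(
        pd.DataFrame(rows, columns=["individual", "missing_loci"])
    )
    return gm.subset(np.flatnonzero(keep)), report
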
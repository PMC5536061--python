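"""Gene-symbol sets: GMT I/O, universe restriction, overlaps and coverage.

Gene symbols are canonicalized by stripping whitespace and uppercasing; no
alias mapping is attempted, so users must pre-map synonyms (e.g. ADFP vs
PLIN2) to a single symbol before analysis.

Overlap frequencies are reported row-relative (``100 * |A∩B| / |A|``) with
one decimal, rounded half away from zero — the convention of published
overlap-frequency matrices for phenotype gene datasets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import ValidationError
from .util import round_half_away

log = logging.getLogger(__name__)


def canonicalize(symbol: str) -> str:
    """Canonical form of a gene symbol: stripped, uppercased."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named set of canonical gene symbols.

    ``source`` is free-text provenance (an accession, a citation, or the
    construction recipe for derived sets).
    """

    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set must have a non-empty name")
        object.__setattr__(self, "genes", frozenset(canonicalize(g) for g in self.genes))

    @property
    def size(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.genes)


@dataclass(frozen=True)
class GeneUniverse:
    """The background gene universe against which all sets are analyzed."""

    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(canonicalize(g) for g in self.genes))
        if not self.genes:
            raise ValidationError("gene universe is empty")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class OverlapResult:
    """Pairwise overlap between two gene sets with reciprocal frequencies.

    ``freq_a`` is the percentage of A's genes shared with B (one decimal);
    ``freq_b`` likewise for B.  Before rounding, ``freq_a * |A| ==
    freq_b * |B| == 100 * common`` exactly.
    """

    name_a: str
    name_b: str
    size_a: int
    size_b: int
    common: int
    freq_a: float = field(init=False)
    freq_b: float = field(init=False)

    def __post_init__(self) -> None:
        if self.size_a <= 0 or self.size_b <= 0:
            raise ValidationError(
                f"overlap frequency undefined for empty set ({self.name_a}, {self.name_b})"
            )
        if not 0 <= self.common <= min(self.size_a, self.size_b):
            raise ValidationError(
                f"common count {self.common} exceeds set sizes "
                f"({self.name_a}={self.size_a}, {self.name_b}={self.size_b})"
            )
        object.__setattr__(self, "freq_a", round_half_away(100.0 * self.common / self.size_a, 1))
        object.__setattr__(self, "freq_b", round_half_away(100.0 * self.common / self.size_b, 1))

    def swapped(self) -> "OverlapResult":
        return OverlapResult(self.name_b, self.name_a, self.size_b, self.size_a, self.common)


# ---------------------------------------------------------------------------
# I/O


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file (tab-separated: name, description, symbols...).

    Symbols are canonicalized and de-duplicated.  A record without a name or
    without at least one symbol, or a duplicated set name, raises
    :class:`ValidationError` naming the offending line.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT record needs name, description and >=1 symbol"
                )
            name = fields[0].strip()
            description = fields[1].strip()
            genes = frozenset(canonicalize(s) for s in fields[2:] if s.strip())
            if not name:
                raise ValidationError(f"{path}:{lineno}: empty set name")
            if not genes:
                raise ValidationError(f"{path}:{lineno}: record has no gene symbols")
            if name in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name=name, genes=genes, source=description))
    if not sets:
        raise ValidationError(f"{path}: no gene sets found (empty file)")
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    """Write sets in GMT dialect with sorted symbols (deterministic output)."""
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.source or "-", *sorted(gs.genes)]) + "\n")


def read_universe(path: str | Path) -> GeneUniverse:
    """Read a universe file: one symbol per line, blank lines ignored."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        genes = frozenset(canonicalize(line) for line in fh if line.strip())
    if not genes:
        raise ValidationError(f"{path}: universe file is empty")
    return GeneUniverse(genes)


def write_universe(universe: GeneUniverse, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(universe.genes):
            fh.write(g + "\n")


def restrict_to_universe(gs: GeneSet, universe: GeneUniverse) -> GeneSet:
    """Restrict a set to the universe.

    Genes outside the universe are counted and logged (never silently
    dropped without trace); the restricted set keeps the original name.
    """
    inside = gs.genes & universe.genes
    dropped = len(gs.genes) - len(inside)
    if dropped:
        log.warning(
            "gene set %s: %d of %d genes outside the %d-gene universe were dropped",
            gs.name, dropped, len(gs.genes), universe.size,
        )
    if not inside:
        raise ValidationError(f"gene set {gs.name!r} has no genes inside the universe")
    return GeneSet(name=gs.name, genes=inside, source=gs.source)


# ---------------------------------------------------------------------------
# Set operations


def overlap(a: GeneSet, b: GeneSet, universe: GeneUniverse | None = None) -> OverlapResult:
    """Overlap of two gene sets (optionally restricted to a universe first)."""
    if universe is not None:
        a = restrict_to_universe(a, universe)
        b = restrict_to_universe(b, universe)
    if not a.genes or not b.genes:
        raise ValidationError("overlap frequency undefined for an empty gene set")
    common = len(a.genes & b.genes)
    return OverlapResult(a.name, b.name, a.size, b.size, common)


def overlap_from_counts(
    name_a: str, name_b: str, size_a: int, size_b: int, common: int
) -> OverlapResult:
    """Overlap record from printed sizes/counts (no gene lists needed)."""
    return OverlapResult(name_a, name_b, size_a, size_b, common)


class OverlapMatrix:
    """Square overlap-frequency matrix with row-relative percentages.

    ``counts`` is symmetric; ``pct`` holds row-relative frequencies
    (``100 * common / row size``, one decimal) as printed in published
    matrices.  The diagonal is left blank in formatted exports.
    """

    def __init__(self, sets: Sequence[GeneSet]):
        names = [s.name for s in sets]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate set names in overlap matrix")
        if len(sets) < 2:
            raise ValidationError("overlap matrix needs at least two sets")
        self.sets = list(sets)
        self.names = names
        self._results: dict[tuple[str, str], OverlapResult] = {}
        for a, b in itertools.combinations(sets, 2):
            r = overlap(a, b)
            self._results[(a.name, b.name)] = r
            self._results[(b.name, a.name)] = r.swapped()

    def cell(self, row: str, col: str) -> OverlapResult:
        return self._results[(row, col)]

    @property
    def counts(self) -> pd.DataFrame:
        df = pd.DataFrame(0, index=self.names, columns=self.names, dtype=int)
        for s in self.sets:
            df.loc[s.name, s.name] = s.size
        for (a, b), r in self._results.items():
            df.loc[a, b] = r.common
        return df

    @property
    def pct(self) -> pd.DataFrame:
        df = pd.DataFrame(float("nan"), index=self.names, columns=self.names)
        for (a, b), r in self._results.items():
            df.loc[a, b] = r.freq_a
        return df

    def to_formatted(self) -> pd.DataFrame:
        """Cells formatted as ``"pct (count)"``, diagonal blank."""
        df = pd.DataFrame("", index=self.names, columns=self.names)
        for (a, b), r in self._results.items():
            df.loc[a, b] = f"{r.freq_a:.1f} ({r.common})"
        return df

    def to_long(self) -> pd.DataFrame:
        rows = [
            {
                "name_a": r.name_a,
                "name_b": r.name_b,
                "size_a": r.size_a,
                "size_b": r.size_b,
                "common": r.common,
                "freq_a": r.freq_a,
                "freq_b": r.freq_b,
            }
            for (a, b), r in sorted(self._results.items())
            if a < b
        ]
        return pd.DataFrame(rows)


def overlap_matrix(sets: Sequence[GeneSet], universe: GeneUniverse | None = None) -> OverlapMatrix:
    if universe is not None:
        sets = [restrict_to_universe(s, universe) for s in sets]
    return OverlapMatrix(sets)


def set_difference(a: GeneSet, b: GeneSet) -> GeneSet:
    """Genes of A not in B; the name records the provenance ``A_minus_B``."""
    return GeneSet(
        name=f"{a.name}_minus_{b.name}",
        genes=a.genes - b.genes,
        source=f"set difference of {a.name} and {b.name}",
    )


def coverage_fraction(dataset: GeneSet, pathways: Iterable[GeneSet]) -> float:
    """Percent of dataset genes inside the union of the pathway target sets."""
    if not dataset.genes:
        raise ValidationError("coverage undefined for an empty dataset")
    union: set[str] = set()
    n_pathways = 0
    for p in pathways:
        union |= p.genes
        n_pathways += 1
    if n_pathways == 0:
        log.warning("coverage_fraction: empty pathway collection, coverage is 0")
        return 0.0
    return 100.0 * len(dataset.genes & union) / dataset.size
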
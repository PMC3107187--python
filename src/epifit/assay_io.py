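"""Replicate-level fitness assay I/O and reduction to per-genotype effects.

The raw observable is a growth rate (doublings per hour) measured for one
genotype in one replicate assay.  Genotype labels follow the convention of
the bundled dataset: single mutants are one uppercase letter (``A``-``I``),
double mutants are two-letter concatenations in alphabetical order (``AB``),
and the wild type carries an arbitrary label (default ``ID11``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DecompositionError, FormatError, InsufficientDataError, ParseError

REQUIRED_COLUMNS = ("genotype", "replicate", "fitness")

DEFAULT_WILD_TYPE = "ID11"


@dataclass(frozen=True)
class AssayReplicate:
    """One fitness measurement of one genotype."""

    genotype: str
    replicate_id: int
    fitness: float

    def __post_init__(self):
        if not self.genotype:
            raise ValueError("genotype label must be nonempty")
        if self.replicate_id < 1:
            raise ValueError("replicate_id must be a positive integer")
        if not math.isfinite(self.fitness):
            raise ValueError(f"fitness must be finite, got {self.fitness!r}")


@dataclass(frozen=True)
class GenotypeSummary:
    """Per-genotype replicate count, mean fitness and standard error.

    ``se_fitness`` is ``None`` when only a single replicate exists (the
    sample SD is undefined); it is never fabricated.
    """

    genotype: str
    n: int
    mean_fitness: float
    se_fitness: float | None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.se_fitness is not None and self.se_fitness < 0:
            raise ValueError("se_fitness must be nonnegative")


@dataclass
class EffectTable:
    """Fitness effects relative to the wild type.

    Parameters
    ----------
    wild_type_label : str
        Label of the reference genotype; its effect is exactly 0.
    effects : dict
        Genotype label -> mean fitness minus wild-type mean fitness.
    pairs : dict
        Double label -> its two constituent single labels.
    mean_fitness : dict
        Genotype label -> mean fitness (absolute scale), kept so that
        downstream fitting can work on the observed scale.
    """

    wild_type_label: str
    effects: dict[str, float]
    pairs: dict[str, tuple[str, str]] = field(default_factory=dict)
    mean_fitness: dict[str, float] = field(default_factory=dict)

    @property
    def singles(self) -> list[str]:
        return sorted(g for g in self.effects if len(g) == 1)

    @property
    def doubles(self) -> list[str]:
        return sorted(self.pairs)

    def effect(self, genotype: str) -> float:
        return self.effects[genotype]


def load_assays(path: str | Path, dialect: str = "auto") -> list[AssayReplicate]:
    """Read a delimited replicate table into :class:`AssayReplicate` records.

    Parameters
    ----------
    path : path-like
        File with a header row naming ``genotype``, ``replicate`` and
        ``fitness`` columns (comma- or tab-delimited).
    dialect : {"auto", ",", "\\t"}
        Delimiter; ``auto`` sniffs between comma and tab from the header.

    Raises
    ------
    FormatError
        If a required column is missing.
    ParseError
        If a fitness or replicate value cannot be parsed; the error names
        the offending 1-based data row.
    """
    path = Path(path)
    if dialect == "auto":
        header = path.open().readline()
        dialect = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=dialect, dtype=str, skipinitialspace=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    records: list[AssayReplicate] = []
    seen: set[tuple[str, int]] = set()
    for idx, row in df.iterrows():
        rownum = int(idx) + 1  # 1-based data row, excluding header
        try:
            rep = int(row["replicate"])
        except (TypeError, ValueError):
            raise ParseError(
                f"row {rownum}: replicate id {row['replicate']!r} is not an integer",
                row=rownum,
            )
        try:
            fitness = float(row["fitness"])
        except (TypeError, ValueError):
            raise ParseError(
                f"row {rownum}: fitness {row['fitness']!r} is not numeric", row=rownum
            )
        genotype = str(row["genotype"]).strip()
        if not genotype or genotype == "nan":
            raise ParseError(f"row {rownum}: empty genotype label", row=rownum)
        key = (genotype, rep)
        if key in seen:
            raise ParseError(
                f"row {rownum}: duplicate (genotype, replicate) pair {key}", row=rownum
            )
        seen.add(key)
        records.append(AssayReplicate(genotype, rep, fitness))
    return records


def write_assays(records: Iterable[AssayReplicate], path: str | Path, dialect: str = ",") -> None:
    """Write replicates as delimited text (inverse of :func:`load_assays`)."""
    df = pd.DataFrame(
        [(r.genotype, r.replicate_id, r.fitness) for r in records],
        columns=list(REQUIRED_COLUMNS),
    )
    df.to_csv(path, sep=dialect, index=False)


def summarize(replicates: Sequence[AssayReplicate]) -> list[GenotypeSummary]:
    """Reduce replicates to per-genotype mean, SE and count.

    The SE uses the unbiased sample SD (``n - 1`` denominator) divided by
    ``sqrt(n)``.  Output order is lexicographic by genotype label.
    """
    if not replicates:
        raise InsufficientDataError("no replicates supplied")
    by_genotype: dict[str, list[float]] = {}
    for r in replicates:
        by_genotype.setdefault(r.genotype, []).append(r.fitness)
    out = []
    for genotype in sorted(by_genotype):
        values = by_genotype[genotype]
        n = len(values)
        mean = sum(values) / n
        if n > 1:
            var = sum((v - mean) ** 2 for v in values) / (n - 1)
            se = math.sqrt(var / n)
        else:
            se = None
        out.append(GenotypeSummary(genotype, n, mean, se))
    return out


def decompose_double(label: str, singles: set[str]) -> tuple[str, str]:
    """Split a two-letter double label into its constituent singles."""
    if len(label) != 2 or label[0] == label[1]:
        raise DecompositionError(f"{label!r} is not a two-letter double label")
    first, second = label[0], label[1]
    if first not in singles or second not in singles:
        raise DecompositionError(
            f"double {label!r} references singles missing from the table"
        )
    return first, second


def effects_relative_to_wt(
    summaries: Sequence[GenotypeSummary], wild_type_label: str = DEFAULT_WILD_TYPE
) -> EffectTable:
    """Compute fitness effects ``s(g) = mean(g) - mean(wild type)``.

    Double labels are annotated with their constituent single labels; a
    double whose letters are not both present as singles raises
    :class:`DecompositionError`.
    """
    means = {s.genotype: s.mean_fitness for s in summaries}
    if wild_type_label not in means:
        raise FormatError(f"wild-type label {wild_type_label!r} not present")
    wt_mean = means[wild_type_label]
    effects = {g: m - wt_mean for g, m in means.items()}
    effects[wild_type_label] = 0.0  # exact by definition
    singles = {g for g in means if len(g) == 1 and g != wild_type_label}
    pairs = {
        g: decompose_double(g, singles)
        for g in means
        if g != wild_type_label and len(g) == 2
    }
    return EffectTable(wild_type_label, effects, pairs, mean_fitness=dict(means))


def summaries_to_frame(
    summaries: Sequence[GenotypeSummary], effects: EffectTable | None = None
) -> pd.DataFrame:
    """Tidy summary table: ``genotype, n, mean, se[, effect]``."""
    df = pd.DataFrame(
        [(s.genotype, s.n, s.mean_fitness, s.se_fitness) for s in summaries],
        columns=["genotype", "n", "mean", "se"],
    )
    if effects is not None:
        df["effect"] = df["genotype"].map(effects.effects)
    return df
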
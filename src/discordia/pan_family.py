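"""Pan-genome gene-family classification and saturation analysis.

Works on an orthogroup count matrix (families x genomes; presence = count >= 1),
the standard OrthoFinder-style output.  With G genomes, families are
partitioned as:

* core        - present in all G genomes
* softcore    - present in >= ceil(softcore_fraction x G) but fewer than G
                (default fraction 0.90, i.e. ">90% of genomes")
* private     - present in exactly one genome
* dispensable - everything else (2 ... softcore threshold - 1)

Saturation curves track pan (union) and core (intersection) family counts as
genomes are added in random order.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "FamilyClassification",
    "SaturationCurve",
    "read_orthogroups",
    "write_orthogroups",
    "classify_families",
    "saturation_curves",
    "group_specific_families",
]

CATEGORIES = ("core", "softcore", "dispensable", "private")

_INT_RE = re.compile(r"^\d+$")


def _validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    if matrix.shape[1] < 2:
        raise ValueError("at least two genomes are required")
    if matrix.columns.duplicated().any():
        raise ValueError("genome ids must be unique")
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate family ids: {dupes}")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if (matrix.to_numpy().sum(axis=1) == 0).any():
        raise ValueError("all-zero family rows are not allowed")
    return matrix


def read_orthogroups(path: "str | Path") -> pd.DataFrame:
    """Read an orthogroup table into a families x genomes count matrix.

    Accepts the OrthoFinder ``Orthogroups.tsv`` dialect (first column the
    family id, one column per genome, cells holding comma-separated gene ids;
    count = number of ids, empty cell = 0) or a plain integer-matrix TSV.
    Ragged rows and duplicate family ids raise with the offending row number.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        genomes = header[1:]
        families, rows = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: row {lineno} has {len(row)} fields, expected {len(header)}"
                )
            families.append(row[0])
            cells = row[1:]
            if all(_INT_RE.match(c) for c in cells if c != ""):
                counts = [int(c) if c != "" else 0 for c in cells]
            else:
                counts = [
                    len([g for g in c.split(",") if g.strip()]) for c in cells
                ]
            rows.append(counts)
    matrix = pd.DataFrame(rows, index=pd.Index(families, name="family"),
                          columns=genomes, dtype=int)
    return _validate_matrix(matrix)


def write_orthogroups(
    matrix: pd.DataFrame, path: "str | Path", style: str = "counts"
) -> None:
    """Write a count matrix as TSV; ``style='genes'`` emits the OrthoFinder
    dialect with synthetic gene ids (count-preserving round trip)."""
    if style == "counts":
        matrix.to_csv(path, sep="\t", index_label="Orthogroup")
        return
    if style != "genes":
        raise ValueError("style must be 'counts' or 'genes'")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["Orthogroup", *matrix.columns])
        for family, row in matrix.iterrows():
            cells = [
                ", ".join(f"{g}|{family}|{i}" for i in range(int(c))) if c else ""
                for g, c in zip(matrix.columns, row)
            ]
            writer.writerow([family, *cells])


@dataclass(frozen=True)
class FamilyClassification:
    categories: pd.Series = field(repr=False)  # family id -> category
    tallies: dict[str, int]
    percentages: dict[str, float]
    n_genomes: int
    softcore_fraction: float

    @property
    def softcore_min_presence(self) -> int:
        return math.ceil(self.softcore_fraction * self.n_genomes)


def classify_families(
    matrix: pd.DataFrame, softcore_fraction: float = 0.90
) -> FamilyClassification:
    """Partition families into core/softcore/dispensable/private by presence
    count (presence = count >= 1)."""
    _validate_matrix(matrix)
    g = matrix.shape[1]
    presence = (matrix.to_numpy() >= 1).sum(axis=1)
    threshold = math.ceil(softcore_fraction * g)
    cats = np.full(matrix.shape[0], "dispensable", dtype=object)
    cats[presence >= threshold] = "softcore"
    cats[presence == g] = "core"
    cats[presence == 1] = "private"
    categories = pd.Series(cats, index=matrix.index, name="category")
    tallies = {c: int((categories == c).sum()) for c in CATEGORIES}
    n = len(categories)
    percentages = {c: round(100.0 * v / n, 2) for c, v in tallies.items()}
    return FamilyClassification(
        categories=categories, tallies=tallies, percentages=percentages,
        n_genomes=g, softcore_fraction=softcore_fraction,
    )


@dataclass(frozen=True)
class SaturationCurve:
    """Per-permutation pan/core trajectories plus their summary.

    ``pan`` and ``core`` are (n_permutations x G) arrays: entry [p, k-1] is
    the pan (union) or core (intersection) family count after the first k
    genomes of permutation p.
    """

    pan: np.ndarray = field(repr=False)
    core: np.ndarray = field(repr=False)
    n_permutations: int = 0
    seed: int = 0

    @property
    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": np.arange(1, self.pan.shape[1] + 1),
            "pan_mean": self.pan.mean(axis=0),
            "pan_min": self.pan.min(axis=0),
            "pan_max": self.pan.max(axis=0),
            "core_mean": self.core.mean(axis=0),
            "core_min": self.core.min(axis=0),
            "core_max": self.core.max(axis=0),
        })


def saturation_curves(
    matrix: pd.DataFrame, n_permutations: int = 100, seed: int = 0
) -> SaturationCurve:
    """Pan/core family counts over random genome orderings.

    Per permutation, pan counts are non-decreasing and core counts
    non-increasing in k; results are reproducible under a fixed seed.
    """
    _validate_matrix(matrix)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    presence = matrix.to_numpy() >= 1
    g = presence.shape[1]
    rng = np.random.default_rng(seed)
    pan = np.empty((n_permutations, g), dtype=int)
    core = np.empty((n_permutations, g), dtype=int)
    for p in range(n_permutations):
        order = rng.permutation(g)
        cols = presence[:, order]
        pan[p] = np.logical_or.accumulate(cols, axis=1).sum(axis=0)
        core[p] = np.logical_and.accumulate(cols, axis=1).sum(axis=0)
    return SaturationCurve(pan=pan, core=core, n_permutations=n_permutations, seed=seed)


def group_specific_families(
    matrix: pd.DataFrame, target_genomes: Sequence[str]
) -> tuple[list[str], int]:
    """Families present in at least one target genome and absent from every
    other genome, plus the total member-gene count over the target genomes."""
    _validate_matrix(matrix)
    targets = list(dict.fromkeys(target_genomes))
    if not targets:
        raise ValueError("target_genomes must be non-empty")
    unknown = [t for t in targets if t not in matrix.columns]
    if unknown:
        raise KeyError(f"unknown genome ids: {unknown}")
    others = [c for c in matrix.columns if c not in targets]
    in_target = (matrix[targets] >= 1).any(axis=1)
    absent_elsewhere = (
        (matrix[others] == 0).all(axis=1) if others else pd.Series(True, index=matrix.index)
    )
    mask = in_target & absent_elsewhere
    families = matrix.index[mask].tolist()
    gene_count = int(matrix.loc[mask, targets].to_numpy().sum())
    return families, gene_count
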
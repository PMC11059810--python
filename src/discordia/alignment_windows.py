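"""Windowed sampling of a whole-genome alignment matrix.

To obtain quasi-independent loci from a multi-genome alignment, fixed-size
windows (default 1 kb) are cut with a large gap between consecutive windows
(default 20 kb, reducing the chance of spanning a recombination breakpoint),
and windows with fewer than a minimum number of parsimony-informative sites
(default 10) are discarded.  A neighbour-joining tree on K2P distances is
available per window so the full pipeline can run self-contained; for real
analyses users typically supply externally estimated gene trees instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix
from skbio.tree import nj

from .ltr_timing import k2p_distance

__all__ = [
    "AlignmentMatrix",
    "WindowConfig",
    "AlignmentWindow",
    "FilterTally",
    "extract_windows",
    "count_informative_sites",
    "filter_windows",
    "nj_tree",
    "nj_from_distances",
    "windows_manifest",
]

_ACGT = (65, 67, 71, 84)  # bytes of A, C, G, T


@dataclass
class AlignmentMatrix:
    """Taxon labels plus equal-length aligned rows (uppercased on input)."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.labels or len(self.labels) != len(self.rows):
            raise ValueError("labels and rows must be non-empty and aligned")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("taxon labels must be unique")
        self.rows = [r.upper() for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("all alignment rows must have equal length")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path: "str | Path") -> "AlignmentMatrix":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path: "str | Path") -> None:
        SeqIO.write(
            [SeqRecord(Seq(row), id=label, description="")
             for label, row in zip(self.labels, self.rows)],
            str(path), "fasta",
        )


@dataclass(frozen=True)
class WindowConfig:
    window_size: int = 1000
    gap_between: int = 20000
    min_informative: int = 10

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.gap_between < 0 or self.min_informative < 0:
            raise ValueError("gap_between and min_informative must be >= 0")


@dataclass
class AlignmentWindow:
    """A column slice [start, end) of the alignment with its informative-site
    count."""

    start: int
    end: int
    labels: list[str]
    rows: list[str]
    informative_count: int = 0


def _byte_matrix(rows: Sequence[str]) -> np.ndarray:
    return np.vstack([
        np.frombuffer(r.upper().encode("ascii"), dtype=np.uint8) for r in rows
    ])


def count_informative_sites(window: "AlignmentWindow | Sequence[str]") -> int:
    """Number of parsimony-informative columns: at least two distinct
    unambiguous bases, each occurring in at least two taxa.  Gaps, N and any
    other ambiguity codes are ignored for state counting."""
    rows = window.rows if isinstance(window, AlignmentWindow) else list(window)
    if len(rows) < 2:
        raise ValueError("at least two rows are required")
    mat = _byte_matrix(rows)
    states_with_2 = np.zeros(mat.shape[1], dtype=np.int16)
    for code in _ACGT:
        states_with_2 += (mat == code).sum(axis=0) >= 2
    return int(np.count_nonzero(states_with_2 >= 2))


def extract_windows(
    alignment: AlignmentMatrix, config: WindowConfig = WindowConfig()
) -> list[AlignmentWindow]:
    """Cut full-length windows left to right with stride
    ``window_size + gap_between``, starting at column 0.  A terminal partial
    window is dropped; an alignment shorter than one window yields an empty
    list."""
    windows = []
    stride = config.window_size + config.gap_between
    for start in range(0, alignment.length - config.window_size + 1, stride):
        end = start + config.window_size
        rows = [r[start:end] for r in alignment.rows]
        windows.append(AlignmentWindow(
            start=start, end=end, labels=list(alignment.labels), rows=rows,
            informative_count=count_informative_sites(rows),
        ))
    return windows


@dataclass(frozen=True)
class FilterTally:
    retained: int
    removed: int


def filter_windows(
    windows: Sequence[AlignmentWindow], min_informative: int = 10
) -> tuple[list[AlignmentWindow], FilterTally]:
    """Keep windows with ``informative_count >= min_informative`` (a window
    with fewer informative sites is filtered out)."""
    kept = [w for w in windows if w.informative_count >= min_informative]
    return kept, FilterTally(retained=len(kept), removed=len(windows) - len(kept))


def nj_from_distances(labels: Sequence[str], matrix: np.ndarray) -> str:
    """Neighbour joining on a precomputed distance matrix; taxa are sorted so
    tie-breaking is deterministic; negative branch lengths are clamped to 0.
    Returns Newick."""
    order = np.argsort(np.asarray(labels, dtype=object))
    labels = [labels[i] for i in order]
    matrix = np.asarray(matrix, dtype=float)[np.ix_(order, order)]
    tree = nj(DistanceMatrix(matrix, labels), neg_as_zero=True)
    return str(tree).strip()


def nj_tree(window: "AlignmentWindow | AlignmentMatrix") -> str:
    """Neighbour-joining tree (Newick) on pairwise K2P distances for a window.

    Raises a ``ValueError`` naming the pair whenever two rows share no
    ungapped, unambiguous sites (distance undefined)."""
    labels, rows = window.labels, window.rows
    if len(labels) < 3:
        raise ValueError("at least three taxa are required for a tree")
    k = len(labels)
    dm = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            try:
                dm[i, j] = dm[j, i] = k2p_distance(rows[i], rows[j])
            except ValueError as exc:
                raise ValueError(
                    f"distance undefined for pair ({labels[i]}, {labels[j]}): {exc}"
                ) from exc
    return nj_from_distances(labels, dm)


def windows_manifest(windows: Sequence[AlignmentWindow], min_informative: int = 10) -> pd.DataFrame:
    """TSV-ready manifest: index, coordinates, informative count, retained flag."""
    return pd.DataFrame({
        "window": range(len(windows)),
        "start": [w.start for w in windows],
        "end": [w.end for w in windows],
        "informative_count": [w.informative_count for w in windows],
        "retained": [w.informative_count >= min_informative for w in windows],
    })
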
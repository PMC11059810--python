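"""LTR retrotransposon insertion dating from paired-LTR divergence.

At insertion the two long terminal repeats of a retrotransposon are identical;
they then diverge neutrally, so the Kimura two-parameter (K2P) distance K
between the 5' and 3' LTRs dates the insertion as T = K / (2 mu) for a
per-site per-year substitution rate mu.  The module computes K2P with pairwise
deletion of gapped/ambiguous columns, dates elements, and summarises cohorts
as per-superfamily age densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.stats import gaussian_kde

__all__ = [
    "LtrElement",
    "SaturationError",
    "TimingProfile",
    "k2p_distance",
    "site_counts",
    "insertion_time",
    "date_elements",
    "timing_profile",
    "read_ltr_pairs",
    "write_ltr_pairs",
]

_PURINE_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_VALID = frozenset(b"ACGT")


class SaturationError(ValueError):
    """K2P distance undefined: too much divergence (log argument <= 0)."""


@dataclass(frozen=True)
class LtrElement:
    """A paired-LTR element, optionally with its distance and age."""

    id: str
    superfamily: str = "unknown"
    ltr5: str = ""
    ltr3: str = ""
    k: float | None = None
    t: float | None = None
    saturated: bool = False


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def site_counts(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) after pairwise deletion
    of columns with a gap or ambiguity code in either sequence."""
    a, b = _encode(seq_a), _encode(seq_b)
    if a.size != b.size:
        raise ValueError("sequences must be aligned to equal length")
    valid_tbl = np.zeros(256, dtype=bool)
    for code in _VALID:
        valid_tbl[code] = True
    mask = valid_tbl[a] & valid_tbl[b]
    a, b = a[mask], b[mask]
    n = int(a.size)
    diff = a != b
    # purines A(65)/G(71), pyrimidines C(67)/T(84): transition iff both purine
    # or both pyrimidine
    purine = np.isin(a, (65, 71)) == np.isin(b, (65, 71))
    transitions = int(np.count_nonzero(diff & purine))
    transversions = int(np.count_nonzero(diff) - transitions)
    return n, transitions, transversions


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance between two aligned sequences.

    With transition fraction P and transversion fraction Q:
    ``K = -(1/2) ln((1 - 2P - Q) sqrt(1 - 2Q))``.

    Raises :class:`SaturationError` when the log argument is non-positive and
    ``ValueError`` when no comparable sites remain.
    """
    n, ts, tv = site_counts(seq_a, seq_b)
    if n == 0:
        raise ValueError("no comparable (ungapped, unambiguous) sites")
    p, q = ts / n, tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P saturated: P={p:.4f}, Q={q:.4f} over {n} sites"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def insertion_time(k: float, mu: float) -> float:
    """Insertion age in years: ``T = K / (2 mu)``."""
    if mu <= 0:
        raise ValueError("substitution rate mu must be positive")
    return k / (2.0 * mu)


def date_elements(elements: Iterable[LtrElement], mu: float) -> list[LtrElement]:
    """Compute K and T per element; saturated elements are flagged, not dropped."""
    dated = []
    for el in elements:
        try:
            k = k2p_distance(el.ltr5, el.ltr3)
        except SaturationError:
            dated.append(replace(el, k=None, t=None, saturated=True))
            continue
        dated.append(replace(el, k=k, t=insertion_time(k, mu), saturated=False))
    return dated


def elements_table(elements: Sequence[LtrElement], mu: float) -> pd.DataFrame:
    """Per-element table of P, Q, K, T and the saturation flag."""
    rows = []
    for el in date_elements(elements, mu):
        n, ts, tv = site_counts(el.ltr5, el.ltr3)
        rows.append({
            "id": el.id, "superfamily": el.superfamily, "sites": n,
            "P": ts / n if n else float("nan"),
            "Q": tv / n if n else float("nan"),
            "K": el.k, "T": el.t, "saturated": el.saturated,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TimingProfile:
    superfamily: str
    times: np.ndarray = field(repr=False)
    grid: np.ndarray = field(repr=False)
    density: np.ndarray = field(repr=False)
    modes: tuple[float, ...]
    hist_counts: np.ndarray = field(repr=False)
    hist_edges: np.ndarray = field(repr=False)
    n_saturated: int = 0


def _kde_profile(times: np.ndarray, bandwidth, grid_size: int) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    hi = float(times.max())
    lo = float(times.min())
    span = max(hi - lo, hi * 0.1, 1.0)
    grid = np.linspace(max(lo - 0.25 * span, 0.0), hi + 0.25 * span, grid_size)
    kde = gaussian_kde(times, bw_method=bandwidth)
    density = kde(grid)
    interior = (density[1:-1] >= density[:-2]) & (density[1:-1] >= density[2:])
    idx = np.flatnonzero(interior) + 1
    if idx.size == 0:
        idx = np.array([int(np.argmax(density))])
    order = np.argsort(density[idx])[::-1]
    modes = tuple(float(grid[i]) for i in idx[order])
    return grid, density, modes


def timing_profile(
    elements: Iterable[LtrElement],
    mu: float,
    bandwidth=None,
    grid_size: int = 512,
    bins: int = 50,
) -> dict[str, TimingProfile]:
    """Per-superfamily insertion-age density (Gaussian KDE + histogram).

    ``bandwidth`` is forwarded to ``scipy.stats.gaussian_kde`` (``bw_method``).
    Modes are local maxima of the KDE on the evaluation grid, ordered by
    density.  A superfamily whose ages are all identical (e.g. a single
    element) degenerates to a spike at that age.  Raises if every element is
    saturated.
    """
    dated = date_elements(elements, mu)
    by_family: dict[str, list[LtrElement]] = {}
    for el in dated:
        by_family.setdefault(el.superfamily, []).append(el)
    profiles: dict[str, TimingProfile] = {}
    any_dated = False
    for family, members in by_family.items():
        times = np.array([el.t for el in members if not el.saturated], dtype=float)
        n_sat = sum(1 for el in members if el.saturated)
        if times.size == 0:
            continue
        any_dated = True
        counts, edges = np.histogram(times, bins=bins, density=True)
        if np.unique(times).size < 2:
            spike = float(times[0])
            grid = np.array([spike])
            density = np.array([math.inf])
            modes = (spike,)
        else:
            grid, density, modes = _kde_profile(times, bandwidth, grid_size)
        profiles[family] = TimingProfile(
            superfamily=family, times=times, grid=grid, density=density,
            modes=modes, hist_counts=counts, hist_edges=edges, n_saturated=n_sat,
        )
    if not any_dated:
        raise ValueError("all elements are saturated; no insertion ages to profile")
    return profiles


# ---------------------------------------------------------------------------
# I/O: paired-LTR FASTA ("<id>/5" and "<id>/3") + metadata TSV (id, superfamily)
# ---------------------------------------------------------------------------

def read_ltr_pairs(
    fasta_path: "str | Path", meta_path: "str | Path | None" = None
) -> list[LtrElement]:
    seqs: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id.endswith("/5") or rec.id.endswith("/3"):
            base, end = rec.id[:-2], rec.id[-1]
        else:
            raise ValueError(f"LTR record id {rec.id!r} lacks a /5 or /3 suffix")
        seqs.setdefault(base, {})[end] = str(rec.seq)
    meta: Mapping[str, str] = {}
    if meta_path is not None:
        table = pd.read_csv(meta_path, sep="\t", dtype=str)
        meta = dict(zip(table.iloc[:, 0], table.iloc[:, 1]))
    elements = []
    for base, ends in sorted(seqs.items()):
        if set(ends) != {"5", "3"}:
            raise ValueError(f"element {base!r} is missing one LTR of the pair")
        elements.append(LtrElement(
            id=base, superfamily=meta.get(base, "unknown"),
            ltr5=ends["5"], ltr3=ends["3"],
        ))
    return elements


def write_ltr_pairs(elements: Iterable[LtrElement], fasta_path: "str | Path") -> None:
    records = []
    for el in elements:
        records.append(SeqRecord(Seq(el.ltr5), id=f"{el.id}/5", description=""))
        records.append(SeqRecord(Seq(el.ltr3), id=f"{el.id}/3", description=""))
    SeqIO.write(records, str(fasta_path), "fasta")
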
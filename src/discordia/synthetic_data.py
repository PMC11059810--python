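"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators cover the pipeline's inputs:

* 3-taxon multispecies-coalescent (MSC) gene trees with an optional
  locus-level introgression pulse (probability ``gamma`` of the recipient
  lineage joining the donor's), emitting Newick trees and ground-truth
  triplet observations;
* direct draws from the exponential / shifted-exponential branch-length
  mixture, for estimator-recovery experiments;
* orthogroup count matrices with planted core/softcore/dispensable/private
  proportions;
* per-genome SV tables with planted group-exclusive deletions, and paired
  LTR sequences diverged for a known time under a two-rate (K80) process.

All randomness flows through explicit integer seeds; no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ltr_timing import LtrElement
from .sv_tools import SV_TYPES, SvRecord
from .triplet_mixture import TripletObservation

__all__ = [
    "MscConfig",
    "MixtureTruth",
    "PlantedSvDesign",
    "simulate_triplet_loci",
    "msc_concordance_probability",
    "sample_mixture_lengths",
    "generate_orthogroup_matrix",
    "generate_sv_tables",
    "mutate_ltr_pair",
]

# Species divergence time of the sister pair before present (coalescent
# units).  Purely cosmetic: it offsets all node heights equally and cancels
# from every internal branch length.
_T_DIV = 1.0


@dataclass(frozen=True)
class MscConfig:
    """Three-taxon MSC simulator parameters.

    ``taxa = (A, B, C)`` with species topology ((A,B),C); ``t2`` is the
    species-tree internal branch in coalescent units (2N generations);
    ``t_root`` the branch above the triplet ancestor to the outgroup
    attachment; ``gamma`` the per-locus introgression probability between
    ``donor`` and ``recipient``; ``subst_scale`` converts coalescent units to
    substitutions/site in the emitted Newick trees.
    """

    taxa: tuple[str, str, str] = ("A", "B", "C")
    outgroup: str = "O"
    t2: float = 1.0
    t_root: float = 1.0
    gamma: float = 0.0
    donor: str | None = None
    recipient: str | None = None
    subst_scale: float = 1.0
    n_loci: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != 3 or self.outgroup in self.taxa:
            raise ValueError("taxa must be three distinct labels plus a distinct outgroup")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.t2 < 0 or self.t_root < 0:
            raise ValueError("t2 and t_root must be >= 0")
        if self.subst_scale <= 0:
            raise ValueError("subst_scale must be positive")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.gamma > 0:
            if self.donor is None or self.recipient is None:
                raise ValueError("gamma > 0 requires donor and recipient")
            if self.donor == self.recipient:
                raise ValueError("donor and recipient must differ")
            if self.donor not in self.taxa or self.recipient not in self.taxa:
                raise ValueError("donor and recipient must be ingroup taxa")


def msc_concordance_probability(t2: float) -> float:
    """P(gene-tree topology == species topology) under the 3-taxon MSC:
    ``1 - (2/3) exp(-t2)``."""
    return 1.0 - (2.0 / 3.0) * math.exp(-t2)


def simulate_triplet_loci(
    config: MscConfig,
) -> tuple[list[str], list[TripletObservation]]:
    """Simulate rooted triplet gene trees under the MSC with an optional
    introgression pulse.

    Per locus: with probability ``gamma`` the recipient lineage follows the
    donor's history, making (donor, recipient) the locally sister pair;
    otherwise the species sister pair (A, B) applies.  The sister pair
    coalesces within the internal branch of length ``t2`` with probability
    ``1 - exp(-t2)`` (waiting time Exp(1) truncated at ``t2``); failing that,
    all three lineages reach the ancestral population, where the first
    coalescence is Exp(rate 3) among a uniformly random pair and the second
    Exp(rate 1).  The gene tree's internal branch is the time between the
    two coalescences.

    Returns Newick strings (branch lengths scaled by ``subst_scale``) and
    ground-truth observations (``t`` in coalescent units).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_loci
    a, b, c = config.taxa
    pairs = [(a, b), (a, c), (b, c)]

    introgressed = (
        rng.random(n) < config.gamma if config.gamma > 0 else np.zeros(n, dtype=bool)
    )
    s = rng.exponential(1.0, n)  # waiting time inside the internal branch
    in_branch = s < config.t2
    w_second = rng.exponential(1.0, n)           # after the first event
    w_deep_first = rng.exponential(1.0 / 3.0, n)  # three lineages, rate 3
    deep_pick = rng.integers(0, 3, n)

    first = np.where(in_branch, _T_DIV + s, _T_DIV + config.t2 + w_deep_first)
    second = np.where(
        in_branch, _T_DIV + config.t2 + w_second, first + w_second
    )

    sister = [(config.donor, config.recipient) if flag else (a, b) for flag in introgressed]

    newicks: list[str] = []
    observations: list[TripletObservation] = []
    scale = config.subst_scale
    out = config.outgroup
    for i in range(n):
        if in_branch[i]:
            x, y = sister[i]
        else:
            x, y = pairs[deep_pick[i]]
        z = ({a, b, c} - {x, y}).pop()
        h1, h2 = first[i], second[i]
        h3 = h2 + config.t_root
        newicks.append(
            f"((({x}:{h1 * scale:.10g},{y}:{h1 * scale:.10g}):{(h2 - h1) * scale:.10g},"
            f"{z}:{h2 * scale:.10g}):{config.t_root * scale:.10g},{out}:{h3 * scale:.10g});"
        )
        observations.append(TripletObservation(
            locus=f"locus_{i}", topology=tuple(sorted((x, y))), t=float(h2 - h1),
        ))
    return newicks, observations


@dataclass(frozen=True)
class MixtureTruth:
    """Ground truth for the branch-length mixture: ILS weight ``pi``,
    exponential mean ``lam``, shift ``c``."""

    pi: float
    lam: float
    c: float = 0.0
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must be in [0, 1]")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.c < 0:
            raise ValueError("c must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def sample_mixture_lengths(truth: MixtureTruth) -> np.ndarray:
    """Draw ``n`` branch lengths: Exp(mean lam) with probability ``pi``,
    else ``c + Exp(mean lam)``."""
    rng = np.random.default_rng(truth.seed)
    ils = rng.random(truth.n) < truth.pi
    draws = rng.exponential(truth.lam, truth.n)
    draws[~ils] += truth.c
    return draws


# ---------------------------------------------------------------------------
# Orthogroup matrices with planted category proportions
# ---------------------------------------------------------------------------

def _apportion(weights: Sequence[float], total: int) -> list[int]:
    """Largest-remainder apportionment so planted counts sum exactly."""
    raw = [w * total for w in weights]
    counts = [int(math.floor(r)) for r in raw]
    remainder = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def generate_orthogroup_matrix(
    n_genomes: int,
    n_families: int,
    category_weights: "Mapping[str, float] | Sequence[float]",
    seed: int = 0,
    softcore_fraction: float = 0.90,
    max_copies: int = 3,
    genome_labels: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Orthogroup count matrix with exactly planted category fractions.

    ``category_weights`` maps {core, softcore, dispensable, private} to
    proportions summing to 1 (a 4-sequence in that order also works).
    Presence counts are drawn uniformly within each category's band; copy
    numbers per present cell are uniform in [1, max_copies].  Returns the
    matrix and the planted per-family labels.
    """
    if n_genomes < 2:
        raise ValueError("n_genomes must be >= 2")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if isinstance(category_weights, Mapping):
        weights = [float(category_weights.get(c, 0.0)) for c in
                   ("core", "softcore", "dispensable", "private")]
    else:
        weights = [float(w) for w in category_weights]
        if len(weights) != 4:
            raise ValueError("expected four category weights")
    if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("category weights must be non-negative and sum to 1")

    g = n_genomes
    threshold = math.ceil(softcore_fraction * g)
    bands = {
        "core": (g, g),
        "softcore": (threshold, g - 1),
        "dispensable": (2, threshold - 1),
        "private": (1, 1),
    }
    names = ("core", "softcore", "dispensable", "private")
    for name, w in zip(names, weights):
        lo, hi = bands[name]
        if w > 0 and lo > hi:
            raise ValueError(
                f"category {name!r} has an empty presence band [{lo}, {hi}] for G={g}"
            )

    rng = np.random.default_rng(seed)
    per_category = _apportion(weights, n_families)
    labels = []
    for name, count in zip(names, per_category):
        labels += [name] * count

    if genome_labels is None:
        genome_labels = [f"g{i + 1:02d}" for i in range(g)]
    elif len(set(genome_labels)) != g:
        raise ValueError("genome_labels must be unique and match n_genomes")

    counts = np.zeros((n_families, g), dtype=int)
    for row, name in enumerate(labels):
        lo, hi = bands[name]
        k = int(rng.integers(lo, hi + 1))
        cols = rng.choice(g, size=k, replace=False)
        counts[row, cols] = rng.integers(1, max_copies + 1, size=k)

    matrix = pd.DataFrame(
        counts,
        index=pd.Index([f"OG{i:07d}" for i in range(n_families)], name="family"),
        columns=list(genome_labels),
    )
    truth = pd.Series(labels, index=matrix.index, name="category")
    return matrix, truth


# ---------------------------------------------------------------------------
# SV tables with planted group-exclusive deletions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSvDesign:
    """Planted SV scenario on a shared reference.

    ``planted`` deletions appear (with start jitter up to ``jitter`` bp) in
    every genome of ``present_genomes`` and in no other genome; background
    SVs are placed uniformly, at least 1 kb away from any planted deletion.
    """

    genomes: tuple[str, ...]
    present_genomes: tuple[str, ...]
    reference_lengths: Mapping[str, int]
    background_counts: Mapping[str, Mapping[str, int]]
    planted: tuple[tuple[str, int, int], ...] = ()
    jitter: int = 0
    size_range: tuple[int, int] = (50, 500)

    def __post_init__(self) -> None:
        if not self.genomes:
            raise ValueError("at least one genome is required")
        unknown = set(self.present_genomes) - set(self.genomes)
        if unknown:
            raise ValueError(f"present_genomes not in genomes: {sorted(unknown)}")
        for chrom, start, end in self.planted:
            if chrom not in self.reference_lengths:
                raise ValueError(f"planted deletion on unknown chromosome {chrom!r}")
            if not 0 <= start < end <= self.reference_lengths[chrom]:
                raise ValueError(
                    f"planted deletion {chrom}:{start}-{end} outside reference bounds"
                )
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


_PLANTED_BUFFER = 1000  # bp separation between background and planted SVs


def generate_sv_tables(
    design: PlantedSvDesign, seed: int = 0
) -> dict[str, list[SvRecord]]:
    """Per-genome Assemblytics-style record sets realizing a planted design."""
    rng = np.random.default_rng(seed)
    planted_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in design.planted:
        planted_by_chrom.setdefault(chrom, []).append((start, end))

    tables: dict[str, list[SvRecord]] = {g: [] for g in design.genomes}
    lo_size, hi_size = design.size_range

    for genome in design.genomes:
        if genome in design.present_genomes:
            for i, (chrom, start, end) in enumerate(design.planted):
                offset = int(rng.integers(-design.jitter, design.jitter + 1)) if design.jitter else 0
                s = max(0, start + offset)
                e = s + (end - start)
                tables[genome].append(SvRecord(
                    reference=chrom, start=s, end=e, type="deletion",
                    size=e - s, genome=genome, id=f"{genome}_planted_{i}",
                ))
        counts = design.background_counts.get(genome, {})
        for sv_type, count in counts.items():
            if sv_type not in SV_TYPES:
                raise ValueError(f"unknown SV type {sv_type!r} in background_counts")
            for i in range(count):
                placed = False
                for _ in range(1000):
                    chrom = str(rng.choice(list(design.reference_lengths)))
                    ref_len = design.reference_lengths[chrom]
                    size = int(rng.integers(lo_size, hi_size + 1))
                    span = 1 if sv_type == "insertion" else size
                    if ref_len <= span:
                        continue
                    start = int(rng.integers(0, ref_len - span))
                    end = start + span
                    clear = all(
                        start - _PLANTED_BUFFER >= pe or end + _PLANTED_BUFFER <= ps
                        for ps, pe in planted_by_chrom.get(chrom, [])
                    )
                    if clear:
                        tables[genome].append(SvRecord(
                            reference=chrom, start=start, end=end, type=sv_type,
                            size=size, genome=genome, id=f"{genome}_{sv_type}_{i}",
                        ))
                        placed = True
                        break
                if not placed:
                    raise ValueError(
                        f"could not place a background {sv_type} in genome {genome}: "
                        "reference too short or too crowded"
                    )
    return tables


# ---------------------------------------------------------------------------
# Diverged LTR pairs under a two-rate (K80) substitution process
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _k80_site_probs(alpha: float, beta: float, t: float) -> tuple[float, float]:
    """(P(transition), P(each transversion)) after time t under K80 with
    transition rate alpha and per-type transversion rate beta."""
    e_ab = math.exp(-2.0 * (alpha + beta) * t)
    e_b = math.exp(-4.0 * beta * t)
    p_transition = 0.25 + 0.25 * e_b - 0.5 * e_ab
    p_transversion_each = 0.25 - 0.25 * e_b
    return p_transition, p_transversion_each


def mutate_ltr_pair(
    length: int,
    true_time: float,
    mu: float,
    ti_tv_ratio: float = 2.0,
    seed: int = 0,
    element_id: str = "ltr_0",
    superfamily: str = "unknown",
) -> LtrElement:
    """Two copies of a random ancestral sequence, independently diverged for
    ``true_time`` years at total rate ``mu`` per site per year.

    ``ti_tv_ratio`` is the transition:transversion *rate* ratio
    alpha / (2 beta); at 0.5 all three substitution directions are
    equally likely.  The K2P estimate of the pair's divergence recovers
    ``2 mu true_time``, hence an insertion age of ``true_time``.
    """
    if length < 100:
        raise ValueError("length must be >= 100")
    if mu <= 0:
        raise ValueError("mu must be positive")
    if true_time < 0:
        raise ValueError("true_time must be >= 0")
    if ti_tv_ratio <= 0:
        raise ValueError("ti_tv_ratio must be positive")

    rng = np.random.default_rng(seed)
    ancestral = rng.integers(0, 4, size=length)  # indices into A,C,G,T

    r = ti_tv_ratio
    alpha = mu * r / (r + 1.0)
    beta = mu / (2.0 * (r + 1.0))
    p_ts, p_tv = _k80_site_probs(alpha, beta, true_time)

    def evolve(states: np.ndarray) -> str:
        u = rng.random(length)
        out = states.copy()
        # ordering A,C,G,T: the transition partner is (i + 2) % 4
        transition = u < p_ts
        tv1 = (u >= p_ts) & (u < p_ts + p_tv)
        tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
        out[transition] = (out[transition] + 2) % 4
        # transversions: the two bases of the other chemical class
        purine = np.isin(out, (0, 2))  # A or G
        out[tv1 & purine] = 1          # -> C
        out[tv1 & ~purine] = 0         # -> A
        out[tv2 & purine] = 3          # -> T
        out[tv2 & ~purine] = 2         # -> G
        return _BASES[out].tobytes().decode("ascii")

    return LtrElement(
        id=element_id, superfamily=superfamily,
        ltr5=evolve(ancestral), ltr3=evolve(ancestral),
    )
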
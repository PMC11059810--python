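"""Structural-variant tables: parsing, summaries, cross-genome intersection.

Consumes Assemblytics-style BED tables (one per genome, all against a shared
reference) with seven SV types: insertion, deletion, tandem expansion/
contraction, repeat expansion/contraction and inversion.  The candidate
filter keeps deletion clusters present (by reciprocal overlap) in every
genome of a designated "present" group and absent from every genome of an
"absent" group — the presence/absence contrast used to nominate deletions
that separate ecological groups — and annotates genes within a configurable
distance of each candidate (default 2000 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

__all__ = [
    "SV_TYPES",
    "SvRecord",
    "CandidateSv",
    "SvSummary",
    "read_assemblytics",
    "write_assemblytics",
    "summarize_svs",
    "match_svs",
    "candidate_deletions",
    "annotate_proximal_genes",
    "read_gff3_genes",
]

SV_TYPES = (
    "insertion",
    "deletion",
    "tandem_expansion",
    "tandem_contraction",
    "repeat_expansion",
    "repeat_contraction",
    "inversion",
)

_ASSEMBLYTICS_COLUMNS = (
    "reference", "start", "stop", "ID", "size", "strand", "type",
    "ref_gap_size", "query_gap_size", "query_coordinates", "method",
)


@dataclass(frozen=True)
class SvRecord:
    """One structural variant on the shared reference (0-based half-open).

    Insertions occupy a 1-bp anchor on the reference ([pos, pos+1)); ``size``
    is the inserted length.
    """

    reference: str
    start: int
    end: int
    type: str
    size: int
    genome: str
    id: str = ""
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.type!r}")
        if self.start >= self.end:
            raise ValueError(f"start must be < end ({self.start} >= {self.end})")
        if self.size <= 0:
            raise ValueError("size must be positive")

    @property
    def length(self) -> int:
        return self.end - self.start


def normalize_sv_type(raw: str) -> str:
    name = raw.strip().lower().replace(" ", "_").replace("-", "_")
    if name not in SV_TYPES:
        raise ValueError(f"unknown SV type {raw!r}")
    return name


def read_assemblytics(path: "str | Path", genome_label: str) -> list[SvRecord]:
    """Parse an Assemblytics-style BED table (header line tolerated); type
    names are normalized to the seven canonical lowercase forms."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("reference", "chrom", "ref"):
                continue
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: expected >=7 tab-separated fields")
            try:
                sv_type = normalize_sv_type(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            start, end = int(fields[1]), int(fields[2])
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            records.append(SvRecord(
                reference=fields[0], start=start, end=max(end, start + 1),
                type=sv_type, size=int(fields[4]), genome=genome_label,
                id=fields[3], strand=fields[5] or "+",
            ))
    return records


def write_assemblytics(records: Iterable[SvRecord], path: "str | Path") -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ASSEMBLYTICS_COLUMNS) + "\n")
        for i, r in enumerate(records):
            fh.write("\t".join(map(str, (
                r.reference, r.start, r.end, r.id or f"sv_{i}", r.size,
                r.strand, r.type, r.end - r.start, 0, ".", "within_alignment",
            ))) + "\n")


@dataclass(frozen=True)
class SvSummary:
    counts: pd.DataFrame = field(repr=False)       # genome x type
    bases: pd.DataFrame = field(repr=False)        # genome x type, summed sizes
    count_ratio: pd.Series = field(repr=False)     # per-genome deletion/insertion
    base_ratio: pd.Series = field(repr=False)
    mean_count_ratio: float = float("nan")
    mean_base_ratio: float = float("nan")


def summarize_svs(records_by_genome: Mapping[str, Sequence[SvRecord]]) -> SvSummary:
    """Per-genome per-type counts and base totals, plus deletion:insertion
    fold ratios averaged across genomes (NaN where insertions are absent)."""
    genomes = list(records_by_genome)
    counts = pd.DataFrame(0, index=genomes, columns=list(SV_TYPES), dtype=int)
    bases = pd.DataFrame(0, index=genomes, columns=list(SV_TYPES), dtype=int)
    for genome, records in records_by_genome.items():
        for r in records:
            counts.loc[genome, r.type] += 1
            bases.loc[genome, r.type] += r.size
    with np.errstate(divide="ignore", invalid="ignore"):
        count_ratio = counts["deletion"] / counts["insertion"].replace(0, np.nan)
        base_ratio = bases["deletion"] / bases["insertion"].replace(0, np.nan)
    return SvSummary(
        counts=counts, bases=bases,
        count_ratio=count_ratio, base_ratio=base_ratio,
        mean_count_ratio=float(count_ratio.mean()),
        mean_base_ratio=float(base_ratio.mean()),
    )


def match_svs(a: SvRecord, b: SvRecord, min_reciprocal_overlap: float = 0.5) -> bool:
    """Cross-genome equivalence of two SVs of the same type on the same
    reference.

    Interval types match when the overlap covers at least
    ``min_reciprocal_overlap`` of *both* records.  Insertions (1-bp anchors)
    match when their breakpoints are within ``(1 - r) x min(size_a, size_b)``.
    """
    if a.reference != b.reference or a.type != b.type:
        return False
    r = min_reciprocal_overlap
    if a.type == "insertion":
        return abs(a.start - b.start) <= (1.0 - r) * min(a.size, b.size)
    overlap = min(a.end, b.end) - max(a.start, b.start)
    if overlap <= 0:
        return False
    return overlap >= r * a.length and overlap >= r * b.length


@dataclass(frozen=True)
class CandidateSv:
    """A deletion cluster present in every present-group genome and absent
    from the absent group; the representative interval is the union of the
    matched records."""

    reference: str
    start: int
    end: int
    present_genomes: frozenset[str]
    absent_genomes: frozenset[str]
    records: tuple[SvRecord, ...]
    proximal_genes: tuple[tuple[str, int], ...] | None = None


def candidate_deletions(
    records_by_genome: Mapping[str, Sequence[SvRecord]],
    present_group: Sequence[str],
    absent_group: Sequence[str],
    min_reciprocal_overlap: float = 0.5,
) -> list[CandidateSv]:
    """Presence/absence deletion filter across genome groups.

    Deletions from the present group are clustered by single-linkage under
    :func:`match_svs`; a cluster qualifies iff every present-group genome
    contributes at least one record and no absent-group genome has a record
    matching any member.  Genome order within either group is irrelevant.
    """
    present = set(present_group)
    absent = set(absent_group)
    if not present or not absent:
        raise ValueError("both groups must be non-empty")
    if present & absent:
        raise ValueError("present and absent groups must be disjoint")
    for g in sorted(present | absent):
        if g not in records_by_genome:
            raise KeyError(f"no SV records for genome {g!r}")

    dels = [
        r
        for g in sorted(present)
        for r in records_by_genome[g]
        if r.type == "deletion"
    ]
    n = len(dels)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if match_svs(dels[i], dels[j], min_reciprocal_overlap):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    clusters: dict[int, list[SvRecord]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(dels[i])

    absent_dels = [
        r
        for g in sorted(absent)
        for r in records_by_genome[g]
        if r.type == "deletion"
    ]
    candidates = []
    for members in clusters.values():
        if {m.genome for m in members} != present:
            continue
        if any(
            match_svs(m, a, min_reciprocal_overlap)
            for m in members
            for a in absent_dels
        ):
            continue
        members = sorted(members, key=lambda r: (r.genome, r.start))
        candidates.append(CandidateSv(
            reference=members[0].reference,
            start=min(m.start for m in members),
            end=max(m.end for m in members),
            present_genomes=frozenset(present),
            absent_genomes=frozenset(absent),
            records=tuple(members),
        ))
    candidates.sort(key=lambda c: (c.reference, c.start, c.end))
    return candidates


def read_gff3_genes(gff3: "str | Path") -> list[tuple[str, str, int, int]]:
    """Gene features from a GFF3 file as (gene id, seqid, start0, end) with
    coordinates converted to 0-based half-open.  Input need not be sorted."""
    db = gffutils.create_db(
        str(gff3), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    return [
        (f.id, f.seqid, f.start - 1, f.end) for f in db.features_of_type("gene")
    ]


def annotate_proximal_genes(
    candidates: Sequence[CandidateSv],
    gff3: "str | Path | Sequence[tuple[str, str, int, int]]",
    max_distance: int = 2000,
) -> list[CandidateSv]:
    """Attach genes whose span lies within ``max_distance`` bp (inclusive) of
    each candidate interval; overlapping genes have distance 0.  Strand is
    ignored.  ``gff3`` may be a path or a pre-parsed gene list."""
    genes = (
        list(gff3) if isinstance(gff3, (list, tuple)) else read_gff3_genes(gff3)
    )
    annotated = []
    for cand in candidates:
        hits = []
        for gene_id, seqid, gstart, gend in genes:
            if seqid != cand.reference:
                continue
            distance = max(0, max(cand.start - gend, gstart - cand.end))
            if distance <= max_distance:
                hits.append((gene_id, distance))
        hits.sort(key=lambda h: (h[1], h[0]))
        annotated.append(replace(cand, proximal_genes=tuple(hits)))
    return annotated


def candidates_table(candidates: Sequence[CandidateSv]) -> pd.DataFrame:
    """Flat export of candidate deletions (and their proximal genes, if set)."""
    rows = []
    for c in candidates:
        rows.append({
            "reference": c.reference, "start": c.start, "end": c.end,
            "present": ",".join(sorted(c.present_genomes)),
            "absent": ",".join(sorted(c.absent_genomes)),
            "genes": ";".join(f"{g}:{d}" for g, d in (c.proximal_genes or ())),
        })
    return pd.DataFrame(rows)
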
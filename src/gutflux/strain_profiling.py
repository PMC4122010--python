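"""Strain presence calling and gene coverage from metagenome alignments.

Reads tabular BLAST (outfmt 6) or SAM alignments, applies identity and
uniqueness filters, computes per-genome depth (Σ aligned bases / genome
length) and breadth (fraction of positions covered ≥ 1×), calls strain
presence against a fold-coverage threshold, scores gene coverage by the
best single scaffold, and tests gene-set enrichment with a one-sided
Fisher exact test computed in log space.

Coordinates are 1-based inclusive on ingestion (the BLAST convention) and
converted to 0-based half-open internally; that conversion is the single
boundary between the two systems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "AlignmentRecord",
    "StrainCall",
    "GeneCoverage",
    "read_blast_tab",
    "read_sam",
    "filter_alignments",
    "genome_coverage",
    "call_strains",
    "aggregate_prevalence",
    "gene_coverage_from_scaffolds",
    "enrichment_test",
    "enrichment_log_pvalue",
]

DEFAULT_MIN_IDENTITY = 99.0  # percent
DEFAULT_DEPTH_THRESHOLD = 10.0  # fold coverage
DEFAULT_GENE_FRACTION = 0.8  # single-scaffold covered fraction


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment: query (read or scaffold) vs subject genome, with
    1-based inclusive subject coordinates (strand-normalised so
    start ≤ end)."""

    query_id: str
    subject_id: str
    identity: float  # percent, 0–100
    length: int  # aligned bases
    subject_start: int
    subject_end: int
    bitscore: float = 0.0
    query_length: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.length <= 0:
            raise ValueError("alignment length must be positive")
        if self.subject_start > self.subject_end:
            object.__setattr__(self, "subject_start", self.subject_end)
            object.__setattr__(self, "subject_end", self.subject_start)

    @property
    def interval(self) -> tuple[int, int]:
        """0-based half-open subject interval."""
        return (self.subject_start - 1, self.subject_end)


@dataclass
class StrainCall:
    strain_id: str
    genome_length: int
    depth: float
    breadth: float
    present: bool
    depth_threshold: float
    min_identity: float


@dataclass
class GeneCoverage:
    gene_id: str
    length: int
    best_fraction: float  # best single-scaffold covered fraction
    covered: bool  # best_fraction >= the gene-fraction threshold


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------

_BLAST6_FIELDS = 12


def read_blast_tab(path: str | Path) -> list[AlignmentRecord]:
    """Parse tabular BLAST outfmt 6 (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore)."""
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < _BLAST6_FIELDS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_BLAST6_FIELDS} tab-separated "
                    f"fields, got {len(parts)}"
                )
            try:
                sstart, send = int(parts[8]), int(parts[9])
                records.append(
                    AlignmentRecord(
                        query_id=parts[0],
                        subject_id=parts[1],
                        identity=float(parts[2]),
                        length=int(parts[3]),
                        subject_start=min(sstart, send),
                        subject_end=max(sstart, send),
                        bitscore=float(parts[11]),
                        query_length=abs(int(parts[7]) - int(parts[6])) + 1,
                    )
                )
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: malformed row ({e})") from None
    return records


def records_from_frame(df: pd.DataFrame) -> list[AlignmentRecord]:
    """AlignmentRecords from a DataFrame in BLAST outfmt-6 column layout."""
    out = []
    for row in df.itertuples(index=False):
        s, e = int(row.sstart), int(row.send)
        out.append(
            AlignmentRecord(
                query_id=str(row.qseqid), subject_id=str(row.sseqid),
                identity=float(row.pident), length=int(row.length),
                subject_start=min(s, e), subject_end=max(s, e),
                bitscore=float(row.bitscore),
                query_length=abs(int(row.qend) - int(row.qstart)) + 1,
            )
        )
    return out


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Parse mapped segments of a SAM file; identity derives from the NM tag
    (100 · (1 − NM / aligned_length)), defaulting to 100 when NM is absent."""
    import pysam

    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.reference_id < 0:
                continue
            alen = aln.query_alignment_length or aln.infer_query_length() or 0
            if alen <= 0:
                continue
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            identity = 100.0 * (1.0 - nm / alen)
            records.append(
                AlignmentRecord(
                    query_id=aln.query_name,
                    subject_id=sam.get_reference_name(aln.reference_id),
                    identity=max(0.0, identity),
                    length=aln.reference_length or alen,
                    subject_start=aln.reference_start + 1,  # SAM is 0-based
                    subject_end=aln.reference_end or (aln.reference_start + alen),
                    bitscore=float(aln.mapping_quality),
                    query_length=aln.query_length or alen,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Filtering and coverage
# ---------------------------------------------------------------------------


def filter_alignments(
    records: Sequence[AlignmentRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    unique_only: bool = True,
) -> list[AlignmentRecord]:
    """Keep alignments with identity ≥ min_identity; with ``unique_only``,
    drop every query that retains more than one alignment (multi-mappers are
    discarded outright, ties are not rescued by bitscore)."""
    kept = [r for r in records if r.identity >= min_identity]
    if not unique_only:
        return kept
    counts: dict[str, int] = {}
    for r in kept:
        counts[r.query_id] = counts.get(r.query_id, 0) + 1
    return [r for r in kept if counts[r.query_id] == 1]


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of 0-based half-open intervals."""
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def genome_coverage(
    records: Sequence[AlignmentRecord], genome_length: int
) -> tuple[float, float]:
    """(depth, breadth): mean fold coverage Σ aligned bases / genome length,
    and fraction of positions covered at least once (interval union)."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    intervals = []
    total_bases = 0
    for r in records:
        s, e = r.interval
        if s < 0 or e > genome_length:
            raise ValueError(
                f"alignment {r.query_id} at [{r.subject_start}, {r.subject_end}] "
                f"outside genome of length {genome_length}"
            )
        intervals.append((s, e))
        total_bases += r.length
    depth = total_bases / genome_length
    breadth = _merged_length(intervals) / genome_length
    return depth, breadth


def call_strains(
    coverages: Mapping[str, tuple[float, float]],
    depth_threshold: float = DEFAULT_DEPTH_THRESHOLD,
    genome_lengths: Mapping[str, int] | None = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[StrainCall]:
    """Presence verdict per strain: present ⇔ depth ≥ depth_threshold
    (boundary inclusive).  ``coverages`` maps strain → (depth, breadth)."""
    if depth_threshold <= 0:
        raise ValueError("depth_threshold must be positive")
    calls = []
    for sid, (depth, breadth) in coverages.items():
        calls.append(
            StrainCall(
                strain_id=sid,
                genome_length=(genome_lengths or {}).get(sid, 0),
                depth=depth,
                breadth=breadth,
                present=depth >= depth_threshold,
                depth_threshold=depth_threshold,
                min_identity=min_identity,
            )
        )
    return calls


def aggregate_prevalence(per_sample_calls: Sequence[Sequence[StrainCall]]) -> pd.DataFrame:
    """Cohort table (strain, n_present, n_samples, prevalence), sorted by
    descending prevalence then strain id."""
    n_samples = len(per_sample_calls)
    counts: dict[str, int] = {}
    for calls in per_sample_calls:
        for c in calls:
            counts.setdefault(c.strain_id, 0)
            if c.present:
                counts[c.strain_id] += 1
    rows = [
        (sid, k, n_samples, k / n_samples if n_samples else math.nan)
        for sid, k in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["strain", "n_present", "n_samples", "prevalence"])
    return df.sort_values(["prevalence", "strain"], ascending=[False, True]).reset_index(drop=True)


def gene_coverage_from_scaffolds(
    records: Sequence[AlignmentRecord],
    genes: Sequence[tuple[str, int, int]],
    fraction_threshold: float = DEFAULT_GENE_FRACTION,
) -> list[GeneCoverage]:
    """Best single-scaffold covered fraction per gene.

    Gene intervals are 1-based inclusive on the subject genome.  For each
    gene the covered fraction is max over scaffolds (query ids) of the
    merged overlap with that scaffold's alignments divided by gene length;
    two scaffolds covering half each do NOT combine.  Identity filtering
    is expected upstream.
    """
    by_query: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        by_query.setdefault(r.query_id, []).append(r)

    out: list[GeneCoverage] = []
    for gid, gstart, gend in genes:
        glen = gend - gstart + 1
        if glen <= 0:
            raise ValueError(f"gene {gid}: zero or negative length")
        g0, g1 = gstart - 1, gend  # 0-based half-open
        best = 0.0
        for qid, rec_list in by_query.items():
            overlaps = []
            for r in rec_list:
                s, e = r.interval
                o_s, o_e = max(s, g0), min(e, g1)
                if o_e > o_s:
                    overlaps.append((o_s, o_e))
            if overlaps:
                best = max(best, _merged_length(overlaps) / glen)
        out.append(
            GeneCoverage(gene_id=gid, length=glen, best_fraction=best,
                         covered=best >= fraction_threshold)
        )
    return out


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


def _log_hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """log P(X = k) for X ~ Hypergeom(N population, K successes, n draws)."""
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - n + k + 1)
        + gammaln(n + 1) + gammaln(N - n + 1) - gammaln(N + 1)
    )


def enrichment_log_pvalue(
    covered_in_set: int, set_size: int, covered_total: int, universe: int
) -> float:
    """Natural log of the one-sided Fisher exact (hypergeometric upper-tail)
    p-value P(X ≥ covered_in_set); stays finite far below float underflow."""
    k, n, K, N = covered_in_set, set_size, covered_total, universe
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K and n - k <= N - K):
        raise ValueError(
            f"inconsistent 2x2 margins: k={k}, set={n}, total={K}, universe={N}"
        )
    hi = min(n, K)
    terms = [_log_hypergeom_pmf(i, N, K, n) for i in range(k, hi + 1)]
    return float(min(0.0, logsumexp(terms))) if terms else -math.inf


def enrichment_test(
    covered_in_set: int, set_size: int, covered_total: int, universe: int
) -> float:
    """One-sided Fisher exact p-value for over-representation of covered
    items in a gene set (upper hypergeometric tail, computed in log space;
    may underflow to 0.0 for astronomically small p — use
    :func:`enrichment_log_pvalue` when the magnitude itself matters)."""
    return math.exp(
        enrichment_log_pvalue(covered_in_set, set_size, covered_total, universe)
    )


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


def profile_sample(
    records: Sequence[AlignmentRecord],
    genome_lengths: Mapping[str, int],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    depth_threshold: float = DEFAULT_DEPTH_THRESHOLD,
    unique_only: bool = True,
) -> list[StrainCall]:
    """Filter → per-strain coverage → presence calls for one sample."""
    kept = filter_alignments(records, min_identity=min_identity,
                             unique_only=unique_only)
    by_subject: dict[str, list[AlignmentRecord]] = {}
    for r in kept:
        by_subject.setdefault(r.subject_id, []).append(r)
    coverages = {}
    for sid, glen in genome_lengths.items():
        coverages[sid] = genome_coverage(by_subject.get(sid, []), glen)
    return call_strains(coverages, depth_threshold=depth_threshold,
                        genome_lengths=genome_lengths, min_identity=min_identity)
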
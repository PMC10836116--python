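"""Poly(A)-site cluster (PAC) calling from aligned 3'-tag reads.

Cleavage sites are the 3'-most aligned base of each uniquely mapped tag in
transcript orientation.  Sites within ``cluster_window_nt`` (inclusive) of
one another on the same chromosome/strand are single-linkage merged into
PACs.  PACs are then filtered with a library-size-adaptive read-support
rule, mitochondrial clusters are removed, and counts are normalized to
reads per 10^7 within each sample.

Coordinates are 1-based inclusive internally; BED I/O converts to/from
0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SampleInfo",
    "AlignedTag",
    "PAC",
    "FilterParams",
    "extract_tags",
    "cluster_sites",
    "filter_pacs",
    "remove_mitochondrial",
    "normalize",
    "read_sample_sheet",
    "read_tags_bed",
    "write_pac_table",
    "read_pac_table",
]

CONDITIONS = ("ZT2", "ZT6", "ZT8", "ZT10", "ZT14", "ZT18", "ZT22", "R0", "R2", "R4", "R8")


@dataclass(frozen=True)
class SampleInfo:
    """One library: condition label, replicate index and sequencing depth."""

    sample_id: str
    condition: str
    replicate: int
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError(f"sample {self.sample_id}: library_size must be > 0")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"sample {self.sample_id}: unknown condition {self.condition!r}"
            )


@dataclass(frozen=True)
class AlignedTag:
    """One mapped tag reduced to its inferred cleavage coordinate (1-based)."""

    chrom: str
    strand: str
    site: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"tag at {self.chrom}:{self.site}: invalid strand {self.strand!r}")
        if self.site < 1:
            raise ValueError("site coordinates are 1-based; got site < 1")


@dataclass
class PAC:
    """A poly(A)-site cluster with per-sample raw (and later normalized) counts."""

    pac_id: str
    chrom: str
    strand: str
    start: int
    end: int
    summit: int
    counts: dict[str, int]
    norm_counts: dict[str, float] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class FilterParams:
    """Clustering window, retention thresholds and normalization scale."""

    cluster_window_nt: int = 25
    lib_size_cutoff: int = 1_700_000
    min_samples: int = 3
    min_reads_small_lib: int = 3
    min_reads_large_lib: int = 4
    scale: int = 10_000_000
    mito_chroms: frozenset[str] = frozenset({"MT", "chrM"})

    def __post_init__(self) -> None:
        for name in (
            "cluster_window_nt",
            "lib_size_cutoff",
            "min_samples",
            "min_reads_small_lib",
            "min_reads_large_lib",
            "scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.mito_chroms = frozenset(self.mito_chroms)


# ---------------------------------------------------------------------------
# tag extraction


def extract_tags(alignments, samples=None, flip_strand: bool = False) -> list[AlignedTag]:
    """Reduce alignments to cleavage-site tags.

    ``alignments`` is an iterable of pysam ``AlignedSegment`` objects (e.g. a
    ``pysam.AlignmentFile``) paired with a sample id via the read-group-less
    convention that the query name is ``<sample_id>:<anything>``, OR an
    iterable of ``(segment, sample_id)`` tuples.

    Non-unique alignments (secondary/supplementary flags, or ``NH > 1``) are
    excluded.  The cleavage site is the 3'-most aligned genomic base in
    transcript orientation: alignment end for + strand, alignment start for
    - strand.  ``flip_strand`` accommodates libraries whose reads map
    antisense to the transcript.
    """
    tags: list[AlignedTag] = []
    for item in alignments:
        if isinstance(item, tuple):
            seg, sample_id = item
        else:
            seg = item
            sample_id = seg.query_name.split(":", 1)[0]
        if seg.is_unmapped:
            continue
        if seg.is_secondary or seg.is_supplementary:
            continue
        try:
            if seg.get_tag("NH") > 1:
                continue
        except KeyError:
            pass
        strand = "-" if seg.is_reverse else "+"
        if flip_strand:
            strand = "-" if strand == "+" else "+"
        if strand == "+":
            site = seg.reference_end  # 0-based exclusive == 1-based inclusive last base
        else:
            site = seg.reference_start + 1
        tags.append(AlignedTag(seg.reference_name, strand, site, sample_id))
    return tags


def read_tags_bed(path: str) -> list[AlignedTag]:
    """Read tags from BED6 (chrom, start, end, name=sample_id, score, strand).

    Each record's cleavage site is the 3'-most base of the interval in
    transcript orientation (end for +, start for -), converted to 1-based.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    sites = np.where(df["strand"] == "+", df["end"], df["start"] + 1)
    return [
        AlignedTag(c, st, int(s), n)
        for c, st, s, n in zip(df["chrom"], df["strand"], sites, df["name"])
    ]


# ---------------------------------------------------------------------------
# clustering


def cluster_sites(tags: list[AlignedTag], params: FilterParams | None = None) -> list[PAC]:
    """Single-linkage cluster cleavage sites into PACs.

    Per chromosome+strand, distinct sites are sorted and a new cluster starts
    whenever the gap to the previous site exceeds ``cluster_window_nt``
    ("within 25 nt" is inclusive: distance <= window stays in the cluster).
    The summit is the member site with the most total reads; ties go to the
    most distal site in transcript orientation (largest coordinate on +,
    smallest on -).
    """
    params = params or FilterParams()
    w = params.cluster_window_nt

    # aggregate: (chrom, strand, site) -> {sample: count}
    per_site: dict[tuple[str, str, int], dict[str, int]] = {}
    for t in tags:
        key = (t.chrom, t.strand, t.site)
        d = per_site.setdefault(key, {})
        d[t.sample_id] = d.get(t.sample_id, 0) + 1

    by_cs: dict[tuple[str, str], list[int]] = {}
    for chrom, strand, site in per_site:
        by_cs.setdefault((chrom, strand), []).append(site)

    pacs: list[PAC] = []
    for (chrom, strand) in sorted(by_cs):
        sites = sorted(by_cs[(chrom, strand)])
        runs: list[list[int]] = [[sites[0]]]
        for s in sites[1:]:
            if s - runs[-1][-1] <= w:
                runs[-1].append(s)
            else:
                runs.append([s])
        for run in runs:
            counts: dict[str, int] = {}
            site_totals: dict[int, int] = {}
            for s in run:
                d = per_site[(chrom, strand, s)]
                site_totals[s] = sum(d.values())
                for sample_id, c in d.items():
                    counts[sample_id] = counts.get(sample_id, 0) + c
            best = max(site_totals.values())
            candidates = [s for s, c in site_totals.items() if c == best]
            summit = max(candidates) if strand == "+" else min(candidates)
            pacs.append(
                PAC(
                    pac_id="",
                    chrom=chrom,
                    strand=strand,
                    start=run[0],
                    end=run[-1],
                    summit=summit,
                    counts=counts,
                )
            )
    for i, p in enumerate(pacs, start=1):
        p.pac_id = f"PAC{i:06d}"
    return pacs


# ---------------------------------------------------------------------------
# filtering / normalization


def _sample_threshold(sample: SampleInfo, params: FilterParams) -> int:
    # library_size >= cutoff uses the stricter rule (boundary not defined by
    # the <1.7M / >1.7M wording; resolved to the conservative side)
    if sample.library_size < params.lib_size_cutoff:
        return params.min_reads_small_lib
    return params.min_reads_large_lib


def filter_pacs(
    pacs: list[PAC],
    samples: list[SampleInfo],
    params: FilterParams | None = None,
) -> list[PAC]:
    """Library-size-adaptive retention filter.

    Each sample's read threshold depends on its own library size (>= 3 reads
    for libraries below the cutoff, >= 4 at or above it).  A PAC is retained
    iff at least one condition group has >= ``min_samples`` replicates whose
    count meets that replicate's threshold.
    """
    params = params or FilterParams()
    groups: dict[str, list[SampleInfo]] = {}
    for s in samples:
        groups.setdefault(s.condition, []).append(s)
    for cond, members in groups.items():
        if len(members) != 5:
            warnings.warn(
                f"condition {cond} has {len(members)} replicates (expected 5); "
                f"retention rule applied with min_samples={params.min_samples} unchanged",
                stacklevel=2,
            )
    retained = []
    for pac in pacs:
        for members in groups.values():
            n_pass = sum(
                1
                for s in members
                if pac.counts.get(s.sample_id, 0) >= _sample_threshold(s, params)
            )
            if n_pass >= params.min_samples:
                retained.append(pac)
                break
    return retained


def remove_mitochondrial(pacs: list[PAC], params: FilterParams | None = None) -> list[PAC]:
    """Drop PACs on mitochondrial chromosomes."""
    params = params or FilterParams()
    return [p for p in pacs if p.chrom not in params.mito_chroms]


def normalize(
    pacs: list[PAC],
    samples: list[SampleInfo],
    params: FilterParams | None = None,
) -> list[PAC]:
    """Scale each sample's counts to reads per ``scale`` (default 10^7).

    The denominator for sample ``s`` is the total count over the retained
    PACs themselves (post-filter, post-mito), so each sample's normalized
    column sums exactly to ``scale`` whenever it has any retained reads.
    Mutates and returns ``pacs``.
    """
    params = params or FilterParams()
    totals = {s.sample_id: 0 for s in samples}
    for pac in pacs:
        for sample_id, c in pac.counts.items():
            if sample_id in totals:
                totals[sample_id] += c
    for sample_id, t in totals.items():
        if t == 0:
            warnings.warn(
                f"sample {sample_id} has no reads in retained PACs; "
                f"normalized counts set to 0",
                stacklevel=2,
            )
    for pac in pacs:
        pac.norm_counts = {
            s.sample_id: (
                pac.counts.get(s.sample_id, 0) / totals[s.sample_id] * params.scale
                if totals[s.sample_id] > 0
                else 0.0
            )
            for s in samples
        }
    return pacs


# ---------------------------------------------------------------------------
# I/O


def read_sample_sheet(path: str) -> list[SampleInfo]:
    """TSV with columns: sample_id, condition, replicate, library_size."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    samples = [
        SampleInfo(r.sample_id, r.condition, int(r.replicate), int(r.library_size))
        for r in df.itertuples()
    ]
    seen = set()
    for s in samples:
        key = (s.condition, s.replicate)
        if key in seen:
            raise ValueError(f"duplicate (condition, replicate) pair {key}")
        seen.add(key)
    return samples


def write_pac_table(pacs: list[PAC], samples: list[SampleInfo], path: str) -> pd.DataFrame:
    """PAC table TSV: coordinates 1-based inclusive; norm columns are reads per 10^7."""
    sample_ids = [s.sample_id for s in samples]
    rows = []
    for p in pacs:
        row: dict = {
            "pac_id": p.pac_id,
            "chrom": p.chrom,
            "strand": p.strand,
            "start": p.start,
            "end": p.end,
            "summit": p.summit,
        }
        for sid in sample_ids:
            row[f"count:{sid}"] = p.counts.get(sid, 0)
        for sid in sample_ids:
            row[f"norm:{sid}"] = p.norm_counts.get(sid, float("nan"))
        rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write("# coordinates 1-based inclusive; norm:* columns are reads per 1e7\n")
        df.to_csv(fh, sep="\t", index=False)
    return df


def read_pac_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def counts_matrix(df: pd.DataFrame, kind: str = "count") -> pd.DataFrame:
    """Extract the (PAC x sample) matrix of ``count:`` or ``norm:`` columns."""
    cols = [c for c in df.columns if c.startswith(kind + ":")]
    mat = df[cols].copy()
    mat.columns = [c.split(":", 1)[1] for c in cols]
    mat.index = df["pac_id"].values
    return mat


def write_pac_bed(pacs: list[PAC], path: str) -> None:
    with open(path, "w") as fh:
        for p in pacs:
            fh.write(
                f"{p.chrom}\t{p.start - 1}\t{p.end}\t{p.pac_id}\t{p.total_count}\t{p.strand}\n"
            )
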
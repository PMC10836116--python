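"""Read-level preprocessing for 3'-tag libraries.

Three steps, applied in order per read: (1) whole-read quality filter
(a minimum fraction of bases at or above a Phred threshold), (2) 5' T /
T-rich trimming (tag reads start in the poly(A) tail, which appears as a
leading T-rich stretch on the read), (3) minimum-length retention.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import IO, Iterator

__all__ = [
    "Read",
    "PreprocessParams",
    "PreprocessSummary",
    "quality_filter",
    "trim_5prime_t",
    "preprocess_fastq",
]


@dataclass
class Read:
    """A sequencing read: bases over {A,C,G,T,N} plus per-base Phred scores."""

    id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but {len(self.quals)} quality values"
            )
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class PreprocessParams:
    """Tunables for the read filters.

    min_q / min_frac : a read passes if at least ``min_frac`` of its bases
        have Phred >= ``min_q`` (boundary inclusive on both).
    min_len : post-trim reads shorter than this are dropped.
    t_window / t_window_min : after removing a leading T run, trimming
        continues through the next ``t_window`` bases whenever at least
        ``t_window_min`` of them are T (removing up to and including the
        last T among them), so interrupted T-rich stretches are removed too.
    """

    min_q: int = 10
    min_frac: float = 0.5
    min_len: int = 16
    t_window: int = 4
    t_window_min: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_frac <= 1.0:
            raise ValueError("min_frac must be in [0, 1]")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.t_window < 1 or self.t_window_min < 1:
            raise ValueError("t_window and t_window_min must be >= 1")


@dataclass
class PreprocessSummary:
    reads_in: int = 0
    reads_out: int = 0
    failed_quality: int = 0
    too_short: int = 0
    bases_trimmed: int = 0
    counts_by_fate: dict = field(default_factory=dict)


def quality_filter(read: Read, params: PreprocessParams | None = None) -> bool:
    """True iff the fraction of bases with Phred >= min_q is >= min_frac."""
    params = params or PreprocessParams()
    if len(read) == 0:
        raise ValueError(f"read {read.id!r} is empty; cannot quality-filter")
    n_good = sum(1 for q in read.quals if q >= params.min_q)
    return n_good / len(read) >= params.min_frac


def trim_5prime_t(read: Read, params: PreprocessParams | None = None) -> Read:
    """Remove the 5' T-rich prefix of a read.

    Deterministic two-phase rule, repeated until a fixed point:

    1. drop every leading ``T``;
    2. look at the next ``t_window`` bases: if at least ``t_window_min`` of
       them are ``T``, drop everything up to and including the last ``T``
       among them and go back to phase 1; otherwise stop.

    Qualities are trimmed in lockstep. May return an empty read.
    """
    params = params or PreprocessParams()
    bases = read.bases
    i = 0
    n = len(bases)
    while i < n:
        while i < n and bases[i] == "T":
            i += 1
        window = bases[i : i + params.t_window]
        if sum(1 for b in window if b == "T") >= params.t_window_min:
            # drop through the last T of the window, then rescan
            last_t = max(k for k, b in enumerate(window) if b == "T")
            i += last_t + 1
        else:
            break
    return Read(read.id, bases[i:], read.quals[i:])


def _open_maybe_gzip(path: str, mode: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _iter_fastq(handle: IO[str]) -> Iterator[tuple[str, str, str]]:
    """Yield (title, seq, qual) tuples; raise on truncated/malformed records."""
    record_index = 0
    while True:
        header = handle.readline()
        if not header:
            return
        seq = handle.readline().rstrip("\n")
        plus = handle.readline()
        qual = handle.readline().rstrip("\n")
        if not header.startswith("@") or not plus.startswith("+") or not qual:
            raise ValueError(f"malformed FASTQ record at index {record_index}")
        if len(seq) != len(qual):
            raise ValueError(
                f"malformed FASTQ record at index {record_index}: "
                f"sequence and quality lengths differ"
            )
        yield header[1:].rstrip("\n"), seq, qual
        record_index += 1


def preprocess_fastq(
    in_path: str,
    out_path: str,
    params: PreprocessParams | None = None,
) -> PreprocessSummary:
    """Filter + trim a FASTQ file; keep trimmed reads of length >= min_len.

    The quality filter is evaluated on the raw read, before trimming.
    Returns a :class:`PreprocessSummary` of read fates.
    """
    params = params or PreprocessParams()
    summary = PreprocessSummary()
    with _open_maybe_gzip(in_path, "r") as fin, _open_maybe_gzip(out_path, "w") as fout:
        for title, seq, qual in _iter_fastq(fin):
            summary.reads_in += 1
            read = Read(title.split()[0], seq, [ord(c) - 33 for c in qual])
            if not quality_filter(read, params):
                summary.failed_quality += 1
                continue
            trimmed = trim_5prime_t(read, params)
            summary.bases_trimmed += len(read) - len(trimmed)
            if len(trimmed) < params.min_len:
                summary.too_short += 1
                continue
            summary.reads_out += 1
            qstr = "".join(chr(q + 33) for q in trimmed.quals)
            fout.write(f"@{trimmed.id}\n{trimmed.bases}\n+\n{qstr}\n")
    summary.counts_by_fate = {
        "pass": summary.reads_out,
        "failed_quality": summary.failed_quality,
        "too_short": summary.too_short,
    }
    return summary


def write_summary_tsv(summary: PreprocessSummary, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for key in ("reads_in", "reads_out", "failed_quality", "too_short", "bases_trimmed"):
            fh.write(f"{key}\t{getattr(summary, key)}\n")
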
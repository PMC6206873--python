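"""Raw small-RNA read cleaning and collapsing.

Single-end small-RNA reads are adapter-ligated: the sequenced read is the
biological insert (a ~18-32 nt small RNA) followed by the 3' sequencing
adapter.  This module trims the adapter, applies quality and length filters,
and collapses the surviving inserts into a library of unique sequences with
counts.  The clean-read total of a library is the denominator used both for
annotation percentages and for TPM normalization downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

VALID_BASES = frozenset("ACGTN")


class MalformedSequenceError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


def _check_alphabet(seq: str, what: str = "sequence") -> str:
    s = seq.upper().replace("U", "T")
    if not set(s) <= VALID_BASES:
        bad = sorted(set(s) - VALID_BASES)
        raise MalformedSequenceError(f"{what} contains invalid characters {bad}: {seq!r}")
    return s


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RawReadSet:
    """A set of raw single-end reads plus the adapter(s) used in the library.

    ``reads`` holds ``(identifier, sequence, quality)`` triples where quality
    is a list of Phred scores, one per base.
    """

    reads: list[tuple[str, str, list[int]]]
    adapter_3p: str
    adapter_5p: str | None = None

    def __post_init__(self) -> None:
        self.adapter_3p = _check_alphabet(self.adapter_3p, "adapter_3p")
        if self.adapter_5p:
            self.adapter_5p = _check_alphabet(self.adapter_5p, "adapter_5p")
        for rid, seq, qual in self.reads:
            if len(seq) != len(qual):
                raise ValueError(f"read {rid}: quality length != sequence length")


@dataclass
class SmallRNALibrary:
    """Collapsed library: unique insert sequence -> read count.

    ``total_clean_reads`` (the library's N) always equals the sum of counts.
    """

    entries: dict[str, int]
    total_clean_reads: int
    label: str = ""

    def __post_init__(self) -> None:
        if sum(self.entries.values()) != self.total_clean_reads:
            raise ValueError("sum of counts must equal total_clean_reads")
        for seq in self.entries:
            if len(seq) < 18 or "N" in seq:
                raise ValueError(f"invalid library sequence {seq!r}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PreprocessStats:
    raw_count: int = 0
    discarded_quality: int = 0
    discarded_adapter_only: int = 0
    discarded_short: int = 0
    clean_count: int = 0
    length_histogram: dict[int, int] = field(default_factory=dict)

    def check_conservation(self) -> None:
        total = (self.clean_count + self.discarded_quality
                 + self.discarded_adapter_only + self.discarded_short)
        if total != self.raw_count:
            raise AssertionError("read-fate conservation violated")

    def to_dict(self) -> dict:
        d = {
            "raw_count": self.raw_count,
            "discarded_quality": self.discarded_quality,
            "discarded_adapter_only": self.discarded_adapter_only,
            "discarded_short": self.discarded_short,
            "clean_count": self.clean_count,
            "clean_fraction": self.clean_count / self.raw_count if self.raw_count else 0.0,
            "length_histogram": {str(k): v for k, v in sorted(self.length_histogram.items())},
        }
        return d


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def trim_adapter(sequence: str, adapter: str, max_mismatch_rate: float = 0.1,
                 min_overlap: int = 5) -> str:
    """Return the insert upstream of the leftmost 3' adapter occurrence.

    The adapter prefix is scanned against every read offset; the leftmost
    offset where the overlapping adapter prefix (at least ``min_overlap`` nt,
    shorter only when the read ends first) matches with a mismatch fraction
    <= ``max_mismatch_rate`` wins.  An adapter at offset 0 is an insert-null
    read and yields the empty string; if no occurrence is found the read is
    returned untouched (the adapter was read through or absent).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = _check_alphabet(sequence)
    adap = _check_alphabet(adapter, "adapter")
    n, m = len(seq), len(adap)
    for i in range(n):
        overlap = min(m, n - i)
        if overlap < min(min_overlap, m):
            break
        mism = sum(1 for a, b in zip(seq[i:i + overlap], adap[:overlap]) if a != b)
        if mism <= max_mismatch_rate * overlap:
            return seq[:i]
    return seq


def filter_and_collapse(raw: RawReadSet, min_length: int = 18, max_length: int = 32,
                        min_mean_quality: float = 20.0, min_base_quality: int = 10,
                        max_mismatch_rate: float = 0.1, label: str = "",
                        ) -> tuple[SmallRNALibrary, PreprocessStats]:
    """Quality-filter, adapter-trim, length-filter and collapse raw reads.

    Discard buckets (each read lands in exactly one):

    * ``discarded_quality`` — mean Phred < ``min_mean_quality``, any base
      below ``min_base_quality``, or an N remaining in the trimmed insert;
    * ``discarded_adapter_only`` — trimming leaves an empty insert;
    * ``discarded_short`` — trimmed insert outside [min_length, max_length].
    """
    if not raw.reads:
        raise ValueError("raw read set is empty")
    stats = PreprocessStats(raw_count=len(raw.reads))
    entries: dict[str, int] = {}
    for _rid, seq, qual in raw.reads:
        if qual and (sum(qual) / len(qual) < min_mean_quality
                     or min(qual) < min_base_quality):
            stats.discarded_quality += 1
            continue
        insert = trim_adapter(seq, raw.adapter_3p, max_mismatch_rate)
        if raw.adapter_5p and insert.startswith(raw.adapter_5p):
            insert = insert[len(raw.adapter_5p):]
        if not insert:
            stats.discarded_adapter_only += 1
            continue
        if "N" in insert:
            stats.discarded_quality += 1
            continue
        if not (min_length <= len(insert) <= max_length):
            stats.discarded_short += 1
            continue
        stats.clean_count += 1
        entries[insert] = entries.get(insert, 0) + 1
        stats.length_histogram[len(insert)] = stats.length_histogram.get(len(insert), 0) + 1
    if stats.clean_count == 0:
        warnings.warn("all reads discarded; library is empty", stacklevel=2)
    stats.check_conservation()
    lib = SmallRNALibrary(entries=entries, total_clean_reads=stats.clean_count, label=label)
    return lib, stats


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    """Stream (id, sequence, Phred+33 quality list) records from a FASTQ file."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"])


def load_raw_readset(path: str | Path, adapter_3p: str,
                     adapter_5p: str | None = None) -> RawReadSet:
    return RawReadSet(reads=list(read_fastq(path)), adapter_3p=adapter_3p,
                      adapter_5p=adapter_5p)


def write_library_fasta(lib: SmallRNALibrary, path: str | Path) -> None:
    """Collapsed-library FASTA with ``>seq{i}_x{count}`` headers."""
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(sorted(lib.entries.items(),
                                                key=lambda kv: (-kv[1], kv[0])), start=1):
            fh.write(f">seq{i}_x{count}\n{seq}\n")


def write_library_tsv(lib: SmallRNALibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for seq, count in sorted(lib.entries.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{seq}\t{count}\n")


def load_library_tsv(path: str | Path, label: str = "") -> SmallRNALibrary:
    entries: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence"):
            raise ValueError("library TSV must start with a 'sequence\\tcount' header")
        for line in fh:
            if line.strip():
                seq, count = line.split("\t")
                entries[seq] = int(count)
    return SmallRNALibrary(entries=entries, total_clean_reads=sum(entries.values()),
                           label=label)


def write_stats(stats: PreprocessStats, path: str | Path) -> None:
    Path(path).write_text(json.dumps(stats.to_dict(), indent=2) + "\n")
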
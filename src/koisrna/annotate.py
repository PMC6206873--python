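"""Hierarchical annotation of collapsed small-RNA sequences.

Each unique sequence receives exactly one annotation category following the
priority rule ncRNA (GenBank > Rfam) > known miRNA > repeat > exon > intron;
anything left over is "other".  Sequence matching is ungapped Hamming search
(read lengths of 18-32 nt make gapped alignment unnecessary) with a
per-tier mismatch tolerance: 1 for the ncRNA/genome tiers, 2 for conserved
miRNA calling.  Unannotated genome-mapped sequences can then be screened for
hairpin-forming novel miRNA candidates.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np

from .preprocess import SmallRNALibrary, _check_alphabet

#: Annotation tiers, highest priority first.  GenBank and Rfam are the two
#: sub-tiers of the ncRNA tier; "genome" means a genome hit with no feature.
PRIORITY = ("genbank_ncRNA", "rfam_ncRNA", "known_miRNA",
            "repeat", "exon", "intron", "genome")

_COMPL = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ReferenceSet:
    """One annotation tier's reference: sequences, or intervals on the genome.

    ``sequences`` maps reference id -> sequence for sequence-based tiers
    (ncRNA classes, known miRNAs, the genome itself); ``intervals`` holds
    0-based half-open ``(chrom, start, end, strand)`` tuples for the
    repeat/exon/intron tiers.  ``subtype`` is the display class used in
    summary tables (e.g. ``tRNA`` for a GenBank tRNA set).
    """

    category: str
    sequences: dict[str, str] | None = None
    intervals: list[tuple[str, int, int, str]] | None = None
    subtype: str = ""

    def __post_init__(self) -> None:
        if self.category not in PRIORITY:
            raise ValueError(f"unknown category {self.category!r}")
        if self.sequences is not None:
            self.sequences = {k: _check_alphabet(v, k) for k, v in self.sequences.items()}
        if not self.subtype:
            self.subtype = self.category


class Hit(NamedTuple):
    query: str
    ref_id: str
    position: int        # 0-based start on the reference forward strand
    strand: str          # '+' or '-'
    mismatches: int


@dataclass
class AnnotationAssignment:
    sequence: str
    category: str        # a PRIORITY entry, or "other"
    best_hit: str | None
    mismatches: int
    subtype: str = ""    # display class (tRNA, rRNA, ... or the category)


@dataclass
class MiRNARecord:
    name: str
    sequence: str
    family: str
    status: str                      # conserved | known_carp | novel_candidate
    counts: dict[str, int] = field(default_factory=dict)
    variant_sequences: list[str] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class HairpinCandidate:
    chrom: str
    start: int
    end: int
    strand: str
    precursor: str
    fold_energy: float
    mature_arm: str      # '5p' | '3p'
    mature_sequence: str


# ---------------------------------------------------------------------------
# Ungapped Hamming search
# ---------------------------------------------------------------------------

class HammingSearcher:
    """Mismatch-tolerant ungapped search over a set of reference sequences.

    Uses pigeonhole seeding: a query allowed ``m`` mismatches is split into
    ``m+1`` disjoint exact seeds; every occurrence within tolerance contains
    at least one seed verbatim.  Seed k-mer indexes are cached per seed
    length, so the cost is proportional to candidate hits, not to
    |query| x |reference|.
    """

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("reference set is empty")
        self.sequences = {k: _check_alphabet(v, k) for k, v in sequences.items()}
        self._kmer_index: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _index_for(self, k: int) -> dict[str, list[tuple[str, int]]]:
        if k not in self._kmer_index:
            idx: dict[str, list[tuple[str, int]]] = {}
            for rid, seq in self.sequences.items():
                for pos in range(len(seq) - k + 1):
                    idx.setdefault(seq[pos:pos + k], []).append((rid, pos))
            self._kmer_index[k] = idx
        return self._kmer_index[k]

    @staticmethod
    def _hamming(a: str, b: str, limit: int) -> int:
        d = 0
        for x, y in zip(a, b):
            if x != y:
                d += 1
                if d > limit:
                    return d
        return d

    def _oriented_hits(self, oriented: str, strand: str, query: str,
                       max_mismatch: int) -> list[Hit]:
        L = len(oriented)
        k = L // (max_mismatch + 1)
        idx = self._index_for(k)
        seen: set[tuple[str, int]] = set()
        hits: list[Hit] = []
        for j in range(max_mismatch + 1):
            seed = oriented[j * k:(j + 1) * k]
            for rid, pos in idx.get(seed, ()):
                start = pos - j * k
                if start < 0 or (rid, start) in seen:
                    continue
                seen.add((rid, start))
                ref = self.sequences[rid]
                if start + L > len(ref):
                    continue
                d = self._hamming(oriented, ref[start:start + L], max_mismatch)
                if d <= max_mismatch:
                    hits.append(Hit(query, rid, start, strand, d))
        return hits

    def search(self, query: str, max_mismatch: int,
               both_strands: bool = True) -> list[Hit]:
        """All minimal-distance hits of ``query`` (and optionally its reverse
        complement) with at most ``max_mismatch`` substitutions."""
        q = _check_alphabet(query)
        hits = self._oriented_hits(q, "+", q, max_mismatch)
        if both_strands:
            hits += self._oriented_hits(revcomp(q), "-", q, max_mismatch)
        if not hits:
            return []
        dmin = min(h.mismatches for h in hits)
        best = [h for h in hits if h.mismatches == dmin]
        best.sort(key=lambda h: (h.ref_id, h.position, h.strand))
        return best


def map_sequences(library: SmallRNALibrary | Iterable[str], reference: ReferenceSet,
                  max_mismatch: int = 1, both_strands: bool = True) -> list[Hit]:
    """Map every unique sequence against a sequence-based reference tier."""
    if max_mismatch not in (0, 1, 2):
        raise ValueError("max_mismatch must be 0, 1 or 2")
    if reference.sequences is None or not reference.sequences:
        raise ValueError(f"reference {reference.category} has no sequences")
    seqs = library.entries if isinstance(library, SmallRNALibrary) else library
    searcher = HammingSearcher(reference.sequences)
    hits: list[Hit] = []
    for seq in seqs:
        hits.extend(searcher.search(seq, max_mismatch, both_strands))
    return hits


def hits_in_intervals(hits: Iterable[Hit], query_lengths: dict[str, int],
                      intervals: list[tuple[str, int, int, str]]) -> list[Hit]:
    """Keep genome hits whose footprint overlaps at least one interval."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {iv[0] for iv in intervals}:
        ivs = sorted((s, e) for c, s, e, _ in intervals if c == chrom)
        by_chrom[chrom] = (np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))
    kept = []
    for h in hits:
        if h.ref_id not in by_chrom:
            continue
        starts, ends = by_chrom[h.ref_id]
        qlen = query_lengths[h.query]
        # overlap iff interval.start < hit.end and interval.end > hit.start
        i = np.searchsorted(starts, h.position + qlen)
        if np.any(ends[:i] > h.position):
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# Hierarchy assignment and summaries
# ---------------------------------------------------------------------------

def assign_hierarchy(hits_by_category: dict[str, list[Hit]],
                     sequences: Iterable[str],
                     subtype_by_category: dict[str, dict[str, str]] | None = None,
                     ) -> dict[str, AnnotationAssignment]:
    """Give each sequence the highest-priority category in which it has a hit.

    Ties within one tier break on (fewest mismatches, lexicographically
    smallest reference id).  ``subtype_by_category`` optionally maps
    category -> {ref_id -> display subtype} (e.g. GenBank ids to tRNA/rRNA).
    """
    best_by_seq: dict[str, dict[str, Hit]] = {}
    for cat, hits in hits_by_category.items():
        if cat not in PRIORITY:
            raise ValueError(f"unknown category {cat!r}")
        for h in sorted(hits, key=lambda h: (h.mismatches, h.ref_id, h.position)):
            slot = best_by_seq.setdefault(h.query, {})
            if cat not in slot:
                slot[cat] = h
    out: dict[str, AnnotationAssignment] = {}
    for seq in sequences:
        slot = best_by_seq.get(seq, {})
        for cat in PRIORITY:
            if cat in slot:
                h = slot[cat]
                sub = ""
                if subtype_by_category and cat in subtype_by_category:
                    sub = subtype_by_category[cat].get(h.ref_id, "")
                # genome-mapped but feature-less sequences display as "other",
                # the known-miRNA tier as "miRNA"
                default = {"known_miRNA": "miRNA", "genome": "other"}.get(cat, cat)
                out[seq] = AnnotationAssignment(seq, cat, h.ref_id, h.mismatches,
                                                sub or default)
                break
        else:
            out[seq] = AnnotationAssignment(seq, "other", None, 0, "other")
    return out


def format_percentage(pct: float) -> str:
    """Summary-table convention: 2 decimals at >=0.1%, 3 decimals below."""
    return f"{pct:.2f}" if pct >= 0.1 else f"{pct:.3f}"


def annotation_summary_from_counts(category_reads: dict[str, int],
                                   total_clean_reads: int):
    """Per-category read counts and percentages of the clean-read total."""
    import pandas as pd

    if total_clean_reads <= 0:
        raise ValueError("total_clean_reads must be positive")
    rows = []
    for cat, n in category_reads.items():
        pct = 100.0 * n / total_clean_reads
        rows.append({"category": cat, "reads": n, "percent": pct,
                     "percent_str": format_percentage(pct)})
    return pd.DataFrame(rows)


def summarize_annotation(assignments: dict[str, AnnotationAssignment],
                         library: SmallRNALibrary):
    """Table of reads and % of clean total per display subtype."""
    counts: dict[str, int] = {}
    for seq, a in assignments.items():
        counts[a.subtype] = counts.get(a.subtype, 0) + library.entries.get(seq, 0)
    return annotation_summary_from_counts(counts, library.total_clean_reads)


# ---------------------------------------------------------------------------
# Conserved miRNA calling and family clustering
# ---------------------------------------------------------------------------

def _anchored_mismatches(query: str, ref: str, max_len_diff: int = 2) -> int | None:
    """Mismatches between query and reference anchored at the 5' end.

    Length differences up to ``max_len_diff`` nt are tolerated as 3'
    overhangs and do not count as mismatches; larger differences disqualify.
    """
    if abs(len(query) - len(ref)) > max_len_diff:
        return None
    return sum(1 for a, b in zip(query, ref) if a != b)


def call_conserved_mirnas(sequences: dict[str, int], reference: dict[str, str],
                          max_mismatch: int = 2, species_prefix: str = "ccr",
                          library_label: str = "lib") -> list[MiRNARecord]:
    """Attach reads to known mature miRNAs within the mismatch tolerance.

    Each sequence goes to the mature with the fewest mismatches (<= 2 by
    default), 3'-end length slack of 2 nt; counts of all sequence variants
    assigned to one mature name are summed.  Matures of the study species
    (``species_prefix``) are flagged ``known_carp``, others ``conserved``.
    """
    ref_norm = {name: _check_alphabet(s, name) for name, s in reference.items()}
    per_name: dict[str, dict[str, int]] = {}
    for seq, count in sequences.items():
        best: tuple[int, int, str] | None = None   # (mism, -overlap, name)
        for name, mature in ref_norm.items():
            d = _anchored_mismatches(seq, mature)
            if d is None or d > max_mismatch:
                continue
            key = (d, -min(len(seq), len(mature)), name)
            if best is None or key < best:
                best = key
        if best is not None:
            per_name.setdefault(best[2], {})[seq] = count
    records = []
    for name in sorted(per_name):
        variants = per_name[name]
        top_seq = max(variants, key=lambda s: (variants[s], s))
        status = "known_carp" if name.startswith(species_prefix + "-") else "conserved"
        records.append(MiRNARecord(name=name, sequence=top_seq,
                                   family=family_name(name), status=status,
                                   counts={library_label: sum(variants.values())},
                                   variant_sequences=sorted(variants)))
    return records


_FAMILY_RE = re.compile(r"^(?:[a-z]{3,4}-)?(let|lin|mir|bantam)-?(\d+)", re.IGNORECASE)


def family_name(name: str) -> str:
    """Normalize a mature miRNA name to its family.

    Strips the species prefix, the arm suffix (-5p/-3p) and lettered or
    numbered paralog suffixes: ccr-miR-125b -> miR-125, let-7a -> let-7.
    """
    m = _FAMILY_RE.match(name)
    if m:
        stem = m.group(1).lower()
        stem = {"mir": "miR"}.get(stem, stem)
        return f"{stem}-{m.group(2)}"
    return re.sub(r"-[35]p$", "", re.sub(r"^[a-z]{3,4}-", "", name))


def cluster_families(records: Iterable[MiRNARecord]) -> dict[str, list[str]]:
    fams: dict[str, list[str]] = {}
    for rec in records:
        fams.setdefault(rec.family or family_name(rec.name), []).append(rec.name)
    for members in fams.values():
        members.sort()
    return fams


# ---------------------------------------------------------------------------
# Novel miRNA candidate screen
# ---------------------------------------------------------------------------

def screen_novel_candidates(genome_hits: list[Hit], genome: dict[str, str],
                            flank: int = 70, energy_threshold: float = -18.0,
                            min_paired: int = 14, min_loop: int = 3,
                            ) -> list[HairpinCandidate]:
    """Minimal hairpin screen for unannotated genome-mapped sequences.

    For each mapped locus the +-``flank`` nt window is extracted and the
    mature sequence is folded against every same-length (+-2 nt) window in
    the opposite flank using the nearest-neighbor duplex model.  A candidate
    is kept when the best duplex reaches ``energy_threshold`` (kcal/mol) and
    pairs at least ``min_paired`` mature bases — a deliberately transparent
    stand-in for full precursor prediction, labeled as a candidate screen.
    """
    from .targets import align_duplex, duplex_energy

    out: list[HairpinCandidate] = []
    for h in sorted(set(genome_hits)):
        chrom_seq = genome.get(h.ref_id)
        if chrom_seq is None:
            warnings.warn(f"chromosome {h.ref_id} absent from genome; skipped")
            continue
        mat_plus = chrom_seq[h.position:h.position + len(h.query)]
        if len(mat_plus) < len(h.query):
            warnings.warn(f"locus {h.ref_id}:{h.position} outside genome bounds; skipped")
            continue
        start = max(0, h.position - flank)
        end = min(len(chrom_seq), h.position + len(h.query) + flank)
        window = chrom_seq[start:end]
        mat_off = h.position - start
        if h.strand == "-":
            window = revcomp(window)
            mat_off = len(window) - (mat_off + len(h.query))
        mature = window[mat_off:mat_off + len(h.query)]
        L = len(mature)
        best: tuple[float, int, int, str] | None = None   # (mfe, paired, pos, arm)
        for wlen in (L - 2, L - 1, L, L + 1, L + 2):
            for pos in range(0, len(window) - wlen + 1):
                if pos < mat_off + L + min_loop and pos + wlen > mat_off - min_loop:
                    continue   # overlaps the mature or leaves no loop
                site = window[pos:pos + wlen]
                d = align_duplex(mature, site)
                paired = sum(1 for s in d.states if s in ("WC", "GU"))
                if paired < min_paired:
                    continue
                try:
                    e = duplex_energy(mature, site, alignment=d)
                except ValueError:
                    continue
                arm = "5p" if pos > mat_off else "3p"
                cand = (e.duplex_mfe, -paired, pos, arm)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        if best is not None and best[0] <= energy_threshold:
            out.append(HairpinCandidate(
                chrom=h.ref_id, start=start, end=end, strand=h.strand,
                precursor=window, fold_energy=best[0], mature_arm=best[3],
                mature_sequence=mature))
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper().replace("U", "T")
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


def load_intervals_tsv(path: str | Path) -> list[tuple[str, int, int, str]]:
    """BED-like TSV: chrom, start, end, strand (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                chrom, s, e, strand = line.rstrip("\n").split("\t")[:4]
                out.append((chrom, int(s), int(e), strand))
    return out


def write_intervals_tsv(intervals: list[tuple[str, int, int, str]],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, strand in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\t{strand}\n")
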
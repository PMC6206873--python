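"""Seeded synthetic data for every pipeline stage, with full ground truth.

The generator emulates the study conditions of a three-library small-RNA
sequencing experiment on fish skin: a read population dominated by 22-23 nt
inserts (~74% of reads), contaminant ncRNA classes at sub-percent to
low-percent proportions, adapter-ligated reads with a small corrupted
fraction (insert-null, too-short, low-quality, N-containing), two-condition
count tables with planted fold changes, Ct matrices with a planted
stability ordering, and UTR sequences with planted target sites.

Every output is reproducible bit-for-bit from one integer seed; independent
generator streams are derived per component so modules can be regenerated
in isolation.  Every generated record carries a truth label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .annotate import ReferenceSet, revcomp
from .preprocess import RawReadSet, trim_adapter
from .refstab import CtMatrix

BASES = np.array(list("ACGT"))

#: read-length distribution shared by all insert classes; 22+23 nt = 74%,
#: matching the ~74% 22-23 nt fraction of the study's clean reads
DEFAULT_LENGTH_DIST: dict[int, float] = {
    18: 0.010, 19: 0.015, 20: 0.030, 21: 0.075, 22: 0.440, 23: 0.300,
    24: 0.070, 25: 0.030, 26: 0.015, 27: 0.008, 28: 0.004, 29: 0.002, 30: 0.001,
}

#: clean-read class proportions, shaped on the study's annotation table:
#: miRNA-dominated, with rRNA/tRNA near 1%, minor snRNA/snoRNA/scRNA,
#: intron ~2.6%, exon ~1%, and an unannotated remainder
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "miRNA": 0.80, "tRNA": 0.009, "rRNA": 0.009, "snRNA": 0.0002,
    "snoRNA": 0.0002, "scRNA": 0.0004, "repeat": 0.005, "exon": 0.010,
    "intron": 0.026, "other": 0.1402,
}

_STREAMS = {"references": 1, "library": 2, "ct": 10, "utr": 11, "counts": 12}
_CONDITIONS = ("BS", "RS", "WS")


@dataclass
class CtDesign:
    """Planted Ct model: Ct_gs = baseline_g + tissue_effect_s + noise.

    Gene baselines sit between ~17 and ~26 cycles and the per-gene noise
    SDs define the true stability ordering (two co-stable genes first).
    The shared tissue effect (SD 0.25) is a global abundance shift that
    geNorm/NormFinder cancel and BestKeeper sees as common variance.
    """

    genes: tuple[str, ...] = ("let-7a", "miR-26b", "U6", "miR-145a-5p", "miR-21",
                              "miR-92a-5p", "miR-15c", "miR-140-3p",
                              "5s_rRNA", "18s_rRNA")
    baselines: tuple[float, ...] = (17.5, 19.0, 22.0, 22.5, 23.0,
                                    23.5, 24.0, 24.5, 25.0, 25.5)
    noise_sds: tuple[float, ...] = (0.10, 0.12, 0.60, 0.70, 0.80,
                                    0.90, 1.00, 1.10, 1.20, 1.30)
    tissue_effect_sd: float = 0.25
    n_tissues: int = 15
    group_shifts: dict | None = None      # gene -> {group -> shift in cycles}
    groups: tuple[str, ...] | None = None  # per-tissue group labels


@dataclass
class SimulationConfig:
    seed: int = 0
    depth: int = 20_000
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    length_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST))
    adapter_3p: str = "TGGAATTCTCGGGTGCCAAGG"
    read_length: int = 50
    n_mirnas: int = 60
    mirna_lognorm_sigma: float = 1.5
    planted_fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    #: corrupted-read fractions (~1.7% total)
    frac_adapter_only: float = 0.005
    frac_short: float = 0.005
    frac_lowqual: float = 0.005
    frac_n: float = 0.002
    seq_error_rate: float = 0.001
    genome_length: int = 50_000
    n_novel_hairpins: int = 4
    novel_fraction_of_other: float = 0.15
    ct: CtDesign = field(default_factory=CtDesign)
    utr_length: int = 2000

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if abs(sum(self.length_dist.values()) - 1.0) > 1e-9:
            raise ValueError("length distribution must sum to 1")


@dataclass
class ReadTruth:
    fate: str        # clean | adapter_only | short | lowqual | n_bases
    klass: str       # miRNA | tRNA | ... | other | novel
    source: str      # reference id / mature name / 'random'
    insert: str


@dataclass
class GroundTruth:
    """Truth labels for generated data; components filled by each generator."""

    reads: dict[str, ReadTruth] = field(default_factory=dict)
    mirna_counts: dict[str, int] = field(default_factory=dict)
    planted_folds: dict[str, float] = field(default_factory=dict)
    site_labels: list[dict] = field(default_factory=list)
    stability_order: list[str] = field(default_factory=list)

    def expected_stats(self) -> dict:
        """Read-fate buckets as the preprocessor should report them."""
        buckets = {"raw_count": len(self.reads), "discarded_quality": 0,
                   "discarded_adapter_only": 0, "discarded_short": 0,
                   "clean_count": 0}
        hist: dict[int, int] = {}
        for t in self.reads.values():
            if t.fate == "clean":
                buckets["clean_count"] += 1
                hist[len(t.insert)] = hist.get(len(t.insert), 0) + 1
            elif t.fate == "adapter_only":
                buckets["discarded_adapter_only"] += 1
            elif t.fate == "short":
                buckets["discarded_short"] += 1
            else:  # lowqual and n_bases both land in the quality bucket
                buckets["discarded_quality"] += 1
        buckets["length_histogram"] = hist
        return buckets


def _rng(config: SimulationConfig, stream: str, offset: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stream] + offset])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


# ---------------------------------------------------------------------------
# References and toy genome
# ---------------------------------------------------------------------------

@dataclass
class ReferenceBundle:
    ncrna: dict[str, ReferenceSet]           # subtype -> sequence reference set
    known_mirnas: dict[str, str]             # mature name -> sequence
    genome: dict[str, str]
    intervals: dict[str, list[tuple[str, int, int, str]]]   # repeat/exon/intron
    hairpins: list[tuple[str, int, int, str]]  # planted novel hairpin loci
    novel_matures: dict[str, str]
    mirna_by_length: dict[int, list[str]] = field(default_factory=dict)

    def reference_sets(self) -> dict[str, ReferenceSet]:
        """All sequence tiers keyed by hierarchy category, plus the genome."""
        sets = dict(self.ncrna)
        sets["known_miRNA"] = ReferenceSet("known_miRNA", sequences=dict(self.known_mirnas),
                                           subtype="miRNA")
        sets["genome"] = ReferenceSet("genome", sequences=dict(self.genome))
        return sets


_NCRNA_DESIGN = {
    # subtype: (tier category, n sequences, length)
    "rRNA": ("genbank_ncRNA", 5, 120),
    "tRNA": ("genbank_ncRNA", 8, 75),
    "snRNA": ("rfam_ncRNA", 5, 100),
    "snoRNA": ("rfam_ncRNA", 5, 90),
    "scRNA": ("rfam_ncRNA", 3, 110),
}


def simulate_references(config: SimulationConfig) -> ReferenceBundle:
    """Random but seed-reproducible reference FASTA sets plus a toy genome.

    The genome embeds exon/intron/repeat intervals and hairpin loci for
    novel-miRNA screening (mature + loop + reverse complement of the
    mature, so each planted arm folds well below the screen threshold).
    """
    rng = _rng(config, "references")
    ncrna: dict[str, ReferenceSet] = {}
    for subtype, (category, n, length) in _NCRNA_DESIGN.items():
        seqs = {f"{subtype}_{i + 1}": _random_seq(rng, length) for i in range(n)}
        ncrna[subtype] = ReferenceSet(category, sequences=seqs, subtype=subtype)

    lengths = sorted(config.length_dist)
    probs = np.array([config.length_dist[l] for l in lengths])
    known: dict[str, str] = {}
    by_length: dict[int, list[str]] = {l: [] for l in lengths}
    arms = ("5p", "3p")
    # guarantee a few matures per length bucket so read lengths can always
    # be drawn from the configured distribution
    per_bucket = max(3, config.n_mirnas // len(lengths))
    idx = 0
    for l in lengths:
        for _ in range(per_bucket):
            idx += 1
            prefix = "ccr" if idx % 3 else "dre"
            name = f"{prefix}-miR-{100 + idx}-{arms[idx % 2]}"
            known[name] = _random_seq(rng, l)
            by_length[l].append(name)

    genome_seq = list(_random_seq(rng, config.genome_length))
    intervals: dict[str, list[tuple[str, int, int, str]]] = {
        "repeat": [], "exon": [], "intron": []}
    cursor = 500
    motif = _random_seq(rng, 200)
    for i in range(8):                                   # repeats share a motif
        genome_seq[cursor:cursor + 200] = list(motif)
        intervals["repeat"].append(("chr1", cursor, cursor + 200, "+"))
        cursor += 1200
    for i in range(10):
        intervals["exon"].append(("chr1", cursor, cursor + 300, "+"))
        cursor += 800
    for i in range(10):
        intervals["intron"].append(("chr1", cursor, cursor + 500, "+"))
        cursor += 1000
    hairpins: list[tuple[str, int, int, str]] = []
    novel: dict[str, str] = {}
    for i in range(config.n_novel_hairpins):
        mature = _random_seq(rng, 22)
        loop = _random_seq(rng, 8)
        hp = mature + loop + revcomp(mature)
        genome_seq[cursor:cursor + len(hp)] = list(hp)
        hairpins.append(("chr1", cursor, cursor + len(hp), "+"))
        novel[f"novel-{i + 1}"] = mature
        cursor += 900
    if cursor > config.genome_length:
        raise ValueError("genome too short for the configured features")
    genome = {"chr1": "".join(genome_seq[:config.genome_length])}
    return ReferenceBundle(ncrna=ncrna, known_mirnas=known, genome=genome,
                           intervals=intervals, hairpins=hairpins,
                           novel_matures=novel, mirna_by_length=by_length)


# ---------------------------------------------------------------------------
# Read library simulation
# ---------------------------------------------------------------------------

def _mirna_abundance(config: SimulationConfig, bundle: ReferenceBundle,
                     condition: str) -> dict[str, float]:
    """Log-normal baseline abundances (sigma ~1.5 mimics the study's dynamic
    range) scaled by any planted fold changes for the condition."""
    rng = _rng(config, "counts")        # shared across conditions: same baseline
    names = sorted(bundle.known_mirnas)
    weights = dict(zip(names, np.exp(rng.normal(0.0, config.mirna_lognorm_sigma,
                                                size=len(names)))))
    for name, fold in config.planted_fold_changes.get(condition, {}).items():
        if name in weights:
            weights[name] *= fold
    return weights


def _phred_string(quals: Iterable[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def simulate_library(config: SimulationConfig, condition: str,
                     bundle: ReferenceBundle | None = None,
                     ) -> tuple[RawReadSet, GroundTruth]:
    """Adapter-ligated single-end reads for one condition, with truth labels.

    Clean reads draw a class from the configured proportions and an insert
    length from the shared length distribution; a small corrupted fraction
    exercises the insert-null / short / low-quality / N filters.  Each
    read's realized trimming fate is validated at construction so the
    truth's fate buckets are exact.
    """
    if bundle is None:
        bundle = simulate_references(config)
    if condition in _CONDITIONS:
        cond_idx = _CONDITIONS.index(condition)
    else:  # stable, interpreter-independent stream id for custom labels
        cond_idx = 3 + sum(condition.encode()) % 997
    rng = _rng(config, "library", offset=cond_idx)
    truth = GroundTruth()
    if config.depth == 0:
        return RawReadSet(reads=[], adapter_3p=config.adapter_3p), truth

    classes = sorted(config.class_proportions)
    class_p = np.array([config.class_proportions[c] for c in classes])
    lengths = sorted(config.length_dist)
    length_p = np.array([config.length_dist[l] for l in lengths])
    abundance = _mirna_abundance(config, bundle, condition)
    truth.planted_folds = dict(config.planted_fold_changes.get(condition, {}))
    bucket_w = {l: np.array([abundance[n] for n in bundle.mirna_by_length[l]])
                for l in lengths if bundle.mirna_by_length.get(l)}
    frac_clean = 1.0 - (config.frac_adapter_only + config.frac_short
                        + config.frac_lowqual + config.frac_n)
    fates = rng.choice(
        ["clean", "adapter_only", "short", "lowqual", "n_bases"], size=config.depth,
        p=[frac_clean, config.frac_adapter_only, config.frac_short,
           config.frac_lowqual, config.frac_n])
    novel_names = sorted(bundle.novel_matures)
    reads: list[tuple[str, str, list[int]]] = []

    def draw_insert(length: int) -> tuple[str, str, str]:
        klass = rng.choice(classes, p=class_p)
        if klass == "miRNA":
            names = bundle.mirna_by_length[length]
            w = bucket_w[length]
            name = names[rng.choice(len(names), p=w / w.sum())]
            return klass, name, bundle.known_mirnas[name]
        if klass in bundle.ncrna:
            ids = sorted(bundle.ncrna[klass].sequences)
            rid = ids[rng.integers(len(ids))]
            src = bundle.ncrna[klass].sequences[rid]
            off = rng.integers(0, len(src) - length + 1)
            return klass, rid, src[off:off + length]
        if klass in ("repeat", "exon", "intron"):
            ivs = bundle.intervals[klass]
            chrom, s, e, _ = ivs[rng.integers(len(ivs))]
            off = rng.integers(s, e - length + 1)
            return klass, f"{chrom}:{off}", bundle.genome[chrom][off:off + length]
        # other: mostly random (unannotated), partly planted novel-hairpin arms
        if novel_names and rng.random() < config.novel_fraction_of_other:
            name = novel_names[rng.integers(len(novel_names))]
            return "novel", name, bundle.novel_matures[name]
        return "other", "random", _random_seq(rng, length)

    def with_errors(insert: str) -> str:
        if config.seq_error_rate <= 0:
            return insert
        out = list(insert)
        for i in range(len(out)):
            if rng.random() < config.seq_error_rate:
                out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
        return "".join(out)

    adapter = config.adapter_3p
    for ridx, fate in enumerate(fates):
        rid = f"{condition}_read{ridx}"
        length = int(lengths[rng.choice(len(lengths), p=length_p)])
        if fate == "clean":
            for _attempt in range(40):
                klass, source, insert0 = draw_insert(length)
                insert = with_errors(insert0)
                if trim_adapter(insert + adapter, adapter) == insert:
                    break
                klass, source = "other", "random"   # pragma: no cover
            seq = (insert + adapter)[:config.read_length]
            qual = list(rng.integers(30, 41, size=len(seq)))
            truth.reads[rid] = ReadTruth(fate, str(klass), str(source), insert)
            if klass in ("miRNA", "novel"):
                truth.mirna_counts[source] = truth.mirna_counts.get(source, 0) + 1
        elif fate == "adapter_only":
            seq = (adapter + _random_seq(rng, config.read_length))[:config.read_length]
            qual = list(rng.integers(30, 41, size=len(seq)))
            truth.reads[rid] = ReadTruth(fate, "artifact", "adapter", "")
        elif fate == "short":
            for _attempt in range(20):
                insert = _random_seq(rng, int(rng.integers(8, 18)))
                if trim_adapter(insert + adapter, adapter) == insert:
                    break
            seq = (insert + adapter)[:config.read_length]
            qual = list(rng.integers(30, 41, size=len(seq)))
            truth.reads[rid] = ReadTruth(fate, "artifact", "short", insert)
        elif fate == "lowqual":
            seq = _random_seq(rng, config.read_length)
            qual = list(rng.integers(2, 16, size=len(seq)))
            truth.reads[rid] = ReadTruth(fate, "artifact", "lowqual", "")
        else:  # n_bases: good quality, N inside the insert
            for _attempt in range(20):
                insert = list(_random_seq(rng, length))
                insert[rng.integers(2, length - 2)] = "N"
                insert = "".join(insert)
                if trim_adapter(insert + adapter, adapter) == insert:
                    break
            seq = (insert + adapter)[:config.read_length]
            qual = list(rng.integers(30, 41, size=len(seq)))
            truth.reads[rid] = ReadTruth(fate, "artifact", "n_bases", insert)
        reads.append((rid, seq, [int(q) for q in qual]))
    return RawReadSet(reads=reads, adapter_3p=adapter), truth


def write_fastq(raw: RawReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in raw.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{_phred_string(qual)}\n")


# ---------------------------------------------------------------------------
# Two-library count tables with planted fold changes
# ---------------------------------------------------------------------------

def simulate_de_counts(seed: int, n_mirnas: int = 200, depth: int = 1_000_000,
                       n_planted: int = 20, fold: float = 4.0,
                       sigma: float = 1.5,
                       ) -> tuple[dict[str, int], dict[str, int], int, int,
                                  dict[str, float]]:
    """Two multinomial count libraries with planted fold changes.

    Returns (counts1, counts2, N1, N2, planted) where ``planted`` maps the
    affected miRNA names to their true fold (half up, half down in
    library 2).  Unplanted miRNAs share identical relative abundances, so
    they are true nulls of the exact test.
    """
    rng = np.random.default_rng([seed, 101])
    names = [f"mir{i:03d}" for i in range(n_mirnas)]
    base = np.exp(rng.normal(0.0, sigma, size=n_mirnas))
    planted_idx = rng.choice(n_mirnas, size=n_planted, replace=False)
    folds = np.ones(n_mirnas)
    for j, i in enumerate(planted_idx):
        folds[i] = fold if j % 2 == 0 else 1.0 / fold
    w1 = base / base.sum()
    w2 = (base * folds) / (base * folds).sum()
    c1 = rng.multinomial(depth, w1)
    c2 = rng.multinomial(depth, w2)
    planted = {names[i]: float(folds[i]) for i in planted_idx}
    return (dict(zip(names, map(int, c1))), dict(zip(names, map(int, c2))),
            depth, depth, planted)


# ---------------------------------------------------------------------------
# Ct matrices
# ---------------------------------------------------------------------------

def simulate_ct(config: SimulationConfig) -> tuple[CtMatrix, list[str]]:
    """Ct matrix with a planted stability ordering.

    Returns the matrix and the true stability order (most stable first,
    by ascending per-gene noise SD).  Generated values must stay within
    the [15, 32] cycle range seen in real reference-gene panels; values
    outside it raise an error rather than being clipped.
    """
    d = config.ct
    if len(d.baselines) != len(d.genes) or len(d.noise_sds) != len(d.genes):
        raise ValueError("CtDesign gene/baseline/noise lengths differ")
    rng = _rng(config, "ct")
    samples = [f"T{i + 1}" for i in range(d.n_tissues)]
    tissue_effect = rng.normal(0.0, d.tissue_effect_sd, size=d.n_tissues)
    values = np.zeros((len(d.genes), d.n_tissues))
    for gi, gene in enumerate(d.genes):
        noise = rng.normal(0.0, d.noise_sds[gi], size=d.n_tissues)
        values[gi] = d.baselines[gi] + tissue_effect + noise
        if d.group_shifts and gene in d.group_shifts and d.groups:
            for si, grp in enumerate(d.groups):
                values[gi, si] += d.group_shifts[gene].get(grp, 0.0)
    if values.min() < 15.0 or values.max() > 32.0:
        raise ValueError("generated Ct values fall outside [15, 32]")
    df = pd.DataFrame(values, index=list(d.genes), columns=samples)
    groups = dict(zip(samples, d.groups)) if d.groups else None
    order = [g for _, g in sorted(zip(d.noise_sds, d.genes))]
    return CtMatrix(values=df, groups=groups), order


# ---------------------------------------------------------------------------
# Planted UTR target sites
# ---------------------------------------------------------------------------

_WOBBLE = {"G": "T", "T": "G"}
_COMPL = {"A": "T", "T": "A", "G": "C", "C": "G"}


class InfeasibleRule(RuntimeError):
    """The guide's base composition cannot host the requested violation."""


def _site_with_states(mirna: str, changes: dict[int, str]) -> str:
    """Perfect-complement site with planted states at 1-based guide positions.

    ``changes[i]`` is 'GU' (wobble, guide base must be G or T) or a concrete
    replacement base creating a full mismatch.
    """
    L = len(mirna)
    site = [_COMPL[b] for b in reversed(mirna)]     # 5'->3' perfect site
    for pos, kind in changes.items():
        m = mirna[pos - 1]
        j = L - pos                                  # site index facing pos
        if kind == "GU":
            if m not in _WOBBLE:
                raise InfeasibleRule(f"no wobble partner for {m} at {pos}")
            site[j] = _WOBBLE[m]
        else:
            site[j] = kind
    return "".join(site)


def _mismatch_base(mirna: str, pos: int, rng: np.random.Generator) -> str:
    """A site base that neither Watson-Crick- nor wobble-pairs guide[pos]."""
    m = mirna[pos - 1]
    banned = {_COMPL[m], _WOBBLE.get(m, "")}
    options = [b for b in "ACGT" if b not in banned]
    return options[rng.integers(len(options))]


def _gu_capable(mirna: str, positions: Iterable[int]) -> list[int]:
    return [p for p in positions if mirna[p - 1] in _WOBBLE]


def _nonadjacent(cands: list[int], n: int) -> list[int]:
    out: list[int] = []
    for p in cands:
        if len(out) == n:
            break
        if all(abs(p - q) > 1 for q in out):
            out.append(p)
    return out


def violating_site(mirna: str, rule: str, rng: np.random.Generator) -> str:
    """A site that fails exactly one of the six rules for this guide.

    Patterns are analytic (e.g. rule 1 via nine G:U wobbles, which exceed
    the weighted-mismatch cap while costing little energy) and verified
    against the rule engine before being returned; guides whose base
    composition cannot host a pattern raise :class:`InfeasibleRule`.
    """
    from .targets import evaluate_site

    L = len(mirna)
    candidates: list[dict[int, str]] = []
    if rule == "r1":        # >4 weighted mismatches (nine wobbles), all else passing
        chosen: list[int] = []
        for p in range(1, L + 1):
            if len(chosen) == 9:
                break
            if p in (10, 11) or mirna[p - 1] not in _WOBBLE:
                continue
            seed_n = sum(1 for q in chosen if q <= 12)
            if p <= 13:      # keep the seed region non-adjacent (rules 3/5)
                if seed_n >= 5 or (chosen and p - chosen[-1] == 1):
                    continue
            elif len(chosen) >= 2 and chosen[-1] == p - 1 and chosen[-2] == p - 2:
                continue     # never a run of three (rule 2)
            chosen.append(p)
        if len(chosen) < 9:
            raise InfeasibleRule("not enough G/U-capable positions for r1")
        candidates.append({p: "GU" for p in chosen})
    elif rule == "r2":      # a run of three non-paired states in the 3' half
        for start in range(14, L - 1):
            candidates.append({p: ("GU" if mirna[p - 1] in _WOBBLE
                                   else _mismatch_base(mirna, p, rng))
                               for p in (start, start + 1, start + 2)})
    elif rule == "r3":      # two adjacent non-paired states within 2-12
        for start in (5, 3, 7, 6, 4, 8):
            candidates.append({p: ("GU" if mirna[p - 1] in _WOBBLE
                                   else _mismatch_base(mirna, p, rng))
                               for p in (start, start + 1)})
    elif rule == "r4":      # mismatch at the slicing site
        for pos in (10, 11):
            candidates.append({pos: _mismatch_base(mirna, pos, rng)})
    elif rule == "r5":      # >2.5 weighted mismatches within 1-12
        # full mismatches sit at position 1 (and 12) where they break the
        # fewest stacks, keeping rule 6 comfortably satisfied
        gus4 = _nonadjacent(_gu_capable(mirna, [3, 5, 7, 9, 12, 4, 6, 8]), 4)
        if len(gus4) >= 4:
            ch = {p: "GU" for p in gus4}
            ch[1] = _mismatch_base(mirna, 1, rng)
            candidates.append(ch)
        gus2 = _nonadjacent(_gu_capable(mirna, [3, 5, 7, 9, 4, 6, 8]), 2)
        if len(gus2) >= 2:
            ch = {p: "GU" for p in gus2}
            ch[1] = _mismatch_base(mirna, 1, rng)
            ch[12] = _mismatch_base(mirna, 12, rng)
            candidates.append(ch)
        candidates.append({1: _mismatch_base(mirna, 1, rng),
                           6: _mismatch_base(mirna, 6, rng),
                           12: _mismatch_base(mirna, 12, rng)})
    elif rule == "r6":      # energy-only failure: isolated 3' mismatches
        slots = [p for p in range(14, L) if p % 2 == 0]
        for n_mm in (3, 4):
            if len(slots) >= n_mm:
                candidates.append({p: _mismatch_base(mirna, p, rng)
                                   for p in slots[:n_mm]})
    else:
        raise ValueError(f"unknown rule {rule!r}")

    failed = {"r1": "r1", "r2": "r2", "r3": "r3", "r4": "r4",
              "r5": "r5", "r6": "r6"}[rule]
    for changes in candidates:
        site = _site_with_states(mirna, changes)
        _, v, _ = evaluate_site(mirna, site)
        flags = {"r1": v.r1, "r2": v.r2, "r3": v.r3, "r4": v.r4,
                 "r5": v.r5, "r6": bool(v.r6)}
        if not flags[failed] and all(ok for r, ok in flags.items() if r != failed):
            return site
    raise InfeasibleRule(f"could not build a site violating exactly {rule}")


def plant_utr_sites(config: SimulationConfig, mirnas: dict[str, str],
                    ) -> tuple[dict[str, str], GroundTruth]:
    """Transcripts with (a) a perfect site, (b) a single-rule-violating
    site, and (c) no site, per miRNA, with per-site truth labels.

    Each miRNA is assigned one violation rule from a rotating schedule;
    rules the guide's composition cannot host fall back to the always
    feasible slicing-site rule (r4).  Labels record the rule actually
    planted.
    """
    from .targets import perfect_complement

    rng = _rng(config, "utr")
    truth = GroundTruth()
    transcripts: dict[str, str] = {}
    schedule = ("r4", "r2", "r3", "r5", "r6", "r1")
    for idx, (name, seq) in enumerate(sorted(mirnas.items())):
        L = len(seq)
        pos = int(rng.integers(200, config.utr_length - L - 200))

        tx = _random_seq(rng, config.utr_length)
        perfect = perfect_complement(seq)
        tx = tx[:pos] + perfect + tx[pos + L:]
        tid = f"{name}_perfect"
        transcripts[tid] = tx
        truth.site_labels.append({"transcript": tid, "mirna": name,
                                  "start": pos, "end": pos + L, "kind": "perfect"})

        rule = schedule[idx % len(schedule)]
        try:
            bad = violating_site(seq, rule, rng)
        except InfeasibleRule:
            rule = "r4"
            bad = violating_site(seq, rule, rng)
        tx2 = _random_seq(rng, config.utr_length)
        tx2 = tx2[:pos] + bad + tx2[pos + len(bad):]
        tid2 = f"{name}_viol_{rule}"
        transcripts[tid2] = tx2
        truth.site_labels.append({"transcript": tid2, "mirna": name,
                                  "start": pos, "end": pos + len(bad),
                                  "kind": f"violates_{rule}"})

        tid3 = f"{name}_none"
        transcripts[tid3] = _random_seq(rng, config.utr_length)
        truth.site_labels.append({"transcript": tid3, "mirna": name,
                                  "start": -1, "end": -1, "kind": "none"})
    return transcripts, truth
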
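"""Rule-based miRNA target-site scoring and UTR scanning.

A candidate site is scored as a gapless antiparallel duplex between the
miRNA guide (5'->3') and the site (read 3'->5'), with G:U wobble pairs
weighted as half a mismatch.  Six rules decide acceptance:

1. weighted mismatches <= 4 over the whole duplex (G:U = 0.5);
2. no more than two adjacent mismatches anywhere in the duplex;
3. no adjacent mismatches in guide positions 2-12;
4. no mismatches at guide positions 10-11 (the slicing site);
5. weighted mismatches <= 2.5 in positions 1-12;
6. duplex free energy >= 75% of the energy of the guide bound to its
   perfect complement.

Energies come from a bundled nearest-neighbor stacking table; broken pairs
contribute nothing and interrupt stacks.  Positions are 1-based from the
guide 5' end throughout.  By default any non-Watson-Crick state (including
G:U) counts toward the adjacency rules 2-4; ``strict_gu=False`` relaxes
rules 2-3 to full mismatches only.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Sequence

from .preprocess import _check_alphabet

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}
_WEIGHT = {"WC": 0.0, "GU": 0.5, "MM": 1.0, "UN": 1.0}
_COMPL = {"A": "T", "T": "A", "G": "C", "C": "G"}


# ---------------------------------------------------------------------------
# Bundled energy parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyParams:
    stacks: dict
    init: float
    gu_penalty: float
    version: str = "nn_stacks_v1"


@lru_cache(maxsize=1)
def load_energy_params() -> EnergyParams:
    stacks: dict[str, float] = {}
    init = gu_penalty = 0.0
    text = resources.files("koisrna.data").joinpath("nn_stacks_v1.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        kind, key, value = line.split("\t")
        if kind == "param":
            if key == "init":
                init = float(value)
            elif key == "gu_penalty":
                gu_penalty = float(value)
        elif kind == "stack":
            stacks[key] = float(value)
    if len(stacks) != 16:
        raise RuntimeError("stack table must define all 16 dinucleotides")
    return EnergyParams(stacks=stacks, init=init, gu_penalty=gu_penalty)


# ---------------------------------------------------------------------------
# Duplex alignment
# ---------------------------------------------------------------------------

@dataclass
class DuplexAlignment:
    mirna: str
    site: str
    offset: int                 # register shift of guide 5' end on reversed site
    states: list[str]           # per guide position: WC | GU | MM | UN
    weighted_mismatch_score: float

    def recount_score(self) -> float:
        return sum(_WEIGHT[s] for s in self.states)


def _classify(m: str, s: str | None) -> str:
    if s is None:
        return "UN"
    if (m, s) in _WC:
        return "WC"
    if (m, s) in _GU:
        return "GU"
    return "MM"


def align_duplex(mirna: str, site: str) -> DuplexAlignment:
    """Gapless antiparallel alignment of a guide against a candidate site.

    The guide's 5' end faces the site's 3' end.  When the lengths differ
    (at most 3 nt) every bulge-free register shift is tried and the one
    minimizing the weighted mismatch score wins; ties prefer the register
    closest to the unshifted one.
    """
    m = _check_alphabet(mirna, "mirna")
    s = _check_alphabet(site, "site")
    if "N" in m or "N" in s:
        raise ValueError("sequences with N cannot be duplex-aligned")
    if abs(len(s) - len(m)) > 3:
        raise ValueError("site and miRNA lengths differ by more than 3 nt")
    rs = s[::-1]                      # site 3'->5', indexed parallel to guide
    d = len(s) - len(m)
    offsets = sorted(set(range(min(0, d), max(0, d) + 1)) | {0},
                     key=lambda k: (abs(k), k))
    best: DuplexAlignment | None = None
    for k in offsets:
        states = []
        for i in range(len(m)):
            j = i + k
            states.append(_classify(m[i], rs[j] if 0 <= j < len(rs) else None))
        score = sum(_WEIGHT[x] for x in states)
        if best is None or score < best.weighted_mismatch_score:
            best = DuplexAlignment(m, s, k, states, score)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------

@dataclass
class RuleVerdict:
    r1: bool
    r2: bool
    r3: bool
    r4: bool
    r5: bool
    r6: bool | None = None      # None until an energy evaluation is attached

    @property
    def overall(self) -> bool:
        return all((self.r1, self.r2, self.r3, self.r4, self.r5, bool(self.r6)))

    def flags(self) -> str:
        return "".join("P" if f else "F"
                       for f in (self.r1, self.r2, self.r3, self.r4, self.r5,
                                 bool(self.r6)))


def evaluate_rules(d: DuplexAlignment, strict_gu: bool = True) -> RuleVerdict:
    """Combinatorial rules 1-5 on an aligned duplex (rule 6 needs energy).

    ``strict_gu`` controls whether a G:U counts as a non-paired state for
    the adjacency rules 2-3 (rule 4 always treats G:U as a violation: a
    wobble carries weight 0.5 > 0, so positions 10-11 must be Watson-Crick).
    """
    nonpair = {"MM", "UN"} if not strict_gu else {"MM", "UN", "GU"}
    bad = [s in nonpair for s in d.states]
    L = len(d.states)

    r1 = d.weighted_mismatch_score <= 4.0
    run = best_run = 0
    for b in bad:
        run = run + 1 if b else 0
        best_run = max(best_run, run)
    r2 = best_run <= 2
    r3 = not any(bad[i] and bad[i + 1] for i in range(1, min(11, L - 1)))
    r4 = L >= 11 and d.states[9] == "WC" and d.states[10] == "WC"
    r5 = sum(_WEIGHT[s] for s in d.states[:12]) <= 2.5
    return RuleVerdict(r1, r2, r3, r4, r5)


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------

@dataclass
class EnergyResult:
    duplex_mfe: float
    perfect_mfe: float

    @property
    def ratio(self) -> float:
        # clamped at 1: the duplex can never beat the perfect complement,
        # but summation order can leave a one-ulp excess
        return min(1.0, self.duplex_mfe / self.perfect_mfe)


def perfect_complement(mirna: str) -> str:
    """The site sequence (5'->3') a guide binds with every pair Watson-Crick."""
    return "".join(_COMPL[b] for b in reversed(mirna))


def duplex_energy(mirna: str, site: str,
                  alignment: DuplexAlignment | None = None,
                  params: EnergyParams | None = None) -> EnergyResult:
    """Nearest-neighbor stacking energy of the duplex and of the perfect one.

    Consecutive paired guide positions contribute the stack energy of the
    guide dinucleotide (plus the G:U penalty per wobble in the stack);
    broken pairs contribute nothing and interrupt stacking.  The duplex
    energy is capped at 0 (an unstable arrangement is reported as
    non-binding rather than positive), so the ratio lies in [0, 1].
    """
    p = params or load_energy_params()
    d = alignment or align_duplex(mirna, site)
    paired = [s in ("WC", "GU") for s in d.states]
    if not any(paired):
        raise ValueError("duplex has no paired positions; energy undefined")
    e = p.init
    for i in range(len(d.states) - 1):
        if paired[i] and paired[i + 1]:
            n_gu = (d.states[i] == "GU") + (d.states[i + 1] == "GU")
            e += p.stacks[d.mirna[i:i + 2]] + p.gu_penalty * n_gu
    perfect = p.init + sum(p.stacks[d.mirna[i:i + 2]]
                           for i in range(len(d.mirna) - 1))
    return EnergyResult(duplex_mfe=min(0.0, e), perfect_mfe=perfect)


# ---------------------------------------------------------------------------
# UTR scanning
# ---------------------------------------------------------------------------

@dataclass
class TargetPrediction:
    mirna_name: str
    transcript_id: str
    start: int                   # 0-based half-open on the transcript
    end: int
    alignment: DuplexAlignment
    verdict: RuleVerdict
    energy: EnergyResult


def evaluate_site(mirna: str, site: str, strict_gu: bool = True,
                  min_ratio: float = 0.75,
                  params: EnergyParams | None = None,
                  ) -> tuple[DuplexAlignment, RuleVerdict, EnergyResult | None]:
    """Align one site and run all six rules."""
    d = align_duplex(mirna, site)
    v = evaluate_rules(d, strict_gu=strict_gu)
    energy = None
    try:
        energy = duplex_energy(mirna, site, alignment=d, params=params)
        v.r6 = energy.ratio >= min_ratio
    except ValueError:
        v.r6 = False
    return d, v, energy


def scan_utr(mirna: str, transcript: str, mirna_name: str = "mirna",
             transcript_id: str = "tx", step: int = 1, strict_gu: bool = True,
             min_ratio: float = 0.75, params: EnergyParams | None = None,
             ) -> list[TargetPrediction]:
    """Slide windows of guide length +-2 over a transcript; emit passing sites.

    Overlapping passing windows are merged, keeping the best site (lowest
    weighted mismatch score, then lowest duplex energy, then leftmost).
    """
    m = _check_alphabet(mirna, "mirna")
    tx = _check_alphabet(transcript, "transcript")
    L = len(m)
    raw: list[TargetPrediction] = []
    for wlen in range(L - 2, L + 3):
        if wlen < 1 or wlen > len(tx):
            continue
        for start in range(0, len(tx) - wlen + 1, step):
            site = tx[start:start + wlen]
            if "N" in site:
                continue
            d = align_duplex(m, site)
            v = evaluate_rules(d, strict_gu=strict_gu)
            if not (v.r1 and v.r2 and v.r3 and v.r4 and v.r5):
                continue
            try:
                e = duplex_energy(m, site, alignment=d, params=params)
            except ValueError:
                continue
            v.r6 = e.ratio >= min_ratio
            if v.overall:
                raw.append(TargetPrediction(mirna_name, transcript_id, start,
                                            start + wlen, d, v, e))
    return merge_overlapping(raw)


def merge_overlapping(preds: list[TargetPrediction]) -> list[TargetPrediction]:
    """Collapse transitively overlapping predictions to their best member."""
    preds = sorted(preds, key=lambda p: (p.start, p.end))
    merged: list[TargetPrediction] = []
    cluster: list[TargetPrediction] = []
    cluster_end = -1
    def flush():
        if cluster:
            merged.append(min(cluster, key=lambda p: (
                p.alignment.weighted_mismatch_score, p.energy.duplex_mfe,
                abs(len(p.alignment.site) - len(p.alignment.mirna)), p.start)))
    for p in preds:
        if cluster and p.start >= cluster_end:
            flush()
            cluster = []
            cluster_end = -1
        cluster.append(p)
        cluster_end = max(cluster_end, p.end)
    flush()
    return merged


def write_predictions_tsv(preds: Sequence[TargetPrediction], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\ttranscript\tstart\tend\tscore\tmfe\tratio\trules\n")
        for p in preds:
            fh.write(f"{p.mirna_name}\t{p.transcript_id}\t{p.start}\t{p.end}\t"
                     f"{p.alignment.weighted_mismatch_score:.1f}\t"
                     f"{p.energy.duplex_mfe:.2f}\t{p.energy.ratio:.4f}\t"
                     f"{p.verdict.flags()}\n")
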
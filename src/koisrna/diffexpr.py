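"""TPM normalization and the exact two-library test for miRNA counts.

With one pooled library per condition there are no replicates, so
differential expression between two libraries is assessed with the exact
test of Audic & Claverie: conditional on observing ``x`` reads of a miRNA
in a library of ``N1`` clean reads, the probability of observing ``y``
reads in a second library of ``N2`` clean reads is

    p(x|y) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1))

which, as a function of y, is a negative-binomial mass function — it sums
to one over y >= 0.  The lower tail C sums p(x|y') for y' <= y; the upper
tail D is taken as the complement 1 - C(y-1) so the infinite sum is never
evaluated directly.  Everything is computed in log space via log-gamma, so
counts far beyond the ~170! overflow limit of the printed factorial form
are handled exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountPair:
    """Counts of one miRNA in two libraries with their clean-read totals."""

    x: int
    y: int
    N1: int
    N2: int

    def __post_init__(self) -> None:
        if min(self.x, self.y, self.N1, self.N2) < 0:
            raise ValueError("counts and totals must be non-negative")
        if self.N1 < self.x or self.N2 < self.y:
            raise ValueError("library total smaller than feature count")


@dataclass
class DETestResult:
    name: str
    tpm1: float
    tpm2: float
    log2fc: float
    p_lower: float       # C(y' <= y | x)
    p_upper: float       # D(y' >= y | x)
    p_two_sided: float
    q: float = math.nan
    call: str = "ns"


# ---------------------------------------------------------------------------
# Normalization and fold change
# ---------------------------------------------------------------------------

def tpm(count: int, total_clean: int) -> float:
    """Transcripts per million: (count / total clean reads) * 1e6."""
    if total_clean <= 0:
        raise ValueError("total_clean must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / total_clean * 1_000_000


def fold_change(tpm_treatment: float, tpm_control: float,
                pseudo: float = 0.0) -> float:
    """log2(treatment/control); positive means up-regulated in treatment.

    ``pseudo`` (a TPM offset) is added to both sides to keep the ratio
    finite when one side is zero; display code uses a count+0.5 pseudo-TPM,
    the exact test itself needs no such device.
    """
    a, b = tpm_treatment + pseudo, tpm_control + pseudo
    if a <= 0 or b <= 0:
        raise ValueError("TPM values must be positive (use a pseudo offset)")
    return math.log2(a / b)


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------

def log_p_x_given_y(x: int, y: int | np.ndarray, N1: int, N2: int):
    """log p(x|y) via log-gamma; overflow-safe for arbitrarily large counts."""
    r = N2 / N1
    y = np.asarray(y)
    return (y * math.log(r) + gammaln(x + y + 1) - gammaln(x + 1) - gammaln(y + 1)
            - (x + y + 1) * math.log1p(r))


def exact_test_tails(pair: CountPair) -> tuple[float, float]:
    """Lower tail C = sum_{y'<=y} p(x|y') and upper tail D = 1 - C(y-1)."""
    ys = np.arange(pair.y + 1)
    probs = np.exp(log_p_x_given_y(pair.x, ys, pair.N1, pair.N2))
    c = float(min(1.0, probs.sum()))
    d = float(min(1.0, max(0.0, 1.0 - probs[:-1].sum())))
    return c, d


def exact_test(pair: CountPair, name: str = "", tpm_pair: tuple[float, float] | None = None,
               fc_pseudo_count: float = 0.5) -> DETestResult:
    """Full test result for one miRNA: TPMs, log2 fold change, tails, p.

    The two-sided p combines the tails as min(1, 2*min(C, D)).  Library 2
    is the treatment in the fold-change orientation (positive log2fc means
    higher in library 2).
    """
    c, d = exact_test_tails(pair)
    p2 = min(1.0, 2.0 * min(c, d))
    if tpm_pair is None:
        tpm1, tpm2 = tpm(pair.x, pair.N1), tpm(pair.y, pair.N2)
    else:
        tpm1, tpm2 = tpm_pair
    if pair.x > 0 and pair.y > 0:
        lfc = fold_change(tpm2, tpm1)
    else:  # pseudo-TPM (count + 0.5) for display when a side is zero
        lfc = math.log2(((pair.y + fc_pseudo_count) / pair.N2)
                        / ((pair.x + fc_pseudo_count) / pair.N1))
    return DETestResult(name=name, tpm1=tpm1, tpm2=tpm2, log2fc=lfc,
                        p_lower=c, p_upper=d, p_two_sided=p2)


# ---------------------------------------------------------------------------
# Multiple testing and DEM calling
# ---------------------------------------------------------------------------

def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values within one comparison."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_dems(results: list[DETestResult], fc_threshold: float = 1.0,
              alpha: float = 0.05, mode: str = "p") -> list[DETestResult]:
    """Annotate results with up/down/ns calls and q-values.

    Default criterion is the two-fold / p < 0.05 rule; ``mode='q'`` switches
    the significance side to BH q <= alpha (the stricter variant used for
    the genome-wide screens, typically alpha = 0.001).
    """
    if mode not in ("p", "q"):
        raise ValueError("mode must be 'p' or 'q'")
    qs = adjust_fdr([r.p_two_sided for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
        sig = (r.p_two_sided < alpha) if mode == "p" else (r.q <= alpha)
        if sig and r.log2fc >= fc_threshold:
            r.call = "up"
        elif sig and r.log2fc <= -fc_threshold:
            r.call = "down"
        else:
            r.call = "ns"
    return results


def exact_test_table(counts1: dict[str, int], counts2: dict[str, int],
                     N1: int, N2: int, fc_threshold: float = 1.0,
                     alpha: float = 0.05, mode: str = "p") -> list[DETestResult]:
    """Run the exact test over the union of features of two libraries."""
    names = sorted(set(counts1) | set(counts2))
    results = [exact_test(CountPair(counts1.get(n, 0), counts2.get(n, 0), N1, N2), n)
               for n in names]
    return call_dems(results, fc_threshold, alpha, mode)


def overlap_dems(dem_lists: dict[str, Iterable[str]]) -> dict[str, int]:
    """Venn region counts over the DEM identity sets of each comparison.

    Keys of the output are '&'-joined sorted comparison labels naming the
    exact region (members of those comparisons and no other), plus 'union'.
    """
    sets = {k: set(v) for k, v in dem_lists.items()}
    labels = sorted(sets)
    regions: dict[str, int] = {}
    union: set[str] = set().union(*sets.values()) if sets else set()
    for item_mask in range(1, 2 ** len(labels)):
        inside = [labels[i] for i in range(len(labels)) if item_mask >> i & 1]
        outside = [l for l in labels if l not in inside]
        region = set.intersection(*(sets[l] for l in inside)) if inside else set()
        for l in outside:
            region -= sets[l]
        regions["&".join(inside)] = len(region)
    regions["union"] = len(union)
    return regions
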
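"""qRT-PCR reference-gene stability: geNorm, NormFinder, BestKeeper, 2^-ddCt.

All three stability algorithms operate on a genes x samples matrix of
threshold-cycle (Ct) values.  Relative quantities assume a PCR efficiency
of 2, i.e. q = 2^(-Ct); geNorm and NormFinder therefore work directly on
(negated) Ct values, which are log2 quantities up to a per-gene constant.

* geNorm: the stability measure M of a gene is the mean, over all other
  genes, of the standard deviation across samples of the pairwise log2
  expression ratio.  Iterative exclusion of the highest-M gene yields the
  ranking and the best-surviving pair.
* NormFinder: a variance-decomposition estimate; with sample groups the
  stability is |intergroup effect| + intragroup standard error, without
  groups it reduces to the standard deviation of the gene's residual after
  removing the per-sample mean profile.
* BestKeeper: descriptive — per-gene SD and CV of raw Ct, plus the Pearson
  correlation with the BestKeeper index (per-sample geometric mean of all
  candidate genes' Ct).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Ct matrix
# ---------------------------------------------------------------------------

@dataclass
class CtMatrix:
    """Genes x samples Ct values with optional per-sample group labels."""

    values: pd.DataFrame                 # index = genes, columns = samples
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] < 2 or v.shape[1] < 3:
            raise ValueError("need at least 2 genes and 3 samples")
        if ((v <= 0) | (v >= 45)).any().any():
            raise ValueError("Ct values must lie in (0, 45)")
        if self.groups is not None:
            missing = set(v.columns) - set(self.groups)
            if missing:
                raise ValueError(f"samples without group label: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def load_ct_tsv(path: str | Path, max_missing_frac: float = 0.2) -> CtMatrix:
    """Read a Ct TSV (genes x samples; optional leading '#group' row).

    Missing cells are imputed with the gene's median (with a warning);
    genes missing more than ``max_missing_frac`` of samples are dropped.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    groups = None
    if df.index[0] == "#group":
        groups = {c: str(df.loc["#group", c]) for c in df.columns}
        df = df.drop(index="#group")
    df = df.astype(float)
    frac_missing = df.isna().mean(axis=1)
    dropped = frac_missing[frac_missing > max_missing_frac].index
    if len(dropped):
        warnings.warn(f"genes excluded for >20% missing Ct: {list(dropped)}")
        df = df.drop(index=dropped)
    if df.isna().any().any():
        warnings.warn("missing Ct cells imputed with per-gene median")
        df = df.apply(lambda row: row.fillna(row.median()), axis=1)
    return CtMatrix(values=df, groups=groups)


# ---------------------------------------------------------------------------
# 2^-ddCt relative quantification
# ---------------------------------------------------------------------------

@dataclass
class RelQuant:
    target: str
    reference: str
    calibrator: str
    delta_ct: pd.Series
    delta_delta_ct: pd.Series
    fold: pd.Series


def delta_delta_ct(ct: CtMatrix, target: str, reference: str,
                   calibrator: str) -> RelQuant:
    """Relative expression of ``target`` normalized to ``reference``.

    dCt = Ct_target - Ct_reference per sample; ddCt subtracts the
    calibrator sample's dCt; fold change = 2^(-ddCt) (1.0 at the
    calibrator by construction).
    """
    if target == reference:
        raise ValueError("target and reference gene must differ")
    if calibrator not in ct.samples:
        raise ValueError(f"calibrator {calibrator!r} is not a sample")
    dct = ct.values.loc[target] - ct.values.loc[reference]
    ddct = dct - dct[calibrator]
    return RelQuant(target, reference, calibrator, dct, ddct, 2.0 ** (-ddct))


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

@dataclass
class GeNormResult:
    m_values: pd.Series                  # M on the full gene set
    pair_matrix: pd.DataFrame            # V_jk = pair M of genes (j, k)
    exclusion_order: list[str]           # removed first (least stable) ... last
    best_pair: tuple[str, str]           # final two, more stable first
    ranking: list[str]                   # most stable first
    pairwise_variation: pd.Series | None = None   # V_{n/n+1}


def _pairwise_v(ct: pd.DataFrame) -> pd.DataFrame:
    """SD across samples of the pairwise log2 ratio, for every gene pair.

    With q = 2^(-Ct) the log2 ratio of genes j and k is Ct_k - Ct_j, so
    V_jk = SD_samples(Ct_k - Ct_j) (sample SD, ddof=1).
    """
    genes = list(ct.index)
    v = pd.DataFrame(np.nan, index=genes, columns=genes, dtype=float)
    arr = ct.to_numpy()
    for a in range(len(genes)):
        for b in range(a + 1, len(genes)):
            sd = float(np.std(arr[b] - arr[a], ddof=1))
            v.iloc[a, b] = v.iloc[b, a] = sd
    return v


def _m_from_v(v: pd.DataFrame) -> pd.Series:
    return v.mean(axis=1, skipna=True)


def genorm(ct: CtMatrix) -> GeNormResult:
    """geNorm M values, the pair matrix, and the iterative-exclusion ranking."""
    df = ct.values
    v_full = _pairwise_v(df)
    m_full = _m_from_v(v_full)
    if np.allclose(v_full.fillna(0.0).to_numpy(), 0.0):
        warnings.warn("degenerate Ct matrix: all pairwise variations are zero; "
                      "ranking follows input order")
        genes = list(df.index)
        return GeNormResult(m_full, v_full, genes[2:][::-1], (genes[0], genes[1]),
                            genes, None)
    remaining = list(df.index)
    excluded: list[str] = []
    final_pair_order: tuple[str, str] | None = None
    while len(remaining) > 2:
        m = _m_from_v(_pairwise_v(df.loc[remaining]))
        worst = m.sort_values(kind="stable").index[-1]
        if len(remaining) == 3:
            # order the surviving pair by M in this last 3-gene round
            survivors = [g for g in remaining if g != worst]
            final_pair_order = tuple(sorted(survivors, key=lambda g: (m[g], g)))
        excluded.append(worst)
        remaining.remove(worst)
    if final_pair_order is None:   # started with exactly 2 genes
        final_pair_order = (remaining[0], remaining[1])
    ranking = list(final_pair_order) + excluded[::-1]
    nf = _pairwise_variation(df, ranking)
    return GeNormResult(m_full, v_full, excluded, final_pair_order, ranking, nf)


def _pairwise_variation(df: pd.DataFrame, ranking: list[str]) -> pd.Series:
    """geNorm V_{n/n+1}: SD of log2(NF_n/NF_{n+1}) over samples, where NF_n
    is the geometric mean quantity of the n most stable genes."""
    out = {}
    log_q = -df  # log2 quantities
    for n in range(2, len(ranking)):
        nf_n = log_q.loc[ranking[:n]].mean(axis=0)
        nf_n1 = log_q.loc[ranking[:n + 1]].mean(axis=0)
        out[f"V{n}/{n + 1}"] = float(np.std(nf_n - nf_n1, ddof=1))
    return pd.Series(out, dtype=float)


def genorm_pair_m(ct: CtMatrix, gene_a: str, gene_b: str) -> float:
    """The M value of a two-gene combination (their pairwise variation)."""
    sub = ct.values.loc[[gene_a, gene_b]]
    return float(np.std(sub.iloc[1] - sub.iloc[0], ddof=1))


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def normfinder(ct: CtMatrix, use_groups: bool = True) -> pd.Series:
    """Model-based stability values (lower = more stable).

    Works on log2 quantities x = -Ct.  Without groups: the per-sample mean
    profile across genes is removed and the stability is the SD of each
    gene's residual.  With groups: per group, the intragroup variance of
    that residual is estimated, plus an intergroup term = the gene's
    group-mean deviation from its overall mean after centering on the group
    effect; stability = mean over groups of |intergroup| + SE(intragroup).
    """
    x = -ct.values
    if ct.groups is None or not use_groups:
        resid = x - x.mean(axis=0)                  # remove sample profile
        resid = resid.sub(resid.mean(axis=1), axis=0)   # remove gene level
        return resid.std(axis=1, ddof=1).rename("stability")
    groups = pd.Series(ct.groups)[x.columns]
    stab = pd.Series(0.0, index=x.index)
    glabels = sorted(groups.unique())
    gene_overall = x.mean(axis=1)
    overall = float(x.to_numpy().mean())
    for g in glabels:
        cols = groups[groups == g].index
        xg = x[cols]
        n_g = len(cols)
        resid = xg.sub(xg.mean(axis=0), axis=1)
        resid = resid.sub(resid.mean(axis=1), axis=0)
        intra_var = resid.var(axis=1, ddof=1)
        d_ig = (xg.mean(axis=1) - gene_overall) - (float(xg.to_numpy().mean()) - overall)
        stab += d_ig.abs() + np.sqrt(intra_var / n_g)
    return (stab / len(glabels)).rename("stability")


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

def bestkeeper(ct: CtMatrix) -> pd.DataFrame:
    """Per-gene SD and CV of raw Ct and Pearson R against the BestKeeper index."""
    df = ct.values
    index = np.exp(np.log(df).mean(axis=0))          # per-sample geometric mean
    rows = []
    for gene in df.index:
        vals = df.loc[gene]
        sd = float(np.std(vals, ddof=1))
        cv = 100.0 * sd / float(np.mean(vals))
        if sd == 0.0 or np.std(index) == 0.0:
            r = np.nan
        else:
            r = float(stats.pearsonr(vals, index)[0])
        rows.append({"gene": gene, "SD": sd, "CV": cv, "R": r})
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    genorm: GeNormResult
    normfinder: pd.Series
    bestkeeper: pd.DataFrame
    consensus: list[str] = field(default_factory=list)


def consensus_rank(report: StabilityReport) -> list[str]:
    """Mean of the three per-method rank positions; ties break on geNorm rank.

    geNorm ranks by the iterative-exclusion order, NormFinder by ascending
    stability value, BestKeeper by ascending SD.  Methods absent from the
    report are simply left out (single-method input passes through).
    """
    ranks: list[pd.Series] = []
    genes = None
    if report.genorm is not None:
        gn = pd.Series({g: i + 1 for i, g in enumerate(report.genorm.ranking)},
                       dtype=float)
        ranks.append(gn)
        genes = list(gn.index)
    if report.normfinder is not None:
        ranks.append(report.normfinder.rank(method="average"))
    if report.bestkeeper is not None:
        ranks.append(report.bestkeeper["SD"].rank(method="average"))
    if not ranks:
        raise ValueError("no method results to rank")
    mean_rank = pd.concat(ranks, axis=1).mean(axis=1)
    genorm_rank = ranks[0] if report.genorm is not None else mean_rank
    order = sorted(mean_rank.index, key=lambda g: (mean_rank[g], genorm_rank[g], g))
    report.consensus = order
    return order


def stability_report(ct: CtMatrix) -> StabilityReport:
    report = StabilityReport(genorm=genorm(ct), normfinder=normfinder(ct),
                             bestkeeper=bestkeeper(ct))
    consensus_rank(report)
    return report


def write_stability_report(report: StabilityReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.genorm.pair_matrix.to_csv(out / "genorm_pair_matrix.tsv", sep="\t",
                                     float_format="%.4f")
    report.genorm.m_values.rename("M").to_csv(out / "genorm_m.tsv", sep="\t",
                                              float_format="%.4f")
    report.normfinder.to_csv(out / "normfinder.tsv", sep="\t", float_format="%.4f")
    report.bestkeeper.to_csv(out / "bestkeeper.tsv", sep="\t", float_format="%.4f")
    (out / "consensus.tsv").write_text(
        "rank\tgene\n" + "".join(f"{i + 1}\t{g}\n"
                                 for i, g in enumerate(report.consensus)))
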
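"""End-to-end orchestration of the three-library small-RNA workflow.

Stages communicate only through their file interfaces (collapsed library
TSVs, annotation summaries, count tables, prediction TSVs), so any stage
can be re-run from intermediates.  A run is fully determined by its
manifest: given the same manifest (including the seed, for simulated
inputs) two runs produce byte-identical report bundles; the run log
records versions and every threshold, and carries no timestamps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import annotate as ann
from . import diffexpr as de
from . import preprocess as pp
from . import refstab as rs
from . import simulate as sim
from . import targets as tg


@dataclass
class Thresholds:
    min_length: int = 18
    max_length: int = 32
    min_mean_quality: float = 20.0
    adapter_mismatch_rate: float = 0.1
    ncrna_mismatch: int = 1
    conserved_mismatch: int = 2
    fc_threshold: float = 1.0
    alpha: float = 0.05
    dem_mode: str = "p"          # 'p' (p<alpha) or 'q' (BH q<=alpha)
    strict_gu: bool = True
    min_energy_ratio: float = 0.75
    hairpin_energy: float = -18.0
    hairpin_flank: int = 70
    max_novel_candidates: int = 50


@dataclass
class RunManifest:
    out_dir: str
    seed: int = 0
    simulate: bool = True
    sim_depth: int = 20_000
    labels: tuple[str, ...] = ("BS", "RS", "WS")
    fastq: dict = field(default_factory=dict)       # label -> path
    adapter_3p: str = "TGGAATTCTCGGGTGCCAAGG"
    refs: dict = field(default_factory=dict)        # see validate()
    contrasts: tuple[str, ...] = ("WS:BS", "RS:BS", "RS:WS")   # treatment:control
    ct_path: str | None = None
    utr_path: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("library labels must be unique")
        for c in self.contrasts:
            t, _, ctl = c.partition(":")
            if not t or not ctl or t not in self.labels or ctl not in self.labels:
                raise ValueError(f"bad contrast {c!r}: use TREATMENT:CONTROL labels")
        if not self.simulate:
            missing = [str(p) for p in list(self.fastq.values())
                       + list(self.refs.values())
                       + ([self.ct_path] if self.ct_path else [])
                       + ([self.utr_path] if self.utr_path else [])
                       if p and not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"manifest references missing files: {missing}")
            if set(self.fastq) != set(self.labels):
                raise ValueError("fastq paths must cover exactly the labels")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunManifest":
        data = yaml.safe_load(Path(path).read_text())
        thr = Thresholds(**data.pop("thresholds", {}))
        m = cls(**{k: v for k, v in data.items()}, )
        m.thresholds = thr
        return m


def _load_reference_bundle(manifest: RunManifest) -> sim.ReferenceBundle:
    if manifest.simulate:
        cfg = sim.SimulationConfig(seed=manifest.seed, depth=manifest.sim_depth,
                                   adapter_3p=manifest.adapter_3p)
        return sim.simulate_references(cfg)
    r = manifest.refs
    ncrna = {}
    for subtype, (category, _, _) in sim._NCRNA_DESIGN.items():
        key = f"{subtype}_fasta"
        if key in r:
            ncrna[subtype] = ann.ReferenceSet(category,
                                              sequences=ann.load_fasta(r[key]),
                                              subtype=subtype)
    genome = ann.load_fasta(r["genome_fasta"]) if "genome_fasta" in r else {}
    intervals = {k: ann.load_intervals_tsv(r[f"{k}_tsv"])
                 for k in ("repeat", "exon", "intron") if f"{k}_tsv" in r}
    return sim.ReferenceBundle(ncrna=ncrna,
                               known_mirnas=ann.load_fasta(r["mirna_fasta"]),
                               genome=genome, intervals=intervals,
                               hairpins=[], novel_matures={})


def annotate_library(lib: pp.SmallRNALibrary, bundle: sim.ReferenceBundle,
                     thr: Thresholds):
    """Tiered annotation of one collapsed library.

    Sequence tiers are searched with the ncRNA tolerance; repeat/exon/
    intron assignments come from genome hits intersected with the interval
    sets.  Returns (assignments, miRNA records, hairpin candidates).
    """
    seqs = list(lib.entries)
    hits_by_cat: dict[str, list[ann.Hit]] = {}
    subtype_map: dict[str, dict[str, str]] = {}
    for subtype, refset in bundle.ncrna.items():
        hits = ann.map_sequences(lib, refset, thr.ncrna_mismatch)
        hits_by_cat.setdefault(refset.category, []).extend(hits)
        subtype_map.setdefault(refset.category, {}).update(
            {rid: subtype for rid in refset.sequences})
    mir_ref = ann.ReferenceSet("known_miRNA", sequences=bundle.known_mirnas,
                               subtype="miRNA")
    if bundle.known_mirnas:
        hits_by_cat["known_miRNA"] = ann.map_sequences(lib, mir_ref,
                                                       thr.ncrna_mismatch,
                                                       both_strands=False)
    genome_hits: list[ann.Hit] = []
    if bundle.genome:
        genome_ref = ann.ReferenceSet("genome", sequences=bundle.genome)
        genome_hits = ann.map_sequences(lib, genome_ref, thr.ncrna_mismatch)
        hits_by_cat["genome"] = genome_hits
        qlens = {s: len(s) for s in lib.entries}
        for cat in ("repeat", "exon", "intron"):
            if bundle.intervals.get(cat):
                hits_by_cat[cat] = ann.hits_in_intervals(genome_hits, qlens,
                                                         bundle.intervals[cat])
    assignments = ann.assign_hierarchy(hits_by_cat, seqs, subtype_map)

    # conserved-miRNA calling (2-mismatch, 5'-anchored) on everything not
    # already consumed by a higher tier
    mir_seqs = {s: lib.entries[s] for s, a in assignments.items()
                if a.category in ("known_miRNA", "genome", "other")}
    records = ann.call_conserved_mirnas(mir_seqs, bundle.known_mirnas,
                                        max_mismatch=thr.conserved_mismatch,
                                        library_label=lib.label)
    conserved_seqs = {v for r in records for v in r.variant_sequences}
    # novel screen: genome-mapped sequences that matched nothing
    leftover_hits = [h for h in genome_hits
                     if assignments[h.query].category == "genome"
                     and h.query not in conserved_seqs]
    leftover_hits = leftover_hits[:thr.max_novel_candidates]
    hairpins = ann.screen_novel_candidates(leftover_hits, bundle.genome,
                                           flank=thr.hairpin_flank,
                                           energy_threshold=thr.hairpin_energy)
    return assignments, records, hairpins


TABLE1_ORDER = ("tRNA", "snoRNA", "snRNA", "rRNA", "scRNA",
                "intron", "exon", "repeat", "miRNA", "other")


def report_tables(out_dir: Path, label: str, assignments, lib,
                  records: list[ann.MiRNARecord]) -> None:
    """Write the per-library report tables in the study's table layouts."""
    summary = ann.summarize_annotation(assignments, lib)
    order = {c: i for i, c in enumerate(TABLE1_ORDER)}
    summary["rank"] = summary["category"].map(lambda c: order.get(c, 99))
    summary = summary.sort_values(["rank", "category"]).drop(columns="rank")
    summary.to_csv(out_dir / f"annotation_summary_{label}.tsv", sep="\t",
                   index=False)
    top = sorted(records, key=lambda r: (-r.total_count, r.name))
    with open(out_dir / f"mirna_table_{label}.tsv", "w") as fh:
        fh.write("miRNA\tsequence\tstatus\tcount\n")
        for r in top:
            fh.write(f"{r.name}\t{r.sequence}\t{r.status}\t{r.total_count}\n")


def run_full(manifest: RunManifest) -> dict:
    """Execute the whole workflow per the manifest; returns a result map."""
    manifest.validate()
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = manifest.thresholds
    stage = "references"
    result: dict = {}
    try:
        bundle = _load_reference_bundle(manifest)
        cfg = sim.SimulationConfig(seed=manifest.seed, depth=manifest.sim_depth,
                                   adapter_3p=manifest.adapter_3p)
        libraries: dict[str, pp.SmallRNALibrary] = {}
        counts: dict[str, dict[str, int]] = {}
        totals: dict[str, int] = {}
        for label in manifest.labels:
            stage = f"preprocess:{label}"
            if manifest.simulate:
                raw, _truth = sim.simulate_library(cfg, label, bundle)
            else:
                raw = pp.load_raw_readset(manifest.fastq[label], manifest.adapter_3p)
            lib, stats = pp.filter_and_collapse(
                raw, thr.min_length, thr.max_length, thr.min_mean_quality,
                max_mismatch_rate=thr.adapter_mismatch_rate, label=label)
            pp.write_library_tsv(lib, out / f"library_{label}.tsv")
            pp.write_stats(stats, out / f"preprocess_stats_{label}.json")
            stage = f"annotate:{label}"
            assignments, records, hairpins = annotate_library(lib, bundle, thr)
            report_tables(out, label, assignments, lib, records)
            with open(out / f"hairpin_candidates_{label}.tsv", "w") as fh:
                fh.write("chrom\tstart\tend\tstrand\tarm\tenergy\tmature\n")
                for h in hairpins:
                    fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\t"
                             f"{h.mature_arm}\t{h.fold_energy:.2f}\t"
                             f"{h.mature_sequence}\n")
            libraries[label] = lib
            counts[label] = {r.name: r.total_count for r in records}
            totals[label] = lib.total_clean_reads
            result[f"n_mirnas_{label}"] = len(records)

        dem_sets: dict[str, list[str]] = {}
        for contrast in manifest.contrasts:
            stage = f"diffexpr:{contrast}"
            treat, _, ctl = contrast.partition(":")
            res = de.exact_test_table(counts[ctl], counts[treat],
                                      totals[ctl], totals[treat],
                                      thr.fc_threshold, thr.alpha, thr.dem_mode)
            df = pd.DataFrame([{
                "name": r.name, f"tpm_{ctl}": r.tpm1, f"tpm_{treat}": r.tpm2,
                "log2fc": r.log2fc, "p": r.p_two_sided, "q": r.q, "call": r.call,
            } for r in res])
            df.to_csv(out / f"de_{treat}_vs_{ctl}.tsv", sep="\t", index=False,
                      float_format="%.6g")
            dem_sets[contrast] = [r.name for r in res if r.call != "ns"]
        stage = "venn"
        venn = de.overlap_dems(dem_sets)
        (out / "dem_venn.json").write_text(json.dumps(venn, indent=2,
                                                      sort_keys=True) + "\n")
        result["dem_counts"] = {k: len(v) for k, v in dem_sets.items()}

        stage = "targets"
        if manifest.simulate or manifest.utr_path:
            if manifest.simulate:
                guide_names = sorted(bundle.known_mirnas)[:4]
                guides = {n: bundle.known_mirnas[n] for n in guide_names}
                utrs, _ = sim.plant_utr_sites(cfg, guides)
            else:
                utrs = ann.load_fasta(manifest.utr_path)
                dems = set().union(*dem_sets.values()) if dem_sets else set()
                guides = {n: s for n, s in bundle.known_mirnas.items() if n in dems}
            preds = []
            for name, guide in sorted(guides.items()):
                for tid, seq in sorted(utrs.items()):
                    preds.extend(tg.scan_utr(guide, seq, name, tid,
                                             strict_gu=thr.strict_gu,
                                             min_ratio=thr.min_energy_ratio))
            tg.write_predictions_tsv(preds, out / "target_predictions.tsv")
            result["n_target_predictions"] = len(preds)

        stage = "refstab"
        if manifest.simulate or manifest.ct_path:
            if manifest.simulate:
                ct, _order = sim.simulate_ct(cfg)
            else:
                ct = rs.load_ct_tsv(manifest.ct_path)
            report = rs.stability_report(ct)
            rs.write_stability_report(report, out / "refstab")
            result["consensus_ranking"] = report.consensus

        stage = "log"
        log = {"package": "koisrna", "version": __version__,
               "seed": manifest.seed, "labels": list(manifest.labels),
               "contrasts": list(manifest.contrasts),
               "thresholds": asdict(thr), "simulated": manifest.simulate}
        (out / "run_log.json").write_text(json.dumps(log, indent=2,
                                                     sort_keys=True) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return result
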
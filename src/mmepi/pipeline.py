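"""End-to-end orchestration: dataset loading, the five analysis stages,
provenance logging, and the machine-readable report.

Stages run in order differential -> states -> denovo -> linking ->
methylation; each stage persists its outputs under the run directory,
and later stages reload those files, so single stages can be re-run
against a populated run directory. Identical config + inputs give
identical outputs (the pipeline itself draws no random numbers).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
import yaml

from . import __version__
from . import io as mio
from .denovo import (audit_de_novo, denovo_table, intersect_atac,
                     select_de_novo, stitch_superenhancers)
from .differential import (annotate_differential, build_consensus,
                           call_differential, stable_baseline)
from .intervals import IntervalSet, coverage_select
from .linking import TADSet, find_coregulated, link_targets
from .methylation import composite_profile, cpg_differential
from .motifs import scan_pwm
from .stats import de_call
from .tables import BASELINE_POPULATIONS, HISTONE_MARKS

logger = logging.getLogger(__name__)

STAGES = ("differential", "states", "denovo", "link", "methmotif")


@dataclass
class PipelineConfig:
    """All paths, thresholds and flags for one pipeline run."""

    dataset_dir: str = "."
    out_dir: str = "results"
    sample_sheet: str = "sample_sheet.tsv"
    gene_annotation: str = "genes.tsv"
    tads: str = "tads.bed"
    chrom_sizes: str = "chrom_sizes.tsv"
    pwms: str = "motifs.meme"
    region_fasta: str = "regions.fa"
    expression: str = "expression.tsv"

    min_frac: float = 0.5
    min_mm_frac: float = 0.66
    min_region_bp: int = 200
    stitch_distance: int = 12_500
    tss_exclusion: int = 2_000
    r_min: float = 0.5
    p_max: float = 0.05
    fdr: float = 0.05
    fc: float = 1.5
    delta_threshold: float = 0.25
    motif_flank: int = 10
    profile_flank: int = 2_000
    bin_bp: int = 50
    min_cov: int = 5
    score_frac: float = 0.8
    fallback_window: int = 1_000_000
    seed: int = 0

    allow_missing_bmpc: bool = False
    adjacency: str = "annotation"
    signed_delta: bool = True

    def __post_init__(self) -> None:
        checks = [
            (0 < self.min_frac <= 1, "min_frac in (0,1]"),
            (0 < self.min_mm_frac <= 1, "min_mm_frac in (0,1]"),
            (self.min_region_bp >= 1, "min_region_bp >= 1"),
            (self.stitch_distance >= 0, "stitch_distance >= 0"),
            (self.tss_exclusion >= 0, "tss_exclusion >= 0"),
            (-1 <= self.r_min <= 1, "r_min in [-1,1]"),
            (0 < self.p_max <= 1, "p_max in (0,1]"),
            (0 < self.fdr <= 1, "fdr in (0,1]"),
            (self.fc >= 1, "fc >= 1"),
            (0 <= self.delta_threshold <= 1, "delta_threshold in [0,1]"),
            (0 < self.score_frac <= 1, "score_frac in (0,1]"),
            (self.adjacency in ("annotation", "target"), "adjacency mode"),
        ]
        for ok, what in checks:
            if not ok:
                raise ValueError(f"config constraint violated: {what}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineReport:
    config: dict
    version: str = __version__
    input_checksums: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


class Dataset:
    """Loaded inputs for one run."""

    def __init__(self, cfg: PipelineConfig):
        base = Path(cfg.dataset_dir)
        self.base = base
        self.samples = mio.read_sample_sheet(base / cfg.sample_sheet)
        self.genome = mio.read_chrom_sizes(base / cfg.chrom_sizes)
        self.genes = mio.read_gene_annotation(base / cfg.gene_annotation)
        self.tads = TADSet(mio.read_bed(base / cfg.tads))
        self.expression = mio.read_expression(base / cfg.expression, self.samples)
        self.methylation = mio.load_methylation(self.samples, base)
        self.pwms = mio.read_meme_pwms(base / cfg.pwms)
        self.sequences = mio.read_fasta(base / cfg.region_fasta)
        self.peaks: dict[tuple[str, str], IntervalSet] = {}
        for row in self.samples.df.itertuples(index=False):
            if row.assay in ("RNA", "WGBS") or not row.path:
                continue
            self.peaks[(row.sample_id, row.assay)] = mio.read_bed(base / row.path)
        self.signal = {}
        for row in self.samples.df.itertuples(index=False):
            if row.signal_path:
                self.signal[row.sample_id] = mio.read_bedgraph(base / row.signal_path)

    def peaks_of(self, population, assay) -> dict[str, IntervalSet]:
        sub = self.samples.select(population=population, assay=assay)
        return {r.sample_id: self.peaks[(r.sample_id, assay)]
                for r in sub.itertuples(index=False)
                if (r.sample_id, assay) in self.peaks}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ------------------------------------------------------------- stages

def stage_differential(ds: Dataset, cfg: PipelineConfig, out: Path) -> dict:
    """Per-mark gain/loss calls plus the annotation panels."""
    out_diff = out / "differential"
    out_diff.mkdir(parents=True, exist_ok=True)
    atac_by_sample = {**ds.peaks_of(list(BASELINE_POPULATIONS), "ATAC"),
                      **ds.peaks_of("MM", "ATAC")}
    de_vs_normals = de_call(
        ds.expression, list(BASELINE_POPULATIONS) + ["bm-PC"], "MM",
        fdr=cfg.fdr, fc=cfg.fc,
    ) if not ds.samples.select(assay="RNA").empty else None

    counts = {}
    for mark in list(HISTONE_MARKS) + ["ATAC"]:
        mm = ds.peaks_of("MM", mark)
        if not mm:
            raise ValueError(f"no MM samples for mark {mark}")
        consensus = {}
        for pop in BASELINE_POPULATIONS:
            pop_peaks = ds.peaks_of(pop, mark)
            if not pop_peaks:
                raise ValueError(f"missing population {pop} for mark {mark}")
            consensus[pop] = build_consensus(
                list(pop_peaks.values()), cfg.min_frac, pop, mark)
        present, absent = stable_baseline(consensus, ds.genome)
        gain, loss = call_differential(
            mark, list(mm.values()), present, absent, ds.genome,
            cfg.min_mm_frac, cfg.min_region_bp)
        for diff in (gain, loss):
            ann = annotate_differential(
                diff, ds.samples, atac_by_sample, ds.methylation,
                ds.genes, de_vs_normals)
            ann.annotations.to_csv(
                out_diff / f"{mark}_{diff.direction}.tsv", sep="\t", index=False)
            mio.write_bed(diff.regions, out_diff / f"{mark}_{diff.direction}.bed")
            counts[f"{mark}_{diff.direction}"] = len(diff)
    if de_vs_normals is not None:
        de_vs_normals.write(out_diff / "de_mm_vs_normals.tsv")
    return counts


def stage_states(ds: Dataset, cfg: PipelineConfig, out: Path) -> dict:
    """Chromatin states on the pooled differential regions, Fig-style
    distribution and transition matrix."""
    from .states import (group_states_per_region, sample_states,
                         transition_matrix)
    out_states = out / "states"
    out_states.mkdir(parents=True, exist_ok=True)
    diff_dir = out / "differential"
    beds = sorted(diff_dir.glob("*_gain.bed")) + sorted(diff_dir.glob("*_loss.bed"))
    beds = [b for b in beds if not b.name.startswith("ATAC")]
    if not beds:
        raise FileNotFoundError("states stage requires differential outputs")
    pooled = coverage_select(
        [mio.read_bed(b) for b in beds if b.stat().st_size > 0], min_count=1)
    if len(pooled) == 0:
        raise ValueError("no differential regions to assign states to")
    calls = sample_states(pooled, ds.samples, ds.peaks)
    calls.to_csv(out_states / "state_calls.tsv", sep="\t", index=False)
    normal = group_states_per_region(calls, BASELINE_POPULATIONS)
    mm = group_states_per_region(calls, ["MM"])
    mat = transition_matrix(normal, mm)
    mat.to_csv(out_states / "transition_matrix.tsv", sep="\t")
    return {"state_regions": len(pooled),
            "transition_matrix_sum": float(mat.to_numpy().sum())}


def stage_denovo(ds: Dataset, cfg: PipelineConfig, out: Path) -> dict:
    """De novo H3K27ac regions, superenhancers, ATAC intersection."""
    out_dn = out / "denovo"
    out_dn.mkdir(parents=True, exist_ok=True)
    gains_path = out / "differential" / "H3K27ac_gain.tsv"
    if not gains_path.exists():
        raise FileNotFoundError("denovo stage requires differential outputs")
    gains = pd.read_csv(gains_path, sep="\t")

    normal_peaks = {}
    for pop in list(BASELINE_POPULATIONS) + ["bm-PC"]:
        for sid, p in ds.peaks_of(pop, "H3K27ac").items():
            normal_peaks[sid] = p
    bmpc = list(ds.peaks_of("bm-PC", "H3K27ac"))
    if not bmpc and not cfg.allow_missing_bmpc:
        raise ValueError(
            "bm-PC H3K27ac data missing: the cell-of-origin filter is "
            "mandatory (set allow_missing_bmpc to override)")
    regions = select_de_novo(
        gains, normal_peaks, min_mm_frac=cfg.min_mm_frac,
        require_bmpc=not cfg.allow_missing_bmpc, bmpc_samples=bmpc)
    residue = audit_de_novo(regions, normal_peaks)
    if residue:
        raise AssertionError(
            f"de novo audit failed: {residue} bp of normal-peak overlap")

    mm_k27 = ds.peaks_of("MM", "H3K27ac")
    mm_consensus = build_consensus(list(mm_k27.values()), cfg.min_frac, "MM", "H3K27ac")
    tracks = {sid: ds.signal[sid] for sid in mm_k27 if sid in ds.signal}
    ses, constituents = stitch_superenhancers(
        mm_consensus.intervals, tracks, ds.genes,
        cfg.stitch_distance, cfg.tss_exclusion)
    se_df = pd.DataFrame([dataclasses.asdict(s) for s in ses])
    se_df.to_csv(out_dn / "superenhancers.tsv", sep="\t", index=False)
    constituents.to_csv(out_dn / "se_constituents.tsv", sep="\t", index=False)

    # superenhancer membership of de novo regions
    super_ids = {s.se_id for s in ses if s.is_super}
    super_ivs = IntervalSet.from_records(
        [(s.chrom, s.start, s.end, None) for s in ses if s.is_super])
    if len(super_ivs) and regions:
        from .intervals import count_overlaps
        ivs = IntervalSet.from_records([(r.chrom, r.start, r.end) for r in regions])
        ind, _ = count_overlaps(ivs, super_ivs)
        sdf = super_ivs.df
        for r, flag in zip(sorted(regions, key=lambda r: (r.chrom, r.start)), ind):
            if not flag:
                continue
            hit = sdf[(sdf["chrom"] == r.chrom) & (sdf["start"] <= r.start)
                      & (sdf["end"] >= r.end)]
            if len(hit):
                matches = [s.se_id for s in ses
                           if s.is_super and s.chrom == r.chrom
                           and s.start <= r.start and s.end >= r.end]
                r.se_id = matches[0] if matches else None

    atac_path = out / "differential" / "ATAC_gain.bed"
    atac_gains = mio.read_bed(atac_path) if atac_path.exists() else IntervalSet()
    regions = intersect_atac(regions, atac_gains)

    table = denovo_table(regions)
    table.to_csv(out_dn / "denovo_regions.tsv", sep="\t", index=False)
    if len(table):
        mio.write_bed(IntervalSet(table[["chrom", "start", "end"]]),
                      out_dn / "denovo_regions.bed", name_prefix="denovo")
    else:
        (out_dn / "denovo_regions.bed").write_text("")
    return {
        "denovo_regions": len(regions),
        "superenhancers": int(sum(s.is_super for s in ses)),
        "stitched_regions": len(ses),
        "atac_gain_flagged": int(sum(r.atac_gain for r in regions)),
        "denovo_in_super": int(sum(1 for r in regions if r.se_id)),
    }


def stage_link(ds: Dataset, cfg: PipelineConfig, out: Path) -> dict:
    """TAD + expression target assignment and coregulated groups."""
    from .denovo import DeNovoRegion
    out_link = out / "linking"
    out_link.mkdir(parents=True, exist_ok=True)
    dn_path = out / "denovo" / "denovo_regions.tsv"
    if not dn_path.exists():
        raise FileNotFoundError("link stage requires denovo outputs")
    dn = pd.read_csv(dn_path, sep="\t")
    regions = [DeNovoRegion(r.chrom, int(r.start), int(r.end),
                            float(r.mm_support))
               for r in dn.itertuples(index=False)]

    rna_pops = [p for p in ds.samples.populations(assay="RNA") if p != "MM"]
    if not rna_pops:
        raise ValueError("no normal populations with RNA data")
    de_by_pop = {pop: de_call(ds.expression, pop, "MM", fdr=cfg.fdr, fc=cfg.fc)
                 for pop in rna_pops}
    links = link_targets(regions, ds.tads, ds.genes, de_by_pop,
                         cfg.fallback_window)
    links_df = pd.DataFrame([dataclasses.asdict(l) for l in links])
    links_df.to_csv(out_link / "links.tsv", sep="\t", index=False)

    target_genes = list(dict.fromkeys(l.gene_id for l in links))
    expr_mm = ds.expression.columns_for("MM")
    groups = find_coregulated(target_genes, ds.genes, expr_mm,
                              cfg.r_min, cfg.p_max, cfg.adjacency)
    rows = []
    for gi, g in enumerate(groups):
        rows.append({
            "group_id": f"group_{gi + 1}", "genes": ",".join(g.genes),
            "n_genes": len(g.genes),
            "pair_r": ",".join(f"{r:.4f}" for r in g.pair_r),
            "pair_p": ",".join(f"{p:.3e}" for p in g.pair_p),
            "chrom": g.chrom, "span_start": g.span_start, "span_end": g.span_end,
        })
    pd.DataFrame(rows).to_csv(out_link / "coexpression_groups.tsv",
                              sep="\t", index=False)
    return {
        "links": len(links),
        "target_genes": len(target_genes),
        "coexpression_groups": len(groups),
        "coexpression_pairs": int(sum(1 for g in groups if len(g.genes) == 2)),
        "coexpression_triplets_plus": int(sum(1 for g in groups if len(g.genes) > 2)),
    }


def stage_methmotif(ds: Dataset, cfg: PipelineConfig, out: Path) -> dict:
    """PWM scanning and motif-anchored methylation analysis."""
    out_mm = out / "methylation"
    out_mm.mkdir(parents=True, exist_ok=True)
    all_hits = []
    for pwm in ds.pwms:
        all_hits += scan_pwm(ds.sequences, pwm, cfg.score_frac)
    hits_df = pd.DataFrame([dataclasses.asdict(h) for h in all_hits])
    hits_df.to_csv(out_mm / "motif_hits.tsv", sep="\t", index=False)

    counts = {"motif_hits": len(all_hits)}
    if all_hits and ds.methylation.samples:
        diffs, frac = cpg_differential(
            all_hits, ds.methylation, ds.samples,
            cfg.motif_flank, cfg.delta_threshold, cfg.min_cov,
            signed=cfg.signed_delta)
        pd.DataFrame([dataclasses.asdict(d) for d in diffs]).to_csv(
            out_mm / "cpg_differential.tsv", sep="\t", index=False)
        profile = composite_profile(
            all_hits, ds.methylation, ds.samples,
            cfg.profile_flank, cfg.bin_bp, min_cov=cfg.min_cov)
        profile.to_csv(out_mm / "composite_profile.tsv", sep="\t", index=False)
        counts["motif_cpgs"] = len(diffs)
        counts["hypo_cpg_fraction"] = round(frac, 4) if frac == frac else None
    return counts


_STAGE_FUNCS = {
    "differential": stage_differential,
    "states": stage_states,
    "denovo": stage_denovo,
    "link": stage_link,
    "methmotif": stage_methmotif,
}


def run_pipeline(cfg: PipelineConfig, stages=None) -> PipelineReport:
    """Execute the requested stages (default: all, in order)."""
    stages = list(STAGES) if stages is None else list(stages)
    bad = [s for s in stages if s not in _STAGE_FUNCS]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    ds = Dataset(cfg)
    if ds.samples.select(population="MM").empty:
        raise ValueError("sample sheet contains no MM samples")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(config=dataclasses.asdict(cfg))
    for name in ("sample_sheet", "gene_annotation", "tads", "chrom_sizes"):
        p = Path(cfg.dataset_dir) / getattr(cfg, name)
        if p.exists():
            report.input_checksums[name] = _checksum(p)
    for name in stages:
        t0 = time.perf_counter()
        logger.info("stage %s: start", name)
        counts = _STAGE_FUNCS[name](ds, cfg, out)
        report.counts.update(counts)
        report.timings_s[name] = round(time.perf_counter() - t0, 2)
        logger.info("stage %s: done in %.1fs", name, report.timings_s[name])
    _audit_report(report, out)
    report.save(out / "report.json")
    return report


def _audit_report(report: PipelineReport, out: Path) -> None:
    """Cross-check report counts against the emitted files."""
    dn_bed = out / "denovo" / "denovo_regions.bed"
    if "denovo_regions" in report.counts and dn_bed.exists():
        n_lines = sum(1 for line in dn_bed.read_text().splitlines() if line.strip())
        if n_lines != report.counts["denovo_regions"]:
            raise AssertionError(
                "report/file mismatch: de novo BED has "
                f"{n_lines} lines vs count {report.counts['denovo_regions']}")
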
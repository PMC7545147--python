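"""Synthetic multi-population, multi-assay dataset with planted truth.

The generator emulates the statistical structure of a multi-layer
myeloma epigenome study so every pipeline stage is testable without
controlled-access patient data:

* background peaks shared by all populations, with per-sample dropout
  and spurious peaks;
* de novo regions carrying H3K27ac, H3K4me1 and ATAC peaks in >= 80%
  of MM samples and in no normal sample of any population (including
  bm-PC), each placed inside a TAD whose designated target genes are
  ~4-fold up-regulated in MM only;
* a planted transcription-factor motif instance at the center of each
  de novo region whose flanking CpGs are highly methylated in normals
  and hypomethylated in MM;
* large H3K27me3/H3K9me3 repressed blocks with MM-wide methylation
  loss;
* adjacent gene pairs (and one triplet by default) coupled through a
  shared latent factor across MM expression samples, plus uncorrelated
  adjacent up-regulated gene pairs serving as the coexpression null;
* per-region mark combinations realizing the planted chromatin-state
  transitions (LowSignal -> ActiveEnh gains, ActiveEnh -> WeakEnh
  losses).

All randomness flows from one seed; per-component substreams are
derived by fixed offsets, so a fixed seed yields byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd

from . import io as mio
from .intervals import IntervalSet
from .motifs import PWM
from .tables import BASELINE_POPULATIONS

__all__ = ["SynthConfig", "TruthManifest", "generate_dataset"]

MOTIF_CONSENSUS = "TTGACGCA"  # non-palindromic, one CpG at offset 4-5
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class SynthConfig:
    """Generator parameters; the defaults are the study conditions."""

    chroms: tuple = (("chr1", 10_000_000), ("chr2", 10_000_000))
    tad_size: int = 50_000

    n_mm: int = 10                  # MM samples per ChIP/ATAC assay
    n_normal_per_pop: int = 2       # per normal population per ChIP/ATAC assay
    n_mm_wgbs: int = 5
    n_normal_wgbs_per_pop: int = 2
    n_rna_mm: int = 37
    n_rna_normal_per_pop: int = 4

    n_genes: int = 300
    n_denovo: int = 200
    n_pairs: int = 40
    n_triplets: int = 1
    n_background_pairs: int = 20
    n_loss: int = 20
    n_repressed_blocks: int = 20
    n_background_peaks: int = 200   # per mark, across the genome
    n_super_tads: int = 15

    region_len: int = 1_500
    peak_width: int = 800
    peak_jitter: int = 50
    peak_dropout: float = 0.10
    spurious_rate: float = 0.05

    expression_cv: float = 0.2
    mm_fold: float = 4.0
    pair_r: float = 0.7

    beta_active_normal: float = 0.85
    beta_active_mm: float = 0.30
    beta_shoulder_mm: float = 0.75
    beta_repressed_normal: float = 0.80
    beta_repressed_mm: float = 0.40
    beta_background: float = 0.80
    beta_concentration: float = 80.0
    coverage_mean: float = 30.0
    profile_cpg_per_region: int = 50
    profile_flank: int = 2_000

    seed: int = 0

    def validate(self) -> None:
        counts = [self.n_mm, self.n_normal_per_pop, self.n_genes, self.n_denovo,
                  self.n_pairs, self.n_triplets, self.n_background_pairs,
                  self.n_loss, self.n_repressed_blocks, self.n_background_peaks]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        for rate in (self.peak_dropout, self.spurious_rate):
            if not (0 <= rate <= 1):
                raise ValueError("rates must lie in [0, 1]")
        committed = 2 * (self.n_pairs + self.n_background_pairs) + 3 * self.n_triplets
        if self.n_denovo and self.n_denovo < committed:
            raise ValueError(
                f"n_denovo={self.n_denovo} cannot host {self.n_pairs} pairs, "
                f"{self.n_triplets} triplets and {self.n_background_pairs} "
                f"background pairs (need >= {committed} regions)")


@dataclass
class TruthManifest:
    """Planted ground truth: the acceptance oracle."""

    config: dict
    planted_denovo: list = field(default_factory=list)
    planted_pairs: list = field(default_factory=list)
    background_pairs: list = field(default_factory=list)
    planted_loss: list = field(default_factory=list)
    planted_hypo_cpgs: list = field(default_factory=list)
    planted_hypo_blocks: list = field(default_factory=list)
    planted_state_changes: dict = field(default_factory=dict)

    def denovo_intervals(self) -> IntervalSet:
        return IntervalSet.from_records(
            [(d["chrom"], d["start"], d["end"]) for d in self.planted_denovo]
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


# --------------------------------------------------------------- layout

def _plan_blocks(cfg: SynthConfig) -> list[dict]:
    """One entry per region-bearing TAD: kind, genes, region count."""
    blocks = []
    for _ in range(cfg.n_pairs):
        blocks.append({"kind": "pair", "n_genes": 2, "n_regions": 2})
    for _ in range(cfg.n_triplets):
        blocks.append({"kind": "triplet", "n_genes": 3, "n_regions": 3})
    for _ in range(cfg.n_background_pairs):
        blocks.append({"kind": "bgpair", "n_genes": 2, "n_regions": 2})
    committed = sum(b["n_regions"] for b in blocks)
    remaining = cfg.n_denovo - committed
    while remaining > 0:
        take = min(2, remaining)
        blocks.append({"kind": "single", "n_genes": 1, "n_regions": take})
        remaining -= take
    return blocks


def _layout(cfg: SynthConfig, rng: np.random.Generator) -> dict:
    """Place TADs, blocks, genes, background peaks and repressed blocks."""
    chrom_names = [c for c, _ in cfg.chroms]
    lengths = dict(cfg.chroms)
    tad = cfg.tad_size

    blocks = _plan_blocks(cfg)
    # flag superenhancer blocks among the single-gene blocks first
    singles = [b for b in blocks if b["kind"] == "single"]
    pool = singles if len(singles) >= cfg.n_super_tads else blocks
    for b in pool[:cfg.n_super_tads]:
        b["is_super"] = True

    # block zone: first 52% of each chromosome, even TAD slots
    capacity = 0
    per_chrom_even: dict[str, list[int]] = {}
    for chrom in chrom_names:
        zone_end = int(0.52 * lengths[chrom])
        n_slots = zone_end // tad
        per_chrom_even[chrom] = [s for s in range(n_slots) if s % 2 == 0]
        capacity += len(per_chrom_even[chrom])
    if len(blocks) > capacity:
        need = math.ceil(len(blocks) / len(chrom_names)) * 2 * tad / 0.52
        raise ValueError(
            f"{len(blocks)} planted TAD blocks exceed genome capacity "
            f"({capacity}); required minimum chromosome length ~{int(need)} bp")

    order = rng.permutation(len(blocks))
    placed = []
    cursors = {c: 0 for c in chrom_names}
    for k, bi in enumerate(order):
        chrom = chrom_names[k % len(chrom_names)]
        slot = per_chrom_even[chrom][cursors[chrom]]
        cursors[chrom] += 1
        b = dict(blocks[bi])
        b["chrom"] = chrom
        b["tad_start"] = slot * tad
        placed.append(b)
    placed.sort(key=lambda b: (b["chrom"], b["tad_start"]))

    # genes: block genes then spacers in odd slots (several per slot if needed)
    genes = []
    gid = 0
    for b in placed:
        b["genes"] = []
        for j in range(b["n_genes"]):
            gid += 1
            start = b["tad_start"] + 2_000 + j * 10_000
            strand = "+" if (gid % 2) else "-"
            genes.append({"gene_id": f"G{gid:04d}", "gene_name": f"GENE{gid}",
                          "chrom": b["chrom"], "start": start, "end": start + 7_000,
                          "strand": strand, "role": b["kind"]})
            b["genes"].append(f"G{gid:04d}")
        b["regions"] = []
        for j in range(b["n_regions"]):
            rs = b["tad_start"] + 32_000 + j * 5_500
            b["regions"].append((rs, rs + cfg.region_len))

    n_targets = gid
    n_spacers = cfg.n_genes - n_targets
    if n_spacers < 0:
        raise ValueError(
            f"n_genes={cfg.n_genes} below the {n_targets} planted target genes")
    odd_slots = []
    for chrom in chrom_names:
        zone_end = int(0.52 * lengths[chrom])
        odd_slots += [(chrom, s * tad) for s in range(zone_end // tad) if s % 2 == 1]
    spacer_slots = (odd_slots * 4)[:n_spacers] if odd_slots else []
    if len(spacer_slots) < n_spacers:
        raise ValueError("genome too small to host all spacer genes")
    seen_per_slot: dict[tuple, int] = {}
    for chrom, slot_start in spacer_slots:
        j = seen_per_slot.get((chrom, slot_start), 0)
        seen_per_slot[(chrom, slot_start)] = j + 1
        gid += 1
        start = slot_start + 2_000 + j * 10_000
        genes.append({"gene_id": f"G{gid:04d}", "gene_name": f"GENE{gid}",
                      "chrom": chrom, "start": start, "end": start + 7_000,
                      "strand": "+", "role": "spacer"})
    genes_df = pd.DataFrame(genes).sort_values(["chrom", "start"]).reset_index(drop=True)

    # TAD tiling (1 kb inter-TAD gaps), emitted for the whole genome
    tad_rows = []
    for chrom in chrom_names:
        for s in range(lengths[chrom] // tad):
            tad_rows.append((chrom, s * tad, s * tad + tad - 1_000))
    tads_df = pd.DataFrame(tad_rows, columns=["chrom", "start", "end"])

    # background distal peaks + loss peaks: 20 kb grid in the middle zone
    bg_slots = []
    for chrom in chrom_names:
        lo, hi = int(0.52 * lengths[chrom]), int(0.78 * lengths[chrom])
        bg_slots += [(chrom, p) for p in range(lo, hi - cfg.peak_width, 20_000)]
    need = cfg.n_background_peaks + cfg.n_loss
    if need > len(bg_slots):
        raise ValueError("background-peak zone too small; increase chromosome length")
    picks = rng.choice(len(bg_slots), size=need, replace=False)
    bg_peaks = [(bg_slots[i][0], bg_slots[i][1], bg_slots[i][1] + cfg.peak_width)
                for i in picks[:cfg.n_background_peaks]]
    loss_peaks = [(bg_slots[i][0], bg_slots[i][1], bg_slots[i][1] + cfg.peak_width)
                  for i in picks[cfg.n_background_peaks:]]
    spurious_pool = [(c, p + 10_000, p + 10_000 + cfg.peak_width)
                     for (c, p) in bg_slots]

    # repressed blocks: 150 kb grid in the last fifth
    rep_slots = []
    for chrom in chrom_names:
        lo, hi = int(0.80 * lengths[chrom]), int(0.99 * lengths[chrom])
        rep_slots += [(chrom, p) for p in range(lo, hi - 100_000, 150_000)]
    if cfg.n_repressed_blocks > len(rep_slots):
        raise ValueError("repressed-block zone too small; increase chromosome length")
    picks = rng.choice(len(rep_slots), size=cfg.n_repressed_blocks, replace=False)
    rep_blocks = [(rep_slots[i][0], rep_slots[i][1], rep_slots[i][1] + 100_000)
                  for i in sorted(picks)]

    return {"blocks": placed, "genes": genes_df, "tads": tads_df,
            "bg_peaks": sorted(bg_peaks), "loss_peaks": sorted(loss_peaks),
            "spurious_pool": spurious_pool, "rep_blocks": rep_blocks,
            "lengths": lengths}


# ---------------------------------------------------------------- peaks

def _jitter(intervals, rng, jitter):
    out = []
    for chrom, s, e in intervals:
        ds, de = rng.integers(-jitter, jitter + 1, size=2) if jitter else (0, 0)
        s2, e2 = max(0, s + int(ds)), e + int(de)
        if e2 - s2 < 50:
            e2 = s2 + 50
        out.append((chrom, s2, e2))
    return out


def _drop(intervals, rng, rate):
    if rate <= 0 or not intervals:
        return list(intervals)
    keep = rng.random(len(intervals)) >= rate
    return [iv for iv, k in zip(intervals, keep) if k]


def _carriers(rng, n: int, dropout: float, min_frac: float) -> np.ndarray:
    """Indices of carrier samples; at least min_frac of n carry the peak."""
    max_drop = int(math.floor((1 - min_frac) * n))
    n_drop = min(int(rng.binomial(n, dropout)), max_drop)
    dropped = rng.choice(n, size=n_drop, replace=False) if n_drop else np.array([], int)
    mask = np.ones(n, dtype=bool)
    mask[dropped] = False
    return np.nonzero(mask)[0]


def _build_peaks(cfg: SynthConfig, lay: dict, rng: np.random.Generator):
    """Per (sample_id, assay) peak interval lists, plus shared structures."""
    genes = lay["genes"]
    promoters = [(g.chrom, max(0, g.start - 500) if g.strand == "+" else g.end - 501,
                  (g.start + 500) if g.strand == "+" else g.end + 500)
                 for g in genes.itertuples(index=False)]
    spacer_bodies = [(g.chrom, g.start, g.end)
                     for g in genes.itertuples(index=False) if g.role == "spacer"]
    regions = [(b["chrom"], rs, re) for b in lay["blocks"] for rs, re in b["regions"]]

    pops_chip = {"MM": [f"MM_{i + 1:02d}" for i in range(cfg.n_mm)]}
    for pop in BASELINE_POPULATIONS:
        pops_chip[pop] = [f"{pop}_{j + 1}" for j in range(cfg.n_normal_per_pop)]
    bmpc_ids = [f"bm-PC_{j + 1}" for j in range(cfg.n_normal_per_pop)]

    # carrier sets for planted regions (>= 80% of MM samples per mark)
    mm_ids = pops_chip["MM"]
    carrier: dict[tuple[int, str], np.ndarray] = {}
    for ridx in range(len(regions)):
        for mark in ("H3K27ac", "H3K4me1", "ATAC"):
            carrier[(ridx, mark)] = _carriers(rng, cfg.n_mm, cfg.peak_dropout, 0.8)

    # MM presence of planted loss peaks is rare (spurious-level)
    loss_mm_presence = rng.random((len(lay["loss_peaks"]), cfg.n_mm)) < 0.05

    peaks: dict[tuple[str, str], list] = {}

    def base_peaks(mark: str, population: str) -> list:
        """Peaks every sample of this population shares, before dropout."""
        out = []
        if mark in ("H3K4me3", "ATAC"):
            out += promoters
        if mark == "H3K36me3":
            out += spacer_bodies
        if mark in ("H3K27ac", "H3K4me1"):
            out += lay["bg_peaks"]
            if population != "MM" or mark == "H3K4me1":
                out += lay["loss_peaks"]  # lost in MM for H3K27ac only
        if mark == "H3K27me3":
            out += lay["rep_blocks"][::2]
        if mark == "H3K9me3":
            out += lay["rep_blocks"][1::2]
        return out

    marks = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K36me3", "H3K27me3", "H3K9me3", "ATAC")
    for mark in marks:
        for pop, ids in pops_chip.items():
            shared = base_peaks(mark, pop)
            for si, sid in enumerate(ids):
                ivs = _drop(shared, rng, cfg.peak_dropout)
                if pop == "MM":
                    if mark in ("H3K27ac", "H3K4me1", "ATAC"):
                        ivs += [regions[r] for r in range(len(regions))
                                if si in carrier[(r, mark)]]
                    if mark == "H3K27ac":
                        ivs += [lp for li, lp in enumerate(lay["loss_peaks"])
                                if loss_mm_presence[li, si]]
                n_spur = int(rng.binomial(max(cfg.n_background_peaks, 1),
                                          cfg.spurious_rate))
                if n_spur and lay["spurious_pool"]:
                    picks = rng.choice(len(lay["spurious_pool"]),
                                       size=min(n_spur, len(lay["spurious_pool"])),
                                       replace=False)
                    ivs += [lay["spurious_pool"][i] for i in picks]
                peaks[(sid, mark)] = _jitter(sorted(set(ivs)), rng, cfg.peak_jitter)
    # bm-PC: H3K27ac only (multiple marks infeasible for this population)
    shared = base_peaks("H3K27ac", "bm-PC")
    for sid in bmpc_ids:
        ivs = _drop(shared, rng, cfg.peak_dropout)
        peaks[(sid, "H3K27ac")] = _jitter(sorted(set(ivs)), rng, cfg.peak_jitter)

    return peaks, pops_chip, bmpc_ids, regions, carrier


# --------------------------------------------------------------- driver

def generate_dataset(cfg: SynthConfig, out_dir: str | Path) -> TruthManifest:
    """Emit the full dataset into out_dir and return the truth manifest."""
    cfg.validate()
    out = Path(out_dir)
    for sub in ("peaks", "signal", "methylation"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    rngs = {name: np.random.default_rng(np.random.SeedSequence([cfg.seed, k]))
            for k, name in enumerate(
                ["layout", "peaks", "signal", "meth", "expr", "seq"])}

    lay = _layout(cfg, rngs["layout"])
    peaks, pops_chip, bmpc_ids, regions, carrier = _build_peaks(
        cfg, lay, rngs["peaks"])

    manifest = TruthManifest(config=_config_dict(cfg))

    # --- truth bookkeeping -------------------------------------------
    ridx = 0
    tad_of: dict[int, str] = {}
    super_of: dict[int, bool] = {}
    for b in lay["blocks"]:
        for rs, re_ in b["regions"]:
            manifest.planted_denovo.append({
                "chrom": b["chrom"], "start": rs, "end": re_,
                "target_genes": b["genes"],
                "is_super": bool(b.get("is_super", False)),
            })
            key = f"{b['chrom']}:{rs}-{re_}"
            manifest.planted_state_changes[key] = ["LowSignal", "ActiveEnh"]
            super_of[ridx] = bool(b.get("is_super", False))
            ridx += 1
        if b["kind"] in ("pair", "triplet"):
            manifest.planted_pairs.append({"genes": b["genes"], "r": cfg.pair_r})
        elif b["kind"] == "bgpair":
            manifest.background_pairs.append({"genes": b["genes"]})
    for chrom, s, e in lay["loss_peaks"]:
        manifest.planted_loss.append({"chrom": chrom, "start": s, "end": e})
        manifest.planted_state_changes[f"{chrom}:{s}-{e}"] = ["ActiveEnh", "WeakEnh"]
    for chrom, s, e in lay["rep_blocks"]:
        manifest.planted_hypo_blocks.append({
            "chrom": chrom, "start": s, "end": e,
            "beta_normal": cfg.beta_repressed_normal,
            "beta_mm": cfg.beta_repressed_mm,
        })

    # --- hard constraint: no normal peak touches a planted region ----
    planted = manifest.denovo_intervals()
    if len(planted):
        from .intervals import count_overlaps
        for (sid, mark), ivs in peaks.items():
            if sid.startswith("MM_"):
                continue
            _, bp = count_overlaps(planted, IntervalSet.from_records(ivs))
            if bp.sum() > 0:
                raise AssertionError(
                    f"generator bug: normal sample {sid}/{mark} peak overlaps "
                    "a planted de novo region")

    # --- write peaks + sample sheet ----------------------------------
    sheet_rows = []
    for (sid, mark), ivs in sorted(peaks.items()):
        rel = f"peaks/{mark}_{sid}.bed"
        mio.write_bed(IntervalSet.from_records(ivs), out / rel)
        pop = "MM" if sid.startswith("MM_") else sid.rsplit("_", 1)[0]
        signal_rel = (f"signal/{sid}.bedgraph"
                      if (mark == "H3K27ac" and pop == "MM") else "")
        sheet_rows.append((sid, pop, mark, rel, signal_rel))

    # --- signal tracks (MM H3K27ac) ----------------------------------
    rng = rngs["signal"]
    amp_of_region = {r: (40.0 if super_of[r] else 6.0) for r in range(len(regions))}
    region_pos = {(c, s, e): i for i, (c, s, e) in enumerate(regions)}
    for si, sid in enumerate(pops_chip.get("MM", [])):
        ivs = peaks[(sid, "H3K27ac")]
        rows = []
        for chrom, s, e in ivs:
            base = 3.0
            for (rc, rs, re_), i in region_pos.items():
                if rc == chrom and abs(rs - s) <= 2 * cfg.peak_jitter:
                    base = amp_of_region[i]
                    break
            value = base * float(rng.lognormal(0, 0.25))
            rows.append((chrom, s, e, round(value, 4)))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        df = df.sort_values(["chrom", "start"])
        mio.write_bedgraph(df, out / "signal" / f"{sid}.bedgraph")

    # --- methylation -------------------------------------------------
    meth_samples = [(f"MM_W{j + 1}", "MM") for j in range(cfg.n_mm_wgbs)]
    for pop in list(BASELINE_POPULATIONS) + ["bm-PC"]:
        meth_samples += [(f"{pop}_W{j + 1}", pop)
                         for j in range(cfg.n_normal_wgbs_per_pop)]
    cpgs = _plan_cpgs(cfg, lay, regions, rngs["meth"], manifest)
    for sid, pop in meth_samples:
        _write_methylation_sample(cfg, cpgs, sid, pop, rngs["meth"], out)
        sheet_rows.append((sid, pop, "WGBS", f"methylation/{sid}.tsv", ""))

    # --- expression --------------------------------------------------
    expr, rna_rows = _build_expression(cfg, lay, rngs["expr"])
    mio.write_expression(expr, out / "expression.tsv")
    sheet_rows += rna_rows

    # --- sequences + PWM ---------------------------------------------
    seqs, motif_positions = _build_sequences(cfg, regions, rngs["seq"])
    mio.write_fasta(seqs, out / "regions.fa")
    pwm = _consensus_pwm()
    mio.write_meme_pwms([pwm], out / "motifs.meme")

    # --- static annotation files -------------------------------------
    genes_df = lay["genes"][["gene_id", "gene_name", "chrom", "start", "end", "strand"]]
    genes_df.to_csv(out / "genes.tsv", sep="\t", index=False)
    lay["tads"].to_csv(out / "tads.bed", sep="\t", header=False, index=False)
    mio.write_chrom_sizes(lay["lengths"], out / "chrom_sizes.tsv")
    sheet = pd.DataFrame(
        sheet_rows,
        columns=["sample_id", "population", "assay", "path", "signal_path"],
    ).sort_values(["assay", "population", "sample_id"])
    sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)

    manifest.save(out / "truth.json")
    return manifest


def _config_dict(cfg: SynthConfig) -> dict:
    d = asdict(cfg)
    d["chroms"] = [list(c) for c in cfg.chroms]
    return d


def _consensus_pwm(p: float = 0.94) -> PWM:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.full((len(MOTIF_CONSENSUS), 4), (1 - p) / 3)
    for i, base in enumerate(MOTIF_CONSENSUS):
        mat[i, idx[base]] = p
    return PWM("SYNTH_TF", mat, np.full(4, 0.25))


def _plan_cpgs(cfg, lay, regions, rng, manifest) -> pd.DataFrame:
    """Global CpG site list with per-group target means."""
    rows = []  # chrom, pos, mean_normal, mean_mm
    L = len(MOTIF_CONSENSUS)
    for chrom, rs, re_ in regions:
        center = (rs + re_) // 2
        mstart = center - L // 2
        hypo_pos = [mstart + 4, mstart - 6, mstart + L + 5]
        for p in hypo_pos:
            rows.append((chrom, int(p), cfg.beta_active_normal, cfg.beta_active_mm))
            manifest.planted_hypo_cpgs.append({
                "chrom": chrom, "pos": int(p),
                "beta_normal": cfg.beta_active_normal,
                "beta_mm": cfg.beta_active_mm,
            })
        offs = rng.integers(-cfg.profile_flank, cfg.profile_flank,
                            size=cfg.profile_cpg_per_region)
        for off in offs:
            pos = int(center + off)
            if abs(off) <= 100:
                mm = cfg.beta_active_mm
            else:
                mm = cfg.beta_shoulder_mm
            rows.append((chrom, pos, cfg.beta_active_normal, mm))
    for chrom, s, e in lay["rep_blocks"]:
        for pos in rng.integers(s, e, size=30):
            rows.append((chrom, int(pos), cfg.beta_repressed_normal,
                         cfg.beta_repressed_mm))
    for chrom, length in lay["lengths"].items():
        lo, hi = int(0.52 * length), int(0.78 * length)
        for pos in rng.integers(lo, hi, size=1000):
            rows.append((chrom, int(pos), cfg.beta_background, cfg.beta_background))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "mean_normal", "mean_mm"])
    return df.drop_duplicates(["chrom", "pos"]).sort_values(["chrom", "pos"])


def _write_methylation_sample(cfg, cpgs, sid, pop, rng, out: Path) -> None:
    mean = cpgs["mean_mm"] if pop == "MM" else cpgs["mean_normal"]
    c = cfg.beta_concentration
    a = np.maximum(mean.to_numpy() * c, 1e-3)
    b = np.maximum((1 - mean.to_numpy()) * c, 1e-3)
    beta = rng.beta(a, b)
    cov = rng.poisson(cfg.coverage_mean, size=len(cpgs))
    df = pd.DataFrame({
        "chrom": cpgs["chrom"].to_numpy(),
        "pos": cpgs["pos"].to_numpy(),
        "beta": np.round(beta, 4),
        "coverage": cov,
    })
    mio.write_methylation(df, out / "methylation" / f"{sid}.tsv")


def _build_expression(cfg, lay, rng):
    """Log-normal abundance matrix with planted fold changes and latents."""
    genes = lay["genes"]
    n = len(genes)
    base = rng.lognormal(np.log(50), 0.6, size=n)
    low = rng.lognormal(np.log(8), 0.4, size=n)
    is_target = (genes["role"] != "spacer").to_numpy()

    rna = [(f"MM_R{j + 1:02d}", "MM") for j in range(cfg.n_rna_mm)]
    for pop in list(BASELINE_POPULATIONS) + ["bm-PC"]:
        rna += [(f"{pop}_R{j + 1}", pop) for j in range(cfg.n_rna_normal_per_pop)]
    sample_ids = [s for s, _ in rna]
    pops = [p for _, p in rna]

    mean = np.empty((n, len(rna)))
    for j, pop in enumerate(pops):
        if pop == "MM":
            mean[:, j] = np.where(is_target, low * cfg.mm_fold, base)
        else:
            mean[:, j] = np.where(is_target, low, base)

    sigma = cfg.expression_cv
    noise = rng.normal(0, 1, size=(n, len(rna)))
    # shared latent factor across MM samples for coexpressed groups
    mm_cols = [j for j, p in enumerate(pops) if p == "MM"]
    gene_row = {g: i for i, g in enumerate(genes["gene_id"])}
    for b in lay["blocks"]:
        if b["kind"] not in ("pair", "triplet"):
            continue
        z = rng.normal(0, 1, size=len(mm_cols))
        w = math.sqrt(cfg.pair_r)
        for g in b["genes"]:
            i = gene_row[g]
            noise[i, mm_cols] = (w * z
                                 + math.sqrt(1 - cfg.pair_r) * noise[i, mm_cols])
    values = mean * np.exp(sigma * noise - 0.5 * sigma ** 2)
    expr = pd.DataFrame(np.round(values, 4), index=genes["gene_id"],
                        columns=sample_ids)
    rows = [(s, p, "RNA", "expression.tsv", "") for s, p in rna]
    return expr, rows


def _build_sequences(cfg, regions, rng):
    """Per-region FASTA with the motif consensus planted at the center."""
    bases = np.array(list("ACGT"))
    L = len(MOTIF_CONSENSUS)
    rc = MOTIF_CONSENSUS.translate(_COMP)[::-1]
    seqs: dict[str, str] = {}
    motif_positions = []
    for chrom, rs, re_ in regions:
        n = re_ - rs
        seq = bases[rng.integers(0, 4, size=n)]
        s = "".join(seq)
        # scrub chance occurrences of the motif on either strand
        for pattern in (MOTIF_CONSENSUS, rc):
            while True:
                k = s.find(pattern)
                if k < 0:
                    break
                repl = "".join(bases[rng.integers(0, 4, size=L)])
                s = s[:k] + repl + s[k + L:]
        center = (rs + re_) // 2
        off = center - L // 2 - rs
        s = s[:off] + MOTIF_CONSENSUS + s[off + L:]
        seqs[f"{chrom}:{rs}-{re_}"] = s
        motif_positions.append((chrom, rs + off, rs + off + L))
    return seqs, motif_positions
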
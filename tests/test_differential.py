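"""Consensus peaks, stable baseline, gain/loss calls, annotation."""

import numpy as np
import pandas as pd
import pytest

from mmepi import io as mio
from mmepi.differential import (
    DifferentialRegionSet, annotate_differential, build_consensus,
    call_differential, stable_baseline,
)
from mmepi.evaluate import block_hypomethylation, region_recovery
from mmepi.intervals import IntervalSet
from mmepi.tables import BASELINE_POPULATIONS, MethylationTable, SampleTable

from conftest import intervals_of, mask_of, random_intervals

GENOME = {"chr1": 100_000}


def _sets(*interval_lists):
    return [IntervalSet.from_records(ivs) for ivs in interval_lists]


class TestConsensus:
    def test_unanimous_identical_peaks(self):
        peaks = _sets(*[[("chr1", 100, 200), ("chr1", 500, 600)]] * 3)
        cons = build_consensus(peaks, min_frac=1.0)
        assert [(iv.start, iv.end) for iv in cons.intervals] == [(100, 200), (500, 600)]
        np.testing.assert_allclose(cons.support, [1.0, 1.0])

    def test_disjoint_peaks_below_threshold(self):
        peaks = _sets([("chr1", 0, 100)], [("chr1", 200, 300)])
        assert len(build_consensus(peaks, min_frac=0.6).intervals) == 0

    def test_empty_sample_list_rejected(self):
        with pytest.raises(ValueError):
            build_consensus([], 0.5)

    @pytest.mark.parametrize("min_frac", [0.3, 0.5, 1.0])
    def test_random_matches_base_vote_oracle(self, min_frac):
        rng = np.random.default_rng(21)
        k = 5
        peaks = [random_intervals(rng, 40, GENOME["chr1"], max_len=800)
                 for _ in range(k)]
        cons = build_consensus(peaks, min_frac)
        votes = np.zeros(GENOME["chr1"], dtype=int)
        for p in peaks:
            votes += mask_of(p.merge(), GENOME["chr1"])
        need = int(np.ceil(min_frac * k - 1e-9))
        assert cons.intervals == intervals_of(votes >= need)


class TestStableBaseline:
    def _consensus(self, by_pop):
        return {p: build_consensus(_sets(ivs), 1.0, p, "H3K27ac")
                for p, ivs in by_pop.items()}

    def test_shared_peak_everywhere(self):
        cons = self._consensus({p: [("chr1", 0, 100)] for p in BASELINE_POPULATIONS})
        present, absent = stable_baseline(cons, GENOME)
        assert [(iv.start, iv.end) for iv in present] == [(0, 100)]
        assert [(iv.start, iv.end) for iv in absent] == [(100, GENOME["chr1"])]

    def test_four_of_five_is_unstable(self):
        by_pop = {p: [("chr1", 0, 100)] for p in BASELINE_POPULATIONS[:-1]}
        by_pop[BASELINE_POPULATIONS[-1]] = [("chr1", 50_000, 50_100)]
        present, absent = stable_baseline(self._consensus(by_pop), GENOME)
        pm = mask_of(present, GENOME["chr1"])
        am = mask_of(absent, GENOME["chr1"])
        assert not pm[:100].any() and not am[:100].any()

    def test_missing_population_reported(self):
        cons = self._consensus({p: [("chr1", 0, 10)] for p in BASELINE_POPULATIONS[:3]})
        with pytest.raises(ValueError, match="MBC|t-PC"):
            stable_baseline(cons, GENOME)

    def test_random_matches_and_nor_oracle(self):
        rng = np.random.default_rng(22)
        by_pop = {p: random_intervals(rng, 30, GENOME["chr1"], max_len=600)
                  for p in BASELINE_POPULATIONS}
        cons = {p: build_consensus([s], 1.0, p, "x") for p, s in by_pop.items()}
        present, absent = stable_baseline(cons, GENOME)
        masks = np.array([mask_of(s.merge(), GENOME["chr1"]) for s in by_pop.values()])
        assert present == intervals_of(masks.all(axis=0))
        assert absent == intervals_of(~masks.any(axis=0))


class TestCallDifferential:
    def _baseline(self, normal_ivs):
        cons = {p: build_consensus(_sets(normal_ivs), 1.0, p, "m")
                for p in BASELINE_POPULATIONS}
        return stable_baseline(cons, GENOME)

    def test_mm_identical_to_normal_yields_nothing(self):
        ivs = [("chr1", 1_000, 2_000)]
        present, absent = self._baseline(ivs)
        gain, loss = call_differential("m", _sets(*[ivs] * 5), present, absent, GENOME)
        assert len(gain) == 0 and len(loss) == 0

    def test_private_recurrent_peak_is_one_gain(self):
        present, absent = self._baseline([("chr1", 90_000, 91_000)])
        mm_ivs = [[("chr1", 5_000, 6_000)]] * 9 + [[("chr1", 50_000, 50_500)]]
        gain, _ = call_differential("m", _sets(*mm_ivs), present, absent,
                                    GENOME, min_mm_frac=0.8)
        assert [(iv.start, iv.end) for iv in gain.regions] == [(5_000, 6_000)]
        assert gain.annotations["mm_support"].iloc[0] == pytest.approx(0.9)

    def test_loss_requires_near_absence_in_mm(self):
        present, absent = self._baseline([("chr1", 10_000, 11_000)])
        # 3 of 10 MM samples still carry the peak: loss at min_mm_frac=0.66
        mm_ivs = [[("chr1", 10_000, 11_000)]] * 3 + [[("chr1", 90_000, 90_100)]] * 7
        gain, loss = call_differential("m", _sets(*mm_ivs), present, absent, GENOME)
        assert [(iv.start, iv.end) for iv in loss.regions] == [(10_000, 11_000)]
        # 4 of 10 carriers: no longer a loss
        mm_ivs = [[("chr1", 10_000, 11_000)]] * 4 + [[("chr1", 90_000, 90_100)]] * 6
        _, loss = call_differential("m", _sets(*mm_ivs), present, absent, GENOME)
        assert len(loss) == 0

    def test_gains_and_losses_are_disjoint(self):
        rng = np.random.default_rng(23)
        normal = random_intervals(rng, 30, GENOME["chr1"], max_len=700)
        cons = {p: build_consensus([normal], 1.0, p, "m") for p in BASELINE_POPULATIONS}
        present, absent = stable_baseline(cons, GENOME)
        mm = [random_intervals(rng, 30, GENOME["chr1"], max_len=700) for _ in range(6)]
        gain, loss = call_differential("m", mm, present, absent, GENOME,
                                       min_region_bp=1)
        gm = mask_of(gain.regions, GENOME["chr1"])
        lm = mask_of(loss.regions, GENOME["chr1"])
        assert not (gm & lm).any()

    def test_raising_min_mm_frac_never_adds_gains(self):
        rng = np.random.default_rng(24)
        present, absent = self._baseline([("chr1", 95_000, 96_000)])
        mm = [random_intervals(rng, 20, 90_000, max_len=500) for _ in range(8)]
        counts = []
        for frac in (0.25, 0.5, 0.75, 1.0):
            gain, _ = call_differential("m", mm, present, absent, GENOME,
                                        min_mm_frac=frac, min_region_bp=1)
            counts.append(len(gain))
        assert counts == sorted(counts, reverse=True)

    def test_no_mm_samples_rejected(self):
        present, absent = self._baseline([("chr1", 0, 10)])
        with pytest.raises(ValueError):
            call_differential("m", [], present, absent, GENOME)


class TestAnnotate:
    def _samples(self):
        rows = [("mm1", "MM", "ATAC", ""), ("mm2", "MM", "ATAC", ""),
                ("n1", "GCBC", "ATAC", ""),
                ("w_mm", "MM", "WGBS", ""), ("w_n", "t-PC", "WGBS", "")]
        return SampleTable(pd.DataFrame(
            rows, columns=["sample_id", "population", "assay", "path"]))

    def test_zero_atac_and_cpg_mean(self):
        regions = IntervalSet.from_records([("chr1", 1_000, 2_000)])
        diff = DifferentialRegionSet("H3K27ac", "gain", regions)
        meth = MethylationTable({
            "w_mm": pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [1100, 1200, 1300],
                                  "beta": [0.2, 0.4, 0.6], "coverage": [30] * 3}),
            "w_n": pd.DataFrame({"chrom": ["chr1"], "pos": [1100],
                                 "beta": [0.9], "coverage": [30]}),
        })
        ann = annotate_differential(
            diff, self._samples(),
            {"mm1": IntervalSet(), "mm2": IntervalSet(), "n1": IntervalSet()},
            meth, None, None)
        row = ann.annotations.iloc[0]
        assert row["atac_fraction_mm"] == 0 and row["atac_fraction_normal"] == 0
        assert row["medmeth_mm"] == pytest.approx(0.4)
        assert row["medmeth_normal"] == pytest.approx(0.9)

    def test_region_without_cpgs_is_nan(self):
        regions = IntervalSet.from_records([("chr1", 5_000, 6_000)])
        diff = DifferentialRegionSet("H3K27ac", "gain", regions)
        meth = MethylationTable({
            "w_mm": pd.DataFrame({"chrom": ["chr1"], "pos": [100],
                                  "beta": [0.5], "coverage": [30]}),
            "w_n": pd.DataFrame({"chrom": ["chr1"], "pos": [100],
                                 "beta": [0.5], "coverage": [30]}),
        })
        ann = annotate_differential(diff, self._samples(), {}, meth, None, None)
        assert np.isnan(ann.annotations["medmeth_mm"].iloc[0])

    def test_host_gene_by_midpoint(self, tmp_path):
        genes = pd.DataFrame({
            "gene_id": ["g1"], "gene_name": ["G"], "chrom": ["chr1"],
            "start": [1_000], "end": [3_000], "strand": ["+"]})
        genes.to_csv(tmp_path / "g.tsv", sep="\t", index=False)
        ga = mio.read_gene_annotation(tmp_path / "g.tsv")
        inside = DifferentialRegionSet("m", "gain", IntervalSet.from_records(
            [("chr1", 2_500, 4_000)]))  # midpoint 3250 outside body
        ann = annotate_differential(inside, self._samples(), {}, None, ga, None)
        assert ann.annotations["host_gene"].iloc[0] == ""
        inside = DifferentialRegionSet("m", "gain", IntervalSet.from_records(
            [("chr1", 1_500, 2_500)]))  # midpoint 2000 inside body
        ann = annotate_differential(inside, self._samples(), {}, None, ga, None)
        assert ann.annotations["host_gene"].iloc[0] == "g1"

    def test_planted_repressed_blocks_hypomethylated(self, default_dataset):
        """MM methylation drops in >=90% of planted repressed blocks."""
        ds_dir, manifest = default_dataset
        samples = mio.read_sample_sheet(ds_dir / "sample_sheet.tsv")
        meth = mio.load_methylation(samples, ds_dir)
        blocks = IntervalSet.from_records(
            [(b["chrom"], b["start"], b["end"]) for b in manifest.planted_hypo_blocks])
        diff = DifferentialRegionSet("H3K27me3", "gain", blocks)
        ann = annotate_differential(diff, samples, {}, meth, None, None)
        assert block_hypomethylation(ann.annotations, manifest) >= 0.9


def test_planted_gain_recovery(pipeline_run):
    """Differential H3K27ac gains recover the planted regions."""
    run_dir, report, manifest = pipeline_run
    gains = mio.read_bed(run_dir / "differential" / "H3K27ac_gain.bed")
    precision, recall = region_recovery(gains, manifest.denovo_intervals())
    assert precision >= 0.95 and recall >= 0.95
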
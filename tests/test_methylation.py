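"""PWM scanning and motif-anchored methylation analysis."""

import numpy as np
import pandas as pd
import pytest

from mmepi.methylation import composite_profile, cpg_differential
from mmepi.motifs import PWM, MotifHit, scan_pwm
from mmepi.tables import MethylationTable, SampleTable

_COMP = str.maketrans("ACGT", "TGCA")


def _pwm(consensus: str, p: float = 0.97) -> PWM:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        mat[i, idx[b]] = p
    return PWM("TF", mat)


def scan_oracle(seq: str, pwm: PWM, score_frac: float):
    """Exhaustive per-window scoring on both strands."""
    bg = pwm.background
    thr = score_frac * pwm.max_score()
    hits = []
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for strand in "+-":
        mat = pwm.matrix if strand == "+" else pwm.matrix[::-1, ::-1]
        b = bg if strand == "+" else bg[::-1]
        for off in range(len(seq) - len(pwm) + 1):
            window = seq[off:off + len(pwm)]
            score = 0.0
            for i, base in enumerate(window):
                if base not in idx:
                    score = -np.inf
                    break
                score += np.log(mat[i, idx[base]] / b[idx[base]])
            if score >= thr:
                hits.append((off, strand, score))
    return hits


class TestScanPwm:
    def test_maximal_match_single_plus_hit(self):
        pwm = _pwm("AAAAAA")
        hits = scan_pwm({"s": "AAAAAA"}, pwm)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (0, 6, "+")

    def test_mismatching_sequence_no_hit(self):
        assert scan_pwm({"s": "CCCCCC"}, _pwm("AAAAAA")) == []

    def test_sequence_shorter_than_motif(self):
        assert scan_pwm({"s": "AAA"}, _pwm("AAAAAA")) == []

    def test_genomic_coordinates_from_header(self):
        pwm = _pwm("ACGTAC")
        hits = scan_pwm({"chr2:1000-1010": "ACGTACGTAC"}, pwm)
        assert hits[0].chrom == "chr2" and hits[0].start == 1000

    def test_n_bases_never_match(self):
        assert scan_pwm({"s": "AANAAA"}, _pwm("AAAAAA")) == []

    def test_random_sequence_matches_window_oracle(self):
        rng = np.random.default_rng(41)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2_000)])
        mat = rng.dirichlet(np.ones(4) * 0.3, size=8)
        pwm = PWM("R", mat)
        hits = scan_pwm({"s": seq}, pwm, score_frac=0.8)
        expected = scan_oracle(seq, pwm, 0.8)
        assert [(h.start, h.strand) for h in hits] == \
            sorted((o, s) for o, s, _ in expected)
        exp_scores = {(o, s): sc for o, s, sc in expected}
        for h in hits:
            assert h.score == pytest.approx(exp_scores[(h.start, h.strand)],
                                            abs=1e-12)

    def test_strand_symmetry_under_reverse_complement(self):
        rng = np.random.default_rng(42)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
        pwm = _pwm("TTGACGCA", p=0.9)
        fwd = scan_pwm({"s": seq}, pwm, score_frac=0.75)
        rc = seq.translate(_COMP)[::-1]
        rev = scan_pwm({"s": rc}, pwm, score_frac=0.75)
        n, L = len(seq), len(pwm)
        mirrored = sorted((n - h.end, "+-"[h.strand == "+"]) for h in fwd)
        assert mirrored == sorted((h.start, h.strand) for h in rev)

    def test_invalid_score_frac(self):
        with pytest.raises(ValueError):
            scan_pwm({}, _pwm("AAAA"), score_frac=0.0)


def _meth_setup(betas_by_sample):
    """Two-group methylation fixture around one hit at [100, 108)."""
    hit = MotifHit("TF", "chr1", 100, 108, "+", 5.0)
    data = {}
    rows = []
    for sid, pop, betas in betas_by_sample:
        data[sid] = pd.DataFrame({
            "chrom": "chr1", "pos": list(betas),
            "beta": list(betas.values()), "coverage": 30})
        rows.append((sid, pop, "WGBS", ""))
    samples = SampleTable(pd.DataFrame(
        rows, columns=["sample_id", "population", "assay", "path"]))
    return [hit], MethylationTable(data), samples


class TestCpGDifferential:
    def test_identical_groups_null(self):
        betas = {104: 0.7, 110: 0.7}
        hits, meth, samples = _meth_setup([
            ("m1", "MM", betas), ("n1", "GCBC", betas)])
        rows, frac = cpg_differential(hits, meth, samples)
        assert all(r.delta == 0 for r in rows)
        assert frac == 0.0

    def test_threshold_arithmetic(self):
        hits, meth, samples = _meth_setup([
            ("m1", "MM", {104: 0.5}), ("n1", "GCBC", {104: 0.8})])
        rows, frac = cpg_differential(hits, meth, samples)
        assert rows[0].delta == pytest.approx(-0.3)
        assert rows[0].hypo_in_mm and frac == 1.0

    def test_flank_bounds_inclusion(self):
        betas_mm = {89: 0.1, 90: 0.1, 117: 0.1, 118: 0.1}
        betas_n = {k: 0.9 for k in betas_mm}
        hits, meth, samples = _meth_setup([
            ("m1", "MM", betas_mm), ("n1", "GCBC", betas_n)])
        rows, _ = cpg_differential(hits, meth, samples, motif_flank=10)
        # window is [90, 118): 89 and 118 fall outside
        assert [r.pos for r in rows] == [90, 117]

    def test_coverage_filter_drops_low_cpgs(self):
        hits, meth, samples = _meth_setup([
            ("m1", "MM", {104: 0.5}), ("n1", "GCBC", {104: 0.8})])
        meth.data["m1"].loc[:, "coverage"] = 2
        meth._index.clear()
        rows, frac = cpg_differential(hits, meth, samples, min_cov=5)
        assert rows == [] and np.isnan(frac)

    def test_sample_order_invariance(self):
        rows = [("m1", "MM", {104: 0.4}), ("m2", "MM", {104: 0.2}),
                ("n1", "GCBC", {104: 0.9}), ("n2", "t-PC", {104: 0.7})]
        _, frac1 = cpg_differential(*_meth_setup(rows))
        _, frac2 = cpg_differential(*_meth_setup(rows[::-1]))
        assert frac1 == frac2


class TestCompositeProfile:
    def test_uniform_field_is_flat(self):
        betas = {100 + off: 0.7 for off in range(-300, 300, 40)}
        hits, meth, samples = _meth_setup([
            ("m1", "MM", betas), ("n1", "GCBC", betas)])
        prof = composite_profile(hits, meth, samples, flank=300, bin_bp=50,
                                 min_cpg=1)
        vals = prof["mean_beta"].dropna()
        assert np.allclose(vals, 0.7)

    def test_single_cpg_bins_at_offset_30(self):
        # hit [100,108): center 104; CpG at 134 -> offset +30 -> bin [0,50)
        hits, meth, samples = _meth_setup([
            ("m1", "MM", {134: 0.5}), ("n1", "GCBC", {134: 0.5})])
        prof = composite_profile(hits, meth, samples, flank=200, bin_bp=50,
                                 min_cpg=1)
        filled = prof[prof["n_cpg"] > 0]
        assert set(filled["bin_start"]) == {0}

    def test_sparse_bins_reported_na(self):
        hits, meth, samples = _meth_setup([
            ("m1", "MM", {134: 0.5}), ("n1", "GCBC", {134: 0.5})])
        prof = composite_profile(hits, meth, samples, flank=100, bin_bp=50,
                                 min_cpg=3)
        assert prof["mean_beta"].isna().all()

    def test_no_hits_rejected(self):
        _, meth, samples = _meth_setup([
            ("m1", "MM", {104: 0.5}), ("n1", "GCBC", {104: 0.5})])
        with pytest.raises(ValueError):
            composite_profile([], meth, samples)
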
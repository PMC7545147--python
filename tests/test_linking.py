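"""TAD assignment, target-gene linking, coregulated groups."""

import numpy as np
import pandas as pd
import pytest

from mmepi import io as mio
from mmepi.denovo import DeNovoRegion
from mmepi.evaluate import coexpression_recovery
from mmepi.linking import TADSet, assign_tad, find_coregulated, link_targets
from mmepi.intervals import IntervalSet
from mmepi.stats import DEResult, de_call
from mmepi.tables import ExpressionMatrix, GeneAnnotation


def _tads(*ivs):
    return TADSet(IntervalSet.from_records(ivs))


def _genes(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    df["gene_name"] = df["gene_id"]
    return GeneAnnotation(df)


def _de(up_genes, all_genes):
    table = pd.DataFrame({
        "gene_id": all_genes,
        "mean_a": 1.0, "mean_b": 10.0,
        "fold_change": [5.0 if g in up_genes else 1.0 for g in all_genes],
        "log2fc": 0.0,
        "p_value": 0.001, "q_value": [0.001 if g in up_genes else 0.9
                                      for g in all_genes],
        "is_de": [g in up_genes for g in all_genes],
    })
    return DEResult(table, 0.05, 1.5)


class TestAssignTad:
    def test_containment_and_midpoint_rule(self):
        tads = _tads(("chr1", 0, 10_000), ("chr1", 10_000, 20_000))
        inside = IntervalSet.from_records([("chr1", 2_000, 3_000)])
        assert assign_tad(inside, tads) == ["TAD_1"]
        straddle = IntervalSet.from_records([("chr1", 9_000, 10_500)])
        # midpoint 9750 on the left side
        assert assign_tad(straddle, tads) == ["TAD_1"]

    def test_gap_maps_to_none(self):
        tads = _tads(("chr1", 0, 1_000), ("chr1", 5_000, 6_000))
        s = IntervalSet.from_records([("chr1", 2_000, 3_000)])
        assert assign_tad(s, tads) == [None]

    def test_overlapping_tads_rejected(self):
        with pytest.raises(ValueError):
            _tads(("chr1", 0, 1_000), ("chr1", 500, 2_000))

    def test_random_against_scan_oracle(self):
        rng = np.random.default_rng(31)
        bounds = np.sort(rng.choice(100_000, size=40, replace=False))
        tad_ivs = [("chr1", int(s), int(e)) for s, e in zip(bounds[::2], bounds[1::2])]
        tads = _tads(*tad_ivs)
        regions = IntervalSet.from_records(
            [("chr1", int(p), int(p) + 100)
             for p in rng.integers(0, 99_800, size=200)])
        got = assign_tad(regions, tads)
        for iv, tid in zip(regions, got):
            mid = iv.midpoint
            expected = None
            for k, (_, s, e) in enumerate(tad_ivs):
                if s <= mid < e:
                    expected = f"TAD_{k + 1}"
            assert tid == expected


class TestLinkTargets:
    def _setup(self):
        tads = _tads(("chr1", 0, 50_000), ("chr1", 50_000, 100_000))
        genes = _genes([("gA", "chr1", 1_000, 5_000, "+"),
                       ("gB", "chr1", 60_000, 65_000, "+")])
        region = DeNovoRegion("chr1", 10_000, 11_000, 0.9)
        return tads, genes, region

    def test_tad_without_up_gene_yields_no_link(self):
        tads, genes, region = self._setup()
        de = {"GCBC": _de(set(), ["gA", "gB"]), "t-PC": _de(set(), ["gA", "gB"])}
        assert link_targets([region], tads, genes, de) == []

    def test_up_in_all_populations_required(self):
        tads, genes, region = self._setup()
        de = {"GCBC": _de({"gA"}, ["gA", "gB"]),
              "t-PC": _de(set(), ["gA", "gB"])}  # up in 1 of 2 only
        assert link_targets([region], tads, genes, de) == []
        de["t-PC"] = _de({"gA"}, ["gA", "gB"])
        links = link_targets([region], tads, genes, de)
        assert [l.gene_id for l in links] == ["gA"]
        assert links[0].same_tad and not links[0].fallback

    def test_fallback_window_outside_tads(self):
        tads = _tads(("chr1", 90_000, 95_000))
        genes = _genes([("gA", "chr1", 1_000, 5_000, "+")])
        region = DeNovoRegion("chr1", 10_000, 11_000, 0.9)
        de = {"GCBC": _de({"gA"}, ["gA"])}
        links = link_targets([region], tads, genes, de, fallback_window=100_000)
        assert len(links) == 1 and links[0].fallback
        # shrinking the window drops the link
        assert link_targets([region], tads, genes, de, fallback_window=1_000) == []


class TestFindCoregulated:
    def _annotation(self, n=4):
        return _genes([(f"g{i}", "chr1", i * 10_000, i * 10_000 + 5_000, "+")
                       for i in range(n)])

    def _expr(self, data):
        return pd.DataFrame(data)

    def test_boundary_r_excluded_strictly(self):
        rng = np.random.default_rng(32)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        expr = self._expr({"g0": x, "g1": y}).T
        from mmepi.stats import pearson_test
        r, _ = pearson_test(x, y)
        got = find_coregulated(["g0", "g1"], self._annotation(2), expr, r_min=r)
        assert got == []
        got = find_coregulated(["g0", "g1"], self._annotation(2), expr,
                               r_min=r - 1e-9, p_max=1.0)
        assert len(got) == (1 if r > 0 else 0)

    def test_chained_pairs_merge_to_triplet(self):
        rng = np.random.default_rng(33)
        z = rng.normal(size=30)
        expr = self._expr({
            "g0": z + rng.normal(0, 0.1, 30),
            "g1": z + rng.normal(0, 0.1, 30),
            "g2": z + rng.normal(0, 0.1, 30),
        }).T
        groups = find_coregulated(["g0", "g1", "g2"], self._annotation(3), expr)
        assert len(groups) == 1
        assert groups[0].genes == ["g0", "g1", "g2"]
        assert len(groups[0].pair_r) == 2

    def test_intervening_gene_breaks_adjacency(self):
        rng = np.random.default_rng(34)
        z = rng.normal(size=30)
        expr = self._expr({
            "g0": z + rng.normal(0, 0.1, 30),
            "g2": z + rng.normal(0, 0.1, 30),
        }).T
        # g1 exists in the annotation between them but is not a target
        groups = find_coregulated(["g0", "g2"], self._annotation(3), expr)
        assert groups == []
        # ... unless adjacency is computed within the target list
        groups = find_coregulated(["g0", "g2"], self._annotation(3), expr,
                                  adjacency="target")
        assert len(groups) == 1

    def test_constant_vector_skipped(self):
        expr = self._expr({"g0": np.ones(10), "g1": np.arange(10.0)}).T
        groups = find_coregulated(["g0", "g1"], self._annotation(2), expr)
        assert groups == []

    def test_too_few_samples_rejected(self):
        expr = self._expr({"g0": [1, 2], "g1": [2, 1]}).T
        with pytest.raises(ValueError):
            find_coregulated(["g0", "g1"], self._annotation(2), expr)

    def test_planted_recovery_with_clean_background(self, pipeline_run):
        run_dir, report, manifest = pipeline_run
        groups = pd.read_csv(run_dir / "linking" / "coexpression_groups.tsv", sep="\t")
        reported = [g.split(",") for g in groups["genes"]]
        recall, background = coexpression_recovery(reported, manifest)
        assert recall >= 0.9
        assert background == 0


def test_links_stable_under_sample_order_permutation(default_dataset):
    """DE-driven linking does not depend on expression column order."""
    ds_dir, manifest = default_dataset
    samples = mio.read_sample_sheet(ds_dir / "sample_sheet.tsv")
    expr = mio.read_expression(ds_dir / "expression.tsv", samples)
    genes = mio.read_gene_annotation(ds_dir / "genes.tsv")
    tads = TADSet(mio.read_bed(ds_dir / "tads.bed"))
    regions = [DeNovoRegion(d["chrom"], d["start"], d["end"], 1.0)
               for d in manifest.planted_denovo[:30]]
    rng = np.random.default_rng(35)
    perm = expr.values.columns.to_numpy()[rng.permutation(expr.values.shape[1])]
    expr2 = ExpressionMatrix(expr.values[perm], expr.populations)
    de1 = {p: de_call(expr, p, "MM") for p in ("GCBC", "bm-PC")}
    de2 = {p: de_call(expr2, p, "MM") for p in ("GCBC", "bm-PC")}
    l1 = link_targets([DeNovoRegion(r.chrom, r.start, r.end, 1.0)
                       for r in regions], tads, genes, de1)
    l2 = link_targets([DeNovoRegion(r.chrom, r.start, r.end, 1.0)
                       for r in regions], tads, genes, de2)
    assert [(l.region_id, l.gene_id) for l in l1] == \
        [(l.region_id, l.gene_id) for l in l2]
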
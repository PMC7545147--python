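"""Shared fixtures: the default synthetic dataset, one full pipeline
run over it, and base-wise oracle helpers used by several suites."""

from __future__ import annotations

import numpy as np
import pytest

from mmepi.intervals import IntervalSet
from mmepi.pipeline import PipelineConfig, run_pipeline
from mmepi.simulate import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The default study-condition dataset (fixed seed)."""
    out = tmp_path_factory.mktemp("dataset")
    manifest = generate_dataset(SynthConfig(seed=0), out)
    return out, manifest


@pytest.fixture(scope="session")
def pipeline_run(default_dataset, tmp_path_factory):
    """One full pipeline run over the default dataset."""
    ds_dir, manifest = default_dataset
    out = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig(dataset_dir=str(ds_dir), out_dir=str(out))
    report = run_pipeline(cfg)
    return out, report, manifest


# ------------------------------------------------- base-wise oracles

def mask_of(intervals: IntervalSet, length: int, chrom: str = "chr1") -> np.ndarray:
    """Boolean genome mask of covered bases on one chromosome."""
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            mask[iv.start:iv.end] = True
    return mask


def intervals_of(mask: np.ndarray, chrom: str = "chr1") -> IntervalSet:
    """Inverse of mask_of: maximal runs of True."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return IntervalSet.from_records(
        [(chrom, int(s), int(e)) for s, e in zip(starts, ends)]
    )


def random_intervals(rng: np.random.Generator, n: int, length: int,
                     max_len: int = 2_000, chrom: str = "chr1") -> IntervalSet:
    starts = rng.integers(0, length - max_len, size=n)
    lens = rng.integers(1, max_len, size=n)
    return IntervalSet.from_records(
        [(chrom, int(s), int(s + l)) for s, l in zip(starts, lens)]
    )
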
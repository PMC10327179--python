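"""Shared fixtures: one default synthetic data set and the pipeline
results derived from it, computed once per session."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from pioneerscan.dyads import NucleosomeRegionSet, call_dyads, call_ndrs
from pioneerscan.scan import (
    MotifHit,
    assign_hits_to_dyads,
    merge_tf_hits,
    pfm_to_pwm,
    scan_peaks,
)
from pioneerscan.simulate import Fixture, make_fixture


@pytest.fixture(scope="session")
def default_fixture() -> Fixture:
    return make_fixture(seed=11)


@dataclass
class PipelineResult:
    fixture: Fixture
    nr_set: NucleosomeRegionSet
    ndrs: list
    hits: dict[str, list[MotifHit]]


@pytest.fixture(scope="session")
def pipeline_result(default_fixture: Fixture) -> PipelineResult:
    """Dyads, NRs, NDRs and motif hits called on the default fixture."""
    fx = default_fixture
    fragments = fx.all_fragments()
    nr_set = call_dyads(fragments, fx.layout.chrom_sizes)
    ndrs = call_ndrs(fragments, fx.layout.chrom_sizes)
    hits = {}
    for tf, peaks in fx.chip_peaks.items():
        pwm = pfm_to_pwm(fx.pfms[tf])
        raw = scan_peaks(fx.genome, peaks, pwm, p_threshold=1e-4)
        # overlapping peaks rescan the same sequence; deduplicate
        hits[tf] = merge_tf_hits([raw])
    return PipelineResult(fx, nr_set, ndrs, hits)


@pytest.fixture(scope="session")
def assigned_nr_hits(pipeline_result: PipelineResult):
    return assign_hits_to_dyads(
        pipeline_result.hits["TF_NR"], pipeline_result.nr_set.dyads
    )
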
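"""Shared fixtures: synthetic bundles and small builders.

Session-scoped bundles are generated once; tests treat them read-only.
"""

from __future__ import annotations

import pytest

from circlac import PipelineConfig, SimConfig, run_pipeline, simulate
from circlac.lac import LAC, ReadEvidence


def make_lac(chrom="chr1", strand="+", start=100, end=400, n_reads=0, mates=None):
    """LAC with synthetic read evidence (each read a distinct fingerprint)."""
    lac = LAC(chrom=chrom, strand=strand, start=start, end=end)
    for i in range(n_reads):
        mate = mates[i] if mates else 1 + i % 2
        lac.reads.append(ReadEvidence(f"r{i}/{mate}", mate, (start, f"{50+i}M", end, "x", 100)))
    return lac


def pipeline_config(bundle) -> PipelineConfig:
    p = bundle.paths
    return PipelineConfig(
        chimeric_junctions=str(p["chimeric"]),
        chimeric_sam=str(p["sam"]),
        exons_gtf=str(p["gtf"]),
        exons_lnc_bed=str(p["lnc_bed"]),
        exons_novel_bed=str(p["novel_bed"]),
        genome_fasta=str(p["fasta"]),
        sj_file=str(p["sj"]),
    )


@pytest.fixture(scope="session")
def clean_bundle(tmp_path_factory):
    """Noise-free bundle: ~200 planted circles, all four classes."""
    return simulate(SimConfig(seed=11), tmp_path_factory.mktemp("sim_clean"))


@pytest.fixture(scope="session")
def clean_result(clean_bundle):
    return run_pipeline(pipeline_config(clean_bundle))


@pytest.fixture(scope="session")
def noisy_bundle(tmp_path_factory):
    """Bundle with duplicates, alignment shifts, RT mismatches, variants."""
    cfg = SimConfig(seed=13).with_noise(mate_dropout=0.3)
    return simulate(cfg, tmp_path_factory.mktemp("sim_noisy"))


@pytest.fixture(scope="session")
def noisy_result(noisy_bundle):
    return run_pipeline(pipeline_config(noisy_bundle))
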
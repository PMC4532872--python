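from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from triocnv.intervals import GenomicInterval
from triocnv.io_model import CnvCall
from triocnv.pipeline import PipelineConfig, run_all
from triocnv.synthetic import SimConfig, generate_bundle

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def gi(chrom: str, start: int, end: int) -> GenomicInterval:
    return GenomicInterval(chrom, start, end)


def make_call(chrom="chr1", start=0, end=100_000, cnv_type="del",
              sample="S1", caller="ipattern", stringent=True, **kw) -> CnvCall:
    return CnvCall(sample_id=sample, caller=caller,
                   interval=GenomicInterval(chrom, start, end),
                   cnv_type=cnv_type, stringent=stringent, **kw)


def bundle_pipeline_config(bundle_dir: Path) -> PipelineConfig:
    return PipelineConfig(
        calls=str(bundle_dir / "calls.tsv"),
        pedigree=str(bundle_dir / "pedigree.ped"),
        control_manifest=str(bundle_dir / "controls" / "manifest.tsv"),
        stable_regions=str(bundle_dir / "stable_regions.bed"),
        genes=str(bundle_dir / "genes.bed"),
        known_loci=str(bundle_dir / "known_loci.bed"),
        probes=str(bundle_dir / "probes.tsv"),
        qc_metrics=str(bundle_dir / "qc_metrics.tsv"),
        phenotypes=str(bundle_dir / "phenotypes.tsv"),
    )


@pytest.fixture(scope="session")
def zero_noise_bundle(tmp_path_factory):
    """Full-scale (115-trio) zero-noise cohort: perfect callers, so the
    pipeline must reproduce the truth ledger exactly."""
    outdir = tmp_path_factory.mktemp("zero_noise_bundle")
    config = SimConfig.zero_noise(seed=7)
    ledger = generate_bundle(config, outdir)
    return config, ledger, outdir


@pytest.fixture(scope="session")
def zero_noise_run(zero_noise_bundle, tmp_path_factory):
    _config, ledger, bundle_dir = zero_noise_bundle
    outdir = tmp_path_factory.mktemp("zero_noise_run")
    summary = run_all(bundle_pipeline_config(bundle_dir), outdir)
    return ledger, summary, outdir
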
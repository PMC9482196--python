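import pytest
from hypothesis import HealthCheck, settings

from capiso import simulate as csim
from capiso.locus import ExonChain, LongReadRecord

settings.register_profile(
    "det",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")


def chain(strand, *exons, chrom="c"):
    return ExonChain(chrom, strand, tuple(exons))


def read(read_id, ch, sample="s1", **kw):
    defaults = dict(subreads=3, quality=0.999, polya_len=60, mapq=60, clipped=0)
    defaults.update(kw)
    return LongReadRecord(read_id=read_id, sample=sample, chain=ch, **defaults)


@pytest.fixture(scope="session")
def zero_truth():
    """Noise-free uniform-depth truth: 23 isoforms, 150 expected reads each."""
    return csim.make_locus(
        seed=11, scenario="uniform", uniform_depth=150.0,
        noise=csim.NoiseParams.zero(),
    )


@pytest.fixture(scope="session")
def zero_reads(zero_truth):
    return csim.simulate_reads(zero_truth, seed=12)


@pytest.fixture(scope="session")
def switch_truth():
    """Default switch scenario with realistic noise, 1000 reads/sample."""
    return csim.make_locus(seed=5)


@pytest.fixture(scope="session")
def switch_reads(switch_truth):
    return csim.simulate_reads(switch_truth, seed=6)
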
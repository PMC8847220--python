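import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture()
def worked_vcf(tmp_path):
    """The packaged 5-sample reconstruction example, written to disk."""
    from dnvphylo import worked_example

    reference, vcf_text, samples = worked_example()
    vcf_path = tmp_path / "example.vcf"
    vcf_path.write_text(vcf_text)
    return reference, vcf_path, samples
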
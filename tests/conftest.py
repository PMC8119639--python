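import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.util imports

from famprior import make_two_family_fixture, run_prioritization


@pytest.fixture(scope="session")
def two_family_fixture(tmp_path_factory):
    """The two-family worked-example dataset (VCF + PED + config)."""
    out = tmp_path_factory.mktemp("two_family_fixture")
    return make_two_family_fixture(out)


@pytest.fixture(scope="session")
def two_family_report(two_family_fixture):
    """The cascade's output on the worked-example dataset."""
    return run_prioritization(
        two_family_fixture.vcf,
        two_family_fixture.ped,
        two_family_fixture.config,
        verbose_trace=True,
    )
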
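import pytest

from scafbuild.io import SequenceIndex
from scafbuild.fixtures import worked_example_case


@pytest.fixture
def simple_index() -> SequenceIndex:
    return SequenceIndex.from_dict(
        {
            "s1": "AAAA",
            "s2": "CCGG",
            "host": "AAAATTTT",
            "patch": "CG",
            "long": "ACGTACGT",
        }
    )


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_case()


@pytest.fixture
def example_paths(tmp_path, worked_example):
    """The worked example written to disk as a plan/FASTA pair for CLI runs."""
    plan = tmp_path / "scaffold.yml"
    fasta = tmp_path / "records.fa"
    plan.write_text(worked_example.plan_text)
    fasta.write_text(worked_example.fasta_text)
    return plan, fasta
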
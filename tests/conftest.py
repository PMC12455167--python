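import pytest

from triscreen.screenflow.backends import BackendProfile
from triscreen.screenflow.criteria import validate_criteria
from triscreen.synthgen import SyntheticCorpusSpec, generate_corpus

RIS_TWO_RECORDS = """\
TY  - JOUR
TI  - A trial
AB  - Text.
AU  - Smith, J
PY  - 2021
ER  -
TY  - JOUR
TI  - Another trial
AB  - More text.
AU  - Jones, K
AU  - Brown, L
PY  - 2019
DO  - 10.1000/abc
ER  -
"""

NBIB_RECORD = """\
PMID- 123
TI  - Long title
      continues here
AB  - X.
DP  - 2020 Mar
FAU - Smith, John
FAU - Jones, Kate
FAU - Brown, Lee
JT  - Journal of Things
LID - 10.1000/xyz [doi]
"""


@pytest.fixture
def ris_text() -> str:
    return RIS_TWO_RECORDS


@pytest.fixture
def nbib_text() -> str:
    return NBIB_RECORD


@pytest.fixture
def criteria():
    return validate_criteria(
        population="hepatocellular carcinoma cirrhosis",
        intervention="resection ablation",
    )


@pytest.fixture
def profiles():
    return {
        role: BackendProfile(role=role, model_name=f"test-{role}")
        for role in ("reviewer", "critic", "arbitrator")
    }


@pytest.fixture(scope="session")
def small_synth():
    """A 200-record synthetic corpus with duplicates and blank abstracts."""
    spec = SyntheticCorpusSpec(
        n_records=200,
        prevalence=0.05,
        duplicate_rate=0.1,
        blank_abstract_rate=0.05,
        seed=42,
    )
    return generate_corpus(spec)
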
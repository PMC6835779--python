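import numpy as np
import pytest

from grainrisk.models import (
    Confidence,
    DigestLabel,
    IdentifiedPeptide,
    Stage,
    load_cd_epitopes,
    load_wa_epitopes,
)


@pytest.fixture(scope="session")
def cd_epitopes():
    return load_cd_epitopes()


@pytest.fixture(scope="session")
def wa_epitopes():
    return load_wa_epitopes()


@pytest.fixture()
def rng():
    return np.random.default_rng(20231114)


def make_peptide(
    sequence,
    sample_id="S1",
    stage=Stage.GD,
    psm=5,
    score=2.5,
    confidence=Confidence.HIGH,
    unambiguous=True,
    digest_label=DigestLabel.GD,
):
    """Construct an identification row with evidence passing default filters."""
    return IdentifiedPeptide(
        sequence=sequence,
        sample_id=sample_id,
        stage=stage,
        digest_label=digest_label,
        psm_count=psm,
        score=score,
        confidence=confidence,
        unambiguous=unambiguous,
    )


def random_protein_sequence(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), size=length))
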
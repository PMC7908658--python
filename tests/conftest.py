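import pytest
from hypothesis import HealthCheck, settings

from trftarget.pipeline import run_synthetic_pipeline
from trftarget.seq import NucleotideSequence, TranscriptRecord, TrfRecord
from trftarget.simulate import SyntheticConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_trf(trf_id="tRF-3001a", seq="UGGUUCGAGCCCAUAGCA", cls="tRF-3"):
    return TrfRecord(trf_id, NucleotideSequence(trf_id, seq), cls)


@pytest.fixture
def trf():
    # seed (positions 2-7) = GGUUCG, seed-match motif = CGAACC
    return make_trf()


@pytest.fixture
def transcript():
    return TranscriptRecord(
        "NM_000001",
        "GENE1",
        utr5="A" * 30,
        cds="AUGGCCGCAUAA" * 5,
        utr3="AAAC" + "CGAACC" * 1 + "AAAUUUGGGCCCAAAUUU" * 5,
    )


@pytest.fixture(scope="session")
def pipeline_result():
    """One full synthetic round trip shared by the slower checks.

    Defaults of the generator are the study conditions; GA runs 20
    generations with population 50.
    """
    cfg = SyntheticConfig(rng_seed=1)
    return run_synthetic_pipeline(
        cfg,
        ga_generations=20,
        ga_population=50,
        n_permutations=10,
        rng_seed=1,
        keep_artifacts=True,
    )
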
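import numpy as np
import pytest

from mycoamp.simdata import RunSpec, make_biomock_fixture
from mycoamp.synmock import PRIMERS, SynMockSpec, design_synmock, extract_subregion


@pytest.fixture(scope="session")
def synmock_members():
    """Default 12-member synthetic mock design."""
    return design_synmock(SynMockSpec())


@pytest.fixture(scope="session")
def synmock_its2(synmock_members):
    """The exact ITS2 random regions, recovered via the fITS7/ITS4 sites."""
    extracted, skipped = extract_subregion(
        synmock_members, PRIMERS["fITS7"], PRIMERS["ITS4"]
    )
    assert skipped == 0
    return extracted


@pytest.fixture(scope="session")
def biomock():
    return make_biomock_fixture(26, seed=0)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_mock_run_spec(
    synmock_its2,
    env_templates,
    n_env_samples: int = 3,
    reads_per_sample: int = 400,
    **overrides,
) -> RunSpec:
    """Spike-in + environmental run: SynMock sample plus disjoint env samples."""
    mock_comp = {name: 1.0 / len(synmock_its2) for name, _ in synmock_its2}
    env_names = [name for name, _ in env_templates]
    per = max(1, len(env_names) // n_env_samples) if n_env_samples else 0
    samples = [("SynMock", mock_comp)]
    for i in range(n_env_samples):
        chunk = env_names[i * per : (i + 1) * per] or env_names[-per:]
        samples.append((f"env{i + 1}", {n: 1.0 / len(chunk) for n in chunk}))
    defaults = dict(
        templates=list(synmock_its2) + list(env_templates),
        samples=samples,
        reads_per_sample=reads_per_sample,
        pcr_bias_sigma=0.5,
        sub_rate=0.0,
        hp_indel_rate=0.0,
        bleed_rate=0.0,
        seed=1,
    )
    defaults.update(overrides)
    return RunSpec(**defaults)
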
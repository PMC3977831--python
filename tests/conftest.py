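import pytest

from jointpsych import (
    BlockDataset,
    PsychometricParams,
    SamplingScheme,
    generate_dataset,
)

# degenerate-ESS warnings are expected at reduced sampler sizes in the
# simulation-heavy tests; they are asserted explicitly where relevant
collect_ignore_glob: list[str] = []


@pytest.fixture(autouse=True)
def _quiet_degenerate_warnings():
    import warnings

    from jointpsych import DegenerateFitWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateFitWarning)
        yield


@pytest.fixture
def default_params() -> PsychometricParams:
    return PsychometricParams(m=0.5, w=0.2, lam=0.02, gamma=0.5)


@pytest.fixture
def fixed_scheme() -> SamplingScheme:
    """Six equally spaced levels spanning asymptotes and rise, 100 trials each."""
    return SamplingScheme(
        intensities=(0.2, 0.32, 0.44, 0.56, 0.68, 0.8),
        trials_per_block=(100,) * 6,
    )


@pytest.fixture
def simulated_pair(default_params) -> list[BlockDataset]:
    return [
        generate_dataset(default_params, "random", seed=10, condition_id="a"),
        generate_dataset(default_params, "random", seed=11, condition_id="b"),
    ]


@pytest.fixture
def tiny_dataset() -> BlockDataset:
    return BlockDataset.from_blocks(
        [(0.2, 12, 20), (0.5, 15, 20), (0.8, 19, 20)], condition_id="tiny"
    )
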
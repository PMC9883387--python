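import numpy as np
import pandas as pd
import pytest

from fermentomics.config import SimulationConfig


@pytest.fixture
def zero_noise_config() -> SimulationConfig:
    """Default study design with all noise switched off."""
    return SimulationConfig(seed=0, noise_cv=0.0, qpcr_noise_sd=0.0, voc_noise_cv=0.0)


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=0)


def make_table(values: dict[str, list[float]], meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Build a samples-by-features table with minimal metadata columns."""
    features = pd.DataFrame(values)
    n = len(features)
    if meta is None:
        meta = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "treatment": ["HBPA"] * n,
            "time_h": [0.0] * n,
            "bio_rep": [1] * n,
            "tech_rep": [1] * n,
        })
    return pd.concat([meta.reset_index(drop=True), features.reset_index(drop=True)], axis=1)


@pytest.fixture
def make_sample_table():
    return make_table


@pytest.fixture
def healthy_config() -> SimulationConfig:
    """A realistic healthy-donor scenario: the default community plus a
    100-OTU rare tail (no treatment effects), moderate replicate noise and
    four biological replicates, so coverage/rarity statistics behave like
    they do in deep 16S surveys."""
    from fermentomics.config import default_baseline_profile, default_effect_matrix

    profile, taxonomy, remainder = default_baseline_profile()
    rng = np.random.default_rng(99)
    n_tail = 100
    for i in range(n_tail):
        ab = float(rng.uniform(0.0005, 0.01))
        profile[f"rare_{i}"] = (ab, 0.0)
        taxonomy[f"rare_{i}"] = "Firmicutes" if i % 2 else "Bacteroidetes"
    tail = sum(profile[f"rare_{i}"][0] for i in range(n_tail))
    f, b = profile["Firmicutes;Other"], profile["Bacteroidetes;Other"]
    profile["Firmicutes;Other"] = (f[0] - tail / 2, f[1])
    profile["Bacteroidetes;Other"] = (b[0] - tail / 2, b[1])
    return SimulationConfig(
        seed=0, noise_cv=0.1, n_bio_reps=4,
        baseline_profile=profile, taxonomy=taxonomy,
        remainder_taxa=remainder, effect_matrix=default_effect_matrix(),
    )
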
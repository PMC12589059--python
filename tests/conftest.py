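import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def fig2_graph():
    from helpers import fig2_style_graph

    return fig2_style_graph()


@pytest.fixture
def clique_bridge():
    from helpers import clique_bridge_network

    return clique_bridge_network()


@pytest.fixture
def synth_dataset():
    """Default small planted dataset: 4 clusters x 12 drugs, no mislabeling."""
    from ddsn.synthetic import GeneratorConfig, generate_dataset

    cfg = GeneratorConfig(
        n_clusters=4, drugs_per_cluster=12, mislabel_fraction=0.0,
        p_within=0.6, p_between=0.02, seed=11,
    )
    return cfg, generate_dataset(cfg)
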
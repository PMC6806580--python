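import numpy as np
import pandas as pd
import pytest

from riverneutral import OtuTable, RiverNetwork


@pytest.fixture
def toy_table() -> OtuTable:
    """3 samples x 4 OTUs with taxonomy and metadata."""
    counts = pd.DataFrame(
        [[6, 2, 0, 2], [2, 2, 4, 2], [1, 0, 3, 6]],
        index=["s1", "s2", "s3"],
        columns=["o1", "o2", "o3", "o4"],
    )
    taxonomy = {
        "o1": ("Eukaryota", "Alveolata", "Ciliophora"),
        "o2": ("Eukaryota", "Alveolata", "Dinoflagellata"),
        "o3": ("Eukaryota", "Stramenopiles"),
        "o4": ("Eukaryota", "Fungi", "Ascomycota"),
    }
    meta = pd.DataFrame(
        {
            "season": ["wet", "wet", "dry"],
            "longitude": [116.3, 116.4, 116.5],
            "latitude": [25.0, 25.1, 25.2],
            "site": ["s1", "s2", "s3"],
        },
        index=["s1", "s2", "s3"],
    )
    return OtuTable(counts, taxonomy=taxonomy, sample_meta=meta)


@pytest.fixture
def random_table() -> OtuTable:
    """40-OTU, 8-sample table with a lognormal abundance spread."""
    rng = np.random.default_rng(42)
    base = rng.lognormal(0, 2, size=40)
    counts = rng.poisson(base[None, :] * rng.uniform(5, 15, size=(8, 1)))
    counts[:, 0] += 1  # keep every sample non-empty
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(8)],
            columns=[f"o{j}" for j in range(40)],
        )
    )


@pytest.fixture
def y_network() -> RiverNetwork:
    """Y-shaped river: two headwater branches (3 km, 4 km) joining at a
    confluence, then 2 km to the outlet."""
    nodes = pd.DataFrame(
        {
            "longitude": [116.30, 116.33, 116.32, 116.34],
            "latitude": [25.00, 25.02, 25.01, 24.99],
        },
        index=["tipA", "tipB", "confluence", "outlet"],
    )
    edges = [
        ("tipA", "confluence", 3.0),
        ("tipB", "confluence", 4.0),
        ("confluence", "outlet", 2.0),
    ]
    return RiverNetwork(nodes=nodes, edges=edges)


@pytest.fixture
def chain_network() -> RiverNetwork:
    """Linear chain source -> A -> B."""
    nodes = pd.DataFrame(
        {
            "longitude": [116.0, 116.01, 116.02],
            "latitude": [25.0, 25.0, 25.0],
        },
        index=["source", "A", "B"],
    )
    return RiverNetwork(
        nodes=nodes, edges=[("source", "A", 1.5), ("A", "B", 2.5)]
    )
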
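import numpy as np
import pytest

from ddifuse.chem import DrugRecord, parse_drug
from ddifuse.config import ModelConfig
from ddifuse.synthetic import SynthConfig, generate_dataset
from ddifuse.tokenizer import build_vocabulary


@pytest.fixture(scope="session")
def toy_dataset():
    """Small planted-rule benchmark shared across tests."""
    return generate_dataset(SynthConfig(n_drugs=30, n_pairs=40, seed=7))


@pytest.fixture(scope="session")
def toy_drugs(toy_dataset):
    return toy_dataset[0]


@pytest.fixture(scope="session")
def toy_pairs(toy_dataset):
    return toy_dataset[1]


@pytest.fixture(scope="session")
def toy_vocab(toy_drugs):
    return build_vocabulary([d.smiles for d in toy_drugs], max_merges=100)


@pytest.fixture(scope="session")
def toy_graphs(toy_drugs):
    return [parse_drug(d) for d in toy_drugs]


@pytest.fixture()
def tiny_config():
    """Down-scaled model widths for fast unit tests; protocol fields untouched."""
    return ModelConfig(
        epochs=2,
        n_repeats=1,
        seq_d_model=16,
        seq_heads=4,
        seq_layers=1,
        seq_k=40,
        graph_hidden=16,
        graph_message_size=8,
        semantic_hidden=32,
        semantic_heads=4,
        semantic_blocks=1,
        fusion_width=16,
        fusion_att_dim=8,
        decoder_hidden1=32,
        decoder_hidden2=16,
        vocab_max_merges=100,
        dropout=0.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_record(smiles: str, drug_id: str = "X") -> DrugRecord:
    return DrugRecord(drug_id=drug_id, smiles=smiles)
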
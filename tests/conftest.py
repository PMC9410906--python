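import numpy as np
import pytest

from acascan.pipeline import AnalysisParams, analyze
from acascan.synthetic_data import (
    ACA_REFERENCE,
    ACR_CANDIDATE_REFERENCE,
    ACR_KNOWN_REFERENCE,
    PlantedPromoterSpec,
    SyntheticConfig,
    generate_genomes,
    make_seed_alignment,
)

ACR_LABELS = {"AcrK1": "known", "AcrC1": "candidate"}


def default_alignments() -> dict[str, list[str]]:
    return {
        name: make_seed_alignment(ref, n=8, subs_rate=0.05, seed=42)
        for name, ref in [
            ("AcaS1", ACA_REFERENCE),
            ("AcrK1", ACR_KNOWN_REFERENCE),
            ("AcrC1", ACR_CANDIDATE_REFERENCE),
        ]
    }


@pytest.fixture(scope="session")
def alignments():
    return default_alignments()


@pytest.fixture(scope="session")
def clean_community():
    """Mutation-free synthetic community with its ground truth."""
    cfg = SyntheticConfig(seed=11)
    genomes, manifest = generate_genomes(cfg)
    return cfg, genomes, manifest


@pytest.fixture(scope="session")
def clean_analysis(clean_community, alignments):
    _, genomes, manifest = clean_community
    result = analyze(genomes, alignments, ACR_LABELS, AnalysisParams(seed=11))
    return genomes, manifest, result


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(7)
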
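import numpy as np
import pandas as pd
import pytest

import inducemap as im


@pytest.fixture(scope="session")
def small_config() -> im.SynthConfig:
    """A scaled-down but structurally complete study configuration."""
    return im.SynthConfig(
        n_genes=500,
        n_pathways=10,
        n_pathway_genes=120,
        n_cazy_genes=60,
        n_reactions=120,
        n_metabolites=80,
        probe_metabolites=("TAUR", "H2SO3"),
        seed=11,
    )


@pytest.fixture(scope="session")
def study(small_config) -> im.StudyData:
    return im.generate_study(small_config)


@pytest.fixture(scope="session")
def study_de(study) -> pd.DataFrame:
    return im.de_table(study.expression)


@pytest.fixture(scope="session")
def study_sig(study_de):
    return im.significant_sets(study_de)


def make_de(calls, inducers, genes=None):
    """Build a DE table by hand from {gene: {inducer: logFC-or-None}}.

    A numeric value means a significant call with that logFC; ``None`` (or an
    absent inducer) means a non-significant row with logFC 0.
    """
    genes = list(genes if genes is not None else calls)
    rows = []
    for g in genes:
        for ind in inducers:
            lfc = calls.get(g, {}).get(ind)
            sig = lfc is not None
            lfc = float(lfc) if sig else 0.0
            rows.append({
                "gene": g, "inducer": ind, "logFC": lfc,
                "p_value": 0.01 if sig else 0.5,
                "significant": sig and lfc != 0,
                "direction": ("up" if lfc > 0 else "down") if sig and lfc else "none",
            })
    return pd.DataFrame(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
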
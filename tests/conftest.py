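import numpy as np
import pytest

from mirkit import synthetic_data as sd


SMALL_FAMILY_LOCI = {"MIR156": 2, "MIR169": 3, "MIR444": 4, "MIR827": 1}


def small_sim_config(seed: int = 11, **kw) -> sd.SimulationConfig:
    """A scaled-down study: few families, few transcripts, fast to run."""
    defaults = dict(
        seed=seed,
        family_loci=dict(SMALL_FAMILY_LOCI),
        n_families=len(SMALL_FAMILY_LOCI),
        query_species=("zma",),
        n_implants=8,
        n_decoys=6,
        n_target_mrnas=8,
        decoy_length_range=(150, 350),
        target_length_range=(200, 400),
    )
    defaults.update(kw)
    return sd.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_simulation():
    """One shared small synthetic transcriptome with ground truth."""
    cfg = small_sim_config()
    rng = np.random.default_rng(cfg.seed)
    transcripts, manifest, refs = sd.simulate_transcriptome(cfg, rng=rng)
    return cfg, transcripts, manifest, refs
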
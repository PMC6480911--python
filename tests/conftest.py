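import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import cpgboost as cb

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_profile(cell_id, sites):
    """CellProfile from [(chrom, pos, state), ...] tuples (already labeled)."""
    df = pd.DataFrame(sites, columns=["chrom", "pos", "state"])
    df["meth_reads"] = 0
    df["total_reads"] = 0
    return cb.CellProfile(cell_id, df)


@pytest.fixture(scope="session")
def sim_small():
    """Shared small simulated world: 3 cells over 2 x 200 kb chromosomes."""
    cfg = cb.SimConfig(m=3, n_chrom=2, chrom_len=200_000, seed=7)
    genome, positions = cb.simulate_genome(cfg)
    latent = cb.simulate_latent(cfg, positions)
    dataset = cb.simulate_profiles(cfg, positions, latent)
    tracks = cb.simulate_tracks(cfg, positions, latent)
    return {
        "cfg": cfg,
        "genome": genome,
        "gs": cb.GenomeSequence(genome),
        "positions": positions,
        "latent": latent,
        "dataset": dataset,
        "tracks": tracks,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
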
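"""Shared fixtures: simulations are generated once per session and reused."""

import numpy as np
import pandas as pd
import pytest

import methylegacy as ml


@pytest.fixture(scope="session")
def default_sim():
    """Full-scale study emulation: 20k CpGs, 3 pollutants, 300 sites/class."""
    return ml.simulate(ml.SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """Small fixture for IO round-trips and pipeline runs."""
    cfg = ml.SimConfig(
        seed=3, n_cpgs=2000, n_genes=15, contig_length=150_000,
        n_direct=30, n_persistent=30, n_legacy=30,
    )
    return ml.simulate(cfg)


@pytest.fixture(scope="session")
def small_fixture_dir(small_sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    ml.write_fixture(outdir, small_sim)
    return outdir


def toy_matrix(meth, total, samples=None, contig="c1", strand="+"):
    """Build a MethylomeMatrix from 2-D lists; NaN marks missing cells."""
    meth = np.asarray(meth, dtype=float)
    total = np.asarray(total, dtype=float)
    n = meth.shape[0]
    if samples is None:
        samples = [f"s{i + 1}" for i in range(meth.shape[1])]
    sites = ml.matrix.make_sites([contig] * n, np.arange(1, n + 1) * 10,
                                 [strand] * n)
    return ml.MethylomeMatrix(sites=sites, meth=meth, total=total,
                              samples=list(samples))


@pytest.fixture
def truth_lookup():
    def build(sim, pollutant):
        tr = sim.truth[sim.truth["pollutant"] == pollutant]
        return dict(zip(tr["site_id"], tr["planted_class"]))

    return build


def dm_site_ids(dm):
    return (dm["contig"].astype(str) + ":" + dm["pos"].astype(str) + ":"
            + dm["strand"].astype(str))
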
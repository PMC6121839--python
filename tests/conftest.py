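import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mutlines import dnmcall, simdata


@pytest.fixture(scope="session")
def at_genome():
    """1 Mb iid genome at 69% AT, fixed seed, shared across tests."""
    return simdata.generate_genome(
        1_000_000, simdata.BaseComposition.from_at_content(0.69),
        n_scaffolds=2, seed=7,
    )


@pytest.fixture(scope="session")
def small_pedigree():
    return simdata.simulate_pedigree(simdata.PedigreeConfig(seed=11))


@pytest.fixture(scope="session")
def clean_experiment(at_genome, small_pedigree):
    """Noise-free rendered experiment: truth must round-trip exactly."""
    truth = simdata.inject_mutations(
        small_pedigree, at_genome, mu_snm=5e-6, mu_ins=1.5e-6, mu_del=3e-6,
        seed=13,
    )
    rcs = simdata.render_callsets(small_pedigree, truth, at_genome, seed=17)
    return at_genome, small_pedigree, truth, rcs


@pytest.fixture(scope="session")
def noisy_experiment(at_genome, small_pedigree):
    """Rendered experiment with all three contamination channels active."""
    truth = simdata.inject_mutations(
        small_pedigree, at_genome, mu_snm=5e-6, mu_ins=1.5e-6, mu_del=3e-6,
        seed=13,
    )
    rcs = simdata.render_callsets(
        small_pedigree, truth, at_genome, error_rate=0.01,
        fp_shared=50, fp_error=50, fp_pool_low=20, seed=19,
    )
    return at_genome, small_pedigree, truth, rcs


def run_chain(genome, rcs, thresholds=None):
    """Convenience wrapper running the full calling chain on a rendering."""
    return dnmcall.run_pipeline(
        rcs.line_calls,
        rcs.pool_calls,
        {(s.scaffold, s.pos): s for s in rcs.pool_sites},
        rcs.depth_tracks,
        rcs.pool_depth_track,
        genome,
        thresholds,
    )
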
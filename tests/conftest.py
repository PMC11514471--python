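import numpy as np
import pandas as pd
import pytest

import micromuscle as mm
from micromuscle import io as mio
from micromuscle.core import CountMatrix
from micromuscle.synthetic import IsomirProfile


@pytest.fixture(scope="session")
def clean_sim():
    """Simulation with no isomiRs, no flanks, no noise: exact round-trip regime."""
    cfg = mm.SimulationConfig(
        seed=101,
        n_hairpins=12,
        n_clusters=2,
        random_flank_n=0,
        isomir_profile=IsomirProfile(),
        baseline_mean_log_mu=4.0,
    )
    fasta, gff3, truth = mm.generate_annotation(cfg)
    counts = mm.simulate_counts(cfg, truth)
    fastqs = mm.simulate_reads(cfg, truth, counts)
    return cfg, fasta, gff3, truth, counts, fastqs


@pytest.fixture(scope="session")
def isomir_sim():
    """Simulation with a rich planted modification mix and 4N flanks."""
    profile = IsomirProfile(
        p_trim3=0.15, p_trim5=0.03, p_nta_u=0.10, p_nta_a=0.08,
        p_templated_ext=0.06, tail_geometric_p=0.6,
    )
    cfg = mm.SimulationConfig(
        seed=202,
        n_hairpins=10,
        n_clusters=2,
        isomir_profile=profile,
        random_flank_n=4,
        baseline_mean_log_mu=4.0,
    )
    fasta, gff3, truth = mm.generate_annotation(cfg)
    counts = mm.simulate_counts(cfg, truth)
    fastqs = mm.simulate_reads(cfg, truth, counts)
    return cfg, fasta, gff3, truth, counts, fastqs


@pytest.fixture(scope="session")
def hairpin_set(clean_sim):
    _, fasta, gff3, *_ = clean_sim
    return mio.read_hairpins(fasta, gff3)


@pytest.fixture()
def two_group_matrix():
    """Deterministic small NB matrix with two conditions."""
    rng = np.random.default_rng(42)
    mu = np.exp(rng.normal(5, 1, 50))
    r = 1 / 0.05
    counts = pd.DataFrame(
        rng.negative_binomial(r, r / (r + mu[:, None]), (50, 6)),
        index=[f"m{i}" for i in range(50)],
        columns=[f"A_{i}" for i in range(3)] + [f"B_{i}" for i in range(3)],
    )
    samples = pd.DataFrame({"condition": ["A"] * 3 + ["B"] * 3}, index=counts.columns)
    return CountMatrix(counts, samples)
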
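import logging

import numpy as np
import pandas as pd
import pytest

from clonevo.simulate import SimulationConfig, simulate_cohort

# keep per-sample INFO chatter out of test output
logging.getLogger("clonevo").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def small_config():
    """A light cohort used wherever the exact scale does not matter."""
    return SimulationConfig(
        n_patients=6,
        mutations_per_sample_range=(60, 120),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study conditions (15 patients, 100X)."""
    return simulate_cohort(SimulationConfig(seed=42))


def make_assigned_frame(ccfs, depth, purity, rng, sample="S1"):
    """Build a CCF-assigned diploid call frame with binomial read draws.

    Helper for clustering tests: every mutation is heterozygous diploid
    (m=1, CNt=CNn=2) so expected VAF = ccf * purity / 2.
    """
    ccfs = np.asarray(ccfs, dtype=float)
    n = len(ccfs)
    depths = np.full(n, depth)
    p = ccfs * purity / 2.0
    alt = rng.binomial(depths, p)
    vaf = alt / depths
    ccf_hat = np.minimum(vaf * 2.0 / purity, 1.0)
    return pd.DataFrame(
        {
            "sample": sample,
            "t_alt_count": alt,
            "t_ref_count": depths - alt,
            "vaf": vaf,
            "purity": purity,
            "major_cn": 1,
            "minor_cn": 1,
            "normal_cn": 2,
            "multiplicity": 1,
            "ccf": ccf_hat,
            "ccf_uncapped": vaf * 2.0 / purity,
            "inconsistent": False,
        }
    )
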
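import numpy as np
import pandas as pd
import pytest

from pmfmeth import (
    BetaMatrix,
    ClockSpec,
    DmpSpec,
    DmrSpec,
    SimConfig,
    generate_cohort,
)

PLANTED_DMPS = tuple(range(100, 125))
PLANTED_CLOCK = tuple(range(300, 330))


@pytest.fixture(scope="session")
def planted_cohort():
    """22-sample cohort with 25 planted DMPs, one DMR cluster and a clock."""
    cfg = SimConfig(
        n_fp=12,
        n_sd=10,
        n_probes=2000,
        n_plates=2,
        dmp_spec=[DmpSpec(PLANTED_DMPS, 0.12)],
        dmr_spec=[DmrSpec("chr5", 2_000_000, 8, 100, 0.15)],
        clock_spec=ClockSpec(PLANTED_CLOCK),
        batch_effect_sd=0.0,
        probe_fail_rate=0.0,
        seed=1,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """33-sample cohort with no planted structure at all."""
    return generate_cohort(
        SimConfig(n_fp=16, n_sd=17, n_probes=2000, probe_fail_rate=0.0, seed=8)
    )


def two_group_frame(rng, n_fp, n_sd, n_probes, noise=0.05, base=0.5):
    """Plain beta DataFrame + group labels for small constructed instances."""
    n = n_fp + n_sd
    X = pd.DataFrame(
        np.clip(base + rng.normal(0, noise, (n, n_probes)), 0, 1),
        index=[f"s{i}" for i in range(n)],
        columns=[f"cg{j:06d}" for j in range(n_probes)],
    )
    y = pd.Series(["FP"] * n_fp + ["SD"] * n_sd, index=X.index)
    return X, y
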
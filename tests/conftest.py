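import numpy as np
import pytest

from proglimit.datasets import SyntheticConfig, generate_synthetic_dataset


def brute_force_c(score, time, event):
    """Independent O(n^2) pair-enumeration oracle for Harrell's C.

    Deliberately naive: explicit double loop, no shared code with the
    implementation under test.
    """
    score = np.asarray(score, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    num = 0.0
    den = 0
    n = len(score)
    for i in range(n):
        if event[i] != 1:
            continue
        for j in range(n):
            if time[i] < time[j]:
                den += 1
                if score[i] > score[j]:
                    num += 1.0
                elif score[i] == score[j]:
                    num += 0.5
    if den == 0:
        raise ZeroDivisionError("no comparable pairs")
    return num / den


@pytest.fixture(scope="session")
def oracle_c():
    return brute_force_c


@pytest.fixture(scope="session")
def signal_ds():
    """Strong latent-factor signal, moderate censoring."""
    return generate_synthetic_dataset(
        SyntheticConfig(
            n_samples=300, n_genes=200, factor_fraction=0.05, loading_scale=2.0,
            hazard_coef=1.5, censor_rate_target=0.3, seed=11,
        ),
        name="signal",
    )


@pytest.fixture(scope="session")
def null_ds():
    """No association between expression and survival."""
    return generate_synthetic_dataset(
        SyntheticConfig(
            n_samples=300, n_genes=200, factor_fraction=0.05, loading_scale=1.0,
            hazard_coef=0.0, censor_rate_target=0.3, seed=13,
        ),
        name="null",
    )
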
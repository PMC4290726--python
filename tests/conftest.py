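import numpy as np
import pytest

from tdnd import ExpressionMatrix, normalize


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def standardized_pair(rng):
    """Two standardized length-24 profiles."""

    def _std(v):
        return (v - v.mean()) / v.std(ddof=1)

    return _std(rng.standard_normal(24)), _std(rng.standard_normal(24))


def make_shifted_system(shift: int, t: int = 24, weight: float = 1.0,
                        n_extra: int = 0, seed: int = 7,
                        probe: bool = False) -> ExpressionMatrix:
    """Target = weight * regulator shifted by `shift`; optional decoys.

    With ``probe=True`` the driver is the deterministic broadband probe,
    for which exact lag recovery is guaranteed; the default Gaussian driver
    exercises realistic profiles at a fixed seed.
    """
    from tdnd.simulate import lag_probe

    rng = np.random.default_rng(seed)
    driver = lag_probe(t + shift) if probe else rng.standard_normal(t + shift)
    cols = {"reg": driver[shift:], "tgt": weight * driver[: t]}
    for k in range(n_extra):
        cols[f"dec{k}"] = rng.standard_normal(t)
    values = np.column_stack(list(cols.values()))
    return ExpressionMatrix(values, list(cols))


@pytest.fixture
def shifted_system():
    return make_shifted_system


@pytest.fixture
def normalized_random_matrix(rng):
    return normalize(
        ExpressionMatrix(rng.standard_normal((24, 6)),
                         [f"g{k}" for k in range(6)])
    )
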
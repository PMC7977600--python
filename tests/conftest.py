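import numpy as np
import pandas as pd
import pytest

from mirarray import de_screen, normalization
from mirarray.synthetic_data import ArraySimConfig, generate_array_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """One default-condition simulated experiment, shared read-only."""
    cfg = ArraySimConfig(seed=11)
    spots, truth = generate_array_experiment(cfg)
    return cfg, spots, truth


@pytest.fixture(scope="session")
def normalized_default(default_experiment):
    cfg, spots, _ = default_experiment
    matrix = normalization.collapse_replicates(spots)
    return matrix, normalization.median_normalize(matrix)


def random_net_matrix(rng: np.random.Generator, n_probes=None, n_samples=None) -> pd.DataFrame:
    """Small random net-intensity matrix with values straddling the floor."""
    n_probes = n_probes or int(rng.integers(3, 21))
    n_samples = n_samples or int(rng.integers(1, 5))
    values = rng.uniform(-20, 500, size=(n_probes, n_samples))
    # guarantee at least one all-above-floor reference probe
    values[0] = rng.uniform(60, 500, size=n_samples)
    return pd.DataFrame(
        values,
        index=[f"P{i:03d}" for i in range(n_probes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )


def brute_force_scale_factors(matrix: pd.DataFrame, floor: float = 50.0) -> dict[str, float]:
    """Independent sorted-quantile oracle for the per-sample divisors."""
    ref = [p for p in matrix.index if all(matrix.loc[p, s] > floor for s in matrix.columns)]
    out = {}
    for s in matrix.columns:
        vals = sorted(matrix.loc[p, s] for p in ref)
        m = len(vals)
        if m % 2 == 1:
            out[s] = vals[m // 2]
        else:
            out[s] = (vals[m // 2 - 1] + vals[m // 2]) / 2.0
    return out


def make_comparison(calls: dict[str, str], treatment="T", control="AL") -> de_screen.ComparisonResult:
    """Build a ComparisonResult directly from probe -> status calls."""
    probes = sorted(calls)
    table = pd.DataFrame(index=pd.Index(probes, name="probe_id"))
    table["status"] = [calls[p] for p in probes]
    table["accepted"] = table["status"] != "filtered"
    fc = {"up": 2.0, "down": 0.4, "unchanged": 1.0, "filtered": np.nan}
    table["fold_change"] = [fc[calls[p]] for p in probes]
    return de_screen.ComparisonResult(treatment=treatment, control=control, table=table)
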
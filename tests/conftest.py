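import numpy as np
import pytest

from timecoda import CohortSimConfig, simulate_cohort


def direct_pivot_ilr(parts, pivot_index):
    """Independent evaluation of the pivot-coordinate log-ratio formula.

    z_j = sqrt((D-j)/(D-j+1)) * ln( x_(j) / gmean(x_(j+1)..x_(D)) ) with the
    pivot part first and the remaining parts in canonical order. Written
    from the textbook formula, not via the package's contrast matrix.
    """
    x = np.asarray(parts, dtype=float)
    D = x.size
    order = [pivot_index] + [j for j in range(D) if j != pivot_index]
    xs = x[order]
    z = []
    for j in range(D - 1):
        tail = xs[j + 1:]
        gm = np.exp(np.mean(np.log(tail)))
        z.append(np.sqrt((D - j - 1) / (D - j)) * np.log(xs[j] / gm))
    return np.array(z)


def random_compositions(rng, n, kappa=1440.0):
    """Strictly positive random 4-part compositions closed to kappa."""
    raw = np.exp(rng.normal(0.0, 1.5, size=(n, 4)))
    return kappa * raw / raw.sum(axis=1, keepdims=True)


@pytest.fixture(scope="session")
def default_cohort():
    """A fixed 45-person synthetic cohort under default study conditions."""
    return simulate_cohort(CohortSimConfig(n_participants=45, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
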
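import numpy as np
import pytest

from cfot import SimulationConfig, counterfactual_match, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """Balanced 3-state simulation, small enough for fast unit tests."""
    cfg = SimulationConfig(n_cells=1200, n_confounder_genes=300,
                           n_response_genes=150, n_states=3, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """Default-scale balanced simulation (5,000 cells, 1,000+500 genes)."""
    return simulate_dataset(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def independent_sim():
    """Default-scale simulation whose response distribution is identical
    across states, so confounder and treatment sources are truly independent
    (the regime where the ICA factorization is identifiable)."""
    return simulate_dataset(SimulationConfig(seed=7, state_specific_response=False))


@pytest.fixture(scope="session")
def small_result(small_sim):
    """Pipeline run on the small simulation, treated-referenced ITE."""
    return counterfactual_match(small_sim.dataset, rank=20, threshold=0.05,
                                smoothness_per_dim=1e-5, seed=7,
                                ite_direction="counterfactual_for_treated")


def xi_oracle(y_ordered) -> float:
    """Brute-force rank-counting Chatterjee coefficient for y in x-sorted order."""
    y = list(y_ordered)
    n = len(y)
    r = [sum(1 for yj in y if yj <= yi) for yi in y]
    l = [sum(1 for yj in y if yj >= yi) for yi in y]
    denom = 2 * sum(li * (n - li) for li in l)
    if denom == 0:
        return 0.0
    num = n * sum(abs(r[i + 1] - r[i]) for i in range(n - 1))
    return 1.0 - num / denom


def lp_ot_cost(cost: np.ndarray, r: np.ndarray, c: np.ndarray) -> float:
    """Exact OT cost <P*, cost> by linear programming (independent oracle)."""
    from scipy.optimize import linprog

    n0, n1 = cost.shape
    A_eq = []
    b_eq = []
    for i in range(n0):
        row = np.zeros((n0, n1))
        row[i, :] = 1.0
        A_eq.append(row.ravel())
        b_eq.append(r[i])
    for j in range(n1 - 1):  # last column constraint is redundant
        col = np.zeros((n0, n1))
        col[:, j] = 1.0
        A_eq.append(col.ravel())
        b_eq.append(c[j])
    res = linprog(cost.ravel(), A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    assert res.success
    return float(res.fun)
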
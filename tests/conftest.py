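import numpy as np
import pytest

from modreorg import (
    default_atlas,
    default_spec,
    simulate_cohort,
    subject_connectivity,
)
from modreorg.atlas_io import RegionAtlas


@pytest.fixture(scope="session")
def atlas116():
    return default_atlas()


@pytest.fixture()
def toy_atlas():
    """6 regions: pairs (1,2) and (3,4), midline 5 and 6."""
    return RegionAtlas(
        region_ids=(1, 2, 3, 4, 5, 6),
        names=("A_L", "A_R", "B_L", "B_R", "M1", "M2"),
        hemispheres=("left", "right", "left", "right", "midline", "midline"),
        partners={1: 2, 2: 1, 3: 4, 4: 3},
        named_subsets={"ab": (1, 2, 3, 4)},
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated CN/AD cohort shared across tests (n=12, T=150)."""
    spec = default_spec(n_per_group=12, T=150, seed=42)
    subjects, gmc = simulate_cohort(spec)
    return spec, subjects, gmc


@pytest.fixture(scope="session")
def small_cohort_cc(small_cohort):
    spec, subjects, gmc = small_cohort
    return spec, [subject_connectivity(s) for s in subjects], gmc


def brute_force_best_q(graph):
    """Exhaustive search over all set partitions (oracle for detection)."""
    from modreorg.modularity import modularity_q

    n = graph.n_nodes
    best = -np.inf
    labels = np.zeros(n, dtype=int)

    def recurse(i, n_used):
        nonlocal best
        if i == n:
            q = modularity_q(graph, labels)
            if q > best:
                best = q
            return
        for c in range(n_used):
            labels[i] = c
            recurse(i + 1, n_used)
        labels[i] = n_used
        recurse(i + 1, n_used + 1)
        labels[i] = 0

    recurse(0, 0)
    return best
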
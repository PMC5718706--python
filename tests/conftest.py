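import numpy as np
import pandas as pd
import pytest

import bulkdecon as bd


@pytest.fixture(scope="session")
def small_reference():
    """3 characterized types, 500 genes, 5 planted markers each."""
    refset, signature = bd.simulate_reference_profiles(
        500, ["Bcells", "Tcells", "NKcells"], markers_per_type=5, seed=11
    )
    return refset, signature


@pytest.fixture(scope="session")
def mixture_setup(small_reference):
    """Reference + cancer profile + equal-content table, ready to mix."""
    refset, signature = small_reference
    cancer = bd.simulate_cancer_profile(refset, signature, leakage=0.0, seed=12)
    profiles = refset.profile.copy()
    profiles["cancer"] = cancer
    contents = bd.MRnaContentTable(
        {"Bcells": 0.4, "Tcells": 0.4, "NKcells": 0.4, "cancer": 0.4}
    )
    return refset, signature, profiles, contents


@pytest.fixture(scope="session")
def unequal_contents():
    return bd.MRnaContentTable(
        {"Bcells": 0.4, "Tcells": 0.9, "NKcells": 0.2, "cancer": 0.6},
        uncharacterized_value=0.6,
    )


_GRID_CACHE: dict = {}


def _simplex_grid(m, n_steps):
    """All grid points of {p >= 0, sum(p) <= 1} at resolution 1/n_steps."""
    key = (m, n_steps)
    if key not in _GRID_CACHE:
        axes = np.meshgrid(*([np.arange(n_steps + 1)] * m), indexing="ij")
        levels = np.stack([a.ravel() for a in axes], axis=1)
        levels = levels[levels.sum(axis=1) <= n_steps]
        _GRID_CACHE[key] = levels.astype(float) / n_steps
    return _GRID_CACHE[key]


def grid_search_simplex(b, C, w, step=1e-2):
    """Brute-force minimizer of the weighted SSE over {p>=0, sum(p)<=1}.

    Exhaustive enumeration of the grid with the given step; independent of
    the package's solver.  Returns (best p, best objective).
    """
    m = C.shape[1]
    n_steps = int(round(1 / step))
    A = np.sqrt(w)[:, None] * C
    y = np.sqrt(w) * b
    P = _simplex_grid(m, n_steps)  # n_points x m
    resid = P @ A.T - y  # n_points x n_genes
    sse = (resid**2).sum(axis=1)
    k = int(np.argmin(sse))
    return P[k], float(sse[k])


def weighted_sse(b, C, w, p):
    r = b - C @ p
    return float((w * r * r).sum())


@pytest.fixture(scope="session")
def grid_oracle():
    return grid_search_simplex
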
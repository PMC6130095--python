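import numpy as np
import pandas as pd
import pytest

import replisig as rs


@pytest.fixture(scope="session")
def small_genome():
    return rs.make_genome(seed=11, n_chrom=1, chrom_length=2_000_000)


@pytest.fixture(scope="session")
def small_domains(small_genome):
    domains, profile, origins = rs.make_domains(small_genome, replicon_length=1_000_000)
    return domains, profile, origins


@pytest.fixture(scope="session")
def small_truth():
    return rs.make_truth(n_samples=6, n_signatures=3, seed=12, asymmetry_ratio=3.0)


@pytest.fixture(scope="session")
def small_cohort(small_genome, small_domains, small_truth):
    domains, _, _ = small_domains
    return rs.make_cohort(
        small_genome, domains, small_truth, mutations_per_sample=2_000, seed=13
    )


def grid_nnls(A, b, n_points=9, n_levels=6):
    """Brute-force multilevel grid search for min_{e>=0} ||Ae - b||_2.

    Independent oracle for the NNLS solver: evaluates the quadratic
    objective on a dense grid over a box guaranteed to contain the optimum,
    then shrinks the box around the best point.  Returns (e, objective,
    final_grid_step).
    """
    A = np.asarray(A, float)
    b = np.asarray(b, float)
    d = A.shape[1]
    G = A.T @ A
    c = A.T @ b
    const = b @ b
    upper = (np.abs(b).sum() + np.sqrt(len(b)) * np.linalg.norm(b)) / np.abs(A).sum(axis=0)
    lo = np.zeros(d)
    hi = upper.copy()
    best = None
    step = (hi - lo) / (n_points - 1)
    for _ in range(n_levels):
        axes = [np.linspace(lo[j], hi[j], n_points) for j in range(d)]
        mesh = np.meshgrid(*axes, indexing="ij")
        E = np.stack([m.ravel() for m in mesh], axis=1)
        f = np.einsum("ij,jk,ik->i", E, G, E) - 2.0 * (E @ c) + const
        i = int(np.argmin(f))
        best = (E[i], float(max(f[i], 0.0)) ** 0.5)
        step = (hi - lo) / (n_points - 1)
        lo = np.maximum(E[i] - step, 0.0)
        hi = E[i] + step
    return best[0], best[1], step
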
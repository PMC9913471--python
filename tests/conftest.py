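"""Shared fixtures: all test data is generated, nothing is bundled."""

from __future__ import annotations

import numpy as np
import pytest

from wssgwas.pedigree import Pedigree
from wssgwas.simulate import make_fixture


@pytest.fixture(scope="session")
def tiny():
    """Small deterministic dataset: 12 boars, 200 SNPs, 2 planted QTL."""
    return make_fixture("tiny", seed=1)


@pytest.fixture(scope="session")
def tiny_vc():
    from wssgwas.mixed_model import VarianceComponents

    return VarianceComponents(sigma_a2=30.0, sigma_p2=35.0, sigma_e2=111.0)


def random_pedigree(n: int, seed: int, p_founder: float = 0.3) -> Pedigree:
    """Random acyclic pedigree: animal i's parents are among 0..i-1."""
    rng = np.random.default_rng(seed)
    triples = []
    for i in range(n):
        if i < 2 or rng.random() < p_founder:
            triples.append((f"a{i}", "0", "0"))
        else:
            s, d = rng.choice(i, size=2, replace=False)
            triples.append((f"a{i}", f"a{s}", f"a{d}"))
    return Pedigree.from_triples(triples)


def tabular_oracle(ped: Pedigree) -> np.ndarray:
    """Independent recursive definition of the numerator relationship matrix.

    a(i,j) for i ≤ j defined from parent averages, memoised; kept free of
    the package's vectorised tabular construction.
    """
    n = len(ped)
    cache: dict[tuple[int, int], float] = {}

    def a(i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        if (i, j) in cache:
            return cache[(i, j)]
        s, d = ped.sire[j], ped.dam[j]
        if i == j:
            val = 1.0 + (0.5 * a(s, d) if (s >= 0 and d >= 0) else 0.0)
        else:
            val = 0.0
            if s >= 0:
                val += 0.5 * a(i, s)
            if d >= 0:
                val += 0.5 * a(i, d)
        cache[(i, j)] = val
        return val

    return np.array([[a(i, j) for j in range(n)] for i in range(n)])
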
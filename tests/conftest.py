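"""Shared fixtures and independent brute-force oracles.

The oracle implementations deliberately avoid the package's vectorized
paths: objective values are recomputed by directly enumerating ordered
codon neighbours, and SPEA2 fitness by literal double loops over the
strength / raw-fitness / density definitions.
"""

import math

import numpy as np
import pytest

import sgcopt
from sgcopt.genetic_code import BASES, CODONS, CODON_INDEX, STOP_CODONS


@pytest.fixture(scope="session")
def sgc():
    return sgcopt.standard_code()


@pytest.fixture(scope="session")
def indices8():
    return sgcopt.load_builtin_indices()


@pytest.fixture(scope="session")
def matrices8(indices8):
    return [sgcopt.cost_matrix(idx) for idx in indices8]


@pytest.fixture(scope="session")
def pairs_sense():
    return sgcopt.neighbor_pairs(sense_only=True)


@pytest.fixture(scope="session")
def ref_table():
    return sgcopt.load_reference_deviation_table()


@pytest.fixture(scope="session")
def brute_force_objective():
    """Objective value by ordered enumeration of all 64 x 9 neighbours."""

    def oracle(code, matrix):
        stops = set(STOP_CODONS)
        total = 0.0
        for codon in CODONS:
            if codon in stops:
                continue
            for pos in range(3):
                for base in BASES:
                    if base == codon[pos]:
                        continue
                    other = codon[:pos] + base + codon[pos + 1:]
                    if other in stops:
                        continue
                    a = code.assignment[CODON_INDEX[codon]]
                    b = code.assignment[CODON_INDEX[other]]
                    total += matrix.costs[a, b]
        return total / 2.0  # each unordered pair was visited twice

    return oracle


@pytest.fixture(scope="session")
def spea2_fitness_oracle():
    """Literal SPEA2 fitness: strengths, raw fitness and k-NN density."""

    def oracle(F, k=None):
        F = np.asarray(F, dtype=float)
        n = len(F)

        def dom(i, j):
            return (F[i] <= F[j]).all() and (F[i] < F[j]).any()

        S = [sum(dom(i, j) for j in range(n)) for i in range(n)]
        R = [sum(S[i] for i in range(n) if dom(i, j)) for j in range(n)]
        if k is None:
            k = round(math.sqrt(n))
        k = min(max(k, 1), n - 1) if n > 1 else 1
        fit = []
        for i in range(n):
            dists = sorted(
                math.dist(F[i], F[j]) for j in range(n) if j != i
            ) or [0.0]
            sigma = dists[k - 1]
            fit.append(R[i] + 1.0 / (sigma + 2.0))
        return np.array(fit)

    return oracle
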
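"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import nbinom

from rnaseqpower import GeneratorConfig, build_parameter_population


def brute_force_exact_pvalue(SA: int, SB: int, nA: int, nB: int, phi: float) -> float:
    """Enumeration oracle for the exact conditional NB test.

    Computes every conditional outcome probability directly from
    ``scipy.stats.nbinom`` pmfs of the pooled per-condition sums --
    independent of the package's ratio-recurrence implementation.
    """
    S = SA + SB
    if S == 0:
        return 1.0
    mu = S / (nA + nB)
    mA, mB = nA * mu, nB * mu
    rA, rB = nA / max(phi, 1e-12), nB / max(phi, 1e-12)
    a = np.arange(S + 1)
    P = nbinom.pmf(a, rA, rA / (rA + mA)) * nbinom.pmf(S - a, rB, rB / (rB + mB))
    return float(P[P <= P[SA] * (1 + 1e-12)].sum() / P.sum())


def counts_with_sums(rng, SA: int, SB: int, nA: int, nB: int):
    """One-transcript count matrix with prescribed per-condition sums."""
    cA = rng.multinomial(SA, np.ones(nA) / nA)
    cB = rng.multinomial(SB, np.ones(nB) / nB)
    mat = np.concatenate([cA, cB])[None, :]
    cond = np.array(["control"] * nA + ["treatment"] * nB)
    return mat, cond


@pytest.fixture(scope="session")
def small_population():
    """A 3,000-transcript parameter population from the built-in generator."""
    return build_parameter_population(
        GeneratorConfig(t=3000, library_size=None), seed=11
    )
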
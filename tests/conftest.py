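"""Shared fixtures and independent oracles for the test suite.

The enumeration oracles below re-derive the two-class mixture likelihood and
posterior with plain python loops, deliberately sharing no code with the
package's EM implementation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from cecdx.records import TestPanel

# the domain class is named Test*; tell pytest it is not a test container
TestPanel.__test__ = False


def enum_mixture_loglik(results, pi, se, sp) -> float:
    """Brute-force log-likelihood of the two-class conditional-independence
    mixture; NaN entries are skipped."""
    total = 0.0
    for row in np.asarray(results, dtype=float):
        a, b = pi, 1.0 - pi
        for k, y in enumerate(row):
            if math.isnan(y):
                continue
            if y == 1:
                a *= se[k]
                b *= 1.0 - sp[k]
            else:
                a *= 1.0 - se[k]
                b *= sp[k]
        total += math.log(a + b)
    return total


def enum_posterior(row, pi, se, sp) -> float:
    """Bayes-rule posterior P(D=1 | pattern) by direct enumeration."""
    a, b = pi, 1.0 - pi
    for k, y in enumerate(np.asarray(row, dtype=float)):
        if math.isnan(y):
            continue
        if y == 1:
            a *= se[k]
            b *= 1.0 - sp[k]
        else:
            a *= 1.0 - se[k]
            b *= sp[k]
    if a + b == 0:
        return pi
    return a / (a + b)


def make_panel(results, test_names=("laparoscopy", "CEC", "CA125")) -> TestPanel:
    arr = np.asarray(results, dtype=float)
    return TestPanel(tuple(test_names), arr,
                     tuple(f"p{i}" for i in range(arr.shape[0])))


def random_panel(rng: np.random.Generator, n: int, k: int = 3,
                 missing: float = 0.0) -> TestPanel:
    res = rng.integers(0, 2, (n, k)).astype(float)
    if missing > 0:
        res[rng.uniform(size=(n, k)) < missing] = np.nan
        # keep at least one observed result per patient
        allnan = np.isnan(res).all(axis=1)
        res[allnan, 0] = rng.integers(0, 2, allnan.sum())
    names = ("laparoscopy", "CEC", "CA125", "T4", "T5")[:k]
    return TestPanel(tuple(names), res, tuple(f"p{i}" for i in range(n)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
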
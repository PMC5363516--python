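from fractions import Fraction
from math import comb

import pytest

from xenosift import SimulationConfig, simulate_cohort, simulate_pileups


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Brute-force two-sided Fisher exact p by exhaustive hypergeometric
    enumeration with exact rational arithmetic (independent of scipy)."""
    r1, r2 = a + b, c + d
    c1, n = a + c, a + b + c + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)

    def pmf(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return float(sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs))


@pytest.fixture(scope="session")
def deep_cohort():
    """Deep pileup cohort: 60 clonal mutations, no artifacts, error-free."""
    config = SimulationConfig(
        seed=42,
        depth=200.0,
        n_common=40,
        n_primary_only=10,
        n_pdx_only=10,
        purity_primary=0.5,
        purity_pdx=1.0,
    )
    refs, truth = simulate_cohort(config)
    pileups = simulate_pileups(truth, config)
    return config, refs, truth, pileups
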
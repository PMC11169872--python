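"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    at = (1.0 - gc) / 2.0
    codes = rng.choice(4, size=length, p=[at, gc / 2.0, gc / 2.0, at])
    return "".join(BASES[c] for c in codes)


def random_dna_fast(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    at = (1.0 - gc) / 2.0
    codes = rng.choice(4, size=length, p=[at, gc / 2.0, gc / 2.0, at])
    return np.frombuffer(b"ACGT", dtype="S1")[codes].tobytes().decode("ascii")


def brute_force_sites(sequence: str, motif: str) -> list[int]:
    """Position-by-position slice comparison; the naive scan oracle."""
    m = len(motif)
    return [i for i in range(len(sequence) - m + 1) if sequence[i : i + m] == motif]


def expected_k_distribution(
    p_base: float,
    line_rate: float,
    sample_rate: float,
    samples_per_line: tuple[int, ...],
) -> np.ndarray:
    """Exact distribution of the number of methylated samples at one CCGG
    site, by enumeration over (base state, per-line flips) and convolution
    of per-line binomial sample-flip counts.  Independent of the simulator
    implementation."""
    n_lines = len(samples_per_line)
    n_total = sum(samples_per_line)
    pk = np.zeros(n_total + 1)
    for base in (0, 1):
        p_b = p_base if base else 1.0 - p_base
        for flips in range(2**n_lines):
            p_cfg = p_b
            dist = np.array([1.0])
            for j, n_j in enumerate(samples_per_line):
                flipped = (flips >> j) & 1
                p_cfg *= line_rate if flipped else 1.0 - line_rate
                state = base ^ flipped
                p_meth = 1.0 - sample_rate if state else sample_rate
                dist = np.convolve(dist, sps.binom.pmf(np.arange(n_j + 1), n_j, p_meth))
            pk[: dist.size] += p_cfg * dist
    return pk


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240530)
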
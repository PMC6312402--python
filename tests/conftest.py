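"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's packed uint64 encoding:
they compare characters directly, so agreement between the two routes is a
real check and not a tautology.
"""

from __future__ import annotations

import re

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from evscreen.library_model import build_library
from evscreen.sequence_design import DesignConstraints

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def naive_hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def naive_min_pairwise_hamming(seqs) -> int:
    best = len(seqs[0]) + 1
    arr = np.array([list(s) for s in seqs])
    for i in range(len(seqs) - 1):
        d = (arr[i + 1:] != arr[i]).sum(axis=1)
        best = min(best, int(d.min()))
    return best


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}
_COMP = str.maketrans("ACGTN", "TGCAN")


def naive_site_match(seq: str, motifs) -> bool:
    """Does any degenerate motif occur in seq on either strand?"""
    for motif in motifs:
        for m in (motif, motif.translate(_COMP)[::-1]):
            pat = "".join(c if len(_IUPAC[c]) == 1 else f"[{_IUPAC[c]}]" for c in m)
            if re.search(pat, seq):
                return True
    return False


def naive_barcode_ok(seq: str, c: DesignConstraints) -> bool:
    """Rule-by-rule scan of a single barcode, written independently."""
    if len(seq) != c.barcode_length:
        return False
    gc = sum(1 for ch in seq if ch in "GC") / len(seq)
    if gc < c.gc_min - 1e-12 or gc > c.gc_max + 1e-12:
        return False
    for base in "ACGT":
        if base * (c.homopolymer_max_run + 1) in seq:
            return False
    return not naive_site_match(seq, c.forbidden_sites.values())


def verify_barcode_set(seqs, c: DesignConstraints) -> None:
    """Assert every design rule with brute force (GC, runs, motifs, pairwise)."""
    for s in seqs:
        assert naive_barcode_ok(s, c), s
    if len(seqs) > 1:
        assert naive_min_pairwise_hamming(list(seqs)) >= c.min_hamming


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def fast_constraints() -> DesignConstraints:
    return DesignConstraints(rng_seed=7, candidate_budget=100_000)


@pytest.fixture(scope="session")
def small_library(fast_constraints):
    """30 genes x 10 guides + 200 controls."""
    genes = [f"G{i:03d}" for i in range(30)]
    return build_library(genes, 200, fast_constraints)
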
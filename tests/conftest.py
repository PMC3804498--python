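"""Shared fixtures and the independent brute-force scoring oracle.

The oracle re-derives every probability and energy by explicit dictionary
counting and per-term loops in pure Python, sharing no code with the
package's vectorized implementation, so it can serve as an independent
check of the worked examples.
"""

from __future__ import annotations

import math
from itertools import product

import pytest

from abpot import FrameworkMSA

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


# --------------------------------------------------------------------------
# brute-force oracle


def _oracle_cap(e_max: float, cap_scale: float) -> float:
    if e_max > 0:
        return cap_scale * e_max
    if e_max < 0:
        return e_max / cap_scale
    return math.log(cap_scale)


def oracle_tables(seqs, p_ref=0.05, cap_scale=1.1):
    """Dict-based positional/conditional energies from explicit counting."""
    m = len(seqs)
    n = len(seqs[0])
    single_counts = {}
    pair_counts = {}
    for s in seqs:
        for i, a in enumerate(s):
            single_counts[(i, a)] = single_counts.get((i, a), 0) + 1
            for j, b in enumerate(s):
                if i != j:
                    pair_counts[(i, a, j, b)] = pair_counts.get((i, a, j, b), 0) + 1

    e_single = {}
    for i in range(n):
        for a in ALPHABET:
            c = single_counts.get((i, a), 0)
            if c > 0:
                e_single[(i, a)] = -math.log((c / m) / p_ref)
    cap_s = _oracle_cap(max(e_single.values()), cap_scale)

    e_cond = {}
    for (i, a, j, b), c in pair_counts.items():
        denom = single_counts[(j, b)]
        e_cond[(i, a, j, b)] = -math.log((c / denom) / p_ref)
    cap_c = _oracle_cap(max(e_cond.values()), cap_scale)

    def get_single(i, a):
        return e_single.get((i, a), cap_s)

    def get_cond(i, a, j, b):
        return e_cond.get((i, a, j, b), cap_c)

    return {
        "n": n,
        "single": get_single,
        "cond": get_cond,
        "cap_single": cap_s,
        "cap_cond": cap_c,
    }


def oracle_score(tables, seq, omega):
    n = tables["n"]
    total = sum(tables["single"](i, seq[i]) for i in range(n))
    coupling = sum(
        tables["cond"](i, seq[i], j, seq[j])
        for i in range(n)
        for j in range(n)
        if i != j
    )
    return total + omega * coupling


def oracle_per_residue(tables, seq, omega):
    n = tables["n"]
    out = []
    for i in range(n):
        v = tables["single"](i, seq[i])
        v += omega * sum(
            tables["cond"](i, seq[i], j, seq[j]) for j in range(n) if j != i
        )
        out.append(v)
    return out


def oracle_restrained(tables, seq, reference, omega, k_res):
    ident = sum(a == b for a, b in zip(seq, reference)) / len(seq)
    return oracle_score(tables, seq, omega) + k_res * (1.0 - ident) ** 2


def enumerate_scores(tables, alphabets, omega):
    """Exhaustive (sequence, score) pairs over per-position alphabets."""
    for combo in product(*alphabets):
        seq = "".join(combo)
        yield seq, oracle_score(tables, seq, omega)


# --------------------------------------------------------------------------
# fixtures


TOY_SEQS = ("ACD", "ACD", "ACE", "GCD")


@pytest.fixture
def toy_msa() -> FrameworkMSA:
    """The 3-position worked example: 4 sequences, 2 variable columns."""
    return FrameworkMSA(
        sequences=TOY_SEQS,
        ids=("s1", "s2", "s3", "s4"),
        chain_type="heavy",
        species="human",
    )


@pytest.fixture
def toy_tables():
    return oracle_tables(TOY_SEQS)
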
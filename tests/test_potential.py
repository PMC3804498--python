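"""Frequency estimation, inverse-Boltzmann energies, scoring, persistence.

The worked examples are checked against the pure-Python counting oracle in
conftest.py, which shares no code with the vectorized implementation.
"""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from abpot import (
    FrameworkMSA,
    FrameworkPotential,
    build_model,
    consensus_sequence,
    estimate_frequencies,
    load_model,
    profile,
    save_model,
    score,
    score_restrained,
    sequence_identity,
)
from abpot.alphabet import AA_INDEX, AMINO_ACIDS

from conftest import (
    enumerate_scores,
    oracle_per_residue,
    oracle_restrained,
    oracle_score,
    oracle_tables,
)


def msa_of(*seqs, chain="heavy", species="x"):
    return FrameworkMSA(tuple(seqs), tuple(f"s{i}" for i in range(len(seqs))),
                        chain, species)


def uniform_msa(n_positions=3):
    """Latin-square construction: every column AND every ordered position
    pair is exactly uniform over the alphabet (400 sequences)."""
    seqs = []
    for a in range(20):
        for b in range(20):
            codes = [a, b] + [(a + b + k) % 20 for k in range(1, n_positions - 1)]
            seqs.append("".join(AMINO_ACIDS[c] for c in codes[:n_positions]))
    return msa_of(*seqs)


class TestFrequencies:
    def test_positional_counts(self):
        msa = msa_of("AC", "AC", "AD", "GC")
        P1, _ = estimate_frequencies(msa)
        assert P1[0, AA_INDEX["A"]] == pytest.approx(3 / 4)
        assert P1[1, AA_INDEX["C"]] == pytest.approx(3 / 4)
        assert P1[0, AA_INDEX["G"]] == pytest.approx(1 / 4)

    def test_conditional_counts(self):
        msa = msa_of("AC", "AC", "AD", "GC")
        _, Pc = estimate_frequencies(msa)
        # two of the three C-at-2 sequences carry A at 1
        assert Pc[0, AA_INDEX["A"], 1, AA_INDEX["C"]] == pytest.approx(2 / 3)
        # never-observed conditioning residue is undefined
        assert np.isnan(Pc[0, AA_INDEX["A"], 1, AA_INDEX["W"]])
        # the i == j diagonal is undefined by construction
        assert np.isnan(Pc[0, AA_INDEX["A"], 0, AA_INDEX["A"]])

    def test_constant_column(self):
        msa = msa_of("WA", "WC", "WG")
        P1, _ = estimate_frequencies(msa)
        assert P1[0, AA_INDEX["W"]] == 1.0
        assert P1[0].sum() == pytest.approx(1.0)
        assert np.count_nonzero(P1[0]) == 1


class TestBuildModel:
    def test_probability_one_twentieth_gives_zero_energy(self):
        m = build_model(uniform_msa())
        assert np.allclose(m.E_single_, 0.0)

    def test_probability_one_gives_minus_ln20(self):
        m = build_model(msa_of("WA", "WC"))
        assert m.E_single_[0, AA_INDEX["W"]] == pytest.approx(-math.log(20))

    def test_cap_from_lowest_nonzero_probability(self):
        # one residue seen once in 1000 sequences -> max finite E = ln 50,
        # cap = 1.1 * ln 50; all other columns constant
        seqs = ["AA"] * 999 + ["CA"]
        m = FrameworkPotential().fit(seqs)
        assert m.cap_single_ == pytest.approx(1.1 * math.log(50), abs=1e-12)
        # the never-seen residues at both positions score the cap
        assert m.E_single_[1, AA_INDEX["W"]] == m.cap_single_

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            FrameworkPotential().fit(["ACDE"])

    def test_row_order_invariance(self, toy_msa):
        m1 = build_model(toy_msa)
        shuffled = FrameworkMSA(
            tuple(reversed(toy_msa.sequences)),
            tuple(reversed(toy_msa.ids)),
            toy_msa.chain_type,
            toy_msa.species,
        )
        m2 = build_model(shuffled)
        assert np.array_equal(m1.E_single_, m2.E_single_)
        assert np.array_equal(m1.E_cond_, m2.E_cond_)

    def test_energy_monotone_in_probability(self):
        seqs = ["A" * 4] * 6 + ["C" * 4] * 3 + ["D" * 4]
        m = FrameworkPotential().fit(seqs)
        a, c, d = (m.E_single_[0, AA_INDEX[x]] for x in "ACD")
        assert a < c < d  # P = 0.6 > 0.3 > 0.1


class TestScore:
    def test_uniform_model_scores_zero_for_any_sequence(self):
        m = build_model(uniform_msa())
        for seq, w in [("AAA", 0.0), ("WYC", 1.0), ("MKV", 2.5)]:
            assert m.score(seq, omega=w) == pytest.approx(0.0, abs=1e-12)

    def test_omega_zero_is_positional_sum(self, toy_msa):
        m = build_model(toy_msa)
        expected = sum(
            m.E_single_[i, AA_INDEX[c]] for i, c in enumerate("ACD")
        )
        assert m.score("ACD", omega=0.0) == pytest.approx(expected, abs=1e-12)

    def test_worked_example_against_bruteforce(self, toy_msa, toy_tables):
        m = build_model(toy_msa)
        for seq in ("ACD", "ACE", "GCD", "GCE", "WCD"):
            for w in (0.0, 1.0, 2.0):
                assert m.score(seq, omega=w) == pytest.approx(
                    oracle_score(toy_tables, seq, w), abs=1e-12
                )

    def test_length_mismatch_rejected(self, toy_msa):
        m = build_model(toy_msa)
        with pytest.raises(ValueError, match="length"):
            m.score("ACDE")

    def test_unfitted_estimator_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            FrameworkPotential().score("ACD")

    def test_training_rows_beat_never_observed_residues(self, toy_msa):
        m = build_model(toy_msa)
        worst_training = max(m.score(s, omega=1.0) for s in toy_msa.sequences)
        never_observed = m.score("WWW", omega=1.0)  # W absent everywhere
        assert worst_training < never_observed


class TestRestraintAndIdentity:
    def test_identity_examples(self):
        assert sequence_identity("ACDE", "ACDE") == 1.0
        assert sequence_identity("ACDE", "ACDF") == 0.75
        assert sequence_identity("AAAA", "CCCC") == 0.0

    def test_identity_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            sequence_identity("ACD", "ACDE")

    def test_restraint_vanishes_at_reference(self, toy_msa):
        m = build_model(toy_msa)
        assert m.score_restrained("ACD", "ACD", omega=1.0, k_res=5.0) == (
            pytest.approx(m.score("ACD", omega=1.0))
        )

    def test_zero_weight_disables_restraint(self, toy_msa):
        m = build_model(toy_msa)
        assert m.score_restrained("ACD", "GCE", omega=1.0, k_res=0.0) == (
            pytest.approx(m.score("ACD", omega=1.0))
        )

    def test_quadratic_identity_deficit(self):
        seqs = ["ACDE"] * 3 + ["ACDF"]
        m = FrameworkPotential().fit(seqs)
        base = m.score("ACDE", omega=0.0)
        restrained = m.score_restrained("ACDE", "ACDF", omega=0.0, k_res=2.0)
        assert restrained - base == pytest.approx(2.0 * 0.25**2, abs=1e-12)


class TestProfile:
    def test_uniform_model_all_zero(self):
        m = build_model(uniform_msa())
        b = m.profile("MKV", omega=1.0)
        assert np.allclose(b.per_residue, 0.0)

    def test_omega_zero_per_residue_is_positional(self, toy_msa):
        m = build_model(toy_msa)
        b = m.profile("GCD", omega=0.0)
        expected = [m.E_single_[i, AA_INDEX[c]] for i, c in enumerate("GCD")]
        assert b.per_residue == pytest.approx(expected)

    def test_worked_example_per_residue_against_bruteforce(
        self, toy_msa, toy_tables
    ):
        m = build_model(toy_msa)
        for seq in ("ACD", "GCE"):
            b = m.profile(seq, omega=1.0)
            assert b.per_residue == pytest.approx(
                oracle_per_residue(toy_tables, seq, 1.0), abs=1e-12
            )

    def test_decomposition_sums(self, toy_msa):
        m = build_model(toy_msa)
        b = m.profile("GCD", omega=2.0, reference="ACD", k_res=3.0)
        assert b.per_residue.sum() == pytest.approx(
            b.single_total + b.coupling_total, abs=1e-9
        )
        assert b.total == pytest.approx(
            b.single_total + b.coupling_total + b.restraint, abs=1e-12
        )
        assert b.total == pytest.approx(
            m.score_restrained("GCD", "ACD", omega=2.0, k_res=3.0), abs=1e-9
        )

    def test_to_frame_columns(self, toy_msa):
        df = build_model(toy_msa).profile("ACD", omega=1.0).to_frame("ACD")
        assert list(df.columns) == ["position", "residue", "single",
                                    "coupling", "total"]
        assert list(df["position"]) == [1, 2, 3]


class TestConsensus:
    def test_consensus_of_toy(self, toy_msa):
        assert consensus_sequence(build_model(toy_msa)) == "ACD"

    def test_modal_tie_broken_alphabetically(self):
        m = FrameworkPotential().fit(["A", "C"] * 2)
        assert consensus_sequence(m) == "A"

    def test_consensus_minimizes_omega_zero_score(self, toy_tables, toy_msa):
        m = build_model(toy_msa)
        observed = [sorted({s[i] for s in toy_msa.sequences})
                    for i in range(3)]
        best_seq = min(enumerate_scores(toy_tables, observed, 0.0),
                       key=lambda kv: kv[1])[0]
        assert best_seq == consensus_sequence(m)
        assert m.score(best_seq, omega=0.0) == min(
            m.score("".join(c), omega=0.0) for c in product(*observed)
        )


# --------------------------------------------------------------------------
# properties over random alignments


aa_text = st.text(alphabet=AMINO_ACIDS, min_size=4, max_size=4)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(seqs=st.lists(aa_text, min_size=2, max_size=25))
def test_model_invariants_random_alignments(seqs):
    """Normalization, energy definition and cap dominance on arbitrary MSAs."""
    m = FrameworkPotential().fit(seqs)
    assert np.allclose(m.P_single_.sum(axis=1), 1.0, rtol=1e-9)

    defined = ~np.isnan(m.P_cond_)
    sums = np.where(defined, m.P_cond_, 0.0).sum(axis=1)  # over residue a
    counted = defined.any(axis=1)
    assert np.allclose(sums[counted], 1.0, rtol=1e-9)

    obs = m.counts_single_ > 0
    assert np.allclose(
        m.E_single_[obs], -np.log(m.P_single_[obs] / m.p_ref), rtol=1e-12
    )
    assert np.all(m.E_single_[~obs] == m.cap_single_)
    assert m.cap_single_ > m.E_single_[obs].max()

    n = m.n_positions_
    off = ~np.eye(n, dtype=bool)
    finite_cond = (m.counts_pair_ > 0) & off[:, None, :, None].repeat(20, 1).repeat(20, 3)
    if finite_cond.any():
        assert m.cap_cond_ > m.E_cond_[finite_cond].max()


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    seqs=st.lists(aa_text, min_size=2, max_size=12),
    query=aa_text,
    ref=aa_text,
    omega=st.floats(0, 4),
    k_res=st.floats(0, 10),
)
def test_decomposition_completeness_random(seqs, query, ref, omega, k_res):
    m = FrameworkPotential().fit(seqs)
    b = m.profile(query, omega=omega, reference=ref, k_res=k_res)
    assert b.per_residue.sum() + b.restraint == pytest.approx(b.total, rel=1e-9)
    assert b.total == pytest.approx(
        m.score_restrained(query, ref, omega=omega, k_res=k_res), rel=1e-9
    )


# --------------------------------------------------------------------------
# persistence


class TestPersistence:
    def test_round_trip_bit_identical_tables(self, toy_msa, tmp_path):
        m = build_model(toy_msa)
        p = tmp_path / "toy.model"
        save_model(m, p)
        m2 = load_model(p)
        for attr in ("P_single_", "E_single_", "E_cond_", "counts_pair_"):
            a, b = getattr(m, attr), getattr(m2, attr)
            assert np.array_equal(a, b, equal_nan=True), attr
        assert m2.cap_single_ == m.cap_single_
        assert m2.cap_cond_ == m.cap_cond_
        assert (m2.p_ref, m2.cap_scale) == (m.p_ref, m.cap_scale)
        assert (m2.species_, m2.chain_type_) == (m.species_, m.chain_type_)
        assert m2.n_sequences_ == m.n_sequences_

    def test_round_trip_preserves_scores_100_positions(self, tmp_path):
        from abpot.synthgen import SyntheticSpec, generate_msa

        rng = np.random.default_rng(7)
        pwm = rng.dirichlet(np.ones(20), size=100)
        spec = SyntheticSpec(100, 150, pwm, seed=3)
        m = build_model(generate_msa(spec))
        p = tmp_path / "big.model"
        m.save(p)
        m2 = load_model(p)
        q = "".join(rng.choice(list(AMINO_ACIDS), 100))
        assert m2.score(q, omega=2.0) == m.score(q, omega=2.0)

    def test_wrong_declared_length_rejected(self, toy_msa, tmp_path):
        m = build_model(toy_msa)
        p = tmp_path / "toy.model"
        m.save(p)
        text = p.read_text().replace("n_positions\t3", "n_positions\t4", 1)
        bad = tmp_path / "bad.model"
        bad.write_text(text)
        with pytest.raises(ValueError):
            load_model(bad)

    def test_not_a_model_file(self, tmp_path):
        p = tmp_path / "junk.model"
        p.write_text("hello\n")
        with pytest.raises(ValueError, match="not an abpot model"):
            load_model(p)

    def test_version_mismatch(self, toy_msa, tmp_path):
        m = build_model(toy_msa)
        p = tmp_path / "toy.model"
        m.save(p)
        text = p.read_text().replace("version=1", "version=99", 1)
        p.write_text(text)
        with pytest.raises(ValueError, match="version"):
            load_model(p)
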
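"""Inverse-Boltzmann statistical potentials for antibody frameworks.

The model behind this module treats a framework sequence as a system of
discrete states, one per alignment position. From a gapless alignment of one
species/chain type two families of probabilities are counted:

* positional: ``P_i(A)``, the frequency of residue ``A`` at position ``i``;
* conditional: ``P_ij(A|B)``, the frequency of ``A`` at ``i`` among the
  sequences carrying ``B`` at ``j`` (an asymmetric quantity, kept for all
  ordered position pairs ``i != j``).

Each probability is converted to a dimensionless statistical energy by the
inverse Boltzmann relation ``E = -ln(P / p_ref)`` with the uniform reference
``p_ref = 1/20`` (the thermal prefactor is dropped throughout). Events never
observed in the alignment cannot be logged; they are assigned a capping
energy derived from the rarest event that *was* observed, scaled by
``cap_scale`` so that absent residues always cost at least as much as the
rarest observed ones.

The total score of a sequence ``S`` is

    F(S) = sum_i E_i(s_i) + omega * sum_{i != j} E_ij(s_i | s_j)

with ``omega`` balancing positional against coupling contributions; lower
scores mean the sequence is more typical of the pool the model was fitted
on. An optional harmonic restraint ``k_res * (1 - ID(S, R))**2`` towards a
reference sequence ``R`` (``ID`` = fractional sequence identity) turns the
score into the objective used for stochastic humanization.

:class:`FrameworkPotential` is a scikit-learn style estimator (``fit`` on an
alignment, score afterwards); the module-level functions mirror it for
script use.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .alphabet import AMINO_ACIDS, N_AA, decode, encode
from .msa import FrameworkMSA, QuerySequence

MODEL_FORMAT_VERSION = "1"

__all__ = [
    "FrameworkPotential",
    "ScoreBreakdown",
    "estimate_frequencies",
    "build_model",
    "score",
    "score_restrained",
    "sequence_identity",
    "profile",
    "save_model",
    "load_model",
]


# --------------------------------------------------------------------------
# helpers


def _as_codes(seq: "str | QuerySequence | np.ndarray") -> np.ndarray:
    if isinstance(seq, QuerySequence):
        return encode(seq.residues)
    if isinstance(seq, str):
        return encode(seq)
    return np.asarray(seq, dtype=np.int8)


def _cap_value(e_max_finite: float, cap_scale: float) -> float:
    """Capping energy for never-observed events.

    The cap is the largest finite energy scaled by ``cap_scale`` so that it
    stays *above* every finite entry. For degenerate models whose rarest
    observed probability exceeds ``p_ref`` (all finite energies negative) a
    plain multiplication would push the cap below the finite range, so the
    magnitude is shrunk instead; an exactly zero maximum maps to
    ``ln(cap_scale)``.
    """
    if e_max_finite > 0:
        return cap_scale * e_max_finite
    if e_max_finite < 0:
        return e_max_finite / cap_scale
    return math.log(cap_scale)


def sequence_identity(a: "str | QuerySequence", b: "str | QuerySequence") -> float:
    """Fraction of identical positions between two equal-length sequences."""
    ca, cb = _as_codes(a), _as_codes(b)
    if ca.shape != cb.shape:
        raise ValueError(f"length mismatch: {ca.size} vs {cb.size}")
    return float(np.mean(ca == cb))


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-residue decomposition of a sequence score.

    ``per_residue[i]`` collects the positional energy of residue ``i`` plus
    its omega-weighted conditional terms (the pair term ``(i, j)`` is
    attributed to position ``i``), so the vector sums to
    ``single_total + coupling_total``. The restraint is reported separately
    and never attributed to residues.
    """

    per_residue: np.ndarray
    singles: np.ndarray
    couplings: np.ndarray
    single_total: float
    coupling_total: float
    restraint: float
    total: float

    def to_frame(self, residues: str):
        """Tabular view (one row per position), for reports and the CLI."""
        import pandas as pd

        n = self.per_residue.size
        return pd.DataFrame(
            {
                "position": np.arange(1, n + 1),
                "residue": list(residues),
                "single": self.singles,
                "coupling": self.couplings,
                "total": self.per_residue,
            }
        )


# --------------------------------------------------------------------------
# estimator


class FrameworkPotential(BaseEstimator):
    """Species/chain-specific scoring model for framework sequences.

    Parameters
    ----------
    p_ref : float, default 1/20
        Reference probability of the inverse-Boltzmann transform.
    cap_scale : float, default 1.1
        Scale applied to the largest finite energy to obtain the cap used
        for zero-frequency events.
    omega : float, default 2.0
        Default weight of the conditional (coupling) term; every scoring
        method accepts an explicit ``omega`` override.

    Attributes (after :meth:`fit`)
    ------------------------------
    n_positions_ : int
    n_sequences_ : int
    counts_single_ : (N, 20) int array of residue counts per position.
    counts_pair_ : (N, 20, N, 20) int array of joint counts; the diagonal
        blocks hold the positional counts.
    P_single_ : (N, 20) positional probabilities.
    P_cond_ : (N, 20, N, 20) conditional probabilities ``P(a at i | b at j)``
        indexed ``[i, a, j, b]``; NaN where undefined (``b`` never at ``j``,
        or ``i == j``).
    E_single_, E_cond_ : energies; capped entries hold the cap value, the
        ``i == j`` diagonal of ``E_cond_`` is zero so that sums over all
        ordered pairs can include it harmlessly.
    cap_single_, cap_cond_ : float caps for the two tables.
    """

    def __init__(self, p_ref: float = 1.0 / N_AA, cap_scale: float = 1.1,
                 omega: float = 2.0):
        self.p_ref = p_ref
        self.cap_scale = cap_scale
        self.omega = omega

    # -- fitting -----------------------------------------------------------

    def fit(self, X: "FrameworkMSA | Sequence[str]", y=None) -> "FrameworkPotential":
        """Count frequencies from a gapless alignment and build all tables."""
        if isinstance(X, FrameworkMSA):
            arr = X.to_array()
            self.chain_type_ = X.chain_type
            self.species_ = X.species
        else:
            seqs = list(X)
            if len(seqs) < 2:
                raise ValueError(
                    f"insufficient data: need at least 2 sequences, got {len(seqs)}"
                )
            arr = np.vstack([_as_codes(s) for s in seqs])
            self.chain_type_ = getattr(self, "chain_type_", "heavy")
            self.species_ = getattr(self, "species_", "unknown")
        m, n = arr.shape
        if m < 2:
            raise ValueError("insufficient data: need at least 2 sequences")

        one_hot = np.zeros((m, n * N_AA), dtype=np.float32)
        rows = np.repeat(np.arange(m), n)
        cols = (np.arange(n) * N_AA)[None, :] + arr
        one_hot[rows, cols.ravel()] = 1.0
        joint = one_hot.T @ one_hot  # exact: integer-valued float32, m < 2**24
        counts_pair = np.rint(joint).astype(np.int64)
        counts_pair = counts_pair.reshape(n, N_AA, n, N_AA)
        counts_single = np.einsum("iaia->ia", counts_pair).copy()

        self._set_tables(counts_single, counts_pair, m)
        return self

    def _set_tables(self, counts_single: np.ndarray, counts_pair: np.ndarray,
                    n_sequences: int) -> None:
        n = counts_single.shape[0]
        m = n_sequences
        self.n_positions_ = n
        self.n_sequences_ = m
        self.counts_single_ = counts_single
        self.counts_pair_ = counts_pair

        P_single = counts_single / m
        with np.errstate(divide="ignore", invalid="ignore"):
            P_cond = counts_pair / counts_single[None, None, :, :]
        diag = np.arange(n)
        P_cond[diag, :, diag, :] = np.nan

        e_single = np.full((n, N_AA), np.nan)
        obs = counts_single > 0
        e_single[obs] = -np.log(P_single[obs] / self.p_ref)
        cap_single = _cap_value(float(np.max(e_single[obs])), self.cap_scale)
        e_single[~obs] = cap_single

        e_cond = np.full_like(P_cond, np.nan)
        obs_pair = counts_pair > 0
        obs_pair[diag, :, diag, :] = False
        e_cond[obs_pair] = -np.log(P_cond[obs_pair] / self.p_ref)
        if obs_pair.any():
            cap_cond = _cap_value(float(np.max(e_cond[obs_pair])), self.cap_scale)
        else:  # single-position model: no ordered pairs exist
            cap_cond = cap_single
        e_cond[~obs_pair] = cap_cond
        e_cond[diag, :, diag, :] = 0.0  # excluded from every pair sum

        self.P_single_ = P_single
        self.P_cond_ = P_cond
        self.E_single_ = e_single
        self.E_cond_ = e_cond
        self.cap_single_ = cap_single
        self.cap_cond_ = cap_cond

    def _check_fitted(self) -> None:
        if not hasattr(self, "E_single_"):
            raise AttributeError("FrameworkPotential is not fitted yet; call fit()")

    def _check_seq(self, seq) -> np.ndarray:
        self._check_fitted()
        codes = _as_codes(seq)
        if codes.size != self.n_positions_:
            raise ValueError(
                f"sequence length {codes.size} does not match model "
                f"length {self.n_positions_}"
            )
        return codes

    # -- scoring -----------------------------------------------------------

    def _pair_matrix(self, codes: np.ndarray) -> np.ndarray:
        """(N, N) matrix of conditional energies E(s_i at i | s_j at j)."""
        idx = np.arange(self.n_positions_)
        return self.E_cond_[idx[:, None], codes[:, None], idx[None, :], codes[None, :]]

    def score(self, X: "str | QuerySequence", omega: float | None = None) -> float:
        """Total score of one sequence; lower = more typical of the pool."""
        codes = self._check_seq(X)
        w = self.omega if omega is None else omega
        single = float(self.E_single_[np.arange(self.n_positions_), codes].sum())
        coupling = float(self._pair_matrix(codes).sum())  # diagonal stored as 0
        return single + w * coupling

    def score_sequences(self, X: Iterable, omega: float | None = None) -> np.ndarray:
        """Vector of scores for an iterable of sequences (or an MSA)."""
        if isinstance(X, FrameworkMSA):
            X = X.sequences
        return np.array([self.score(s, omega=omega) for s in X])

    def score_restrained(self, X, reference, omega: float | None = None,
                         k_res: float = 0.0) -> float:
        """Score plus the harmonic identity restraint to ``reference``."""
        base = self.score(X, omega=omega)
        ident = sequence_identity(_as_codes(X), _as_codes(reference))
        return base + k_res * (1.0 - ident) ** 2

    def profile(self, X, omega: float | None = None, reference=None,
                k_res: float = 0.0) -> ScoreBreakdown:
        """Decompose a sequence's score into per-residue contributions."""
        codes = self._check_seq(X)
        w = self.omega if omega is None else omega
        singles = self.E_single_[np.arange(self.n_positions_), codes].copy()
        couplings = w * self._pair_matrix(codes).sum(axis=1)
        restraint = 0.0
        if reference is not None:
            ref_codes = _as_codes(reference)
            if ref_codes.size != codes.size:
                raise ValueError("reference length does not match sequence length")
            ident = float(np.mean(codes == ref_codes))
            restraint = k_res * (1.0 - ident) ** 2
        single_total = float(singles.sum())
        coupling_total = float(couplings.sum())
        return ScoreBreakdown(
            per_residue=singles + couplings,
            singles=singles,
            couplings=couplings,
            single_total=single_total,
            coupling_total=coupling_total,
            restraint=restraint,
            total=single_total + coupling_total + restraint,
        )

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the model as structured text (see docs/formats.md).

        Integer count tables are stored rather than float energies: loading
        rebuilds the probability/energy tables through the identical code
        path, so a round-trip reproduces every table bit-for-bit while the
        file stays diffable.
        """
        self._check_fitted()
        n = self.n_positions_
        buf = io.StringIO()
        buf.write(f"#abpot-model\tversion={MODEL_FORMAT_VERSION}\n")
        buf.write(f"n_positions\t{n}\n")
        buf.write(f"n_sequences\t{self.n_sequences_}\n")
        buf.write(f"p_ref\t{self.p_ref!r}\n")
        buf.write(f"cap_scale\t{self.cap_scale!r}\n")
        buf.write(f"omega\t{self.omega!r}\n")
        buf.write(f"chain_type\t{self.chain_type_}\n")
        buf.write(f"species\t{self.species_}\n")
        buf.write(f"alphabet\t{AMINO_ACIDS}\n")
        buf.write("counts_single\n")
        for i in range(n):
            buf.write(" ".join(map(str, self.counts_single_[i])) + "\n")
        buf.write("counts_pair\n")
        for i in range(n):
            for j in range(i + 1, n):
                block = self.counts_pair_[i, :, j, :].ravel()
                buf.write(f"{i} {j} " + " ".join(map(str, block)) + "\n")
        Path(path).write_text(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "FrameworkPotential":
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith("#abpot-model"):
            raise ValueError(f"{path}: not an abpot model file")
        version = lines[0].split("version=", 1)[-1].strip()
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported model format version {version!r}")
        header: dict[str, str] = {}
        k = 1
        while k < len(lines) and lines[k] != "counts_single":
            key, _, value = lines[k].partition("\t")
            header[key] = value
            k += 1
        required = {"n_positions", "n_sequences", "p_ref", "cap_scale",
                    "chain_type", "species", "alphabet"}
        missing = required - header.keys()
        if missing:
            raise ValueError(f"{path}: missing header fields {sorted(missing)}")
        if header["alphabet"] != AMINO_ACIDS:
            raise ValueError(f"{path}: unexpected alphabet")
        n = int(header["n_positions"])
        m = int(header["n_sequences"])

        model = cls(
            p_ref=float(header["p_ref"]),
            cap_scale=float(header["cap_scale"]),
            omega=float(header.get("omega", 2.0)),
        )
        model.chain_type_ = header["chain_type"]
        model.species_ = header["species"]

        if k >= len(lines) or lines[k] != "counts_single":
            raise ValueError(f"{path}: counts_single section missing")
        k += 1
        counts_single = np.zeros((n, N_AA), dtype=np.int64)
        for i in range(n):
            row = np.array(lines[k + i].split(), dtype=np.int64)
            if row.size != N_AA:
                raise ValueError(
                    f"{path}: counts_single row {i} has {row.size} entries, "
                    f"expected {N_AA} (declared n_positions={n})"
                )
            counts_single[i] = row
        k += n
        if k >= len(lines) or lines[k] != "counts_pair":
            raise ValueError(
                f"{path}: counts_pair section missing after {n} single rows "
                f"(declared n_positions inconsistent with tables?)"
            )
        k += 1
        counts_pair = np.zeros((n, N_AA, n, N_AA), dtype=np.int64)
        expected_rows = n * (n - 1) // 2
        body = lines[k:]
        if len(body) != expected_rows:
            raise ValueError(
                f"{path}: expected {expected_rows} pair-count rows for "
                f"n_positions={n}, found {len(body)}"
            )
        for line in body:
            vals = np.array(line.split(), dtype=np.int64)
            if vals.size != 2 + N_AA * N_AA:
                raise ValueError(f"{path}: malformed pair-count row")
            i, j = int(vals[0]), int(vals[1])
            block = vals[2:].reshape(N_AA, N_AA)
            counts_pair[i, :, j, :] = block
            counts_pair[j, :, i, :] = block.T
        # diagonal blocks are diag(counts_single), exactly as fit() produces
        aa = np.arange(N_AA)
        for i in range(n):
            counts_pair[i, aa, i, aa] = counts_single[i]

        if counts_single.sum() != n * m:
            raise ValueError(
                f"{path}: count tables inconsistent with n_sequences={m}"
            )
        model._set_tables(counts_single, counts_pair, m)
        return model


# --------------------------------------------------------------------------
# functional surface


def estimate_frequencies(msa: FrameworkMSA) -> tuple[np.ndarray, np.ndarray]:
    """Raw positional and conditional probability tables of an alignment.

    Returns ``(P_single, P_cond)`` with ``P_cond[i, a, j, b] = P(a at i |
    b at j)``; undefined entries (``b`` never at ``j``, or ``i == j``)
    are NaN.
    """
    model = FrameworkPotential().fit(msa)
    return model.P_single_, model.P_cond_


def build_model(msa: FrameworkMSA, p_ref: float = 1.0 / N_AA,
                cap_scale: float = 1.1, omega: float = 2.0) -> FrameworkPotential:
    """Fit a :class:`FrameworkPotential` on an alignment."""
    return FrameworkPotential(p_ref=p_ref, cap_scale=cap_scale, omega=omega).fit(msa)


def score(model: FrameworkPotential, seq, omega: float | None = None) -> float:
    return model.score(seq, omega=omega)


def score_restrained(model: FrameworkPotential, seq, reference,
                     omega: float | None = None, k_res: float = 0.0) -> float:
    return model.score_restrained(seq, reference, omega=omega, k_res=k_res)


def profile(model: FrameworkPotential, seq, omega: float | None = None,
            reference=None, k_res: float = 0.0) -> ScoreBreakdown:
    return model.profile(seq, omega=omega, reference=reference, k_res=k_res)


def consensus_sequence(model: FrameworkPotential) -> str:
    """Per-position modal-residue sequence (ties broken alphabetically).

    With ``omega = 0`` and no restraint this is the global score optimum,
    since the positional terms are independent and energies decrease
    strictly with probability.
    """
    model._check_fitted()
    return decode(np.argmax(model.counts_single_, axis=1))


def save_model(model: FrameworkPotential, path: str | Path) -> None:
    model.save(path)


def load_model(path: str | Path) -> FrameworkPotential:
    return FrameworkPotential.load(path)
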
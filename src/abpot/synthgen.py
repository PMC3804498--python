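"""Synthetic framework alignments with known statistical structure.

Real framework alignments combine strong positional preferences with
species-specific pairwise couplings (largely germline-gene fingerprints).
This module generates alignments whose positional frequencies and pairwise
joint distributions are *specified exactly*, so every estimator and the
sampler can be tested against analytic ground truth without any external
dataset.

Coupled position pairs are required to be mutually disjoint, which keeps the
generative distribution factorizable: uncoupled positions are independent
categorical draws from their probability row, coupled pairs are joint
categorical draws over the 400 residue combinations.

The ``*_species_pair`` helpers freeze the two-population study conditions
used throughout the validation suite: 60 positions at modal mass 0.7, 3000
sequences per species, a 30% positional shift and/or five coupled pairs
present in species A only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AMINO_ACIDS, N_AA
from .msa import FrameworkMSA

__all__ = [
    "SyntheticSpec",
    "generate_msa",
    "generate_two_species",
    "shifted_species_pair",
    "coupled_species_pair",
    "read_spec",
    "write_spec",
]

_TOL = 1e-9


@dataclass
class SyntheticSpec:
    """Exact generative description of one synthetic alignment.

    pwm : (N, 20) array, one probability row per position (rows at coupled
        positions are implied by the pair's joint distribution and must
        equal its marginals).
    couplings : list of ``((i, j), joint)`` with ``joint`` a (20, 20)
        distribution over residue pairs; coupled pairs must be disjoint.
    """

    n_positions: int
    n_sequences: int
    pwm: np.ndarray
    couplings: list[tuple[tuple[int, int], np.ndarray]] = field(default_factory=list)
    seed: int | None = None
    species: str = "synthetic"
    chain_type: str = "heavy"

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.shape != (self.n_positions, N_AA):
            raise ValueError(
                f"pwm shape {self.pwm.shape} does not match "
                f"({self.n_positions}, {N_AA})"
            )
        if np.any(self.pwm < -_TOL):
            raise ValueError("pwm entries must be non-negative")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("every pwm row must sum to 1")
        used: set[int] = set()
        for (i, j), joint in self.couplings:
            joint = np.asarray(joint, dtype=float)
            if i == j or not (0 <= i < self.n_positions) or not (
                0 <= j < self.n_positions
            ):
                raise ValueError(f"invalid coupled pair ({i}, {j})")
            if {i, j} & used:
                raise ValueError("coupled position pairs must be disjoint")
            used.update((i, j))
            if joint.shape != (N_AA, N_AA):
                raise ValueError("joint distributions must be 20x20")
            if np.any(joint < -_TOL) or not np.isclose(joint.sum(), 1.0, atol=1e-6):
                raise ValueError("every joint distribution must sum to 1")

    @property
    def coupled_positions(self) -> set[int]:
        out: set[int] = set()
        for (i, j), _ in self.couplings:
            out.update((i, j))
        return out


def _sample_categorical(p: np.ndarray, size: int,
                        rng: np.random.Generator) -> np.ndarray:
    cdf = np.cumsum(p)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(size), side="right")


def generate_msa(spec: SyntheticSpec) -> FrameworkMSA:
    """Draw an alignment from a :class:`SyntheticSpec` (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    m, n = spec.n_sequences, spec.n_positions
    arr = np.zeros((m, n), dtype=np.int8)
    coupled = spec.coupled_positions
    for i in range(n):
        if i in coupled:
            continue
        arr[:, i] = _sample_categorical(spec.pwm[i], m, rng)
    for (i, j), joint in spec.couplings:
        flat = _sample_categorical(np.asarray(joint, dtype=float).ravel(), m, rng)
        arr[:, i], arr[:, j] = np.divmod(flat, N_AA)
    seqs = ["".join(AMINO_ACIDS[c] for c in row) for row in arr]
    ids = [f"{spec.species}_{k}" for k in range(m)]
    return FrameworkMSA(sequences=tuple(seqs), ids=tuple(ids),
                        chain_type=spec.chain_type, species=spec.species)


def generate_two_species(spec_a: SyntheticSpec,
                         spec_b: SyntheticSpec) -> tuple[FrameworkMSA, FrameworkMSA]:
    """Two alignments representing two species; lengths must agree."""
    if spec_a.n_positions != spec_b.n_positions:
        raise ValueError(
            f"species specs differ in length: {spec_a.n_positions} vs "
            f"{spec_b.n_positions}"
        )
    return generate_msa(spec_a), generate_msa(spec_b)


# --------------------------------------------------------------------------
# structured-text spec files


def write_spec(spec: SyntheticSpec, path) -> None:
    """Write a :class:`SyntheticSpec` as structured text."""
    from pathlib import Path

    lines = ["#abpot-synthspec\tversion=1",
             f"n_positions\t{spec.n_positions}",
             f"n_sequences\t{spec.n_sequences}",
             f"seed\t{'' if spec.seed is None else spec.seed}",
             f"species\t{spec.species}",
             f"chain_type\t{spec.chain_type}",
             "pwm"]
    for row in spec.pwm:
        lines.append(" ".join(repr(float(v)) for v in row))
    for (i, j), joint in spec.couplings:
        lines.append(f"coupling\t{i}\t{j}")
        for row in np.asarray(joint, dtype=float):
            lines.append(" ".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_spec(path) -> SyntheticSpec:
    """Read a :class:`SyntheticSpec` written by :func:`write_spec`."""
    from pathlib import Path

    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines or not lines[0].startswith("#abpot-synthspec"):
        raise ValueError(f"{path}: not a synthetic-spec file")
    header: dict[str, str] = {}
    k = 1
    while k < len(lines) and lines[k] != "pwm":
        key, _, value = lines[k].partition("\t")
        header[key] = value
        k += 1
    if k == len(lines):
        raise ValueError(f"{path}: pwm section missing")
    k += 1
    n = int(header["n_positions"])
    pwm = np.array([np.array(lines[k + i].split(), dtype=float)
                    for i in range(n)])
    k += n
    couplings = []
    while k < len(lines):
        parts = lines[k].split("\t")
        if parts[0] != "coupling" or len(parts) != 3:
            raise ValueError(f"{path}: malformed coupling header {lines[k]!r}")
        i, j = int(parts[1]), int(parts[2])
        joint = np.array([np.array(lines[k + 1 + r].split(), dtype=float)
                          for r in range(N_AA)])
        couplings.append(((i, j), joint))
        k += 1 + N_AA
    seed = int(header["seed"]) if header.get("seed") else None
    return SyntheticSpec(
        n_positions=n,
        n_sequences=int(header["n_sequences"]),
        pwm=pwm,
        couplings=couplings,
        seed=seed,
        species=header.get("species", "synthetic"),
        chain_type=header.get("chain_type", "heavy"),
    )


# --------------------------------------------------------------------------
# frozen two-population study conditions


def _modal_row(modal: int, modal_mass: float) -> np.ndarray:
    row = np.full(N_AA, (1.0 - modal_mass) / (N_AA - 1))
    row[modal] = modal_mass
    return row


def _diagonal_joint(modal_i: int, modal_j: int, modal_mass: float) -> np.ndarray:
    """Joint with mass ``modal_mass`` on the modal combination and the rest
    on a bijection between the remaining residues, so both marginals equal
    the positional rows while off-bijection combinations have probability 0."""
    joint = np.zeros((N_AA, N_AA))
    joint[modal_i, modal_j] = modal_mass
    others_i = [a for a in range(N_AA) if a != modal_i]
    others_j = [b for b in range(N_AA) if b != modal_j]
    for a, b in zip(others_i, others_j):
        joint[a, b] = (1.0 - modal_mass) / (N_AA - 1)
    return joint


def _species_pair(n_positions: int, n_sequences: int, modal_mass: float,
                  frac_shifted: float, n_coupled: int,
                  seed: int) -> tuple[SyntheticSpec, SyntheticSpec]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_positions)
    coupled_pos = order[: 2 * n_coupled]
    n_shift = int(round(frac_shifted * n_positions))
    shifted = order[2 * n_coupled: 2 * n_coupled + n_shift]

    modal_a = rng.integers(N_AA, size=n_positions)
    modal_b = modal_a.copy()
    for p in shifted:
        modal_b[p] = (modal_a[p] + 1 + rng.integers(N_AA - 1)) % N_AA

    pwm_a = np.vstack([_modal_row(int(a), modal_mass) for a in modal_a])
    pwm_b = np.vstack([_modal_row(int(b), modal_mass) for b in modal_b])

    couplings_a = []
    for k in range(n_coupled):
        i, j = int(coupled_pos[2 * k]), int(coupled_pos[2 * k + 1])
        couplings_a.append(
            ((i, j), _diagonal_joint(int(modal_a[i]), int(modal_a[j]), modal_mass))
        )

    spec_a = SyntheticSpec(n_positions, n_sequences, pwm_a,
                           couplings=couplings_a, seed=int(rng.integers(2**31)),
                           species="species_a")
    spec_b = SyntheticSpec(n_positions, n_sequences, pwm_b,
                           couplings=[], seed=int(rng.integers(2**31)),
                           species="species_b")
    return spec_a, spec_b


def shifted_species_pair(seed: int, n_positions: int = 60,
                         n_sequences: int = 3000, modal_mass: float = 0.7,
                         frac_shifted: float = 0.3,
                         n_coupled: int = 5) -> tuple[SyntheticSpec, SyntheticSpec]:
    """Discrimination fixture: species B shifts the modal residue at 30% of
    positions and lacks species A's five coupled pairs."""
    return _species_pair(n_positions, n_sequences, modal_mass, frac_shifted,
                         n_coupled, seed)


def coupled_species_pair(seed: int, n_positions: int = 60,
                         n_sequences: int = 3000, modal_mass: float = 0.7,
                         n_coupled: int = 5) -> tuple[SyntheticSpec, SyntheticSpec]:
    """Coupling-isolation fixture: positional margins identical in both
    species; the species differ only in the coupled-pair joints."""
    return _species_pair(n_positions, n_sequences, modal_mass, 0.0,
                         n_coupled, seed)
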
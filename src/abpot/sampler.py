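"""Metropolis Monte Carlo sampling of framework sequences.

Stochastic humanization treats re-engineering of a (typically murine)
framework as minimization of the restrained objective

    F(S) = score(S; omega) + k_res * (1 - ID(S, R))**2

where ``R`` is the parental sequence. The sampler walks sequence space with
two move types — a single random mutation at a random position, and a double
mutation at two distinct random positions — and accepts a proposal with the
classical Metropolis probability ``min(1, exp(-beta * dF))``. ``beta`` plays
the role of an inverse temperature in score units and is tuned for
acceptance rate, not for any physical meaning; values giving roughly 20-50%
acceptance sample efficiently.

Score differences are evaluated incrementally (only the terms touching the
mutated positions are recomputed), which is exact because the objective is a
sum over positions and ordered position pairs; a test asserts agreement with
full recomputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import N_AA, decode
from .potential import FrameworkPotential, _as_codes

__all__ = [
    "SamplerConfig",
    "TrajectoryEntry",
    "Trajectory",
    "propose_single",
    "propose_double",
    "accept",
    "run",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Knobs of one sampling run.

    omega : weight of the coupling term (default 2, a good compromise
        between coupling fidelity and breadth of the sampled space).
    k_res : weight of the harmonic identity restraint to the parent.
    beta : inverse-temperature-like acceptance parameter (>= 0).
    n_steps : number of proposals.
    p_double : probability of attempting the double-mutation move.
    seed : seed of the single pseudo-random stream used for the whole run.
    record_every : thinning interval of the recorded trajectory.
    """

    omega: float = 2.0
    k_res: float = 0.0
    beta: float = 1.0
    n_steps: int = 5000
    p_double: float = 0.5
    seed: int | None = None
    record_every: int = 10

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0.0 <= self.p_double <= 1.0:
            raise ValueError("p_double must lie in [0, 1]")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass(frozen=True)
class TrajectoryEntry:
    step: int
    sequence: str
    score: float          # full restrained objective at this step
    identity: float       # identity to the reference (parental) sequence
    accepted: bool        # whether the proposal at this step was accepted


@dataclass
class Trajectory:
    """Thinned record of a sampling run plus the best state ever visited."""

    entries: list[TrajectoryEntry]
    config: SamplerConfig
    reference: str
    best_sequence: str
    best_score: float

    def scores(self) -> np.ndarray:
        return np.array([e.score for e in self.entries])

    def identities(self) -> np.ndarray:
        return np.array([e.identity for e in self.entries])

    def final(self) -> TrajectoryEntry:
        return self.entries[-1]

    def write_fasta(self, path: str | Path) -> None:
        """Sampled sequences as FASTA; ids encode step and objective."""
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f">step_{e.step}_score_{e.score:.4f}\n{e.sequence}\n")
            fh.write(f">best_score_{self.best_score:.4f}\n{self.best_sequence}\n")

    def write_log(self, path: str | Path, model: FrameworkPotential) -> None:
        """Tab-separated log: step, objective terms, identity, accepted."""
        import pandas as pd

        rows = []
        for e in self.entries:
            b = model.profile(e.sequence, omega=self.config.omega,
                              reference=self.reference, k_res=self.config.k_res)
            rows.append(
                {
                    "step": e.step,
                    "score": e.score,
                    "single": b.single_total,
                    "coupling": b.coupling_total,
                    "restraint": b.restraint,
                    "identity": e.identity,
                    "accepted": int(e.accepted),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# moves and acceptance


def propose_single(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Copy of ``codes`` mutated at one uniform position to one of the 19
    other residues (uniformly)."""
    new = codes.copy()
    pos = int(rng.integers(codes.size))
    new[pos] = (new[pos] + 1 + rng.integers(N_AA - 1)) % N_AA
    return new

def propose_double(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Copy of ``codes`` mutated at two distinct uniform positions."""
    if codes.size < 2:
        raise ValueError("double mutation needs a sequence of length >= 2")
    new = codes.copy()
    i, j = rng.choice(codes.size, size=2, replace=False)
    new[i] = (new[i] + 1 + rng.integers(N_AA - 1)) % N_AA
    new[j] = (new[j] + 1 + rng.integers(N_AA - 1)) % N_AA
    return new


def accept(delta_f: float, beta: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept with probability min(1, exp(-beta*dF))."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if delta_f <= 0:
        return True
    return float(rng.random()) < math.exp(-beta * delta_f)


# --------------------------------------------------------------------------
# incremental score updates


def _delta_single_mutation(model: FrameworkPotential, codes: np.ndarray,
                           pos: int, new_code: int, omega: float) -> float:
    """Exact score change of mutating ``codes[pos] -> new_code``.

    Only the positional term at ``pos`` and the 2(N-1) ordered pair terms
    touching ``pos`` change; conditioning positions other than ``pos`` keep
    their residues, so all remaining terms cancel.
    """
    old_code = int(codes[pos])
    if new_code == old_code:
        return 0.0
    e_cond = model.E_cond_
    idx = np.arange(codes.size)
    d = model.E_single_[pos, new_code] - model.E_single_[pos, old_code]
    # pairs (pos, j): residue at pos conditioned on the rest
    d_pairs = (e_cond[pos, new_code, idx, codes]
               - e_cond[pos, old_code, idx, codes]).sum()
    # pairs (i, pos): the rest conditioned on the residue at pos
    d_pairs += (e_cond[idx, codes, pos, new_code]
                - e_cond[idx, codes, pos, old_code]).sum()
    # the two diagonal-touching combinations are stored as 0, so no exclusion
    # is needed beyond what the tables already encode
    return float(d + omega * d_pairs)


# --------------------------------------------------------------------------
# main loop


def run(model: FrameworkPotential, start, config: SamplerConfig,
        reference=None) -> Trajectory:
    """Run the Metropolis sampler and return the thinned trajectory.

    ``reference`` defaults to ``start`` (the parental chain), matching the
    humanization protocol where identity is restrained to the starting
    sequence. Deterministic given ``config.seed``.
    """
    codes = _as_codes(start).copy()
    if codes.size != model.n_positions_:
        raise ValueError(
            f"start length {codes.size} does not match model length "
            f"{model.n_positions_}"
        )
    ref_codes = codes.copy() if reference is None else _as_codes(reference).copy()
    if ref_codes.size != codes.size:
        raise ValueError("reference length does not match start length")

    rng = np.random.default_rng(config.seed)
    n = codes.size
    omega, beta, k_res = config.omega, config.beta, config.k_res

    base = model.score(codes, omega=omega)
    n_match = int(np.sum(codes == ref_codes))
    objective = base + k_res * (1.0 - n_match / n) ** 2

    best_codes = codes.copy()
    best_objective = objective

    entries = [TrajectoryEntry(0, decode(codes), objective, n_match / n, True)]

    for step in range(1, config.n_steps + 1):
        use_double = n >= 2 and float(rng.random()) < config.p_double
        if use_double:
            i, j = rng.choice(n, size=2, replace=False)
            positions = (int(i), int(j))
        else:
            positions = (int(rng.integers(n)),)
        delta_score = 0.0
        work = codes
        for pos in positions:
            new_code = int((work[pos] + 1 + rng.integers(N_AA - 1)) % N_AA)
            delta_score += _delta_single_mutation(model, work, pos, new_code, omega)
            if work is codes:
                work = codes.copy()
            work[pos] = new_code

        new_match = n_match
        for pos in positions:
            if codes[pos] == ref_codes[pos]:
                new_match -= 1
            if work[pos] == ref_codes[pos]:
                new_match += 1
        delta_restraint = k_res * ((1.0 - new_match / n) ** 2
                                   - (1.0 - n_match / n) ** 2)

        accepted = accept(delta_score + delta_restraint, beta, rng)
        if accepted:
            codes = work
            n_match = new_match
            objective += delta_score + delta_restraint
            if objective < best_objective:
                best_objective = objective
                best_codes = codes.copy()

        if step % config.record_every == 0 or step == config.n_steps:
            entries.append(
                TrajectoryEntry(step, decode(codes), objective,
                                n_match / n, accepted)
            )

    return Trajectory(
        entries=entries,
        config=config,
        reference=decode(ref_codes),
        best_sequence=decode(best_codes),
        best_score=best_objective,
    )
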
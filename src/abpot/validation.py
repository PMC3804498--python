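"""End-to-end validation experiments on synthetic two-species data.

Each function runs one complete study — generate alignments under frozen
conditions, fit models, score or sample, measure — and returns the summary
statistics. They exist so that the test suite and the reproduction script
execute exactly the same protocols.

Study conditions (fixed; see docs/methods.md for rationale):

* two-species pools: 60 positions, modal mass 0.7, 3000 training sequences
  per species, 500 held-out evaluation sequences per species;
* discrimination fixture: modal residue shifted at 30% of positions and five
  coupled pairs present in species A only;
* coupling-isolation fixture: identical positional margins, differences only
  in the five coupled-pair joints;
* humanization: species-A model at omega = 2, parental sequences drawn from
  species B, k_res = 7e4 (chosen from the flip-cost analysis so greedy
  descent stalls near identity 0.8), beta = 1, 4000 proposals, 20 seeds.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from sklearn.metrics import roc_auc_score

from .potential import FrameworkPotential, build_model, consensus_sequence
from .sampler import SamplerConfig, run
from .synthgen import (
    coupled_species_pair,
    generate_msa,
    shifted_species_pair,
)

N_EVAL = 500


def _seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(2**31, size=n)]


def _pool_auc(model: FrameworkPotential, msa_a, msa_b, omega: float) -> float:
    """AUC of the model score separating pool A (low) from pool B (high)."""
    scores = np.r_[
        model.score_sequences(msa_a, omega=omega),
        model.score_sequences(msa_b, omega=omega),
    ]
    labels = np.r_[np.zeros(msa_a.n_sequences), np.ones(msa_b.n_sequences)]
    return float(roc_auc_score(labels, scores))


def discrimination_experiment(seed: int, omega: float = 2.0) -> dict:
    """Fig-1-style check: can a species-A model separate held-out A from B?"""
    s_fix, s_a, s_b = _seeds(seed, 3)
    spec_a, spec_b = shifted_species_pair(seed=s_fix)
    model = build_model(generate_msa(spec_a))
    eval_a = generate_msa(replace(spec_a, n_sequences=N_EVAL, seed=s_a))
    eval_b = generate_msa(replace(spec_b, n_sequences=N_EVAL, seed=s_b))
    return {
        "auc": _pool_auc(model, eval_a, eval_b, omega),
        "n_eval": 2 * N_EVAL,
    }


def coupling_only_experiment(seed: int) -> dict:
    """Coupling-isolation check: margins matched, only coupled pairs differ."""
    s_fix, s_a, s_b = _seeds(seed, 3)
    spec_a, spec_b = coupled_species_pair(seed=s_fix)
    model = build_model(generate_msa(spec_a))
    eval_a = generate_msa(replace(spec_a, n_sequences=N_EVAL, seed=s_a))
    eval_b = generate_msa(replace(spec_b, n_sequences=N_EVAL, seed=s_b))
    return {
        "auc_omega0": _pool_auc(model, eval_a, eval_b, 0.0),
        "auc_omega2": _pool_auc(model, eval_a, eval_b, 2.0),
        "n_eval": 2 * N_EVAL,
    }


def consensus_recovery_experiment(seed: int, n_runs: int = 20,
                                  n_steps: int = 5000) -> dict:
    """Greedy sampling at omega = 0 should find the consensus optimum."""
    s_fix, *run_seeds = _seeds(seed, 1 + n_runs)
    spec, _ = shifted_species_pair(seed=s_fix, n_positions=4, n_sequences=60,
                                   n_coupled=0)
    model = build_model(generate_msa(spec))
    target = consensus_sequence(model)
    found = 0
    for s in run_seeds:
        cfg = SamplerConfig(omega=0.0, k_res=0.0, beta=50.0, n_steps=n_steps,
                            seed=s, record_every=n_steps)
        found += run(model, "W" * 4, cfg).best_sequence == target
    return {"success_rate": found / n_runs, "n_runs": n_runs,
            "consensus": target, "model": model}


def humanization_experiment(seed: int, n_runs: int = 20, omega: float = 2.0,
                            k_res: float = 7e4, beta: float = 1.0,
                            n_steps: int = 4000) -> dict:
    """Fig-3-style trade-off: optimize a species-B parent under a species-A
    model; success = final identity >= 0.75 AND final model score inside the
    central 90% of the species-A score distribution."""
    s_fix, s_pool, s_start, *run_seeds = _seeds(seed, 3 + n_runs)
    spec_a, spec_b = shifted_species_pair(seed=s_fix)
    model = build_model(generate_msa(spec_a))
    pool_a = generate_msa(replace(spec_a, n_sequences=N_EVAL, seed=s_pool))
    lo, hi = np.percentile(model.score_sequences(pool_a, omega=omega), [5, 95])
    parents = generate_msa(replace(spec_b, n_sequences=n_runs, seed=s_start))

    successes = 0
    identities, scores = [], []
    for start, s in zip(parents.sequences, run_seeds):
        cfg = SamplerConfig(omega=omega, k_res=k_res, beta=beta,
                            n_steps=n_steps, seed=s, record_every=n_steps)
        final = run(model, start, cfg).final()
        final_score = model.score(final.sequence, omega=omega)
        identities.append(final.identity)
        scores.append(final_score)
        successes += final.identity >= 0.75 and lo <= final_score <= hi
    return {
        "success_rate": successes / n_runs,
        "mean_final_identity": float(np.mean(identities)),
        "mean_final_score": float(np.mean(scores)),
        "score_band": (float(lo), float(hi)),
        "n_runs": n_runs,
    }


def metropolis_experiment(seed: int, n_trials: int = 10_000) -> dict:
    """Empirical acceptance frequency at dF = ln 2, beta = 1 (expected 1/2),
    and the downhill-always-accepted contract."""
    from math import log

    from .sampler import accept

    rng = np.random.default_rng(seed)
    accepted = sum(accept(log(2.0), 1.0, rng) for _ in range(n_trials))
    downhill_ok = all(accept(-d, 1.0, rng) for d in (0.0, 0.5, 3.0, 100.0))
    return {
        "acceptance_at_ln2": accepted / n_trials,
        "downhill_always_accepted": downhill_ok,
        "n_trials": n_trials,
    }
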
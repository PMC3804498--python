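# Methods

This note documents the statistical model, the conventions the
implementation fixes where several readings are possible, the synthetic
data used for validation, and the known limitations.

## Scoring model

**Estimation.** A model is fitted on a gapless, fixed-length alignment of
framework sequences from one species and chain type (heavy, κ or λ), after
exact-duplicate removal. Positional probabilities are plain frequencies
`P_i(A) = c_i(A)/M`; conditional probabilities are `P_ij(A|B) =
c_ij(A,B)/c_j(B)` for every ordered pair `i ≠ j`. No pseudo-counts enter
the probabilities themselves; sparsity is handled entirely by the energy
cap below. Conditionals with `c_j(B) = 0` are undefined (stored as NaN in
the probability table) and score the cap.

**Energies.** `E = −ln(P/p_ref)` with `p_ref = 1/20`. A uniform reference
is used deliberately: the pools are chain-type- and species-specific and
their composition differs from any proteome-wide background, so a
"better" background would add no accuracy, only a constant shift per
position. Energies are dimensionless (the kT prefactor is dropped).

**Zero-frequency cap.** Each table (positional, conditional) gets one
global cap: the largest finite energy in that table — equivalently the
energy of the lowest non-zero probability — multiplied by `cap_scale =
1.1`. A single global cap (rather than per-position caps) keeps
never-observed residues at least as expensive as the rarest observed event
anywhere in the model; per-position caps would make unseen residues cheap
exactly at diverse positions, defeating the cap's purpose as an upper
limit. Degenerate edge cases: if the largest finite energy is negative
(possible only for very small or fully conserved training sets, where
every observed probability exceeds 1/20), multiplying by 1.1 would push
the cap *below* the finite range, so the magnitude is divided by
`cap_scale` instead; an exactly zero maximum maps to `ln(cap_scale)`. In
all cases the cap is strictly above every finite energy (property-tested).

**Total score.** `F(S) = Σ_i E_i(s_i) + ω·Σ_{i≠j} E_ij(s_i|s_j)`, with the
conditional sum over *all ordered pairs*. Conditional probabilities are
inherently asymmetric, and nothing in the model privileges `i < j`; `ω`
absorbs the resulting scale. The sum is not normalized by the number of
pairs — users comparing `ω` values across models of different length
should keep in mind that the coupling term grows like `N−1` relative to
the positional term. Absolute scores are therefore comparable only within
one model and one `ω`.

**Restraint.** `F_total = F + k_res·(1 − ID)²`, harmonic in the identity
deficit — the minimal smooth penalty that anchors sampling around a
reference sequence. The functional form is isolated in one place
(`score_restrained` / the sampler's restraint delta), so alternatives are
a one-line change.

**Per-residue decomposition.** The profile attributes the ordered pair
term `(i, j)` to position `i`, so per-residue contributions sum exactly to
the positional-plus-coupling total; the restraint is reported separately
and never attributed to residues.

## Sampler

Metropolis Monte Carlo over sequence space. Moves: with probability
`p_double` (default 0.5) a double mutation at two distinct uniform
positions, otherwise a single mutation at one uniform position; the mutant
residue is uniform over the 19 alternatives. Proposals are *not*
frequency-biased — selection pressure belongs in the acceptance step, and
with `β = 1` the stationary distribution of the positional term alone is
exactly the training frequency profile (`exp(ln P) ∝ P`), which makes
`β = 1` a natural default. Acceptance: `min(1, exp(−β·ΔF))`. Users should
tune `β` for roughly 20–50% acceptance on their model.

ΔF is computed incrementally: a mutation at position `p` changes one
positional term and the `2(N−1)` ordered pair terms touching `p`; a double
mutation is applied as two sequential single mutations on a working copy.
Incremental and full recomputation agree to floating precision (tested).
The trajectory records the current state every `record_every` proposals
regardless of acceptance, plus the best state ever visited; one seeded
pseudo-random stream drives the whole run, so trajectories are bit-
reproducible given the seed.

`k_res` selection for a target identity: with greedy descent the k-th
reverted position costs `k_res·(2k−1)/N²` of restraint while a typical
beneficial flip gains `ΔE·(1 + ω(N−1))` of score. Setting these equal at
the desired number of flips gives `k_res ≈ gain·N/(2(1−ID_target))`. For
the 60-position validation fixture at `ω = 2` (flip gain ≈ 450) and a
target identity of 0.8 this yields `k_res ≈ 7·10⁴`, the value frozen in
the validation studies.

## Synthetic data and validation studies

The generator draws uncoupled positions independently from per-position
probability rows and coupled position pairs jointly from 20×20
distributions. Coupled pairs must be disjoint, which keeps the generative
law exactly factorizable and every expectation analytic. The frozen
two-species conditions used by the validation suite and
`scripts/acceptance.py`:

* 60 positions, 3000 training and 500 evaluation sequences per species —
  comparable to the curated per-chain pools such models are built from
  (order 10³–10⁴ unique sequences);
* every position has one modal residue at mass 0.7 with the remaining 0.3
  spread uniformly — a moderate conservation level chosen so that both
  positional and coupling signals face realistic per-sequence variance;
* *discrimination fixture*: species B shifts the modal residue at 30% of
  positions; species A additionally carries five coupled pairs (joint:
  modal combination at 0.7, remainder on a residue bijection, so coupling
  margins equal the positional rows);
* *coupling-isolation fixture*: identical margins everywhere, differences
  only in the coupled-pair joints.

What the generator does **not** emulate: germline-gene mosaic structure
(block-correlated positions), somatic-hypermutation hotspots, length
variation, and the broad network of weak couplings present in real
repertoires. Passing the synthetic studies therefore demonstrates the
estimator and sampler machinery, not performance on real antibody data.

Measured outcomes under these conditions (recomputed by
`scripts/acceptance.py`): the species-A model separates held-out pools
with AUC ≈ 0.995; greedy `ω = 0` sampling recovers the consensus optimum
in essentially every run; restrained humanization reaches identity ≈ 0.8
with final scores inside the central 90% of the species-A distribution in
≈ 95% of runs; Metropolis acceptance at `ΔF = ln 2, β = 1` is 0.5 within
binomial noise.

One negative result is deliberate and instructive: in the
coupling-isolation fixture, *pool classification by total score* stays at
chance even at `ω = 2` (AUC ≈ 0.51). Under independence `P(A|B) → P(A)`,
so the coupling sum of any sequence approaches `(N−1)×` its positional
sum; the matched-margin background noise is amplified by the same factor
as the margins themselves, and the five-pair signal (order
`2ω·5·(cap+|ln 20|) ≈ 80` score units) drowns in a within-class spread of
order `(1+ω(N−1))·σ_single ≈ 1600`. This is a property of the
`p_ref`-referenced conditional energy, not a bug: couplings *do* steer
*sampling* — the sampled ensembles at `ω ≥ 1` respect the training
species' couplings while `ω = 0` ensembles violate them (tested via the
mean conditional energy of sampled sequences) — but they cannot dominate a
per-sequence classification against an equally-weighted positional
background with only five genuinely coupled pairs. A mutual-information
style reference (`E_ij` relative to `P_i(A)` instead of `p_ref`) would
change this; it is not the convention implemented here.

## Numerical choices

* Probabilities are exact rational counts divided in double precision;
  normalization invariants are asserted at 1e−9 relative tolerance.
* Joint counts are accumulated via a one-hot float32 matrix product
  (exact for pool sizes below 2²⁴) and stored as integers.
* Consensus ties break alphabetically (first index of the maximum count)
  for determinism.
* The conditional-energy diagonal `i = j` is stored as 0 so that sums over
  all ordered pairs need no masking.
* Model files store the integer count tables, not the float energies;
  loading rebuilds all tables through the identical code path, so a
  round-trip is bit-exact and files stay diffable.

## Scope and limitations

* Input alignments must be pre-aligned and pre-masked. The package does
  not compute Kabat/IMGT/Chothia numbering: framework alignment within a
  chain type is trivial precisely because lengths are conserved, and
  numbering raw sequences is a separate, solved problem.
* No authoritative CDR mask ships with the package. Which CDR stretches
  are structurally conserved enough to score is a curation decision; the
  mask is user configuration (`examples/heavy_mask_example.tsv` documents
  only the format).
* Couplings are raw conditional frequencies, not fitted (Potts/DCA-style)
  interaction parameters; no structural or causal interpretation is
  implied.
* Scores quantify typicality within the training pool. They are not
  immunogenicity predictions, and rare-but-fully-human germlines score
  worse than common ones by construction.
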
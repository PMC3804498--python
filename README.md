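# abpot — statistical potentials for antibody framework sequences

`abpot` builds knowledge-based scoring functions for the framework regions
of antibody variable domains and uses them for *humanness* assessment and
*stochastic humanization*. It is aimed at antibody engineers who want to
flag unusual framework residues, compare a candidate sequence against the
phenotypic pool of a species (rather than against germline identity), and
generate framework variants that are more human-like while staying close to
a parental sequence.

## The model

Framework regions are length-conserved within a chain type, so a curated
per-chain set of sequences forms a gapless, fixed-length alignment. From an
alignment of M sequences over N positions the package counts

* positional probabilities `P_i(A)` — the frequency of amino acid `A` at
  position `i`, and
* conditional probabilities `P_ij(A|B)` — the frequency of `A` at `i`
  among sequences carrying `B` at `j`, for all ordered pairs `i ≠ j`.

Each probability becomes a dimensionless statistical energy through the
inverse Boltzmann relation (the thermal prefactor is omitted):

```
E_i(A)     = −ln( P_i(A)    / p_ref )
E_ij(A|B)  = −ln( P_ij(A|B) / p_ref )        p_ref = 1/20
```

Zero-frequency events cannot be logged; they receive a cap equal to the
largest finite energy of their table scaled by 1.1, so residues never seen
at a position cost slightly more than the rarest ones that were. The total
score of a sequence `S = s_1 … s_N` is

```
F(S) = Σ_i E_i(s_i)  +  ω · Σ_{i≠j} E_ij(s_i|s_j)
```

where `ω` balances positional against coupling contributions (default 2).
Lower scores mean "more typical of the pool the model was fitted on"; a
model fitted on human sequences therefore measures humanness by phenotypic
comparison with the human repertoire. Pairwise couplings are retained
because they act as a species-specific fingerprint (largely reflecting
germline-gene co-usage) that positional frequencies alone miss.

For sequence optimization a harmonic identity restraint turns the score
into an objective,

```
F_total(S) = F(S) + k_res · (1 − ID(S, R))²
```

with `ID(S, R)` the fractional identity to the parental sequence `R`. A
Metropolis Monte Carlo sampler (single and double random mutations,
acceptance probability `min(1, exp(−β·ΔF))`) then minimizes `F_total`,
trading humanness against closeness to the parent — stochastic
humanization.

The package also ships a synthetic-alignment generator with exactly
specified positional frequencies and pairwise couplings, so the whole
pipeline is testable against analytic ground truth without any external
database.

## Worked example

```python
import numpy as np
from dataclasses import replace
from abpot import build_model, generate_msa, run, SamplerConfig
from abpot.synthgen import shifted_species_pair

# two synthetic species: B shifts the modal residue at 30% of 60 positions
# and lacks A's five coupled pairs
spec_a, spec_b = shifted_species_pair(seed=0)
model = build_model(generate_msa(spec_a))

pool_a = generate_msa(replace(spec_a, n_sequences=200, seed=1))
pool_b = generate_msa(replace(spec_b, n_sequences=200, seed=2))
sa = model.score_sequences(pool_a)   # omega defaults to 2
sb = model.score_sequences(pool_b)
print(f"species A score: {sa.mean():.0f} +/- {sa.std():.0f}")
print(f"species B score: {sb.mean():.0f} +/- {sb.std():.0f}")

# stochastically humanize one species-B parent towards species A
parent = pool_b.sequences[0]
cfg = SamplerConfig(omega=2.0, k_res=7e4, beta=1.0, n_steps=4000, seed=3)
traj = run(model, parent, cfg)
final = traj.final()
print(f"parent score:    {model.score(parent):.0f}")
print(f"final score:     {model.score(final.sequence):.0f}")
print(f"identity kept:   {final.identity:.2f}")
```

prints

```
species A score: -10485 +/- 1803
species B score: -4386 +/- 1313
parent score:    -4798
final score:     -10711
identity kept:   0.80
```

The species-A model cleanly separates the two pools (B sequences score
about 6000 units higher), and restrained sampling moves a B parent into the
bulk of the A score distribution while keeping 80% of its positions
untouched — the humanization trade-off.

The same operations are available from the shell:

```
abpot build    --msa human_heavy.fasta --chain-type heavy --species human --out FH.model
abpot score    --model FH.model --fasta queries.fasta --out scores.tsv
abpot profile  --model FH.model --fasta query.fasta   --out profile.tsv
abpot humanize --model FH.model --start-fasta parent.fasta --seed 1 --out-prefix traj
abpot generate --spec synth_spec.txt --out synthetic.fasta
```

`profile` writes a per-position table (positional term, coupling term,
total) that highlights which residues are uncommon for the model's species;
every subcommand writes a `.manifest` file recording parameters, input
digests and the seed. Input alignments are expected pre-aligned and
pre-masked; position masks (which CDR stretches to drop from a full
numbered chain) are user-supplied two-column tables — see
`examples/heavy_mask_example.tsv` for the format (illustrative only).

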
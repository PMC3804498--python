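# File formats

All files are plain text. Fields within a line are tab-separated unless
noted; numeric tables use single spaces.

## Alignments and queries (FASTA)

Standard FASTA. Sequence lines may be wrapped arbitrarily on input and are
written wrapped at 60 columns. Residues must be the 20 canonical amino
acids (lowercase accepted and uppercased on read); gaps and ambiguity
codes are rejected with the offending record and position named.
Alignments must contain at least two records, all of equal length.

## Position mask

Two whitespace-separated columns: position label, keep flag (`1` keep,
`0` drop). `#` starts a comment line. The number of `1` entries must equal
the model/alignment length the mask is used with.

```
# label  keep
H1  1
H2  1
...
H31 0
```

## Model file (version 1)

Written by `FrameworkPotential.save` / `abpot build`. Layout, in order:

```
#abpot-model<TAB>version=1
n_positions<TAB><N>
n_sequences<TAB><M>
p_ref<TAB><float repr>
cap_scale<TAB><float repr>
omega<TAB><float repr>
chain_type<TAB><heavy|kappa|lambda>
species<TAB><label>
alphabet<TAB>ACDEFGHIKLMNPQRSTVWY
counts_single
<N lines: 20 space-separated integer counts, alphabet order>
counts_pair
<N(N-1)/2 lines: "i j" followed by the 400 counts of the (i, j) block,
 row-major over (residue at i, residue at j), for all i < j>
```

Counts, not energies, are stored: probabilities and energies are rebuilt
deterministically on load, so save→load round-trips reproduce every table
bit-for-bit. Field order is fixed so model files are diffable. Loaders
reject unknown versions, alphabet mismatches, and tables inconsistent with
the declared `n_positions`/`n_sequences`.

## Synthetic-alignment spec

```
#abpot-synthspec<TAB>version=1
n_positions<TAB><N>
n_sequences<TAB><M>
seed<TAB><int, may be empty>
species<TAB><label>
chain_type<TAB><heavy|kappa|lambda>
pwm
<N lines: 20 space-separated probabilities (float repr), one row per position>
coupling<TAB><i><TAB><j>
<20 lines: 20 probabilities, the joint over (residue at i, residue at j)>
```

The `coupling` section repeats once per coupled pair; pairs must be
disjoint. Rows and joints must each sum to 1.

## Sampler config

Key = value lines (`#` comments) mirroring `SamplerConfig`: `omega`,
`k_res`, `beta`, `n_steps`, `p_double`, `seed`, `record_every`. CLI flags
override file values.

## Outputs

* `abpot score`: TSV with columns `id`, `score`.
* `abpot profile`: TSV with columns `position` (1-based), `residue`,
  `single`, `coupling`, `total`.
* `abpot humanize`: `<prefix>.fasta` (thinned trajectory; ids encode step
  and objective, final record is the best state) and `<prefix>.tsv` with
  columns `step`, `score` (full objective), `single`, `coupling`,
  `restraint`, `identity`, `accepted`.
* Every subcommand writes `<output>.manifest`: subcommand, package
  version, timestamp, resolved parameters (`param:` lines), input paths
  with SHA-256 digests (`input:` lines).
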
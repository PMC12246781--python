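# Methods

## Model and procedure

`fragani` computes ANIb-style average nucleotide identity by fragment
orthology. The assumptions behind the procedure are those of the
fragment-based ANI family: the two genomes share enough colinear (or
rearranged but contiguous-at-the-1-kb-scale) sequence that 1020-bp
windows of one genome have a well-defined homolog in the other, and
orthology can be recognised as a reciprocal best alignment hit without
any whole-genome synteny model. Contig orientation is arbitrary (drafts
and MAGs), so both strands are always searched.

Pipeline: per-contig partition into 1020-bp windows at offset 0 →
ambiguity filter → all-vs-all fragment alignment in both directions →
per-query best hit → reciprocal pairs passing the coverage rule → mean
of the 2n directional identities.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `fragment_length` | 1020 | bp | the fragment-ANI convention; three 340-bp codon-frame thirds, and small enough that drafts keep most windows |
| `max_ambiguous_fraction` | 0.80 | fraction | fragments with **strictly more** than 80% ambiguous positions are discarded; at exactly 816/1020 the fragment is kept |
| `min_coverage` | 0.35 | fraction | an alignment must span ⌈0.35 × 1020⌉ = 357 columns in **both** directions for the pair to count |
| backend `min_score` (builtin) | 40 | raw score | reporting cutoff standing in for blastn's `-evalue 1e-15`; Karlin–Altschul gives S ≈ 47 for ±1 scoring at fragment/database sizes of ~1 kb vs ~100 kb, and no alignment between unrelated fragments plausibly reaches 40 |
| backend `word_size` (builtin) | 13 | bp | exact-word seed used only to skip fragment pairs; see below |
| builtin scoring | +1/−1, gap open 5, extend 2 | — | mirrors blastn's `-reward 1 -penalty -1`; gap of length L costs 5 + 2L |

Ambiguity is defined as any character outside {A,C,G,T} after
uppercasing: the aligner cannot score R/Y/W/… as matches any more than
N, so the filter and the identity computation use one definition.

## Design choices where the design was open

- **Averaging convention.** "Average over all reciprocal hits" is read
  per-hit: both directional identities of every pair enter the mean
  (2n values), not the mean of per-pair averages. The two differ only
  in weighting; the choice is pinned by test so it stays auditable.
- **Coverage rule.** Applied to *both* directions' alignment lengths
  (gap columns included), with "at least" read as non-strict (≥ 357).
  The denominator is the nominal fragment length — legal because every
  retained fragment has exactly that length.
- **One alignment per fragment pair.** blastn's `-num_alignments 1`
  limits subjects, not HSPs per subject; the highest bit-score segment
  per (query, subject) pair is kept (ties: lower e-value, higher
  identity, longer alignment).
- **Best-hit tie-breaking.** Highest bit score, then lower e-value,
  then higher identity, then lexicographically smallest subject id —
  fully deterministic, so hit tables and ANI values are reproducible
  bit-for-bit across runs and worker counts.
- **Builtin aligner determinism.** Among co-optimal local alignments
  the traceback prefers diagonal over gap-in-subject over gap-in-query,
  gap states prefer opening over extending, and the best cell with the
  smallest (i, j) wins. The pure-Python dynamic-programming oracle in
  the test suite implements the same conventions independently.
- **Seeding is not a sensitivity parameter.** The builtin backend only
  aligns fragment pairs that share an exact 13-bp word on some strand.
  Because reported hits must reach `min_score` = 40 and the probability
  that two unrelated 1020-bp fragments reach that score is ~3·10⁻¹⁴,
  seeding can only skip alignments that would be discarded anyway: the
  reported hit set is provably (to that probability) identical to the
  unseeded one, which is what the exhaustive-oracle test checks.
- **Identity values are used as reported** by the backend (blastn's
  3-decimal percent; the builtin's exact matches/columns ratio) — never
  re-derived from mismatch counts.
- **Exact symmetry.** The mean over directional identities uses a
  correctly-rounded sum (`math.fsum`), so ANI(A,B) = ANI(B,A) to the
  last bit even though the pair lists are enumerated in different orders.
- **Worker contract.** The query set may be partitioned across threads
  arbitrarily (the alignment kernel releases the GIL); hit lists are
  normalised to (query id, descending bit score, subject id) order, so
  results are invariant to `workers`.

## Synthetic data: what it emulates and what it does not

`random_genome` draws i.i.d. bases at a configurable GC content;
`mutate_genome` applies independent per-base substitutions (uniform over
the three other bases) and optional geometric-length indels;
`inject_ambiguity` overwrites non-overlapping blocks with N. All three
are pure functions of their seed.

A substitutions-only mutant at rate *p* has expected identity
100(1 − *p*), which gives divergence-recovery tests a closed-form
oracle; the defaults used in tests (100-kb genomes, *p* ∈ {0.01, 0.02,
0.05}, substitutions only) keep that oracle clean, with indels enabled
only in robustness tests.

What the generator does *not* emulate: repeat families, mobile
elements, horizontal transfer, rearrangements, compositional skew and
real gene content. Passing tests therefore demonstrate that the
pipeline implements the stated algorithm correctly and recovers known
divergence on homogeneous sequence; they do not certify accuracy on
repeat-rich real genomes, where ANI methods genuinely differ.

## Numerical notes and degenerate inputs

- Thresholds on counts are computed in integers (⌈·⌉ for coverage,
  strict `>` on the ambiguous count) so no float comparison sits on a
  boundary.
- A genome with zero usable fragments (too short, or everything
  filtered) raises a distinct error naming the genome; zero reciprocal
  pairs raises "no orthologous fragments" — ANI is undefined there, not
  0 — which the CLI maps to exit code 1.
- The agreement fit is closed-form two-parameter OLS; a zero-variance
  predictor is a distinct degenerate-fit error, and n < 3 is rejected.
  Adjusted R² uses the single-predictor form 1 − (1 − R²)(n−1)/(n−2).
- Problem sizes in tests and in `scripts/acceptance.py` (100-kb genomes
  for identity/divergence recovery, ~4–20-kb genomes for symmetry,
  oracle and cross-backend panels) were chosen so the full validation
  runs in a few minutes on one CPU while keeping ≥ 98 fragments per
  genome in the headline checks.

## Known limitations

- The builtin backend is not bit-compatible with blastn (different gap
  statistics, x-drop heuristics and rounding); parity is asserted only
  within tolerance (observed ≲ 0.001 ANI points at 2% divergence on
  synthetic pairs).
- Fragments are never tiled across contig junctions, so heavily
  fragmented assemblies lose up to 1019 bp per contig.
- No alignment-fraction output, no MinHash/sketching estimators, and no
  many-vs-many database mode — one query vs one reference per call.
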
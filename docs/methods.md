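# Methods

## The screening model

A Cas9 target site is modelled as a fixed 23-nt window on the forward strand:
a 20-nt spacer, one unconstrained base, then the `GG` of the NGG
protospacer-adjacent motif (PAM). The scanner slides this window one
nucleotide at a time, so overlapping and bookended sites are all reported —
no de-overlapping or greedy selection is performed. Coordinates are 1-based
inclusive; a window starting at position *p* spans [*p*, *p* + 22].

Specificity is a dataset-level property of the **seed**, the 3′-most 12 nt of
the spacer (window positions 9–20, immediately 5′ of the PAM), which
dominates Cas9 off-target discrimination. A candidate is *specific* when its
seed occurs exactly once in the entire input. This is deliberately a
uniqueness test, not a mismatch-tolerant off-target search: one exact seed
match elsewhere disqualifies a site, and near-matches are ignored.

Spacers are partitioned four ways by the strength of their first and
twentieth bases (strong = G/C, weak = A/T), for users who need targets that
begin or end with a particular nucleotide class. The labels
(`A/T_N18_A/T`, `A/T_N7_S11_A/T`, …) are whitespace-free motif tokens: `N18`
marks the 18 unconstrained inner spacer bases, `N7_S11` the 7 unconstrained
bases followed by the seed's 11 inner bases.

### Assumptions and their consequences

- **Forward strand only.** Reverse-complement scanning is out of scope; a
  reverse-strand site is found by scanning the reverse-complemented FASTA.
  Seed uniqueness is likewise evaluated on the forward strand only.
- **Strict alphabet.** Windows containing any non-ACGT character — including
  N and all other IUPAC ambiguity codes — are rejected whole, and the PAM's
  N must be a concrete base. Rationale: a seed containing N cannot be
  meaningfully tested for uniqueness. On real assemblies with N-runs this
  choice can shift counts slightly relative to tools that expand ambiguity
  codes.
- **Fixed geometry.** 20-nt spacer, NGG PAM, 12-nt seed. The `ScanConfig`
  fields exist to make the contract explicit and validated, not to offer
  alternative chemistries (NAG PAMs, truncated guides, …).

## Seed-uniqueness modes

The phrase "seed not repeated in the input" admits two readings, and both are
implemented:

- `substring` (default): count every overlapping occurrence of the seed as a
  substring of every input sequence, PAM context or not. The stricter and
  more conservative filter.
- `candidate`: count only occurrences at candidate (PAM-bearing) sites —
  uniqueness among potential Cas9 binding events.

Every candidate occurrence is also a substring occurrence, so candidate mode
never flags fewer sites specific than substring mode (an invariant the tests
enforce). On genome-scale data the two differ by a few percent; which one a
given published count corresponds to cannot generally be determined without
rerunning the original tool, which is why both are exposed as a flag.

## Counting machinery

Substring counting uses a dense histogram over all 4¹² two-bit-encoded
12-mers (A=0, C=1, G=2, T=3, big-endian base 4), built in one numpy pass per
sequence and queried for the candidate seeds. Peak memory is O(4¹²) counters
(~134 MB at int64) plus O(candidates), independent of input length, so a
100-Mb chromosome streams through on ordinary hardware. Windows containing a
non-ACGT byte are skipped by a validity mask rather than failing the pass.
Candidate mode is a plain Counter over candidate seeds.

## Statistics

`summarize` reports total and specific site counts, the number of sequences
carrying (specific) sites, and **mean specific spacing**: the start-to-start
difference of consecutive specific sites within each sequence, with all gaps
pooled across sequences and weighted equally. The definition is this
package's convention; per-sequence averaging or span/count ratios give
slightly different numbers on heterogeneous inputs. With fewer than two
specific sites in every sequence the spacing is undefined and serialized as
`NA`. On uniform random ACGT sequence the expected candidate density is 1/16
per offset (the probability that two fixed positions are both G), giving an
expected specific-site spacing near 16 nt; AT-rich real genomes are sparser,
with spacings in the low twenties.

## Synthetic datasets

`pamscan.synth` generates FASTA datasets with exact planted ground truth:
i.i.d. background at a chosen GC fraction (default 0.5; the benchmark tests
use 0.36–0.45, typical of plant and insect genomes), plus non-overlapping
23-nt plants of two kinds. *Unique-seed* plants are verified post hoc against
the fully assembled dataset — colliding plants are redrawn — so their
specificity is guaranteed, not merely probable. *Duplicated-seed* pairs share
one seed under two distinct 8-nt prefixes, exercising seed-level rather than
site-level uniqueness. Generation is fully deterministic given `rng_seed`.

What the generator does **not** emulate: repeat families, isochore GC
structure, assembly gaps (N-runs), and real codon/k-mer biases. Passing the
planted-truth tests therefore demonstrates algorithmic correctness of the
scan-index-mark pipeline, not calibrated performance on any particular
genome; genome-scale counts on real data are obtained with
`scripts/reproduce_genome_scale.py` on downloaded inputs.

Brute-force oracles (`oracle_scan`, per-offset character comparison;
`oracle_count_substring`, overlapping find) provide the independent route
the property tests compare against.

## Numerical and I/O choices

- FASTA ingest uppercases, converts U→T, tokenizes identifiers at the first
  whitespace, accepts IUPAC ambiguity letters, and rejects empty-sequence
  records by name. Parsing is delegated to Biopython.
- Reports are written with the stdlib csv writer: tab or comma separated,
  minimal quoting, trailing newline; `txt`/`xls` output is tab-separated text
  with that extension (no binary spreadsheets). Reports re-parse losslessly,
  and an all-sites report (with the `specific` column) is lossless for every
  run statistic.
- The default report contains specific sites only; `--all-sites` writes every
  candidate with an explicit true/false column, reconciling "show me usable
  targets" with "show me everything you considered".
- The pipeline is deterministic: identical input and configuration produce
  byte-identical reports.

## Problem sizes in the test suite

The suite verifies the scanner against the oracle on ~1,000 random sequences
up to 300 nt, recovers planted truth on ten 100-kb genomes (50 unique plants,
25 duplicate pairs each), checks PAM density on 1 Mb of uniform sequence
against the 1/16 expectation within three standard errors, and exercises the
genome-scale reproduction pathway on a 300-kb synthetic genome. These sizes
were chosen to make every property decisive at interactive runtimes; the
machinery itself is the same one used at chromosome scale.

## Known limitations

Single-stranded, single-PAM, exact-seed screening only; no on-target
efficiency scores; no mismatch-tolerant off-target enumeration; no gzip
transparency. The per-offset density argument above assumes base
independence and is only an approximation on real genomes.
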
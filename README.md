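# pamscan

Find **specific CRISPR-Cas9 target sites** in arbitrary FASTA nucleotide
datasets — genes, chromosomes, or whole genomes — on a laptop, with no web
service or reference index.

CRISPR-Cas9 cleaves where a 20-nt guide spacer base-pairs with the target
immediately 5′ of an **NGG protospacer-adjacent motif (PAM)**. Off-target
cleavage is governed mainly by the 3′-most 12 nt of the spacer (the **seed**):
a site whose seed occurs exactly once in the whole dataset is a safe, *specific*
target. pamscan reimplements the classic SSFinder screening workflow as a
tested Python library plus a thin command-line tool:

1. **Scan** — slide a 23-nt window one base at a time along the forward strand
   of every sequence; keep windows that are unambiguous A/C/G/T and end in
   `GG` (spacer₍₂₀₎ · N · GG). All coordinates are 1-based inclusive.
2. **Seed filter** — count each candidate's 12-nt seed across the *entire*
   input (dense 2-bit-encoded k-mer histogram, O(4¹²) memory regardless of
   genome size) and mark sites with count 1 as specific. Two countings are
   available: `substring` (every overlapping occurrence anywhere, the default)
   and `candidate` (occurrences at candidate sites only).
3. **Classify** — partition spacers by their first and twentieth nucleotide,
   strong (S = G/C) vs weak (W = A/T): `G/C_N18_G/C`, `G/C_N18_A/T`,
   `A/T_N18_A/T`, `A/T_N18_G/C`.
4. **Report** — seven columns per site: identifier, classification,
   site_with_pam, start, end, seed_condition, specific_target. The last column
   is the 20-nt spacer, ready to drop into a guide-RNA construct.

A synthetic-genome generator with exact planted ground truth
(`pamscan.synth`) and brute-force oracles back the test suite.

## Worked example

Four example sites, one per spacer group, planted in a 408-nt sequence of
T-filler (see `examples/01_scan_and_report.py`):

```sh
$ pamscan --input example.fasta --output report.tsv --stats stats.txt
$ cat report.tsv
identifier	classification	site_with_pam	start	end	seed_condition	specific_target
Sequence_1	A/T_N18_A/T	ACTTCTTCGTCCAACTTCTTCGG	6	28	A/T_N7_S11_A/T	ACTTCTTCGTCCAACTTCTT
Sequence_1	G/C_N18_A/T	CCAAAGTTCTATTTGAGCTAAGG	68	90	G/C_N7_S11_A/T	CCAAAGTTCTATTTGAGCTA
Sequence_1	G/C_N18_G/C	CTAACCGACCTTCAGCTAACAGG	154	176	G/C_N7_S11_G/C	CTAACCGACCTTCAGCTAAC
Sequence_1	A/T_N18_G/C	TTTGCAAGCCTCATCCATTGTGG	386	408	A/T_N7_S11_G/C	TTTGCAAGCCTCATCCATTG
$ cat stats.txt
total_sites: 4
specific_sites: 4
sequences_with_sites: 1
sequences_with_specific_sites: 1
mean_specific_spacing: 126.667
```

The first row reads: positions 6–28 of `Sequence_1` hold the 23-mer
`ACTTCTTCGTCCAACTTCTTCGG`; its spacer starts and ends with a weak (A/T) base;
its seed (`GTCCAACTTCTT`) is unique in the input, so the 20-mer
`ACTTCTTCGTCCAACTTCTT` is a specific target. `mean_specific_spacing` is the
mean start-to-start distance between consecutive specific sites within a
sequence, pooled over sequences.

Useful flags: `--format tsv|csv|txt|xls` (txt/xls are tab-separated text with
that extension), `--mode substring|candidate`, `--all-sites` (report
non-specific candidates too, with a true/false `specific` column),
`--interactive` (prompt for directory, file name and format). Without
`--output` the report lands next to the input as `SSFinder-output.<ext>`,
matching the original SSFinder workflow.

From Python, the same pipeline is
`read_fasta → scan_candidates → build_seed_index → mark_specific →
write_report / summarize`; `examples/` holds one short script per capability.

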
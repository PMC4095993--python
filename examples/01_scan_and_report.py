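"""Scan a small FASTA for specific CRISPR-Cas9 target sites and print the report.

Builds a 408-nt sequence carrying one example site from each of the four
spacer groups, runs the full pipeline, and prints the seven-column report.
Each row is a 23-nt window ending in the NGG PAM whose 12-nt seed is unique
in the input; column 7 is the 20-nt spacer ready for guide-RNA design.
"""

import tempfile
from pathlib import Path

from pamscan import RunConfig, run

SITES = {  # site 23-mer -> 1-based start position
    "ACTTCTTCGTCCAACTTCTTCGG": 6,
    "CCAAAGTTCTATTTGAGCTAAGG": 68,
    "CTAACCGACCTTCAGCTAACAGG": 154,
    "TTTGCAAGCCTCATCCATTGTGG": 386,
}

chars = ["T"] * 408
for site, start in SITES.items():
    chars[start - 1 : start + 22] = site

with tempfile.TemporaryDirectory() as tmp:
    fasta = Path(tmp) / "example.fasta"
    fasta.write_text(">Sequence_1\n" + "".join(chars) + "\n")
    stats, report = run(RunConfig(input_path=fasta, output_path=Path(tmp) / "out.tsv"))
    print(report.read_text())
    print(f"{stats.total_sites} candidate sites, {stats.specific_sites} specific")
    print("Each start/end pair spans 23 nt; the classification labels give the")
    print("strong(G/C)/weak(A/T) identity of the spacer's first and last base.")
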
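import pytest

from pamscan import SequenceRecord

# The four documented example sites, one per spacer group:
# (group code, 23-mer site with PAM, 1-based start, 1-based end)
PRINTED_SITES = [
    ("WW", "ACTTCTTCGTCCAACTTCTTCGG", 6, 28),
    ("SW", "CCAAAGTTCTATTTGAGCTAAGG", 68, 90),
    ("SS", "CTAACCGACCTTCAGCTAACAGG", 154, 176),
    ("WS", "TTTGCAAGCCTCATCCATTGTGG", 386, 408),
]


def build_four_site_sequence() -> str:
    """One 408-nt sequence holding each example site at its documented start.

    The filler is all T, so the only GG dinucleotides — and therefore the
    only possible PAM positions — are the final two bases of each planted
    site: the scanner must find exactly these four windows.
    """
    chars = ["T"] * 408
    for _, site, start, _ in PRINTED_SITES:
        chars[start - 1 : start - 1 + 23] = site
    return "".join(chars)


@pytest.fixture(scope="session")
def four_site_record() -> SequenceRecord:
    return SequenceRecord("Sequence_1", build_four_site_sequence())


@pytest.fixture
def four_site_fasta(tmp_path, four_site_record):
    path = tmp_path / "example.fasta"
    path.write_text(f">{four_site_record.identifier}\n{four_site_record.sequence}\n")
    return path
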
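import pytest

from venompep.io import load_reference_peptides


@pytest.fixture(scope="session")
def reference_rows():
    """The packaged Palearctic-viper peptide table, parsed and validated."""
    return load_reference_peptides()


@pytest.fixture(scope="session")
def family_section_rows(reference_rows):
    """Rows of the three K/N/R family sections (the BPP/svMP-i grammar's
    coverage target)."""
    return [r for r in reference_rows if r.section in ("K", "N", "R")]
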
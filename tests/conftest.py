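"""Shared fixtures: synthetic chains and libraries (no external files)."""

import pytest

from nucleofit.fixtures import FixtureSpec, generate_chain
from nucleofit.library import build_library, extract_annotated_residues


@pytest.fixture(scope="session")
def helix12():
    """Clean 12-mer single strand with the A-form-like preset."""
    return generate_chain(FixtureSpec(sequence="GCAUGCAUGCAU"))


@pytest.fixture(scope="session")
def duplex6():
    """Clean 6-bp duplex (12 residues, two chains)."""
    return generate_chain(FixtureSpec(sequence="GCGAUC", form="duplex"))


@pytest.fixture(scope="session")
def helix_library(helix12):
    """Library built from the 12-mer itself (contains its exact conformers)."""
    return build_library(extract_annotated_residues([helix12]),
                         k1=2, k2=2, seed=0, name="helix12")


@pytest.fixture(scope="session")
def duplex_library(duplex6):
    return build_library(extract_annotated_residues([duplex6]),
                         k1=2, k2=2, seed=0, name="duplex6")
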
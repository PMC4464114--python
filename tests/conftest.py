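"""Shared fixtures: small peptide sets, alignments and trees built in code."""

from __future__ import annotations

import numpy as np
import pytest

from hpaa_phylo.phylo_core import Alignment, SubstitutionModel, Tree
from hpaa_phylo.phylo_core.model import AA_ORDER
from hpaa_phylo.proteome_io import Peptide


@pytest.fixture(scope="session")
def jtt_g4() -> SubstitutionModel:
    return SubstitutionModel(alpha=0.5, ncat=4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150504)


@pytest.fixture
def random_peptides(rng) -> list[Peptide]:
    """Twenty random 100-residue peptides without injected tracts."""
    return [
        Peptide(id=f"p{i:02d}", sequence="".join(rng.choice(list(AA_ORDER), 100)))
        for i in range(20)
    ]


def random_alignment(rng, ids, n_sites: int) -> Alignment:
    return Alignment.from_dict(
        {sid: "".join(rng.choice(list(AA_ORDER), n_sites)) for sid in ids}
    )


@pytest.fixture
def four_taxon_tree() -> Tree:
    return Tree.from_newick("((A:0.2,B:0.3):0.15,C:0.25,D:0.1);")
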
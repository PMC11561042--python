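import numpy as np
import pandas as pd
import pytest

from metnet import make_synthetic, make_toy_example, SyntheticSpec
from metnet.reconstruction import RANKS, Reaction, ReconstructionBundle, Strain


@pytest.fixture(scope="session")
def toy():
    return make_toy_example()


@pytest.fixture(scope="session")
def toy_dir(toy, tmp_path_factory):
    from metnet.fixtures import write_dataset

    path = tmp_path_factory.mktemp("toy")
    write_dataset(toy, path)
    return path


@pytest.fixture(scope="session")
def synthetic():
    """One moderate seeded synthetic dataset shared across tests."""
    return make_synthetic(SyntheticSpec(seed=7))


def make_bundle(
    n_taxa=3,
    strains_per_taxon=2,
    n_reactions=8,
    n_subsystems=3,
    density=0.5,
    seed=0,
    ce_on=(),
):
    """Small random bundle builder for unit/property tests."""
    rng = np.random.default_rng(seed)
    strains, rids = [], [f"r{k:02d}" for k in range(n_reactions)]
    for i in range(n_taxa):
        for j in range(strains_per_taxon):
            strains.append(
                Strain(
                    f"t{i}_s{j}",
                    dict(
                        zip(
                            RANKS,
                            ("Bacteria", "P", "C", "O", "F",
                             f"Genus{i}", f"epithet{i}"),
                        )
                    ),
                )
            )
    reactions = [
        Reaction(
            rid,
            subsystem=f"sub{k % n_subsystems}" if n_subsystems else "",
            is_exchange=rid in ce_on,
            ce_subsystem=f"ce{k % 2}" if rid in ce_on else "",
        )
        for k, rid in enumerate(rids)
    ]
    sids = sorted(s.strain_id for s in strains)
    mat = (rng.random((len(sids), n_reactions)) < density).astype("int8")
    for c in np.flatnonzero(mat.sum(axis=0) == 0):
        mat[rng.integers(len(sids)), c] = 1
    presence = pd.DataFrame(mat, index=sids, columns=sorted(rids))
    return ReconstructionBundle(strains, reactions, presence, name="test")


@pytest.fixture
def small_bundle():
    return make_bundle()
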
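"""Synthetic reconstruction bundles and 16S datasets for testing/demos.

Two generators live here. :func:`make_toy_example` is a frozen,
deterministic miniature: three species-level taxa observed in six
samples (three control, three test), mapped to a four-strain bundle with
six reactions in two subsystems. Its hard constraints are the worked
properties of the method: sample m1 has relative abundances
(0.7, 0.3, 0) over taxa a1-a3; reaction v4 is carried by exactly half of
taxon a3's strains (R entry 0.5); subsystem p1 contains exactly
reactions v1-v3 (global S row 1/3 each). All other counts and presence
entries are free choices frozen here.

:func:`make_synthetic` draws arbitrarily sized bundles and
Dirichlet-multinomial count tables with an optional per-taxon log2
fold-change between two groups, for property tests and power/type-I
simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .reconstruction import (
    RANKS,
    Reaction,
    ReconstructionBundle,
    Strain,
    write_bundle,
)

_TOY_LINEAGES = {
    "B_uniformis_1": ("Bacteria", "Bacteroidota", "Bacteroidia",
                      "Bacteroidales", "Bacteroidaceae", "Bacteroides",
                      "uniformis"),
    "E_coli_K12": ("Bacteria", "Pseudomonadota", "Gammaproteobacteria",
                   "Enterobacterales", "Enterobacteriaceae", "Escherichia",
                   "coli"),
    "F_prausnitzii_A": ("Bacteria", "Bacillota", "Clostridia",
                        "Eubacteriales", "Oscillospiraceae",
                        "Faecalibacterium", "prausnitzii"),
    "F_prausnitzii_B": ("Bacteria", "Bacillota", "Clostridia",
                        "Eubacteriales", "Oscillospiraceae",
                        "Faecalibacterium", "prausnitzii"),
}

# strain -> carried reactions; v4 in exactly 1 of the 2 F. prausnitzii
# strains is the one non-0/1 ratio of the example
_TOY_PRESENCE = {
    "B_uniformis_1": ("v1", "v2", "v3"),
    "E_coli_K12": ("v2", "v3", "v4"),
    "F_prausnitzii_A": ("v4", "v5", "v6"),
    "F_prausnitzii_B": ("v5", "v6"),
}

_TOY_SUBSYSTEMS = {"v1": "p1", "v2": "p1", "v3": "p1",
                   "v4": "p2", "v5": "p2", "v6": "p2"}

# counts (rows: a1 B. uniformis, a2 E. coli, a3 F. prausnitzii);
# m1 fixed at 70:30:0; the test group (m4-m6) shifts mass to a3
_TOY_COUNTS = {
    "m1": (70, 30, 0),
    "m2": (60, 40, 0),
    "m3": (80, 15, 5),
    "m4": (10, 20, 70),
    "m5": (5, 25, 70),
    "m6": (15, 15, 70),
}

_TOY_TAXA = ("Bacteroides uniformis", "Escherichia coli",
             "Faecalibacterium prausnitzii")


@dataclass
class ToyExample:
    """The frozen miniature dataset plus its reconstruction bundle."""

    bundle: ReconstructionBundle
    feature_table: pd.DataFrame  # feature x sample counts
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame


def make_toy_example() -> ToyExample:
    """Build the deterministic toy dataset (no randomness involved)."""
    strains = [
        Strain(sid, dict(zip(RANKS, lineage)))
        for sid, lineage in _TOY_LINEAGES.items()
    ]
    reactions = [
        Reaction(rid, subsystem=sub) for rid, sub in _TOY_SUBSYSTEMS.items()
    ]
    presence = pd.DataFrame(
        0, index=sorted(_TOY_LINEAGES), columns=sorted(_TOY_SUBSYSTEMS),
        dtype="int8",
    )
    for sid, rids in _TOY_PRESENCE.items():
        presence.loc[sid, list(rids)] = 1
    bundle = ReconstructionBundle(strains, reactions, presence, name="toy")

    samples = sorted(_TOY_COUNTS)
    table = pd.DataFrame(
        {m: _TOY_COUNTS[m] for m in samples},
        index=pd.Index(["asv1", "asv2", "asv3"], name="feature_id"),
        dtype=float,
    )
    lineage_of = {
        "asv1": _TOY_LINEAGES["B_uniformis_1"],
        "asv2": _TOY_LINEAGES["E_coli_K12"],
        "asv3": _TOY_LINEAGES["F_prausnitzii_A"],
    }
    taxonomy = pd.DataFrame(
        [lineage_of[f] for f in table.index],
        index=table.index, columns=list(RANKS),
    )
    metadata = pd.DataFrame(
        {"condition": ["control"] * 3 + ["test"] * 3},
        index=pd.Index(samples, name="sample_id"),
    )
    return ToyExample(bundle, table, taxonomy, metadata)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic generator.

    Defaults emulate a desk-scale 16S study: a few dozen species-level
    taxa with a handful of strains each, a bundle of a few hundred
    reactions grouped into subsystems (plus a small compound-exchange
    family), two balanced sample groups, and overdispersed compositional
    counts (Dirichlet-multinomial). ``group_effect`` is a log2
    fold-change applied to ``affected_taxa`` in the second group.
    """

    n_taxa: int = 30
    strains_per_taxon: int = 3
    n_reactions: int = 150
    n_subsystems: int = 15
    n_samples: int = 24
    reaction_density: float = 0.25
    abundance_concentration: float = 30.0
    group_effect: float = 0.0
    affected_taxa: tuple[int, ...] = ()
    n_ce_subsystems: int = 2
    n_exchange_reactions: int = 10
    n_unmatched_taxa: int = 2
    sequencing_depth: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_reactions < 1 or self.n_samples < 2:
            raise ValueError("infeasible synthetic spec: need >=1 taxon, "
                             ">=1 reaction, >=2 samples")
        if not 0 < self.reaction_density <= 1:
            raise ValueError("reaction_density must be in (0, 1]")
        if self.strains_per_taxon < 1 or self.sequencing_depth < 1:
            raise ValueError("strains_per_taxon and sequencing_depth must "
                             "be positive")
        if any(i >= self.n_taxa for i in self.affected_taxa):
            raise ValueError("affected_taxa index out of range")


@dataclass
class SyntheticDataset:
    bundle: ReconstructionBundle
    feature_table: pd.DataFrame  # feature x sample counts
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame
    spec: SyntheticSpec = field(repr=False, default=None)


def make_synthetic(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a seeded, reproducible bundle + count table + metadata."""
    rng = np.random.default_rng(spec.seed)

    genus = [f"Genus{i:03d}" for i in range(spec.n_taxa)]
    epithet = [f"intestinalis{i:03d}" for i in range(spec.n_taxa)]
    strains = []
    for i in range(spec.n_taxa):
        for j in range(spec.strains_per_taxon):
            lineage = dict(zip(RANKS, (
                "Bacteria", f"Phylum{i % 5}", f"Class{i % 5}",
                f"Order{i % 5}", f"Family{i % 7}", genus[i], epithet[i],
            )))
            strains.append(Strain(f"G{i:03d}_S{j}", lineage))

    n_ex = min(spec.n_exchange_reactions, spec.n_reactions)
    rids = [f"EX_met{k:03d}_e" for k in range(n_ex)] + [
        f"rxn{k:04d}" for k in range(spec.n_reactions - n_ex)
    ]
    reactions = []
    for k, rid in enumerate(rids):
        if rid.startswith("EX_") and spec.n_ce_subsystems > 0:
            reactions.append(Reaction(
                rid, subsystem="", is_exchange=True,
                ce_subsystem=f"ce_group{k % spec.n_ce_subsystems}",
            ))
        else:
            reactions.append(Reaction(
                rid, subsystem=f"ss{k % max(spec.n_subsystems, 1):02d}",
            ))

    sids = sorted(s.strain_id for s in strains)
    rids_sorted = sorted(rids)
    mat = (rng.random((len(sids), len(rids_sorted)))
           < spec.reaction_density).astype("int8")
    for c in np.flatnonzero(mat.sum(axis=0) == 0):
        mat[rng.integers(len(sids)), c] = 1  # every reaction in >=1 strain
    presence = pd.DataFrame(mat, index=sids, columns=rids_sorted)
    bundle = ReconstructionBundle(strains, reactions, presence,
                                  name=f"synthetic-seed{spec.seed}")

    # Dirichlet-multinomial counts with a group shift on designated taxa
    n_total = spec.n_taxa + spec.n_unmatched_taxa
    base = rng.dirichlet(np.ones(n_total))
    shift = np.ones(n_total)
    for i in spec.affected_taxa:
        shift[i] = 2.0 ** spec.group_effect
    samples = [f"s{j:03d}" for j in range(spec.n_samples)]
    n_a = spec.n_samples // 2
    groups = ["A"] * n_a + ["B"] * (spec.n_samples - n_a)
    counts = np.zeros((n_total, spec.n_samples))
    for j, g in enumerate(groups):
        w = base * (shift if g == "B" else 1.0)
        w = w / w.sum()
        p = rng.dirichlet(spec.abundance_concentration * w)
        counts[:, j] = rng.multinomial(spec.sequencing_depth, p)

    fids = [f"asv{i:04d}" for i in range(n_total)]
    lineages = []
    for i in range(n_total):
        if i < spec.n_taxa:
            lineages.append((
                "Bacteria", f"Phylum{i % 5}", f"Class{i % 5}",
                f"Order{i % 5}", f"Family{i % 7}", genus[i], epithet[i],
            ))
        else:  # deliberately absent from the bundle
            u = i - spec.n_taxa
            lineages.append((
                "Bacteria", "PhylumX", "ClassX", "OrderX", "FamilyX",
                f"Novelgenus{u:02d}", f"incognita{u:02d}",
            ))
    table = pd.DataFrame(counts, index=pd.Index(fids, name="feature_id"),
                         columns=samples)
    taxonomy = pd.DataFrame(lineages, index=table.index, columns=list(RANKS))
    metadata = pd.DataFrame(
        {"group": groups}, index=pd.Index(samples, name="sample_id")
    )
    return SyntheticDataset(bundle, table, taxonomy, metadata, spec)


def _lineage_string(row: Sequence[str]) -> str:
    prefixes = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
    return "; ".join(p + n for p, n in zip(prefixes, row))


def write_dataset(
    dataset: ToyExample | SyntheticDataset, out_dir: str | Path
) -> None:
    """Emit the full TSV file set consumed by the CLI.

    Writes the bundle files (strains/reactions/presence[/ce_map].tsv)
    plus feature_table.tsv, taxonomy.tsv (silva-strings dialect), and
    metadata.tsv into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_bundle(dataset.bundle, out)
    ft = dataset.feature_table.copy()
    ft.index.name = "feature-id"
    ft.to_csv(out / "feature_table.tsv", sep="\t")
    tax = pd.DataFrame(
        {
            "Feature ID": dataset.taxonomy.index,
            "Taxon": [
                _lineage_string(dataset.taxonomy.loc[f, list(RANKS)])
                for f in dataset.taxonomy.index
            ],
        }
    )
    tax.to_csv(out / "taxonomy.tsv", sep="\t", index=False)
    md = dataset.metadata.copy()
    md.index.name = "sample-id"
    md.to_csv(out / "metadata.tsv", sep="\t")
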
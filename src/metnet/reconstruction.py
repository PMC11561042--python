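"""Metabolic-reconstruction bundles and taxon matching.

A *bundle* is the package's file-level contract for a collection of
strain-resolved genome-scale metabolic models (an AGORA/AGREDA-like
resource): a strain list with ranked lineages, a reaction list with
subsystem annotation, a binary strain x reaction presence matrix, and an
optional map assigning exchange reactions to compound-exchange (CE)
subsystems (families of exchanged metabolites such as short-chain fatty
acids).

Taxa observed in a 16S experiment are matched against strain lineages at
genus or species level after a light name normalization; taxa with no
matching strain are discarded downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError

#: Canonical rank order for lineages, coarsest first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_RANK_PREFIX = re.compile(r"^[a-zA-Z]__")
_WS = re.compile(r"[\s_]+")


def normalize_name(name: str) -> str:
    """Normalize a taxon name for matching.

    Case-insensitive; a leading ``g__``/``s__``-style rank prefix is
    stripped; underscores and runs of whitespace collapse to single
    spaces. This reconciles Silva-style lineage tokens with the strain
    naming used in reconstruction resources.
    """
    name = _RANK_PREFIX.sub("", name.strip())
    return _WS.sub(" ", name).strip().lower()


def species_key(genus: str, species: str) -> str:
    """Binomial match key ``"genus species"`` (normalized), or ``""``.

    Species epithets are not unique across genera, so the species-level
    key always carries the genus. If the species field already starts
    with the genus name (full binomial stored), it is used as-is.
    """
    g = normalize_name(genus)
    s = normalize_name(species)
    if not g or not s:
        return ""
    if s == g or s.startswith(g + " "):
        return s
    return f"{g} {s}"


@dataclass(frozen=True)
class Strain:
    """One organism-level metabolic model within a reconstruction."""

    strain_id: str
    lineage: Mapping[str, str]  # rank -> name, possibly empty strings

    def __post_init__(self) -> None:
        if not self.strain_id:
            raise SchemaError("strain_id must be non-empty")
        if self.lineage.get("species") and not self.lineage.get("genus"):
            raise SchemaError(
                f"strain {self.strain_id!r}: species set but genus empty"
            )

    @property
    def genus_key(self) -> str:
        return normalize_name(self.lineage.get("genus", ""))

    @property
    def species_key(self) -> str:
        return species_key(
            self.lineage.get("genus", ""), self.lineage.get("species", "")
        )


@dataclass(frozen=True)
class Reaction:
    """A reaction with its annotated subsystem and exchange status.

    ``ce_subsystem`` is only meaningful for exchange reactions; a
    reaction may carry both an annotated subsystem and a CE subsystem
    and then contributes to both rows of the subsystem matrix.
    """

    reaction_id: str
    subsystem: str = ""
    is_exchange: bool = False
    ce_subsystem: str = ""

    def __post_init__(self) -> None:
        if self.ce_subsystem and not self.is_exchange:
            raise SchemaError(
                f"reaction {self.reaction_id!r}: CE subsystem on a "
                "non-exchange reaction"
            )


@dataclass(frozen=True)
class TaxonMatch:
    """A sample taxon together with the reconstruction strains it maps to."""

    taxon_name: str
    strain_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.strain_ids:
            raise SchemaError(f"taxon {self.taxon_name!r}: empty strain list")


@dataclass
class ReconstructionBundle:
    """Validated in-memory reconstruction bundle.

    ``presence`` is a strain x reaction 0/1 DataFrame whose index/columns
    are the (lexicographically sorted) strain and reaction IDs.
    """

    strains: list[Strain]
    reactions: list[Reaction]
    presence: pd.DataFrame
    name: str = "bundle"
    _by_reaction: dict[str, Reaction] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.strains = sorted(self.strains, key=lambda s: s.strain_id)
        self.reactions = sorted(self.reactions, key=lambda r: r.reaction_id)
        sids = [s.strain_id for s in self.strains]
        rids = [r.reaction_id for r in self.reactions]
        if len(set(sids)) != len(sids):
            raise SchemaError("duplicate strain_id in bundle")
        if len(set(rids)) != len(rids):
            raise SchemaError("duplicate reaction_id in bundle")
        if set(self.presence.index) != set(sids) or set(
            self.presence.columns
        ) != set(rids):
            raise SchemaError(
                "presence matrix dimensions/labels do not match the strain "
                "and reaction lists"
            )
        self.presence = self.presence.loc[sids, rids].astype("int8")
        self.presence.index.name = "strain_id"
        self.presence.columns.name = "reaction_id"
        vals = self.presence.to_numpy()
        if not ((vals == 0) | (vals == 1)).all():
            raise SchemaError("presence entries must be 0 or 1")
        orphan = self.presence.columns[(vals.sum(axis=0) == 0)]
        if len(orphan):
            raise SchemaError(
                "reactions present in zero strains: "
                + ", ".join(map(str, orphan[:5]))
            )
        self._by_reaction = {r.reaction_id: r for r in self.reactions}

    # -- queries ---------------------------------------------------------

    @property
    def strain_ids(self) -> list[str]:
        return [s.strain_id for s in self.strains]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.reaction_id for r in self.reactions]

    def reaction(self, reaction_id: str) -> Reaction:
        return self._by_reaction[reaction_id]

    def subsystem_members(self) -> dict[str, list[str]]:
        """Map subsystem name -> sorted member reaction IDs.

        The universe is the union of annotated subsystems and CE
        subsystems; a reaction carrying both contributes to both. A
        reaction with neither belongs to no subsystem.
        """
        members: dict[str, list[str]] = {}
        for r in self.reactions:
            for sub in (r.subsystem, r.ce_subsystem):
                if sub:
                    members.setdefault(sub, []).append(r.reaction_id)
        return {k: sorted(v) for k, v in sorted(members.items())}


def subsystem_universe(bundle: ReconstructionBundle) -> list[str]:
    """Sorted union of annotated and CE subsystem names in the bundle."""
    return list(bundle.subsystem_members())


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kw)


def load_bundle(
    strains_path: str | Path,
    reactions_path: str | Path,
    presence_path: str | Path,
    ce_map_path: str | Path | None = None,
    name: str = "bundle",
) -> ReconstructionBundle:
    """Load and validate a reconstruction bundle from its TSV file set.

    ``presence.tsv`` is accepted either in long form (columns
    ``strain_id``, ``reaction_id``; one row per presence) or as a dense
    0/1 matrix (first column ``strain_id``, remaining columns reaction
    IDs). Reactions named in the CE map are flagged as exchanges and
    their CE subsystems join the subsystem universe.
    """
    sdf = _read_tsv(strains_path)
    required = ["strain_id", *RANKS]
    missing = [c for c in required if c not in sdf.columns]
    if missing:
        raise SchemaError(f"strains file missing columns: {missing}")
    strains = [
        Strain(row["strain_id"], {rk: row[rk] for rk in RANKS})
        for _, row in sdf.iterrows()
    ]

    rdf = _read_tsv(reactions_path)
    if "reaction_id" not in rdf.columns:
        raise SchemaError("reactions file missing column 'reaction_id'")
    if "subsystem" not in rdf.columns:
        rdf["subsystem"] = ""

    ce: dict[str, str] = {}
    if ce_map_path is not None:
        cdf = _read_tsv(ce_map_path)
        if not {"reaction_id", "ce_subsystem"} <= set(cdf.columns):
            raise SchemaError(
                "ce_map file must have columns reaction_id, ce_subsystem"
            )
        known = set(rdf["reaction_id"])
        for _, row in cdf.iterrows():
            if row["reaction_id"] not in known:
                raise SchemaError(
                    f"ce_map names unknown reaction {row['reaction_id']!r}"
                )
            ce[row["reaction_id"]] = row["ce_subsystem"]

    reactions = [
        Reaction(
            row["reaction_id"],
            subsystem=row["subsystem"],
            is_exchange=row["reaction_id"] in ce,
            ce_subsystem=ce.get(row["reaction_id"], ""),
        )
        for _, row in rdf.iterrows()
    ]

    pdf = _read_tsv(presence_path)
    sids = sorted(s.strain_id for s in strains)
    rids = sorted(r.reaction_id for r in reactions)
    if list(pdf.columns) == ["strain_id", "reaction_id"]:
        presence = pd.DataFrame(0, index=sids, columns=rids, dtype="int8")
        for _, row in pdf.iterrows():
            if row["strain_id"] not in presence.index:
                raise SchemaError(
                    f"presence names unknown strain {row['strain_id']!r}"
                )
            if row["reaction_id"] not in presence.columns:
                raise SchemaError(
                    f"presence names unknown reaction {row['reaction_id']!r}"
                )
            presence.loc[row["strain_id"], row["reaction_id"]] = 1
    else:
        first = pdf.columns[0]
        presence = pdf.set_index(first)
        try:
            presence = presence.astype("int8")
        except ValueError as exc:
            raise SchemaError(f"non-binary presence matrix: {exc}") from exc

    return ReconstructionBundle(strains, reactions, presence, name=name)


def match_taxa(
    bundle: ReconstructionBundle,
    taxon_names: Sequence[str],
    level: str,
) -> tuple[list[TaxonMatch], list[tuple[str, str]]]:
    """Match taxon names to bundle strains at genus or species level.

    Returns one :class:`TaxonMatch` per input name that matches at least
    one strain lineage (after :func:`normalize_name`), preserving input
    order, plus a discard list of ``(name, reason)`` for the rest.
    """
    if level not in ("genus", "species"):
        raise ValueError(f"level must be 'genus' or 'species', got {level!r}")
    lookup: dict[str, list[str]] = {}
    for s in bundle.strains:
        key = s.genus_key if level == "genus" else s.species_key
        if key:
            lookup.setdefault(key, []).append(s.strain_id)
    matches: list[TaxonMatch] = []
    discarded: list[tuple[str, str]] = []
    for nm in taxon_names:
        hit = lookup.get(normalize_name(nm))
        if hit:
            matches.append(TaxonMatch(nm, tuple(sorted(hit))))
        else:
            discarded.append((nm, "no reconstruction match"))
    return matches, discarded


def write_bundle(bundle: ReconstructionBundle, out_dir: str | Path) -> None:
    """Write a bundle back to its TSV schema (long-form presence)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"strain_id": s.strain_id, **{rk: s.lineage.get(rk, "") for rk in RANKS}}
            for s in bundle.strains
        ]
    ).to_csv(out / "strains.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"reaction_id": r.reaction_id, "subsystem": r.subsystem}
            for r in bundle.reactions
        ]
    ).to_csv(out / "reactions.tsv", sep="\t", index=False)
    long = bundle.presence.stack()
    long = long[long == 1]
    pd.DataFrame(
        {
            "strain_id": long.index.get_level_values(0),
            "reaction_id": long.index.get_level_values(1),
        }
    ).to_csv(out / "presence.tsv", sep="\t", index=False)
    ce_rows = [
        {"reaction_id": r.reaction_id, "ce_subsystem": r.ce_subsystem}
        for r in bundle.reactions
        if r.ce_subsystem
    ]
    if ce_rows:
        pd.DataFrame(ce_rows).to_csv(out / "ce_map.tsv", sep="\t", index=False)
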
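"""Feature-table ingestion and abundance-matrix construction.

Implements the contextualization step of the pipeline: parse the
ASV/OTU count table, taxonomy assignments, and sample metadata; collapse
features to an unambiguous genus- or species-level assignment; convert
counts to per-sample relative frequencies; and restrict to taxa that
match strains in the selected reconstruction, yielding the taxon x
sample abundance matrix X.

Normalization happens *before* deletion of unmatched taxa, so X columns
may sum to less than 1 after restriction; ``renormalize_after_match``
rescales them back to 1 if requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError
from .reconstruction import (
    RANKS,
    ReconstructionBundle,
    TaxonMatch,
    match_taxa,
    normalize_name,
    _RANK_PREFIX,
)

log = logging.getLogger(__name__)

#: Substrings marking a rank name as ambiguous (common 16S practice).
DEFAULT_AMBIGUITY_MARKERS = (
    "uncultured",
    "metagenome",
    "sp.",
    "unidentified",
)


@dataclass
class AbundanceMatrix:
    """Relative abundances of reconstruction-matched taxa (matrix X).

    ``values`` is taxon x sample in [0, 1]; ``matches`` is aligned
    row-wise with ``values.index``; ``discard_log`` records dropped
    items as ``(item, reason)``.
    """

    values: pd.DataFrame
    matches: list[TaxonMatch]
    discard_log: list[tuple[str, str]] = field(default_factory=list)

    @property
    def taxon_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _clean_display(name: str) -> str:
    return " ".join(_RANK_PREFIX.sub("", name.strip()).replace("_", " ").split())


def parse_feature_table(path: str | Path) -> pd.DataFrame:
    """Parse an ASV/OTU count TSV into a feature x sample DataFrame.

    The first column is the feature ID; a QIIME2-style ``#OTU ID``
    header (and a leading ``# Constructed from biom file`` comment) is
    tolerated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    # skip pure comment lines, but a '#OTU ID' line is the header
    start = 0
    for i, line in enumerate(lines):
        if line.startswith("#") and not line.startswith("#OTU ID"):
            start = i + 1
        else:
            start = i
            break
    rows = [line.split("\t") for line in lines[start:] if line.strip()]
    if not rows:
        raise ParseError(f"{path}: empty feature table")
    header = rows[0]
    samples = header[1:]
    ids, data = [], []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ParseError(f"{path}: row {r} has {len(row)} fields, "
                             f"expected {len(header)}")
        ids.append(row[0])
        vals = []
        for c, cell in enumerate(row[1:], start=2):
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric count at row {r}, column {c}: "
                    f"{cell!r}"
                ) from None
            if v < 0:
                raise ParseError(
                    f"{path}: negative count at row {r}, column {c}"
                )
            vals.append(v)
        data.append(vals)
    if len(set(ids)) != len(ids):
        raise SchemaError(f"{path}: duplicate feature IDs")
    if len(set(samples)) != len(samples):
        raise SchemaError(f"{path}: duplicate sample IDs")
    return pd.DataFrame(data, index=pd.Index(ids, name="feature_id"),
                        columns=samples, dtype=float)


def parse_taxonomy(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Parse taxonomy assignments into a feature x rank DataFrame.

    Two dialects: ``silva-strings`` (columns ``Feature ID`` and a
    semicolon-delimited ``Taxon`` lineage, optional ``Confidence``) and
    ``rank-columns`` (explicit columns per rank). ``None`` auto-detects.
    Rank prefixes (``d__`` etc.) are stripped; missing ranks are empty
    strings. Raw case/spelling is preserved; normalization happens at
    match time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.lower().replace("-", " ").replace("_", " "): c for c in df.columns}
    if dialect is None:
        dialect = "silva-strings" if "taxon" in cols else "rank-columns"
    id_col = cols.get("feature id") or cols.get("otu id") or df.columns[0]
    ids = df[id_col]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise SchemaError(f"{path}: feature {dup!r} listed twice")
    if dialect == "silva-strings":
        if "taxon" not in cols:
            raise SchemaError(f"{path}: no 'Taxon' column for silva-strings")
        lineages = []
        for s in df[cols["taxon"]]:
            parts = [
                _RANK_PREFIX.sub("", p.strip()) for p in s.split(";")
            ] if s.strip() else []
            parts = (parts + [""] * len(RANKS))[: len(RANKS)]
            lineages.append(parts)
        out = pd.DataFrame(lineages, index=ids, columns=list(RANKS))
    elif dialect == "rank-columns":
        missing = [rk for rk in RANKS if rk not in cols]
        if missing:
            raise SchemaError(f"{path}: missing rank columns {missing}")
        out = pd.DataFrame(
            {rk: df[cols[rk]].values for rk in RANKS}, index=ids
        )
    else:
        raise ValueError(f"unknown taxonomy dialect {dialect!r}")
    if "confidence" in cols:
        out["confidence"] = pd.to_numeric(df[cols["confidence"]].values,
                                          errors="coerce")
    out.index.name = "feature_id"
    return out


def parse_metadata(path: str | Path) -> pd.DataFrame:
    """Parse QIIME2-dialect sample metadata (``#q2:types`` line skipped)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if len(df) and str(df.iloc[0, 0]).startswith("#q2:types"):
        df = df.iloc[1:].reset_index(drop=True)
    id_col = df.columns[0]
    if id_col.lower() not in ("#sampleid", "sample-id", "sample_id", "sampleid", "id"):
        raise SchemaError(
            f"{path}: first metadata column {id_col!r} is not a sample-id column"
        )
    if df[id_col].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample IDs")
    return df.set_index(id_col).rename_axis("sample_id")


def taxon_label(lineage: Sequence[str] | pd.Series, level: str) -> str:
    """Display label of a lineage at genus/species level ('' if absent).

    Species labels are binomials (``"Genus epithet"``); a species field
    that already repeats the genus is not duplicated.
    """
    get = (lambda rk: lineage[RANKS.index(rk)]) if not isinstance(
        lineage, pd.Series
    ) else (lambda rk: lineage[rk])
    genus = _clean_display(get("genus"))
    if level == "genus":
        return genus
    species = _clean_display(get("species"))
    if not genus or not species:
        return ""
    if normalize_name(species).startswith(normalize_name(genus)):
        return species
    return f"{genus} {species}"


def collapse_to_level(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    level: str,
    ambiguity_markers: Sequence[str] = DEFAULT_AMBIGUITY_MARKERS,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Collapse features to unambiguous taxa at ``level``, merging counts.

    Features with an empty name at ``level``, an ambiguity marker in the
    name, or no taxonomy entry are dropped (logged with reason
    "ambiguous assignation"). Features sharing a (normalized) name are
    merged by summing counts. Returns the collapsed table (taxon label x
    sample, sorted rows) and the discard log.
    """
    if level not in ("genus", "species"):
        raise ValueError(f"level must be 'genus' or 'species', got {level!r}")
    discard: list[tuple[str, str]] = []
    groups: dict[str, str] = {}  # normalized key -> display label
    assign: dict[str, str] = {}  # feature_id -> normalized key
    for fid in table.index:
        if fid not in taxonomy.index:
            discard.append((fid, "ambiguous assignation"))
            continue
        label = taxon_label(taxonomy.loc[fid], level)
        low = label.lower()
        if not label or any(m in low for m in ambiguity_markers):
            discard.append((fid, "ambiguous assignation"))
            continue
        key = normalize_name(label)
        groups.setdefault(key, label)
        assign[fid] = key
    if not assign:
        log.warning("collapse_to_level: no unambiguous features at %s level",
                    level)
        return (
            pd.DataFrame(columns=table.columns, dtype=float),
            discard,
        )
    kept = table.loc[list(assign)]
    collapsed = kept.groupby([assign[f] for f in kept.index]).sum()
    collapsed.index = [groups[k] for k in collapsed.index]
    collapsed = collapsed.sort_index()
    collapsed.index.name = "taxon"
    return collapsed, discard


def build_abundance_matrix(
    collapsed: pd.DataFrame,
    bundle: ReconstructionBundle,
    level: str,
    renormalize_after_match: bool = False,
) -> AbundanceMatrix:
    """Relative frequencies restricted to reconstruction-matched taxa.

    Per sample, counts are divided by the total over *all* collapsed
    features (pre-deletion columns sum to 1); rows whose taxon has no
    strain match in the bundle are then deleted. With
    ``renormalize_after_match`` the remaining columns are rescaled to
    sum to 1.
    """
    if collapsed.empty:
        raise SchemaError("collapsed feature table is empty")
    totals = collapsed.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise SchemaError(
            f"sample(s) with zero total count: {', '.join(map(str, zero.index))}"
        )
    rel = collapsed / totals

    matches, discarded = match_taxa(bundle, list(rel.index), level)
    kept = [m.taxon_name for m in matches]
    values = rel.loc[kept]
    if renormalize_after_match:
        col = values.sum(axis=0)
        if (col == 0).any():
            bad = list(col.index[col == 0])
            raise SchemaError(
                f"cannot renormalize: no matched abundance in sample(s) {bad}"
            )
        values = values / col
    return AbundanceMatrix(values=values, matches=matches,
                           discard_log=list(discarded))
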
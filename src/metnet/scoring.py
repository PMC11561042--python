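"""Reaction and subsystem activity scoring.

The reaction x taxon matrix R holds, for each matched taxon, the
fraction of its strains that carry each reaction (``ratio`` mode), or an
all-or-nothing indicator (``full`` mode, the convention used by mgPipe).
Reaction activity per sample is the product

    W = R . X

with X the taxon x sample relative-abundance matrix, so W_kj is the
presence ratio of reaction k in sample j weighted by taxon abundance.
Subsystem activity aggregates W through a subsystem x reaction matrix S,

    Y = S . W

where each global-mode row of S spreads weight 1/|members| over a
subsystem's member reactions (rows sum to 1). The ``contextualized``
mode instead renormalizes each row per sample over the member reactions
actually present there (W_kj > 0), again following mgPipe's convention.
All scores land in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .features import AbundanceMatrix
from .reconstruction import ReconstructionBundle, TaxonMatch

log = logging.getLogger(__name__)


def build_reaction_matrix(
    bundle: ReconstructionBundle,
    matches: Sequence[TaxonMatch],
    weight_mode: str = "ratio",
) -> pd.DataFrame:
    """Reaction x taxon matrix R of strain-presence ratios.

    ``ratio``: R_ki = (strains of taxon i carrying reaction k) / (strains
    of taxon i). ``full``: R_ki = 1 whenever any strain of taxon i
    carries reaction k.
    """
    if weight_mode not in ("ratio", "full"):
        raise ValueError(f"weight_mode must be 'ratio' or 'full', got "
                         f"{weight_mode!r}")
    if not matches:
        raise SchemaError("no taxon matches: cannot build reaction matrix")
    cols = {}
    for m in matches:
        missing = set(m.strain_ids) - set(bundle.presence.index)
        if missing:
            raise SchemaError(
                f"taxon {m.taxon_name!r} references unknown strains {missing}"
            )
        sub = bundle.presence.loc[list(m.strain_ids)]
        frac = sub.mean(axis=0)
        cols[m.taxon_name] = (frac > 0).astype(float) if weight_mode == "full" else frac
    R = pd.DataFrame(cols).astype(float)
    R.index.name = "reaction_id"
    R.columns.name = "taxon"
    return R


def compute_reaction_scores(
    R: pd.DataFrame, X: AbundanceMatrix | pd.DataFrame
) -> pd.DataFrame:
    """Reaction activity W = R . X (reaction x sample)."""
    Xv = X.values if isinstance(X, AbundanceMatrix) else X
    if list(R.columns) != list(Xv.index):
        raise SchemaError(
            "taxon order mismatch between reaction matrix and abundances"
        )
    W = pd.DataFrame(
        R.to_numpy() @ Xv.to_numpy(), index=R.index, columns=Xv.columns
    )
    W.index.name = "reaction_id"
    return W


@dataclass
class SubsystemMatrix:
    """Subsystem x reaction normalization matrix S.

    ``global`` mode holds a single matrix; ``contextualized`` mode holds
    one matrix per sample (member-reaction weights renormalized over the
    reactions with nonzero activity in that sample). ``dropped`` lists
    subsystems excluded for having no member among the given reactions.
    """

    subsystem_names: list[str]
    reaction_ids: list[str]
    mode: str
    matrix: pd.DataFrame | None = None
    per_sample: dict[str, pd.DataFrame] | None = None
    dropped: list[str] = field(default_factory=list)


def build_subsystem_matrix(
    bundle: ReconstructionBundle,
    reaction_ids: Sequence[str],
    mode: str = "global",
    W: pd.DataFrame | None = None,
    presence_epsilon: float = 0.0,
) -> SubsystemMatrix:
    """Build S over ``reaction_ids`` in global or contextualized mode.

    Contextualized mode requires the reaction activity W and counts, per
    sample, only member reactions with W_kj > ``presence_epsilon``; a
    subsystem with no present member in a sample gets an all-zero row
    there (its activity is 0).
    """
    if mode not in ("global", "contextualized"):
        raise ValueError(f"mode must be 'global' or 'contextualized', got "
                         f"{mode!r}")
    reaction_ids = list(reaction_ids)
    members_all = bundle.subsystem_members()
    rset = set(reaction_ids)
    members = {z: [r for r in rs if r in rset] for z, rs in members_all.items()}
    dropped = sorted(z for z, rs in members.items() if not rs)
    for z in dropped:
        log.warning("subsystem %r has no annotated reaction among the "
                    "given reactions; excluded", z)
    members = {z: rs for z, rs in members.items() if rs}
    names = sorted(members)
    annotated = {r for rs in members.values() for r in rs}
    unannotated = sorted(rset - annotated)
    if unannotated:
        log.info("%d unannotated reactions contribute to W only: %s%s",
                 len(unannotated), ", ".join(unannotated[:5]),
                 "..." if len(unannotated) > 5 else "")

    def _matrix(present: set[str] | None) -> pd.DataFrame:
        S = pd.DataFrame(0.0, index=names, columns=reaction_ids)
        for z, rs in members.items():
            use = rs if present is None else [r for r in rs if r in present]
            if use:
                S.loc[z, use] = 1.0 / len(use)
        S.index.name = "subsystem"
        return S

    if mode == "global":
        return SubsystemMatrix(names, reaction_ids, mode, matrix=_matrix(None),
                               dropped=dropped)
    if W is None:
        raise ValueError("contextualized mode requires the reaction activity W")
    if list(W.index) != reaction_ids:
        raise SchemaError("reaction order mismatch between W and reaction_ids")
    per_sample = {
        j: _matrix(set(W.index[W[j] > presence_epsilon])) for j in W.columns
    }
    return SubsystemMatrix(names, reaction_ids, mode, per_sample=per_sample,
                           dropped=dropped)


def compute_subsystem_scores(S: SubsystemMatrix, W: pd.DataFrame) -> pd.DataFrame:
    """Subsystem activity Y = S . W (subsystem x sample).

    In contextualized mode each sample's column uses that sample's S.
    """
    if list(W.index) != S.reaction_ids:
        raise SchemaError("reaction order mismatch between S and W")
    if S.mode == "global":
        Y = pd.DataFrame(
            S.matrix.to_numpy() @ W.to_numpy(),
            index=S.subsystem_names, columns=W.columns,
        )
    else:
        cols = {}
        for j in W.columns:
            if j not in S.per_sample:
                raise SchemaError(f"no contextualized S for sample {j!r}")
            cols[j] = S.per_sample[j].to_numpy() @ W[j].to_numpy()
        Y = pd.DataFrame(cols, index=S.subsystem_names)
    Y.index.name = "subsystem"
    return Y


@dataclass
class GenerateFeaturesResult:
    """End-to-end scoring output: W, Y, the intermediates, and the log."""

    reaction_scores: pd.DataFrame
    subsystem_scores: pd.DataFrame
    abundance: AbundanceMatrix
    reaction_matrix: pd.DataFrame
    subsystem_matrix: SubsystemMatrix
    discard_log: list[tuple[str, str, str]]  # (item, stage, reason)
    params: dict


def generate_features(
    feature_table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    bundle: ReconstructionBundle,
    level: str = "species",
    weight_mode: str = "ratio",
    subsystem_mode: str = "global",
    renormalize_after_match: bool = False,
) -> GenerateFeaturesResult:
    """Run the full pipeline: collapse, normalize, match, score.

    Defaults follow the method's stated defaults: species-level
    collapse, strain-ratio reaction weights, global subsystem
    normalization, no post-match renormalization.
    """
    from .estimators import MetabolicActivityScorer

    est = MetabolicActivityScorer(
        bundle=bundle,
        taxonomy=taxonomy,
        level=level,
        weight_mode=weight_mode,
        subsystem_mode=subsystem_mode,
        renormalize_after_match=renormalize_after_match,
    )
    est.fit(feature_table.T)
    return GenerateFeaturesResult(
        reaction_scores=est.reaction_scores_,
        subsystem_scores=est.subsystem_scores_,
        abundance=est.abundance_,
        reaction_matrix=est.R_,
        subsystem_matrix=est.S_,
        discard_log=est.discard_log_,
        params=est.get_params(deep=False) | {"bundle": bundle.name,
                                             "taxonomy": "<table>"},
    )
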
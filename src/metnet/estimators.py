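"""Scikit-learn style estimator wrapping the scoring pipeline.

:class:`MetabolicActivityScorer` is a transformer mapping an ASV/OTU
count table (samples x features, as sklearn expects) to normalized
reaction- or subsystem-level metabolic activity scores in [0, 1]. The
reconstruction bundle and taxonomy table are configuration: they play
the role of a fixed annotation resource, not of training data. ``fit``
collapses and matches the training table's taxa against the bundle and
freezes the matched taxon set and the R/S matrices; ``transform`` scores
any table of the same features (or a superset/subset — taxa absent from
a new table contribute zero abundance).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import SchemaError
from .features import (
    AbundanceMatrix,
    build_abundance_matrix,
    collapse_to_level,
)
from .reconstruction import ReconstructionBundle
from . import scoring


class MetabolicActivityScorer(BaseEstimator, TransformerMixin):
    """Transform taxonomic counts into metabolic activity scores.

    Parameters
    ----------
    bundle : ReconstructionBundle
        Strain-resolved metabolic reconstruction to contextualize into.
    taxonomy : pandas.DataFrame
        Per-feature ranked lineages (as returned by
        :func:`metnet.features.parse_taxonomy`).
    level : {'species', 'genus'}, default='species'
        Taxonomic rank for collapsing and strain matching.
    weight_mode : {'ratio', 'full'}, default='ratio'
        Strain-presence ratio R entries, or all-or-nothing (mgPipe-style).
    subsystem_mode : {'global', 'contextualized'}, default='global'
        Global S rows (1/|members|), or per-sample renormalization over
        reactions present in the sample (mgPipe-style).
    renormalize_after_match : bool, default=False
        Rescale abundance columns to sum to 1 after dropping unmatched
        taxa.
    target : {'reaction', 'subsystem'}, default='reaction'
        Which score table :meth:`transform` returns.
    presence_epsilon : float, default=0.0
        Activity threshold used by the contextualized presence test.

    Attributes
    ----------
    taxon_names_ : list of str
        Matched taxa, aligned with the rows of the abundance matrix.
    matches_ : list of TaxonMatch
        Strain assignments per matched taxon.
    R_ : pandas.DataFrame
        Reaction x taxon strain-presence matrix.
    S_ : metnet.scoring.SubsystemMatrix
        Subsystem x reaction normalization matrix.
    abundance_ : metnet.features.AbundanceMatrix
        Training-table abundances (matrix X).
    reaction_scores_, subsystem_scores_ : pandas.DataFrame
        Scores of the training table (W and Y, feature x sample).
    discard_log_ : list of (item, stage, reason)
        Features/taxa dropped during collapse and matching.
    """

    def __init__(
        self,
        bundle: ReconstructionBundle | None = None,
        taxonomy: pd.DataFrame | None = None,
        level: str = "species",
        weight_mode: str = "ratio",
        subsystem_mode: str = "global",
        renormalize_after_match: bool = False,
        target: str = "reaction",
        presence_epsilon: float = 0.0,
    ):
        self.bundle = bundle
        self.taxonomy = taxonomy
        self.level = level
        self.weight_mode = weight_mode
        self.subsystem_mode = subsystem_mode
        self.renormalize_after_match = renormalize_after_match
        self.target = target
        self.presence_epsilon = presence_epsilon

    # ------------------------------------------------------------------

    def _validate_params_(self) -> None:
        if self.bundle is None or self.taxonomy is None:
            raise ValueError("bundle and taxonomy must be provided")
        if self.target not in ("reaction", "subsystem"):
            raise ValueError(f"target must be 'reaction' or 'subsystem', "
                             f"got {self.target!r}")

    @staticmethod
    def _as_counts(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError(
                "X must be a samples x features pandas DataFrame whose "
                "columns are feature IDs"
            )
        counts = X.T.astype(float)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        return counts

    def fit(self, X: pd.DataFrame, y=None) -> "MetabolicActivityScorer":
        """Collapse, match, and build R/S from the training table."""
        self._validate_params_()
        counts = self._as_counts(X)
        collapsed, drop_collapse = collapse_to_level(
            counts, self.taxonomy, self.level
        )
        abundance = build_abundance_matrix(
            collapsed, self.bundle, self.level,
            renormalize_after_match=self.renormalize_after_match,
        )
        R = scoring.build_reaction_matrix(
            self.bundle, abundance.matches, weight_mode=self.weight_mode
        )
        W = scoring.compute_reaction_scores(R, abundance)
        S = scoring.build_subsystem_matrix(
            self.bundle, list(W.index), mode=self.subsystem_mode,
            W=W if self.subsystem_mode == "contextualized" else None,
            presence_epsilon=self.presence_epsilon,
        )
        Y = scoring.compute_subsystem_scores(S, W)

        self.collapsed_ = collapsed
        self.abundance_ = abundance
        self.matches_ = abundance.matches
        self.taxon_names_ = list(abundance.values.index)
        self.R_ = R
        self.S_ = S
        self.reaction_scores_ = W
        self.subsystem_scores_ = Y
        self.discard_log_ = (
            [(item, "collapse", reason) for item, reason in drop_collapse]
            + [(item, "match", reason) for item, reason in abundance.discard_log]
        )
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Score a count table against the fitted R/S (samples x scores)."""
        check_is_fitted(self, "R_")
        counts = self._as_counts(X)
        collapsed, _ = collapse_to_level(counts, self.taxonomy, self.level)
        totals = collapsed.sum(axis=0) if not collapsed.empty else pd.Series(
            0.0, index=counts.columns
        )
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise SchemaError(f"sample(s) with zero total count: {bad}")
        rel = collapsed / totals
        Xmat = rel.reindex(self.taxon_names_).fillna(0.0)
        if self.renormalize_after_match:
            col = Xmat.sum(axis=0)
            if (col == 0).any():
                raise SchemaError(
                    "cannot renormalize: samples with no matched abundance"
                )
            Xmat = Xmat / col
        W = scoring.compute_reaction_scores(self.R_, Xmat)
        if self.target == "reaction":
            return W.T
        S = (
            self.S_
            if self.subsystem_mode == "global"
            else scoring.build_subsystem_matrix(
                self.bundle, list(W.index), mode="contextualized", W=W,
                presence_epsilon=self.presence_epsilon,
            )
        )
        return scoring.compute_subsystem_scores(S, W).T

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "R_")
        names = (
            list(self.reaction_scores_.index)
            if self.target == "reaction"
            else list(self.subsystem_scores_.index)
        )
        return np.asarray(names, dtype=object)
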
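"""Scikit-learn style estimators over the alignment library.

The estimators follow the usual contract — keyword-only constructor
parameters, ``fit(X)`` with list-of-structures input, fitted attributes
with a trailing underscore, ``get_params``/``set_params`` — so they
compose with sklearn pipelines and model selection.
:class:`StructureFeaturizer` is a transformer: it aligns a structure
family and turns it into a flat (n_structures, n_columns * n_features)
matrix ready for an imputer and a downstream classifier.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .dp import GapPenalties
from .features import aligned_feature_matrix, extract_features
from .metrics import alignment_quality
from .multiple import multiple_align
from .pairwise import AlignmentParams, pairwise_align, tree_score

__all__ = ["PairwiseAligner", "MultipleAligner", "StructureFeaturizer"]


class _ParamsMixin:
    def _alignment_params(self) -> AlignmentParams:
        return AlignmentParams(
            gamma=self.gamma,
            coord_penalties=GapPenalties(self.gap_open, self.gap_extend),
            sec_penalties=GapPenalties(self.sec_gap_open, self.sec_gap_extend),
            consensus_weight=self.consensus_weight,
            segment_length=self.segment_length,
            refine_iterations=self.refine_iterations,
        )


class PairwiseAligner(BaseEstimator, _ParamsMixin):
    """Pairwise structure alignment as an estimator.

    ``fit(X)`` takes exactly two :class:`~stralign.ProteinStructure`
    objects and exposes the alignment, the rigid transform taking the
    first onto the second, the summed RBF score and the normalized
    (per-aligned-pair) score.
    """

    def __init__(
        self,
        gamma: float = 0.03,
        gap_open: float = 1.0,
        gap_extend: float = 0.01,
        sec_gap_open: float = 1.0,
        sec_gap_extend: float = 0.0,
        consensus_weight: float = 1.0,
        segment_length: int = 30,
        refine_iterations: int = 1,
    ):
        self.gamma = gamma
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self.sec_gap_open = sec_gap_open
        self.sec_gap_extend = sec_gap_extend
        self.consensus_weight = consensus_weight
        self.segment_length = segment_length
        self.refine_iterations = refine_iterations

    def fit(self, X, y=None):
        X = list(X)
        if len(X) != 2:
            raise ValueError("PairwiseAligner.fit expects exactly 2 structures")
        aln, transform = pairwise_align(X[0], X[1], self._alignment_params())
        self.alignment_ = aln
        self.transform_ = transform
        self.score_ = aln.score
        self.normalized_score_ = tree_score(aln)
        return self


class MultipleAligner(BaseEstimator, _ParamsMixin):
    """Consensus-weighted progressive multiple structure alignment.

    Fitted attributes: ``alignment_`` (the gapped index rows),
    ``tree_`` (guide tree), ``pairwise_scores_`` (normalized all-vs-all
    similarities) and ``root_`` (the final alignment node with averaged
    coordinates and consensus row). ``quality(structures)`` computes the
    standard metrics for the fitted alignment.
    """

    def __init__(
        self,
        gamma: float = 0.03,
        gap_open: float = 1.0,
        gap_extend: float = 0.01,
        sec_gap_open: float = 1.0,
        sec_gap_extend: float = 0.0,
        consensus_weight: float = 1.0,
        segment_length: int = 30,
        refine_iterations: int = 1,
    ):
        self.gamma = gamma
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self.sec_gap_open = sec_gap_open
        self.sec_gap_extend = sec_gap_extend
        self.consensus_weight = consensus_weight
        self.segment_length = segment_length
        self.refine_iterations = refine_iterations

    def fit(self, X, y=None):
        X = list(X)
        msa, tree, scores, root = multiple_align(
            X, self._alignment_params(), return_state=True
        )
        self.alignment_ = msa
        self.tree_ = tree
        self.pairwise_scores_ = scores
        self.root_ = root
        self.structures_ = X
        return self

    def quality(self, reference=None):
        return alignment_quality(self.alignment_, self.structures_, reference)


class StructureFeaturizer(TransformerMixin, BaseEstimator, _ParamsMixin):
    """Structure family -> flat aligned feature matrix.

    ``fit(X)`` aligns the family (or adopts ``msa`` if given) and extracts
    per-residue features; ``transform(X)`` returns an
    (n_structures, n_columns * n_features) float array with NaN at gap
    cells and undefined features, suitable for an imputer + estimator
    pipeline. ``drop_gap_columns=True`` keeps only fully aligned columns,
    the usual preprocessing before supervised learning.
    """

    def __init__(
        self,
        gamma: float = 0.03,
        gap_open: float = 1.0,
        gap_extend: float = 0.01,
        sec_gap_open: float = 1.0,
        sec_gap_extend: float = 0.0,
        consensus_weight: float = 1.0,
        segment_length: int = 30,
        refine_iterations: int = 1,
        msa=None,
        drop_gap_columns: bool = False,
        gnm_cutoff: float = 10.0,
        anm_cutoff: float = 15.0,
        n_modes: int = 50,
        probe: float = 1.4,
        sphere_points: int = 256,
    ):
        self.gamma = gamma
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self.sec_gap_open = sec_gap_open
        self.sec_gap_extend = sec_gap_extend
        self.consensus_weight = consensus_weight
        self.segment_length = segment_length
        self.refine_iterations = refine_iterations
        self.msa = msa
        self.drop_gap_columns = drop_gap_columns
        self.gnm_cutoff = gnm_cutoff
        self.anm_cutoff = anm_cutoff
        self.n_modes = n_modes
        self.probe = probe
        self.sphere_points = sphere_points

    def fit(self, X, y=None):
        X = list(X)
        if self.msa is not None:
            self.alignment_ = self.msa
        else:
            self.alignment_ = multiple_align(X, self._alignment_params())
        per_structure = {
            s.id: extract_features(
                s,
                gnm_cutoff=self.gnm_cutoff,
                anm_cutoff=self.anm_cutoff,
                n_modes=self.n_modes,
                probe=self.probe,
                sphere_points=self.sphere_points,
            )
            for s in X
        }
        matrix = aligned_feature_matrix(self.alignment_, per_structure)
        if self.drop_gap_columns:
            matrix = matrix.drop_gap_columns()
        self.feature_matrix_ = matrix
        self.feature_names_ = [
            f"col{c}_{name}"
            for c in range(matrix.column_count)
            for name in matrix.feature_names
        ]
        return self

    def transform(self, X):
        matrix = self.feature_matrix_
        order = {sid: k for k, sid in enumerate(matrix.structure_ids)}
        rows = [order[s.id] for s in X]
        return matrix.values[rows].reshape(len(rows), -1)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
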
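"""Scikit-learn-style estimators for score construction and binning.

:class:`GeneticRiskScorer` is the fit/transform face of the method:
``fit(X, y)`` runs the per-SNP dominant/recessive association scan on a
coded genotype matrix against case/control labels, gates the
significant SNPs through forward stepwise logistic regression, and
builds the OR-weighted score model; ``transform(X)`` evaluates the
score per subject.  :class:`ChaidDiscretizer` fits the ordinal CHAID
partition of a score against the outcome and maps scores to risk-group
indices.  Both follow sklearn conventions (``get_params``/
``set_params``, fitted attributes with a trailing underscore) and
compose with sklearn pipelines.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import association as assoc
from .association import AssociationResult
from .chaid import Stratification, chaid_bin
from .cohort import MISSING
from .logistic import forward_stepwise
from .score import ScoreModel, build_score_model


def _coded_frame(X) -> pd.DataFrame:
    """Accept a DataFrame of genotype codes or a plain array; NaN is
    treated as missing."""
    if isinstance(X, pd.DataFrame):
        df = X.copy()
    else:
        arr = np.asarray(X)
        df = pd.DataFrame(arr, columns=[f"snp{i}" for i in range(arr.shape[1])])
    out = df.astype(float)
    out = out.where(~out.isna(), MISSING)
    return out.astype(np.int8)


def _case_vector(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        y = y == "case"
    return y.astype(int)


class GeneticRiskScorer(BaseEstimator, TransformerMixin):
    """Odds-ratio-weighted genetic risk score fitted on case-control
    genotype data.

    Parameters
    ----------
    p_threshold : float, default 0.05
        Univariate significance required for a SNP to become a
        candidate score term.
    p_enter : float, default 0.05
        Likelihood-ratio entry threshold of the forward stepwise gate.
    use_stepwise : bool, default True
        Gate candidates through forward stepwise logistic regression;
        when False all univariately significant SNPs enter.
    weight_source : {"univariate-OR", "stepwise"}, default "univariate-OR"
        Weights from the univariate odds ratio (the published
        convention) or from the stepwise fit's exp(coefficients).
    missing_policy : {"exclude", "zero"}, default "exclude"
        Subjects missing a scored genotype get a NaN score (exclude)
        or count the missing indicator as 0 (zero).
    model_policy : {"best-of-two", "all"}, default "best-of-two"
        Per-SNP encoding selection of the scan.

    Attributes
    ----------
    scan_results_ : list of AssociationResult, sorted by p.
    candidate_results_ : the univariately significant subset.
    stepwise_ : StepwiseResult of the gate (None if disabled).
    model_ : fitted ScoreModel.
    terms_ : model_.terms.
    max_score_ : sum of term weights.
    """

    def __init__(
        self,
        p_threshold: float = 0.05,
        p_enter: float = 0.05,
        use_stepwise: bool = True,
        weight_source: str = "univariate-OR",
        missing_policy: str = "exclude",
        model_policy: str = "best-of-two",
    ):
        self.p_threshold = p_threshold
        self.p_enter = p_enter
        self.use_stepwise = use_stepwise
        self.weight_source = weight_source
        self.missing_policy = missing_policy
        self.model_policy = model_policy

    # -- fit -----------------------------------------------------------
    def fit(self, X, y, panel: pd.DataFrame | None = None):
        """Scan, gate and weight.  ``X`` is a subject x SNP matrix of
        genotype codes (0 hom-major, 1 het, 2 hom-minor, -1/NaN
        missing); ``y`` a case indicator.  ``panel`` optionally
        supplies gene and allele metadata for term labels."""
        codes = _coded_frame(X)
        yv = _case_vector(y)
        if codes.shape[0] != yv.shape[0]:
            raise ValueError("X and y lengths differ")
        self.feature_names_in_ = np.asarray(codes.columns, dtype=object)
        self.n_features_in_ = codes.shape[1]

        self.scan_results_ = assoc.scan_codes(codes, yv, self.model_policy, panel=panel)
        # candidates: per SNP the better encoding, univariately significant
        best_per_snp: dict[str, AssociationResult] = {}
        for r in self.scan_results_:
            if r.table is None or math.isnan(r.p):
                continue
            prev = best_per_snp.get(r.snp_id)
            if prev is None or r.p < prev.p:
                best_per_snp[r.snp_id] = r
        self.candidate_results_ = [
            r for r in best_per_snp.values()
            if r.p < self.p_threshold and not math.isnan(r.or_point) and r.or_point != 1.0
        ]
        self.candidate_results_.sort(key=lambda r: r.p)

        selected = self.candidate_results_
        self.stepwise_ = None
        if self.use_stepwise and self.candidate_results_:
            design, keep = self._risk_indicator_design(codes, self.candidate_results_)
            if design.shape[1] and keep.sum() > design.shape[1]:
                self.stepwise_ = forward_stepwise(
                    design.loc[keep], yv[keep.to_numpy()], p_enter=self.p_enter
                )
                chosen = set(self.stepwise_.selected)
                selected = [r for r in self.candidate_results_ if r.snp_id in chosen]

        if not selected:
            self.model_ = ScoreModel(terms=[], kind="genetic")
        elif self.weight_source == "stepwise" and self.stepwise_ is not None:
            # design columns are risk-direction indicators, so a sound
            # joint effect has coef > 0 and weight exp(coef) >= 1
            from .score import ScoreTerm, _round_half_away

            terms = []
            for r in selected:
                coef = self.stepwise_.fit.coef(r.snp_id)
                weight = _round_half_away(math.exp(coef), 1)
                if coef <= 0 or weight < 1.0:
                    continue
                risk = r.or_point > 1
                terms.append(ScoreTerm(
                    source=r.snp_id,
                    weight=weight,
                    classes=frozenset(r.model.exposed_codes if risk else r.model.complement_codes),
                    label=r.exposed_label if risk else r.complement_label,
                ))
            terms.sort(key=lambda t: (-t.weight, t.source))
            self.model_ = ScoreModel(terms=terms, kind="genetic")
        else:
            self.model_ = build_score_model(selected, alpha=self.p_threshold)
        self.terms_ = self.model_.terms
        self.max_score_ = self.model_.max_score
        return self

    @staticmethod
    def _risk_indicator_design(
        codes: pd.DataFrame, results: list[AssociationResult]
    ) -> tuple[pd.DataFrame, pd.Series]:
        """Risk-direction indicator columns for the stepwise gate plus a
        complete-case row mask (subjects missing any candidate genotype
        are dropped from the gate)."""
        cols = {}
        miss = pd.Series(False, index=codes.index)
        for r in results:
            col = codes[r.snp_id]
            classes = r.model.exposed_codes if r.or_point > 1 else r.model.complement_codes
            cols[r.snp_id] = col.isin(list(classes)).astype(float)
            miss |= col == MISSING
        design = pd.DataFrame(cols, index=codes.index)
        return design, ~miss

    # -- transform -------------------------------------------------------
    def transform(self, X) -> np.ndarray:
        """Per-subject scores as an (n, 1) array (NaN for incomplete
        subjects under the exclude policy)."""
        check_is_fitted(self, "model_")
        codes = _coded_frame(X)
        tenths = np.zeros(len(codes), dtype=np.int64)
        incomplete = np.zeros(len(codes), dtype=bool)
        for term in self.model_.terms:
            if term.source not in codes.columns:
                raise ValueError(f"score term references unknown SNP {term.source!r}")
            col = codes[term.source].to_numpy()
            miss = col == MISSING
            incomplete |= miss
            ind = np.isin(col, list(term.classes)) & ~miss
            tenths += term.weight_tenths * ind.astype(np.int64)
        scores = tenths / 10.0
        if self.missing_policy == "exclude":
            scores = np.where(incomplete, np.nan, scores)
        return scores[:, None]


class ChaidDiscretizer(BaseEstimator, TransformerMixin):
    """Ordinal CHAID binning of a discrete score against an outcome.

    ``fit(X, y)`` learns contiguous risk groups (X: scores, shape (n,)
    or (n, 1)); ``transform(X)`` maps scores to 0-based group indices.

    Attributes
    ----------
    stratification_ : fitted Stratification.
    groups_ : list of RiskGroup.
    adjusted_p_ : Bonferroni-adjusted significance of the partition.
    boundaries_ : upper score bound of each group but the last.
    """

    def __init__(self, merge_alpha: float = 0.05, min_group: int = 10):
        self.merge_alpha = merge_alpha
        self.min_group = min_group

    def fit(self, X, y):
        scores = np.asarray(X, dtype=float).ravel()
        self.stratification_ = chaid_bin(
            scores, y, merge_alpha=self.merge_alpha, min_group=self.min_group
        )
        self.groups_ = self.stratification_.groups
        self.adjusted_p_ = self.stratification_.adjusted_p
        self.boundaries_ = np.array([g.upper for g in self.groups_[:-1]])
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "stratification_")
        scores = np.asarray(X, dtype=float).ravel()
        # side="left": a score equal to a group's upper bound stays in
        # that (closed) group
        idx = np.searchsorted(self.boundaries_, scores, side="left")
        return idx[:, None]
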
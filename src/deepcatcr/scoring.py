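"""Repertoire-level cancer predictors.

A donor's repertoire is reduced to a single composite score over the
per-sequence cancer probabilities f(TCR_i) of its retained clonotypes:

* mean scorer:      S_R = (1/N) sum_i f(TCR_i)
* variance scorer:  V_R = (1/N) sum_i (f(TCR_i) - mu_R)^2

The variance scorer quantifies the dispersion of per-sequence scores — the
signature of heterogeneous clonal expansion early in tumorigenesis — and can
separate cohorts whose mean scores coincide.  The population (1/N)
normalisation is used by default; the unbiased 1/(N-1) form is available via
``ddof=1``.

Before scoring, each repertoire passes through the screening preprocessing
chain: CDR3 quality filters, selection of the most abundant clones, and an
optional similarity clustering that keeps the putatively antigen-specific
subset.  Each unique retained sequence contributes once, regardless of clone
count (abundance weighting is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import roc_auc, sensitivity_at_specificity
from .repertoire import (Repertoire, clustered_subset, filter_repertoire,
                         select_top_clones)

__all__ = ["PreprocessingConfig", "RepertoireScore", "CohortResult",
           "RepertoireScorer", "score_repertoire", "score_cohort"]

SPECIFICITY_FLOORS = (0.98, 0.95, 0.90)


class UnscorableSampleError(ValueError):
    """No sequences survive preprocessing for this repertoire."""


@dataclass
class PreprocessingConfig:
    """The repertoire preprocessing chain applied before scoring."""

    min_len: int = 11
    max_len: int = 20
    top_n: int = 10_000
    cluster: bool = True
    max_mismatch: int = 1
    public_set: set | None = None


@dataclass
class RepertoireScore:
    sample_id: str
    scorer: str  # "mean" | "variance"
    value: float
    n_scored: int
    mean_component: float  # mu_R, always recorded


@dataclass
class CohortResult:
    scores: list[RepertoireScore]
    labels: list[int]
    auc: float
    roc_points: np.ndarray
    sensitivity_at: dict[float, float]
    unscorable: list[str] = field(default_factory=list)


def _retained_sequences(repertoire: Repertoire,
                        config: PreprocessingConfig) -> list[str]:
    filtered, _ = filter_repertoire(repertoire, config.min_len, config.max_len,
                                    config.public_set)
    top = select_top_clones(filtered, config.top_n)
    seqs = list(dict.fromkeys(top.sequences))  # unique, order preserved
    if config.cluster:
        seqs = clustered_subset(seqs, max_mismatch=config.max_mismatch)
    return seqs


def composite_score(per_sequence_scores: np.ndarray, scorer: str,
                    ddof: int = 0) -> tuple[float, float]:
    """(value, mu_R) for a vector of per-sequence scores."""
    s = np.asarray(per_sequence_scores, dtype=float)
    mu = float(s.mean())
    if scorer == "mean":
        return mu, mu
    if scorer == "variance":
        if s.size <= ddof:
            return 0.0, mu
        return float(np.sum((s - mu) ** 2) / (s.size - ddof)), mu
    raise ValueError(f"unknown scorer {scorer!r}")


def score_repertoire(
    repertoire: Repertoire,
    model,
    scorer: str = "mean",
    preprocessing: PreprocessingConfig | None = None,
    ddof: int = 0,
    weighted: bool = False,
) -> RepertoireScore:
    """Composite cancer score of one repertoire.

    ``model`` is any object with a ``decision_function(sequences) -> scores``
    method (normally a fitted :class:`DeepCaTCRClassifier` carrying a
    projection).  ``weighted=True`` weights each unique sequence by its total
    clone count instead of counting it once.
    """
    preprocessing = preprocessing or PreprocessingConfig()
    seqs = _retained_sequences(repertoire, preprocessing)
    if not seqs:
        raise UnscorableSampleError(
            f"sample {repertoire.sample_id!r}: no sequences survive preprocessing")
    per_seq = np.asarray(model.decision_function(seqs), dtype=float)
    if weighted:
        totals = {}
        for c in repertoire.clones:
            totals[c.cdr3_aa] = totals.get(c.cdr3_aa, 0.0) + c.count
        w = np.array([totals.get(s, 1.0) for s in seqs], dtype=float)
        mu = float(np.average(per_seq, weights=w))
        if scorer == "mean":
            value = mu
        else:
            value = float(np.average((per_seq - mu) ** 2, weights=w))
    else:
        value, mu = composite_score(per_seq, scorer, ddof=ddof)
    return RepertoireScore(
        sample_id=repertoire.sample_id,
        scorer=scorer,
        value=value,
        n_scored=len(seqs),
        mean_component=mu,
    )


def score_cohort(
    repertoires: list[Repertoire],
    model,
    scorer: str = "mean",
    preprocessing: PreprocessingConfig | None = None,
    spec_floors: tuple[float, ...] = SPECIFICITY_FLOORS,
    **kw,
) -> CohortResult:
    """Score every donor and evaluate cohort-level discrimination.

    Labels come from ``Repertoire.label`` ("cancer" -> 1, "healthy" -> 0).
    Unscorable samples are reported and excluded from the ROC analysis.
    """
    if len(repertoires) < 2:
        raise ValueError("cohort evaluation needs at least two samples")
    scores: list[RepertoireScore] = []
    labels: list[int] = []
    unscorable: list[str] = []
    for rep in repertoires:
        try:
            rs = score_repertoire(rep, model, scorer, preprocessing, **kw)
        except UnscorableSampleError:
            unscorable.append(rep.sample_id)
            continue
        scores.append(rs)
        labels.append(1 if rep.label == "cancer" else 0)
    values = np.array([s.value for s in scores])
    y = np.array(labels)
    if np.unique(y).size == 2:
        auc, points = roc_auc(y, values)
        sens = {f: sensitivity_at_specificity(y, values, f) for f in spec_floors}
    else:
        auc, points, sens = float("nan"), np.empty((0, 3)), {}
    return CohortResult(scores=scores, labels=labels, auc=auc,
                        roc_points=points, sensitivity_at=sens,
                        unscorable=unscorable)


class RepertoireScorer:
    """Convenience wrapper binding a model and preprocessing configuration.

    >>> scorer = RepertoireScorer(model, statistic="variance")
    >>> result = scorer.score_cohort(repertoires)
    """

    def __init__(self, model, statistic: str = "mean",
                 preprocessing: PreprocessingConfig | None = None,
                 ddof: int = 0, weighted: bool = False):
        if statistic not in ("mean", "variance"):
            raise ValueError("statistic must be 'mean' or 'variance'")
        self.model = model
        self.statistic = statistic
        self.preprocessing = preprocessing or PreprocessingConfig()
        self.ddof = ddof
        self.weighted = weighted

    def score_repertoire(self, repertoire: Repertoire) -> RepertoireScore:
        return score_repertoire(repertoire, self.model, self.statistic,
                                self.preprocessing, ddof=self.ddof,
                                weighted=self.weighted)

    def score_cohort(self, repertoires: list[Repertoire],
                     spec_floors: tuple[float, ...] = SPECIFICITY_FLOORS
                     ) -> CohortResult:
        return score_cohort(repertoires, self.model, self.statistic,
                            self.preprocessing, spec_floors,
                            ddof=self.ddof, weighted=self.weighted)
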
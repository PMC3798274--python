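"""Scoring reconstructions against ground truth or reference genomes.

Includes pooled accuracy/recall, threshold-sweep ROC/AUC, the
error-versus-variation diagnostic, genus-level Jaccard similarity,
genus-specific element detection, and the naive per-taxon correlation
baseline that the linear deconvolution is meant to improve upon.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .calling import PresenceCalls
from .deconvolve import GenomicContent
from .errors import (
    AlignmentError,
    ParameterError,
    UndefinedStatisticError,
)
from .io_tables import ElementCounts, ReferenceLengths, ReferencePresence, TaxonProfile

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport",
    "GenusSimilarity",
    "accuracy_recall",
    "roc_auc",
    "error_variation_correlation",
    "jaccard_genus_similarity",
    "genus_specific_elements",
    "correlation_baseline",
]


@dataclass(eq=False)
class EvalReport:
    """Pooled confusion-matrix summary of presence/absence predictions."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None = None
    per_element_error: pd.Series | None = None

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            warnings.warn("recall undefined: no present elements in truth")
            return float("nan")
        return self.tp / (self.tp + self.fn)

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "confusion": {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn},
        }
        if self.auc is not None:
            out["auc"] = self.auc
        return out


@dataclass(eq=False)
class GenusSimilarity:
    """Reconstructed-taxon x reference-genus Jaccard similarities."""

    similarity: pd.DataFrame      # taxa x genera, values in [0, 1] or NaN
    best_match: pd.Series         # taxon -> argmax genus
    elements_used: list[str] = field(default_factory=list)


def _truth_presence(truth, presence_cutoff: float) -> pd.DataFrame:
    """Accept a ReferencePresence or a copies/prevalence DataFrame."""
    if isinstance(truth, ReferencePresence):
        return truth.presence()
    df = pd.DataFrame(truth)
    return df >= presence_cutoff


def _align_pair(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = a.index.intersection(b.index)
    cols = a.columns.intersection(b.columns)
    if rows.empty or cols.empty:
        raise AlignmentError("calls and truth share no (taxon, element) scope")
    return a.loc[rows, cols], b.loc[rows, cols]


def accuracy_recall(calls: PresenceCalls, truth, presence_cutoff: float = 1.0) -> EvalReport:
    """Pooled accuracy and recall over all aligned (taxon, element) pairs.

    ``truth`` is either a :class:`ReferencePresence` (its own 0.1 copy
    cutoff applies) or a copies/prevalence matrix thresholded at
    ``presence_cutoff``.
    """
    truth_p = _truth_presence(truth, presence_cutoff)
    pred, actual = _align_pair(calls.calls, truth_p)
    p = pred.to_numpy(bool)
    t = actual.to_numpy(bool)
    return EvalReport(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def roc_auc(
    content: GenomicContent,
    reference: ReferenceLengths,
    truth,
    presence_cutoff: float = 1.0,
) -> tuple[float, pd.DataFrame]:
    """Threshold-sweep ROC for presence prediction, pooled over all pairs.

    The score of a (taxon, element) pair is the predicted/reference length
    ratio; sweeping the presence threshold over every distinct score traces
    the ROC curve.  AUC by the trapezoidal rule equals the pairwise
    probability P(score_present > score_absent) + ½·P(tie).
    """
    truth_p = _truth_presence(truth, presence_cutoff)
    lengths = reference.for_elements(content.element_ids)
    ratio = content.data.div(lengths, axis=1)
    scores_df, actual = _align_pair(ratio, truth_p)
    y = actual.to_numpy(bool).ravel()
    s = scores_df.to_numpy(float).ravel()
    if y.all() or not y.any():
        raise UndefinedStatisticError("AUC undefined: truth has a single class")
    fpr, tpr, thresholds = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return auc, curve


def per_element_relative_error(
    content: GenomicContent, truth_lengths: pd.DataFrame
) -> pd.Series:
    """Mean relative length error per element, over carrying taxa only.

    error_j = mean_{k: true l_jk > 0} |predicted_jk − true_jk| / true_jk.
    Elements with no carrying taxon in scope are NaN.
    """
    pred, true = _align_pair(content.data, pd.DataFrame(truth_lengths))
    carrying = true > 0
    rel = (pred - true).abs() / true.where(carrying)
    return rel.mean(axis=0)


def error_variation_correlation(
    content: GenomicContent,
    truth_lengths: pd.DataFrame,
    counts: ElementCounts,
    axis: str = "samples",
) -> tuple[float, float]:
    """Pearson correlation of per-element prediction error with variation.

    Variation is the coefficient of variation (sd/mean, ddof=1) of the
    element's read counts across samples (``axis="samples"``) or of its
    true prevalence across taxa (``axis="taxa"``).  Deconvolution leans on
    covariation, so more variable elements should be predicted better —
    a negative correlation.
    """
    if axis not in ("samples", "taxa"):
        raise ParameterError("axis must be 'samples' or 'taxa'")
    err = per_element_relative_error(content, truth_lengths)
    if axis == "samples":
        col = counts.data
        cv = col.std(axis=0, ddof=1) / col.mean(axis=0)
    else:
        true = pd.DataFrame(truth_lengths)
        cv = true.std(axis=0, ddof=1) / true.mean(axis=0)
    joined = pd.concat({"err": err, "cv": cv}, axis=1, join="inner").replace(
        [np.inf, -np.inf], np.nan
    ).dropna()
    if len(joined) < 3:
        raise UndefinedStatisticError("need >= 3 elements with defined error and CV")
    if joined["err"].std() == 0 or joined["cv"].std() == 0:
        raise UndefinedStatisticError("zero variance on one axis; correlation undefined")
    r, p = stats.pearsonr(joined["err"], joined["cv"])
    return float(r), float(p)


def _jaccard(a: set, b: set) -> float:
    union = a | b
    if not union:
        return float("nan")  # empty vs empty: excluded from means
    return len(a & b) / len(union)


def jaccard_genus_similarity(
    calls: PresenceCalls,
    references: ReferencePresence,
    counts: ElementCounts,
    top_k: int = 500,
) -> GenusSimilarity:
    """Jaccard similarity between reconstructed taxa and reference genera.

    Restricted to the ``top_k`` elements with the highest count CV across
    samples (the informative, variable part of the catalog).  The
    genus-level value is the mean over that genus's genomes; empty-vs-empty
    comparisons are undefined and excluded from the mean.
    """
    shared = [e for e in calls.element_ids if e in set(counts.element_ids)]
    shared = [e for e in shared if e in set(references.element_ids)]
    if not shared:
        raise AlignmentError("no shared elements between calls, counts and references")
    if top_k > len(shared):
        top_k = len(shared)
    col = counts.data[shared]
    cv = (col.std(axis=0, ddof=1) / col.mean(axis=0)).replace([np.inf, -np.inf], np.nan)
    top = list(cv.sort_values(ascending=False).index[:top_k])
    top_set = set(top)

    ref_presence = references.presence()[top]
    genome_sets = {g: set(ref_presence.columns[ref_presence.loc[g]]) for g in ref_presence.index}
    call_sets = {
        t: set(e for e in calls.calls.columns[calls.calls.loc[t]] if e in top_set)
        for t in calls.taxon_ids
    }

    genera = sorted(references.genus.unique())
    sim = pd.DataFrame(index=calls.taxon_ids, columns=genera, dtype=float)
    for t, tset in call_sets.items():
        for genus in genera:
            genomes = references.genus.index[references.genus == genus]
            vals = [_jaccard(tset, genome_sets[g]) for g in genomes]
            vals = [v for v in vals if not np.isnan(v)]
            sim.loc[t, genus] = float(np.mean(vals)) if vals else float("nan")
    best = sim.astype(float).idxmax(axis=1)
    return GenusSimilarity(similarity=sim, best_match=best, elements_used=top)


def genus_specific_elements(
    references: ReferencePresence, in_frac: float = 0.8, out_frac: float = 0.2
) -> dict[str, set[str]]:
    """Elements typifying each genus: common inside it, rare elsewhere.

    An element is specific to genus g when present in >= ``in_frac`` of
    g's genomes and in < ``out_frac`` of all other genomes.  Strain
    averaging is assumed to have happened upstream (copy numbers may be
    fractional).
    """
    genera = sorted(references.genus.unique())
    if len(genera) < 2:
        raise ParameterError("genus-specific elements need at least two genera")
    presence = references.presence()
    out: dict[str, set[str]] = {}
    for genus in genera:
        inside = presence.loc[references.genus == genus]
        outside = presence.loc[references.genus != genus]
        in_ok = inside.mean(axis=0) >= in_frac
        out_ok = outside.mean(axis=0) < out_frac
        out[genus] = set(presence.columns[in_ok & out_ok])
    return out


def correlation_baseline(
    counts: ElementCounts,
    profile: TaxonProfile,
    r_threshold: float,
    method: str = "pearson",
) -> PresenceCalls:
    """Naive baseline: element j present in taxon k when corr(D_·j, g_·k)
    reaches ``r_threshold`` across samples.

    Correlations undefined because of a constant vector are treated as
    absent (with a warning).  ``method`` is ``"pearson"`` or ``"spearman"``.
    """
    if method not in ("pearson", "spearman"):
        raise ParameterError("method must be 'pearson' or 'spearman'")
    if counts.n_samples < 3:
        raise ParameterError("correlation baseline needs >= 3 samples")
    d = counts.data.loc[profile.data.index]
    if method == "spearman":
        dmat = d.rank(axis=0).to_numpy()
        gmat = profile.data.rank(axis=0).to_numpy()
    else:
        dmat = d.to_numpy()
        gmat = profile.data.to_numpy()
    dc = dmat - dmat.mean(axis=0)
    gc = gmat - gmat.mean(axis=0)
    dn = np.linalg.norm(dc, axis=0)
    gn = np.linalg.norm(gc, axis=0)
    undef_d = dn == 0
    undef_g = gn == 0
    if undef_d.any() or undef_g.any():
        warnings.warn(
            "constant vectors give undefined correlations; calling those absent"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (gc.T @ dc) / np.outer(np.where(gn == 0, np.nan, gn),
                                      np.where(dn == 0, np.nan, dn))
    calls = pd.DataFrame(
        np.nan_to_num(corr, nan=-np.inf) >= r_threshold,
        index=profile.taxon_ids,
        columns=d.columns,
    )
    return PresenceCalls(calls=calls, threshold=r_threshold,
                         reference=f"{method}_correlation")
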
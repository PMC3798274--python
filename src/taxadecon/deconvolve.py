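"""Linear deconvolution of mixed-community element counts.

The model: the read count D_ij of genomic element j in sample i is
proportional to Σ_k g_ik · l_jk, where g_ik is the relative abundance of
taxon k in sample i and l_jk the prevalence of the element in that taxon's
genome (nucleotides; copy number × per-copy length).  The unknown
per-sample proportionality constant N_i (reads per nucleotide of community
genomic material) is eliminated with a *constant genomic element* C —
an element of known, near-identical prevalence l_C in every taxon, such as
16S rRNA or a summed set of universal single-copy ribosomal genes:

    y_ij = D_ij · l_C / D_iC  ≈  Σ_k g_ik · l_jk        (rows g sum to 1)

For each element j this is an ordinary linear system over samples; solving
it by (non-negative / lasso) least squares yields one prevalence per taxon.
Elements are solved independently, so results do not depend on execution
order and per-element method choices are possible.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

from .errors import (
    DegenerateSampleError,
    DimensionError,
    FilterError,
    MappingError,
    NormalizationError,
    ParameterError,
    SolverError,
)
from .io_tables import ElementCounts, TaxonProfile, align_samples

logger = logging.getLogger(__name__)

__all__ = [
    "ConstantElement",
    "GenomicContent",
    "normalize_taxon_profile",
    "build_response",
    "filter_taxa",
    "filter_elements",
    "solve_element",
    "deconvolve",
]

#: condition number above which the design is reported as ill-conditioned
COND_WARN = 1e8

METHODS = ("ls", "nnls", "lasso")


@dataclass(frozen=True)
class ConstantElement:
    """The normalization element set: ids plus its combined known length.

    Several elements can be pooled (their counts summed, their lengths
    summed) to damp annotation noise in any single one.
    """

    element_ids: tuple[str, ...]
    combined_length: float

    def __post_init__(self) -> None:
        if not self.element_ids:
            raise ParameterError("ConstantElement needs at least one element id")
        if self.combined_length <= 0:
            raise ParameterError("ConstantElement combined_length must be > 0")

    def per_sample_counts(self, counts: ElementCounts) -> pd.Series:
        """Summed constant-element count D_iC per sample."""
        missing = [e for e in self.element_ids if e not in counts.data.columns]
        if missing:
            raise MappingError(f"constant element ids absent from counts: {missing}")
        return counts.data[list(self.element_ids)].sum(axis=1)


@dataclass(eq=False)
class GenomicContent:
    """Taxa x elements predicted prevalences (nt).

    Plain least squares can yield negative prevalences; they are kept as-is
    (presence calling downstream treats them as absent).  ``nnls`` and
    positive-lasso results are non-negative.
    """

    data: pd.DataFrame
    method: str = "ls"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ParameterError(f"method must be one of {METHODS}")
        self.data = self.data.astype(float)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def element_ids(self) -> list[str]:
        return list(self.data.columns)


def normalize_taxon_profile(profile: TaxonProfile) -> TaxonProfile:
    """Scale every sample's taxon abundances to sum to one."""
    sums = profile.data.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        raise DegenerateSampleError(
            f"all-zero abundance rows for samples {list(profile.data.index[zero])}"
        )
    return TaxonProfile(profile.data.div(sums, axis=0))


def build_response(counts: ElementCounts, constant: ConstantElement) -> pd.DataFrame:
    """Normalized responses y_ij = D_ij · l_C / D_iC (nt units).

    Samples whose constant-element count is zero cannot be normalized and
    are dropped with a warning.
    """
    d_c = constant.per_sample_counts(counts)
    usable = d_c > 0
    if not usable.any():
        raise NormalizationError("constant-element count is zero in every sample")
    if (~usable).any():
        dropped = list(d_c.index[~usable])
        logger.warning(
            "build_response: dropping %d samples with zero constant-element count: %s",
            len(dropped), dropped,
        )
    body = counts.data.loc[usable]
    return body.mul(constant.combined_length / d_c[usable], axis=0)


def filter_taxa(
    profile: TaxonProfile,
    min_sample_fraction: float = 0.5,
    min_peak_abundance: float = 0.0,
    *,
    renormalize: bool = True,
) -> TaxonProfile:
    """Keep taxa seen in enough samples and, optionally, peaking high enough.

    A taxon is retained when it has nonzero abundance in at least
    ``min_sample_fraction`` of samples *and* its maximum abundance exceeds
    ``min_peak_abundance`` (strict, matching the ">5% in at least one
    sample" convention for genus-level work).  Retained rows are
    renormalized to sum to one by default; samples left with no retained
    taxon are dropped with a warning.
    """
    present = profile.data > 0
    frac = present.mean(axis=0)
    peak = profile.data.max(axis=0)
    keep = (frac >= min_sample_fraction) & (peak > min_peak_abundance)
    if not keep.any():
        raise FilterError("filter_taxa removed every taxon")
    out = profile.data.loc[:, keep]
    if renormalize:
        sums = out.sum(axis=1)
        dead = sums <= 0
        if dead.any():
            logger.warning(
                "filter_taxa: dropping %d samples with no retained taxa: %s",
                int(dead.sum()), list(out.index[dead]),
            )
            out = out.loc[~dead]
            sums = sums[~dead]
        out = out.div(sums, axis=0)
    return TaxonProfile(out)


def filter_elements(
    counts: ElementCounts,
    min_mean_fraction_of_top: float = 0.001,
    min_sample_fraction: float = 0.0,
    core_ref=None,
    core_max: float = 0.75,
    spurious_min: float = 0.01,
) -> ElementCounts:
    """Drop low-signal, near-universal ("core") and spurious elements.

    Retains elements whose mean count exceeds ``min_mean_fraction_of_top``
    of the largest element mean (the 0.1%-of-top rule) and that are
    observed in at least ``min_sample_fraction`` of samples.  With a
    reference-presence catalog, elements present in >= ``core_max`` of
    reference genomes (uninformative core genes) or in < ``spurious_min``
    (likely spurious annotations) are removed as well.
    """
    means = counts.data.mean(axis=0)
    keep = means > min_mean_fraction_of_top * means.max()
    keep &= (counts.data > 0).mean(axis=0) >= min_sample_fraction
    if core_ref is not None:
        ref_pres = core_ref.presence().mean(axis=0)
        ref_frac = pd.Series(0.0, index=counts.data.columns)
        shared = ref_pres.index.intersection(ref_frac.index)
        ref_frac[shared] = ref_pres[shared]
        keep &= (ref_frac < core_max) & (ref_frac >= spurious_min)
    if not keep.any():
        raise FilterError("filter_elements removed every element")
    return ElementCounts(counts.data.loc[:, keep])


def solve_element(
    y_j: np.ndarray,
    G: np.ndarray,
    method: str = "ls",
    *,
    positive: bool = False,
    cv_folds: int = 5,
    _checked: bool = False,
) -> np.ndarray:
    """Solve one element's per-sample system G·l = y for the taxon prevalences.

    ``ls`` minimizes ||G·l − y||² via SVD-based least squares; ``nnls`` adds
    l >= 0; ``lasso`` adds an L1 penalty with the strength chosen by
    cross-validated MSE along the exact LARS path (folds seeded
    deterministically), permitting fewer samples than taxa.  ``positive``
    constrains lasso coefficients to be non-negative.
    """
    if method not in METHODS:
        raise ParameterError(f"method must be one of {METHODS}")
    G = np.asarray(G, dtype=float)
    y = np.asarray(y_j, dtype=float).ravel()
    n, p = G.shape
    if y.shape[0] != n:
        raise DimensionError(f"response has {y.shape[0]} samples, design has {n}")
    if method in ("ls", "nnls"):
        if n < p:
            raise DimensionError(
                f"{method} needs at least as many samples ({n}) as taxa ({p}); "
                "use method='lasso' for underdetermined systems"
            )
        if not _checked:
            _check_design(G)
        if method == "ls":
            sol, *_ = np.linalg.lstsq(G, y, rcond=None)
            return sol
        sol, _ = _scipy_nnls(G, y)
        return sol
    # lasso via the LARS path: the whole piecewise-linear coefficient path
    # is computed exactly (no iterative tolerance), and the penalty strength
    # is picked by cross-validated MSE over the path knots.  As the penalty
    # goes to zero the path ends at the least-squares solution, so on
    # noise-free consistent systems lasso recovers the truth too.
    if not np.any(y):  # zero response -> zero solution
        return np.zeros(p)
    from sklearn.linear_model import LassoLarsCV
    from sklearn.model_selection import KFold

    folds = min(cv_folds, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate-fold chatter
        model = LassoLarsCV(
            fit_intercept=False,
            positive=positive,
            cv=KFold(n_splits=folds, shuffle=True, random_state=0),
            max_n_alphas=2000,
        ).fit(G, y)
    return model.coef_


def _check_design(G: np.ndarray) -> float:
    """Rank/conditioning guard for the exact (non-regularized) solvers."""
    n, p = G.shape
    s = np.linalg.svd(G, compute_uv=False)
    rank = int((s > s.max() * max(n, p) * np.finfo(float).eps).sum()) if s.size else 0
    if rank < p:
        raise SolverError(
            f"design is rank-deficient: rank {rank} < {p} taxa "
            f"(condition number {np.inf if s.min() == 0 else s.max() / s.min():.3g})"
        )
    cond = s.max() / s.min()
    if cond > COND_WARN:
        logger.warning("design condition number %.3g exceeds %.1g", cond, COND_WARN)
    return cond


def deconvolve(
    counts: ElementCounts,
    profile: TaxonProfile,
    constant: ConstantElement,
    method: str = "ls",
    *,
    positive: bool = False,
    taxon_min_sample_fraction: float | None = None,
    taxon_min_peak_abundance: float = 0.0,
    element_min_mean_fraction: float | None = None,
    cv_folds: int = 5,
) -> GenomicContent:
    """Reconstruct the taxa x elements prevalence matrix.

    Orchestrates: optional taxon/element filters → sample alignment →
    profile normalization → constant-element response normalization →
    one independent regression per element.  The per-sample sequencing
    scale cancels, so multiplying any sample's counts (constant element
    included) by a positive factor leaves the result unchanged.
    """
    if taxon_min_sample_fraction is not None:
        profile = filter_taxa(
            profile, taxon_min_sample_fraction, taxon_min_peak_abundance
        )
    if element_min_mean_fraction is not None:
        counts = filter_elements(counts, element_min_mean_fraction)
    profile, counts = align_samples(profile, counts)
    profile = normalize_taxon_profile(profile)
    response = build_response(counts, constant)
    # build_response may drop unnormalizable samples
    profile_data = profile.data.loc[response.index]
    G = profile_data.to_numpy()
    n, p = G.shape
    if method in ("ls", "nnls"):
        if n < p:
            raise DimensionError(
                f"{method} needs at least as many samples ({n}) as taxa ({p})"
            )
        _check_design(G)
    Y = response.to_numpy()
    sols = np.empty((p, Y.shape[1]))
    for j in range(Y.shape[1]):
        sols[:, j] = solve_element(
            Y[:, j], G, method, positive=positive, cv_folds=cv_folds, _checked=True
        )
    content = pd.DataFrame(sols, index=profile_data.columns, columns=response.columns)
    return GenomicContent(
        data=content,
        method=method,
        provenance={
            "n_samples": n,
            "n_taxa": p,
            "n_elements": int(Y.shape[1]),
            "constant_element_ids": list(constant.element_ids),
            "constant_length": constant.combined_length,
            "taxon_min_sample_fraction": taxon_min_sample_fraction,
            "element_min_mean_fraction": element_min_mean_fraction,
            "positive": positive,
        },
    )
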
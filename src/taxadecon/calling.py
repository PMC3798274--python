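"""Presence/absence calling, the convoluted null model, and constant-element
selection.

A predicted prevalence becomes a presence call by comparison with the
average length of the ortholog across sequenced genomes: the ratio
predicted/reference is an implied copy-number estimate, and an element is
called present when it reaches the threshold (a threshold of 0.25 reads as
"at least a quarter copy").
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deconvolve import ConstantElement, GenomicContent
from .errors import (
    NormalizationError,
    ParameterError,
    SelectionError,
)
from .io_tables import ElementCounts, ReferenceLengths

logger = logging.getLogger(__name__)

__all__ = [
    "PresenceCalls",
    "CandidateCatalog",
    "call_presence",
    "convoluted_null",
    "select_constant_elements",
]


@dataclass(eq=False)
class PresenceCalls:
    """Binary taxa x elements presence matrix with its calling threshold."""

    calls: pd.DataFrame  # boolean
    threshold: float     # length-ratio threshold (>0), or a correlation cutoff
    reference: str = ""

    def __post_init__(self) -> None:
        self.calls = self.calls.astype(bool)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def element_ids(self) -> list[str]:
        return list(self.calls.columns)

    # write_matrix duck-typing
    @property
    def data(self) -> pd.DataFrame:
        return self.calls


@dataclass(eq=False)
class CandidateCatalog:
    """Constant-element candidates: presence fraction and length statistics.

    One row per candidate element, columns ``presence`` (fraction of catalog
    genomes carrying it), ``length_mean`` (nt) and ``length_cv``
    (sd/mean of the length across genomes).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"presence", "length_mean", "length_cv"}
        missing = required - set(self.table.columns)
        if missing:
            raise ParameterError(f"candidate catalog lacks columns {sorted(missing)}")
        t = self.table
        if ((t["presence"] < 0) | (t["presence"] > 1)).any():
            raise ParameterError("candidate presence fractions must be in [0, 1]")
        if (t["length_cv"] < 0).any():
            raise ParameterError("candidate length CVs must be >= 0")


def call_presence(
    content: GenomicContent, reference: ReferenceLengths, threshold: float
) -> PresenceCalls:
    """Call an element present where predicted/reference length >= threshold.

    The comparison is inclusive, so a threshold of 1.0 calls exact-length
    predictions present.  Negative predicted lengths (possible under plain
    least squares) give negative ratios and are therefore always absent.
    """
    if threshold <= 0:
        raise ParameterError("presence threshold must be > 0")
    lengths = reference.for_elements(content.element_ids)
    ratio = content.data.div(lengths, axis=1)
    return PresenceCalls(
        calls=ratio >= threshold, threshold=threshold, reference="reference_lengths"
    )


def convoluted_null(
    counts: ElementCounts, constant: ConstantElement, taxon_ids
) -> GenomicContent:
    """Null model: every taxon gets the identical community-average genome.

    The shared length of element j is its average per-sample relative
    abundance, normalized by the constant element's average relative
    abundance and known length:

        l_j = mean_i(D_ij / Σ_j' D_ij') · l_C / mean_i(D_iC / Σ_j' D_ij')

    Deconvolution must beat this "convoluted" baseline to demonstrate that
    it resolves taxon-specific content rather than community averages.
    """
    taxon_ids = list(taxon_ids)
    if not taxon_ids:
        raise ParameterError("convoluted_null needs at least one taxon id")
    totals = counts.data.sum(axis=1)
    usable = totals > 0
    if not usable.any():
        raise NormalizationError("all samples have zero total counts")
    rel = counts.data.loc[usable].div(totals[usable], axis=0)
    mean_rel = rel.mean(axis=0)
    mean_rel_c = float(mean_rel[list(constant.element_ids)].sum())
    if mean_rel_c <= 0:
        raise NormalizationError("constant element has zero mean relative abundance")
    shared = mean_rel * (constant.combined_length / mean_rel_c)
    data = pd.DataFrame(
        np.tile(shared.to_numpy(), (len(taxon_ids), 1)),
        index=taxon_ids,
        columns=counts.data.columns,
    )
    return GenomicContent(data=data, method="ls", provenance={"model": "convoluted_null"})


def select_constant_elements(
    catalog: CandidateCatalog, anchor_cv: float, min_presence: float = 0.98
) -> ConstantElement:
    """Pick constant elements: near-universal and more length-stable than
    the anchor gene (typically 16S rRNA).

    Candidates with presence >= ``min_presence`` and length CV strictly
    below ``anchor_cv`` are pooled; the combined length is the sum of their
    mean lengths (and downstream their counts are summed likewise).
    """
    if anchor_cv < 0:
        raise ParameterError("anchor_cv must be >= 0")
    t = catalog.table
    chosen = t[(t["presence"] >= min_presence) & (t["length_cv"] < anchor_cv)]
    if chosen.empty:
        raise SelectionError(
            "no candidate passed selection; relax min_presence or anchor_cv"
        )
    logger.info(
        "select_constant_elements: %d of %d candidates selected", len(chosen), len(t)
    )
    return ConstantElement(
        element_ids=tuple(chosen.index.astype(str)),
        combined_length=float(chosen["length_mean"].sum()),
    )
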
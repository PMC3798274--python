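"""Synthetic community and metagenome generator.

The generator produces abstract model genomes and shotgun count tables with
a controlled statistical structure, so the whole deconvolution pipeline can
be exercised end to end without any external data.  Genes have no sequence;
their only property is a length in nucleotides.  The generative model:

* A global catalog of N gene orthology groups.  Each variable gene has a
  length drawn uniformly from 400–500 nt, shared across every species that
  carries it, and is assigned to a random 20–80% subset of species; every
  species carries at least 10 variable genes.  Within a carrier, a gene has
  a 5% chance of duplication, with higher copy numbers decreasing
  geometrically: P(copies = c) ∝ 0.05^(c−1).
* One 1500-nt single-copy "constant gene" present in every species — the
  abstract analog of a universal single-copy marker such as 16S rRNA —
  used downstream to normalize away the per-sample sequencing scale.
* Typical species abundances c_k drawn i.i.d. Exponential(mean 1).  Sample
  profiles are a_ik = c_k · exp(ν·r_ik) with r_ik ~ N(0,1): ν = 0 gives
  identical (perfectly correlated) profiles, and the per-species
  coefficient of variation across samples is sqrt(exp(ν²) − 1).
* Shotgun sequencing as multinomial read sampling at fixed depth, with
  per-element weights proportional to Σ_k a_ik · copies_kj · length_j.
  Species below ``detection_cutoff`` (default 0.5%) of the most abundant
  species in a sample are treated as absent: removed from read generation
  and zeroed in the observed profile, which is then renormalized.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deconvolve import ConstantElement
from .errors import DegenerateSampleError, ParameterError
from .io_tables import ElementCounts, ReferenceLengths, TaxonProfile

__all__ = [
    "SyntheticCommunity",
    "SimulatedSampleSet",
    "simulate_genomes",
    "simulate_abundance_profiles",
    "simulate_metagenomes",
    "expected_counts",
]

CONSTANT_GENE_ID = "const"


@dataclass(eq=False)
class SyntheticCommunity:
    """Ground-truth model genomes plus typical abundances."""

    gene_lengths: pd.Series        # element id -> length (nt)
    genomes: pd.DataFrame          # species x elements, integer copy numbers
    constant_gene: str             # id of the single-copy normalization gene
    typical_abundances: pd.Series  # species id -> c_k > 0
    seed: int | None = None

    @property
    def species_ids(self) -> list[str]:
        return list(self.genomes.index)

    @property
    def element_ids(self) -> list[str]:
        return list(self.genomes.columns)

    @property
    def n_species(self) -> int:
        return self.genomes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.genomes.shape[1]

    def true_content(self) -> pd.DataFrame:
        """Species x elements prevalence matrix in nt (copies x length)."""
        return self.genomes * self.gene_lengths

    def reference_lengths(self) -> ReferenceLengths:
        """Per-element average length over carrying species.

        Lengths are shared across homologs here, so this is just the gene
        length itself — exposed in the shape presence calling expects.
        """
        return ReferenceLengths(self.gene_lengths.astype(float))

    def constant_element(self) -> ConstantElement:
        return ConstantElement(
            element_ids=(self.constant_gene,),
            combined_length=float(self.gene_lengths[self.constant_gene]),
        )


@dataclass(eq=False)
class SimulatedSampleSet:
    """Generated samples: truth, post-cutoff observed profile, and counts."""

    true_abundances: pd.DataFrame   # samples x species, pre-cutoff a_ik
    observed_profile: TaxonProfile  # post-cutoff, renormalized
    counts: ElementCounts           # samples x elements read counts
    depth: float
    seed: int | None = None


def _species_ids(n: int) -> list[str]:
    return [f"sp_{k + 1:03d}" for k in range(n)]


def _element_ids(n_variable: int) -> list[str]:
    return [f"gene_{j + 1:03d}" for j in range(n_variable)] + [CONSTANT_GENE_ID]


def simulate_genomes(
    n_species: int,
    n_elements: int,
    seed=None,
    *,
    duplication_rate: float = 0.05,
    min_genes: int = 10,
    carrier_range: tuple[float, float] = (0.2, 0.8),
    length_range: tuple[int, int] = (400, 500),
    constant_length: int = 1500,
) -> SyntheticCommunity:
    """Draw a community of model genomes.

    ``n_elements`` counts the whole catalog including the constant gene, so
    it must be at least ``min_genes + 1``.  Copy numbers for carried genes
    follow P(c) ∝ duplication_rate^(c−1), i.e. a duplication probability of
    5% at the default rate.
    """
    if n_species < 1:
        raise ParameterError("n_species must be >= 1")
    if n_elements < min_genes + 1:
        raise ParameterError(
            f"n_elements must be >= {min_genes + 1} "
            f"({min_genes} variable genes plus the constant gene)"
        )
    if not 0 < duplication_rate < 1:
        raise ParameterError("duplication_rate must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_var = n_elements - 1
    elements = _element_ids(n_var)
    species = _species_ids(n_species)

    lengths = pd.Series(
        np.concatenate([
            rng.integers(length_range[0], length_range[1] + 1, n_var),
            [constant_length],
        ]).astype(float),
        index=elements,
    )

    lo = max(1, math.ceil(carrier_range[0] * n_species))
    hi = max(lo, math.floor(carrier_range[1] * n_species))
    copies = np.zeros((n_species, n_var), dtype=int)
    for j in range(n_var):
        n_carriers = int(rng.integers(lo, hi + 1))
        carriers = rng.choice(n_species, size=n_carriers, replace=False)
        # geometric(p) has support {1, 2, ...}; with p = 1 - rate the chance
        # of >= 2 copies is exactly the duplication rate.
        copies[carriers, j] = rng.geometric(1.0 - duplication_rate, size=n_carriers)

    # top up species below the minimum gene count
    for k in range(n_species):
        have = int((copies[k] > 0).sum())
        if have < min_genes:
            absent = np.flatnonzero(copies[k] == 0)
            extra = rng.choice(absent, size=min_genes - have, replace=False)
            copies[k, extra] = rng.geometric(1.0 - duplication_rate, size=extra.size)

    genomes = pd.DataFrame(copies, index=species, columns=elements[:-1])
    genomes[CONSTANT_GENE_ID] = 1  # single copy everywhere

    c = pd.Series(rng.exponential(1.0, n_species), index=species)
    return SyntheticCommunity(
        gene_lengths=lengths,
        genomes=genomes,
        constant_gene=CONSTANT_GENE_ID,
        typical_abundances=c,
        seed=seed if isinstance(seed, int) else None,
    )


def simulate_abundance_profiles(
    community: SyntheticCommunity, n_samples: int, nu: float, seed=None
) -> pd.DataFrame:
    """Draw correlated per-sample species abundances a_ik = c_k·exp(ν·r_ik)."""
    if nu < 0:
        raise ParameterError("nu must be >= 0")
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    c = community.typical_abundances.to_numpy()
    r = rng.standard_normal((n_samples, community.n_species))
    a = c[None, :] * np.exp(nu * r)
    return pd.DataFrame(
        a,
        index=[f"S{i + 1:03d}" for i in range(n_samples)],
        columns=community.species_ids,
    )


def _cutoff_and_weights(
    community: SyntheticCommunity,
    profiles: pd.DataFrame,
    detection_cutoff: float,
    cutoff_affects_reads: bool,
):
    """Apply the per-sample detection cutoff; return (observed, read weights).

    ``observed`` is the renormalized post-cutoff profile.  ``weights`` are
    the per-sample element sampling probabilities, computed from the
    post-cutoff abundances by default; with ``cutoff_affects_reads=False``
    (a sensitivity-analysis variant) reads are generated from the full
    abundances while only the profile is zeroed.
    """
    a = profiles.to_numpy(dtype=float)
    if (a <= 0).any():
        raise ParameterError("abundance profiles must be strictly positive")
    keep = a >= detection_cutoff * a.max(axis=1, keepdims=True)
    if not keep.any(axis=1).all():
        bad = list(profiles.index[~keep.any(axis=1)])
        raise DegenerateSampleError(f"every species cut in samples {bad}")
    post = np.where(keep, a, 0.0)
    observed = post / post.sum(axis=1, keepdims=True)

    content = community.true_content().to_numpy()  # species x elements, nt
    basis = post if cutoff_affects_reads else a
    w = basis @ content
    totals = w.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        bad = list(profiles.index[(totals == 0).ravel()])
        raise DegenerateSampleError(f"zero total genomic weight in samples {bad}")
    return observed, w / totals


def simulate_metagenomes(
    community: SyntheticCommunity,
    profiles: pd.DataFrame,
    depth: float,
    detection_cutoff: float = 0.005,
    seed=None,
    *,
    cutoff_affects_reads: bool = True,
) -> SimulatedSampleSet:
    """Generate multinomial read counts for each sample at fixed depth."""
    if depth < 0:
        raise ParameterError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    observed, p = _cutoff_and_weights(
        community, profiles, detection_cutoff, cutoff_affects_reads
    )
    depth_i = int(depth)
    counts = np.vstack([rng.multinomial(depth_i, p[i]) for i in range(p.shape[0])])
    return SimulatedSampleSet(
        true_abundances=profiles.copy(),
        observed_profile=TaxonProfile(
            pd.DataFrame(observed, index=profiles.index, columns=community.species_ids)
        ),
        counts=ElementCounts(
            pd.DataFrame(counts.astype(float), index=profiles.index, columns=community.element_ids)
        ),
        depth=depth,
        seed=seed if isinstance(seed, int) else None,
    )


def expected_counts(
    community: SyntheticCommunity,
    profiles: pd.DataFrame,
    depth: float,
    detection_cutoff: float = 0.005,
    *,
    cutoff_affects_reads: bool = True,
) -> ElementCounts:
    """Noise-free limit: the multinomial expectation depth × w_ij.

    Fractional counts are allowed; feeding these to the deconvolution gives
    a consistent linear system and hence exact recovery, which the test
    suite uses as an oracle.
    """
    if depth < 0:
        raise ParameterError("depth must be >= 0")
    _, p = _cutoff_and_weights(community, profiles, detection_cutoff, cutoff_affects_reads)
    return ElementCounts(
        pd.DataFrame(depth * p, index=profiles.index, columns=community.element_ids)
    )
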
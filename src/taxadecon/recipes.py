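"""End-to-end experiment recipes.

These wire the simulator, solver, caller and evaluators into the named
experiments the CLI's ``reproduce`` command runs, and return plain dicts
of the headline numbers plus the intermediate objects for inspection.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import calling, evaluation, simulator
from .deconvolve import (
    ConstantElement,
    GenomicContent,
    deconvolve,
    filter_elements,
    filter_taxa,
)
from .io_tables import ElementCounts

__all__ = ["simple_synthetic_experiment", "strain_benchmark"]

#: presence thresholds scanned when checking robustness of the calls
THRESHOLD_GRID = tuple(round(0.1 * t, 1) for t in range(1, 10))


def _spawn_seeds(seed, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def simple_synthetic_experiment(
    seed: int,
    *,
    n_species: int = 60,
    n_elements: int = 100,
    n_samples: int = 100,
    nu: float = 0.10,
    depth: float = 5_000_000,
    detection_cutoff: float = 0.005,
    method: str = "ls",
    threshold: float = 0.5,
    taxon_min_sample_fraction: float = 0.5,
    noise_free: bool = False,
) -> dict:
    """The headline synthetic study: simulate, deconvolve, call, evaluate.

    Defaults are the main study conditions: 60 species over a catalog of
    100 orthology groups (the 100th being the 1500-nt constant gene),
    100 samples at inter-sample variation ν = 0.10, 5M reads per sample,
    0.5% detection cutoff, species kept when present in at least half the
    samples, least-squares solving and a presence threshold of 0.5 of the
    gene length.  ``noise_free=True`` swaps multinomial counts for their
    expectation (the exact-recovery regime).
    """
    s_genomes, s_profiles, s_reads = _spawn_seeds(seed, 3)
    community = simulator.simulate_genomes(n_species, n_elements, s_genomes)
    profiles = simulator.simulate_abundance_profiles(community, n_samples, nu, s_profiles)
    samples = simulator.simulate_metagenomes(
        community, profiles, depth, detection_cutoff, s_reads
    )
    counts: ElementCounts = samples.counts
    if noise_free:
        counts = simulator.expected_counts(community, profiles, depth, detection_cutoff)

    profile = filter_taxa(samples.observed_profile, taxon_min_sample_fraction)
    constant = community.constant_element()
    content = deconvolve(counts, profile, constant, method)

    reference = community.reference_lengths()
    truth_copies = community.genomes.loc[content.taxon_ids, content.element_ids]
    truth_lengths = community.true_content().loc[content.taxon_ids, content.element_ids]

    calls = calling.call_presence(content, reference, threshold)
    report = evaluation.accuracy_recall(calls, truth_copies, presence_cutoff=1)

    sweep = {}
    for t in THRESHOLD_GRID:
        rep_t = evaluation.accuracy_recall(
            calling.call_presence(content, reference, t), truth_copies, presence_cutoff=1
        )
        sweep[t] = rep_t.accuracy
    perfect = [t for t, acc in sweep.items() if acc == 1.0]
    # contiguous zero-error block around the working threshold
    block = [t for t in perfect]
    lo = hi = None
    if threshold in perfect or any(abs(t - threshold) < 1e-9 for t in perfect):
        grid = list(THRESHOLD_GRID)
        i = min(range(len(grid)), key=lambda k: abs(grid[k] - threshold))
        lo = hi = i
        while lo > 0 and sweep[grid[lo - 1]] == 1.0:
            lo -= 1
        while hi < len(grid) - 1 and sweep[grid[hi + 1]] == 1.0:
            hi += 1
        block = grid[lo:hi + 1]

    # error-vs-variation diagnostic over the variable genes only: the
    # constant gene is the normalization anchor, not a reconstructed gene
    variable = [e for e in content.element_ids if e != community.constant_gene]
    var_content = GenomicContent(content.data[variable], method=content.method)
    var_counts = ElementCounts(counts.data[variable])
    r_samples, p_samples = evaluation.error_variation_correlation(
        var_content, truth_lengths[variable], var_counts, axis="samples"
    )
    r_taxa, p_taxa = evaluation.error_variation_correlation(
        var_content, truth_lengths[variable], var_counts, axis="taxa"
    )

    return {
        "community": community,
        "samples": samples,
        "content": content,
        "calls": calls,
        "truth_copies": truth_copies,
        "truth_lengths": truth_lengths,
        "report": report,
        "accuracy": report.accuracy,
        "recall": report.recall,
        "threshold": threshold,
        "threshold_sweep": sweep,
        "perfect_block": tuple(block),
        "error_cv_correlation_samples": (r_samples, p_samples),
        "error_cv_correlation_taxa": (r_taxa, p_taxa),
        "n_pairs": int(np.prod(calls.calls.shape)),
    }


def strain_benchmark(
    taxa_path,
    elements_path,
    truth_lengths_path,
    reference_lengths_path,
    *,
    constant_ids: tuple[str, ...],
    constant_length: float,
    method: str = "ls",
    threshold: float = 0.1,
    element_min_mean_fraction: float = 0.001,
) -> dict:
    """Deconvolve a small externally supplied strain community and score it.

    Expects TSV tables: per-sample strain relative abundances, per-sample
    element counts, a strains x elements true-prevalence matrix (nt), and
    per-element average ortholog lengths.  Reports pooled accuracy/recall
    at ``threshold``, the threshold-sweep AUC, and the convoluted-null
    comparison.
    """
    from .io_tables import read_abundance_table, read_reference_lengths, _read_tsv

    profile = read_abundance_table(taxa_path, "taxon")
    counts = read_abundance_table(elements_path, "element")
    truth_lengths = _read_tsv(truth_lengths_path).astype(float)
    reference = read_reference_lengths(reference_lengths_path)
    constant = ConstantElement(tuple(constant_ids), float(constant_length))

    counts = filter_elements(counts, element_min_mean_fraction)
    content = deconvolve(counts, profile, constant, method)
    shared_elements = [e for e in content.element_ids if e in truth_lengths.columns]
    content = GenomicContent(content.data[shared_elements], method=method)
    truth = truth_lengths.loc[content.taxon_ids, shared_elements]

    calls = calling.call_presence(content, reference, threshold)
    report = evaluation.accuracy_recall(calls, truth, presence_cutoff=1e-9)
    auc, curve = evaluation.roc_auc(content, reference, truth, presence_cutoff=1e-9)

    null = calling.convoluted_null(
        ElementCounts(counts.data[shared_elements]), constant, content.taxon_ids
    )
    null_calls = calling.call_presence(null, reference, threshold)
    null_report = evaluation.accuracy_recall(null_calls, truth, presence_cutoff=1e-9)
    null_auc, _ = evaluation.roc_auc(null, reference, truth, presence_cutoff=1e-9)

    return {
        "content": content,
        "calls": calls,
        "report": report,
        "accuracy": report.accuracy,
        "recall": report.recall,
        "auc": auc,
        "roc_curve": curve,
        "null_accuracy": null_report.accuracy,
        "null_auc": null_auc,
    }
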
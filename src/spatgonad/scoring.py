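"""Gene-module scoring with expression-matched control genes.

A module score for a pixel averages, over the module genes, the gene's
normalized expression minus the mean of its expression-matched control
genes, so that the score is centred at zero for gene sets with no
coordinated signal. Genes are ordered by their mean expression across
pixels and cut into equal-frequency bins; each module gene draws up to
``n_ctrl`` controls uniformly without replacement from its own bin (itself
excluded). Averaging the per-gene differences — rather than pooling every
control into one multiset — weights each module gene equally, which keeps
random gene sets unbiased even when bin sizes are slightly uneven.

Scores are exactly invariant to adding a constant to the whole matrix and
are reproducible for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import NormalizedMatrix

__all__ = ["ModuleScore", "score_module", "score_named_modules"]

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 24
DEFAULT_N_CTRL = 100


@dataclass
class ModuleScore:
    """Per-pixel score for one named gene set, with control provenance."""

    module_name: str
    gene_set: list[str]                 # module genes present in the matrix
    control_assignment: dict[str, list[str]]
    scores: np.ndarray                  # per pixel, same order as pixel_ids
    pixel_ids: list[str]
    n_bins: int
    n_ctrl: int
    seed: int


def _expression_bins(norm: NormalizedMatrix, n_bins: int) -> dict[str, int]:
    """Equal-frequency bin id per gene, ordered by mean expression.

    Ties are broken by gene symbol so the binning is deterministic.
    """
    means = norm.values.mean(axis=1)
    symbols = np.array(norm.gene_ids)
    order = np.lexsort((symbols, means))  # primary: mean, secondary: symbol
    splits = np.array_split(order, n_bins)
    bin_of: dict[str, int] = {}
    for b, idx in enumerate(splits):
        for i in idx:
            bin_of[norm.gene_ids[i]] = b
    return bin_of


def score_module(
    norm: NormalizedMatrix,
    gene_set,
    module_name: str = "module",
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> ModuleScore:
    """Score one gene set against expression-matched controls.

    Module genes absent from the matrix are dropped with a warning; an
    empty intersection is an error.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_ctrl < 1:
        raise ValueError("n_ctrl must be >= 1")
    gene_set = list(dict.fromkeys(gene_set))  # dedupe, keep order
    universe = set(norm.gene_ids)
    present = [g for g in gene_set if g in universe]
    missing = [g for g in gene_set if g not in universe]
    if missing:
        logger.warning(
            "module %r: %d/%d genes absent from matrix (e.g. %s)",
            module_name, len(missing), len(gene_set), missing[:5],
        )
    if not present:
        raise ValueError(
            f"module {module_name!r} has no genes in the expression matrix"
        )
    n_bins = min(n_bins, norm.n_genes)
    bin_of = _expression_bins(norm, n_bins)
    members_by_bin: dict[int, list[str]] = {}
    for g in norm.gene_ids:
        members_by_bin.setdefault(bin_of[g], []).append(g)
    # sort bin members for deterministic sampling independent of input order
    for b in members_by_bin:
        members_by_bin[b] = sorted(members_by_bin[b])

    rng = np.random.default_rng(seed)
    control_assignment: dict[str, list[str]] = {}
    for g in present:
        candidates = [c for c in members_by_bin[bin_of[g]] if c != g]
        k = min(n_ctrl, len(candidates))
        if k == 0:
            control_assignment[g] = []
            continue
        chosen = rng.choice(len(candidates), size=k, replace=False)
        control_assignment[g] = [candidates[i] for i in sorted(chosen)]

    gene_index = {g: i for i, g in enumerate(norm.gene_ids)}
    # average of per-gene (module value − matched-control mean) differences:
    # each module gene weighs equally however large its bin is, which keeps
    # random gene sets centred at zero even when bin sizes are uneven
    diffs = np.zeros(norm.n_pixels)
    for g in present:
        gvals = norm.values[gene_index[g]]
        ctrl = control_assignment[g]
        if ctrl:
            gvals = gvals - norm.values[[gene_index[c] for c in ctrl]].mean(axis=0)
        diffs += gvals
    scores = diffs / len(present)
    return ModuleScore(
        module_name=module_name,
        gene_set=present,
        control_assignment=control_assignment,
        scores=scores,
        pixel_ids=list(norm.pixel_ids),
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
    )


def score_named_modules(
    norm: NormalizedMatrix,
    module_spec: dict,
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> list[ModuleScore]:
    """Score several named gene sets with one seed stream.

    ``module_spec`` maps module name to gene list. Per-module seeds are
    derived deterministically from ``seed``; duplicate names are an error.
    """
    names = list(module_spec)
    if len(names) != len(set(names)):
        raise ValueError("duplicate module names in module_spec")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31, size=max(len(names), 1))
    out = []
    for name, child in zip(names, child_seeds):
        out.append(
            score_module(
                norm, module_spec[name], module_name=name,
                n_bins=n_bins, n_ctrl=n_ctrl, seed=int(child),
            )
        )
    return out
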
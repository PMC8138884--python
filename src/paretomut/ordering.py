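"""Deterministic gene and sample orderings for alteration plots.

Genes are ordered by a greedy set-cover heuristic: starting from an empty
partial cover (or an optional forced prefix), the gene covering the most
currently uncovered samples is appended; once no gene adds new samples the
remaining genes follow by decreasing total alteration count.  Samples are
ordered memo-sort style: within each group, by their binary alteration
pattern over the gene order read as a binary number (first gene most
significant), descending — the canonical oncoprint "staircase" layout.
Both orderings are pure functions of their inputs (no hidden randomness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .metrics import AlterationMatrix, GeneSelection


@dataclass(frozen=True)
class PlotOrder:
    """Gene and sample permutations plus optional group segmentation.

    ``group_boundaries`` lists (label, start, stop) half-open column ranges;
    sample_order never interleaves groups.
    """

    gene_order: tuple[str, ...]
    sample_order: tuple[str, ...]
    group_boundaries: tuple[tuple[str, int, int], ...] | None = None


def greedy_gene_order(
    matrix: AlterationMatrix,
    selection,
    seed_genes=(),
) -> list[str]:
    """Order the selected genes by greedy marginal sample coverage.

    Ties are broken by higher total alteration count, then by the gene's
    position in the matrix column order.  ``seed_genes`` forces a prefix
    (the "initial solution" of the greedy cover).
    """
    if isinstance(selection, GeneSelection):
        members = set(selection.members)
    else:
        members = set(selection)
    if not members:
        raise ConfigurationError("selection must be nonempty")
    genes = [g for g in matrix.gene_ids if g in members]
    matrix.column_indices(members)  # raise on unknown genes
    cols = {g: matrix.values[:, matrix.column_indices([g])[0]].astype(bool)
            for g in genes}
    totals = {g: int(cols[g].sum()) for g in genes}
    pos = {g: i for i, g in enumerate(genes)}

    ordered: list[str] = []
    for g in seed_genes:
        if g not in members:
            raise ConfigurationError(f"seed gene {g!r} not in selection")
        if g not in ordered:
            ordered.append(g)
    covered = np.zeros(matrix.n_samples, dtype=bool)
    for g in ordered:
        covered |= cols[g]
    remaining = [g for g in genes if g not in ordered]

    while remaining:
        gains = [(int((cols[g] & ~covered).sum()), g) for g in remaining]
        best_gain = max(gain for gain, _ in gains)
        if best_gain == 0:
            break
        candidates = [g for gain, g in gains if gain == best_gain]
        pick = min(candidates, key=lambda g: (-totals[g], pos[g]))
        ordered.append(pick)
        covered |= cols[pick]
        remaining.remove(pick)

    remaining.sort(key=lambda g: (-totals[g], pos[g]))
    ordered.extend(remaining)
    return ordered


def sample_order(
    matrix: AlterationMatrix,
    gene_order,
    groups=None,
) -> list[str]:
    """Memo-sort samples by alteration pattern over ``gene_order``.

    ``groups`` is an ordered mapping {label: sample ids}; when given, the
    sort is applied within each group and groups are concatenated in
    mapping order.  Without groups all matrix samples form one block.
    Ties are broken by sample id.
    """
    gene_order = list(gene_order)
    if not gene_order:
        raise ConfigurationError("gene_order must be nonempty")
    idx = matrix.column_indices(gene_order)
    frame = matrix.data
    sample_pos = {s: i for i, s in enumerate(frame.index)}

    def sort_block(samples):
        rows = []
        for s in samples:
            if s not in sample_pos:
                raise ConfigurationError(f"unknown sample id {s!r}")
            pattern = tuple(int(v) for v in matrix.values[sample_pos[s], idx])
            rows.append((tuple(-b for b in pattern), s))
        rows.sort()
        return [s for _, s in rows]

    if groups is None:
        return sort_block(list(frame.index))
    out: list[str] = []
    for label in groups:
        out.extend(sort_block(list(groups[label])))
    return out


def make_plot_order(
    matrix: AlterationMatrix,
    selection,
    groups=None,
    seed_genes=(),
) -> PlotOrder:
    """Convenience: greedy gene order + memo-sorted samples + boundaries."""
    genes = greedy_gene_order(matrix, selection, seed_genes=seed_genes)
    samples = sample_order(matrix, genes, groups=groups)
    boundaries = None
    if groups is not None:
        boundaries = []
        start = 0
        for label in groups:
            stop = start + len(list(groups[label]))
            boundaries.append((label, start, stop))
            start = stop
        boundaries = tuple(boundaries)
    return PlotOrder(tuple(genes), tuple(samples), boundaries)
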
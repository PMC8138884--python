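"""Alteration-matrix data model and the two optimization objectives.

The central container is :class:`AlterationMatrix`, a binary samples x genes
incidence structure (1 = the sample carries an alteration in that gene).
On top of it the module defines the two quantities the optimizer trades off:

* ``coverage`` -- the number of samples carrying at least one alteration in
  any gene of a selection (written gamma(G) in the mutual-exclusivity
  literature),
* ``overlap`` -- the number of alteration events beyond the first per
  sample (omega(G)); omega(G) = 0 means the selection is perfectly
  mutually exclusive.

Overlap follows the Dendrix-family event-sum convention

    omega(G) = sum_{g in G} gamma({g}) - gamma(G)

which equals the per-sample sum of max(0, k - 1) excess events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UnknownGeneError

#: Objective mode: maximize coverage, minimize overlap.
COVERAGE_OVERLAP = "coverage_overlap"
#: Objective mode: maximize coverage, minimize the number of selected genes.
COVERAGE_SIZE = "coverage_size"

MODES = (COVERAGE_OVERLAP, COVERAGE_SIZE)


def _check_mode(mode: str) -> str:
    if mode not in MODES:
        raise ConfigurationError(
            f"objective mode must be one of {MODES}, got {mode!r}"
        )
    return mode


class AlterationMatrix:
    """Binary samples x genes incidence of genomic alteration events.

    Parameters
    ----------
    data
        DataFrame with sample ids as index, gene ids as columns and
        0/1 entries.  A boolean frame is accepted and cast.
    alteration_kind
        Free-text label for the event type the matrix encodes
        (e.g. ``"mutation"`` or ``"overexpression"``).
    """

    def __init__(self, data: pd.DataFrame, alteration_kind: str = "alteration"):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ConfigurationError(f"duplicate sample id: {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise ConfigurationError(f"duplicate gene id: {dup!r}")
        values = data.to_numpy()
        if values.size and not np.isin(values, (0, 1, True, False)).all():
            raise ConfigurationError("alteration matrix entries must be 0 or 1")
        self._data = pd.DataFrame(
            values.astype(np.int8),
            index=data.index.astype(str),
            columns=data.columns.astype(str),
        )
        self.alteration_kind = alteration_kind
        self._col_index = {g: i for i, g in enumerate(self._data.columns)}

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        values,
        sample_ids,
        gene_ids,
        alteration_kind: str = "alteration",
    ) -> "AlterationMatrix":
        frame = pd.DataFrame(np.asarray(values), index=list(sample_ids),
                             columns=list(gene_ids))
        return cls(frame, alteration_kind)

    # -- accessors ------------------------------------------------------------

    @property
    def data(self) -> pd.DataFrame:
        """The underlying int8 DataFrame (do not mutate)."""
        return self._data

    def to_dataframe(self) -> pd.DataFrame:
        return self._data.copy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def n_samples(self) -> int:
        return self._data.shape[0]

    @property
    def n_genes(self) -> int:
        return self._data.shape[1]

    @property
    def values(self) -> np.ndarray:
        """int8 array of shape (n_samples, n_genes)."""
        return self._data.to_numpy()

    def gene_counts(self) -> pd.Series:
        """Per-gene total alteration counts (gamma of each singleton)."""
        return self._data.sum(axis=0)

    def column_indices(self, genes) -> np.ndarray:
        """Column positions for ``genes``; raises on any unknown gene."""
        idx = []
        for g in genes:
            try:
                idx.append(self._col_index[g])
            except KeyError:
                raise UnknownGeneError(g) from None
        return np.asarray(idx, dtype=np.intp)

    def subset(self, samples=None, genes=None) -> "AlterationMatrix":
        """Restriction to the given samples and/or genes (order as given)."""
        frame = self._data
        if samples is not None:
            frame = frame.loc[list(samples)]
        if genes is not None:
            self.column_indices(genes)  # raise UnknownGeneError early
            frame = frame[list(genes)]
        return AlterationMatrix(frame, self.alteration_kind)

    def equals(self, other: "AlterationMatrix") -> bool:
        return (
            self.alteration_kind == other.alteration_kind
            and self._data.equals(other._data)
        )

    def __repr__(self) -> str:
        return (
            f"AlterationMatrix({self.n_samples} samples x {self.n_genes} genes,"
            f" kind={self.alteration_kind!r})"
        )


@dataclass(frozen=True)
class GeneSelection:
    """A subset G of the gene universe; the optimizer's solution encoding.

    Members are normalized to a sorted tuple so two selections over the same
    gene set compare equal and lexicographic comparison is well defined.
    """

    members: tuple[str, ...]

    def __init__(self, members=()):
        members = tuple(sorted(set(members)))
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


@dataclass(frozen=True)
class ObjectiveVector:
    """(coverage, second objective) for one selection under one mode."""

    coverage: int
    second: int
    mode: str = field(compare=True)

    def __post_init__(self):
        _check_mode(self.mode)
        if self.coverage < 0 or self.second < 0:
            raise ConfigurationError("objective values must be non-negative")

    def as_tuple(self) -> tuple[int, int]:
        return (self.coverage, self.second)


def covered_sample_mask(selection: GeneSelection, matrix: AlterationMatrix) -> np.ndarray:
    """Boolean mask over matrix samples covered by the selection."""
    idx = matrix.column_indices(selection.members)
    if idx.size == 0:
        return np.zeros(matrix.n_samples, dtype=bool)
    return matrix.values[:, idx].any(axis=1)


def coverage(selection: GeneSelection, matrix: AlterationMatrix) -> int:
    """Number of samples with >= 1 alteration in any gene of the selection."""
    return int(covered_sample_mask(selection, matrix).sum())


def coverage_fraction(selection: GeneSelection, matrix: AlterationMatrix) -> float:
    """Coverage as a fraction of all samples (0 for an empty matrix)."""
    if matrix.n_samples == 0:
        return 0.0
    return coverage(selection, matrix) / matrix.n_samples


def overlap(selection: GeneSelection, matrix: AlterationMatrix) -> int:
    """Alteration events in the selection beyond the first per sample."""
    idx = matrix.column_indices(selection.members)
    if idx.size == 0:
        return 0
    counts = matrix.values[:, idx].sum(axis=1)
    return int(counts.sum() - (counts > 0).sum())


def objective_vector(
    selection: GeneSelection, matrix: AlterationMatrix, mode: str
) -> ObjectiveVector:
    """Bundle coverage with the mode's second objective."""
    _check_mode(mode)
    cov = coverage(selection, matrix)
    if mode == COVERAGE_OVERLAP:
        second = overlap(selection, matrix)
    else:
        second = len(selection)
    return ObjectiveVector(cov, second, mode)
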
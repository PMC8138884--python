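"""Readers, writers, binarization and clinical preprocessing operations.

File dialects: tab-separated by default with comma auto-detection, UTF-8,
case-sensitive identifiers.  All preprocessing operations are pure — they
return new objects and leave their inputs untouched — so pipelines such as
merge -> regroup -> derive -> filter_samples -> filter_genes compose freely.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError
from .metrics import AlterationMatrix, GeneSelection, ObjectiveVector
from .moea import ParetoSet


class _Sentinel:
    def __init__(self, name):
        self._name = name

    def __repr__(self):
        return self._name


#: Condition value matching a missing attribute value.
MISSING = _Sentinel("MISSING")
#: Condition value matching any non-missing attribute value.
PRESENT = _Sentinel("PRESENT")


class ClinicalTable:
    """Per-sample categorical clinical annotations (NaN = missing)."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ConfigurationError(f"duplicate sample id: {dup!r}")
        self._data = data.copy()
        self._data.index = self._data.index.astype(str)

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def attributes(self) -> list[str]:
        return list(self._data.columns)

    def subset(self, samples) -> "ClinicalTable":
        return ClinicalTable(self._data.loc[list(samples)])

    def equals(self, other: "ClinicalTable") -> bool:
        return self._data.equals(other._data)

    def __repr__(self):
        return (f"ClinicalTable({len(self._data)} samples, "
                f"{len(self._data.columns)} attributes)")


class ExpressionMatrix:
    """Continuous samples x genes expression values (NaN = missing)."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates or data.columns.has_duplicates:
            raise ConfigurationError("duplicate sample or gene ids")
        self._data = data.astype(float)
        self._data.index = self._data.index.astype(str)
        with np.errstate(invalid="ignore"):
            if np.isinf(self._data.to_numpy()).any():
                raise ConfigurationError("expression values must be finite or NaN")

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self._data.columns)


# ---------------------------------------------------------------------------
# Delimited readers / writers
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _read_table(path, delimiter=None) -> pd.DataFrame:
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split(sep)[1:]
    seen: set[str] = set()
    for name in header:  # pandas would silently mangle duplicate headers
        if name in seen:
            raise ParseError(f"{path}: duplicate column id {name!r}")
        seen.add(name)
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                            engine="python", on_bad_lines="error")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return frame


def read_alteration_table(
    path, delimiter=None, transpose: bool = False,
    alteration_kind: str = "alteration",
) -> AlterationMatrix:
    """Read a delimited 0/1 table (samples x genes; ``transpose`` flips)."""
    frame = _read_table(path, delimiter)
    if transpose:
        frame = frame.T
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    values = np.empty(frame.shape, dtype=np.int8)
    for j, gene in enumerate(frame.columns):
        col = frame.iloc[:, j]
        bad = ~col.isin(["0", "1"])
        if bad.any():
            row = col.index[bad][0]
            raise ParseError(
                f"{path}: non-binary cell at sample {row!r}, gene {gene!r}"
            )
        values[:, j] = col.astype(np.int8)
    return AlterationMatrix(
        pd.DataFrame(values, index=frame.index, columns=frame.columns),
        alteration_kind,
    )


def write_alteration_table(matrix: AlterationMatrix, path, delimiter="\t") -> None:
    matrix.data.to_csv(path, sep=delimiter, index_label="sample")


def read_clinical_table(path, delimiter=None) -> ClinicalTable:
    frame = _read_table(path, delimiter)
    return ClinicalTable(frame)


def write_clinical_table(clinical: ClinicalTable, path, delimiter="\t") -> None:
    clinical.data.to_csv(path, sep=delimiter, index_label="sample", na_rep="")


def read_expression_table(path, delimiter=None) -> ExpressionMatrix:
    frame = _read_table(path, delimiter)
    return ExpressionMatrix(frame.apply(pd.to_numeric))


def write_expression_table(expr: ExpressionMatrix, path, delimiter="\t") -> None:
    expr.data.to_csv(path, sep=delimiter, index_label="sample", na_rep="")


_MAF_SAMPLE_COLS = ("Tumor_Sample_Barcode", "sample", "sample_id")
_MAF_GENE_COLS = ("Hugo_Symbol", "gene", "gene_id")


def read_maf_like(path, delimiter=None) -> AlterationMatrix:
    """Read a per-mutation record list (MAF dialect) into a binary matrix.

    Recognizes ``Tumor_Sample_Barcode`` / ``Hugo_Symbol`` (or plain
    ``sample`` / ``gene``) columns; multiple records per (sample, gene)
    collapse to a single flag.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    records = pd.read_csv(path, sep=sep, dtype=str, engine="python",
                          comment="#")
    sample_col = next((c for c in _MAF_SAMPLE_COLS if c in records.columns), None)
    gene_col = next((c for c in _MAF_GENE_COLS if c in records.columns), None)
    if sample_col is None or gene_col is None:
        raise ParseError(
            f"{path}: expected sample column (one of {_MAF_SAMPLE_COLS}) and "
            f"gene column (one of {_MAF_GENE_COLS}); found {list(records.columns)}"
        )
    records = records.dropna(subset=[sample_col, gene_col])
    if records.empty:
        warnings.warn(f"{path}: no mutation records; returning empty matrix")
        return AlterationMatrix(pd.DataFrame(dtype=np.int8), "mutation")
    incidence = (
        pd.crosstab(records[sample_col], records[gene_col])
        .gt(0)
        .astype(np.int8)
    )
    incidence.index.name = None
    incidence.columns.name = None
    return AlterationMatrix(incidence, "mutation")


# ---------------------------------------------------------------------------
# Binarization and merging
# ---------------------------------------------------------------------------


def binarize_expression(
    expr: ExpressionMatrix, sd_multiplier: float = 1.0, ddof: int = 1
) -> AlterationMatrix:
    """Call overexpression per gene by a standard-deviation threshold.

    For each gene g with per-sample mean m_g and standard deviation s_g
    (missing values excluded, sample SD with ``ddof`` degrees of freedom),
    sample s is altered iff value(s, g) > m_g + sd_multiplier * s_g.
    Genes with zero SD or fewer than two finite values yield no alterations
    (the latter with a warning).  The call is invariant under positive
    affine transforms of a gene's values.
    """
    if sd_multiplier <= 0:
        raise ConfigurationError("sd_multiplier must be > 0")
    frame = expr.data
    finite_counts = frame.notna().sum(axis=0)
    sparse = finite_counts < 2
    if sparse.any():
        warnings.warn(
            "genes with fewer than 2 finite values yield no alterations: "
            + ", ".join(map(str, frame.columns[sparse]))
        )
    means = frame.mean(axis=0)
    sds = frame.std(axis=0, ddof=ddof)
    thresholds = means + sd_multiplier * sds
    altered = frame.gt(thresholds, axis="columns").astype(np.int8)
    altered.loc[:, sparse] = 0
    return AlterationMatrix(altered, "overexpression")


def merge_studies(
    primary: AlterationMatrix, secondary: AlterationMatrix
) -> AlterationMatrix:
    """Union of two studies; the primary wins on duplicate samples.

    The gene set is the union (primary's order first); samples are the
    primary's plus the secondary's not already present; absent cells are 0.
    """
    if primary.alteration_kind != secondary.alteration_kind:
        raise ConfigurationError(
            f"alteration kinds differ: {primary.alteration_kind!r} vs "
            f"{secondary.alteration_kind!r}"
        )
    genes = list(primary.gene_ids)
    genes += [g for g in secondary.gene_ids if g not in set(genes)]
    extra = [s for s in secondary.sample_ids
             if s not in set(primary.sample_ids)]
    top = primary.data.reindex(columns=genes, fill_value=0)
    bottom = secondary.data.loc[extra].reindex(columns=genes, fill_value=0)
    merged = pd.concat([top, bottom]).astype(np.int8)
    return AlterationMatrix(merged, primary.alteration_kind)


# ---------------------------------------------------------------------------
# Clinical preprocessing
# ---------------------------------------------------------------------------


def regroup_attribute(
    clinical: ClinicalTable,
    attribute: str,
    mapping: dict,
    unmapped: str = "keep",
) -> ClinicalTable:
    """Harmonize an attribute's levels through a rename mapping.

    Unmapped levels pass through (``unmapped="keep"``) or become missing
    (``unmapped="missing"``).  Missing values stay missing.
    """
    if attribute not in clinical.attributes:
        raise ConfigurationError(f"unknown attribute {attribute!r}")
    if any(v == "" for v in mapping.values()):
        raise ConfigurationError("mapping to empty string is not allowed")
    if unmapped not in ("keep", "missing"):
        raise ConfigurationError("unmapped must be 'keep' or 'missing'")
    frame = clinical.data.copy()

    def translate(v):
        if pd.isna(v):
            return v
        if v in mapping:
            return mapping[v]
        return v if unmapped == "keep" else np.nan

    frame[attribute] = frame[attribute].map(translate)
    return ClinicalTable(frame)


def _condition_holds(value, spec) -> bool:
    if spec is MISSING:
        return pd.isna(value)
    if spec is PRESENT:
        return not pd.isna(value)
    if isinstance(spec, (list, tuple, set, frozenset)):
        return not pd.isna(value) and value in spec
    return not pd.isna(value) and value == spec


def derive_attribute(
    clinical: ClinicalTable,
    target: str,
    rules,
    overwrite: bool = False,
) -> ClinicalTable:
    """Fill a target attribute from a first-match-wins condition list.

    ``rules`` is a sequence of ``(conditions, value)`` where conditions is
    a dict mapping attribute -> expected value (a string, a collection of
    strings, or the :data:`MISSING` / :data:`PRESENT` sentinels); an empty
    dict matches every sample.  Samples matching no rule get a missing
    value.  Existing non-missing target values are preserved unless
    ``overwrite`` is set.
    """
    frame = clinical.data.copy()
    for conditions, _value in rules:
        for attr in conditions:
            if attr not in frame.columns and attr != target:
                raise ConfigurationError(f"rule references unknown attribute {attr!r}")
    existing = frame[target] if target in frame.columns else pd.Series(
        np.nan, index=frame.index, dtype=object
    )
    out = []
    for sample in frame.index:
        if not overwrite and not pd.isna(existing.loc[sample]):
            out.append(existing.loc[sample])
            continue
        value = np.nan
        for conditions, rule_value in rules:
            if all(
                _condition_holds(frame.at[sample, attr], spec)
                for attr, spec in conditions.items()
            ):
                value = rule_value
                break
        out.append(value)
    frame[target] = out
    return ClinicalTable(frame)


def _clause_mask(clinical: ClinicalTable, clause) -> tuple[str, pd.Series]:
    """Boolean mask of samples MATCHED (to be dropped) by one clause."""
    if len(clause) == 4:
        label, attribute, op, value = clause
    else:
        attribute, op, value = clause
        label = f"{attribute} {op} {value}"
    frame = clinical.data
    if op == "all":
        return label, pd.Series(True, index=frame.index)
    if op == "none":
        return label, pd.Series(False, index=frame.index)
    if attribute not in frame.columns:
        raise ConfigurationError(f"predicate on unknown attribute {attribute!r}")
    col = frame[attribute]
    if op == "eq":
        mask = col.notna() & (col == value)
    elif op == "ne":
        mask = col.notna() & (col != value)
    elif op == "in":
        mask = col.notna() & col.isin(list(value))
    elif op == "missing":
        mask = col.isna()
    elif op == "not_missing":
        mask = col.notna()
    else:
        raise ConfigurationError(f"unknown predicate op {op!r}")
    return label, mask


def filter_samples(
    matrix: AlterationMatrix,
    clinical: ClinicalTable,
    drop_clauses,
) -> tuple[AlterationMatrix, ClinicalTable, dict[str, int]]:
    """Drop samples matching any clause; keep the rest (order preserved).

    A clause is ``(label, attribute, op, value)`` (label optional) with
    ``op`` in {"eq", "ne", "in", "missing", "not_missing", "all", "none"}.
    Clauses are applied in order; the returned counts record how many
    samples each clause newly deleted.
    """
    missing = [s for s in matrix.sample_ids if s not in set(clinical.sample_ids)]
    if missing:
        raise ConfigurationError(
            f"matrix sample {missing[0]!r} absent from clinical table"
        )
    dropped = pd.Series(False, index=clinical.data.index)
    counts: dict[str, int] = {}
    for clause in drop_clauses:
        label, mask = _clause_mask(clinical, clause)
        new = mask & ~dropped
        counts[label] = int(new.sum())
        dropped |= mask
    kept = [s for s in matrix.sample_ids if not dropped.loc[s]]
    return matrix.subset(samples=kept), clinical.subset(kept), counts


def filter_genes(
    matrix: AlterationMatrix,
    min_frequency: float = 0.0,
    within_samples=None,
    keep_list=None,
    drop_zero: bool = True,
) -> AlterationMatrix:
    """Restrict genes by whitelist and in-group alteration frequency.

    Retains genes present in ``keep_list`` (when given) whose alteration
    frequency within ``within_samples`` (all samples by default) is
    >= ``min_frequency`` (inclusive).  With ``min_frequency == 0``,
    ``drop_zero`` controls whether genes with zero total alterations are
    dropped.
    """
    if not 0.0 <= min_frequency <= 1.0:
        raise ConfigurationError("min_frequency must lie in [0, 1]")
    within = list(within_samples) if within_samples is not None else matrix.sample_ids
    if min_frequency > 0 and not within:
        raise ConfigurationError(
            "within_samples is empty but min_frequency > 0"
        )
    unknown = [s for s in within if s not in set(matrix.sample_ids)]
    if unknown:
        raise ConfigurationError(f"unknown sample id {unknown[0]!r}")
    keep = set(keep_list) if keep_list is not None else None

    frame = matrix.data
    group = frame.loc[within] if within else frame.iloc[0:0]
    kept_genes = []
    for gene in matrix.gene_ids:
        if keep is not None and gene not in keep:
            continue
        if min_frequency > 0:
            freq = group[gene].sum() / len(within)
            if freq < min_frequency:
                continue
        elif drop_zero and frame[gene].sum() == 0:
            continue
        kept_genes.append(gene)
    return matrix.subset(genes=kept_genes)


# ---------------------------------------------------------------------------
# Dataset bundles and Pareto tables
# ---------------------------------------------------------------------------


def export_dataset(
    matrix: AlterationMatrix,
    clinical: ClinicalTable | None,
    directory,
    manifest: dict | None = None,
) -> Path:
    """Write a dataset bundle (alterations.tsv, clinical.tsv, manifest.json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_alteration_table(matrix, directory / "alterations.tsv")
    if clinical is not None:
        write_clinical_table(clinical, directory / "clinical.tsv")
    info = {
        "format_version": 1,
        "alteration_kind": matrix.alteration_kind,
        "n_samples": matrix.n_samples,
        "n_genes": matrix.n_genes,
    }
    info.update(manifest or {})
    (directory / "manifest.json").write_text(
        json.dumps(info, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return directory


def read_dataset(directory) -> tuple[AlterationMatrix, ClinicalTable | None, dict]:
    """Read a bundle written by :func:`export_dataset`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text(encoding="utf-8"))
        if manifest_path.exists() else {}
    )
    matrix = read_alteration_table(
        directory / "alterations.tsv",
        alteration_kind=manifest.get("alteration_kind", "alteration"),
    )
    clinical_path = directory / "clinical.tsv"
    clinical = read_clinical_table(clinical_path) if clinical_path.exists() else None
    return matrix, clinical, manifest


def write_pareto_table(pareto: ParetoSet, path, delimiter="\t") -> None:
    """Serialize a Pareto set as a delimited table (one entry per row)."""
    rows = [
        {
            "coverage": vec.coverage,
            "second_objective": vec.second,
            "n_genes": len(sel),
            "genes": ",".join(sel.members),
        }
        for sel, vec in pareto.entries
    ]
    frame = pd.DataFrame(rows, columns=["coverage", "second_objective",
                                        "n_genes", "genes"])
    frame.to_csv(path, sep=delimiter, index=False)


def read_pareto_table(path, mode: str, delimiter="\t") -> ParetoSet:
    frame = pd.read_csv(path, sep=delimiter, dtype={"genes": str})
    entries = []
    for _, row in frame.iterrows():
        genes = () if pd.isna(row["genes"]) or row["genes"] == "" else \
            tuple(str(row["genes"]).split(","))
        entries.append(
            (GeneSelection(genes),
             ObjectiveVector(int(row["coverage"]), int(row["second_objective"]),
                             mode))
        )
    return ParetoSet.from_candidates(entries, mode)
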
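"""Synthetic alteration data with planted structure, and an HNSCC-like fixture.

Two generators:

* :func:`generate_planted` builds binary matrices containing one or more
  planted mutually exclusive gene modules — each covered sample carries
  exactly one uniformly chosen module gene, optionally one extra module
  gene at a configurable overlap rate — on top of i.i.d. background noise
  genes.  The ground-truth modules are returned so recovery of the planted
  signal by the optimizer can be measured.

* :func:`generate_hnsc_fixture` emulates the head-and-neck squamous cell
  carcinoma (HNSCC) cohort layout used in the package's preprocessing
  pipeline: 522 expression-profiled samples with primary-site labels
  (including exactly 2 lip and 10 hypopharynx samples), p16/HPV clinical
  attributes leaving exactly 19 samples without a derivable HPV status,
  and a cancer-testis-antigen (CTA) style gene panel of which exactly 208
  genes survive binarization plus the keep-list / frequency filter.  The
  fixture emulates reference cohort COUNTS only — gene names are synthetic
  CTA-style placeholders, not real tumor biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import (
    ClinicalTable,
    ExpressionMatrix,
    binarize_expression,
    derive_attribute,
    filter_genes,
    filter_samples,
    regroup_attribute,
)
from .metrics import AlterationMatrix


@dataclass(frozen=True)
class PlantedModuleConfig:
    """Configuration of a planted mutually-exclusive-module matrix.

    Defaults describe the package's reference recovery scenario: one
    4-gene module covering 90% of 200 samples with no planted overlap,
    plus 20 noise genes altered i.i.d. at 5% per cell.
    """

    n_samples: int = 200
    modules: tuple[int, ...] = (4,)
    module_coverage: float = 0.9
    module_overlap_rate: float = 0.0
    n_noise_genes: int = 20
    noise_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "modules", tuple(self.modules))
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if any(m < 1 for m in self.modules):
            raise ConfigurationError("module gene counts must be >= 1")
        for name in ("module_coverage", "module_overlap_rate", "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.n_noise_genes < 0:
            raise ConfigurationError("n_noise_genes must be >= 0")
        if self.module_overlap_rate > 0 and any(m < 2 for m in self.modules):
            raise ConfigurationError(
                "module_overlap_rate > 0 requires modules of >= 2 genes"
            )


def generate_planted(
    config: PlantedModuleConfig,
) -> tuple[AlterationMatrix, list[list[str]]]:
    """Generate a planted-module matrix and its ground-truth modules.

    Per module, ``round(module_coverage * n_samples)`` samples (drawn
    without replacement) receive exactly one uniformly chosen module gene
    alteration; with probability ``module_overlap_rate`` a covered sample
    receives one additional, distinct module gene.  Noise genes are
    altered i.i.d. at ``noise_rate``.  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]
    gene_names: list[str] = []
    modules: list[list[str]] = []
    for mi, size in enumerate(config.modules):
        names = [f"MOD{mi + 1}_G{j + 1}" for j in range(size)]
        modules.append(names)
        gene_names.extend(names)
    noise_names = [f"NOISE{j + 1:03d}" for j in range(config.n_noise_genes)]
    gene_names.extend(noise_names)

    values = np.zeros((n, len(gene_names)), dtype=np.int8)
    col = {g: i for i, g in enumerate(gene_names)}
    for names in modules:
        size = len(names)
        n_cov = int(round(config.module_coverage * n))
        covered = rng.choice(n, size=n_cov, replace=False)
        primary = rng.integers(size, size=n_cov)
        values[covered, [col[names[p]] for p in primary]] = 1
        if config.module_overlap_rate > 0:
            extra_mask = rng.random(n_cov) < config.module_overlap_rate
            offsets = 1 + rng.integers(size - 1, size=n_cov)
            secondary = (primary + offsets) % size
            for s, p2, take in zip(covered, secondary, extra_mask):
                if take:
                    values[s, col[names[p2]]] = 1
    if config.n_noise_genes:
        noise = rng.random((n, config.n_noise_genes)) < config.noise_rate
        values[:, len(gene_names) - config.n_noise_genes:] |= noise.astype(np.int8)

    frame = pd.DataFrame(values, index=samples, columns=gene_names)
    return AlterationMatrix(frame, "mutation"), modules


# ---------------------------------------------------------------------------
# HNSCC-like fixture
# ---------------------------------------------------------------------------

#: Raw primary-site label -> harmonized site.
HNSC_SITE_MAP = {
    "Oral Tongue": "oral cavity",
    "Floor of Mouth": "oral cavity",
    "Oral Cavity": "oral cavity",
    "Base of Tongue": "oropharynx",
    "Tonsil": "oropharynx",
    "Larynx": "larynx",
    "Hypopharynx": "hypopharynx",
    "Lip": "lip",
}

#: First-match-wins HPV-status derivation from p16 status and primary site:
#: p16 positivity counts as HPV-positive only in the oropharynx; p16-negative
#: samples are HPV-negative; everything else remains missing.  Samples with a
#: directly assigned HPV status are never overwritten.
HNSC_HPV_RULES = (
    ({"HPV_STATUS_P16": "positive", "PRIMARY_SITE": "oropharynx"}, "positive"),
    ({"HPV_STATUS_P16": "negative"}, "negative"),
)

#: Sample-deletion clauses of the HNSCC preprocessing pipeline.
HNSC_DROP_CLAUSES = (
    ("lip", "PRIMARY_SITE", "eq", "lip"),
    ("hypopharynx", "PRIMARY_SITE", "eq", "hypopharynx"),
    ("missing HPV status", "HPV_STATUS", "missing", None),
)

# cohort layout: (raw site label, count) summing to 522
_SITE_LAYOUT = (
    ("Oral Tongue", 130),
    ("Floor of Mouth", 70),
    ("Oral Cavity", 120),
    ("Base of Tongue", 55),
    ("Tonsil", 60),
    ("Larynx", 75),
    ("Hypopharynx", 10),
    ("Lip", 2),
)
_N_SAMPLES = 522
_N_MISSING_HPV = {"oral cavity": 12, "oropharynx": 4, "larynx": 3}  # = 19
_N_CTA_INFORMATIVE = 208
_N_CTA_SILENT = 12     # CTA genes without any overexpression
_N_NON_CTA = 20        # informative genes outside the CTA keep list
_OP_HPV_POSITIVE = 81  # ~72.7% of the 111 surviving oropharynx samples


def hnsc_keep_list(gene_ids) -> list[str]:
    """The CTA whitelist of the fixture: genes named with the CTA prefix."""
    return [g for g in gene_ids if str(g).startswith("CTA")]


def generate_hnsc_fixture(seed: int = 0) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Generate the 522-sample HNSCC-like expression + clinical fixture."""
    rng = np.random.default_rng(seed)
    samples = [f"HN-{i + 1:04d}" for i in range(_N_SAMPLES)]

    raw_sites: list[str] = []
    for label, count in _SITE_LAYOUT:
        raw_sites.extend([label] * count)
    order = rng.permutation(_N_SAMPLES)
    raw_sites = [raw_sites[i] for i in order]
    harmonized = [HNSC_SITE_MAP[s] for s in raw_sites]

    # choose the 19 samples left without a derivable HPV status, disjoint
    # from the lip / hypopharynx groups that are deleted first
    missing_hpv = np.zeros(_N_SAMPLES, dtype=bool)
    for site, count in _N_MISSING_HPV.items():
        pool = [i for i, h in enumerate(harmonized) if h == site]
        picked = rng.choice(pool, size=count, replace=False)
        missing_hpv[picked] = True

    # HPV-positive targets: predominant in the oropharynx, sporadic elsewhere
    op_idx = [i for i, h in enumerate(harmonized)
              if h == "oropharynx" and not missing_hpv[i]]
    positives = set(rng.choice(op_idx, size=_OP_HPV_POSITIVE, replace=False))
    for site, n_pos in (("oral cavity", 15), ("larynx", 5)):
        pool = [i for i, h in enumerate(harmonized)
                if h == site and not missing_hpv[i]]
        positives.update(rng.choice(pool, size=n_pos, replace=False))

    hpv_direct: list = [np.nan] * _N_SAMPLES
    p16: list = [np.nan] * _N_SAMPLES
    for i in range(_N_SAMPLES):
        if missing_hpv[i]:
            continue  # neither direct status nor p16 -> stays missing
        status = "positive" if i in positives else "negative"
        direct = rng.random() < 0.5
        if status == "positive" and harmonized[i] != "oropharynx":
            direct = True  # p16 positivity is only meaningful in the oropharynx
        if direct:
            hpv_direct[i] = status
        else:
            p16[i] = status

    clinical = ClinicalTable(pd.DataFrame(
        {
            "PRIMARY_SITE": raw_sites,
            "HPV_STATUS": hpv_direct,
            "HPV_STATUS_P16": p16,
        },
        index=samples,
    ))

    # expression: CTA panel + silent CTAs + informative non-CTA genes
    surviving = [i for i, h in enumerate(harmonized)
                 if h not in ("lip", "hypopharynx") and not missing_hpv[i]]
    n_surviving = len(surviving)
    gene_names = (
        [f"CTA{i + 1:03d}" for i in range(_N_CTA_INFORMATIVE + _N_CTA_SILENT)]
        + [f"NONCTA{i + 1:02d}" for i in range(_N_NON_CTA)]
    )
    values = rng.normal(0.0, 1.0, size=(_N_SAMPLES, len(gene_names)))
    for j, gene in enumerate(gene_names):
        if gene.startswith("CTA") and j >= _N_CTA_INFORMATIVE:
            values[:, j] = 3.0  # constant column: no overexpression possible
            continue
        # plant >= 26 overexpressed survivors so the gene clears a 5%
        # frequency filter within the 491-sample cohort
        n_out = int(rng.integers(26, 61))
        out_idx = rng.choice(surviving, size=n_out, replace=False)
        values[out_idx, j] = rng.normal(7.0, 0.5, size=n_out)
    assert n_surviving == 491

    expr = ExpressionMatrix(pd.DataFrame(values, index=samples,
                                         columns=gene_names))
    return expr, clinical


def hnsc_preprocess(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    sd_multiplier: float = 1.0,
    min_frequency: float = 0.05,
):
    """Run the full HNSCC preprocessing pipeline on an expression cohort.

    Steps: SD-threshold binarization -> primary-site regrouping -> HPV
    status derivation -> deletion of lip / hypopharynx / missing-HPV
    samples -> CTA keep-list plus in-cohort frequency filter.  Returns
    ``(matrix, clinical, info)`` where info records the per-clause
    deletion counts and the resulting shape.
    """
    matrix = binarize_expression(expr, sd_multiplier=sd_multiplier)
    clinical = regroup_attribute(clinical, "PRIMARY_SITE", HNSC_SITE_MAP)
    clinical = derive_attribute(clinical, "HPV_STATUS", HNSC_HPV_RULES)
    matrix, clinical, deleted = filter_samples(matrix, clinical,
                                               HNSC_DROP_CLAUSES)
    matrix = filter_genes(
        matrix,
        min_frequency=min_frequency,
        keep_list=hnsc_keep_list(matrix.gene_ids),
    )
    info = {
        "deleted": deleted,
        "n_samples": matrix.n_samples,
        "n_genes": matrix.n_genes,
    }
    return matrix, clinical, info
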
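"""Bulk-proteome comparison of paired plasma and synovial-fluid samples.

Consumes a label-free quantification (LFQ) report — genes x samples MaxLFQ
matrix plus per-sample unique-peptide counts, as produced by a DIA search
engine downstream of protein inference — and implements the filtering,
imputation, categorization and paired-correlation analyses:

* detection filter: a protein must have unique peptides in at least 6 of the
  9 plasma samples or at least 6 of the 9 SF samples (parameterized for other
  cohort sizes),
* missing values imputed with the lowest LFQ value observed in the table,
* correlation filter: immunoglobulin variable-domain entries removed and a
  protein's LFQ must exceed 5e5 somewhere,
* seven-category annotation (plasma, cartilage, neutrophil, erythrocyte,
  platelet, generic cell, noncategorized),
* plasma-vs-SF Pearson correlation of log10 abundances, patient-averaged or
  per patient, and a molecular-weight-stratified variant over annotated
  proteins and protein assemblies.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, FormatError, SynofabError

__all__ = [
    "CATEGORIES",
    "DEFAULT_MIN_LFQ",
    "DEFAULT_SIZE_BINS_KDA",
    "ProteinQuantTable",
    "filter_by_detection",
    "impute_missing",
    "filter_for_correlation",
    "paired_abundance_correlation",
    "normalized_abundance",
    "categorize",
    "category_summary",
    "size_stratified_correlation",
]

#: The seven admissible protein categories.
CATEGORIES = (
    "plasma",
    "cartilage",
    "neutrophil",
    "erythrocyte",
    "platelet",
    "generic_cell",
    "noncategorized",
)

DEFAULT_MIN_LFQ = 5e5

#: Molecular-weight strata (kDa) for the size-dependence analysis.
DEFAULT_SIZE_BINS_KDA: dict[str, tuple[float, float]] = {
    "low": (40.0, 100.0),
    "medium": (110.0, 500.0),
    "high": (510.0, 1000.0),
}


@dataclasses.dataclass
class ProteinQuantTable:
    """Genes x samples LFQ matrix with peptide evidence and sample metadata.

    Attributes
    ----------
    lfq
        Genes x sample_ids matrix of MaxLFQ values; NaN marks a missing value.
    peptides
        Same shape; unique-peptide counts per gene and sample (0 = not
        detected).
    samples
        Indexed by sample_id with columns ``patient`` and ``fluid``
        (``plasma`` or ``SF``).
    categories
        Optional gene -> category labels (one of :data:`CATEGORIES`).
    """

    lfq: pd.DataFrame
    peptides: pd.DataFrame
    samples: pd.DataFrame
    categories: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.lfq.columns.equals(self.peptides.columns) or not self.lfq.index.equals(
            self.peptides.index
        ):
            raise FormatError("lfq and peptide tables must share genes and samples")
        unknown = set(self.samples["fluid"]) - {"plasma", "SF"}
        if unknown:
            raise FormatError(f"unknown fluid labels: {sorted(unknown)}")
        missing = set(self.lfq.columns) - set(self.samples.index)
        if missing:
            raise FormatError(f"samples absent from metadata: {sorted(missing)}")
        self.lfq.index.name = "gene"
        self.peptides.index.name = "gene"

    def fluid_samples(self, fluid: str) -> list[str]:
        return [s for s in self.lfq.columns if self.samples.loc[s, "fluid"] == fluid]

    def subset(self, genes: Sequence[str]) -> "ProteinQuantTable":
        cats = self.categories.loc[self.categories.index.isin(genes)] if self.categories is not None else None
        return ProteinQuantTable(
            lfq=self.lfq.loc[genes].copy(),
            peptides=self.peptides.loc[genes].copy(),
            samples=self.samples,
            categories=cats,
        )


def filter_by_detection(
    table: ProteinQuantTable,
    min_samples: int = 6,
    group_size: int | None = 9,
) -> ProteinQuantTable:
    """Keep proteins with peptide evidence in enough samples of either fluid.

    A gene survives when its unique-peptide count is > 0 in at least
    ``min_samples`` plasma samples OR at least ``min_samples`` SF samples
    (a per-fluid OR, so fluid-specific proteins are kept). When ``group_size``
    is given, both fluid groups must have exactly that many samples.
    """
    plasma = table.fluid_samples("plasma")
    sf = table.fluid_samples("SF")
    if group_size is not None and (len(plasma) != group_size or len(sf) != group_size):
        raise ConfigurationError(
            f"group_size={group_size} but metadata has {len(plasma)} plasma and "
            f"{len(sf)} SF samples"
        )
    detected = table.peptides > 0
    keep = (detected[plasma].sum(axis=1) >= min_samples) | (
        detected[sf].sum(axis=1) >= min_samples
    )
    return table.subset(table.lfq.index[keep])


def impute_missing(table: ProteinQuantTable) -> ProteinQuantTable:
    """Replace missing LFQ values with the lowest LFQ observed in the table.

    The imputation constant is the global minimum over all genes and samples
    (not a per-gene minimum): a single detection floor for the whole run.
    """
    values = table.lfq.to_numpy(float)
    if not np.isfinite(values).any():
        raise SynofabError("impute_missing: table has no observed LFQ values")
    floor = float(np.nanmin(values))
    out = dataclasses.replace(table, lfq=table.lfq.fillna(floor))
    return out


def filter_for_correlation(
    table: ProteinQuantTable,
    min_lfq: float = DEFAULT_MIN_LFQ,
    ig_variable_genes: Sequence[str] = (),
) -> ProteinQuantTable:
    """Drop immunoglobulin variable-domain entries and never-abundant genes.

    Variable-domain immunoglobulin entries reflect individual antibody clones
    rather than bulk proteins and are removed outright; a remaining gene must
    exceed ``min_lfq`` in at least one sample.
    """
    ig = set(ig_variable_genes)
    keep = [g for g in table.lfq.index if g not in ig]
    sub = table.subset(keep)
    above = (sub.lfq > min_lfq).any(axis=1)
    return sub.subset(sub.lfq.index[above])


def _log10_lfq(table: ProteinQuantTable) -> pd.DataFrame:
    values = table.lfq.where(table.lfq > 0)
    return np.log10(values)


def paired_abundance_correlation(
    table: ProteinQuantTable,
    mode: str = "averaged",
    log: bool = True,
) -> dict:
    """Plasma-vs-SF Pearson correlation of protein abundances.

    ``averaged`` mode correlates, per gene, the mean log10 LFQ over plasma
    samples against the mean over SF samples (one coefficient); ``per_patient``
    mode computes one coefficient per patient on that patient's paired
    samples. ``log=False`` correlates raw LFQ values instead.

    Returns a dict with ``r`` (float, or Series per patient) and ``pairs``
    (the gene-level value pairs behind each coefficient).
    """
    if mode not in ("averaged", "per_patient"):
        raise ConfigurationError(f"mode must be 'averaged' or 'per_patient', got {mode!r}")
    data = _log10_lfq(table) if log else table.lfq
    if len(data) < 3:
        raise SynofabError(f"correlation needs >= 3 genes, got {len(data)}")
    plasma = table.fluid_samples("plasma")
    sf = table.fluid_samples("SF")
    if mode == "averaged":
        pairs = pd.DataFrame(
            {"plasma": data[plasma].mean(axis=1), "SF": data[sf].mean(axis=1)}
        ).dropna()
        r = float(stats.pearsonr(pairs["plasma"], pairs["SF"]).statistic)
        return {"r": r, "pairs": pairs}
    rs: dict[str, float] = {}
    pairs_by_patient: dict[str, pd.DataFrame] = {}
    for patient, grp in table.samples.groupby("patient"):
        p = [s for s in grp.index if grp.loc[s, "fluid"] == "plasma" and s in data.columns]
        s = [s for s in grp.index if grp.loc[s, "fluid"] == "SF" and s in data.columns]
        if len(p) != 1 or len(s) != 1:
            raise ConfigurationError(
                f"per_patient mode needs one plasma and one SF sample for patient {patient!r}"
            )
        pp = pd.DataFrame({"plasma": data[p[0]], "SF": data[s[0]]}).dropna()
        rs[str(patient)] = float(stats.pearsonr(pp["plasma"], pp["SF"]).statistic)
        pairs_by_patient[str(patient)] = pp
    return {"r": pd.Series(rs), "pairs": pairs_by_patient}


def normalized_abundance(values: Sequence[float] | pd.Series) -> np.ndarray:
    """Min-max normalize a gene's abundances across samples into [0, 1].

    Subtracts the minimum and divides by the range, so the smallest value maps
    to 0 and the largest to 1; constant input has no defined normalization.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise SynofabError("normalized_abundance needs >= 2 samples")
    rng = np.nanmax(x) - np.nanmin(x)
    if rng == 0 or not np.isfinite(rng):
        raise SynofabError("normalized_abundance: constant vector has no defined normalization")
    return (x - np.nanmin(x)) / rng


def _validate_category_map(cat_map: Mapping[str, str] | pd.Series) -> pd.Series:
    series = pd.Series(dict(cat_map) if not isinstance(cat_map, pd.Series) else cat_map, dtype=object)
    bad = sorted(set(series) - set(CATEGORIES))
    if bad:
        raise FormatError(
            f"category map contains labels outside the seven admissible categories: {bad}"
        )
    return series


def categorize(table: ProteinQuantTable, cat_map: Mapping[str, str] | pd.Series) -> ProteinQuantTable:
    """Attach one of the seven category labels to every gene.

    Genes absent from the map default to ``noncategorized``; a map entry with
    a label outside :data:`CATEGORIES` is a format error.
    """
    series = _validate_category_map(cat_map)
    labels = series.reindex(table.lfq.index).fillna("noncategorized")
    labels.name = "category"
    return dataclasses.replace(table, categories=labels)


def category_summary(table: ProteinQuantTable) -> pd.DataFrame:
    """Per-category gene counts and per-fluid mean log10 abundance.

    Also reports ``sf_minus_plasma_log10``, the SF-enrichment of each category
    in log units (positive for SF-enriched categories).
    """
    if table.categories is None:
        raise SynofabError("table has no category labels; call categorize first")
    data = _log10_lfq(table)
    plasma = table.fluid_samples("plasma")
    sf = table.fluid_samples("SF")
    rows = []
    for cat in CATEGORIES:
        genes = table.categories.index[table.categories == cat]
        genes = [g for g in genes if g in data.index]
        if not genes:
            continue
        mp = float(data.loc[genes, plasma].mean(axis=None))
        ms = float(data.loc[genes, sf].mean(axis=None))
        rows.append(
            {
                "category": cat,
                "n_genes": len(genes),
                "mean_log10_plasma": mp,
                "mean_log10_sf": ms,
                "sf_minus_plasma_log10": ms - mp,
            }
        )
    return pd.DataFrame(rows).set_index("category")


def size_stratified_correlation(
    table: ProteinQuantTable,
    mw_annotations: pd.DataFrame,
    bins_kda: Mapping[str, tuple[float, float]] = DEFAULT_SIZE_BINS_KDA,
    min_genes: int = 3,
) -> dict:
    """Plasma-vs-SF correlation within molecular-weight strata.

    Each annotated gene is assigned to a stratum by its assembly molecular
    weight (the mass of the functional multimer, e.g. pentameric IgM) when
    present, else its monomer weight. Per stratum, Pearson r is computed on
    patient-averaged log10 abundances; strata with fewer than ``min_genes``
    genes report NaN. Genes whose effective mass falls between strata are
    excluded and listed.

    Parameters
    ----------
    mw_annotations
        Indexed by gene with columns ``monomer_kda`` and optionally
        ``assembly_kda``.
    """
    data = _log10_lfq(table)
    plasma = table.fluid_samples("plasma")
    sf = table.fluid_samples("SF")
    x = data[plasma].mean(axis=1)
    y = data[sf].mean(axis=1)

    effective = mw_annotations.get("assembly_kda")
    mono = mw_annotations["monomer_kda"]
    if effective is None:
        eff = mono.astype(float)
    else:
        eff = effective.astype(float).fillna(mono.astype(float))

    annotated = [g for g in eff.index if g in data.index and np.isfinite(eff[g])]
    assigned: dict[str, list[str]] = {name: [] for name in bins_kda}
    excluded: list[str] = []
    for g in annotated:
        kda = float(eff[g])
        for name, (lo, hi) in bins_kda.items():
            if lo <= kda <= hi:
                assigned[name].append(g)
                break
        else:
            excluded.append(g)

    result: dict[str, dict] = {}
    for name, genes in assigned.items():
        if len(genes) < min_genes:
            result[name] = {"r": float("nan"), "genes": genes}
            continue
        r = float(stats.pearsonr(x.loc[genes], y.loc[genes]).statistic)
        result[name] = {"r": r, "genes": genes}
    return {"bins": result, "excluded": excluded}
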
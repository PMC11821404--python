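"""Readers and writers for the pipeline's table contracts.

All interchange formats are plain text: component tables as CSV with the
header ``sample_id,mass_da,rt_min,sum_intensity,score,top_cs_mz`` (a
column-name mapping adapts vendor deconvolution exports), the LFQ table as
TSV with ``unique_peptides.<sample>`` and ``lfq.<sample>`` column pairs,
category maps and molecular-weight annotations as two/three-column TSV, and
matrices/reports as TSV/JSON.
"""

from __future__ import annotations

import importlib.resources
import json
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .fab_core import COMPONENT_COLUMNS, FabClone, catalog_to_frame
from .fab_quant import Repertoire
from .proteome_compare import ProteinQuantTable

__all__ = [
    "read_component_csv",
    "write_component_csv",
    "read_lfq_tsv",
    "write_lfq_tsv",
    "read_sample_meta",
    "write_sample_meta",
    "read_category_map",
    "read_size_annotations",
    "default_size_annotations",
    "write_clone_catalog",
    "write_repertoires",
    "write_matrix_tsv",
    "write_json",
]


def read_component_csv(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read one deconvolution component table.

    ``column_map`` maps canonical names to the file's column names, e.g.
    ``{"mass_da": "Average Mass", "rt_min": "Apex RT"}`` for a
    BioPharmaFinder-style export; unmapped canonical names are looked up
    as-is. A missing ``sample_id`` column is filled from the file stem.
    """
    df = pd.read_csv(path)
    if column_map:
        rename = {src: dst for dst, src in column_map.items() if src in df.columns}
        df = df.rename(columns=rename)
    if "sample_id" not in df.columns:
        df["sample_id"] = Path(path).stem
    missing = [c for c in COMPONENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: component table lacks columns {missing}")
    return df[COMPONENT_COLUMNS].copy()


def write_component_csv(components: pd.DataFrame, path) -> None:
    """Write a component table under the canonical header (extra columns dropped)."""
    components[COMPONENT_COLUMNS].to_csv(path, index=False)


def write_lfq_tsv(table: ProteinQuantTable, path) -> None:
    samples = list(table.lfq.columns)
    out = pd.DataFrame(index=table.lfq.index)
    for s in samples:
        out[f"unique_peptides.{s}"] = table.peptides[s]
    for s in samples:
        out[f"lfq.{s}"] = table.lfq[s]
    out.index.name = "gene"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_lfq_tsv(path, sample_meta: pd.DataFrame) -> ProteinQuantTable:
    """Read a genes x samples LFQ table with unique-peptide counts.

    Malformed numeric cells are reported with their 1-based line number.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA", ""], index_col="gene")
    pep_cols = [c for c in raw.columns if c.startswith("unique_peptides.")]
    lfq_cols = [c for c in raw.columns if c.startswith("lfq.")]
    if not pep_cols or not lfq_cols:
        raise FormatError(f"{path}: expected 'unique_peptides.<sample>' and 'lfq.<sample>' columns")
    samples = [c.removeprefix("lfq.") for c in lfq_cols]
    if set(samples) != {c.removeprefix("unique_peptides.") for c in pep_cols}:
        raise FormatError(f"{path}: peptide and LFQ sample columns disagree")

    def numeric(cols: list[str], prefix: str) -> pd.DataFrame:
        block = raw[cols]
        conv = block.apply(pd.to_numeric, errors="coerce")
        bad = conv.isna() & block.notna()
        if bad.to_numpy().any():
            gene = bad.index[bad.any(axis=1)][0]
            line = int(raw.index.get_loc(gene)) + 2  # header is line 1
            raise FormatError(f"{path}: malformed {prefix} value at line {line} (gene {gene})")
        conv.columns = [c.split(".", 1)[1] for c in cols]
        return conv

    lfq = numeric(lfq_cols, "LFQ")
    peptides = numeric(pep_cols, "unique-peptide")[lfq.columns].fillna(0).astype(int)
    return ProteinQuantTable(lfq=lfq, peptides=peptides, samples=sample_meta.loc[lfq.columns])


def write_sample_meta(sample_meta: pd.DataFrame, path) -> None:
    payload = sample_meta.reset_index().to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def read_sample_meta(path) -> pd.DataFrame:
    with open(path) as fh:
        payload = json.load(fh)
    df = pd.DataFrame(payload)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: sample metadata lacks 'sample_id'")
    return df.set_index("sample_id")


def read_category_map(path) -> pd.Series:
    """Read a two-column (gene, category) TSV; labels validated by categorize()."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["gene", "category"], dtype=str)
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise FormatError(f"{path}: duplicate gene {dup!r} in category map")
    return df.set_index("gene")["category"]


def read_size_annotations(path) -> pd.DataFrame:
    """Read gene molecular-weight annotations (monomer_kda, optional assembly_kda)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene" not in df.columns or "monomer_kda" not in df.columns:
        raise FormatError(f"{path}: size annotations need 'gene' and 'monomer_kda' columns")
    if "assembly_kda" not in df.columns:
        df["assembly_kda"] = np.nan
    return df.set_index("gene")[["monomer_kda", "assembly_kda"]].astype(float)


def default_size_annotations() -> pd.DataFrame:
    """Packaged molecular-weight annotations for the size-stratified analysis."""
    ref = importlib.resources.files("synofab.data") / "size_annotations.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_size_annotations(p)


def write_clone_catalog(clones: Sequence[FabClone], path, sample_ids: Sequence[str] | None = None) -> None:
    catalog_to_frame(clones, sample_ids).to_csv(path, sep="\t", index=False)


def write_repertoires(repertoires: Mapping[str, Repertoire], path) -> None:
    rows = []
    for rep in repertoires.values():
        for cid, r in rep.clones.iterrows():
            rows.append(
                {
                    "patient": rep.patient,
                    "fluid": rep.fluid,
                    "clone_id": cid,
                    "consensus_mass_da": r["mass_da"],
                    "consensus_rt_min": r["rt_min"],
                    "conc_ug_ml": r["conc_ug_ml"],
                }
            )
    pd.DataFrame(
        rows,
        columns=["patient", "fluid", "clone_id", "consensus_mass_da", "consensus_rt_min", "conc_ug_ml"],
    ).to_csv(path, sep="\t", index=False)


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
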
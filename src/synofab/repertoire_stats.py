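"""Repertoire-level statistics: overlap, correlation structure, paired regression.

Given quantified per-sample IgG1 Fab repertoires (plasma and synovial fluid of
the same patients), this module computes the summaries used to compare
repertoires within and between patients:

* pairwise overlap percentages (share of one sample's clones re-found in
  another sample within the mass/RT matching windows),
* Pearson correlation matrices of log10 clone concentrations over the union
  of each pair's clones, with absences imputed at a detection-floor constant
  (default 0.01 ug/ml),
* ordinary least-squares regression of log10 SF concentration on log10 plasma
  concentration for a paired sample,
* top-N clone contribution summaries and concentration-weighted mass
  profiles.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SynofabError
from .fab_core import MASS_MAX_DA, MASS_MIN_DA, ToleranceModel
from .fab_quant import Repertoire

__all__ = [
    "DEFAULT_IMPUTE_UG_ML",
    "RegressionResult",
    "overlap_matrix",
    "repertoire_correlation_matrix",
    "paired_fluid_regression",
    "top_contributions",
    "mass_profile",
]

#: Concentration imputed for a clone absent from one fluid (detection floor).
DEFAULT_IMPUTE_UG_ML = 0.01


def _clone_positions(rep: Repertoire) -> tuple[np.ndarray, np.ndarray]:
    return rep.clones["mass_da"].to_numpy(float), rep.clones["rt_min"].to_numpy(float)


def overlap_matrix(
    repertoires: Sequence[Repertoire],
    tol: ToleranceModel,
    intensity_weighted: bool = False,
) -> pd.DataFrame:
    """Pairwise repertoire overlap, in percent.

    Entry (A, B) is the percentage of A's clones matched in B, a clone of A
    counting as matched when some clone of B lies within the mass and RT
    windows. The matrix is not symmetric in general (|A| != |B|); the diagonal
    is forced to 100. An empty repertoire yields NaN entries in its row.

    With ``intensity_weighted=True`` clones are weighted by concentration
    instead of counted, giving the share of A's total concentration that is
    matched in B.
    """
    ids = [r.sample_id for r in repertoires]
    out = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    pos = [_clone_positions(r) for r in repertoires]
    for i, a in enumerate(repertoires):
        ma, ra = pos[i]
        if ma.size == 0:
            continue
        w = a.clones["conc_ug_ml"].to_numpy(float) if intensity_weighted else np.ones(ma.size)
        for j, _b in enumerate(repertoires):
            if i == j:
                out.iloc[i, j] = 100.0
                continue
            mb, rb = pos[j]
            if mb.size == 0:  # undefined comparison, reported as missing
                continue
            dm = np.abs(ma[:, None] - mb[None, :]) <= tol.window_mass_da
            dr = np.abs(ra[:, None] - rb[None, :]) <= tol.window_rt_min
            matched = (dm & dr).any(axis=1)
            total = w.sum()
            out.iloc[i, j] = 100.0 * float(w[matched].sum()) / float(total) if total > 0 else np.nan
    return out


def _log_conc_union(
    a: Mapping[int, float] | pd.Series,
    b: Mapping[int, float] | pd.Series,
    impute: float,
) -> tuple[np.ndarray, np.ndarray]:
    sa = pd.Series(dict(a) if not isinstance(a, pd.Series) else a, dtype=float)
    sb = pd.Series(dict(b) if not isinstance(b, pd.Series) else b, dtype=float)
    union = sa.index.union(sb.index)
    xa = sa.reindex(union).fillna(impute).to_numpy()
    xb = sb.reindex(union).fillna(impute).to_numpy()
    return np.log10(xa), np.log10(xb)


def repertoire_correlation_matrix(
    repertoires: Sequence[Repertoire],
    impute_ug_ml: float = DEFAULT_IMPUTE_UG_ML,
    min_union: int = 3,
) -> pd.DataFrame:
    """Concentration-based Pearson correlation of repertoires.

    For each sample pair the correlation is computed on log10 concentrations
    over the union of the pair's clones (matched by catalog clone id, i.e. by
    the tolerance windows used during clustering); a clone absent from one
    sample takes the imputation constant. Symmetric with unit diagonal; a pair
    with fewer than ``min_union`` union clones is reported as NaN.
    """
    if impute_ug_ml <= 0:
        raise SynofabError("imputation constant must be > 0 ug/ml")
    ids = [r.sample_id for r in repertoires]
    conc = [r.concentrations for r in repertoires]
    out = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    for i in range(len(repertoires)):
        out.iloc[i, i] = 1.0
        for j in range(i + 1, len(repertoires)):
            x, y = _log_conc_union(conc[i], conc[j], impute_ug_ml)
            if x.size < min_union or np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r = float(stats.pearsonr(x, y).statistic)
            out.iloc[i, j] = out.iloc[j, i] = r
    return out


@dataclasses.dataclass(frozen=True)
class RegressionResult:
    """OLS fit of log10 SF concentration on log10 plasma concentration."""

    r2: float
    slope: float
    intercept: float
    pvalue: float
    n: int


def paired_fluid_regression(
    plasma: Repertoire,
    sf: Repertoire,
    impute_ug_ml: float = DEFAULT_IMPUTE_UG_ML,
) -> RegressionResult:
    """Regress a patient's SF repertoire on its plasma repertoire (log10 scale).

    The regression runs over the union of the pair's clones with absences
    imputed; the p-value is the two-sided t-test on the slope.

    Raises
    ------
    SynofabError
        If the patients differ, the union has fewer than 3 clones, or the
        plasma (predictor) concentrations are constant after imputation.
    """
    if plasma.patient != sf.patient:
        raise SynofabError(
            f"paired regression requires one patient, got {plasma.patient!r} and {sf.patient!r}"
        )
    x, y = _log_conc_union(plasma.concentrations, sf.concentrations, impute_ug_ml)
    if x.size < 3:
        raise SynofabError(f"paired regression needs >= 3 union clones, got {x.size}")
    if np.ptp(x) == 0:
        raise SynofabError("degenerate regression: constant plasma concentrations")
    fit = stats.linregress(x, y)
    return RegressionResult(
        r2=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pvalue=float(fit.pvalue),
        n=int(x.size),
    )


def top_contributions(repertoire: Repertoire, n: int = 10) -> pd.DataFrame:
    """Fractional contribution of the most concentrated clones.

    Returns the ``n`` most abundant clones with their fraction of the total
    concentration, plus a ``remainder`` row pooling everything else; fractions
    sum to 1. Concentration ties are broken toward the lower consensus mass.
    """
    if len(repertoire) == 0:
        raise SynofabError("top_contributions: empty repertoire")
    df = repertoire.clones.sort_values(
        ["conc_ug_ml", "mass_da"], ascending=[False, True], kind="stable"
    )
    total = float(df["conc_ug_ml"].sum())
    if total <= 0:
        raise SynofabError("top_contributions: total concentration is zero")
    head = df.head(n)
    rows = [
        {"clone_id": cid, "conc_ug_ml": float(r["conc_ug_ml"]), "fraction": float(r["conc_ug_ml"]) / total}
        for cid, r in head.iterrows()
    ]
    rest = float(df["conc_ug_ml"].iloc[n:].sum())
    if len(df) > n:
        rows.append({"clone_id": "remainder", "conc_ug_ml": rest, "fraction": rest / total})
    return pd.DataFrame(rows)


def mass_profile(
    repertoire: Repertoire,
    bin_width_da: float = 100.0,
    mass_range_da: tuple[float, float] = (MASS_MIN_DA, MASS_MAX_DA),
) -> pd.DataFrame:
    """Concentration-weighted histogram of clone masses.

    Bins are half-open ``[start, end)`` (numpy convention; the final bin is
    closed) over the Fab mass window, so a mass on an interior edge counts
    once. Total weight equals the summed concentration of clones inside the
    range.
    """
    if len(repertoire) == 0:
        raise SynofabError("mass_profile: empty repertoire")
    if bin_width_da <= 0:
        raise SynofabError(f"mass_profile: bin width must be > 0 Da, got {bin_width_da}")
    lo, hi = mass_range_da
    edges = np.arange(lo, hi + bin_width_da, bin_width_da)
    if edges[-1] < hi:
        edges = np.append(edges, edges[-1] + bin_width_da)
    weights, _ = np.histogram(
        repertoire.clones["mass_da"].to_numpy(float),
        bins=edges,
        weights=repertoire.clones["conc_ug_ml"].to_numpy(float),
    )
    return pd.DataFrame(
        {"bin_start_da": edges[:-1], "bin_end_da": edges[1:], "weight_ug_ml": weights}
    )
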
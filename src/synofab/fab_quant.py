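"""Internal-standard identification and conversion of clone intensities to ug/ml.

Every sample receives a 1:1 spike of two recombinant mAbs (by default
trastuzumab and alemtuzumab) before Fab generation. After cross-sample
clustering the spiked standards appear in the catalog as two clones at known
(mass, RT); their per-sample intensities anchor the conversion from summed
intensity to concentration:

    conc [ug/ml] = (I_clone / mean(I_standards)) * spike_ng_per_mab
                   / volume_ml / 1000

so a clone as intense as the average standard at a 200 ng per-mAb spike and
0.1 ml applied fluid reads 2.0 ug/ml. The standards are then removed from the
repertoire. Reference (therapeutic) mAbs such as adalimumab are traced by
their distinctive mass and RT against the quantified repertoire.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import QuantificationError
from .fab_core import FabClone, ToleranceModel

__all__ = [
    "StandardMab",
    "StandardReport",
    "Repertoire",
    "identify_standards",
    "quantify_clone",
    "quantify_repertoires",
    "find_reference_clone",
]


@dataclasses.dataclass(frozen=True)
class StandardMab:
    """One spiked standard: expected Fab mass/RT and the per-mAb spike amount."""

    name: str
    mass_da: float
    rt_min: float
    spike_ng: float


@dataclasses.dataclass
class StandardReport:
    """Outcome of standard identification across the clone catalog.

    ``intensities`` is a standards x samples table (NaN where a standard was
    not observed in a sample); ``mean_intensity`` is the per-sample arithmetic
    mean over the standards (the quantification denominator); samples listed
    in ``invalid_samples`` are missing at least one standard and must not be
    quantified silently.
    """

    matched_clone_ids: dict[str, list[int]]
    intensities: pd.DataFrame
    mean_intensity: pd.Series
    invalid_samples: dict[str, list[str]]
    geometric_mean: bool = False

    def is_valid(self, sample_id: str) -> bool:
        return sample_id not in self.invalid_samples


@dataclasses.dataclass
class Repertoire:
    """Quantified clone repertoire of one (patient, fluid) sample.

    ``clones`` is indexed by catalog clone_id with columns ``mass_da``,
    ``rt_min``, ``intensity`` and ``conc_ug_ml``; spiked standards are absent.
    """

    sample_id: str
    patient: str
    fluid: str
    volume_ml: float
    clones: pd.DataFrame

    def __post_init__(self) -> None:
        if self.fluid not in ("plasma", "SF"):
            raise ValueError(f"fluid must be 'plasma' or 'SF', got {self.fluid!r}")

    @property
    def concentrations(self) -> pd.Series:
        return self.clones["conc_ug_ml"]

    def __len__(self) -> int:
        return len(self.clones)


def identify_standards(
    clones: Sequence[FabClone],
    standards: Sequence[StandardMab],
    tol: ToleranceModel,
    sample_ids: Sequence[str],
    geometric_mean: bool = False,
) -> tuple[StandardReport, list[FabClone]]:
    """Locate the spiked standards in the catalog and subtract them.

    Matching is per sample: in each sample, each standard is matched to at
    most one clone that has a member in that sample within the matching
    windows of the expected (mass, RT) — nearest by member |Δmass| then |Δrt|
    — and within one sample no clone serves two standards. Every clone that
    answered for a standard anywhere is removed from the returned catalog.
    A sample in which any standard finds no member is recorded in
    ``invalid_samples`` (an explicit error record, never a silent zero).
    """
    intensities = pd.DataFrame(
        np.nan, index=[s.name for s in standards], columns=list(sample_ids), dtype=float
    )
    std_clone_ids: dict[str, set[int]] = {s.name: set() for s in standards}
    taken_all: set[int] = set()
    for sid in sample_ids:
        taken: set[int] = set()
        for std in standards:
            best: tuple[float, float, int, float] | None = None
            for c in clones:
                if c.clone_id in taken:
                    continue
                m = c.members.get(str(sid))
                if m is None:
                    continue
                dm = abs(m[0] - std.mass_da)
                dr = abs(m[1] - std.rt_min)
                if dm <= tol.window_mass_da and dr <= tol.window_rt_min:
                    key = (dm, dr, c.clone_id, m[2])
                    if best is None or key[:3] < best[:3]:
                        best = key
            if best is not None:
                taken.add(best[2])
                taken_all.add(best[2])
                std_clone_ids[std.name].add(best[2])
                intensities.loc[std.name, sid] = best[3]
    matched: dict[str, list[int]] = {k: sorted(v) for k, v in std_clone_ids.items()}

    invalid: dict[str, list[str]] = {}
    for sid in sample_ids:
        missing = [s.name for s in standards if not np.isfinite(intensities.loc[s.name, sid])]
        if missing:
            invalid[sid] = missing
    if geometric_mean:
        mean = np.exp(np.log(intensities).mean(axis=0))
    else:
        mean = intensities.mean(axis=0)
    report = StandardReport(matched, intensities, mean, invalid, geometric_mean)
    remaining = [c for c in clones if c.clone_id not in taken_all]
    return report, remaining


def quantify_clone(
    intensity: float,
    mean_std_intensity: float,
    spike_ng_per_mab: float,
    volume_ml: float,
) -> float:
    """Convert one clone intensity to ug/ml via the standard spike.

    Linear in intensity, inverse in applied volume; global intensity scale
    cancels because the standard mean scales with it.
    """
    if not mean_std_intensity > 0:
        raise QuantificationError(
            f"mean standard intensity must be > 0, got {mean_std_intensity}"
        )
    if not volume_ml > 0:
        raise QuantificationError(f"applied volume must be > 0 ml, got {volume_ml}")
    ng_per_ml = (intensity / mean_std_intensity) * spike_ng_per_mab / volume_ml
    return ng_per_ml / 1000.0


def quantify_repertoires(
    clones: Sequence[FabClone],
    report: StandardReport,
    sample_meta: pd.DataFrame,
    spike_ng_per_mab: float,
) -> dict[str, Repertoire]:
    """Build per-sample quantified repertoires from a standard-free catalog.

    Parameters
    ----------
    clones
        Catalog with standards already removed (see :func:`identify_standards`).
    sample_meta
        Indexed by sample_id with columns ``patient``, ``fluid``, ``volume_ml``.

    Samples flagged invalid in the standard report are skipped: their
    quantification is undefined, and the caller decides how to surface the
    error records.
    """
    out: dict[str, Repertoire] = {}
    for sid, meta in sample_meta.iterrows():
        if not report.is_valid(str(sid)):
            continue
        denom = float(report.mean_intensity[sid])
        rows = []
        for c in clones:
            m = c.members.get(str(sid))
            if m is None:
                continue
            mass, rt, inten = m
            rows.append(
                {
                    "clone_id": c.clone_id,
                    "mass_da": mass,
                    "rt_min": rt,
                    "intensity": inten,
                    "conc_ug_ml": quantify_clone(
                        inten, denom, spike_ng_per_mab, float(meta["volume_ml"])
                    ),
                }
            )
        frame = pd.DataFrame(
            rows, columns=["clone_id", "mass_da", "rt_min", "intensity", "conc_ug_ml"]
        ).set_index("clone_id")
        out[str(sid)] = Repertoire(
            sample_id=str(sid),
            patient=str(meta["patient"]),
            fluid=str(meta["fluid"]),
            volume_ml=float(meta["volume_ml"]),
            clones=frame,
        )
    return out


def find_reference_clone(
    repertoire: Repertoire,
    reference: Mapping[str, float],
    tol: ToleranceModel,
    exclude: set[int] | None = None,
) -> pd.Series | None:
    """Trace a reference (therapeutic) mAb in a quantified repertoire.

    Returns the clone row (with ``conc_ug_ml``) of highest concentration
    within the matching windows of the reference ``mass_da``/``rt_min``, or
    ``None`` when absent. Pass ``exclude`` (clone ids already claimed) when
    querying several references so no clone answers twice.
    """
    df = repertoire.clones
    mask = (df["mass_da"].sub(float(reference["mass_da"])).abs() <= tol.window_mass_da) & (
        df["rt_min"].sub(float(reference["rt_min"])).abs() <= tol.window_rt_min
    )
    if exclude:
        mask &= ~df.index.isin(list(exclude))
    hits = df.loc[mask]
    if hits.empty:
        return None
    return hits.loc[hits["conc_ug_ml"].idxmax()]
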
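"""Synthetic paired plasma / synovial-fluid cohorts with known ground truth.

Real cohorts of this kind consist of (1) per-run intact-Fab deconvolution
component tables — a few hundred (~140-450) IgG1 clones per sample with
log-normal concentrations spanning roughly 0.1 to beyond 100 ug/ml, high
clone sharing between the plasma and SF of one patient and near-zero sharing
between patients, plus two spiked standard mAbs per sample — and (2) a bulk
LFQ protein table where plasma-protein abundances span ~4 orders of magnitude
and correlate between the fluids, while cartilage, neutrophil and generic
cellular proteins appear only in SF.

The generator emulates exactly that regime at the deconvolution-output level
(no spectra or peak shapes) and records the full ground truth, so every
downstream stage — filtering, tolerance calibration, clustering, spike-in
quantification, overlap/correlation statistics and the proteome analyses —
is testable by parameter recovery.

Intensity model: the emitted summed intensity of a clone with true
concentration ``c`` [ug/ml] in a sample with applied volume ``v`` [ml] is

    I = c * 1000 * v / spike_ng_per_mab * S * eta

where ``S`` is the base intensity of a standard spike and ``eta`` a unit-mean
log-normal factor with coefficient of variation ``intensity_cv``. This is the
exact inverse of the spike-in quantification formula, so quantification
recovers ``c`` up to ``eta`` and the (smaller) noise on the standards.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from typing import Any

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .proteome_compare import ProteinQuantTable

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "ground_truth_repertoires",
    "inject_therapeutic",
    "intensity_cv_for_target_log_r",
    "proteome_noise_sd_for_target_r",
]

SF_ONLY_CATEGORIES = ("cartilage", "neutrophil", "generic_cell")


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int | None = None):
    """Unit-mean multiplicative log-normal noise with coefficient of variation cv."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of the synthetic paired-fluid cohort.

    Defaults reproduce the study regime: nine patients, 140-450 clones per
    sample, 90% clone sharing between a patient's plasma and SF, none between
    patients, heavy-tailed clone concentrations, and two standard mAbs spiked
    1:1 into every sample.
    """

    n_patients: int = 9
    clones_per_sample_range: tuple[int, int] = (140, 450)
    shared_fraction_within_patient: float = 0.9
    shared_fraction_between_patients: float = 0.0
    log10_conc_mean: float = 0.3
    log10_conc_sd: float = 1.0
    mass_range_da: tuple[float, float] = (46_000.0, 51_000.0)
    rt_range_min: tuple[float, float] = (12.0, 40.0)
    sigma_mass_da: float = 1.5
    sigma_rt_min: float = 0.05
    intensity_cv: float = 0.2
    std_intensity_cv: float = 0.05
    clone_dropout_rate: float = 0.0
    standard_mabs: tuple[Mapping[str, float], ...] = (
        {"name": "trastuzumab", "mass_da": 47_637.0, "rt_min": 20.0, "spike_ng": 200.0},
        {"name": "alemtuzumab", "mass_da": 47_176.0, "rt_min": 23.5, "spike_ng": 200.0},
    )
    volume_ml_plasma: float = 0.01
    volume_ml_sf: float = 0.05
    std_base_intensity: float = 1e8
    proteome_params: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "n_plasma_proteins": 300,
            "n_sf_only_proteins_per_category": 20,
            "log10_lfq_mean": 7.0,
            "log10_lfq_sd": 1.0,
            "plasma_sf_log_noise_sd": 0.3,
            "missing_rate": 0.05,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        lo, hi = self.clones_per_sample_range
        if not (0 < lo <= hi):
            raise ConfigurationError("clones_per_sample_range must satisfy 0 < min <= max")
        for name in ("shared_fraction_within_patient", "shared_fraction_between_patients",
                     "clone_dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("log10_conc_sd", "sigma_mass_da", "sigma_rt_min", "intensity_cv",
                     "std_intensity_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("mass_range_da", "rt_range_min"):
            a, b = getattr(self, name)
            if not a <= b:
                raise ConfigurationError(f"{name} must be ordered low <= high")
        if len(self.standard_mabs) < 1:
            raise ConfigurationError("standard_mabs must list at least one standard")
        spikes = {float(m["spike_ng"]) for m in self.standard_mabs}
        if len(spikes) != 1:
            raise ConfigurationError("standard_mabs: spike_ng must be equal (1:1 mix)")
        for name in ("volume_ml_plasma", "volume_ml_sf", "std_base_intensity"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        pp = self.proteome_params
        for key in ("n_plasma_proteins", "n_sf_only_proteins_per_category",
                    "log10_lfq_mean", "log10_lfq_sd", "plasma_sf_log_noise_sd",
                    "missing_rate"):
            if key not in pp:
                raise ConfigurationError(f"proteome_params missing field {key!r}")
        if not 0.0 <= float(pp["missing_rate"]) < 1.0:
            raise ConfigurationError("proteome_params.missing_rate must lie in [0, 1)")

    @property
    def spike_ng_per_mab(self) -> float:
        return float(self.standard_mabs[0]["spike_ng"])

    @property
    def spike_ng_total(self) -> float:
        return self.spike_ng_per_mab * len(self.standard_mabs)


@dataclasses.dataclass
class GroundTruth:
    """True clone and protein registries behind a synthetic cohort.

    ``clones`` has one row per true clone per patient (uid, true mass/RT,
    true concentration per fluid — NaN where absent — sharing flags and
    emission flags after dropout); ``proteins`` has one row per gene with its
    category and true mean log10 LFQ.
    """

    clones: pd.DataFrame
    proteins: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "clones": self.clones.to_dict(orient="list"),
            "proteins": self.proteins.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, allow_nan=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(pd.DataFrame(payload["clones"]), pd.DataFrame(payload["proteins"]))


@dataclasses.dataclass
class SyntheticCohort:
    """A generated cohort: component tables, LFQ table, metadata, ground truth.

    ``components`` stacks all per-sample deconvolution tables; the
    ``clone_uid`` column traces each row to the ground-truth registry
    (``STD:<name>`` for spiked standards) and is dropped when writing the
    canonical CSV contract.
    """

    components: pd.DataFrame
    lfq: ProteinQuantTable
    sample_meta: pd.DataFrame
    ground_truth: GroundTruth
    config: CohortConfig

    def components_of(self, sample_id: str) -> pd.DataFrame:
        return self.components[self.components["sample_id"] == sample_id].reset_index(drop=True)


def intensity_cv_for_target_log_r(target_r: float, log10_conc_sd: float) -> float:
    """Intensity CV giving a prescribed true plasma-SF log-concentration Pearson r.

    Shared clones carry one true concentration and independent per-fluid
    log-normal intensity noise, so the true correlation of paired log10
    concentrations is ``rho = s^2 / (s^2 + sigma_log^2)`` with ``s`` the clone
    log10-concentration SD. Inverting for the log-normal sigma and converting
    to a CV yields the generator knob for a target ``rho``.
    """
    if not 0 < target_r < 1:
        raise ConfigurationError("target_r must lie in (0, 1)")
    sigma_log10 = log10_conc_sd * np.sqrt((1.0 - target_r) / target_r)
    sigma_ln = sigma_log10 * np.log(10.0)
    return float(np.sqrt(np.expm1(sigma_ln**2)))


def proteome_noise_sd_for_target_r(
    target_r: float, log10_lfq_sd: float, n_per_group: int = 9
) -> float:
    """Per-sample log10 noise SD giving a prescribed patient-averaged Pearson r.

    In averaged mode each fluid's gene value is the mean over ``n`` samples,
    so the noise variance entering the correlation is ``sigma^2 / n`` and
    ``rho = tau^2 / (tau^2 + sigma^2 / n)`` with ``tau`` the gene-level
    log10 SD.
    """
    if not 0 < target_r < 1:
        raise ConfigurationError("target_r must lie in (0, 1)")
    return float(log10_lfq_sd * np.sqrt(n_per_group * (1.0 - target_r) / target_r))


def _emit_component(
    rng: np.random.Generator,
    sample_id: str,
    clone_uid: str,
    mass: float,
    rt: float,
    intensity: float,
    sigma_mass: float,
    sigma_rt: float,
) -> dict[str, Any]:
    obs_mass = mass + (rng.normal(0.0, sigma_mass) if sigma_mass > 0 else 0.0)
    obs_rt = rt + (rng.normal(0.0, sigma_rt) if sigma_rt > 0 else 0.0)
    charge = 25
    return {
        "sample_id": sample_id,
        "mass_da": obs_mass,
        "rt_min": max(obs_rt, 0.0),
        "sum_intensity": intensity,
        "score": float(rng.uniform(60.0, 95.0)),
        "top_cs_mz": obs_mass / charge + 1.007,
        "clone_uid": clone_uid,
    }


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full paired-fluid cohort from a validated configuration.

    Per patient, a per-sample clone count is drawn uniformly from the
    configured range; a binomial share of those clones is present in both
    fluids (with one shared true concentration), the rest are fluid-unique.
    With a nonzero between-patient sharing fraction a clone's identity (mass,
    RT) may be reused from a global pool across patients. Both standard mAbs
    are emitted in every sample with their own, smaller intensity CV. The LFQ
    table pairs plasma-protein abundances across fluids and leaves SF-only
    categories missing in plasma. Fixed seed implies byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.clones_per_sample_range
    mass_lo, mass_hi = config.mass_range_da
    rt_lo, rt_hi = config.rt_range_min

    pool: list[tuple[str, float, float]] = []  # (uid, mass, rt) reusable across patients
    clone_rows: list[dict[str, Any]] = []
    comp_rows: list[dict[str, Any]] = []
    meta_rows: list[dict[str, Any]] = []
    uid_counter = 0

    def new_identity(patient: str) -> tuple[str, float, float, bool]:
        nonlocal uid_counter
        if pool and rng.random() < config.shared_fraction_between_patients:
            uid, m, r = pool[int(rng.integers(len(pool)))]
            return uid, m, r, True
        uid_counter += 1
        uid = f"C{uid_counter:05d}"
        m = float(rng.uniform(mass_lo, mass_hi))
        r = float(rng.uniform(rt_lo, rt_hi))
        pool.append((uid, m, r))
        return uid, m, r, False

    for p in range(1, config.n_patients + 1):
        patient = f"P{p:02d}"
        n_clones = int(rng.integers(lo, hi + 1))
        n_shared = int(rng.binomial(n_clones, config.shared_fraction_within_patient))
        n_unique = n_clones - n_shared
        sample_of = {"plasma": f"{patient}_plasma", "SF": f"{patient}_SF"}
        volume = {"plasma": config.volume_ml_plasma, "SF": config.volume_ml_sf}
        for fluid in ("plasma", "SF"):
            meta_rows.append(
                {
                    "sample_id": sample_of[fluid],
                    "patient": patient,
                    "fluid": fluid,
                    "volume_ml": volume[fluid],
                    "spike_ng_total": config.spike_ng_total,
                }
            )

        specs: list[tuple[str, float, float, bool, bool, bool]] = []
        # (uid, mass, rt, in_plasma, in_sf, shared_between)
        for _ in range(n_shared):
            uid, m, r, between = new_identity(patient)
            specs.append((uid, m, r, True, True, between))
        for _ in range(n_unique):
            uid, m, r, between = new_identity(patient)
            specs.append((uid, m, r, True, False, between))
        for _ in range(n_unique):
            uid, m, r, between = new_identity(patient)
            specs.append((uid, m, r, False, True, between))

        for uid, m, r, in_plasma, in_sf, between in specs:
            conc = float(10.0 ** rng.normal(config.log10_conc_mean, config.log10_conc_sd))
            emitted = {"plasma": False, "SF": False}
            for fluid, present in (("plasma", in_plasma), ("SF", in_sf)):
                if not present:
                    continue
                if config.clone_dropout_rate > 0 and rng.random() < config.clone_dropout_rate:
                    continue
                intensity = (
                    conc
                    * 1000.0
                    * volume[fluid]
                    / config.spike_ng_per_mab
                    * config.std_base_intensity
                    * float(_lognormal_factor(rng, config.intensity_cv))
                )
                comp_rows.append(
                    _emit_component(
                        rng, sample_of[fluid], uid, m, r, intensity,
                        config.sigma_mass_da, config.sigma_rt_min,
                    )
                )
                emitted[fluid] = True
            clone_rows.append(
                {
                    "clone_uid": uid,
                    "patient": patient,
                    "mass_da": m,
                    "rt_min": r,
                    "conc_plasma_ug_ml": conc if in_plasma else np.nan,
                    "conc_sf_ug_ml": conc if in_sf else np.nan,
                    "shared_within": in_plasma and in_sf,
                    "shared_between": between,
                    "emitted_plasma": emitted["plasma"],
                    "emitted_sf": emitted["SF"],
                }
            )

        for fluid in ("plasma", "SF"):
            for mab in config.standard_mabs:
                intensity = config.std_base_intensity * float(
                    _lognormal_factor(rng, config.std_intensity_cv)
                )
                comp_rows.append(
                    _emit_component(
                        rng, sample_of[fluid], f"STD:{mab['name']}",
                        float(mab["mass_da"]), float(mab["rt_min"]), intensity,
                        config.sigma_mass_da, config.sigma_rt_min,
                    )
                )

    components = pd.DataFrame(comp_rows)
    sample_meta = pd.DataFrame(meta_rows).set_index("sample_id")
    lfq_table, protein_truth = _generate_proteome(rng, config, sample_meta)
    truth = GroundTruth(clones=pd.DataFrame(clone_rows), proteins=protein_truth)
    return SyntheticCohort(components, lfq_table, sample_meta, truth, config)


def _generate_proteome(
    rng: np.random.Generator, config: CohortConfig, sample_meta: pd.DataFrame
) -> tuple[ProteinQuantTable, pd.DataFrame]:
    pp = config.proteome_params
    n_plasma = int(pp["n_plasma_proteins"])
    n_sf_cat = int(pp["n_sf_only_proteins_per_category"])
    mu = float(pp["log10_lfq_mean"])
    tau = float(pp["log10_lfq_sd"])
    noise = float(pp["plasma_sf_log_noise_sd"])
    missing_rate = float(pp["missing_rate"])

    samples = list(sample_meta.index)
    sf_samples = [s for s in samples if sample_meta.loc[s, "fluid"] == "SF"]

    genes: list[str] = []
    categories: list[str] = []
    prefix = {"cartilage": "CAR", "neutrophil": "NEU", "generic_cell": "CEL"}
    for i in range(n_plasma):
        genes.append(f"PLA{i + 1:04d}")
        categories.append("plasma")
    for cat in SF_ONLY_CATEGORIES:
        for i in range(n_sf_cat):
            genes.append(f"{prefix[cat]}{i + 1:04d}")
            categories.append(cat)

    n_genes, n_samples = len(genes), len(samples)
    true_log10 = rng.normal(mu, tau, size=n_genes)
    values = true_log10[:, None] + rng.normal(0.0, noise, size=(n_genes, n_samples))
    sf_mask = np.array([s in set(sf_samples) for s in samples])
    plasma_only_missing = np.array([c != "plasma" for c in categories])[:, None] & ~sf_mask[None, :]
    dropout = rng.random((n_genes, n_samples)) < missing_rate
    present = ~(plasma_only_missing | dropout)
    pep_draw = rng.integers(2, 30, size=(n_genes, n_samples))
    lfq = pd.DataFrame(
        np.where(present, 10.0**values, np.nan), index=genes, columns=samples
    )
    peptides = pd.DataFrame(
        np.where(present, pep_draw, 0).astype(int), index=genes, columns=samples
    )

    cat_series = pd.Series(categories, index=genes, name="category")
    table = ProteinQuantTable(lfq=lfq, peptides=peptides, samples=sample_meta[["patient", "fluid"]], categories=cat_series)
    truth = pd.DataFrame(
        {"gene": genes, "category": categories, "true_log10_lfq": true_log10}
    )
    return table, truth


def ground_truth_repertoires(cohort: SyntheticCohort) -> dict[str, "object"]:
    """Quantified per-sample repertoires keyed by *true* clone identity.

    Applies the spike-in quantification formula to the emitted component
    intensities, but resolves clone identity through the generator's tracing
    uids instead of mass/RT window matching. This isolates the statistical
    recovery of repertoire-level estimands (correlations, regressions) from
    window-matching error, which is characterized separately.
    """
    from .fab_quant import Repertoire  # local import to avoid a cycle

    config = cohort.config
    out: dict[str, Repertoire] = {}
    for sid, meta in cohort.sample_meta.iterrows():
        comp = cohort.components_of(str(sid))
        is_std = comp["clone_uid"].str.startswith("STD:")
        mean_std = float(comp.loc[is_std, "sum_intensity"].mean())
        clones = comp.loc[~is_std]
        volume = float(meta["volume_ml"])
        conc = (
            clones["sum_intensity"] / mean_std * config.spike_ng_per_mab / volume / 1000.0
        )
        frame = pd.DataFrame(
            {
                "clone_id": clones["clone_uid"].to_numpy(),
                "mass_da": clones["mass_da"].to_numpy(),
                "rt_min": clones["rt_min"].to_numpy(),
                "intensity": clones["sum_intensity"].to_numpy(),
                "conc_ug_ml": conc.to_numpy(),
            }
        ).set_index("clone_id")
        out[str(sid)] = Repertoire(
            sample_id=str(sid),
            patient=str(meta["patient"]),
            fluid=str(meta["fluid"]),
            volume_ml=volume,
            clones=frame,
        )
    return out


def concentration_recovery_errors(
    cohort: SyntheticCohort,
    repertoires: Mapping[str, "object"],
    window_mass_da: float,
    window_rt_min: float,
    min_true_ug_ml: float = 0.1,
) -> np.ndarray:
    """Relative concentration errors of recovered clones against ground truth.

    Each recovered clone is matched to the nearest true clone of its patient
    (within the given windows); clones without a match or with a true
    concentration below ``min_true_ug_ml`` are skipped. Returns the array of
    ``|recovered - true| / true``.
    """
    errors: list[float] = []
    truth = cohort.ground_truth.clones
    for rep in repertoires.values():
        col = "conc_plasma_ug_ml" if rep.fluid == "plasma" else "conc_sf_ug_ml"
        t = truth[(truth["patient"] == rep.patient) & truth[col].notna()]
        tm = t["mass_da"].to_numpy()
        tr = t["rt_min"].to_numpy()
        tc = t[col].to_numpy()
        for _cid, row in rep.clones.iterrows():
            dm = np.abs(tm - row["mass_da"])
            dr = np.abs(tr - row["rt_min"])
            ok = (dm <= window_mass_da) & (dr <= window_rt_min)
            if not ok.any():
                continue
            cand = np.flatnonzero(ok)
            j = cand[np.argmin(dm[cand] + 1e3 * dr[cand])]
            if tc[j] >= min_true_ug_ml:
                errors.append(abs(row["conc_ug_ml"] - tc[j]) / tc[j])
    return np.asarray(errors)


def inject_therapeutic(
    cohort: SyntheticCohort,
    mab: Mapping[str, float],
    sample_ids: Sequence[str],
) -> SyntheticCohort:
    """Add a systemically administered therapeutic mAb to selected samples.

    The mAb (``name``, ``mass_da``, ``rt_min``, ``conc_ug_ml``) appears as one
    extra component per designated sample, emitted at exactly the intensity
    the cohort's quantification model assigns to its concentration (no extra
    noise, so end-to-end recovery isolates pipeline error). Injecting into
    zero samples returns an identical cohort.
    """
    config = cohort.config
    extra = []
    for sid in sample_ids:
        if sid not in cohort.sample_meta.index:
            raise ConfigurationError(f"sample_ids: unknown sample {sid!r}")
        volume = float(cohort.sample_meta.loc[sid, "volume_ml"])
        intensity = (
            float(mab["conc_ug_ml"])
            * 1000.0
            * volume
            / config.spike_ng_per_mab
            * config.std_base_intensity
        )
        extra.append(
            {
                "sample_id": sid,
                "mass_da": float(mab["mass_da"]),
                "rt_min": float(mab["rt_min"]),
                "sum_intensity": intensity,
                "score": 90.0,
                "top_cs_mz": float(mab["mass_da"]) / 25 + 1.007,
                "clone_uid": f"REF:{mab['name']}",
            }
        )
    if not extra:
        return dataclasses.replace(cohort, components=cohort.components.copy())
    components = pd.concat([cohort.components, pd.DataFrame(extra)], ignore_index=True)
    return dataclasses.replace(cohort, components=components)
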
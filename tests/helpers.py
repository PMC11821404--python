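"""Shared test utilities: independent oracles and small builders."""

from __future__ import annotations

import numpy as np
import pandas as pd

from synofab.fab_quant import Repertoire


def make_repertoire(
    sample_id: str,
    concs: dict,
    patient: str = "P01",
    fluid: str = "plasma",
    masses: dict | None = None,
    rts: dict | None = None,
    volume_ml: float = 0.1,
) -> Repertoire:
    """Build a quantified repertoire from clone_id -> concentration."""
    ids = list(concs)
    frame = pd.DataFrame(
        {
            "clone_id": ids,
            "mass_da": [masses[i] if masses else 48_000.0 + 50.0 * k for k, i in enumerate(ids)],
            "rt_min": [rts[i] if rts else 20.0 for i in ids],
            "intensity": [1.0] * len(ids),
            "conc_ug_ml": [float(concs[i]) for i in ids],
        }
    ).set_index("clone_id")
    return Repertoire(sample_id, patient, fluid, volume_ml, frame)


def brute_force_cluster(components: pd.DataFrame, window_mass: float, window_rt: float):
    """Literal, list-based re-execution of the greedy clustering rule.

    Components in descending intensity (ties: ascending mass); each joins the
    existing clone whose intensity-weighted consensus is within both windows
    and that lacks a member from its sample (ties: smallest |dmass|, then
    smallest |drt|), else founds a new clone. Returns the partition as a list
    of row-index lists.
    """
    rows = list(components.index)
    order = sorted(
        rows,
        key=lambda i: (-components.at[i, "sum_intensity"], components.at[i, "mass_da"]),
    )
    clones = []  # dicts: members(list), samples(set), mass, rt, w
    for i in order:
        m = components.at[i, "mass_da"]
        r = components.at[i, "rt_min"]
        w = components.at[i, "sum_intensity"]
        s = components.at[i, "sample_id"]
        best = None
        for j, cl in enumerate(clones):
            if s in cl["samples"]:
                continue
            dm, dr = abs(cl["mass"] - m), abs(cl["rt"] - r)
            if dm <= window_mass and dr <= window_rt:
                if best is None or (dm, dr) < best[0]:
                    best = ((dm, dr), j)
        if best is None:
            clones.append({"members": [i], "samples": {s}, "mass": m, "rt": r, "w": w})
        else:
            cl = clones[best[1]]
            cl["members"].append(i)
            cl["samples"].add(s)
            tot = cl["w"] + w
            if tot > 0:
                cl["mass"] = (cl["mass"] * cl["w"] + m * w) / tot
                cl["rt"] = (cl["rt"] * cl["w"] + r * w) / tot
            cl["w"] = tot
    return [sorted(cl["members"]) for cl in clones]


def random_components(
    rng: np.random.Generator,
    n: int,
    n_samples: int = 3,
    mass_span: float = 30.0,
    rt_span: float = 1.0,
) -> pd.DataFrame:
    """Random dense component table designed to stress window matching."""
    return pd.DataFrame(
        {
            "sample_id": rng.choice([f"S{k}" for k in range(n_samples)], size=n),
            "mass_da": 48_000.0 + rng.uniform(0, mass_span, size=n),
            "rt_min": 20.0 + rng.uniform(0, rt_span, size=n),
            # strictly distinct intensities keep the processing order unambiguous
            "sum_intensity": rng.uniform(1.0, 100.0, size=n) + np.arange(n) * 1e-3,
            "score": 80.0,
            "top_cs_mz": 1_900.0,
        }
    )


def partition_from_clones(clones, components: pd.DataFrame):
    """Recover the row-index partition from FabClone members.

    Relies on (sample_id, intensity) being unique per row, which
    random_components guarantees.
    """
    lookup = {
        (row["sample_id"], row["sum_intensity"]): idx for idx, row in components.iterrows()
    }
    partition = []
    for c in clones:
        partition.append(
            sorted(lookup[(sid, m[2])] for sid, m in c.members.items())
        )
    return partition


def canonical(partition) -> set:
    return {tuple(p) for p in partition}
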
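"""Class-wise activity profiles and within-class homogeneity testing.

Each library member carries five previously measured biochemical activities:
intrinsic fluorescence (Flu), tetramer formation (Tet), dimer formation
(Dim), peroxidase-mimicking activity (Per) and GTP binding (GTP).  Per-class
means are linearly renormalized to a 0–100 scale (100 = the maximum class
mean for that activity) for radar-plot display, and within-class relative
standard deviation is compared against random same-size groups by a
permutation test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

ACTIVITIES = ("Flu", "Tet", "Dim", "Per", "GTP")

__all__ = [
    "ActivityProfile",
    "class_profiles",
    "profiles_table",
    "rsd_within_class",
    "rsd_random_null",
    "radar_export",
    "write_radar_json",
    "read_radar_json",
]


@dataclass(frozen=True)
class ActivityProfile:
    """Raw and 0–100-renormalized mean activities of one class."""

    class_name: str
    raw_means: dict[str, float]
    renorm: dict[str, float]


def _check_table(t: pd.DataFrame) -> None:
    missing = [c for c in ("class", *ACTIVITIES) if c not in t.columns]
    if missing:
        raise ValueError(f"activity table missing column(s): {missing}")
    if t[list(ACTIVITIES)].isna().any().any():
        raise ValueError("activity table contains missing values")
    if "seq_id" in t.columns and t["seq_id"].duplicated().any():
        raise ValueError("duplicate seq_id in activity table")


def class_profiles(t: pd.DataFrame) -> list[ActivityProfile]:
    """Per-class activity means, renormalized so the top class mean of each
    activity maps to 100 (pure scaling; zero activity stays at zero)."""
    _check_table(t)
    if (t.groupby("class").size() < 1).any():
        raise ValueError("every class needs at least one sequence")
    means = t.groupby("class")[list(ACTIVITIES)].mean()
    col_max = means.max(axis=0)
    renorm = means.copy()
    for act in ACTIVITIES:
        if col_max[act] == 0:
            warnings.warn(f"activity {act} is zero for every class", stacklevel=2)
            renorm[act] = 0.0
        else:
            renorm[act] = 100.0 * means[act] / col_max[act]
    return [
        ActivityProfile(
            class_name=cls,
            raw_means={a: float(means.loc[cls, a]) for a in ACTIVITIES},
            renorm={a: float(renorm.loc[cls, a]) for a in ACTIVITIES},
        )
        for cls in means.index
    ]


def profiles_table(profiles: list[ActivityProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row: dict[str, object] = {"class": p.class_name}
        row.update({f"raw_{a}": p.raw_means[a] for a in ACTIVITIES})
        row.update({f"renorm_{a}": p.renorm[a] for a in ACTIVITIES})
        rows.append(row)
    return pd.DataFrame(rows)


def rsd_within_class(t: pd.DataFrame, class_name: str, activity: str) -> float:
    """Sample SD / mean of one activity within one class."""
    _check_table(t)
    vals = t.loc[t["class"] == class_name, activity].to_numpy(dtype=float)
    if vals.size < 2:
        raise ValueError(f"class {class_name!r} has fewer than 2 members")
    mean = vals.mean()
    if mean == 0:
        raise ValueError(f"mean {activity} of class {class_name!r} is zero")
    return float(vals.std(ddof=1) / mean)


def rsd_random_null(
    t: pd.DataFrame,
    class_name: str,
    activity: str,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Permutation test: is the class more homogeneous than random groups?

    Draws ``n_perm`` random groups of the class's size (without replacement
    within a draw) from the whole table and computes their RSDs.  The
    one-sided p-value is the add-one-smoothed fraction of null RSDs at or
    below the observed within-class RSD; small p means the class is
    unusually uniform.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    observed = rsd_within_class(t, class_name, activity)
    size = int((t["class"] == class_name).sum())
    values = t[activity].to_numpy(dtype=float)
    if size > values.size:
        raise ValueError("class larger than table")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    null_rsds = np.empty(n_perm)
    for i in range(n_perm):
        group = rng.choice(values, size=size, replace=False)
        m = group.mean()
        null_rsds[i] = np.inf if m == 0 else group.std(ddof=1) / m
    p = (1 + int(np.sum(null_rsds <= observed))) / (1 + n_perm)
    return {
        "observed_rsd": observed,
        "null_rsds": null_rsds,
        "p": float(p),
        "class_size": size,
    }


def radar_export(profiles: list[ActivityProfile]) -> list[dict]:
    """Lossless JSON-ready records for radar plotting (one per class,
    five axes each)."""
    return [
        {
            "class": p.class_name,
            "raw_means": dict(p.raw_means),
            "renorm": dict(p.renorm),
        }
        for p in profiles
    ]


def write_radar_json(profiles: list[ActivityProfile], path) -> None:
    with open(path, "w") as fh:
        json.dump(radar_export(profiles), fh, indent=2)


def read_radar_json(path) -> list[ActivityProfile]:
    with open(path) as fh:
        records = json.load(fh)
    return [
        ActivityProfile(
            class_name=r["class"],
            raw_means={a: float(v) for a, v in r["raw_means"].items()},
            renorm={a: float(v) for a, v in r["renorm"].items()},
        )
        for r in records
    ]
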
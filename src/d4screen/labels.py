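"""Converting confirmatory potency measurements into threshold activity labels.

Each molecule x receptor pair is reduced to one consensus potency, then
labelled active / inactive / unknown at the five activity thresholds
1, 10, 100, 1000 and 10,000 nM.  "Active at t" means potency at or below t
(boundary inclusive).  Censored measurements (reported only as "<v" or ">v")
yield unknown labels wherever the bound does not decide the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

RECEPTORS: tuple[str, ...] = ("D2", "D3", "D4", "D5")
THRESHOLDS_NM: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0, 10000.0)

#: Endpoint precedence: binding constants are assay-concentration-independent,
#: so Ki outranks Kd outranks IC50 when a molecule has several endpoints.
ENDPOINT_PRECEDENCE: tuple[str, ...] = ("Ki", "Kd", "IC50")

Qualifier = Literal["eq", "lt", "gt"]
Label = Literal["active", "inactive", "unknown"]


@dataclass(frozen=True)
class ActivityMeasurement:
    """One confirmatory potency observation."""

    mol_id: str
    receptor: str
    endpoint: str
    value_nM: float
    qualifier: Qualifier = "eq"

    def __post_init__(self):
        if self.receptor not in RECEPTORS:
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if self.endpoint not in ENDPOINT_PRECEDENCE:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if not self.value_nM > 0:
            raise ValueError(f"value_nM must be positive, got {self.value_nM}")
        if self.qualifier not in ("eq", "lt", "gt"):
            raise ValueError(f"unknown qualifier {self.qualifier!r}")


@dataclass(frozen=True)
class ConsensusPotency:
    """Aggregated potency for one molecule x receptor."""

    endpoint: str
    value_nM: float
    qualifier: Qualifier
    conflict: bool = False


@dataclass(frozen=True)
class ThresholdLabel:
    mol_id: str
    receptor: str
    threshold_nM: float
    label: Label


def consensus_potency(measurements: Sequence[ActivityMeasurement]) -> ConsensusPotency:
    """Aggregate replicate measurements of one molecule x receptor.

    The highest-precedence endpoint present (Ki > Kd > IC50) is chosen.
    Within it, exact (qualifier ``eq``) values are combined by geometric
    mean, the conventional average for log-normal potencies.  With only
    censored values, the least informative consistent bound is returned:
    the largest ``lt`` bound, or — absent any ``lt`` — the smallest ``gt``
    bound.  A ``lt`` bound at or below a ``gt`` bound is contradictory and
    sets the conflict flag.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValueError("no measurements")
    if len({(m.mol_id, m.receptor) for m in measurements}) > 1:
        raise ValueError("measurements span multiple molecule/receptor pairs")

    for endpoint in ENDPOINT_PRECEDENCE:
        chosen = [m for m in measurements if m.endpoint == endpoint]
        if chosen:
            break

    eq_vals = [m.value_nM for m in chosen if m.qualifier == "eq"]
    lt_vals = [m.value_nM for m in chosen if m.qualifier == "lt"]
    gt_vals = [m.value_nM for m in chosen if m.qualifier == "gt"]

    if lt_vals and gt_vals and min(lt_vals) <= max(gt_vals):
        # some lt bound sits at or below some gt bound: no potency satisfies both
        return ConsensusPotency(endpoint, float(min(lt_vals)), "lt", conflict=True)
    if eq_vals:
        gm = eq_vals[0] if len(eq_vals) == 1 else float(np.exp(np.mean(np.log(eq_vals))))
        return ConsensusPotency(endpoint, float(gm), "eq")
    if lt_vals:
        return ConsensusPotency(endpoint, float(max(lt_vals)), "lt")
    return ConsensusPotency(endpoint, float(min(gt_vals)), "gt")


def build_threshold_labels(
    consensus: ConsensusPotency,
    mol_id: str,
    receptor: str,
    thresholds: Sequence[float] = THRESHOLDS_NM,
) -> list[ThresholdLabel]:
    """Five per-threshold labels from one consensus potency.

    Exact potency p: active at every t with p <= t (inclusive boundary),
    inactive otherwise.  ``gt v``: inactive at t <= v, unknown above.
    ``lt v``: active at t >= v, unknown below.  A conflicting consensus
    yields all-unknown labels.
    """
    labels: list[ThresholdLabel] = []
    for t in thresholds:
        if consensus.conflict:
            lab: Label = "unknown"
        elif consensus.qualifier == "eq":
            lab = "active" if consensus.value_nM <= t else "inactive"
        elif consensus.qualifier == "gt":
            lab = "inactive" if t <= consensus.value_nM else "unknown"
        else:  # lt
            lab = "active" if t >= consensus.value_nM else "unknown"
        labels.append(ThresholdLabel(mol_id, receptor, float(t), lab))
    return labels


def read_activity_csv(path) -> list[ActivityMeasurement]:
    """Read measurements from CSV with columns mol_id, receptor, endpoint, value_nM, qualifier."""
    df = pd.read_csv(path, dtype={"mol_id": str})
    required = {"mol_id", "receptor", "endpoint", "value_nM", "qualifier"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return [
        ActivityMeasurement(
            mol_id=row.mol_id,
            receptor=row.receptor,
            endpoint=row.endpoint,
            value_nM=float(row.value_nM),
            qualifier=row.qualifier,
        )
        for row in df.itertuples()
    ]


def label_table(measurements: Iterable[ActivityMeasurement]) -> pd.DataFrame:
    """Long-format label table for a batch of measurements.

    Groups by (mol_id, receptor), aggregates with :func:`consensus_potency`
    and expands with :func:`build_threshold_labels`.  Every present pair
    yields exactly five rows.
    """
    groups: dict[tuple[str, str], list[ActivityMeasurement]] = {}
    for m in measurements:
        groups.setdefault((m.mol_id, m.receptor), []).append(m)
    rows = []
    for (mol_id, receptor), ms in groups.items():
        cons = consensus_potency(ms)
        for lab in build_threshold_labels(cons, mol_id, receptor):
            rows.append((lab.mol_id, lab.receptor, lab.threshold_nM, lab.label))
    return pd.DataFrame(rows, columns=["mol_id", "receptor", "threshold_nM", "label"])


def label_matrix(
    labels: pd.DataFrame, receptor: str, mol_ids: Sequence[str]
) -> np.ndarray:
    """(n_molecules, 5) float matrix for one receptor: 1 active, 0 inactive, NaN unknown.

    Molecules without measurements at this receptor are all-NaN (training
    masks unknowns, it never imputes them).
    """
    sub = labels[labels["receptor"] == receptor]
    pivot = sub.pivot_table(
        index="mol_id", columns="threshold_nM", values="label", aggfunc="first", observed=True
    )
    Y = np.full((len(mol_ids), len(THRESHOLDS_NM)), np.nan)
    code = {"active": 1.0, "inactive": 0.0, "unknown": np.nan}
    index = {m: i for i, m in enumerate(mol_ids)}
    for mol_id, row in pivot.iterrows():
        i = index.get(mol_id)
        if i is None:
            continue
        for j, t in enumerate(THRESHOLDS_NM):
            if t in row and isinstance(row[t], str):
                Y[i, j] = code[row[t]]
    return Y
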
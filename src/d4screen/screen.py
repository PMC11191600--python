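"""Composing per-receptor profiles into activity/selectivity scores and the funnel.

The activity score of a molecule is P(active <= 10 nM at D4).  The
selectivity score composes four independent predictions,

    S = P_D4,10nM * (1 - P_D2,1000nM) * (1 - P_D3,1000nM) * (1 - P_D5,1000nM),

the probability of being active at 10 nM on D4 while inactive at 1000 nM on
every anti-target — selectivity at two orders of magnitude.  Because S
multiplies four predictions, the error of each component accumulates in the
final score; this is a property of the score, not a bug, and the evaluation
module quantifies it.  The funnel keeps molecules with activity score at or
above the cutoff (default 0.8), prefers those whose selectivity score
exceeds its cutoff (default 0.4), and selects a fixed number of candidates
(default 89) in rank order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .features import FingerprintConfig, MorganFeaturizer
from .labels import RECEPTORS
from .molecules import MoleculeRecord
from .qsar import ReceptorModel, ThresholdProbabilityProfile

ACTIVITY_THRESHOLD_NM = 10.0
OFFTARGET_THRESHOLD_NM = 1000.0
OFFTARGETS: tuple[str, ...] = ("D2", "D3", "D5")


@dataclass(frozen=True)
class FunnelConfig:
    """Screening-funnel cutoffs and selection size.

    ``activity_cutoff`` is inclusive (scores *at or above* pass);
    ``selectivity_cutoff`` is strict (scores must *exceed* it).
    """

    activity_cutoff: float = 0.8
    selectivity_cutoff: float = 0.4
    n_select: int = 89
    selectivity_mode: str = "product"

    def __post_init__(self):
        if not (0 <= self.activity_cutoff <= 1 and 0 <= self.selectivity_cutoff <= 1):
            raise ValueError("cutoffs must lie in [0, 1]")
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")
        if self.selectivity_mode not in ("product", "min"):
            raise ValueError("selectivity_mode must be 'product' or 'min'")


@dataclass(frozen=True)
class ScreeningScore:
    mol_id: str
    activity_score: float
    selectivity_score: float
    passed_activity: bool
    passed_selectivity: bool
    rank: int


def activity_score(profile_d4: ThresholdProbabilityProfile) -> float:
    """P(active <= 10 nM at D4): the 10 nM entry of the D4 profile."""
    if profile_d4.receptor != "D4":
        raise ValueError(f"activity score needs the D4 profile, got {profile_d4.receptor}")
    if ACTIVITY_THRESHOLD_NM not in profile_d4.probs:
        raise KeyError(f"profile lacks the {ACTIVITY_THRESHOLD_NM} nM threshold")
    return float(profile_d4.probs[ACTIVITY_THRESHOLD_NM])


def selectivity_score(
    profiles: Mapping[str, ThresholdProbabilityProfile], mode: str = "product"
) -> float:
    """Composed probability of 100-fold D4 selectivity.

    Product mode multiplies P_D4,10nM with each anti-target's probability of
    inactivity at 1000 nM (independence approximation).  Min mode replaces
    the product over anti-targets with the single worst one.
    """
    missing = [r for r in RECEPTORS if r not in profiles]
    if missing:
        raise KeyError(f"profiles missing receptors: {missing}")
    act = activity_score(profiles["D4"])
    inactive = []
    for r in OFFTARGETS:
        probs = profiles[r].probs
        if OFFTARGET_THRESHOLD_NM not in probs:
            raise KeyError(f"{r} profile lacks the {OFFTARGET_THRESHOLD_NM} nM threshold")
        inactive.append(1.0 - float(probs[OFFTARGET_THRESHOLD_NM]))
    if mode == "product":
        return act * float(np.prod(inactive))
    if mode == "min":
        return act * min(inactive)
    raise ValueError(f"unknown selectivity mode {mode!r}")


def compose_scores(
    mol_ids: Sequence[str],
    act_d4: np.ndarray,
    off_1000: Mapping[str, np.ndarray],
    funnel: FunnelConfig = FunnelConfig(),
) -> list[ScreeningScore]:
    """Vectorized scoring + ranking from score components.

    ``act_d4`` holds P_D4,10nM per molecule; ``off_1000`` maps each
    anti-target to its P_r,1000nM vector.  Ranking: activity passers first,
    ordered by selectivity score descending (ties: activity descending, then
    mol_id); non-passers after, by activity descending (ties: mol_id).
    Ranks are unique and contiguous from 1.
    """
    act = np.asarray(act_d4, dtype=float)
    inact = np.stack([1.0 - np.asarray(off_1000[r], dtype=float) for r in OFFTARGETS])
    if funnel.selectivity_mode == "product":
        sel = act * inact.prod(axis=0)
    else:
        sel = act * inact.min(axis=0)
    passed_act = act >= funnel.activity_cutoff
    passed_sel = sel > funnel.selectivity_cutoff

    def sort_key(i: int):
        if passed_act[i]:
            return (0, -sel[i], -act[i], mol_ids[i])
        return (1, -act[i], mol_ids[i], "")

    order = sorted(range(len(mol_ids)), key=sort_key)
    scores = [None] * len(mol_ids)
    for rank, i in enumerate(order, start=1):
        scores[rank - 1] = ScreeningScore(
            mol_id=mol_ids[i],
            activity_score=float(act[i]),
            selectivity_score=float(sel[i]),
            passed_activity=bool(passed_act[i]),
            passed_selectivity=bool(passed_sel[i]),
            rank=rank,
        )
    return scores


def screen_library(
    models: Mapping[str, ReceptorModel],
    molecules: Sequence[MoleculeRecord],
    funnel: FunnelConfig = FunnelConfig(),
    feature_config: FingerprintConfig = FingerprintConfig(),
    batch_size: int = 4096,
) -> list[ScreeningScore]:
    """Score and rank an entire library through the four receptor models.

    Evaluation streams in batches of ``batch_size`` molecules so memory
    stays bounded on large decks; the ranking is independent of the batch
    size.  All four models must share the feature configuration hash.
    """
    if not molecules:
        raise ValueError("empty library")
    missing = [r for r in RECEPTORS if r not in models]
    if missing:
        raise ValueError(f"models missing receptors: {missing}")
    hashes = {models[r].feature_config_hash for r in RECEPTORS}
    if hashes != {feature_config.config_hash}:
        raise ValueError("models/features disagree on the featurization config")

    featurizer = MorganFeaturizer(radius=feature_config.radius, n_bits=feature_config.n_bits).fit([])
    act_parts: list[np.ndarray] = []
    off_parts: dict[str, list[np.ndarray]] = {r: [] for r in OFFTARGETS}
    for start in range(0, len(molecules), batch_size):
        batch = molecules[start : start + batch_size]
        X = featurizer.transform(batch)
        d4 = models["D4"].classifier.predict_proba(X, monotone=True)
        act_parts.append(d4[:, 1])  # column 1 = 10 nM
        for r in OFFTARGETS:
            pr = models[r].classifier.predict_proba(X, monotone=True)
            off_parts[r].append(pr[:, 3])  # column 3 = 1000 nM
    act = np.concatenate(act_parts)
    off = {r: np.concatenate(off_parts[r]) for r in OFFTARGETS}
    return compose_scores([m.mol_id for m in molecules], act, off, funnel)


def select_candidates(
    scores: Sequence[ScreeningScore], funnel: FunnelConfig = FunnelConfig()
) -> list[str]:
    """Pick up to ``n_select`` candidates in rank order, two-tier priority.

    First every molecule passing both filters, then — if the quota is not
    filled — molecules passing only the activity filter.  Molecules failing
    the activity filter are never selected.
    """
    ranked = sorted(scores, key=lambda s: s.rank)
    dual = [s.mol_id for s in ranked if s.passed_activity and s.passed_selectivity]
    act_only = [s.mol_id for s in ranked if s.passed_activity and not s.passed_selectivity]
    return (dual + act_only)[: funnel.n_select]
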
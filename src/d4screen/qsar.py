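"""Per-receptor multitask threshold classifiers.

One model per receptor predicts, for every molecule, the probability of
being active at or below each of the five thresholds.  The five tasks share
a hidden representation (a small feed-forward network trained with a masked,
class-weighted cross-entropy), because "active at <= 10 nM" and "active at
<= 100 nM" are nested events of the same underlying potency.  Nestedness is
enforced at prediction time by isotonic projection of the five raw
probabilities, which is idempotent and leaves already-monotone profiles
untouched.

All randomness (initialization, minibatch shuffling, splits) funnels through
one integer seed recorded in the training manifest; repeated runs are
bit-identical, as are predictions after an archive save/load round trip.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score

from .features import FingerprintConfig
from .labels import RECEPTORS, THRESHOLDS_NM


def enforce_threshold_monotonicity(raw) -> np.ndarray:
    """Isotonic (least-squares, equal-weight) projection onto nondecreasing profiles.

    Accepts a length-5 vector or an (n, 5) matrix of probabilities in [0, 1]
    and returns the nearest nondecreasing profile(s) in the least-squares
    sense, via the minimax characterization

        out_j = max_{i <= j} min_{l >= j} mean(raw_{i..l}).

    Idempotent; already-monotone input is returned exactly.
    """
    arr = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("probabilities must be finite")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    squeeze = arr.ndim == 1
    Y = np.atleast_2d(arr)
    n, k = Y.shape
    csum = np.concatenate([np.zeros((n, 1)), np.cumsum(Y, axis=1)], axis=1)
    out = np.empty_like(Y)
    for j in range(k):
        best = np.full(n, -np.inf)
        for i in range(j + 1):
            cur = np.full(n, np.inf)
            for l in range(j, k):
                cur = np.minimum(cur, (csum[:, l + 1] - csum[:, i]) / (l + 1 - i))
            best = np.maximum(best, cur)
        out[:, j] = best
    return out[0] if squeeze else out


@dataclass(frozen=True)
class ThresholdProbabilityProfile:
    """Per molecule x receptor: the five monotone probabilities P(active <= t)."""

    mol_id: str
    receptor: str
    probs: Mapping[float, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.probs[t] for t in THRESHOLDS_NM])


class MultitaskThresholdClassifier(BaseEstimator):
    """Shared-trunk feed-forward classifier for the five threshold tasks.

    Parameters
    ----------
    hidden_units:
        Width of the single shared hidden (ReLU) layer.
    n_epochs, batch_size, learning_rate, l2:
        Adam training schedule; defaults are sized for a few thousand
        molecules with 2048-bit fingerprints.
    class_weight:
        ``"balanced"`` reweights each task's loss by inverse class frequency
        (the 1 nM task is rare-positive), ``None`` leaves it uniform.
    random_state:
        Seed for initialization and minibatch shuffling; fixed seed, fixed
        data => identical fitted parameters and predictions.

    Labels are a (n, 5) float matrix with entries 1 (active), 0 (inactive)
    or NaN (unknown).  Unknowns are masked out of the loss, never imputed.
    A task missing either class is masked entirely and predicts its
    empirical prior.
    """

    def __init__(
        self,
        hidden_units: int = 64,
        n_epochs: int = 60,
        batch_size: int = 128,
        learning_rate: float = 1e-3,
        l2: float = 1e-6,
        class_weight: str | None = "balanced",
        random_state: int = 0,
    ):
        self.hidden_units = hidden_units
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.l2 = l2
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, Y):
        X = np.asarray(X, dtype=np.float64)
        Y = np.asarray(Y, dtype=np.float64)
        if Y.ndim != 2 or Y.shape[1] != len(THRESHOLDS_NM):
            raise ValueError(f"Y must be (n, {len(THRESHOLDS_NM)})")
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        n, d = X.shape
        k = Y.shape[1]
        observed = ~np.isnan(Y)
        n_pos = np.nansum(Y == 1, axis=0).astype(float)
        n_obs = observed.sum(axis=0).astype(float)
        n_neg = n_obs - n_pos
        self.task_mask_ = (n_pos >= 1) & (n_neg >= 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            prior = np.where(n_obs > 0, n_pos / np.maximum(n_obs, 1), 0.5)
        self.task_prior_ = np.clip(prior, 1e-3, 1 - 1e-3)
        if not self.task_mask_.any():
            raise ValueError("all tasks masked: every task lacks an active or an inactive")

        W = observed.astype(float)
        if self.class_weight == "balanced":
            with np.errstate(divide="ignore", invalid="ignore"):
                w_pos = np.where(n_pos > 0, n_obs / (2.0 * n_pos), 0.0)
                w_neg = np.where(n_neg > 0, n_obs / (2.0 * n_neg), 0.0)
            Yz = np.nan_to_num(Y)
            W = W * (Yz * w_pos + (1.0 - Yz) * w_neg)
        W[:, ~self.task_mask_] = 0.0
        Yt = np.nan_to_num(Y)

        rng = np.random.default_rng(self.random_state)
        h = self.hidden_units
        W1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h))
        b1 = np.zeros(h)
        W2 = rng.normal(0.0, np.sqrt(2.0 / h), size=(h, k))
        b2 = np.log(self.task_prior_ / (1 - self.task_prior_))

        params = [W1, b1, W2, b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        losses = []
        for _ in range(self.n_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb, wb = X[idx], Yt[idx], W[idx]
                z1 = xb @ W1 + b1
                hb = np.maximum(z1, 0.0)
                p = expit(hb @ W2 + b2)
                wsum = wb.sum()
                if wsum == 0:
                    continue
                pc = np.clip(p, 1e-12, 1 - 1e-12)
                epoch_loss += -np.sum(wb * (yb * np.log(pc) + (1 - yb) * np.log(1 - pc)))
                # gradient of weighted BCE wrt pre-sigmoid activation
                dz2 = wb * (p - yb) / wsum
                gW2 = hb.T @ dz2 + self.l2 * W2
                gb2 = dz2.sum(axis=0)
                dh = (dz2 @ W2.T) * (z1 > 0)
                gW1 = xb.T @ dh + self.l2 * W1
                gb1 = dh.sum(axis=0)
                t += 1
                for p_, g_, m_, v_ in zip(params, [gW1, gb1, gW2, gb2], m, v):
                    m_ *= beta1
                    m_ += (1 - beta1) * g_
                    v_ *= beta2
                    v_ += (1 - beta2) * g_ * g_
                    mhat = m_ / (1 - beta1**t)
                    vhat = v_ / (1 - beta2**t)
                    p_ -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            if not np.isfinite(epoch_loss):
                raise FloatingPointError("non-finite training loss")
            losses.append(epoch_loss / max(W.sum(), 1.0))
        self.W1_, self.b1_, self.W2_, self.b2_ = W1, b1, W2, b2
        self.loss_curve_ = np.array(losses)
        self.n_features_in_ = d
        return self

    def _raw_proba(self, X: np.ndarray) -> np.ndarray:
        out = np.empty((X.shape[0], len(THRESHOLDS_NM)))
        for start in range(0, X.shape[0], 8192):
            xb = np.asarray(X[start : start + 8192], dtype=np.float64)
            hb = np.maximum(xb @ self.W1_ + self.b1_, 0.0)
            out[start : start + 8192] = expit(hb @ self.W2_ + self.b2_)
        out[:, ~self.task_mask_] = self.task_prior_[~self.task_mask_]
        return out

    def predict_proba(self, X, monotone: bool = True) -> np.ndarray:
        """(n, 5) matrix of threshold probabilities, monotone by default."""
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        p = self._raw_proba(X)
        return enforce_threshold_monotonicity(p) if monotone else p


def split_dataset(
    n_molecules: int,
    fraction: float = 0.8,
    strategy: str = "random",
    seed: int = 0,
    smiles: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic train/validation split over molecule indices.

    ``strategy="scaffold"`` groups molecules by Bemis–Murcko framework and
    keeps each framework entirely on one side, the harder and more honest
    protocol for structure–activity models; ``"random"`` splits molecules
    independently.  Returns (train_idx, val_idx), disjoint and exhaustive.
    """
    if n_molecules < 20:
        raise ValueError("need at least 20 molecules to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if strategy == "random":
        order = rng.permutation(n_molecules)
        n_train = int(round(fraction * n_molecules))
        return np.sort(order[:n_train]), np.sort(order[n_train:])
    if strategy == "scaffold":
        if smiles is None:
            raise ValueError("scaffold strategy requires smiles")
        from rdkit.Chem.Scaffolds.MurckoScaffold import MurckoScaffoldSmiles

        groups: dict[str, list[int]] = {}
        for i, smi in enumerate(smiles):
            groups.setdefault(MurckoScaffoldSmiles(smiles=smi), []).append(i)
        keys = sorted(groups)
        rng.shuffle(keys)
        train: list[int] = []
        target = fraction * n_molecules
        for key in keys:
            if len(train) < target:
                train.extend(groups[key])
        train_idx = np.sort(np.array(train, dtype=int))
        val_idx = np.setdiff1d(np.arange(n_molecules), train_idx)
        return train_idx, val_idx
    raise ValueError(f"unknown strategy {strategy!r}")


@dataclass
class ReceptorModel:
    """A trained per-receptor model plus its provenance manifest."""

    receptor: str
    classifier: MultitaskThresholdClassifier
    feature_config_hash: str
    thresholds: tuple[float, ...] = THRESHOLDS_NM
    manifest: dict = field(default_factory=dict)


def train_receptor_model(
    X,
    Y,
    receptor: str,
    feature_config: FingerprintConfig = FingerprintConfig(),
    seed: int = 0,
    val_fraction: float = 0.2,
    strategy: str = "random",
    smiles: Sequence[str] | None = None,
    **hyperparams,
) -> ReceptorModel:
    """Split, fit and validate one receptor's multitask classifier.

    The classifier is fitted on the training side only; per-task validation
    AUROC (where the validation side has both classes) is recorded in the
    manifest together with the seed, split description and hyperparameters.
    Tasks lacking a class in training are masked with a warning.
    """
    if receptor not in RECEPTORS:
        raise ValueError(f"unknown receptor {receptor!r}")
    X = np.asarray(X)
    Y = np.asarray(Y, dtype=float)
    train_idx, val_idx = split_dataset(
        X.shape[0], fraction=1 - val_fraction, strategy=strategy, seed=seed, smiles=smiles
    )
    clf = MultitaskThresholdClassifier(random_state=seed, **hyperparams)
    clf.fit(X[train_idx], Y[train_idx])
    if not clf.task_mask_.all():
        masked = [t for t, ok in zip(THRESHOLDS_NM, clf.task_mask_) if not ok]
        warnings.warn(f"{receptor}: tasks masked for lack of a class: {masked}")
    proba = clf.predict_proba(X[val_idx], monotone=True)
    auroc: dict[str, float | None] = {}
    for j, t in enumerate(THRESHOLDS_NM):
        yv = Y[val_idx, j]
        obs = ~np.isnan(yv)
        if obs.sum() >= 2 and len(np.unique(yv[obs])) == 2:
            auroc[str(t)] = float(roc_auc_score(yv[obs], proba[obs, j]))
        else:
            auroc[str(t)] = None
    manifest = {
        "receptor": receptor,
        "seed": seed,
        "split": {"strategy": strategy, "val_fraction": val_fraction,
                  "n_train": int(train_idx.size), "n_val": int(val_idx.size)},
        "hyperparams": clf.get_params(),
        "val_auroc": auroc,
        "masked_tasks": [t for t, ok in zip(THRESHOLDS_NM, clf.task_mask_) if not ok],
    }
    return ReceptorModel(
        receptor=receptor,
        classifier=clf,
        feature_config_hash=feature_config.config_hash,
        manifest=manifest,
    )


def predict_profiles(
    model: ReceptorModel,
    X,
    mol_ids: Sequence[str],
    feature_config: FingerprintConfig | None = None,
) -> list[ThresholdProbabilityProfile]:
    """Monotone threshold-probability profiles for a feature matrix."""
    if feature_config is not None and feature_config.config_hash != model.feature_config_hash:
        raise ValueError(
            f"feature config mismatch: model expects {model.feature_config_hash}, "
            f"got {feature_config.config_hash}"
        )
    proba = model.classifier.predict_proba(np.asarray(X), monotone=True)
    return [
        ThresholdProbabilityProfile(
            mol_id=mol_id,
            receptor=model.receptor,
            probs={t: float(proba[i, j]) for j, t in enumerate(model.thresholds)},
        )
        for i, mol_id in enumerate(mol_ids)
    ]


_ARCHIVE_VERSION = 1


def save_model(model: ReceptorModel, path: str | Path) -> None:
    """Serialize a receptor model to a single versioned archive (.npz)."""
    clf = model.classifier
    np.savez(
        Path(path),
        version=np.array(_ARCHIVE_VERSION),
        W1=clf.W1_,
        b1=clf.b1_,
        W2=clf.W2_,
        b2=clf.b2_,
        task_mask=clf.task_mask_,
        task_prior=clf.task_prior_,
        meta=np.array(
            json.dumps(
                {
                    "receptor": model.receptor,
                    "feature_config_hash": model.feature_config_hash,
                    "thresholds": list(model.thresholds),
                    "manifest": model.manifest,
                    "params": clf.get_params(),
                }
            )
        ),
    )


def load_model(path: str | Path) -> ReceptorModel:
    """Reload an archive; reloaded models predict bit-identically."""
    with np.load(Path(path), allow_pickle=False) as archive:
        if int(archive["version"]) != _ARCHIVE_VERSION:
            raise ValueError(f"unsupported archive version {archive['version']}")
        meta = json.loads(str(archive["meta"]))
        clf = MultitaskThresholdClassifier(**meta["params"])
        clf.W1_ = archive["W1"]
        clf.b1_ = archive["b1"]
        clf.W2_ = archive["W2"]
        clf.b2_ = archive["b2"]
        clf.task_mask_ = archive["task_mask"]
        clf.task_prior_ = archive["task_prior"]
        clf.n_features_in_ = clf.W1_.shape[0]
    return ReceptorModel(
        receptor=meta["receptor"],
        classifier=clf,
        feature_config_hash=meta["feature_config_hash"],
        thresholds=tuple(meta["thresholds"]),
        manifest=meta["manifest"],
    )
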
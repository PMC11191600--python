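"""Hashed circular-substructure fingerprints shared by every model.

The descriptor is a binary Morgan fingerprint (radius 2, 2048 bits by
default): deterministic, canonicalization-invariant, and configurable so a
different descriptor block can be slotted in later.  A configuration hash
travels with every feature matrix and trained model so that features and
parameters can never be silently mixed across settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin

from .molecules import MoleculeError, MoleculeRecord


@dataclass(frozen=True)
class FingerprintConfig:
    """Featurization settings: circular-substructure radius and bit-vector length."""

    radius: int = 2
    n_bits: int = 2048

    @property
    def config_hash(self) -> str:
        payload = json.dumps({"family": "morgan-binary", **asdict(self)}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _generator(config: FingerprintConfig):
    return rdFingerprintGenerator.GetMorganGenerator(radius=config.radius, fpSize=config.n_bits)


def featurize_molecule(smiles: str, config: FingerprintConfig = FingerprintConfig()) -> np.ndarray:
    """Binary fingerprint of one molecule as a dense uint8 vector.

    Deterministic; identical canonical structures give identical vectors.
    Any molecule with at least one heavy atom sets at least one bit.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"unparseable structure: {smiles!r}")
    fp = _generator(config).GetFingerprint(mol)
    vec = np.zeros(config.n_bits, dtype=np.uint8)
    vec[list(fp.GetOnBits())] = 1
    return vec


def featurize_library(
    records: Sequence[MoleculeRecord], config: FingerprintConfig = FingerprintConfig()
) -> tuple[np.ndarray, list[str]]:
    """Feature matrix for a library, rows in input order.

    Returns ``(X, mol_ids)`` with ``X[i] == featurize_molecule(records[i])``.
    All offending ids are collected before raising, so a single bad entry in
    a large deck is reported alongside its peers.
    """
    gen = _generator(config)
    X = np.zeros((len(records), config.n_bits), dtype=np.uint8)
    bad: list[str] = []
    for i, rec in enumerate(records):
        mol = Chem.MolFromSmiles(rec.smiles_canonical)
        if mol is None:
            bad.append(rec.mol_id)
            continue
        X[i, list(gen.GetFingerprint(mol).GetOnBits())] = 1
    if bad:
        raise MoleculeError(f"unparseable records: {bad}")
    return X, [rec.mol_id for rec in records]


class MorganFeaturizer(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer mapping SMILES (or records) to fingerprint bits.

    Stateless apart from its configuration; ``fit`` only records the
    configuration hash.  Accepts an iterable of SMILES strings or of
    :class:`MoleculeRecord`.
    """

    def __init__(self, radius: int = 2, n_bits: int = 2048):
        self.radius = radius
        self.n_bits = n_bits

    @property
    def config(self) -> FingerprintConfig:
        return FingerprintConfig(radius=self.radius, n_bits=self.n_bits)

    def fit(self, X, y=None):
        self.config_hash_ = self.config.config_hash
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        config = self.config
        smiles = [x.smiles_canonical if isinstance(x, MoleculeRecord) else x for x in X]
        out = np.zeros((len(smiles), config.n_bits), dtype=np.uint8)
        gen = _generator(config)
        for i, smi in enumerate(smiles):
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise MoleculeError(f"unparseable structure: {smi!r}")
            out[i, list(gen.GetFingerprint(mol).GetOnBits())] = 1
        return out


def save_features(
    X: np.ndarray, mol_ids: Sequence[str], config: FingerprintConfig, path: str | Path
) -> None:
    """Persist a feature matrix as a compressed sparse table plus sidecar manifest."""
    path = Path(path)
    sparse.save_npz(path, sparse.csr_matrix(np.asarray(X, dtype=np.uint8)))
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash,
        "mol_ids": list(mol_ids),
    }
    path.with_suffix(path.suffix + ".manifest.json").write_text(json.dumps(manifest))


def load_features(
    path: str | Path, expected: FingerprintConfig | None = None
) -> tuple[np.ndarray, list[str], FingerprintConfig]:
    """Reload a persisted feature matrix, verifying the configuration hash."""
    path = Path(path)
    manifest = json.loads(path.with_suffix(path.suffix + ".manifest.json").read_text())
    config = FingerprintConfig(**manifest["config"])
    if config.config_hash != manifest["config_hash"]:
        raise ValueError("feature manifest hash mismatch")
    if expected is not None and expected.config_hash != config.config_hash:
        raise ValueError(
            f"feature config mismatch: expected {expected.config_hash}, found {config.config_hash}"
        )
    X = sparse.load_npz(path if path.suffix == ".npz" else path.with_suffix(".npz")).toarray()
    return X.astype(np.uint8), list(manifest["mol_ids"]), config
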
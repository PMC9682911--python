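"""Molecular representations: circular fingerprints, fragment counts, fragprints.

Three descriptor families are supported for a SMILES input:

``fingerprint``
    Binary Morgan/ECFP-style circular fingerprint (default radius 3,
    2048 bits).
``fragments``
    Non-negative occurrence counts of the frozen functional-group
    catalogue in :mod:`azogp.fragments`.
``fragprints``
    Concatenation of the two blocks — bit block first, count block second.
    These are the count vectors fed to the Tanimoto kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .fragments import CATALOGUE, CATALOGUE_VERSION, compiled_catalogue

logger = logging.getLogger(__name__)

# RDKit prints parse errors to stderr by default; we report via exceptions.
RDLogger.DisableLog("rdApp.error")

MODES = ("fingerprint", "fragments", "fragprints")


class InvalidMoleculeError(ValueError):
    """Raised when a SMILES string cannot be parsed/sanitised."""


@dataclass(frozen=True)
class FeatureConfig:
    """Featurization hyperparameters.

    radius and n_bits follow the convention widely used with Tanimoto-kernel
    GPs on this class of dataset; both are exposed because neither is
    canonical.
    """

    radius: int = 3
    n_bits: int = 2048
    catalogue_version: str = CATALOGUE_VERSION

    @property
    def n_fragments(self) -> int:
        return len(CATALOGUE)

    def n_features(self, mode: str = "fragprints") -> int:
        if mode == "fingerprint":
            return self.n_bits
        if mode == "fragments":
            return self.n_fragments
        if mode == "fragprints":
            return self.n_bits + self.n_fragments
        raise ValueError(f"unknown mode {mode!r}")

    def to_dict(self) -> dict:
        return {
            "radius": self.radius,
            "n_bits": self.n_bits,
            "catalogue_version": self.catalogue_version,
            "n_fragments": self.n_fragments,
        }


DEFAULT_CONFIG = FeatureConfig()

_CATALOGUE_PATTERNS = compiled_catalogue()
_FP_GENERATORS: dict[tuple[int, int], object] = {}


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise InvalidMoleculeError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES form; idempotent for valid input."""
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def _fingerprint(mol: Chem.Mol, config: FeatureConfig) -> np.ndarray:
    key = (config.radius, config.n_bits)
    gen = _FP_GENERATORS.get(key)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=config.radius, fpSize=config.n_bits
        )
        _FP_GENERATORS[key] = gen
    return np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.float64)


def _fragment_counts(mol: Chem.Mol) -> np.ndarray:
    counts = np.empty(len(_CATALOGUE_PATTERNS), dtype=np.float64)
    for k, (_, patt) in enumerate(_CATALOGUE_PATTERNS):
        counts[k] = len(mol.GetSubstructMatches(patt))
    return counts


def featurize(
    smiles: str, mode: str = "fragprints", config: FeatureConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Featurize one molecule; identical output for any spelling of the
    same molecule (the molecular graph, not the string, is hashed)."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    mol = _mol_from_smiles(smiles)
    if mode == "fingerprint":
        vec = _fingerprint(mol, config)
    elif mode == "fragments":
        vec = _fragment_counts(mol)
    else:
        vec = np.concatenate([_fingerprint(mol, config), _fragment_counts(mol)])
    if mol.GetNumHeavyAtoms() >= 2 and not vec.any():
        # guard against silent featurization failure
        logger.warning("all-zero %s vector for %r", mode, smiles)
    return vec


@dataclass
class Reject:
    index: int
    smiles: str
    reason: str


@dataclass
class LibraryFeatures:
    matrix: np.ndarray
    kept_indices: list[int]
    rejects: list[Reject] = field(default_factory=list)


def featurize_library(
    smiles_list,
    mode: str = "fragprints",
    config: FeatureConfig = DEFAULT_CONFIG,
) -> LibraryFeatures:
    """Batch featurization with partial-failure semantics.

    Row ``i`` of the matrix corresponds to ``kept_indices[i]`` in the input
    list; invalid entries are collected in ``rejects`` with a reason.
    Duplicate SMILES yield duplicate rows — no silent deduplication.
    """
    smiles_list = list(smiles_list)
    if not smiles_list:
        raise ValueError("empty SMILES library")
    rows, kept, rejects = [], [], []
    for i, smi in enumerate(smiles_list):
        try:
            rows.append(featurize(smi, mode=mode, config=config))
            kept.append(i)
        except InvalidMoleculeError as exc:
            logger.info("rejecting library entry %d (%r): %s", i, smi, exc)
            rejects.append(Reject(index=i, smiles=str(smi), reason=str(exc)))
    if not rows:
        raise ValueError("no valid molecules in library")
    return LibraryFeatures(
        matrix=np.vstack(rows), kept_indices=kept, rejects=rejects
    )
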
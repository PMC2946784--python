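"""Local position-subset peptide encoding.

A peptide is represented only by a chosen subset of residue positions on a
9-slot template: slots 1-8 are anchored at the N-terminus (slot s = residue
s), slot 9 is the C-terminal residue whatever the peptide length. On
nonamers the template is the identity, so position subsets read directly as
p1..p9 of the classical TAP motif literature. Each selected residue is
expanded into a one-hot identity block and/or numeric physicochemical
descriptors (hydrophobicity, aromaticity, charge, residue weight), all
scaled into [-1, 1].

The numeric scales live in a replaceable registry (`SCALE_SETS`): the
descriptor *names* are fixed by the problem, the exact per-residue values are
a package default (Kyte-Doolittle hydrophobicity, {F,W,Y} aromaticity
indicator, K/R=+1 D/E=-1 charge with histidine neutral, and min-max rescaled
monoisotopic residue mass).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, EncodingError
from .seqio import AMINO_ACIDS, LabeledPeptideSet, Peptide

# Kyte-Doolittle hydropathy index, the field's default hydrophobicity scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Monoisotopic residue (not free amino acid) masses, Da.
MONOISOTOPIC_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

AROMATIC = frozenset("FWY")
BASIC = frozenset("KR")
ACIDIC = frozenset("DE")

DESCRIPTOR_ORDER = ("hydrophobicity", "aromaticity", "charge", "residue_weight")
VALID_DESCRIPTORS = ("onehot",) + DESCRIPTOR_ORDER


def _minmax_01(scale: Mapping[str, float]) -> dict[str, float]:
    lo, hi = min(scale.values()), max(scale.values())
    return {aa: (v - lo) / (hi - lo) for aa, v in scale.items()}


def _default_scales() -> dict[str, dict[str, float]]:
    return {
        "hydrophobicity": {aa: v / 4.5 for aa, v in KYTE_DOOLITTLE.items()},
        "aromaticity": {aa: float(aa in AROMATIC) for aa in AMINO_ACIDS},
        "charge": {
            aa: (1.0 if aa in BASIC else -1.0 if aa in ACIDIC else 0.0)
            for aa in AMINO_ACIDS
        },
        "residue_weight": _minmax_01(MONOISOTOPIC_MASS),
    }


#: Registry of named numeric scale sets; swap in alternatives here.
SCALE_SETS: dict[str, dict[str, dict[str, float]]] = {
    "default": _default_scales(),
}

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def map_positions(peptide_length: int, positions: Sequence[int]) -> list[int]:
    """Resolve template positions to 1-based residue indices.

    Slots 1-8 are N-anchored (slot s -> residue s); slot 9 is the C-terminal
    residue (index = peptide length). For short peptides, slots 4-8 are only
    valid when they do not reach the C-terminal residue (slot <= length - 1).
    """
    if peptide_length < 4:
        raise ConfigError(f"peptide length {peptide_length} < 4")
    indices: list[int] = []
    for pos in positions:
        if not (1 <= pos <= 9):
            raise ConfigError(
                f"template position {pos} invalid: must be 1-8 (N-anchored) or 9 (C)"
            )
        if pos == 9:
            indices.append(peptide_length)
        else:
            if pos >= 4 and pos > peptide_length - 1:
                raise ConfigError(
                    f"template position {pos} exceeds peptide length "
                    f"{peptide_length} (slots 4-8 need length >= slot+1)"
                )
            indices.append(pos)
    return indices


@dataclass(frozen=True)
class EncodingConfig:
    """Feature-space definition: position subset + descriptor scheme.

    positions: sorted unique template slots in 1..9.
    descriptors: subset of {onehot, hydrophobicity, aromaticity, charge,
        residue_weight}, emitted per position in that fixed order.
    scale_set: name of the numeric scale registry entry.
    """

    positions: tuple[int, ...]
    descriptors: tuple[str, ...] = VALID_DESCRIPTORS
    scale_set: str = "default"

    def __post_init__(self) -> None:
        pos = tuple(sorted(set(int(p) for p in self.positions)))
        if not pos:
            raise ConfigError("positions must be non-empty")
        if len(pos) != len(self.positions):
            raise ConfigError(f"duplicate positions in {self.positions}")
        for p in pos:
            if not (1 <= p <= 9):
                raise ConfigError(f"template position {p} outside 1..9")
        object.__setattr__(self, "positions", pos)
        desc = tuple(d for d in VALID_DESCRIPTORS if d in set(self.descriptors))
        unknown = set(self.descriptors) - set(VALID_DESCRIPTORS)
        if unknown:
            raise ConfigError(f"unknown descriptor(s): {sorted(unknown)}")
        if not desc:
            raise ConfigError("at least one descriptor required")
        object.__setattr__(self, "descriptors", desc)
        if self.scale_set not in SCALE_SETS:
            raise ConfigError(f"unknown scale set {self.scale_set!r}")

    @property
    def per_position_dim(self) -> int:
        n_numeric = sum(1 for d in self.descriptors if d != "onehot")
        return (20 if "onehot" in self.descriptors else 0) + n_numeric

    @property
    def n_features(self) -> int:
        return len(self.positions) * self.per_position_dim

    def to_dict(self) -> dict:
        return {
            "positions": list(self.positions),
            "descriptors": list(self.descriptors),
            "scale_set": self.scale_set,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EncodingConfig":
        return cls(
            positions=tuple(d["positions"]),
            descriptors=tuple(d["descriptors"]),
            scale_set=d.get("scale_set", "default"),
        )

    @property
    def config_id(self) -> str:
        """Stable short hash identifying the feature space."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _residue_features(config: EncodingConfig) -> np.ndarray:
    """20 x per_position_dim lookup table, row = residue."""
    scales = SCALE_SETS[config.scale_set]
    table = np.zeros((20, config.per_position_dim))
    for aa, row in _AA_INDEX.items():
        col = 0
        if "onehot" in config.descriptors:
            table[row, row] = 1.0
            col = 20
        for d in config.descriptors:
            if d == "onehot":
                continue
            table[row, col] = scales[d][aa]
            col += 1
    return table


def encode_peptide(peptide: Peptide | str, config: EncodingConfig) -> np.ndarray:
    """Encode one peptide into its fixed-length local-description vector."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else Peptide(peptide).sequence
    indices = map_positions(len(seq), config.positions)
    table = _residue_features(config)
    blocks = []
    for idx in indices:
        aa = seq[idx - 1]
        row = _AA_INDEX.get(aa)
        if row is None:
            raise EncodingError(f"residue {aa!r} at position {idx} not encodable")
        blocks.append(table[row])
    return np.concatenate(blocks)


class PeptideEncoder(BaseEstimator, TransformerMixin):
    """Sklearn transformer: peptide sequences -> local-description features.

    Parameters
    ----------
    positions : sequence of int
        Template slots (1-8 N-anchored, 9 = C-terminal residue).
    descriptors : sequence of str
        Any of onehot / hydrophobicity / aromaticity / charge / residue_weight.
    scale_set : str
        Name of the numeric scale registry entry.

    The transformer is stateless (nothing is learned from data); ``fit``
    validates the configuration and freezes the lookup table.
    """

    def __init__(
        self,
        positions: Sequence[int] = (1, 2, 3, 9),
        descriptors: Sequence[str] = VALID_DESCRIPTORS,
        scale_set: str = "default",
    ):
        self.positions = positions
        self.descriptors = descriptors
        self.scale_set = scale_set

    def _make_config(self) -> EncodingConfig:
        return EncodingConfig(
            positions=tuple(self.positions),
            descriptors=tuple(self.descriptors),
            scale_set=self.scale_set,
        )

    def fit(self, X: Sequence, y=None) -> "PeptideEncoder":
        self.config_ = self._make_config()
        self.table_ = _residue_features(self.config_)
        self.n_features_out_ = self.config_.n_features
        return self

    def transform(self, X: Sequence) -> np.ndarray:
        if not hasattr(self, "config_"):
            self.fit(X)
        seqs = [
            p.sequence if isinstance(p, Peptide) else Peptide(str(p)).sequence
            for p in X
        ]
        if not seqs:
            raise EncodingError("cannot encode an empty peptide collection")
        out = np.empty((len(seqs), self.n_features_out_))
        for i, seq in enumerate(seqs):
            try:
                indices = map_positions(len(seq), self.config_.positions)
                rows = [_AA_INDEX[seq[idx - 1]] for idx in indices]
            except (ConfigError, KeyError) as exc:
                raise EncodingError(f"record {i} ({seq!r}): {exc}") from exc
            out[i] = self.table_[rows].ravel()
        return out


def encode_set(
    pset: LabeledPeptideSet, config: EncodingConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a labeled set into (feature matrix, +1/-1 label vector)."""
    enc = PeptideEncoder(
        positions=config.positions,
        descriptors=config.descriptors,
        scale_set=config.scale_set,
    ).fit([])
    X = enc.transform([p for p, _ in pset])
    y = np.asarray(pset.labels, dtype=int)
    return X, y
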
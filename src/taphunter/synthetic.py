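"""Synthetic peptide datasets with a TAP-like position-specific binding motif.

The generator emulates the residue preferences reported for peptide
transport by TAP: aromatic (F/W/Y) or acidic (D/E) residues favoured at p1,
hydrophobic or basic (K/R) residues at p2, hydrophobic-aromatic residues at
p3, p7 and the C-terminus, and proline disfavoured at p1 and p2. Binders are
sampled position-wise from per-slot residue distributions obtained by
applying multiplicative enrichment weights ``exp(effect_size * w)`` to a
background distribution and renormalizing; non-binders are sampled from the
background alone. A single scalar ``effect_size`` therefore controls class
separability: at 0 the two classes are identically distributed (the null),
and separability grows monotonically with it.

The background is uniform over the 20 residues by default (isolating motif
signal for testing); a natural-abundance background is available by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .seqio import AMINO_ACIDS, LabeledPeptideSet, Peptide, ProteinRecord

_AA = np.array(list(AMINO_ACIDS))
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Residue classes driving the motif (classes, not descriptor scales, so the
#: generator and the encoder stay consistent without being identical).
HYDROPHOBIC = frozenset("AVLIMFWYC")
AROMATIC = frozenset("FWY")
BASIC = frozenset("KR")
ACIDIC = frozenset("DE")

# Swiss-Prot-like natural residue abundances (approximate, normalized).
_NATURAL = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0672, "G": 0.0708, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0664, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}


def background_frequencies(kind: str = "uniform") -> np.ndarray:
    if kind == "uniform":
        return np.full(20, 1.0 / 20)
    if kind == "natural":
        v = np.array([_NATURAL[aa] for aa in AMINO_ACIDS])
        return v / v.sum()
    raise ValidationError(f"unknown background {kind!r}")


@dataclass(frozen=True)
class MotifProfile:
    """Position-specific enrichment model for binder peptides.

    position_weights maps template slot (1-8 N-anchored, 9 = C terminus) to a
    per-residue log-enrichment exponent w; the binder distribution at that
    slot is background * exp(effect_size * w), renormalized. Slots absent
    from the map (and every residue of a slot's interior beyond the template)
    use the background. effect_size = 0 makes binders and non-binders
    identically distributed.
    """

    position_weights: Mapping[int, Mapping[str, float]]
    effect_size: float = 1.0
    background: np.ndarray = field(default_factory=lambda: background_frequencies())
    length_distribution: Mapping[int, float] = field(
        default_factory=lambda: {9: 1.0}
    )

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValidationError(f"effect_size must be >= 0, got {self.effect_size}")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (20,) or np.any(bg <= 0) or abs(bg.sum() - 1) > 1e-9:
            raise ValidationError("background must be a positive 20-vector summing to 1")
        object.__setattr__(self, "background", bg)
        total = sum(self.length_distribution.values())
        if abs(total - 1) > 1e-9:
            raise ValidationError("length distribution must sum to 1")
        for L in self.length_distribution:
            if not (4 <= L <= 21):
                raise ValidationError(f"peptide length {L} outside 4..21")

    def position_distribution(self, slot: int) -> np.ndarray:
        """Binder residue distribution at a template slot (sums to 1)."""
        weights = self.position_weights.get(slot)
        if weights is None or self.effect_size == 0:
            return self.background.copy()
        w = np.array([weights.get(aa, 0.0) for aa in AMINO_ACIDS])
        p = self.background * np.exp(self.effect_size * w)
        return p / p.sum()


def _class_weights(*groups: tuple[frozenset, float]) -> dict[str, float]:
    # overlapping classes (e.g. F is both hydrophobic and aromatic) keep the
    # larger exponent rather than stacking
    out: dict[str, float] = {}
    for members, w in groups:
        for aa in members:
            out[aa] = max(out.get(aa, w), w)
    return out


def default_tap_profile(
    effect_size: float = 1.0,
    background: str = "uniform",
    length_distribution: Mapping[int, float] | None = None,
) -> MotifProfile:
    """The default TAP-like motif.

    p1: aromatic and acidic residues enriched, proline depleted;
    p2: hydrophobic and basic residues enriched, proline depleted;
    p3, p7, C (slot 9): hydrophobic-aromatic residues enriched;
    all other slots: background.
    """
    if effect_size < 0:
        raise ValidationError(f"effect_size must be >= 0, got {effect_size}")
    p1 = _class_weights((AROMATIC, 1.0), (ACIDIC, 1.0))
    p1["P"] = -1.0
    p2 = _class_weights((HYDROPHOBIC, 1.0), (BASIC, 1.0))
    p2["P"] = -1.0
    fwy = _class_weights((AROMATIC, 1.0))
    return MotifProfile(
        position_weights={1: p1, 2: p2, 3: dict(fwy), 7: dict(fwy), 9: dict(fwy)},
        effect_size=effect_size,
        background=background_frequencies(background),
        length_distribution=dict(length_distribution or {9: 1.0}),
    )


@dataclass
class SyntheticDataset:
    """A generated labeled set plus the provenance needed to regenerate it."""

    peptides: LabeledPeptideSet
    profile: MotifProfile
    seed: int
    n_pos: int
    n_neg: int


def _slot_for_index(idx1: int, length: int) -> int | None:
    """Template slot for a 1-based residue index, or None for the interior."""
    if idx1 == length:
        return 9
    if idx1 <= min(8, length - 1):
        return idx1
    return None


def _sample_binder(profile: MotifProfile, length: int, rng: np.random.Generator) -> str:
    chars = []
    for idx1 in range(1, length + 1):
        slot = _slot_for_index(idx1, length)
        p = (
            profile.position_distribution(slot)
            if slot is not None
            else profile.background
        )
        chars.append(_AA[rng.choice(20, p=p)])
    return "".join(chars)


def generate(
    profile: MotifProfile, n_pos: int, n_neg: int, seed: int, name: str = "synthetic"
) -> SyntheticDataset:
    """Generate a labeled set: n_pos binders from the motif, n_neg
    non-binders from the background; globally unique sequences;
    bit-reproducible for a given (profile, n_pos, n_neg, seed)."""
    if n_pos < 1 or n_neg < 1:
        raise ValidationError("n_pos and n_neg must be >= 1")
    capacity = sum(
        20 ** L for L in profile.length_distribution if profile.length_distribution[L] > 0
    )
    if n_pos + n_neg > capacity:
        raise ValidationError(
            f"requested {n_pos + n_neg} peptides exceeds distinct-sequence "
            f"capacity {capacity}"
        )
    rng = np.random.default_rng(seed)
    lengths = sorted(profile.length_distribution)
    length_p = np.array([profile.length_distribution[L] for L in lengths])
    seen: set[str] = set()
    records: list[tuple[Peptide, int]] = []
    max_attempts = 1000 * (n_pos + n_neg)
    attempts = 0
    for label, n in ((+1, n_pos), (-1, n_neg)):
        made = 0
        while made < n:
            attempts += 1
            if attempts > max_attempts:
                raise ValidationError(
                    "could not generate enough unique sequences; "
                    "reduce n or broaden the length distribution"
                )
            L = lengths[rng.choice(len(lengths), p=length_p)]
            if label == +1:
                seq = _sample_binder(profile, L, rng)
            else:
                seq = "".join(_AA[rng.choice(20, size=L, p=profile.background)])
            if seq in seen:
                continue
            seen.add(seq)
            records.append((Peptide(seq), label))
            made += 1
    pset = LabeledPeptideSet(records=records, name=name)
    return SyntheticDataset(
        peptides=pset, profile=profile, seed=seed, n_pos=n_pos, n_neg=n_neg
    )


def generate_protein_with_implants(
    profile: MotifProfile,
    protein_length: int,
    n_implants: int,
    k: int = 9,
    seed: int = 0,
    protein_id: str = "synthetic_protein",
) -> tuple[ProteinRecord, list[int]]:
    """A background protein with binder-motif k-mers implanted.

    Returns the protein and the sorted 1-based start positions of the
    non-overlapping implants.
    """
    if k < 4:
        raise ValidationError(f"implant length k={k} must be >= 4")
    if n_implants < 0:
        raise ValidationError("n_implants must be >= 0")
    if n_implants * k > protein_length:
        raise ValidationError(
            f"{n_implants} implants of length {k} cannot fit in "
            f"{protein_length} residues"
        )
    rng = np.random.default_rng(seed)
    seq = list("".join(_AA[rng.choice(20, size=protein_length, p=profile.background)]))
    starts: list[int] = []
    max_tries = 10_000
    tries = 0
    while len(starts) < n_implants:
        tries += 1
        if tries > max_tries:
            raise ValidationError(
                f"could not place {n_implants} non-overlapping implants of "
                f"length {k} in {protein_length} residues"
            )
        s0 = int(rng.integers(0, protein_length - k + 1))
        if any(s0 < t0 + k and t0 < s0 + k for t0 in starts):
            continue
        starts.append(s0)
        implant = _sample_binder(profile, k, rng)
        seq[s0 : s0 + k] = implant
    protein = ProteinRecord(id=protein_id, sequence="".join(seq))
    return protein, sorted(s + 1 for s in starts)
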
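"""Coarse-grained polymer sequences and full-factorial design-space generation.

The design space is built from four monomer bead types: ``W`` (good-solvent,
weakly surface-attractive), ``R`` (bad-solvent, strongly surface-adsorbing),
and ``Ta`` / ``Tr`` (theta-solvent beads that differ in their surface
interaction).  A full-factorial design of experiments crosses a set of count
levels over the four types; each resulting composition is expanded into a
number of distinct random monomer arrangements.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np

MONOMER_TYPES: tuple[str, ...] = ("W", "R", "Ta", "Tr")
_BRACKET_RE = re.compile(r"\[([A-Za-z]+)\]")


def _check_symbol(symbol: str) -> str:
    if symbol not in MONOMER_TYPES:
        raise ValueError(f"unknown monomer symbol {symbol!r}; expected one of {MONOMER_TYPES}")
    return symbol


@dataclass(frozen=True)
class Composition:
    """Monomer counts per bead type; the coordinates of one DoE point."""

    counts: tuple[int, int, int, int]  # ordered as MONOMER_TYPES

    def __post_init__(self):
        if len(self.counts) != len(MONOMER_TYPES):
            raise ValueError("composition needs one count per monomer type")
        if any(c < 0 or int(c) != c for c in self.counts):
            raise ValueError(f"counts must be non-negative integers, got {self.counts}")
        if self.total < 1:
            raise ValueError("composition must contain at least one bead")

    @property
    def total(self) -> int:
        """Degree of polymerization N."""
        return int(sum(self.counts))

    def as_dict(self) -> dict[str, int]:
        return dict(zip(MONOMER_TYPES, (int(c) for c in self.counts)))

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "Composition":
        for key in counts:
            _check_symbol(key)
        return cls(tuple(int(counts.get(t, 0)) for t in MONOMER_TYPES))


@dataclass(frozen=True)
class PolymerSequence:
    """An ordered bead string; identified by its canonical bracket notation."""

    beads: tuple[str, ...]

    def __post_init__(self):
        if not self.beads:
            raise ValueError("empty sequence")
        for b in self.beads:
            _check_symbol(b)

    @property
    def id(self) -> str:
        return "".join(f"[{b}]" for b in self.beads)

    def __str__(self) -> str:
        return self.id

    def __len__(self) -> int:
        return len(self.beads)

    @property
    def composition(self) -> Composition:
        return Composition(tuple(self.beads.count(t) for t in MONOMER_TYPES))

    @classmethod
    def from_string(cls, text: str) -> "PolymerSequence":
        symbols = _BRACKET_RE.findall(text)
        if "".join(f"[{s}]" for s in symbols) != text.strip():
            raise ValueError(f"not a valid bracket-notation sequence: {text!r}")
        return cls(tuple(_check_symbol(s) for s in symbols))


def random_sequence(composition: Composition, seed) -> PolymerSequence:
    """Uniformly random arrangement of a composition's multiset of beads.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if composition.total < 1:
        raise ValueError("cannot arrange an empty composition")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beads = [t for t, c in zip(MONOMER_TYPES, composition.counts) for _ in range(c)]
    perm = rng.permutation(len(beads))
    return PolymerSequence(tuple(beads[i] for i in perm))


@dataclass
class DesignSpace:
    """A finite candidate list plus its feature matrix and provenance."""

    sequences: list[PolymerSequence]
    features: np.ndarray
    feature_names: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in design space")
        if self.features.shape != (len(self.sequences), len(self.feature_names)):
            raise ValueError("feature matrix shape inconsistent with sequences/names")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]


_MAX_REDRAWS = 1000


def enumerate_compositions(levels, n_factors: int) -> list[Composition]:
    """All |levels|^n_factors compositions; factor i sets the count of type i."""
    levels = sorted(int(v) for v in levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    if not 1 <= n_factors <= len(MONOMER_TYPES):
        raise ValueError(f"n_factors must be in 1..{len(MONOMER_TYPES)}")
    comps = []
    for combo in itertools.product(levels, repeat=n_factors):
        counts = list(combo) + [0] * (len(MONOMER_TYPES) - n_factors)
        comps.append(Composition(tuple(counts)))
    return comps


def full_factorial_design(
    levels,
    n_factors: int = 4,
    sequences_per_point: int = 5,
    seed: int = 0,
    interaction_table: dict[str, float] | None = None,
) -> DesignSpace:
    """Full-factorial DoE over bead counts, expanded into random sequences.

    Returns ``len(levels)**n_factors * sequences_per_point`` candidates.  The
    default settings of 4 factors, levels {4, 6, 8, 10, 12} and 5 sequences
    per composition give the 3125-polymer dispersant design space.  Distinct
    arrangements per composition are enforced by redrawing (bounded), so the
    result is deterministic given ``seed``.
    """
    from .features import featurize_all  # local import to avoid a cycle

    if sequences_per_point < 1:
        raise ValueError("sequences_per_point must be >= 1")
    comps = enumerate_compositions(levels, n_factors)
    rng = np.random.default_rng(seed)
    sequences: list[PolymerSequence] = []
    for comp in comps:
        seen: set[str] = set()
        draws = 0
        while len(seen) < sequences_per_point:
            seq = random_sequence(comp, rng)
            draws += 1
            if seq.id not in seen:
                seen.add(seq.id)
                sequences.append(seq)
            elif draws > _MAX_REDRAWS + sequences_per_point:
                raise RuntimeError(
                    f"could not draw {sequences_per_point} distinct arrangements "
                    f"for composition {comp.as_dict()} after {draws} attempts"
                )
    features, names = featurize_all(sequences, interaction_table)
    provenance = {
        "levels": sorted(int(v) for v in levels),
        "n_factors": int(n_factors),
        "sequences_per_point": int(sequences_per_point),
        "seed": int(seed),
    }
    return DesignSpace(sequences, features, names, provenance)
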
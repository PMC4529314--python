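"""Binary genotypes over the internal reactions of a reaction universe.

A metabolic genotype is a presence/absence vector over the N variable
(internal) reactions of a :class:`~fluxspace.universe.ReactionUniverse`.
Genotypes are stored as integer bit masks: bit ``i`` corresponds to the
``i``-th internal reaction in the universe's declared order.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class Genotype:
    """A fixed-length bit vector over internal reactions.

    Parameters
    ----------
    mask:
        Integer whose bit ``i`` is 1 when internal reaction ``i`` is present.
    n_bits:
        Total number of internal reactions N in the universe.
    """

    mask: int
    n_bits: int

    def __post_init__(self) -> None:
        if self.mask < 0 or self.mask >> self.n_bits:
            raise ValueError(
                f"mask {self.mask:#x} does not fit in {self.n_bits} bits"
            )

    @property
    def size(self) -> int:
        """Number of present reactions (popcount)."""
        return self.mask.bit_count()

    def has(self, i: int) -> bool:
        return bool(self.mask >> i & 1)

    def with_bit(self, i: int) -> "Genotype":
        return Genotype(self.mask | (1 << i), self.n_bits)

    def without_bit(self, i: int) -> "Genotype":
        return Genotype(self.mask & ~(1 << i), self.n_bits)

    def bits(self) -> tuple[int, ...]:
        """Indices of present reactions, ascending."""
        return tuple(i for i in range(self.n_bits) if self.mask >> i & 1)

    def to_hex(self) -> str:
        width = (self.n_bits + 3) // 4
        return f"{self.mask:0{width}x}"

    @classmethod
    def from_hex(cls, s: str, n_bits: int) -> "Genotype":
        return cls(int(s, 16), n_bits)

    @classmethod
    def full(cls, n_bits: int) -> "Genotype":
        return cls((1 << n_bits) - 1, n_bits)

    @classmethod
    def empty(cls, n_bits: int) -> "Genotype":
        return cls(0, n_bits)

    @classmethod
    def from_bits(cls, bits, n_bits: int) -> "Genotype":
        mask = 0
        for i in bits:
            if not 0 <= i < n_bits:
                raise ValueError(f"bit index {i} out of range for N={n_bits}")
            mask |= 1 << i
        return cls(mask, n_bits)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"Genotype({self.to_hex()}, n={self.size}/{self.n_bits})"


def genotype_distance(g1: Genotype, g2: Genotype) -> int:
    """Minimal number of reaction swaps between two same-size genotypes.

    Equal to half the Hamming distance of the two bit vectors.  Raises if
    the genotypes have different sizes (a swap preserves size, so the swap
    metric is only defined within a size class).
    """
    if g1.n_bits != g2.n_bits:
        raise ValueError("genotypes come from universes of different N")
    if g1.size != g2.size:
        raise ValueError("swap distance is defined for equal-size genotypes")
    return (g1.mask ^ g2.mask).bit_count() // 2


def hamming(m1: int, m2: int) -> int:
    return (m1 ^ m2).bit_count()
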
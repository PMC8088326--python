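"""Codon algebra for degenerate and spiked codon design.

A codon position synthesized from a nucleotide mixture is modelled as a
12-tuple: three blocks of four numbers giving, for each triplet position,
the share of T, C, A and G in the synthesis mix.  Two flavours exist:

* :class:`BaseCodon` — a binary 12-tuple recording only which nucleotides
  are present at each position (the *support*).  Base codons are in
  bijection with the three-letter IUPAC ambiguity strings; there are
  ``15**3 == 3375`` of them (each block is a non-empty subset of TCAG).
* :class:`SpikedCodon` — a real-valued 12-tuple whose blocks each sum to
  one.  A degenerate codon is the special case with equimolar fractions
  on its support.

Every codon encodes a distribution over the 21-symbol amino-acid alphabet
(20 residues plus STOP) under a :class:`GeneticCode`; a multiset of codons
encodes the equal-weight mixture of its codons' distributions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable, IUPACData

logger = logging.getLogger(__name__)

#: Nucleotide order of every 4-block, fixed once for the whole package.
NUCLEOTIDES = "TCAG"
NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

STOP = "*"
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Canonical 21-symbol alphabet: the 20 residues (alphabetical) plus STOP.
DEFAULT_SYMBOLS: tuple[str, ...] = tuple(AA20) + (STOP,)

#: The 64 concrete codons in (T, C, A, G) lexicographic order.
CODONS64: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
)
CODON_INDEX = {c: i for i, c in enumerate(CODONS64)}
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

IUPAC_LETTERS = "ACGTRYSWKMBDHVN"
IUPAC_TO_BASES = {
    letter: frozenset(IUPACData.ambiguous_dna_values[letter])
    for letter in IUPAC_LETTERS
}
BASES_TO_IUPAC = {bases: letter for letter, bases in IUPAC_TO_BASES.items()}


class CodonFormatError(ValueError):
    """Raised for strings that are not valid (possibly ambiguous) codons."""


def _check_concrete(codon: str) -> str:
    codon = codon.upper().replace("U", "T")
    if codon not in CODON_INDEX:
        raise CodonFormatError(f"not a concrete TCAG codon: {codon!r}")
    return codon


def codon_bits(codon: str) -> tuple[int, ...]:
    """12-bit indicator tuple of a concrete codon (one bit set per block)."""
    codon = _check_concrete(codon)
    bits = [0] * 12
    for i, nt in enumerate(codon):
        bits[4 * i + NT_INDEX[nt]] = 1
    return tuple(bits)


# ---------------------------------------------------------------------------
# Genetic code


class GeneticCode:
    """A total map from the 64 concrete codons to amino-acid symbols.

    The default is the standard nuclear code (NCBI translation table 1,
    stops TAA/TAG/TGA rendered as ``"*"``).  Codon reassignment — e.g. to
    free a stop codon for an unnatural residue — is expressed by
    :meth:`with_reassignments`, which may introduce user-labelled symbols
    beyond the canonical 21.
    """

    def __init__(self, table: Mapping[str, str], name: str = "custom"):
        table = {_check_concrete(c): str(s) for c, s in table.items()}
        if len(table) != 64:
            raise ValueError(f"genetic code must map all 64 codons, got {len(table)}")
        self._table = table
        self.name = name

    # -- constructors -------------------------------------------------
    @classmethod
    @lru_cache(maxsize=None)
    def standard(cls) -> "GeneticCode":
        return cls.from_ncbi_id(1)

    @classmethod
    def from_ncbi_id(cls, table_id: int) -> "GeneticCode":
        ncbi = CodonTable.unambiguous_dna_by_id[table_id]
        table = dict(ncbi.forward_table)
        for c in ncbi.stop_codons:
            table[c] = STOP
        return cls(table, name=ncbi.names[0] if ncbi.names else str(table_id))

    @classmethod
    def from_tsv(cls, path) -> "GeneticCode":
        """Read a 64-row ``codon<TAB>symbol`` table."""
        table = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                codon, symbol = line.split("\t")[:2]
                table[codon] = symbol
        return cls(table, name=str(path))

    def with_reassignments(self, reassignments: Mapping[str, str]) -> "GeneticCode":
        table = dict(self._table)
        for codon, symbol in reassignments.items():
            table[_check_concrete(codon)] = str(symbol)
        return GeneticCode(table, name=f"{self.name}+reassigned")

    # -- queries ------------------------------------------------------
    def __getitem__(self, codon: str) -> str:
        return self._table[_check_concrete(codon)]

    def items(self):
        return self._table.items()

    @property
    def symbols(self) -> frozenset:
        return frozenset(self._table.values())

    def symbol_alphabet(self) -> tuple[str, ...]:
        """Canonical symbol ordering: the default 21, then extras sorted."""
        extras = sorted(self.symbols - set(DEFAULT_SYMBOLS))
        present = [s for s in DEFAULT_SYMBOLS] + extras
        return tuple(present)

    def aa_indices(self, symbols: Sequence[str]) -> np.ndarray:
        """Index of each of the 64 codons' symbols in *symbols* (-1 if absent)."""
        pos = {s: i for i, s in enumerate(symbols)}
        return np.array([pos.get(self._table[c], -1) for c in CODONS64], dtype=int)

    def translate(self, dna: str) -> str:
        """Codon-wise translation of an unambiguous DNA string."""
        dna = dna.upper().replace("U", "T")
        if len(dna) % 3:
            raise ValueError(f"sequence length {len(dna)} is not a multiple of 3")
        return "".join(self._table[_check_concrete(dna[i : i + 3])]
                       for i in range(0, len(dna), 3))

    def __repr__(self):
        return f"GeneticCode({self.name!r})"


# ---------------------------------------------------------------------------
# Base codons


@dataclass(frozen=True)
class BaseCodon:
    """Binary 12-tuple: which nucleotides each triplet position admits."""

    bits: tuple[int, ...]

    def __post_init__(self):
        if len(self.bits) != 12 or any(b not in (0, 1) for b in self.bits):
            raise ValueError("BaseCodon needs a 12-tuple of 0/1 bits")
        for i in range(3):
            if sum(self.bits[4 * i : 4 * i + 4]) < 1:
                raise ValueError(f"position {i + 1} admits no nucleotide")

    # -- constructors -------------------------------------------------
    @classmethod
    def from_iupac(cls, s: str) -> "BaseCodon":
        s = s.upper().replace("U", "T")
        if len(s) != 3 or any(ch not in IUPAC_TO_BASES for ch in s):
            raise CodonFormatError(
                f"{s!r} is not a 3-letter IUPAC ambiguity string over {IUPAC_LETTERS}"
            )
        bits = []
        for ch in s:
            bases = IUPAC_TO_BASES[ch]
            bits.extend(1 if nt in bases else 0 for nt in NUCLEOTIDES)
        return cls(tuple(bits))

    @classmethod
    def from_codon(cls, codon: str) -> "BaseCodon":
        return cls(codon_bits(codon))

    # -- views --------------------------------------------------------
    @property
    def blocks(self) -> tuple[tuple[int, ...], ...]:
        return tuple(self.bits[4 * i : 4 * i + 4] for i in range(3))

    @property
    def block_sizes(self) -> tuple[int, int, int]:
        return tuple(sum(b) for b in self.blocks)  # type: ignore[return-value]

    @property
    def degeneracy(self) -> int:
        a, b, c = self.block_sizes
        return a * b * c

    def block_nucleotides(self) -> tuple[str, ...]:
        return tuple(
            "".join(nt for nt, bit in zip(NUCLEOTIDES, blk) if bit)
            for blk in self.blocks
        )

    def expand(self) -> tuple[str, ...]:
        """All concrete codons the pattern can produce, in TCAG order."""
        return _expand_bits(self.bits)

    def contains(self, codon: str) -> bool:
        fb = codon_bits(codon)
        return all(m >= f for m, f in zip(self.bits, fb))

    def to_iupac(self) -> str:
        return "".join(BASES_TO_IUPAC[frozenset(nts)] for nts in self.block_nucleotides())

    def __repr__(self):
        return f"BaseCodon({self.to_iupac()})"


@lru_cache(maxsize=4096)
def _expand_bits(bits: tuple[int, ...]) -> tuple[str, ...]:
    options = [
        [nt for nt, bit in zip(NUCLEOTIDES, bits[4 * i : 4 * i + 4]) if bit]
        for i in range(3)
    ]
    return tuple("".join(p) for p in itertools.product(*options))


# ---------------------------------------------------------------------------
# Spiked codons


@dataclass(frozen=True)
class SpikedCodon:
    """Real-valued 12-tuple of nucleotide fractions; each block sums to 1."""

    fractions: tuple[float, ...]

    _TOL = 1e-9

    def __post_init__(self):
        if len(self.fractions) != 12:
            raise ValueError("SpikedCodon needs a 12-tuple of fractions")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative")
        for i in range(3):
            s = sum(self.fractions[4 * i : 4 * i + 4])
            if abs(s - 1.0) > self._TOL:
                raise ValueError(f"block {i + 1} sums to {s!r}, expected 1")

    # -- constructors -------------------------------------------------
    @classmethod
    def equimolar(cls, base: BaseCodon) -> "SpikedCodon":
        fracs = []
        for blk in base.blocks:
            k = sum(blk)
            fracs.extend(b / k for b in blk)
        return cls(tuple(fracs))

    @classmethod
    def from_iupac(cls, s: str) -> "SpikedCodon":
        return cls.equimolar(BaseCodon.from_iupac(s))

    @classmethod
    def from_matrix(cls, m) -> "SpikedCodon":
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 4):
            raise ValueError("expected a 3x4 fraction matrix (rows=positions)")
        return cls(tuple(m.reshape(12)))

    # -- views --------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float).reshape(3, 4)

    @property
    def support(self) -> BaseCodon:
        return BaseCodon(tuple(1 if f > 0 else 0 for f in self.fractions))

    @property
    def is_degenerate(self) -> bool:
        eq = SpikedCodon.equimolar(self.support)
        return all(abs(a - b) <= 1e-9 for a, b in zip(self.fractions, eq.fractions))

    def codon_weights(self) -> Iterable[tuple[str, float]]:
        """(concrete codon, probability) pairs over the support."""
        m = self.matrix
        for codon in self.support.expand():
            w = 1.0
            for i, nt in enumerate(codon):
                w *= m[i, NT_INDEX[nt]]
            yield codon, w

    def __repr__(self):
        return f"SpikedCodon({self.support.to_iupac()}, fractions={self.fractions})"


Codon = BaseCodon | SpikedCodon


def excludes(m: Codon, f: str) -> bool:
    """True iff codon pattern *m* can never produce the concrete codon *f*.

    This is the forbidden-codon condition: some tuple position where *f*
    is non-zero has a zero entry in *m*.
    """
    vals = m.bits if isinstance(m, BaseCodon) else m.fractions
    fb = codon_bits(f)
    return any(fv and not mv for fv, mv in zip(fb, vals))


# ---------------------------------------------------------------------------
# Amino-acid distributions


class AminoAcidDistribution:
    """Non-negative weights over an amino-acid alphabet, normalized to 1.

    The default alphabet has 21 symbols: the 20 canonical residues plus
    STOP (``"*"``).  Reassigned genetic codes may extend it.
    """

    __slots__ = ("symbols", "weights")

    def __init__(self, weights, symbols: Sequence[str] = DEFAULT_SYMBOLS,
                 normalize: bool = True):
        symbols = tuple(symbols)
        arr = np.asarray(weights, dtype=float).copy()
        if arr.shape != (len(symbols),):
            raise ValueError(f"{len(symbols)} symbols but weight shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("negative weights are not allowed")
        total = arr.sum()
        if total <= 0:
            raise ValueError("weights sum to zero")
        if normalize:
            arr = arr / total
        elif abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {total!r}, expected 1")
        arr.flags.writeable = False
        self.symbols = symbols
        self.weights = arr

    # -- constructors -------------------------------------------------
    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float],
                     symbols: Sequence[str] | None = None) -> "AminoAcidDistribution":
        if symbols is None:
            extras = [s for s in mapping if s not in DEFAULT_SYMBOLS]
            symbols = tuple(DEFAULT_SYMBOLS) + tuple(sorted(extras))
        unknown = set(mapping) - set(symbols)
        if unknown:
            raise KeyError(f"unknown residue symbols: {sorted(unknown)}")
        w = [float(mapping.get(s, 0.0)) for s in symbols]
        return cls(w, symbols)

    @classmethod
    def uniform(cls, residues: Iterable[str],
                symbols: Sequence[str] | None = None) -> "AminoAcidDistribution":
        residues = list(residues)
        return cls.from_mapping({r: 1.0 for r in residues}, symbols)

    # -- queries ------------------------------------------------------
    def __getitem__(self, symbol: str) -> float:
        return float(self.weights[self.symbols.index(symbol)])

    def __len__(self):
        return len(self.symbols)

    def to_dict(self, drop_zero: bool = False) -> dict[str, float]:
        d = dict(zip(self.symbols, map(float, self.weights)))
        if drop_zero:
            d = {k: v for k, v in d.items() if v > 0}
        return d

    def as_series(self):
        import pandas as pd

        return pd.Series(self.weights, index=list(self.symbols), name="weight")

    def reindex(self, symbols: Sequence[str]) -> "AminoAcidDistribution":
        symbols = tuple(symbols)
        dropped = [s for s, w in zip(self.symbols, self.weights)
                   if w > 0 and s not in symbols]
        if dropped:
            raise ValueError(f"reindex would drop weight on {dropped}")
        d = self.to_dict()
        return AminoAcidDistribution([d.get(s, 0.0) for s in symbols], symbols,
                                     normalize=False)

    def distance(self, other: "AminoAcidDistribution", norm: str = "L2") -> float:
        if other.symbols != self.symbols:
            other = other.reindex(self.symbols)
        return vector_norm(self.weights - other.weights, norm)

    @property
    def support(self) -> tuple[str, ...]:
        return tuple(s for s, w in zip(self.symbols, self.weights) if w > 0)

    def __repr__(self):
        top = sorted(self.to_dict(drop_zero=True).items(),
                     key=lambda kv: -kv[1])[:6]
        body = ", ".join(f"{s}={w:.3f}" for s, w in top)
        return f"AminoAcidDistribution({body}{', ...' if len(self.support) > 6 else ''})"


NORMS = ("L1", "L2", "Linf")


def vector_norm(diff: np.ndarray, norm: str = "L2") -> float:
    """L1 / L2 / Linf norm of a difference vector."""
    if norm == "L2":
        return float(np.sqrt(np.sum(diff * diff)))
    if norm == "L1":
        return float(np.sum(np.abs(diff)))
    if norm == "Linf":
        return float(np.max(np.abs(diff)))
    raise ValueError(f"unknown norm {norm!r}; choose from {NORMS}")


def aa_distribution(codon: Codon, code: GeneticCode | None = None,
                    symbols: Sequence[str] | None = None) -> AminoAcidDistribution:
    """Amino-acid distribution encoded by one (spiked or base) codon.

    The weight of symbol *s* is the total probability of the concrete
    codons translating to *s*, with codon probability the product of its
    three per-position nucleotide fractions.
    """
    code = code or GeneticCode.standard()
    if symbols is None:
        symbols = code.symbol_alphabet()
    if isinstance(codon, BaseCodon):
        codon = SpikedCodon.equimolar(codon)
    pos = {s: i for i, s in enumerate(symbols)}
    weights = np.zeros(len(symbols))
    for concrete, w in codon.codon_weights():
        weights[pos[code[concrete]]] += w
    return AminoAcidDistribution(weights, tuple(symbols))


def mixture_distribution(multiset: Sequence[Codon], code: GeneticCode | None = None,
                         symbols: Sequence[str] | None = None) -> AminoAcidDistribution:
    """Equal-weight mixture of the distributions of a codon multiset."""
    if not multiset:
        raise ValueError("empty codon multiset")
    code = code or GeneticCode.standard()
    if symbols is None:
        symbols = code.symbol_alphabet()
    total = np.zeros(len(symbols))
    for c in multiset:
        total += aa_distribution(c, code, symbols).weights
    return AminoAcidDistribution(total / len(multiset), tuple(symbols))


# ---------------------------------------------------------------------------
# Enumeration

_NONEMPTY_BLOCKS: tuple[tuple[int, ...], ...] = tuple(
    blk for blk in itertools.product((0, 1), repeat=4) if any(blk)
)

#: All 3375 valid base-codon bit tuples in canonical (sorted) order.
ALL_BASE_BITS: tuple[tuple[int, ...], ...] = tuple(sorted(
    b1 + b2 + b3
    for b1 in _NONEMPTY_BLOCKS
    for b2 in _NONEMPTY_BLOCKS
    for b3 in _NONEMPTY_BLOCKS
))


def enumerate_base_codons(forbidden: Iterable[str] = (),
                          allowed_symbols: Iterable[str] | None = None,
                          code: GeneticCode | None = None,
                          max_degeneracy: int | None = None) -> list[BaseCodon]:
    """All base codons compatible with the given constraints.

    A base codon is kept when (a) its expansion contains no forbidden
    concrete codon, (b) every codon in its expansion translates to an
    allowed symbol, and (c) its degeneracy does not exceed
    *max_degeneracy* (when set).  The result is deterministic and sorted
    canonically by bit tuple; with no constraints it has all 3375 codons.
    """
    code = code or GeneticCode.standard()
    forbidden = {_check_concrete(f) for f in forbidden}
    allowed = None
    if allowed_symbols is not None:
        allowed = set(allowed_symbols)
        if not allowed:
            raise ValueError("allowed_symbols must be non-empty when given")
    out = []
    for bits in ALL_BASE_BITS:
        bc = BaseCodon(bits)
        if max_degeneracy is not None and bc.degeneracy > max_degeneracy:
            continue
        codons = bc.expand()
        if forbidden and any(c in forbidden for c in codons):
            continue
        if allowed is not None and any(code[c] not in allowed for c in codons):
            continue
        out.append(bc)
    if not out:
        logger.warning("constraints eliminated all 3375 base codons")
    return out


def encoded_symbols(base: BaseCodon, code: GeneticCode | None = None) -> set[str]:
    """Set of amino-acid symbols a base codon's expansion can produce."""
    code = code or GeneticCode.standard()
    return {code[c] for c in base.expand()}
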
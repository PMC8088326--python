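"""In-silico validation of designed templates.

Given a designed randomized region (a codon multiset) plus optional
constant DNA and protein context, this module samples concrete DNA
sequences position-by-position according to the design's nucleotide
fractions, translates them, and computes the quality-control statistics a
library designer inspects before ordering an oligonucleotide: achieved
amino-acid composition and its deviation from the target (both as norms
on the (0,1) scale and per-residue percentage points on the (0,100)
scale), sequence uniqueness, per-position nucleotide frequencies, the
expected molecular-weight distribution of the encoded proteins, and the
library's theoretical diversity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Data import IUPACData

from .codons import (
    AminoAcidDistribution,
    BaseCodon,
    GeneticCode,
    NT_INDEX,
    NUCLEOTIDES,
    STOP,
    SpikedCodon,
    mixture_distribution,
    vector_norm,
)

#: Average residue masses (free amino acid minus one water), daltons.
WATER_AVERAGE = 18.0153
WATER_MONOISOTOPIC = 18.010565
RESIDUE_MASS_AVERAGE = {
    aa: IUPACData.protein_weights[aa] - WATER_AVERAGE
    for aa in IUPACData.protein_weights
}
RESIDUE_MASS_MONOISOTOPIC = {
    aa: IUPACData.monoisotopic_protein_weights[aa] - WATER_MONOISOTOPIC
    for aa in IUPACData.monoisotopic_protein_weights
}

_NT_BYTES = np.frombuffer(NUCLEOTIDES.encode(), dtype=np.uint8)
_CHAR_TO_NT = np.full(256, -1, dtype=np.int8)
for _nt, _i in NT_INDEX.items():
    _CHAR_TO_NT[ord(_nt)] = _i


def translate(dna: str, code: GeneticCode | None = None) -> str:
    """Codon-wise translation; STOP codons render as ``"*"``.

    The input must be unambiguous DNA of length divisible by 3.
    """
    code = code or GeneticCode.standard()
    return code.translate(dna)


@dataclass
class TemplateDesign:
    """A designed template: randomized codons plus constant context.

    ``five_prime_constant``/``three_prime_constant`` are literal DNA
    flanks (no ambiguity codes); ``protein_prefix``/``protein_suffix``
    are constant residues (e.g. linker and purification tag) included in
    mass accounting but not encoded by the randomized region given here.
    """

    codons: list[SpikedCodon]
    five_prime_constant: str = ""
    three_prime_constant: str = ""
    protein_prefix: str = ""
    protein_suffix: str = ""

    def __post_init__(self):
        if not self.codons:
            raise ValueError("a template needs at least one randomized codon")
        self.codons = [
            SpikedCodon.equimolar(c) if isinstance(c, BaseCodon) else c
            for c in self.codons
        ]
        for region in (self.five_prime_constant, self.three_prime_constant):
            if any(ch not in NT_INDEX for ch in region):
                raise ValueError(
                    f"constant DNA region {region!r} contains non-TCAG characters"
                )

    @classmethod
    def from_iupac(cls, template: str, **kwargs) -> "TemplateDesign":
        """Equimolar (degenerate) design from a concatenated IUPAC string."""
        if len(template) % 3:
            raise ValueError("template length must be a multiple of 3")
        codons = [SpikedCodon.from_iupac(template[i : i + 3])
                  for i in range(0, len(template), 3)]
        return cls(codons=codons, **kwargs)

    @property
    def length(self) -> int:
        return len(self.codons)

    def position_fractions(self) -> np.ndarray:
        """(3l, 4) matrix of per-position nucleotide fractions (T, C, A, G)."""
        return np.vstack([c.matrix for c in self.codons])

    def mixture(self, code: GeneticCode | None = None,
                symbols=None) -> AminoAcidDistribution:
        return mixture_distribution(self.codons, code, symbols)


def _sample_matrix(design: TemplateDesign, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """(n, 3l) matrix of nucleotide indices for the randomized region."""
    probs = design.position_fractions()
    L = probs.shape[0]
    out = np.empty((n, L), dtype=np.int8)
    for j in range(L):
        cum = np.cumsum(probs[j])
        cum[-1] = 1.0
        out[:, j] = np.searchsorted(cum, rng.random(n), side="right")
    return out


def sample_sequences(design: TemplateDesign, n: int,
                     rng: np.random.Generator) -> list[str]:
    """Draw *n* concrete DNA sequences from the design.

    Each randomized position is drawn independently with the design's
    nucleotide fractions; constant flanks are attached verbatim.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    idx = _sample_matrix(design, n, rng)
    chars = _NT_BYTES[idx]
    width = chars.shape[1]
    region = chars.reshape(-1).view(f"S{width}")
    pre, post = design.five_prime_constant, design.three_prime_constant
    return [pre + b.decode() + post for b in region]


def _region_matrix(design: TemplateDesign, sequences: Sequence[str]) -> np.ndarray:
    """Nucleotide-index matrix of the randomized region of given sequences."""
    start = len(design.five_prime_constant)
    L = 3 * design.length
    joined = "".join(s[start : start + L] for s in sequences)
    if len(joined) != L * len(sequences):
        raise ValueError("sequence shorter than the template's randomized region")
    raw = np.frombuffer(joined.encode(), dtype=np.uint8)
    idx = _CHAR_TO_NT[raw].reshape(len(sequences), L)
    if (idx < 0).any():
        raise ValueError("sequences contain non-TCAG characters in the region")
    return idx


@dataclass
class SampleStats:
    """Composition and diversity statistics of a sampled sequence set."""

    n: int
    composition: AminoAcidDistribution
    per_residue_deviation_pct: np.ndarray | None
    distances: dict | None
    uniqueness_fraction: float
    position_freqs: np.ndarray  # (4, 3l), rows T, C, A, G
    mass_mean: float | None = None
    mass_sd: float | None = None
    n_stop_excluded: int | None = None

    def to_json(self, path=None, indent: int = 2) -> str:
        payload = {
            "n": self.n,
            "composition": self.composition.to_dict(),
            "uniqueness_fraction": self.uniqueness_fraction,
            "per_residue_deviation_pct": (
                None if self.per_residue_deviation_pct is None
                else dict(zip(self.composition.symbols,
                              map(float, self.per_residue_deviation_pct)))
            ),
            "distances": self.distances,
            "mass_mean": self.mass_mean,
            "mass_sd": self.mass_sd,
            "n_stop_excluded": self.n_stop_excluded,
        }
        text = json.dumps(payload, indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def position_freqs_tsv(self, path=None) -> str:
        """Logo-ready TSV: rows T, C, A, G; one column per position."""
        lines = ["\t".join(["nt"] + [str(i + 1)
                                     for i in range(self.position_freqs.shape[1])])]
        for nt, row in zip(NUCLEOTIDES, self.position_freqs):
            lines.append("\t".join([nt] + [f"{v:.6f}" for v in row]))
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def composition_stats(sequences: Sequence[str], design: TemplateDesign,
                      target: AminoAcidDistribution | None = None,
                      code: GeneticCode | None = None,
                      protein_level_uniqueness: bool = False) -> SampleStats:
    """Pooled composition of the randomized region of sampled sequences.

    Deviations (when a target is given) are reported both as L1/L2/Linf
    norms on the (0,1) scale and per residue in percentage points on the
    (0,100) scale.  Uniqueness is #distinct/#total, at the DNA level by
    default.
    """
    if not sequences:
        raise ValueError("empty sequence set")
    code = code or GeneticCode.standard()
    symbols = target.symbols if target is not None else code.symbol_alphabet()
    idx = _region_matrix(design, sequences)
    n, L = idx.shape

    counts = np.zeros((L, 4), dtype=np.int64)
    cols = np.broadcast_to(np.arange(L), (n, L))
    np.add.at(counts, (cols.reshape(-1), idx.reshape(-1).astype(np.intp)), 1)
    position_freqs = (counts / n).T  # (4, L)

    codon_idx = (16 * idx[:, 0::3].astype(np.int32)
                 + 4 * idx[:, 1::3] + idx[:, 2::3])
    aa_idx = code.aa_indices(symbols)
    if (aa_idx[np.unique(codon_idx)] < 0).any():
        raise ValueError("sampled codons translate to symbols outside the alphabet")
    aa = aa_idx[codon_idx]
    comp_counts = np.bincount(aa.reshape(-1), minlength=len(symbols))
    composition = AminoAcidDistribution(comp_counts, symbols)

    if protein_level_uniqueness:
        distinct = len({a.tobytes() for a in aa})
    else:
        start = len(design.five_prime_constant)
        distinct = len({s[start : start + 3 * design.length] for s in sequences})
    uniqueness = distinct / n

    deviation_pct = None
    distances = None
    if target is not None:
        diff = composition.weights - target.weights
        deviation_pct = diff * 100.0
        l2 = vector_norm(diff, "L2")
        distances = {
            "L1": vector_norm(diff, "L1"),
            "L2": l2,
            "Linf": vector_norm(diff, "Linf"),
            "sum_squared": l2 ** 2,
            "mean_squared_per_symbol": l2 ** 2 / len(diff),
        }
    return SampleStats(
        n=n,
        composition=composition,
        per_residue_deviation_pct=deviation_pct,
        distances=distances,
        uniqueness_fraction=uniqueness,
        position_freqs=position_freqs,
    )


@dataclass
class MassStats:
    """Mean/SD of the encoded protein mass, daltons."""

    mean: float
    sd: float
    mode: str
    n: int | None = None
    n_stop_excluded: int | None = None


def _mass_vector(symbols, masses: str) -> np.ndarray:
    table = (RESIDUE_MASS_AVERAGE if masses == "average"
             else RESIDUE_MASS_MONOISOTOPIC)
    if masses not in ("average", "monoisotopic"):
        raise ValueError("masses must be 'average' or 'monoisotopic'")
    out = np.zeros(len(symbols))
    for i, s in enumerate(symbols):
        if s == STOP:
            out[i] = np.nan  # never summed: stop rows are excluded
        else:
            try:
                out[i] = table[s]
            except KeyError:
                raise KeyError(f"no {masses} mass for residue symbol {s!r}")
    return out


def mass_distribution(design: TemplateDesign, n: int | None = None,
                      rng: np.random.Generator | None = None,
                      mode: str = "sampled", masses: str = "average",
                      code: GeneticCode | None = None) -> MassStats:
    """Expected molecular-weight distribution of the encoded proteins.

    ``sampled`` draws *n* sequences, translates them and reports the
    mean/SD of the full-length protein mass; sequences containing a stop
    codon would not yield the tagged full-length product, so they are
    excluded and counted.  ``closed_form`` uses per-position independence:
    each position's residue distribution is conditioned on not being a
    stop, which makes the closed form exactly the mean/SD of the sampled
    (stop-free) ensemble in the infinite-sample limit.

    Average residue masses are the default (linear-mode MALDI convention);
    pass ``masses="monoisotopic"`` for monoisotopic values.
    """
    code = code or GeneticCode.standard()
    symbols = code.symbol_alphabet()
    water = WATER_AVERAGE if masses == "average" else WATER_MONOISOTOPIC
    mass_vec = _mass_vector(symbols, masses)
    const_mass = water + sum(
        _mass_vector((aa,), masses)[0]
        for aa in design.protein_prefix + design.protein_suffix
    )
    stop_i = symbols.index(STOP)

    if mode == "closed_form":
        mean = const_mass
        var = 0.0
        for codon in design.codons:
            from .codons import aa_distribution

            w = aa_distribution(codon, code, symbols).weights.copy()
            p_stop = w[stop_i]
            if p_stop >= 1:
                raise ValueError("a position encodes only STOP")
            w[stop_i] = 0.0
            w = w / w.sum()
            m = float(np.nansum(w * np.nan_to_num(mass_vec)))
            m2 = float(np.nansum(w * np.nan_to_num(mass_vec) ** 2))
            mean += m
            var += m2 - m * m
        return MassStats(mean=mean, sd=math.sqrt(var), mode=mode)

    if mode != "sampled":
        raise ValueError("mode must be 'sampled' or 'closed_form'")
    if n is None or rng is None:
        raise ValueError("sampled mode needs n and rng")
    idx = _sample_matrix(design, n, rng)
    codon_idx = (16 * idx[:, 0::3].astype(np.int32)
                 + 4 * idx[:, 1::3] + idx[:, 2::3])
    aa = code.aa_indices(symbols)[codon_idx]
    has_stop = (aa == stop_i).any(axis=1)
    kept = aa[~has_stop]
    if kept.shape[0] == 0:
        raise ValueError("every sampled sequence contained a stop codon")
    m = np.nan_to_num(mass_vec)[kept].sum(axis=1) + const_mass
    return MassStats(mean=float(m.mean()), sd=float(m.std(ddof=1)),
                     mode=mode, n=int(kept.shape[0]),
                     n_stop_excluded=int(has_stop.sum()))


def diversity(design: TemplateDesign, sample_size: int = 10_000,
              rng: np.random.Generator | None = None,
              code: GeneticCode | None = None) -> tuple[int, float]:
    """(exact DNA diversity, protein diversity estimate).

    DNA diversity is the exact product of per-position support sizes
    (arbitrary-precision integer).  Protein diversity is estimated by
    birthday-collision counting on a seeded sample of translated
    sequences: with c colliding pairs among m samples the estimate is
    m(m-1)/(2c); with no collisions the sample only certifies a lower
    bound and ``inf`` is returned.
    """
    code = code or GeneticCode.standard()
    dna_div = 1
    for codon in design.codons:
        for size in codon.support.block_sizes:
            dna_div *= size
    rng = rng if rng is not None else np.random.default_rng(0)
    m = sample_size
    idx = _sample_matrix(design, m, rng)
    codon_idx = (16 * idx[:, 0::3].astype(np.int32)
                 + 4 * idx[:, 1::3] + idx[:, 2::3])
    symbols = code.symbol_alphabet()
    aa = code.aa_indices(symbols)[codon_idx]
    seen: dict[bytes, int] = {}
    for row in aa:
        key = row.tobytes()
        seen[key] = seen.get(key, 0) + 1
    collisions = sum(k * (k - 1) // 2 for k in seen.values())
    if collisions == 0:
        return dna_div, math.inf
    return dna_div, m * (m - 1) / (2 * collisions)


def sample_stats(design: TemplateDesign, n: int, rng: np.random.Generator,
                 target: AminoAcidDistribution | None = None,
                 code: GeneticCode | None = None,
                 masses: str = "average") -> SampleStats:
    """One-stop validation: sample once, compute composition and mass stats."""
    code = code or GeneticCode.standard()
    sequences = sample_sequences(design, n, rng)
    stats = composition_stats(sequences, design, target, code)

    # Mass statistics from the same sampled ensemble.
    symbols = code.symbol_alphabet()
    water = WATER_AVERAGE if masses == "average" else WATER_MONOISOTOPIC
    mass_vec = _mass_vector(symbols, masses)
    const_mass = water + sum(
        _mass_vector((aa,), masses)[0]
        for aa in design.protein_prefix + design.protein_suffix
    )
    idx = _region_matrix(design, sequences)
    codon_idx = (16 * idx[:, 0::3].astype(np.int32)
                 + 4 * idx[:, 1::3] + idx[:, 2::3])
    aa = code.aa_indices(symbols)[codon_idx]
    stop_i = symbols.index(STOP)
    has_stop = (aa == stop_i).any(axis=1)
    kept = aa[~has_stop]
    if kept.shape[0]:
        m = np.nan_to_num(mass_vec)[kept].sum(axis=1) + const_mass
        stats.mass_mean = float(m.mean())
        stats.mass_sd = float(m.std(ddof=1)) if kept.shape[0] > 1 else 0.0
    stats.n_stop_excluded = int(has_stop.sum())
    return stats
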
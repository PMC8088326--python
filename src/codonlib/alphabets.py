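"""Built-in target distributions used for design examples and benchmarks.

Three families cover the common use cases: a uniform target over the full
canonical alphabet, a uniform target over a reduced "early" alphabet of
ten residues thought to predate the full genetic code, and the average
residue frequencies of natural proteins (Swiss-Prot release averages).
"""

from __future__ import annotations

from .codons import AA20, AminoAcidDistribution

#: Ten-residue reduced alphabet approximating an early genetic code.
EARLY_ALPHABET: tuple[str, ...] = tuple("ASDGLETIPV")

#: Average amino-acid frequencies (%) in UniProtKB/Swiss-Prot (2019-era
#: release statistics), a stand-in for "natural" protein composition.
NATURAL_FREQUENCIES_PCT: dict[str, float] = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}


def uniform20() -> AminoAcidDistribution:
    """Uniform target over all 20 canonical residues (no STOP)."""
    return AminoAcidDistribution.uniform(AA20)


def uniform_early10() -> AminoAcidDistribution:
    """Uniform target over the ten-residue early alphabet A,S,D,G,L,E,T,I,P,V."""
    return AminoAcidDistribution.uniform(EARLY_ALPHABET)


def natural() -> AminoAcidDistribution:
    """Swiss-Prot average composition, normalized."""
    return AminoAcidDistribution.from_mapping(NATURAL_FREQUENCIES_PCT)


BUILTIN_TARGETS = {
    "uniform20": uniform20,
    "early10": uniform_early10,
    "uniform10": uniform_early10,
    "natural": natural,
}
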
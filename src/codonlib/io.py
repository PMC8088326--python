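"""Readers, writers, template export and design reports.

Targets come in as TSV or JSON residue->weight tables, templates go out
as FASTA (degenerate IUPAC strings) or per-position nucleotide ratio
tables (TSV, percent scale), and a run's full provenance is captured in a
JSON report that is bit-identically regenerable from (config, seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Data import IUPACData

from .codons import (
    AminoAcidDistribution,
    BaseCodon,
    NUCLEOTIDES,
    STOP,
    SpikedCodon,
)
from .design import LibraryDesigner, ReplicateSet

logger = logging.getLogger(__name__)

_THREE_TO_ONE = {k.upper(): v for k, v in IUPACData.protein_letters_3to1.items()}
_STOP_ALIASES = {"*", "STOP", "TER", "TERM"}


def _parse_residue(token: str) -> str:
    token = token.strip()
    if token.upper() in _STOP_ALIASES:
        return STOP
    if len(token) == 1 and token.upper() in IUPACData.protein_letters:
        return token.upper()
    if len(token) == 3 and token.upper() in _THREE_TO_ONE:
        return _THREE_TO_ONE[token.upper()]
    raise ValueError(f"unknown residue code {token!r}")


def read_target_distribution(path) -> AminoAcidDistribution:
    """Read a residue->weight table (JSON object or two-column TSV).

    Residues may use 1- or 3-letter codes (plus ``*``/``STOP``); weights
    are non-negative and normalized to sum to one; omitted residues get
    weight zero.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        raw = json.loads(text)
        if not isinstance(raw, dict):
            raise ValueError("JSON target must be an object of residue: weight")
        items = list(raw.items())
    else:
        items = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split("\t" if "\t" in line else None)
            if len(parts) < 2:
                raise ValueError(f"cannot parse target line {line!r}")
            items.append((parts[0], parts[1]))
    weights: dict[str, float] = {}
    for token, value in items:
        residue = _parse_residue(str(token))
        w = float(value)
        if w < 0:
            raise ValueError(f"negative weight {w} for residue {residue}")
        weights[residue] = weights.get(residue, 0.0) + w
    if not weights or sum(weights.values()) <= 0:
        raise ValueError("target distribution has no positive weight")
    return AminoAcidDistribution.from_mapping(weights)


def read_codon_usage(path) -> dict[str, float]:
    """Read a codon-usage TSV of ``codon<TAB>frequency`` rows.

    Per-thousand tables (values summing to ~1000) are auto-detected and
    rescaled to relative frequencies.
    """
    usage: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split("\t" if "\t" in line else None)
        codon = parts[0].upper().replace("U", "T")
        usage[codon] = float(parts[1])
    total = sum(usage.values())
    if total > 10:  # per-thousand or percent table
        usage = {c: v / total for c, v in usage.items()}
    return usage


# ---------------------------------------------------------------------------
# Template export


def quantize_block(fractions: Sequence[float], step: float = 0.01) -> list[float]:
    """Round a 4-block of fractions to multiples of *step*, preserving support.

    The block is re-normalized by largest-remainder so the rounded values
    sum to exactly one, and any support nucleotide that rounding would
    zero out is bumped to the minimum step (taken from the largest entry).
    """
    f = np.asarray(fractions, dtype=float)
    units = int(round(1.0 / step))
    scaled = f * units
    floor = np.floor(scaled).astype(int)
    remainder = scaled - floor
    short = units - floor.sum()
    for i in np.argsort(-remainder)[:short]:
        floor[i] += 1
    # Preserve support: no positive fraction may quantize to zero.
    for i in range(4):
        if f[i] > 0 and floor[i] == 0:
            donor = int(np.argmax(floor))
            floor[donor] -= 1
            floor[i] = 1
            logger.warning(
                "quantization would zero a support nucleotide; bumped to %g", step
            )
    return [v / units for v in floor]


def export_template(multiset: Sequence[SpikedCodon], mode: str,
                    path=None, quantization_step: float = 0.01,
                    shuffle_seed: int | None = None, record_id: str = "design"):
    """Export a designed multiset as an orderable template artifact.

    Degenerate mode returns (and optionally writes as FASTA) the
    concatenated IUPAC triplet string; spiked mode returns a per-position
    ratio DataFrame (percent scale, quantized to *quantization_step*).
    ``shuffle_seed`` applies a reproducible random codon order; the
    mixture composition is order-invariant.
    """
    import pandas as pd

    codons = list(multiset)
    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(len(codons))
        codons = [codons[i] for i in order]
    if mode == "degenerate":
        seq = "".join(
            (c if isinstance(c, BaseCodon) else c.support).to_iupac()
            for c in codons
        )
        if path is not None:
            record = SeqRecord(Seq(seq), id=record_id,
                               description="degenerate codon library template")
            SeqIO.write([record], str(path), "fasta")
        return seq
    if mode != "spiked":
        raise ValueError("mode must be 'degenerate' or 'spiked'")
    rows = []
    for j, codon in enumerate(codons):
        if isinstance(codon, BaseCodon):
            codon = SpikedCodon.equimolar(codon)
        m = codon.matrix
        for i in range(3):
            q = quantize_block(m[i], quantization_step)
            rows.append({"position": 3 * j + i + 1,
                         "T": 100 * q[0], "C": 100 * q[1],
                         "A": 100 * q[2], "G": 100 * q[3]})
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return frame


def read_ratio_table(path) -> list[SpikedCodon]:
    """Read a spiked-template ratio TSV back into codons."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t")
    need = {"position", *NUCLEOTIDES}
    if not need.issubset(frame.columns):
        raise ValueError(f"ratio table must have columns {sorted(need)}")
    frame = frame.sort_values("position")
    if len(frame) % 3:
        raise ValueError("ratio table rows must come in codon triplets")
    mat = frame[list(NUCLEOTIDES)].to_numpy(dtype=float)
    if mat.max() > 1.5:  # percent scale
        mat = mat / 100.0
    mat = mat / mat.sum(axis=1, keepdims=True)
    return [SpikedCodon.from_matrix(mat[i : i + 3]) for i in range(0, len(mat), 3)]


def read_template_fasta(path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one template record, got {len(records)}")
    return str(records[0].seq).upper()


def write_fasta(sequences: Sequence[str], path, prefix: str = "seq"):
    records = [SeqRecord(Seq(s), id=f"{prefix}{i}", description="")
               for i, s in enumerate(sequences)]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Combinatorics helper


def vertical_oligo_count(options_per_position: int, positions: int) -> int:
    """Oligos needed by a vertical (one oligo per combination) scheme.

    With *k* codon options at each of *p* mutagenized positions a
    vertical design needs ``k**p`` separate oligonucleotides, versus one
    degenerate oligo — e.g. 3 options at 3 positions already demand 27.
    """
    if options_per_position < 1 or positions < 1:
        raise ValueError("both arguments must be >= 1")
    return options_per_position ** positions


# ---------------------------------------------------------------------------
# Reports


def build_report(designer: LibraryDesigner, replicates: ReplicateSet,
                 config_echo: Mapping | None = None,
                 quantization_step: float = 0.01) -> dict:
    """Assemble the JSON-serializable design report for a replicate set."""
    best = replicates.best
    template: dict = {"iupac_support": best.as_iupac()}
    if designer.mode == "spiked":
        frame = export_template(best.multiset, "spiked",
                                quantization_step=quantization_step)
        template["ratio_table_pct"] = frame.to_dict(orient="records")
    comp = []
    for s, t, a in zip(best.target.symbols, best.target.weights,
                       best.achieved.weights):
        if t == 0 and a == 0:
            continue
        comp.append({"symbol": s, "target_pct": 100 * t,
                     "achieved_pct": 100 * a, "deviation_pp": 100 * (a - t)})
    report = {
        "config": dict(config_echo or {}),
        "pool_size": len(designer.pool),
        "mode": designer.mode,
        "norm": designer.norm,
        "length": designer.length,
        "template": template,
        "composition": comp,
        "distance_metrics": best.distance_metrics(),
        "best_replicate": {
            "seed": best.seed,
            "final_distance": best.final_distance,
            "accepted": best.accepted_count,
            "rejected": best.rejected_count,
        },
        "replicates": [
            {"seed": r.seed, "final_distance": r.final_distance,
             "accepted": r.accepted_count, "rejected": r.rejected_count}
            for r in replicates.results
        ],
    }
    return report


def write_report(report: Mapping, path):
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
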
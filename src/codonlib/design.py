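"""Stochastic design of codon multisets matching a target composition.

The designer searches for a multiset of ``l`` codons whose mixture
amino-acid distribution is as close as possible (in an L1/L2/Linf sense)
to a target distribution, subject to a forbidden-codon constraint.  The
search is an evolutionary hill climb: start from ``l`` random codons,
repeatedly propose a replacement, accept it only if the distance to the
target strictly decreases, and stop once ``rejection_factor * l``
consecutive proposals have been rejected.

Two design modes exist.  In *degenerate* mode every codon is an equimolar
IUPAC degenerate codon and a proposal swaps in a fresh random codon.  In
*spiked* mode per-position nucleotide ratios are free; the default
proposal is likewise a fresh random spiked codon, and an optional local
move (``ratio_shift_prob``) instead re-draws the nucleotide ratios at one
position of an existing codon, which can refine solutions further once
the search has nearly converged.

The public surface follows the model/results convention:
``LibraryDesigner(target, length, ...).fit(seed)`` returns a
:class:`DesignResult` holding the multiset, the achieved distribution and
diagnostics, with :meth:`DesignResult.summary` for a human-readable view.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .codons import (
    AminoAcidDistribution,
    BaseCodon,
    GeneticCode,
    NORMS,
    SpikedCodon,
    STOP,
    STOP_CODONS,
    enumerate_base_codons,
    mixture_distribution,
    vector_norm,
)

logger = logging.getLogger(__name__)

MODES = ("degenerate", "spiked")


class InfeasibleTargetError(ValueError):
    """The constraints leave no codon pool able to encode the target."""


# ---------------------------------------------------------------------------
# Free functions mirroring the algorithm's primitives


def dist(target: AminoAcidDistribution, multiset: Sequence, norm: str = "L2",
         code: GeneticCode | None = None) -> float:
    """Distance between a target distribution and a codon multiset's mixture."""
    mix = mixture_distribution(multiset, code, symbols=target.symbols)
    return vector_norm(target.weights - mix.weights, norm)


def propose_codon(pool: Sequence[BaseCodon], mode: str,
                  rng: np.random.Generator) -> SpikedCodon:
    """Draw one random codon on a uniformly chosen base codon from the pool.

    Degenerate mode gives the equimolar codon; spiked mode draws each
    position's fractions from a flat Dirichlet over the support.
    """
    if not pool:
        raise InfeasibleTargetError("empty base-codon pool")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
    base = pool[int(rng.integers(len(pool)))]
    if mode == "degenerate":
        return SpikedCodon.equimolar(base)
    fracs = []
    for blk in base.blocks:
        k = sum(blk)
        draw = rng.dirichlet(np.ones(k))
        it = iter(draw)
        fracs.extend(float(next(it)) if b else 0.0 for b in blk)
    return SpikedCodon(tuple(fracs))


def preselect_pool(target: AminoAcidDistribution,
                   code: GeneticCode | None = None,
                   forbidden: Iterable[str] = (),
                   forbid_stops: bool = True,
                   codon_usage: Mapping[str, float] | None = None,
                   min_usage: float = 0.0,
                   max_degeneracy: int | None = None) -> list[BaseCodon]:
    """Pre-select base codons able to serve the target distribution.

    Removes every base codon that can produce a forbidden codon, a codon
    of a zero-weight residue, a stop codon (unless allowed), or — when a
    codon-usage table is given — a concrete codon whose relative usage
    falls below ``min_usage``.
    """
    code = code or GeneticCode.standard()
    forbidden = {f.upper().replace("U", "T") for f in forbidden}
    if forbid_stops:
        if STOP in target.symbols and target[STOP] > 0:
            raise InfeasibleTargetError(
                "target puts weight on STOP but stop codons are forbidden; "
                "pass forbid_stops=False to design read-through libraries"
            )
        forbidden |= STOP_CODONS
    if codon_usage is not None:
        low = {c.upper().replace("U", "T") for c, u in codon_usage.items()
               if u < min_usage}
        forbidden |= low
    allowed = set(target.support) - {STOP} if forbid_stops else set(target.support)
    pool = enumerate_base_codons(forbidden=forbidden, allowed_symbols=allowed,
                                 code=code, max_degeneracy=max_degeneracy)
    logger.info("pre-selected %d of 3375 base codons", len(pool))
    return pool


# ---------------------------------------------------------------------------
# Results


@dataclass
class DesignResult:
    """Outcome of one optimization run."""

    multiset: list[SpikedCodon]
    final_distance: float
    distance_trace: list[float]
    accepted_count: int
    rejected_count: int
    seed: int
    target: AminoAcidDistribution
    achieved: AminoAcidDistribution
    norm: str
    mode: str
    model: "LibraryDesigner | None" = field(default=None, repr=False)

    @property
    def length(self) -> int:
        return len(self.multiset)

    @property
    def per_residue_deviation_pct(self) -> np.ndarray:
        """Signed achieved-minus-target deviation per symbol, percentage points."""
        return (self.achieved.weights - self.target.weights) * 100.0

    def distance_metrics(self) -> dict[str, float]:
        diff = self.target.weights - self.achieved.weights
        l2 = vector_norm(diff, "L2")
        return {
            "L1": vector_norm(diff, "L1"),
            "L2": l2,
            "Linf": vector_norm(diff, "Linf"),
            "sum_squared": l2 ** 2,
            "mean_squared_per_symbol": l2 ** 2 / len(diff),
        }

    def as_iupac(self) -> str:
        """The template as concatenated IUPAC triplets (codon supports)."""
        return "".join(c.support.to_iupac() for c in self.multiset)

    def ratio_table(self):
        """Per-position nucleotide fractions as a tidy DataFrame."""
        import pandas as pd

        rows = []
        for j, codon in enumerate(self.multiset):
            m = codon.matrix
            for i in range(3):
                rows.append({"position": 3 * j + i + 1,
                             "T": m[i, 0], "C": m[i, 1],
                             "A": m[i, 2], "G": m[i, 3]})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Codon library design results",
            "=" * 60,
            f"mode: {self.mode}   norm: {self.norm}   length: {self.length} codons",
            f"seed: {self.seed}   accepted: {self.accepted_count}   "
            f"rejected: {self.rejected_count}",
            f"final {self.norm} distance: {self.final_distance:.6g}",
            f"template (IUPAC support): {self.as_iupac()}",
            "-" * 60,
            f"{'symbol':>6} {'target %':>10} {'achieved %':>11} {'dev (pp)':>9}",
        ]
        for s, t, a in zip(self.target.symbols, self.target.weights,
                           self.achieved.weights):
            if t == 0 and a == 0:
                continue
            lines.append(f"{s:>6} {100 * t:>10.3f} {100 * a:>11.3f} "
                         f"{100 * (a - t):>+9.3f}")
        return "\n".join(lines)

    def to_template(self, **kwargs):
        """Convert to a :class:`codonlib.sampling.TemplateDesign`."""
        from .sampling import TemplateDesign

        return TemplateDesign(codons=list(self.multiset), **kwargs)

    def plot_composition(self, ax=None):
        """Bar plot of target vs achieved composition (percent scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        sym = [s for s, t, a in zip(self.target.symbols, self.target.weights,
                                    self.achieved.weights) if t > 0 or a > 0]
        t = [100 * self.target[s] for s in sym]
        a = [100 * self.achieved[s] for s in sym]
        x = np.arange(len(sym))
        ax.bar(x - 0.2, t, width=0.4, label="target")
        ax.bar(x + 0.2, a, width=0.4, label="achieved")
        ax.set_xticks(x, sym)
        ax.set_ylabel("occurrence (%)")
        ax.legend(frameon=False)
        return ax


@dataclass
class ReplicateSet:
    """Results of several independent seeded runs of the same design."""

    results: list[DesignResult]

    @property
    def best(self) -> DesignResult:
        """Lowest final distance; ties broken by lowest replicate index."""
        return min(self.results, key=lambda r: (r.final_distance,))

    @property
    def distances(self) -> np.ndarray:
        return np.array([r.final_distance for r in self.results])

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "replicate": range(len(self.results)),
            "seed": [r.seed for r in self.results],
            "distance": self.distances,
            "accepted": [r.accepted_count for r in self.results],
        })


# ---------------------------------------------------------------------------
# The designer model


class LibraryDesigner:
    """Design a codon multiset whose mixture matches a target composition.

    Parameters
    ----------
    target :
        The desired amino-acid distribution (an
        :class:`~codonlib.codons.AminoAcidDistribution` or a plain
        ``symbol -> weight`` mapping, normalized automatically).
    length :
        Number of codons in the randomized region.
    mode :
        ``"degenerate"`` (equimolar IUPAC codons) or ``"spiked"``
        (free per-position nucleotide ratios).
    norm :
        Distance used as the objective; L2 by default.
    forbidden, forbid_stops, codon_usage/min_usage, max_degeneracy :
        Pool pre-selection constraints; see :func:`preselect_pool`.
    rejection_factor :
        The run stops after ``rejection_factor * length`` consecutive
        rejected proposals (default 1000).
    ratio_shift_prob :
        In spiked mode, the probability that a proposal shifts the ratios
        of one position of an existing codon instead of swapping in a
        fresh random codon.  Default 0 (whole-codon proposals only);
        ignored in degenerate mode.
    pool :
        Pre-built base-codon pool, bypassing pre-selection (mainly for
        testing and custom workflows).
    """

    def __init__(self, target, length: int, mode: str = "degenerate", *,
                 norm: str = "L2",
                 genetic_code: GeneticCode | None = None,
                 forbidden: Iterable[str] = (),
                 forbid_stops: bool = True,
                 codon_usage: Mapping[str, float] | None = None,
                 min_usage: float = 0.0,
                 max_degeneracy: int | None = None,
                 rejection_factor: int = 1000,
                 ratio_shift_prob: float | None = None,
                 pool: Sequence[BaseCodon] | None = None):
        if not isinstance(target, AminoAcidDistribution):
            target = AminoAcidDistribution.from_mapping(dict(target))
        if length < 1:
            raise ValueError("length must be >= 1")
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
        if norm not in NORMS:
            raise ValueError(f"unknown norm {norm!r}; choose from {NORMS}")
        if rejection_factor < 1:
            raise ValueError("rejection_factor must be >= 1")
        self.code = genetic_code or GeneticCode.standard()
        self.length = int(length)
        self.mode = mode
        self.norm = norm
        self.rejection_factor = int(rejection_factor)
        self.forbidden = frozenset(f.upper().replace("U", "T") for f in forbidden) | (
            STOP_CODONS if forbid_stops else frozenset()
        )
        self.forbid_stops = forbid_stops
        if ratio_shift_prob is None:
            ratio_shift_prob = 0.0
        if mode == "degenerate":
            ratio_shift_prob = 0.0
        if not 0.0 <= ratio_shift_prob <= 1.0:
            raise ValueError("ratio_shift_prob must lie in [0, 1]")
        self.ratio_shift_prob = float(ratio_shift_prob)

        if pool is None:
            pool = preselect_pool(target, self.code, forbidden, forbid_stops,
                                  codon_usage, min_usage, max_degeneracy)
        self.pool = list(pool)
        if not self.pool:
            raise InfeasibleTargetError(
                "no base codon survives pre-selection under these constraints"
            )
        self.target = target
        self._prepare_arrays()
        self._check_feasibility()

    @classmethod
    def from_target_file(cls, path, length: int, mode: str = "degenerate",
                         **kwargs) -> "LibraryDesigner":
        from .io import read_target_distribution

        return cls(read_target_distribution(path), length, mode, **kwargs)

    # -- setup --------------------------------------------------------
    def _prepare_arrays(self):
        # Extend the symbol axis so every codon the pool can emit has an index.
        symbols = list(self.target.symbols)
        extra = sorted(
            {self.code[c] for b in self.pool for c in b.expand()} - set(symbols)
        )
        symbols += extra
        self.symbols: tuple[str, ...] = tuple(symbols)
        self._target_vec = np.concatenate(
            [self.target.weights, np.zeros(len(extra))]
        )
        S = len(symbols)
        aa_idx = self.code.aa_indices(symbols)  # (64,), -1 for absent symbols
        C = np.zeros((64, S + 1))
        C[np.arange(64), aa_idx] = 1.0  # -1 lands in the dummy last column
        self._C64 = C
        P = len(self.pool)
        sup = np.zeros((P, 3, 4))
        for k, b in enumerate(self.pool):
            sup[k] = np.array(b.bits, dtype=float).reshape(3, 4)
        self._support = sup
        eq = sup / sup.sum(axis=2, keepdims=True)
        self._eq_frac = eq
        self._deg_aa = self._aa_of(eq)

    def _check_feasibility(self):
        encodable = set()
        for b in self.pool:
            encodable |= {self.code[c] for c in b.expand()}
        missing = [s for s in self.target.support if s not in encodable]
        if missing:
            raise InfeasibleTargetError(
                f"no selectable codon can encode residues {missing}"
            )

    def _aa_of(self, F: np.ndarray) -> np.ndarray:
        """Amino-acid weight vectors (K, S) for fraction matrices F (K, 3, 4)."""
        W = (F[:, 0, :, None, None] * F[:, 1, None, :, None]
             * F[:, 2, None, None, :]).reshape(F.shape[0], 64)
        return (W @ self._C64)[:, :-1]

    def _metric(self, diffs: np.ndarray) -> np.ndarray:
        # L2 is compared on the squared scale (monotone, cheaper).
        if self.norm == "L2":
            return np.einsum("ks,ks->k", diffs, diffs)
        if self.norm == "L1":
            return np.abs(diffs).sum(axis=1)
        return np.abs(diffs).max(axis=1)

    def _to_report_scale(self, val: float) -> float:
        return math.sqrt(val) if self.norm == "L2" else val

    def _draw_redraws(self, rng: np.random.Generator, pool_idx: np.ndarray,
                      G: np.ndarray) -> np.ndarray:
        """Fraction matrices for fresh-codon proposals on given pool entries."""
        if self.mode == "degenerate":
            return self._eq_frac[pool_idx].copy()
        F = G * self._support[pool_idx]
        F /= F.sum(axis=2, keepdims=True)
        return F

    # -- fitting ------------------------------------------------------
    def fit(self, seed: int = 0) -> DesignResult:
        """Run the hill climb once; identical (config, seed) gives identical results."""
        rng = np.random.default_rng(seed)
        l, P = self.length, len(self.pool)
        D = self._target_vec
        spiked = self.mode == "spiked"

        # Initial multiset: l independent fresh proposals.
        init_idx = rng.integers(P, size=l)
        G0 = rng.standard_exponential((l, 3, 4))
        Mfrac = self._draw_redraws(rng, init_idx, G0)
        Maa = self._aa_of(Mfrac)
        Ssum = Maa.sum(axis=0)
        d_old = float(self._metric((D - Ssum / l)[None, :])[0])
        trace = [self._to_report_scale(d_old)]

        limit = self.rejection_factor * l
        rejected = accepted = total_rejected = 0
        chunk = 64
        while rejected < limit:
            K = chunk
            pool_idx = rng.integers(P, size=K)
            repl_idx = rng.integers(l, size=K)
            G = rng.standard_exponential((K, 3, 4))
            if spiked and self.ratio_shift_prob > 0:
                shift = rng.random(K) < self.ratio_shift_prob
                block_idx = rng.integers(3, size=K)
            else:
                shift = np.zeros(K, dtype=bool)
                block_idx = np.zeros(K, dtype=int)

            s = 0
            any_accept = False
            while s < K and rejected < limit:
                pi, ri = pool_idx[s:], repl_idx[s:]
                F = self._draw_redraws(rng, pi, G[s:])
                sh = np.flatnonzero(shift[s:])
                if sh.size:
                    base = Mfrac[ri[sh]].copy()
                    b = block_idx[s:][sh]
                    blk = G[s:][sh, b] * (base[np.arange(sh.size), b] > 0)
                    blk /= blk.sum(axis=1, keepdims=True)
                    base[np.arange(sh.size), b] = blk
                    F[sh] = base
                AA = self._aa_of(F)
                newsum = Ssum[None, :] - Maa[ri] + AA
                vals = self._metric(D[None, :] - newsum / l)
                cap = limit - rejected
                improving = np.flatnonzero(vals < d_old)
                if improving.size and improving[0] < cap:
                    k = int(improving[0])
                    rejected += k
                    total_rejected += k
                    r = int(ri[k])
                    Ssum = Ssum - Maa[r] + AA[k]
                    Maa[r] = AA[k]
                    Mfrac[r] = F[k]
                    d_old = float(vals[k])
                    trace.append(self._to_report_scale(d_old))
                    accepted += 1
                    rejected = 0
                    any_accept = True
                    s += k + 1
                else:
                    n_rej = min(K - s, cap)
                    rejected += n_rej
                    total_rejected += n_rej
                    s = K
            chunk = 64 if any_accept else min(chunk * 2, 8192)

        multiset = [SpikedCodon.from_matrix(Mfrac[i]) for i in range(l)]
        achieved = mixture_distribution(multiset, self.code, self.symbols)
        final = vector_norm(self._target_vec - achieved.weights, self.norm)
        logger.info("fit(seed=%s): distance=%.6g accepted=%d rejected=%d",
                    seed, final, accepted, total_rejected)
        return DesignResult(
            multiset=multiset,
            final_distance=final,
            distance_trace=trace,
            accepted_count=accepted,
            rejected_count=total_rejected,
            seed=int(seed),
            target=AminoAcidDistribution(self._target_vec, self.symbols,
                                         normalize=False),
            achieved=achieved,
            norm=self.norm,
            mode=self.mode,
            model=self,
        )

    def fit_replicates(self, replicates: int = 10, seed: int = 0) -> ReplicateSet:
        """Independent runs with seeds ``seed, seed+1, ..., seed+replicates-1``."""
        if replicates < 1:
            raise ValueError("replicates must be >= 1")
        return ReplicateSet([self.fit(seed + k) for k in range(replicates)])


# ---------------------------------------------------------------------------
# Benchmarking


def benchmark(distributions: Mapping[str, AminoAcidDistribution],
              lengths: Sequence[int], replicates: int = 10,
              mode: str = "degenerate", seed: int = 0,
              **designer_kwargs):
    """Grid of seeded designs: every (distribution, length) cell, replicated.

    Returns a tidy DataFrame with one row per run
    (``distribution_id, length, replicate, mode, seed, distance``).
    """
    import pandas as pd

    rows = []
    cell = 0
    for name, target in distributions.items():
        for length in lengths:
            designer = LibraryDesigner(target, length, mode, **designer_kwargs)
            for rep in range(replicates):
                run_seed = seed + 1000 * cell + rep
                res = designer.fit(run_seed)
                rows.append({"distribution_id": name, "length": length,
                             "replicate": rep, "mode": mode, "seed": run_seed,
                             "distance": res.final_distance})
            cell += 1
    return pd.DataFrame(rows)


def summarize_benchmark(frame):
    """Per-cell mean distance and coefficient of variation."""
    g = frame.groupby(["distribution_id", "length", "mode"])["distance"]
    out = g.agg(["mean", "std", "min", "max"]).reset_index()
    out["cv"] = out["std"] / out["mean"]
    return out
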
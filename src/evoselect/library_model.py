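"""Degenerate-oligonucleotide (doped) library model.

A target window of a coding sequence is mutagenised by synthesising the
corresponding oligonucleotides with a small fraction of each incorrect base
spiked into every coupling step.  Each nucleotide position therefore mutates
independently with a per-position substitution probability set by the doping
ratio of the synthesis segment that covers it.  This module owns the target
coordinates, enumerates the reachable single-nucleotide variants, derives the
distribution of substitution counts per molecule (a convolution of one
binomial per synthesis segment), and samples mutated molecules for the
selection simulator.

Coordinates are 1-based and inclusive on the coding strand of the CDS;
codon 1 is the initiator Met.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

BASES = ("A", "C", "G", "T")
_BASE_SET = frozenset(BASES)


@dataclass(frozen=True)
class TargetRegion:
    """A coding sequence plus the codon window subjected to mutagenesis.

    Parameters
    ----------
    cds_sequence : str
        Coding sequence, A/C/G/T only, length divisible by 3.
    codon_start, codon_end : int
        1-based inclusive codon window (codon 1 = initiator Met).
    """

    cds_sequence: str
    codon_start: int
    codon_end: int

    def __post_init__(self) -> None:
        seq = self.cds_sequence.upper()
        object.__setattr__(self, "cds_sequence", seq)
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise ValueError(
                f"CDS length must be a positive multiple of 3, got {len(seq)}"
            )
        n_codons = len(seq) // 3
        if self.codon_start < 1:
            raise ValueError(f"codon_start={self.codon_start} must be >= 1")
        if self.codon_end < self.codon_start:
            raise ValueError(
                f"codon_end={self.codon_end} < codon_start={self.codon_start}"
            )
        if self.codon_end > n_codons:
            raise ValueError(
                f"codon_end={self.codon_end} exceeds CDS length of {n_codons} codons"
            )

    # -- coordinate bookkeeping -------------------------------------------
    @property
    def nt_start(self) -> int:
        """First CDS nucleotide of the window (1-based)."""
        return 3 * (self.codon_start - 1) + 1

    @property
    def nt_end(self) -> int:
        """Last CDS nucleotide of the window (1-based, inclusive)."""
        return 3 * self.codon_end

    @property
    def length(self) -> int:
        return self.nt_end - self.nt_start + 1

    @property
    def n_codons(self) -> int:
        return self.codon_end - self.codon_start + 1

    @property
    def window_sequence(self) -> str:
        return self.cds_sequence[self.nt_start - 1 : self.nt_end]

    def codon_of(self, cds_pos: int) -> int:
        """Residue (codon) number containing a 1-based CDS position."""
        return (cds_pos - 1) // 3 + 1

    def contains(self, cds_pos: int) -> bool:
        return self.nt_start <= cds_pos <= self.nt_end


def region_nt_span(region: TargetRegion) -> tuple[int, int, int]:
    """Return ``(start_nt, end_nt, length)`` of the window in CDS coordinates.

    For a window of codons 79-137 this is ``(235, 411, 177)``.
    """
    return region.nt_start, region.nt_end, region.length


def enumerate_single_substitutions(
    region: TargetRegion,
) -> list[tuple[int, str, str]]:
    """All single-nucleotide substitutions reachable inside the window.

    Returns one ``(cds_pos, ref_base, alt_base)`` triple per possibility:
    exactly ``3 * region.length`` entries (531 for a 59-codon window).
    """
    window = region.window_sequence
    bad = set(window) - _BASE_SET
    if bad:
        raise ValueError(
            f"window contains ambiguity codes {sorted(bad)}; only A/C/G/T allowed"
        )
    out: list[tuple[int, str, str]] = []
    for offset, ref in enumerate(window):
        pos = region.nt_start + offset
        for alt in BASES:
            if alt != ref:
                out.append((pos, ref, alt))
    return out


@dataclass(frozen=True)
class DopingScheme:
    """Segmented per-position substitution probabilities of a doped synthesis.

    ``segments`` is an ordered list of ``(length_nt, per_position_substitution
    probability)`` covering the window 5'->3'.  ``alt_base_distribution`` gives
    the probabilities of the three non-reference bases (in alphabetical order
    of the bases excluding the reference); equal spiking of the three wrong
    phosphoramidites implies the uniform default.  ``efficiency`` is a scalar
    multiplying every per-position probability, exposed because doping
    chemistry commonly under-incorporates relative to the nominal mix: fit it
    with :func:`fit_efficiency` to match an observed wild-type fraction.
    """

    segments: tuple[tuple[int, float], ...]
    alt_base_distribution: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        segs = tuple((int(length), float(p)) for length, p in self.segments)
        object.__setattr__(self, "segments", segs)
        object.__setattr__(
            self, "alt_base_distribution", tuple(float(x) for x in self.alt_base_distribution)
        )
        if not segs:
            raise ValueError("scheme needs at least one segment")
        for length, p in segs:
            if length <= 0:
                raise ValueError(f"segment length {length} must be positive")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"substitution probability {p} outside [0, 1]")
        if len(self.alt_base_distribution) != 3 or any(
            x < 0 for x in self.alt_base_distribution
        ):
            raise ValueError("alt_base_distribution must be 3 nonnegative probabilities")
        if abs(sum(self.alt_base_distribution) - 1.0) > 1e-9:
            raise ValueError("alt_base_distribution must sum to 1")
        if self.efficiency < 0:
            raise ValueError("efficiency must be nonnegative")
        if any(self.efficiency * p > 1.0 + 1e-12 for _, p in segs):
            raise ValueError("efficiency * p exceeds 1 for some segment")

    @classmethod
    def default(cls, efficiency: float = 1.0) -> "DopingScheme":
        """Two tandem oligos covering 177 nt: 100 nt at 1.5% (3 x 0.5%), then
        77 nt at 1.0% (3 x 0.33%) per-position substitution probability."""
        return cls(segments=((100, 0.015), (77, 0.010)), efficiency=efficiency)

    @property
    def total_length(self) -> int:
        return sum(length for length, _ in self.segments)

    def position_probs(self) -> np.ndarray:
        """Effective per-position substitution probabilities, 5'->3'."""
        parts = [
            np.full(length, self.efficiency * p) for length, p in self.segments
        ]
        return np.concatenate(parts)

    def with_efficiency(self, efficiency: float) -> "DopingScheme":
        return dataclasses.replace(self, efficiency=efficiency)


@dataclass(frozen=True)
class MutationSpectrum:
    """Distribution of per-molecule substitution counts.

    ``pmf`` indexes probabilities by substitution count k; ``class_fractions``
    buckets them into wild type (k=0), single, double, triple and four-plus.
    """

    pmf: np.ndarray
    class_fractions: dict[str, float]


def substitution_count_pmf(
    scheme: DopingScheme, max_k: int | None = None
) -> MutationSpectrum:
    """Exact pmf of the number of substitutions per synthesised molecule.

    Positions mutate independently, so each segment contributes a
    Binomial(L_i, p_i) count and the total is their convolution.  ``max_k``
    optionally truncates the *reported* pmf; class fractions always use the
    full distribution.
    """
    if max_k is not None and max_k < 0:
        raise ValueError(f"max_k must be >= 0, got {max_k}")
    full = np.array([1.0])
    for length, p in scheme.segments:
        seg = stats.binom.pmf(np.arange(length + 1), length, scheme.efficiency * p)
        full = np.convolve(full, seg)
    tail4 = float(full[4:].sum()) if full.size > 4 else 0.0
    classes = {
        "wild_type": float(full[0]),
        "single": float(full[1]) if full.size > 1 else 0.0,
        "double": float(full[2]) if full.size > 2 else 0.0,
        "triple": float(full[3]) if full.size > 3 else 0.0,
        "four_plus": tail4,
    }
    pmf = full if max_k is None else full[: max_k + 1]
    return MutationSpectrum(pmf=pmf, class_fractions=classes)


def fit_efficiency(scheme: DopingScheme, wt_fraction: float) -> float:
    """Efficiency scalar reproducing an observed wild-type (k=0) fraction.

    Solves ``prod_i (1 - s*p_i)^{L_i} = wt_fraction`` for s.  Useful when the
    realised library carries far fewer substitutions than the nominal doping
    predicts (e.g. ~70% wild type observed against ~10% predicted).
    """
    if not 0.0 < wt_fraction < 1.0:
        raise ValueError("wt_fraction must be in (0, 1)")
    p_max = max(p for _, p in scheme.segments)
    if p_max == 0:
        raise ValueError("scheme has all-zero doping; efficiency is undetermined")

    def log_wt(s: float) -> float:
        return sum(
            length * np.log1p(-s * p) for length, p in scheme.segments
        ) - np.log(wt_fraction)

    hi = min(1.0 / p_max * (1 - 1e-12), 1e6)
    if log_wt(hi) > 0:
        raise ValueError("wt_fraction unreachable even at maximal doping")
    return float(optimize.brentq(log_wt, 0.0, hi))


def sample_library_molecule(
    region: TargetRegion, scheme: DopingScheme, rng: np.random.Generator
) -> tuple[str, tuple[tuple[int, str, str], ...]]:
    """Draw one mutagenised window molecule.

    Each window position mutates independently with its segment's effective
    probability; the replacement base is drawn from the scheme's alt-base
    distribution over the three non-reference bases in alphabetical order.
    Returns the mutated window sequence and the substitution list in CDS
    coordinates.  Deterministic for a fixed ``rng`` state.
    """
    probs = scheme.position_probs()
    if probs.size != region.length:
        raise ValueError(
            f"scheme covers {probs.size} nt but window is {region.length} nt"
        )
    window = region.window_sequence
    hits = np.flatnonzero(rng.random(region.length) < probs)
    if hits.size == 0:
        return window, ()
    alt_probs = np.asarray(scheme.alt_base_distribution)
    choices = rng.choice(3, size=hits.size, p=alt_probs)
    seq = list(window)
    subs = []
    for offset, which in zip(hits.tolist(), choices.tolist()):
        ref = window[offset]
        alts = [b for b in BASES if b != ref]
        alt = alts[which]
        seq[offset] = alt
        subs.append((region.nt_start + offset, ref, alt))
    return "".join(seq), tuple(subs)


def expected_colonies(total_colonies: int, class_fraction: float) -> int:
    """Colonies of a mutation class in a library of ``total_colonies``.

    Plain bookkeeping (e.g. 27,500 colonies at a 16.6% single-substitution
    fraction -> 4,565 single-mutant colonies), rounded to the nearest colony.
    """
    if total_colonies < 0:
        raise ValueError("total_colonies must be nonnegative")
    if not 0.0 <= class_fraction <= 1.0:
        raise ValueError("class_fraction must be in [0, 1]")
    return int(round(total_colonies * class_fraction))
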
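"""Assay arithmetic for characterising selected recombinase variants.

Implements the numeric transformations of the biochemical and cellular
assays: conversion of a coupled-assay NADH absorbance slope into an ATP
hydrolysis rate, apparent k_cat normalised by available protomer binding
sites (one site per 3 nt of ssDNA, or protein-limited), percent-of-maximum
and percent-decline comparisons, transconjugant frequency per 10^6 donors,
competition-plate QC and mutant-fraction trajectories, UV survival percent,
and SOS-reporter specific fluorescence.

Report-style rounding is one decimal, round-half-even; raw values are always
returned unrounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

#: NADH molar extinction coefficient at 380 nm (mM^-1 cm^-1).
NADH_EXTINCTION_380 = 1.21
#: Spectrophotometer cell path length (cm).
DEFAULT_PATH_CM = 1.0
#: Nucleotides of ssDNA covered per recombinase protomer.
SITE_SIZE_NT = 3


def round_report(x: float, ndigits: int = 1) -> float:
    """Banker's rounding for report output (round-half-even)."""
    return round(x, ndigits)


@dataclass(frozen=True)
class BindingSiteContext:
    """Concentrations determining the available protomer binding sites.

    ssDNA is in uM nucleotides; protein in uM protomers; ``site_size`` in
    nucleotides per protomer.
    """

    ssdna_uM: float
    protein_uM: float
    site_size: int = SITE_SIZE_NT

    def __post_init__(self) -> None:
        if self.ssdna_uM <= 0 or self.protein_uM <= 0 or self.site_size <= 0:
            raise ValueError("concentrations and site size must be positive")

    @property
    def sites_uM(self) -> float:
        """Available binding sites: DNA-limited (ssDNA/site_size) or
        protein-limited, whichever is smaller."""
        return min(self.protein_uM, self.ssdna_uM / self.site_size)


def nadh_slope_to_rate(
    slope_per_min: float,
    extinction_mM: float = NADH_EXTINCTION_380,
    path_cm: float = DEFAULT_PATH_CM,
) -> float:
    """ATP hydrolysis rate (uM/min) from an A380 slope (per min).

    NADH oxidation is stoichiometric with ATP regeneration, so
    rate = |slope| / (extinction x path), converted from mM to uM.  The slope
    may be passed as the (negative) raw slope or as a magnitude.
    """
    if extinction_mM <= 0 or path_cm <= 0:
        raise ValueError("extinction coefficient and path length must be positive")
    return abs(slope_per_min) / (extinction_mM * path_cm) * 1000.0


def apparent_kcat(rate_uM_per_min: float, ctx: BindingSiteContext) -> float:
    """Observed hydrolysis rate divided by available binding sites (min^-1)."""
    sites = ctx.sites_uM
    if sites <= 0:
        raise ValueError("no available binding sites")
    return rate_uM_per_min / sites


def rate_from_kcat(kcat_per_min: float, ctx: BindingSiteContext) -> float:
    """Inverse of :func:`apparent_kcat` (uM ATP/min)."""
    return kcat_per_min * ctx.sites_uM


def percent_of_max(k_obs: float, k_max: float) -> float:
    """Activity as a percent of the maximal (cssDNA) rate."""
    if k_max <= 0:
        raise ValueError("k_max must be positive")
    return 100.0 * k_obs / k_max


def percent_decline(before: float, after: float) -> float:
    """Percent decline of a rate after a challenge (e.g. RecX addition)."""
    if before <= 0:
        raise ValueError("pre-challenge rate must be positive")
    return 100.0 * (before - after) / before


def transconjugant_frequency(colonies: float, donors: float) -> float:
    """Recombinant colonies per 10^6 donor cells."""
    if donors <= 0:
        raise ValueError("donor count must be positive")
    if colonies < 0:
        raise ValueError("colony count must be nonnegative")
    return 1e6 * colonies / donors


def fold_change(a: float, b: float) -> float:
    """Ratio of two frequencies (variant over wild type)."""
    if b <= 0:
        raise ValueError("denominator must be positive")
    return a / b


def propagate_ratio(a: float, sa: float, b: float, sb: float) -> tuple[float, float]:
    """First-order uncertainty propagation for a ratio a/b.

    Returns (ratio, sd).  Derived, not part of the assays' own reporting.
    """
    if a == 0 or b == 0:
        raise ValueError("propagation needs nonzero means")
    r = a / b
    return r, abs(r) * math.hypot(sa / a, sb / b)


MIN_TOTAL_COLONIES = 40
MAX_TOTAL_COLONIES = 300
MIN_COMPETITOR_COLONIES = 20


def qc_plate(red: int, white: int) -> tuple[bool, str]:
    """Competition-plate inclusion rule.

    Plates are countable with 40-300 total colonies, and plates with fewer
    than 20 colonies of either competitor are excluded as outlier-prone.
    """
    if red < 0 or white < 0:
        raise ValueError("colony counts must be nonnegative")
    total = red + white
    if not MIN_TOTAL_COLONIES <= total <= MAX_TOTAL_COLONIES:
        return False, f"total {total} outside [{MIN_TOTAL_COLONIES}, {MAX_TOTAL_COLONIES}]"
    if min(red, white) < MIN_COMPETITOR_COLONIES:
        return False, f"competitor below {MIN_COMPETITOR_COLONIES} colonies"
    return True, "included"


@dataclass
class CompetitionResult:
    """Per-plate QC flags and the per-cycle percent-mutant trajectory."""

    plates: pd.DataFrame
    trajectory: pd.DataFrame


def competition_fraction(
    plate_counts: list[list[tuple[int, int]]], mutant_color: str = "red"
) -> CompetitionResult:
    """Percent-mutant trajectory from (red, white) plate counts per cycle.

    ``plate_counts[c]`` lists the plates of growth cycle c.  Excluded plates
    are flagged with the reason; the fraction uses included plates only and a
    cycle with no included plates reports NaN.  The rule is order-independent
    and idempotent (it depends only on each plate's own counts).
    """
    if mutant_color not in ("red", "white"):
        raise ValueError("mutant_color must be 'red' or 'white'")
    plate_rows = []
    traj_rows = []
    for cycle, plates in enumerate(plate_counts):
        mutant = 0
        total = 0
        n_inc = 0
        for plate_no, (red, white) in enumerate(plates):
            included, reason = qc_plate(red, white)
            plate_rows.append(
                {
                    "cycle": cycle,
                    "plate": plate_no,
                    "red": red,
                    "white": white,
                    "included": included,
                    "reason": reason,
                }
            )
            if included:
                n_inc += 1
                mutant += red if mutant_color == "red" else white
                total += red + white
        traj_rows.append(
            {
                "cycle": cycle,
                "n_plates": len(plates),
                "n_included": n_inc,
                "percent_mutant": 100.0 * mutant / total if total else float("nan"),
            }
        )
    return CompetitionResult(
        plates=pd.DataFrame(plate_rows), trajectory=pd.DataFrame(traj_rows)
    )


def survival_percent(treated_cfu: float, untreated_cfu: float) -> float:
    """Percent survival after a treatment (e.g. a UV dose)."""
    if untreated_cfu <= 0:
        raise ValueError("untreated count must be positive")
    if treated_cfu < 0:
        raise ValueError("treated count must be nonnegative")
    return 100.0 * treated_cfu / untreated_cfu


def specific_fluorescence(fluorescence: float, od600: float) -> float:
    """SOS-reporter fluorescence normalised by culture density.

    Raises on a zero/negative OD600, mirroring the suppression of early
    low-density time points where the ratio is dominated by noise.
    """
    if od600 <= 0:
        raise ValueError("OD600 must be positive")
    return fluorescence / od600
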
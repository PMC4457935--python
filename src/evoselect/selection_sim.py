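"""Synthetic-data generator for the iterative conjugational selection.

A plasmid library drawn from the doping model (or specified explicitly) is
carried through selection cycles in which the next pool is one multinomial
draw of ``bottleneck`` colonies with probabilities proportional to
frequency x fitness — fitness being the relative transconjugant yield of a
protein variant (wild type = 1).  Each cycle's population is then "sequenced"
into paired-end FASTQ reads with configurable per-base error, alongside
ground-truth frequency tables, so the analysis pipeline can be validated
end to end without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference as _reference
from .amplicon_enrichment import ReadPair, revcomp, translate_genotype
from .library_model import DopingScheme, TargetRegion, sample_library_molecule

#: Default relative transconjugant yield of an enhanced variant
#: (~352.8 / 125.3 colonies per 10^6 donors, variant vs wild type).
ENHANCED_FITNESS_DEFAULT = 2.8

#: Default colony bottlenecks of the six selection cycles.
DEFAULT_BOTTLENECKS = (2000, 10000, 800, 75, 75, 40)

Genotype = tuple[tuple[int, str, str], ...]

_ENC = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class VariantFitness:
    """Relative transconjugant yield per protein-variant label (WT = 1)."""

    values: dict[str, float] = field(default_factory=dict)
    default: float = 1.0

    def __post_init__(self) -> None:
        if self.default <= 0 or any(v <= 0 for v in self.values.values()):
            raise ValueError("fitness values must be positive")

    def get(self, label: str) -> float:
        return self.values.get(label, self.default)

    @classmethod
    def from_yields(
        cls, yields: dict[str, float], wt_yield: float
    ) -> "VariantFitness":
        """Fitness map from transconjugant yields (colonies per 10^6 donors)."""
        if wt_yield <= 0:
            raise ValueError("wt_yield must be positive")
        return cls(values={k: v / wt_yield for k, v in yields.items()})


@dataclass(frozen=True)
class SelectionConfig:
    """Cycle count, per-cycle colony bottlenecks and initial pool size."""

    bottlenecks: tuple[int, ...] = DEFAULT_BOTTLENECKS
    initial_size: int = 27500
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bottlenecks or any(b < 1 for b in self.bottlenecks):
            raise ValueError("bottlenecks must be >= 1")
        if self.initial_size < 1:
            raise ValueError("initial_size must be >= 1")

    @property
    def n_cycles(self) -> int:
        return len(self.bottlenecks)


@dataclass(frozen=True)
class SequencingConfig:
    """Paired-end amplicon read generation parameters.

    The amplicon is the target window plus ``flank`` reference nucleotides on
    each side.  Reads are truncated at the amplicon end, so the default read
    length (longer than the default amplicon) makes the pair fully
    overlapping — the usual design for short-amplicon deep sequencing.
    ``error_rate`` is the mean per-base substitution error; the quality model
    is "constant" or "decline" (Phred falling linearly 5'->3', with per-base
    error probabilities scaled so their mean equals ``error_rate``).
    """

    read_length: int = 250
    n_pairs: int = 10000
    error_rate: float = 0.003
    flank: int = 25
    quality_model: str = "decline"
    q_high: int = 35
    q_low: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.read_length < 12:
            raise ValueError("read_length too short to merge")
        if self.n_pairs < 1 or self.flank < 0:
            raise ValueError("n_pairs must be >= 1 and flank >= 0")
        if self.quality_model not in ("constant", "decline"):
            raise ValueError(f"unknown quality model {self.quality_model!r}")


def protein_label(genotype: Genotype, region: TargetRegion) -> str:
    """Protein-level label of a genotype ("WT" for none/silent-only)."""
    return translate_genotype(genotype, region).label


def initialize_population(
    region: TargetRegion,
    scheme: DopingScheme,
    n_molecules: int,
    rng: np.random.Generator,
) -> dict[Genotype, int]:
    """Sample ``n_molecules`` library molecules, aggregated by genotype."""
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    pop: dict[Genotype, int] = {}
    for _ in range(n_molecules):
        _, subs = sample_library_molecule(region, scheme, rng)
        pop[subs] = pop.get(subs, 0) + 1
    return pop


def population_from_fractions(
    fractions: dict[str, float], n_molecules: int, region: TargetRegion
) -> dict[Genotype, int]:
    """Build a population from protein-label fractions.

    Labels are amino-acid changes (``"V79L"``, ``"E86G/C90G"``) realised by
    deterministic single-nucleotide substitutions, plus ``"WT"`` which
    absorbs rounding remainders.
    """
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    pop: dict[Genotype, int] = {}
    assigned = 0
    for label, frac in fractions.items():
        if label == "WT":
            continue
        subs = tuple(
            _reference.substitution_for_aa_change(region, part)
            for part in label.split("/")
        )
        count = int(round(frac * n_molecules))
        if count > 0:
            pop[tuple(sorted(subs))] = count
            assigned += count
    wt = n_molecules - assigned
    if wt < 0:
        raise ValueError("variant fractions exceed 1 after rounding")
    if wt > 0:
        pop[()] = wt
    return pop


def _sorted_genotypes(pop: dict[Genotype, int]) -> list[Genotype]:
    return sorted(pop)


def selection_cycle(
    pop: dict[Genotype, int],
    fitness: VariantFitness,
    bottleneck: int,
    rng: np.random.Generator,
    region: TargetRegion,
) -> dict[Genotype, int]:
    """One conjugation/selection round as a single multinomial bottleneck.

    The expected post-cycle frequency of genotype g is
    ``f_g * w_g / sum_h f_h * w_h`` and the realised counts sum to
    ``bottleneck``.
    """
    if bottleneck < 1:
        raise ValueError("bottleneck must be >= 1")
    if not pop:
        raise ValueError("population is empty")
    genotypes = _sorted_genotypes(pop)
    counts = np.array([pop[g] for g in genotypes], dtype=float)
    weights = np.array([fitness.get(protein_label(g, region)) for g in genotypes])
    probs = counts * weights
    probs /= probs.sum()
    new_counts = rng.multinomial(bottleneck, probs)
    return {g: int(c) for g, c in zip(genotypes, new_counts) if c > 0}


def deterministic_selection(
    initial: dict[str, float], fitness: VariantFitness, n_cycles: int
) -> list[dict[str, float]]:
    """Infinite-population limit: the exact frequency update per cycle.

    ``f'_g = f_g w_g / sum f w`` iterated ``n_cycles`` times over label-level
    frequencies; returns the frequency map after each cycle.
    """
    freqs = dict(initial)
    out = []
    for _ in range(n_cycles):
        weighted = {k: f * fitness.get(k) for k, f in freqs.items()}
        z = sum(weighted.values())
        freqs = {k: v / z for k, v in weighted.items()}
        out.append(dict(freqs))
    return out


def _amplicon_bounds(region: TargetRegion, flank: int) -> tuple[int, int]:
    start = max(1, region.nt_start - flank)
    end = min(len(region.cds_sequence), region.nt_end + flank)
    return start, end


def _error_profile(cfg: SequencingConfig, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-base error probabilities and the Phred qualities written out."""
    if cfg.quality_model == "constant":
        q = np.full(length, cfg.q_high, dtype=float)
    else:
        q = np.linspace(cfg.q_high, cfg.q_low, length)
    e_raw = 10.0 ** (-q / 10.0)
    if cfg.error_rate == 0.0:
        return np.zeros(length), np.full(length, 40, dtype=np.int16)
    e = np.clip(e_raw * (cfg.error_rate / e_raw.mean()), 1e-6, 0.75)
    phred = np.clip(np.round(-10.0 * np.log10(e)), 2, 40).astype(np.int16)
    return e, phred


def _apply_cds_substitutions(cds: str, genotype: Genotype) -> str:
    seq = list(cds)
    for pos, ref, alt in genotype:
        if seq[pos - 1] != ref:
            raise ValueError(f"reference mismatch at CDS {pos}")
        seq[pos - 1] = alt
    return "".join(seq)


def generate_reads(
    pop: dict[Genotype, int],
    region: TargetRegion,
    cfg: SequencingConfig,
    rng: np.random.Generator,
    id_prefix: str = "read",
) -> list[ReadPair]:
    """Paired-end reads of the amplicon, sampled by genotype frequency.

    Per-base substitution errors are i.i.d. at the configured profile and
    uniform over the three alternative bases; written qualities match the
    per-base error probabilities.  Deterministic for a fixed ``rng`` state.
    """
    genotypes = _sorted_genotypes(pop)
    counts = np.array([pop[g] for g in genotypes], dtype=float)
    probs = counts / counts.sum()
    per_genotype = rng.multinomial(cfg.n_pairs, probs)
    a_start, a_end = _amplicon_bounds(region, cfg.flank)
    amp_len = a_end - a_start + 1
    read_len = min(cfg.read_length, amp_len)
    err, phred = _error_profile(cfg, read_len)
    pairs: list[ReadPair] = []
    serial = 0
    for genotype, n_reads in zip(genotypes, per_genotype):
        if n_reads == 0:
            continue
        mutated = _apply_cds_substitutions(region.cds_sequence, genotype)
        amplicon = mutated[a_start - 1 : a_end]
        fwd_codes = _ENC[
            np.frombuffer(amplicon[:read_len].encode(), dtype=np.uint8)
        ]
        rev_codes = _ENC[
            np.frombuffer(revcomp(amplicon[-read_len:]).encode(), dtype=np.uint8)
        ]
        for _ in range(int(n_reads)):
            reads = []
            for codes in (fwd_codes, rev_codes):
                hits = np.flatnonzero(rng.random(read_len) < err)
                out = codes.copy()
                if hits.size:
                    out[hits] = (out[hits] + rng.integers(1, 4, hits.size)) % 4
                reads.append(_LETTERS[out].tobytes().decode("ascii"))
            pairs.append(
                ReadPair(
                    id=f"{id_prefix}_{serial}",
                    forward=reads[0],
                    forward_qual=phred.copy(),
                    reverse=reads[1],
                    reverse_qual=phred.copy(),
                )
            )
            serial += 1
    return pairs


def truth_label_fractions(
    pop: dict[Genotype, int], region: TargetRegion
) -> pd.DataFrame:
    """Ground-truth amino-acid-change fractions of a population.

    Every colony carrying a label counts toward it (multi-mutant attribution,
    matching the analysis side); the ``WT`` row is the wild-type-protein
    fraction.
    """
    total = sum(pop.values())
    label_counts: dict[str, int] = {}
    wt = 0
    for genotype, count in pop.items():
        rec = translate_genotype(genotype, region)
        if not rec.aa_changes:
            wt += count
        for label in rec.aa_changes:
            label_counts[label] = label_counts.get(label, 0) + count
    rows = [{"label": "WT", "count": wt, "fraction": wt / total}]
    for label in sorted(label_counts):
        rows.append(
            {
                "label": label,
                "count": label_counts[label],
                "fraction": label_counts[label] / total,
            }
        )
    return pd.DataFrame(rows).set_index("label")


@dataclass
class CycleResult:
    cycle: int
    population: dict[Genotype, int]
    truth: pd.DataFrame
    read_pairs: list[ReadPair]


@dataclass
class ExperimentResult:
    region: TargetRegion
    cycles: list[CycleResult]
    initial_population: dict[Genotype, int]


def run_experiment(
    region: TargetRegion,
    initial_population: dict[Genotype, int],
    fitness: VariantFitness,
    selection_cfg: SelectionConfig,
    sequencing_cfg: SequencingConfig,
    sequencing_seed: int = 1,
    outdir: str | Path | None = None,
) -> ExperimentResult:
    """Run the full selection + sequencing simulation.

    Two independent RNG streams (selection and sequencing) make the two
    stages separately reproducible.  If ``outdir`` is given, per-cycle FASTQ
    pairs, truth TSVs and a JSON config echo are written there.
    """
    sel_rng = np.random.default_rng(selection_cfg.seed)
    seq_rng = np.random.default_rng(sequencing_seed)
    pop = dict(initial_population)
    cycles: list[CycleResult] = []
    for i, bottleneck in enumerate(selection_cfg.bottlenecks, start=1):
        pop = selection_cycle(pop, fitness, bottleneck, sel_rng, region)
        reads = generate_reads(
            pop, region, sequencing_cfg, seq_rng, id_prefix=f"c{i}"
        )
        cycles.append(
            CycleResult(
                cycle=i,
                population=pop,
                truth=truth_label_fractions(pop, region),
                read_pairs=reads,
            )
        )
    result = ExperimentResult(
        region=region, cycles=cycles, initial_population=dict(initial_population)
    )
    if outdir is not None:
        _write_experiment(result, selection_cfg, sequencing_cfg, Path(outdir))
    return result


def write_fastq(pairs: list[ReadPair], r1_path: Path, r2_path: Path) -> None:
    """Write a read-pair list as two Phred+33 FASTQ files."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    def records(which: str):
        for p in pairs:
            seq = p.forward if which == "fwd" else p.reverse
            qual = p.forward_qual if which == "fwd" else p.reverse_qual
            rec = SeqRecord(Seq(seq), id=p.id, description="")
            rec.letter_annotations["phred_quality"] = [int(q) for q in qual]
            yield rec

    with open(r1_path, "w") as fh:
        seqio_write(records("fwd"), fh, "fastq")
    with open(r2_path, "w") as fh:
        seqio_write(records("rev"), fh, "fastq")


def _write_experiment(
    result: ExperimentResult,
    selection_cfg: SelectionConfig,
    sequencing_cfg: SequencingConfig,
    outdir: Path,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for cyc in result.cycles:
        write_fastq(
            cyc.read_pairs,
            outdir / f"cycle{cyc.cycle}_R1.fastq",
            outdir / f"cycle{cyc.cycle}_R2.fastq",
        )
        cyc.truth.to_csv(outdir / f"cycle{cyc.cycle}_truth.tsv", sep="\t")
    echo = {
        "selection": {
            "bottlenecks": list(selection_cfg.bottlenecks),
            "initial_size": selection_cfg.initial_size,
            "seed": selection_cfg.seed,
        },
        "sequencing": {
            "read_length": sequencing_cfg.read_length,
            "n_pairs": sequencing_cfg.n_pairs,
            "error_rate": sequencing_cfg.error_rate,
            "flank": sequencing_cfg.flank,
            "quality_model": sequencing_cfg.quality_model,
        },
    }
    (outdir / "config.json").write_text(json.dumps(echo, indent=2))
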
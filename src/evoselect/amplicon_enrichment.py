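"""Amplicon deep-sequencing variant-frequency and enrichment analysis.

Paired-end reads from a mutagenised amplicon are merged on their overlap (or
quality-trimmed and concatenated when they do not overlap), locally aligned
to the coding sequence with the classic Smith-Waterman algorithm, and reduced
to nucleotide substitutions inside the target window.  Substitutions are
translated with the standard codon table to classify each read as wild-type
protein (no change or silent only) or a single/double/triple/four-plus
missense genotype, populations are tabulated per cycle with a detection
threshold (default: report only variants above 0.5% of the population), and
across-cycle enrichment trajectories are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import _kernels
from .library_model import TargetRegion

CLASSES = ("wild_type_protein", "single", "double", "triple", "four_plus")

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """uint8 codes: A=0 C=1 G=2 T=3, other=4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class ReadPair:
    """One paired-end read with per-base Phred qualities."""

    id: str
    forward: str
    forward_qual: np.ndarray
    reverse: str
    reverse_qual: np.ndarray

    def __post_init__(self) -> None:
        self.forward_qual = np.asarray(self.forward_qual, dtype=np.int16)
        self.reverse_qual = np.asarray(self.reverse_qual, dtype=np.int16)
        if len(self.forward) != self.forward_qual.size:
            raise ValueError(f"{self.id}: forward sequence/quality length mismatch")
        if len(self.reverse) != self.reverse_qual.size:
            raise ValueError(f"{self.id}: reverse sequence/quality length mismatch")


@dataclass
class MergedRead:
    """Consensus of an overlapping pair, or the concatenated fallback."""

    sequence: str
    qualities: np.ndarray
    merged: bool


def merge_read_pairs(
    pair: ReadPair, min_overlap: int = 6, max_mismatch_frac: float = 0.08
) -> MergedRead | None:
    """Merge a pair on the best ungapped overlap, or return None.

    The reverse read is reverse-complemented and slid along the forward read;
    the overlap with the lowest mismatch fraction (ties to the longer
    overlap) wins if it is at least ``min_overlap`` bases with mismatch
    fraction <= ``max_mismatch_frac``.  Where the reads disagree the
    higher-quality base is kept (forward on quality ties); where they agree
    the higher of the two qualities is kept.
    """
    f = encode(pair.forward)
    rc_seq = revcomp(pair.reverse)
    rc = encode(rc_seq)
    rq = pair.reverse_qual[::-1]
    offset = _kernels.best_overlap(f, rc, min_overlap, max_mismatch_frac)
    if offset < 0:
        return None
    out_len = max(f.size, offset + rc.size)
    seq = np.full(out_len, 4, dtype=np.uint8)
    qual = np.zeros(out_len, dtype=np.int16)
    seq[: f.size] = f
    qual[: f.size] = pair.forward_qual
    ov = min(f.size - offset, rc.size)
    # overlap consensus
    fo = f[offset : offset + ov]
    fq = pair.forward_qual[offset : offset + ov]
    ro = rc[:ov]
    rqo = rq[:ov]
    take_rev = (ro != fo) & (rqo > fq)
    cons = np.where(take_rev, ro, fo)
    cons_q = np.where(ro == fo, np.maximum(fq, rqo), np.where(take_rev, rqo, fq))
    seq[offset : offset + ov] = cons
    qual[offset : offset + ov] = cons_q
    if offset + rc.size > f.size:
        seq[f.size :] = rc[ov:]
        qual[f.size :] = rq[ov:]
    letters = np.array(list("ACGTN"))
    return MergedRead("".join(letters[seq]), qual, merged=True)


def quality_trim(
    sequence: str, qualities: np.ndarray, q_threshold: int = 20
) -> tuple[str, np.ndarray]:
    """Truncate a read at its first base below the quality threshold.

    Everything from the 5'-most sub-threshold base onward is removed (the
    fixed point of repeatedly clipping the read at its 3'-most low-quality
    base), so the surviving prefix contains only bases at or above the
    threshold.  Never lengthens the read.
    """
    qual = np.asarray(qualities, dtype=np.int16)
    if len(sequence) != qual.size:
        raise ValueError("sequence/quality length mismatch")
    low = np.flatnonzero(qual < q_threshold)
    if low.size == 0:
        return sequence, qual
    cut = int(low[0])
    return sequence[:cut], qual[:cut]


def join_unmerged(pair: ReadPair) -> MergedRead:
    """Concatenate forward read and reverse-complemented reverse read."""
    seq = pair.forward + revcomp(pair.reverse)
    qual = np.concatenate([pair.forward_qual, pair.reverse_qual[::-1]])
    return MergedRead(seq, qual, merged=False)


@dataclass(frozen=True)
class Scoring:
    """Smith-Waterman scoring; first gap base costs ``gap_open``."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclass
class AlignmentResult:
    """A local alignment of a read against the CDS.

    Spans are 1-based inclusive (CDS coordinates on the reference side).
    ``aligned_pairs`` lists ``(query_pos, ref_pos)`` per alignment column
    with ``None`` marking a gap.
    """

    query: str
    reference: str
    score: float
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    aligned_pairs: list[tuple[int | None, int | None]]

    def recompute_score(self, scoring: Scoring) -> float:
        """Score of the stored alignment path under ``scoring`` (invariant
        check: must equal ``self.score``)."""
        total = 0.0
        in_gap = False
        for qp, rp in self.aligned_pairs:
            if qp is None or rp is None:
                total += scoring.gap_extend if in_gap else scoring.gap_open
                in_gap = True
            else:
                in_gap = False
                if self.query[qp - 1] == self.reference[rp - 1]:
                    total += scoring.match
                else:
                    total += scoring.mismatch
        return total


def smith_waterman(
    query: str, reference: str, scoring: Scoring = Scoring()
) -> AlignmentResult:
    """Optimal local alignment (affine gaps, deterministic tie-breaking)."""
    if not query or not reference:
        raise ValueError("smith_waterman requires non-empty sequences")
    score, qs, qe, rs, re_, q_idx, r_idx = _kernels.sw_align(
        encode(query),
        encode(reference),
        float(scoring.match),
        float(scoring.mismatch),
        float(scoring.gap_open),
        float(scoring.gap_extend),
    )
    pairs: list[tuple[int | None, int | None]] = []
    for qp, rp in zip(q_idx.tolist(), r_idx.tolist()):
        pairs.append(
            (qp + 1 if qp >= 0 else None, rp + 1 if rp >= 0 else None)
        )
    return AlignmentResult(
        query=query,
        reference=reference,
        score=float(score),
        query_start=qs + 1,
        query_end=qe + 1,
        ref_start=rs + 1,
        ref_end=re_ + 1,
        aligned_pairs=pairs,
    )


def call_substitutions(
    aln: AlignmentResult, region: TargetRegion
) -> tuple[list[tuple[int, str, str]], np.ndarray]:
    """Substitutions and coverage mask inside the target window.

    Substitutions are reported only at aligned, non-gap positions carrying an
    unambiguous base; positions under gaps, outside the aligned span, or read
    as N are marked uncovered (neither reference nor variant).  The mask is
    indexed by window offset (0 = first window position).
    """
    mask = np.zeros(region.length, dtype=bool)
    subs: list[tuple[int, str, str]] = []
    for qp, rp in aln.aligned_pairs:
        if rp is None or not region.contains(rp):
            continue
        if qp is None:
            continue  # deletion: stays uncovered
        base = aln.query[qp - 1]
        if base not in "ACGT":
            continue  # N: uncovered
        mask[rp - region.nt_start] = True
        ref = aln.reference[rp - 1]
        if base != ref:
            subs.append((rp, ref, base))
    return subs, mask


@dataclass
class GenotypeRecord:
    """Substitutions on a read, their protein consequences and class."""

    substitutions: tuple[tuple[int, str, str], ...]
    aa_changes: tuple[str, ...]
    genotype_class: str
    n_reads: int = 1

    @property
    def label(self) -> str:
        """Protein-level label, e.g. ``"E86G/C90G"`` or ``"WT"``."""
        return "/".join(self.aa_changes) if self.aa_changes else "WT"


def translate_genotype(
    subs: list[tuple[int, str, str]] | tuple, region: TargetRegion
) -> GenotypeRecord:
    """Translate nucleotide substitutions into amino-acid consequences.

    Changes are named one-letter style (``V79L``); reads with no substitution
    or only silent ones are class ``wild_type_protein``, otherwise the class
    counts the changed residues.  Substitutions outside the window are an
    error.
    """
    by_codon: dict[int, list[tuple[int, str, str]]] = {}
    for pos, ref, alt in subs:
        if not region.contains(pos):
            raise ValueError(
                f"substitution at CDS position {pos} outside window "
                f"{region.nt_start}-{region.nt_end}"
            )
        if region.cds_sequence[pos - 1] != ref:
            raise ValueError(
                f"reference base mismatch at CDS {pos}: expected "
                f"{region.cds_sequence[pos - 1]}, got {ref}"
            )
        by_codon.setdefault(region.codon_of(pos), []).append((pos, ref, alt))
    changes = []
    for residue in sorted(by_codon):
        start = 3 * (residue - 1)  # 0-based CDS offset of the codon
        codon = list(region.cds_sequence[start : start + 3])
        for pos, _ref, alt in by_codon[residue]:
            codon[(pos - 1) - start] = alt
        ref_aa = str(Seq(region.cds_sequence[start : start + 3]).translate())
        new_aa = str(Seq("".join(codon)).translate())
        if new_aa != ref_aa:
            changes.append(f"{ref_aa}{residue}{new_aa}")
    n = len(changes)
    cls = CLASSES[min(n, 4)]
    return GenotypeRecord(
        substitutions=tuple(sorted(subs)),
        aa_changes=tuple(changes),
        genotype_class=cls,
    )


@dataclass
class AnalysisResult:
    """Per-read genotype calls plus per-position base counts."""

    records: list[GenotypeRecord]
    n_pairs: int
    n_merged: int
    n_unclassified: int
    position_counts: pd.DataFrame


def analyze_read_pairs(
    pairs,
    region: TargetRegion,
    scoring: Scoring = Scoring(),
    q_trim_threshold: int = 20,
    min_overlap: int = 6,
    max_mismatch_frac: float = 0.08,
    min_window_coverage: float = 0.9,
) -> AnalysisResult:
    """Full read-pair pipeline: merge -> (trim+join) -> align -> call.

    Reads covering at least ``min_window_coverage`` of the window become
    genotype records; the rest still contribute to per-position counts.
    """
    counts = np.zeros((region.length, 4), dtype=np.int64)
    covered = np.zeros(region.length, dtype=np.int64)
    records: list[GenotypeRecord] = []
    n_merged = 0
    n_unclassified = 0
    n_pairs = 0
    win_codes = encode(region.window_sequence)
    for pair in pairs:
        n_pairs += 1
        merged = merge_read_pairs(pair, min_overlap, max_mismatch_frac)
        if merged is not None:
            n_merged += 1
        else:
            fseq, fq = quality_trim(pair.forward, pair.forward_qual, q_trim_threshold)
            rseq, rq = quality_trim(pair.reverse, pair.reverse_qual, q_trim_threshold)
            trimmed = ReadPair(pair.id, fseq, fq, rseq, rq)
            merged = join_unmerged(trimmed)
        if not merged.sequence:
            n_unclassified += 1
            continue
        aln = smith_waterman(merged.sequence, region.cds_sequence, scoring)
        subs, mask = call_substitutions(aln, region)
        covered += mask
        obs = np.where(mask, win_codes, 4).astype(np.int64)
        for pos, _ref, alt in subs:
            obs[pos - region.nt_start] = "ACGT".index(alt)
        hit = obs < 4
        np.add.at(counts, (np.flatnonzero(hit), obs[hit]), 1)
        if mask.mean() >= min_window_coverage:
            records.append(translate_genotype(subs, region))
        else:
            n_unclassified += 1
    position_counts = pd.DataFrame(
        counts,
        columns=list("ACGT"),
        index=pd.RangeIndex(region.nt_start, region.nt_end + 1, name="cds_pos"),
    )
    position_counts["covered"] = covered
    return AnalysisResult(
        records=records,
        n_pairs=n_pairs,
        n_merged=n_merged,
        n_unclassified=n_unclassified,
        position_counts=position_counts,
    )


@dataclass
class PopulationTable:
    """Per-cycle variant frequencies at genotype and amino-acid-change level.

    ``aa_changes`` counts every read carrying a label (so a double-mutant
    read contributes to two labels) and splits each label's support by the
    genotype class it occurred in.  ``genotypes`` aggregates whole protein
    genotypes.  Entries at or below ``threshold`` are suppressed from the
    ``reported_*`` views but retained internally.
    """

    cycle: object
    total_reads: int
    threshold: float
    aa_changes: pd.DataFrame
    genotypes: pd.DataFrame
    class_fractions: dict[str, float]

    @property
    def reported_aa_changes(self) -> pd.DataFrame:
        return self.aa_changes[self.aa_changes["fraction"] > self.threshold]

    @property
    def reported_genotypes(self) -> pd.DataFrame:
        return self.genotypes[self.genotypes["fraction"] > self.threshold]

    def fraction_of(self, label: str) -> float:
        """Fraction of reads carrying an amino-acid change (0 if unseen)."""
        if label in self.aa_changes.index:
            return float(self.aa_changes.loc[label, "fraction"])
        return 0.0


def tabulate_population(
    records: list[GenotypeRecord], threshold: float = 0.005, cycle=None
) -> PopulationTable:
    """Aggregate genotype records into a per-cycle population table."""
    if not records:
        raise ValueError("no genotype records to tabulate")
    total = sum(r.n_reads for r in records)
    class_counts = dict.fromkeys(CLASSES, 0)
    geno_counts: dict[str, list] = {}
    aa_counts: dict[str, dict[str, int]] = {}
    for rec in records:
        class_counts[rec.genotype_class] += rec.n_reads
        g = geno_counts.setdefault(rec.label, [0, rec.genotype_class])
        g[0] += rec.n_reads
        for label in rec.aa_changes:
            d = aa_counts.setdefault(
                label, dict.fromkeys(("single", "double", "triple", "four_plus"), 0)
            )
            d[rec.genotype_class] += rec.n_reads
    aa_rows = []
    for label, split in aa_counts.items():
        count = sum(split.values())
        aa_rows.append(
            {
                "label": label,
                "count": count,
                "fraction": count / total,
                **split,
            }
        )
    aa_df = pd.DataFrame(
        aa_rows,
        columns=["label", "count", "fraction", "single", "double", "triple", "four_plus"],
    )
    if not aa_df.empty:
        aa_df = aa_df.sort_values("fraction", ascending=False).set_index("label")
    else:
        aa_df = aa_df.set_index("label")
    geno_df = pd.DataFrame(
        [
            {"label": lbl, "count": c, "fraction": c / total, "class": cls}
            for lbl, (c, cls) in geno_counts.items()
        ]
    ).sort_values("fraction", ascending=False).set_index("label")
    return PopulationTable(
        cycle=cycle,
        total_reads=total,
        threshold=threshold,
        aa_changes=aa_df,
        genotypes=geno_df,
        class_fractions={c: class_counts[c] / total for c in CLASSES},
    )


@dataclass
class Trajectory:
    """One variant's population fraction across selection cycles."""

    label: str
    cycles: tuple
    fractions: tuple[float, ...]
    monotone_increase: bool
    fold_change: float


def enrichment_trajectories(
    tables: list[PopulationTable], level: str = "aa_change"
) -> list[Trajectory]:
    """Across-cycle trajectories for every variant reported in any cycle.

    A label absent from a cycle is recorded at fraction 0.  The monotone flag
    requires a strict increase at every step; the fold change is
    last/first (infinite if the variant was absent initially).
    """
    if len(tables) < 2:
        raise ValueError("need at least two cycles for trajectories")
    cycles = [t.cycle for t in tables]
    if any(a >= b for a, b in zip(cycles, cycles[1:])):
        raise ValueError(f"cycle labels must be strictly increasing, got {cycles}")
    if level == "aa_change":
        reported = [set(t.reported_aa_changes.index) for t in tables]
        lookup = [t.fraction_of for t in tables]
    elif level == "genotype":
        reported = [
            set(t.reported_genotypes.index) - {"WT"} for t in tables
        ]
        lookup = [
            (lambda tbl: lambda lab: float(tbl.genotypes.loc[lab, "fraction"])
             if lab in tbl.genotypes.index else 0.0)(t)
            for t in tables
        ]
    else:
        raise ValueError(f"unknown level {level!r}")
    labels = sorted(set().union(*reported))
    out = []
    for label in labels:
        fr = tuple(fn(label) for fn in lookup)
        monotone = all(b > a for a, b in zip(fr, fr[1:]))
        if fr[0] > 0:
            fold = fr[-1] / fr[0]
        elif fr[-1] > 0:
            fold = float("inf")
        else:
            fold = float("nan")
        out.append(
            Trajectory(
                label=label,
                cycles=tuple(cycles),
                fractions=fr,
                monotone_increase=monotone,
                fold_change=fold,
            )
        )
    return out
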
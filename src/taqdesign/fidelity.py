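"""Polymerase fidelity from per-position amplicon sequencing base counts.

The estimator follows the standard PCR-sequencing accounting: every read base
that differs from the reference at a non-primer position is attributed to the
polymerase. The substitution frequency in the final amplicon pool is

    f = N_alt / N_alt+ref

(summed over all unmasked positions), and the per-nucleotide per-cycle error
rate is

    p = E * f / n

where E is the PCR efficiency per cycle (in (1, 2]) and n the number of
amplification cycles. Fidelity is reported as nucleotides per error, 1/p.
Base calls below a quality threshold (default Q >= 30 retained) are discarded
before counting, primer-covered positions are masked, and only substitutions
are counted (indels are ignored). The 12 directed substitution types form the
error spectrum, split into transitions (A<->G, C<->T) and transversions.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BASES = ("A", "C", "G", "T")
TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})
SUBSTITUTION_TYPES = tuple((r, a) for r in BASES for a in BASES if r != a)


class FidelityError(ValueError):
    pass


@dataclass
class PositionCounts:
    """Read base counts at one 0-based amplicon position."""

    position: int
    ref_base: str
    counts: dict[str, int]
    in_primer: bool = False
    mean_q: float | None = None

    def __post_init__(self) -> None:
        if self.ref_base not in BASES:
            raise FidelityError(f"bad reference base {self.ref_base!r}")
        self.counts = {b: int(self.counts.get(b, 0)) for b in BASES}
        if any(c < 0 for c in self.counts.values()):
            raise FidelityError("negative counts")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def alt(self) -> int:
        return self.total - self.counts[self.ref_base]


@dataclass
class Spectrum:
    """Directed substitution-type counts and relative frequencies."""

    counts: dict[tuple[str, str], int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def relative(self) -> dict[tuple[str, str], float]:
        t = self.total
        return {k: (v / t if t else 0.0) for k, v in self.counts.items()}

    @property
    def transitions(self) -> int:
        return sum(v for k, v in self.counts.items() if k in TRANSITIONS)

    @property
    def transversions(self) -> int:
        return self.total - self.transitions

    @property
    def transversion_transition_ratio(self) -> float:
        return self.transversions / self.transitions if self.transitions else math.inf


@dataclass
class FidelityResult:
    f: float
    efficiency: float
    cycles: int
    p: float
    fidelity_nt_per_error: float
    spectrum: Spectrum


def filter_counts(raw_calls: Sequence[tuple[int, str, Sequence[tuple[str, int]]]],
                  q_threshold: int = 30) -> list[PositionCounts]:
    """Build count tables from per-position (base, quality) calls, retaining
    calls with Q >= ``q_threshold``."""
    out = []
    for position, ref_base, calls in raw_calls:
        kept = [b for b, q in calls if q >= q_threshold]
        counts = {b: kept.count(b) for b in BASES}
        out.append(PositionCounts(position, ref_base, counts))
    return out


def mask_primers(counts: Sequence[PositionCounts],
                 primer_intervals: Sequence[tuple[int, int]]) -> list[PositionCounts]:
    """Flag positions inside any 0-based half-open interval as primer-covered.

    Overlapping intervals mask their union. Masked positions are excluded
    from all downstream sums.
    """
    for start, stop in primer_intervals:
        if stop < start:
            raise FidelityError(f"inverted interval [{start}, {stop})")
    masked = []
    for pc in counts:
        inside = any(start <= pc.position < stop for start, stop in primer_intervals)
        masked.append(replace(pc, counts=dict(pc.counts),
                              in_primer=pc.in_primer or inside))
    return masked


def _unmasked(counts: Iterable[PositionCounts]) -> list[PositionCounts]:
    return [pc for pc in counts if not pc.in_primer]


def substitution_frequency(counts: Sequence[PositionCounts]) -> float:
    """f = (sum of non-reference calls) / (sum of all calls) over unmasked
    positions."""
    kept = _unmasked(counts)
    total = sum(pc.total for pc in kept)
    if total == 0:
        raise FidelityError("no unmasked reads")
    alt = sum(pc.alt for pc in kept)
    return alt / total


def error_rate(f: float, efficiency: float, cycles: int) -> tuple[float, float]:
    """(p, fidelity in nt/error) from the amplicon substitution frequency.

    p = E * f / n; fidelity is 1/p (infinite when f = 0).
    """
    if not (1.0 < efficiency <= 2.0):
        raise FidelityError(f"efficiency {efficiency} outside (1, 2]")
    if cycles < 1:
        raise FidelityError("cycles must be >= 1")
    if not (0.0 <= f <= 1.0):
        raise FidelityError(f"f = {f} outside [0, 1]")
    p = efficiency * f / cycles
    return p, (1.0 / p if p > 0 else math.inf)


def substitution_spectrum(counts: Sequence[PositionCounts]) -> Spectrum:
    """Tally the 12 directed ref -> alt substitution types over unmasked
    positions."""
    tally = {t: 0 for t in SUBSTITUTION_TYPES}
    for pc in _unmasked(counts):
        for base in BASES:
            if base != pc.ref_base and pc.counts[base]:
                tally[(pc.ref_base, base)] += pc.counts[base]
    return Spectrum(tally)


def estimate_fidelity(counts: Sequence[PositionCounts], efficiency: float,
                      cycles: int) -> FidelityResult:
    """Full estimate from masked count tables: f, p, nt/error, and spectrum."""
    f = substitution_frequency(counts)
    p, nt_per_error = error_rate(f, efficiency, cycles)
    return FidelityResult(f=f, efficiency=efficiency, cycles=cycles, p=p,
                          fidelity_nt_per_error=nt_per_error,
                          spectrum=substitution_spectrum(counts))


def replicate_average(results: Sequence[FidelityResult]) -> FidelityResult:
    """Average replicate estimates: arithmetic mean of f and p; spectra are
    summed and renormalized. Mixed (E, n) policies are rejected."""
    if not results:
        raise FidelityError("no replicates")
    if len({(r.efficiency, r.cycles) for r in results}) > 1:
        raise FidelityError("replicates differ in (efficiency, cycles)")
    f = float(np.mean([r.f for r in results]))
    p = float(np.mean([r.p for r in results]))
    tally = {t: sum(r.spectrum.counts.get(t, 0) for r in results)
             for t in SUBSTITUTION_TYPES}
    return FidelityResult(f=f, efficiency=results[0].efficiency,
                          cycles=results[0].cycles, p=p,
                          fidelity_nt_per_error=1.0 / p if p > 0 else math.inf,
                          spectrum=Spectrum(tally))


# --------------------------------------------------------------------------
# Text I/O: counts TSV and BED-style primer intervals
# --------------------------------------------------------------------------

def read_counts_tsv(path: str | Path) -> list[PositionCounts]:
    """Counts TSV: columns position (0-based), ref, A, C, G, T[, mean_q]."""
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(PositionCounts(
                position=int(row["position"]), ref_base=row["ref"].upper(),
                counts={b: int(row[b]) for b in BASES},
                mean_q=float(row["mean_q"]) if row.get("mean_q") else None))
    return out


def write_counts_tsv(counts: Sequence[PositionCounts], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["position", "ref", *BASES])
        for pc in counts:
            writer.writerow([pc.position, pc.ref_base] +
                            [pc.counts[b] for b in BASES])


def read_primer_bed(path: str | Path) -> list[tuple[int, int]]:
    """BED-style 0-based half-open intervals (chrom ignored)."""
    intervals = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        intervals.append((int(fields[1]), int(fields[2])))
    return intervals


def write_spectrum_tsv(spectrum: Spectrum, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["ref", "alt", "count", "relative", "class"])
        rel = spectrum.relative
        for (r, a) in SUBSTITUTION_TYPES:
            cls = "transition" if (r, a) in TRANSITIONS else "transversion"
            writer.writerow([r, a, spectrum.counts[(r, a)],
                             f"{rel[(r, a)]:.6g}", cls])
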
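"""Synthetic genomes with planted replichore structure, for testing.

Two generation modes are supported:

- deterministic ("none" noise): per-strand base excesses are laid down by
  error diffusion, so that after ``t`` nucleotides of an arc exactly
  ``floor(t * rate)`` excess bases have been emitted.  Worked-example
  targets are therefore exact.  Positions not carrying an excess base are
  filled with a skew-neutral alternation of A and T.
- binomial: every base is an independent draw from per-arc base
  probabilities chosen so that P(G) - P(C) and P(T) - P(A) equal the
  planted rates, giving realistic sampling noise.

Genes are placed on a regular grid, never straddling the replichore
breakpoints, with ATG starts, TAA stops and an interior composition that
honors the requested G share of coding G+C nucleotides.
"""

from __future__ import annotations

import csv
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .genome_io import GeneAnnotation, SequenceRecord
from .skew_model import FitParams, model_eval
from .skew_scan import DEFAULT_INTERVAL, SkewTrack, _checkpoint_positions

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3
_COMP = np.array([_T, _G, _C, _A], dtype=np.uint8)

# guards floor() against binary representation error of decimal rates
_FLOOR_EPS = 1e-9

DEFAULT_GENE_LENGTH = 999


@dataclass
class SyntheticSpec:
    """Ground-truth parameters for one synthetic chromosome."""

    length: int
    gc_alpha1: float = 0.04
    gc_alpha2: float = 0.04
    ta_alpha1: float = 0.03
    ta_alpha2: float = 0.03
    div: float = 0.5
    shift: float = 0.0
    gene_density: float = 0.0
    leading_strand_gene_fraction: float = 0.75
    codon_g_fraction: float = 0.5
    noise: str = "none"  # "none" | "binomial"
    seed: int = 0
    gene_length: int = DEFAULT_GENE_LENGTH

    def __post_init__(self) -> None:
        if self.length < 2 * DEFAULT_INTERVAL:
            raise ValueError("length must be at least two checkpoint intervals")
        for rate in (self.gc_alpha1, self.gc_alpha2, self.ta_alpha1, self.ta_alpha2):
            if not -0.5 < rate < 0.5:
                raise ValueError(f"rates must lie in (-0.5, 0.5), got {rate}")
        if not 0.0 < self.div < 1.0:
            raise ValueError("div must be in (0, 1)")
        if not 0.0 <= self.shift < 1.0:
            raise ValueError("shift must be in [0, 1)")
        for frac in (
            self.gene_density,
            self.leading_strand_gene_fraction,
            self.codon_g_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.noise not in ("none", "binomial"):
            raise ValueError("noise must be 'none' or 'binomial'")
        if self.gene_length % 3 != 0 or self.gene_length < 9:
            raise ValueError("gene_length must be a multiple of 3, >= 9")


@dataclass
class GroundTruth:
    """The SyntheticSpec echoed back, plus realized counts from the genome."""

    spec: SyntheticSpec
    leading_arc_length: int
    lagging_arc_length: int
    genes_leading: int
    genes_lagging: int
    genes_plus: int
    genes_minus: int
    g_minus_c: int
    t_minus_a: int


def simulate_track(
    params: FitParams,
    length: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    interval: int = DEFAULT_INTERVAL,
) -> SkewTrack:
    """Sample the piecewise-linear model on the checkpoint grid, plus noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    positions = _checkpoint_positions(length, interval)
    values = model_eval(params, length, positions)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=len(values))
    return SkewTrack(interval, positions, values)


def _excess_positions(n: int, rate: float) -> np.ndarray:
    """Positions t in [0, n) where floor((t+1)*rate) increments (error diffusion)."""
    t = np.arange(n + 1, dtype=np.float64)
    marks = np.floor(t * abs(rate) + _FLOOR_EPS).astype(np.int64)
    return np.nonzero(np.diff(marks) == 1)[0]


def _arc_excess_marks(
    n: int, gc_rate: float, ta_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Excess-base positions for one arc, as (gc_positions, ta_positions).

    GC excess bases are never displaced, so the prefix G-C count is exactly
    ``floor(t * |gc_rate|)``; TA excess bases collide occasionally with GC
    ones and are deferred to the next free slot.
    """
    g_pos = _excess_positions(n, gc_rate)
    taken = np.zeros(n, dtype=bool)
    taken[g_pos] = True
    free = np.nonzero(~taken)[0]
    t_demand = _excess_positions(n, ta_rate)
    if len(t_demand) and len(free):
        idx = np.searchsorted(free, t_demand)
        # force strictly increasing slot indices so no slot is double-booked
        seq = np.arange(len(idx))
        idx = np.maximum.accumulate(idx - seq) + seq
        idx = idx[idx < len(free)]
        t_pos = free[idx]
    else:
        t_pos = np.empty(0, dtype=np.int64)
    return g_pos, t_pos


def _gene_profile(codon_g_fraction: float, strand: int) -> np.ndarray:
    """Reference-strand base probabilities of a gene interior.

    Coding nucleotides are 50% G+C; among those, the G share in the gene's
    reading direction is ``codon_g_fraction`` (A/T split evenly).  For
    minus-strand genes the reference strand carries the complement.
    """
    p = np.array(
        [0.25, 0.5 * (1.0 - codon_g_fraction), 0.5 * codon_g_fraction, 0.25]
    )
    if strand == -1:
        p = p[[3, 2, 1, 0]]  # complement: A<->T, C<->G
    return p


def _cycle_from_profile(p: np.ndarray, length: int) -> np.ndarray:
    """Deterministic repeating layout realizing base fractions ``p`` exactly."""
    counts = np.floor(p * 20 + _FLOOR_EPS).astype(int)
    counts[np.argmax(p)] += 20 - counts.sum()
    cycle = np.repeat(np.arange(4), counts)
    return np.tile(cycle, length // 20 + 1)[:length].astype(np.uint8)


def _arc_of(position: float, length: int, div: float, shift: float) -> str:
    offset = (position - shift * length) % length
    return "leading" if offset < div * length else "lagging"


def _place_genes(
    spec: SyntheticSpec, rng: np.random.Generator | None
) -> list[tuple[int, int, int]]:
    """Regular-grid gene placement: (start, end, strand) triples.

    Genes never straddle the origin or terminus breakpoints and never wrap
    the sequence end, which keeps per-arc ground truth exactly computable.
    """
    if spec.gene_density == 0:
        return []
    glen = spec.gene_length
    period = int(round(glen / spec.gene_density))
    if period < glen + 2:
        raise ValueError(
            f"gene_density {spec.gene_density} infeasible for gene length {glen}"
        )
    origin = spec.shift * spec.length
    terminus = ((spec.shift + spec.div) % 1.0) * spec.length
    placements: list[tuple[int, int, int]] = []
    lead_acc = 0.0
    for start in range(1, spec.length - glen, period):
        end = start + glen
        if any(start < bp < end for bp in (origin, terminus)):
            continue
        arc = _arc_of(start, spec.length, spec.div, spec.shift)
        if rng is not None:
            on_leading = rng.random() < spec.leading_strand_gene_fraction
        else:
            lead_acc += spec.leading_strand_gene_fraction
            on_leading = lead_acc >= 1.0 - _FLOOR_EPS
            if on_leading:
                lead_acc -= 1.0
        # a leading-strand gene is co-oriented with the replication fork
        if arc == "leading":
            strand = 1 if on_leading else -1
        else:
            strand = -1 if on_leading else 1
        placements.append((start, end, strand))
    return placements


def simulate_genome(
    spec: SyntheticSpec,
) -> tuple[SequenceRecord, list[GeneAnnotation], GroundTruth]:
    """Generate a synthetic chromosome with planted skews and genes.

    The planted per-position excesses are laid down genome-wide, inside and
    outside genes, so fitted slopes recover the planted rates at any gene
    density; the gene codon composition shapes only the non-excess filler.
    """
    length = spec.length
    rng = np.random.default_rng(spec.seed) if spec.noise == "binomial" else None

    origin = int(round(spec.shift * length)) % length
    lead_len = int(round(spec.div * length))
    placements = _place_genes(spec, rng)

    arcs = [
        (origin, lead_len, spec.gc_alpha1, spec.ta_alpha1),
        (
            (origin + lead_len) % length,
            length - lead_len,
            -spec.gc_alpha2,
            -spec.ta_alpha2,
        ),
    ]

    if rng is not None:
        # per-position base probabilities: gene profile or flat background,
        # tilted by the arc's planted excesses
        probs = np.full((length, 4), 0.25)
        for start, end, strand in placements:
            probs[start:end] = _gene_profile(spec.codon_g_fraction, strand)
        for arc_start, arc_len, gc_rate, ta_rate in arcs:
            pos = (arc_start + np.arange(arc_len)) % length
            tilt = np.array(
                [-ta_rate / 2, -gc_rate / 2, gc_rate / 2, ta_rate / 2]
            )
            probs[pos] += tilt
        if np.any(probs < 0):
            raise ValueError("rates too large for the binomial base model")
        cum = np.cumsum(probs, axis=1)
        u = rng.random(length)[:, None]
        codes = (u > cum[:, :3]).sum(axis=1).astype(np.uint8)
    else:
        # skew-neutral background: T at even offsets, A at odd
        codes = np.where(np.arange(length) % 2 == 0, _T, _A).astype(np.uint8)
        # gene fillers are shuffled with a seed-derived generator: exact
        # composition, but no periodic resonance with the excess marks
        layout_rng = np.random.default_rng((spec.seed, 0x5EED))
        for start, end, strand in placements:
            profile = _gene_profile(spec.codon_g_fraction, strand)
            filler = _cycle_from_profile(profile, end - start)
            layout_rng.shuffle(filler)
            codes[start:end] = filler
        for arc_start, arc_len, gc_rate, ta_rate in arcs:
            g_rel, t_rel = _arc_excess_marks(arc_len, gc_rate, ta_rate)
            codes[(arc_start + g_rel) % length] = _G if gc_rate >= 0 else _C
            codes[(arc_start + t_rel) % length] = _T if ta_rate >= 0 else _A

    # boundary codons override everything: ATG start, TAA stop (reading frame)
    for start, end, strand in placements:
        if strand == 1:
            codes[start : start + 3] = [_A, _T, _G]
            codes[end - 3 : end] = [_T, _A, _A]
        else:
            codes[start : start + 3] = _COMP[np.array([_T, _A, _A])][::-1]
            codes[end - 3 : end] = _COMP[np.array([_A, _T, _G])][::-1]

    accession = f"SYN{spec.seed:04d}"
    genes: list[GeneAnnotation] = []
    counts = {"leading": 0, "lagging": 0, 1: 0, -1: 0}
    for start, end, strand in placements:
        genes.append(
            GeneAnnotation(seq_id=accession, start=start, end=end, strand=strand)
        )
        counts[_arc_of(start, length, spec.div, spec.shift)] += 1
        counts[strand] += 1

    residues = _BASES[codes].tobytes().decode("ascii")
    record = SequenceRecord(
        accession=accession,
        description="synthetic chromosome",
        residues=residues,
    )
    truth = GroundTruth(
        spec=spec,
        leading_arc_length=lead_len,
        lagging_arc_length=length - lead_len,
        genes_leading=counts["leading"],
        genes_lagging=counts["lagging"],
        genes_plus=counts[1],
        genes_minus=counts[-1],
        g_minus_c=int(np.sum(codes == _G) - np.sum(codes == _C)),
        t_minus_a=int(np.sum(codes == _T) - np.sum(codes == _A)),
    )
    return record, genes, truth


def write_ground_truth(truths: list[GroundTruth], path: str | Path) -> None:
    """Write ground-truth records as CSV, one row per replicate."""
    rows = []
    for truth in truths:
        row = asdict(truth.spec)
        row.update(
            {k: v for k, v in asdict(truth).items() if k != "spec"}
        )
        rows.append(row)
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
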
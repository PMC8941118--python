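"""Single-pass chromosome scanning: cumulative skews, codon tallies, DnaA.

Each chromosome is traversed once from beginning to end while running totals
are kept for cumulative GC and TA skew, the same skews restricted to the
three codon positions of protein-coding genes and to non-coding regions, a
strand-bias counter, a non-genic nucleotide counter, and per-base counts.
All totals are snapshotted at fixed nucleotide intervals (default 4096) plus
once at the end of the sequence.

Conventions:

- The scan is strictly reference-strand: the letters counted are those of
  the sequence as written.  Only the codon-position classification is
  gene-aware (phase counted from each gene's own 5' end).
- Ambiguous (non-ACGT) bases advance the position but touch no counter.
- A nucleotide inside at least one CDS is "genic"; overlapping genes
  contribute additively to the codon-position and strand-bias counters, so
  the partition invariant (codon positions + non-coding == total) holds
  exactly when genes do not overlap and are in frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome_io import GeneAnnotation, SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_INTERVAL = 4096

# Base codes: A=0 C=1 G=2 T=3, anything else 4 (counted nowhere).
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_START_CODONS = ("ATG", "GTG", "TTG")
_STOP_CODONS = ("TAG", "TAA", "TGA")


@dataclass
class SkewTrack:
    """Cumulative counter values sampled at fixed nucleotide intervals."""

    interval: int
    positions: np.ndarray  # increasing offsets; multiples of interval + final
    values: np.ndarray  # running totals, one per position

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values must have equal length")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


#: Names of the eleven skew tracks held by a ScanProfile, in export order.
SKEW_NAMES = (
    "gc",
    "ta",
    "gc0",
    "gc1",
    "gc2",
    "ta0",
    "ta1",
    "ta2",
    "gcng",
    "tang",
    "sb",
)


@dataclass
class ScanProfile:
    """All per-checkpoint counters for one chromosome."""

    accession: str
    length: int
    interval: int
    positions: np.ndarray
    gcskew: np.ndarray
    taskew: np.ndarray
    gcskew0: np.ndarray
    gcskew1: np.ndarray
    gcskew2: np.ndarray
    taskew0: np.ndarray
    taskew1: np.ndarray
    taskew2: np.ndarray
    gcskewNG: np.ndarray
    taskewNG: np.ndarray
    pospos: np.ndarray
    ngcount: np.ndarray
    acount: np.ndarray
    ccount: np.ndarray
    gcount: np.ndarray
    tcount: np.ndarray

    @property
    def relpos(self) -> np.ndarray:
        return self.positions / self.length

    _TRACK_FIELDS = {
        "gc": "gcskew",
        "ta": "taskew",
        "gc0": "gcskew0",
        "gc1": "gcskew1",
        "gc2": "gcskew2",
        "ta0": "taskew0",
        "ta1": "taskew1",
        "ta2": "taskew2",
        "gcng": "gcskewNG",
        "tang": "taskewNG",
        "sb": "pospos",
    }

    def track(self, name: str) -> SkewTrack:
        """Return one of the eleven skew counters as a SkewTrack."""
        try:
            values = getattr(self, self._TRACK_FIELDS[name])
        except KeyError:
            raise KeyError(f"unknown track {name!r}; one of {SKEW_NAMES}") from None
        return SkewTrack(self.interval, self.positions, values)


@dataclass
class StartStopTally:
    """Start/stop codon census over all protein-coding genes of a record."""

    protgenecount: int = 0
    startATG: int = 0
    startGTG: int = 0
    startTTG: int = 0
    startXXX: int = 0
    stopTAG: int = 0
    stopTAA: int = 0
    stopTGA: int = 0
    stopXXX: int = 0


def cumulative_skew(residues: str, plus_base: str, minus_base: str) -> np.ndarray:
    """Running ``count(plus_base) - count(minus_base)`` over every prefix.

    The value at index ``i`` covers ``residues[0..i]`` inclusive; characters
    other than the two counted bases leave the total unchanged.

    >>> cumulative_skew("GGGCCC", "G", "C").tolist()
    [1, 2, 3, 2, 1, 0]
    """
    if not residues:
        raise ValueError("residues must be non-empty")
    codes = _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    contrib = np.zeros(len(codes), dtype=np.int64)
    contrib[codes == _CODE[ord(plus_base.upper())]] = 1
    contrib[codes == _CODE[ord(minus_base.upper())]] = -1
    return np.cumsum(contrib)


def windowed_skew(residues: str, window: int) -> np.ndarray:
    """Per-window ``(G - C) / (G + C)`` over consecutive non-overlapping windows.

    A window with no G or C yields 0; a trailing partial window is dropped.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    codes = _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    n_windows = len(codes) // window
    codes = codes[: n_windows * window].reshape(n_windows, window)
    g = (codes == _CODE[ord("G")]).sum(axis=1)
    c = (codes == _CODE[ord("C")]).sum(axis=1)
    denom = g + c
    out = np.zeros(n_windows, dtype=np.float64)
    nonzero = denom > 0
    out[nonzero] = (g[nonzero] - c[nonzero]) / denom[nonzero]
    return out


def codon_position_of(offset_in_cds: int, strand: int, cds_length: int) -> int:
    """Codon position {0,1,2} of a base, counted from the gene's own 5' end."""
    if not 0 <= offset_in_cds < cds_length:
        raise ValueError("offset outside CDS")
    if strand == 1:
        return offset_in_cds % 3
    return (cds_length - 1 - offset_in_cds) % 3


def _checkpoint_positions(length: int, interval: int) -> np.ndarray:
    positions = np.arange(interval, length + 1, interval, dtype=np.int64)
    if len(positions) == 0 or positions[-1] != length:
        positions = np.append(positions, length)
    return positions


def scan_chromosome(
    record: SequenceRecord,
    genes: list[GeneAnnotation],
    interval: int = DEFAULT_INTERVAL,
) -> ScanProfile:
    """Traverse a chromosome once, maintaining all cumulative counters.

    Codon-position sub-totals are updated only inside protein-coding genes
    (genes whose length is not a multiple of 3 are excluded from the
    codon-position bookkeeping with a warning); non-coding sub-totals only
    outside all genes.  The strand-bias counter gains +1 per covering
    positive-sense gene and -1 per negative-sense gene at each position.
    """
    if interval < 1:
        raise ValueError("interval must be >= 1")
    length = len(record)
    codes = _CODE[np.frombuffer(record.residues.encode("ascii"), dtype=np.uint8)]

    gc_contrib = np.zeros(length, dtype=np.int64)
    gc_contrib[codes == 2] = 1  # G
    gc_contrib[codes == 1] = -1  # C
    ta_contrib = np.zeros(length, dtype=np.int64)
    ta_contrib[codes == 3] = 1  # T
    ta_contrib[codes == 0] = -1  # A

    coverage = np.zeros(length, dtype=np.int32)
    strand_weight = np.zeros(length, dtype=np.int32)
    phase_weight = [np.zeros(length, dtype=np.int32) for _ in range(3)]

    for gene in genes:
        if gene.seq_id != record.accession:
            raise ValueError(
                f"gene {gene.name or gene.start} references {gene.seq_id!r}, "
                f"not {record.accession!r}"
            )
        if gene.end > length:
            raise ValueError(
                f"gene [{gene.start}, {gene.end}) exceeds sequence length {length}"
            )
        coverage[gene.start : gene.end] += 1
        strand_weight[gene.start : gene.end] += gene.strand
        glen = len(gene)
        if glen % 3 != 0:
            logger.warning(
                "%s: gene at %d has length %d (not a multiple of 3); "
                "excluded from codon-position accounting",
                record.accession,
                gene.start,
                glen,
            )
            continue
        offsets = np.arange(glen)
        if gene.strand == 1:
            phases = offsets % 3
        else:
            phases = (glen - 1 - offsets) % 3
        for k in range(3):
            phase_weight[k][gene.start + offsets[phases == k]] += 1

    genic = coverage > 0
    positions = _checkpoint_positions(length, interval)
    idx = positions - 1

    def snap(contrib: np.ndarray) -> np.ndarray:
        return np.cumsum(contrib, dtype=np.int64)[idx]

    return ScanProfile(
        accession=record.accession,
        length=length,
        interval=interval,
        positions=positions,
        gcskew=snap(gc_contrib),
        taskew=snap(ta_contrib),
        gcskew0=snap(gc_contrib * phase_weight[0]),
        gcskew1=snap(gc_contrib * phase_weight[1]),
        gcskew2=snap(gc_contrib * phase_weight[2]),
        taskew0=snap(ta_contrib * phase_weight[0]),
        taskew1=snap(ta_contrib * phase_weight[1]),
        taskew2=snap(ta_contrib * phase_weight[2]),
        gcskewNG=snap(gc_contrib * (~genic)),
        taskewNG=snap(ta_contrib * (~genic)),
        pospos=snap(strand_weight.astype(np.int64)),
        ngcount=snap((~genic).astype(np.int64)),
        acount=snap((codes == 0).astype(np.int64)),
        ccount=snap((codes == 1).astype(np.int64)),
        gcount=snap((codes == 2).astype(np.int64)),
        tcount=snap((codes == 3).astype(np.int64)),
    )


def tally_codons(record: SequenceRecord, genes: list[GeneAnnotation]) -> StartStopTally:
    """Classify the first and last codon of every gene (reading direction)."""
    tally = StartStopTally()
    for gene in genes:
        seq = record.residues[gene.start : gene.end]
        if gene.strand == -1:
            seq = seq.translate(_COMPLEMENT)[::-1]
        tally.protgenecount += 1
        start, stop = seq[:3], seq[-3:] if len(seq) >= 6 else ""
        if len(seq) < 6:
            # too short to carry distinct start and stop codons
            start, stop = seq[:3] if len(seq) >= 3 else "", ""
        if start in _START_CODONS:
            setattr(tally, f"start{start}", getattr(tally, f"start{start}") + 1)
        else:
            tally.startXXX += 1
        if stop in _STOP_CODONS:
            setattr(tally, f"stop{stop}", getattr(tally, f"stop{stop}") + 1)
        else:
            tally.stopXXX += 1
    return tally


def find_dnaA(genes: list[GeneAnnotation]) -> int:
    """Start offset of the first gene named dnaA (case-insensitive), else -1."""
    matches = [g.start for g in genes if g.name.lower() == "dnaa"]
    return min(matches) if matches else -1
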
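"""CSV serialization of scan and fit outputs.

Five products are written, all RFC-4180 CSV with a mandatory header row:

- ``skplot.csv``: every checkpoint of every chromosome (one big file).
- ``results.csv``: one row per chromosome with all fitted parameters.
- ``genomes.csv``: one summary row per chromosome (base counts, taxonomy,
  start/stop codon tallies, DnaA position).
- ``codongc.csv``: coding-nucleotide composition, split by replication strand.
- ``<accession>_fit.csv``: per-chromosome observed vs predicted skews.

Floats are written with 6 significant digits; integers unpadded.  The codon
position counters carry three positions (0-2) plus an explicit non-coding
column rather than an unnamed fourth slot.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np

from .genome_io import SequenceRecord, UNKNOWN_TAXON
from .skew_model import ChromosomeResult, FitParams, model_eval
from .skew_scan import SKEW_NAMES, ScanProfile, StartStopTally

logger = logging.getLogger(__name__)

SKPLOT_COLUMNS = [
    "name",
    "abspos",
    "relpos",
    "gcskew",
    "taskew",
    "gcskew0",
    "gcskew1",
    "gcskew2",
    "taskew0",
    "taskew1",
    "taskew2",
    "gcskewNG",
    "taskewNG",
    "pospos",
    "ngcount",
    "acount",
    "ccount",
    "gcount",
    "tcount",
]

RESULTS_COLUMNS = ["name"]
for _skew in SKEW_NAMES:
    RESULTS_COLUMNS += [f"alpha1{_skew}", f"alpha2{_skew}", f"{_skew}RMS"]
RESULTS_COLUMNS += ["div", "shift"]

GENOMES_COLUMNS = [
    "name",
    "fullname",
    "acount",
    "ccount",
    "gcount",
    "tcount",
    "plasmid",
    "realm1",
    "realm2",
    "realm3",
    "realm4",
    "realm5",
    "protgenecount",
    "startATG",
    "startGTG",
    "startTTG",
    "startXXX",
    "stopTAG",
    "stopTAA",
    "stopTGA",
    "stopXXX",
    "dnaApos",
]

CODONGC_COLUMNS = [
    "name",
    "afrac",
    "cfrac",
    "gfrac",
    "tfrac",
    "leadafrac",
    "leadcfrac",
    "leadgfrac",
    "leadtfrac",
    "lagafrac",
    "lagcfrac",
    "laggfrac",
    "lagtfrac",
    "ggcfrac",
    "cgcfrac",
    "atafrac",
    "ttafrac",
]

FIT_COLUMNS = ["abspos", "relpos"]
for _skew in SKEW_NAMES:
    FIT_COLUMNS += [f"{_skew}skew", f"pred{_skew}skew"]


def _fmt(value) -> str:
    """6 significant digits for floats, unpadded integers, '' for None."""
    if value is None:
        return ""
    if isinstance(value, (bool, np.bool_)):
        return str(int(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        if np.isinf(value):
            return "inf"
        return format(float(value), ".6g")
    return str(value)


def _open_out(file: str | Path | IO[str]):
    if isinstance(file, (str, Path)):
        return open(file, "w", newline=""), True
    return file, False


def _write_rows(file, columns: list[str], rows: Iterable[list]) -> None:
    handle, own = _open_out(file)
    try:
        writer = csv.writer(handle)
        writer.writerow(columns)
        for row in rows:
            writer.writerow([_fmt(v) for v in row])
    finally:
        if own:
            handle.close()


def write_skplot(profiles: list[ScanProfile], file: str | Path | IO[str]) -> None:
    """One row per checkpoint per chromosome; relpos in [0, 1]."""
    if not profiles:
        raise ValueError("need at least one profile")

    def rows():
        for p in profiles:
            relpos = p.relpos
            for i in range(len(p.positions)):
                yield [
                    p.accession,
                    int(p.positions[i]),
                    float(relpos[i]),
                    int(p.gcskew[i]),
                    int(p.taskew[i]),
                    int(p.gcskew0[i]),
                    int(p.gcskew1[i]),
                    int(p.gcskew2[i]),
                    int(p.taskew0[i]),
                    int(p.taskew1[i]),
                    int(p.taskew2[i]),
                    int(p.gcskewNG[i]),
                    int(p.taskewNG[i]),
                    int(p.pospos[i]),
                    int(p.ngcount[i]),
                    int(p.acount[i]),
                    int(p.ccount[i]),
                    int(p.gcount[i]),
                    int(p.tcount[i]),
                ]

    _write_rows(file, SKPLOT_COLUMNS, rows())


def write_results(results: list[ChromosomeResult], file: str | Path | IO[str]) -> None:
    """One row per chromosome; div and shift appear once (from the GC fit)."""

    def rows():
        for r in results:
            row = [r.accession, r.gc.alpha1, r.gc.alpha2, r.gc.rms]
            for skew in SKEW_NAMES:
                if skew == "gc":
                    continue
                fit = r.constrained.get(skew)
                if fit is None:
                    logger.warning(
                        "%s: missing constrained fit for %s", r.accession, skew
                    )
                    row += [None, None, None]
                else:
                    row += [fit.alpha1, fit.alpha2, fit.rms]
            row += [r.div, r.shift]
            yield row

    _write_rows(file, RESULTS_COLUMNS, rows())


def write_genomes(
    records: list[SequenceRecord],
    tallies: Mapping[str, StartStopTally],
    taxonomy: Mapping[str, tuple[str, ...]],
    dnaA: Mapping[str, int],
    file: str | Path | IO[str],
) -> None:
    """One summary row per chromosome."""
    for acc in tallies:
        if acc not in {r.accession for r in records}:
            raise ValueError(f"tally for unknown accession {acc!r}")

    def rows():
        for r in records:
            tally = tallies.get(r.accession, StartStopTally())
            realms = taxonomy.get(r.accession, UNKNOWN_TAXON)
            yield [
                r.accession,
                r.description,
                r.residues.count("A"),
                r.residues.count("C"),
                r.residues.count("G"),
                r.residues.count("T"),
                1 if r.is_plasmid else 0,
                *realms,
                tally.protgenecount,
                tally.startATG,
                tally.startGTG,
                tally.startTTG,
                tally.startXXX,
                tally.stopTAG,
                tally.stopTAA,
                tally.stopTGA,
                tally.stopXXX,
                dnaA.get(r.accession, -1),
            ]

    _write_rows(file, GENOMES_COLUMNS, rows())


def write_codongc(
    compositions: Mapping[str, Mapping[str, float]], file: str | Path | IO[str]
) -> None:
    """Coding-nucleotide composition rows (see coding_composition)."""

    def rows():
        for acc, comp in compositions.items():
            yield [acc] + [comp[c] for c in CODONGC_COLUMNS[1:]]

    _write_rows(file, CODONGC_COLUMNS, rows())


def write_fit_csv(
    profile: ScanProfile, result: ChromosomeResult, file: str | Path | IO[str]
) -> None:
    """Observed and predicted values for every skew, at checkpoint resolution."""
    if profile.accession != result.accession:
        raise ValueError(
            f"profile {profile.accession!r} does not match result {result.accession!r}"
        )
    positions = profile.positions
    predictions = {}
    for skew in SKEW_NAMES:
        if skew == "gc":
            params = result.gc
        else:
            fit = result.constrained[skew]
            params = FitParams(fit.alpha1, fit.alpha2, result.div, result.shift)
        predictions[skew] = model_eval(params, profile.length, positions)

    def rows():
        relpos = profile.relpos
        for i in range(len(positions)):
            row = [int(positions[i]), float(relpos[i])]
            for skew in SKEW_NAMES:
                observed = profile.track(skew).values[i]
                row += [float(observed), float(predictions[skew][i])]
            yield row

    _write_rows(file, FIT_COLUMNS, rows())


def coding_composition(
    record: SequenceRecord, genes, div: float, shift: float
) -> dict[str, float]:
    """Base fractions of coding nucleotides, total and per replication strand.

    Bases are counted in each gene's reading direction (reverse-complemented
    for minus-strand genes).  A gene belongs to the leading strand when it is
    co-oriented with the replication fork of the arc holding its midpoint.
    """
    from .skew_scan import _COMPLEMENT  # reference-strand complement table

    length = len(record)
    counts = {group: {b: 0 for b in "ACGT"} for group in ("all", "lead", "lag")}
    for gene in genes:
        seq = record.residues[gene.start : gene.end]
        if gene.strand == -1:
            seq = seq.translate(_COMPLEMENT)[::-1]
        mid = ((gene.start + gene.end) / 2 - shift * length) % length
        on_leading_arc = mid < div * length
        co_oriented = (gene.strand == 1) == on_leading_arc
        group = "lead" if co_oriented else "lag"
        for base in "ACGT":
            n = seq.count(base)
            counts["all"][base] += n
            counts[group][base] += n

    def fracs(c: dict[str, int]) -> dict[str, float]:
        total = sum(c.values())
        if total == 0:
            return {b: 0.0 for b in "ACGT"}
        return {b: c[b] / total for b in "ACGT"}

    comp: dict[str, float] = {}
    for prefix, group in (("", "all"), ("lead", "lead"), ("lag", "lag")):
        f = fracs(counts[group])
        for base in "ACGT":
            comp[f"{prefix}{base.lower()}frac"] = f[base]
    gc_total = counts["all"]["G"] + counts["all"]["C"]
    at_total = counts["all"]["A"] + counts["all"]["T"]
    comp["ggcfrac"] = counts["all"]["G"] / gc_total if gc_total else 0.0
    comp["cgcfrac"] = counts["all"]["C"] / gc_total if gc_total else 0.0
    comp["atafrac"] = counts["all"]["A"] / at_total if at_total else 0.0
    comp["ttafrac"] = counts["all"]["T"] / at_total if at_total else 0.0
    return comp
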
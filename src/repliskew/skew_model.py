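"""Four-parameter piecewise-linear replichore model and its fitting.

The model describes a cumulative skew curve over a circular chromosome of
length ``L``: slope ``+alpha1`` on the leading arc (fraction ``div`` of the
chromosome, starting at offset ``shift * L``) and slope ``-alpha2`` on the
complementary lagging arc.  The curve is anchored so its value at position 0
is 0, matching how cumulative counters start.

Fitting minimizes the RMSE between the model and the checkpoint values of a
:class:`~repliskew.skew_scan.SkewTrack` with a multi-start downhill-simplex
(Nelder-Mead) search; the goodness-of-fit is the RMSE divided by the
absolute mean observed skew, so well-skewed chromosomes are not penalized.

The GC skew, being the most strongly defined, fixes ``div`` and ``shift``;
every other skew is then fitted with only its two slopes free (a linear
least-squares problem, solved exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .skew_scan import SKEW_NAMES, ScanProfile, SkewTrack

#: Database quality threshold: fits with gcRMS below this are considered good.
RMS_QUALITY_CUT = 0.16

#: Number of simplex starting points.
DEFAULT_STARTS = 10

_DIV_EPS = 1e-6
_MEAN_FLOOR = 1e-9


class DegenerateTrackError(ValueError):
    """Raised when a track carries no signal to fit (all-zero values)."""


@dataclass
class FitParams:
    """Fitted replichore model parameters for one skew."""

    alpha1: float  # per-nucleotide slope on the leading arc
    alpha2: float  # per-nucleotide slope magnitude on the lagging arc
    div: float  # leading-strand fraction of the chromosome, in (0, 1)
    shift: float  # origin offset as fraction of chromosome length, in [0, 1)
    rms: float = np.nan  # RMSE / |mean skew|


@dataclass
class ConstrainedFit:
    """Slopes-only fit of a secondary skew under the GC div/shift."""

    alpha1: float
    alpha2: float
    rms: float


@dataclass
class ChromosomeResult:
    """All fits for one chromosome: GC four-parameter fit plus constrained fits.

    ``div`` and ``shift`` are stored once, on the GC fit, and shared by all
    constrained fits.
    """

    accession: str
    gc: FitParams
    constrained: dict[str, ConstrainedFit]

    @property
    def div(self) -> float:
        return self.gc.div

    @property
    def shift(self) -> float:
        return self.gc.shift


def _leading_prefix_measure(
    positions: np.ndarray, length: float, div: float, shift: float
) -> np.ndarray:
    """Number of leading-arc nucleotides in [0, p) for each position p.

    The leading arc is the circular interval [shift*L, shift*L + div*L); it
    is split into at most two linear pieces for the overlap computation.
    """
    s = shift * length
    d = div * length
    hi = min(s + d, length)
    wrap = max(s + d - length, 0.0)
    lead = np.clip(np.minimum(positions, hi) - s, 0.0, hi - s)
    if wrap > 0:
        lead = lead + np.clip(positions, 0.0, wrap)
    return lead


def model_eval(
    params: FitParams, length: int, positions: np.ndarray | list[int]
) -> np.ndarray:
    """Evaluate the piecewise-linear model at the given positions (closed form)."""
    if not 0.0 < params.div < 1.0:
        raise ValueError(f"div must be in (0, 1), got {params.div}")
    if not 0.0 <= params.shift < 1.0:
        raise ValueError(f"shift must be in [0, 1), got {params.shift}")
    positions = np.asarray(positions, dtype=np.float64)
    if np.any(positions < 0) or np.any(positions > length):
        raise ValueError("positions must lie within [0, length]")
    lead = _leading_prefix_measure(positions, float(length), params.div, params.shift)
    return params.alpha1 * lead - params.alpha2 * (positions - lead)


def goodness(observed: np.ndarray, predicted: np.ndarray) -> float:
    """RMSE divided by the absolute mean of the observed values.

    Returns ``inf`` (rather than raising) when the observed mean is below
    the machine floor, flagging a degenerate normalization.
    """
    observed = np.asarray(observed, dtype=np.float64)
    predicted = np.asarray(predicted, dtype=np.float64)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    if observed.size == 0:
        raise ValueError("need at least one value")
    rmse = float(np.sqrt(np.mean((observed - predicted) ** 2)))
    mean = abs(float(np.mean(observed)))
    if mean < _MEAN_FLOOR:
        return float("inf")
    return rmse / mean


def canonicalize(params: FitParams) -> FitParams:
    """Relabel arcs so the rising-GC arc is "leading" and wrap shift into [0,1).

    If ``alpha1 < 0`` the leading/lagging labels are swapped: slopes are
    negated and exchanged, ``div`` becomes ``1 - div`` and ``shift`` moves to
    the start of the other arc.  The evaluated curve is unchanged.
    """
    alpha1, alpha2, div, shift = params.alpha1, params.alpha2, params.div, params.shift
    if alpha1 < 0:
        alpha1, alpha2 = -alpha2, -params.alpha1
        shift = shift + div
        div = 1.0 - div
    shift = shift % 1.0
    return replace(params, alpha1=alpha1, alpha2=alpha2, div=div, shift=shift)


def _rmse_objective(
    x: np.ndarray, positions: np.ndarray, values: np.ndarray, length: float
) -> float:
    a1, a2, div, shift = x
    if not _DIV_EPS < div < 1.0 - _DIV_EPS:
        return 1e30
    shift = shift % 1.0
    lead = _leading_prefix_measure(positions, length, div, shift)
    pred = a1 * lead - a2 * (positions - lead)
    return float(np.sqrt(np.mean((values - pred) ** 2)))


def _start_points(values: np.ndarray, length: float) -> list[np.ndarray]:
    # Attempt 1: average observed skew over the whole genome, no shift,
    # evenly distributed strands.  Attempts 2-10 walk shift over a grid.
    a0 = abs(float(values[-1])) / length
    if a0 == 0.0:
        a0 = max(float(np.max(np.abs(values))) / length, 1e-4)
    starts = [np.array([a0, a0, 0.5, 0.0])]
    starts += [np.array([a0, a0, 0.5, s]) for s in np.arange(0.1, 0.91, 0.1)]
    return starts


def fit_four_param(
    track: SkewTrack, length: int, starts: int = DEFAULT_STARTS
) -> FitParams:
    """Fit (alpha1, alpha2, div, shift) to a track by multi-start Nelder-Mead.

    The best of ``starts`` simplex runs (lowest RMSE, ties broken by smaller
    shift) is polished with one further simplex run, canonicalized, and
    returned with its goodness-of-fit in ``rms``.
    """
    if len(track) < 8:
        raise ValueError("need at least 8 checkpoints to fit four parameters")
    positions = track.positions.astype(np.float64)
    values = track.values.astype(np.float64)
    if np.all(values == 0):
        raise DegenerateTrackError("all-zero track: goodness-of-fit undefined")
    flen = float(length)

    candidates = []
    for x0 in _start_points(values, flen)[:starts]:
        res = minimize(
            _rmse_objective,
            x0,
            args=(positions, values, flen),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        candidates.append((res.fun, res.x[3] % 1.0, res.x))
    candidates.sort(key=lambda c: (c[0], c[1]))
    best = candidates[0][2]

    # Polish: restart the simplex at the winner to escape premature collapse.
    res = minimize(
        _rmse_objective,
        best,
        args=(positions, values, flen),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    a1, a2, div, shift = res.x
    params = FitParams(
        alpha1=float(a1),
        alpha2=float(a2),
        div=float(np.clip(div, _DIV_EPS, 1.0 - _DIV_EPS)),
        shift=float(shift % 1.0),
    )
    params = canonicalize(params)
    predicted = model_eval(params, length, positions)
    params.rms = goodness(values, predicted)
    return params


def fit_constrained(
    track: SkewTrack, length: int, div: float, shift: float
) -> ConstrainedFit:
    """Fit only the two slopes of a track, with div and shift held fixed.

    With the breakpoints fixed the model is linear in (alpha1, alpha2), so
    the RMSE-optimal slopes are obtained by exact least squares.  Slopes may
    come out negative (discordant skews).
    """
    positions = track.positions.astype(np.float64)
    values = track.values.astype(np.float64)
    lead = _leading_prefix_measure(positions, float(length), div, shift)
    design = np.column_stack([lead, -(positions - lead)])
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    predicted = design @ coef
    return ConstrainedFit(
        alpha1=float(coef[0]), alpha2=float(coef[1]), rms=goodness(values, predicted)
    )


def fit_profile(
    profile: ScanProfile, starts: int = DEFAULT_STARTS
) -> ChromosomeResult:
    """Fit all eleven skews of a scanned chromosome.

    The GC skew picks ``div`` and ``shift``; all other skews are fitted under
    that fixed constraint.
    """
    gc = fit_four_param(profile.track("gc"), profile.length, starts=starts)
    constrained = {}
    for name in SKEW_NAMES:
        if name == "gc":
            continue
        constrained[name] = fit_constrained(
            profile.track(name), profile.length, gc.div, gc.shift
        )
    return ChromosomeResult(accession=profile.accession, gc=gc, constrained=constrained)


def asymmetry_flags(result: ChromosomeResult) -> tuple[bool, bool]:
    """Flags for skew asymmetry (slope ratio >= 3) and strand asymmetry.

    A chromosome is skew-asymmetric when one strand's GC slope magnitude is
    at least 3 times the other's, and strand-asymmetric when one replichore
    is at least 3 times longer than the other.
    """
    lo = min(abs(result.gc.alpha1), abs(result.gc.alpha2))
    hi = max(abs(result.gc.alpha1), abs(result.gc.alpha2))
    skew_asymmetric = True if lo == 0 else hi >= 3 * lo
    div = result.gc.div
    strand_asymmetric = max(div, 1 - div) >= 3 * min(div, 1 - div)
    return skew_asymmetric, strand_asymmetric


def bias_product(codon_gc_excess: float, strand_bias_slope: float) -> float:
    """Product of codon bias and strand bias, the predicted skew slope.

    ``codon_gc_excess`` is the signed G excess among coding G+C nucleotides,
    ``2 * ggcfrac - 1``; ``strand_bias_slope`` is the fitted leading-strand
    slope of the strand-bias counter.
    """
    return codon_gc_excess * strand_bias_slope
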
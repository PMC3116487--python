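"""Raw spectra -> homoscedastic peaks x profiles intensity matrix.

The chain: log transform, median smoothing, tophat (morphological
opening) baseline removal, CWT peak picking against a mean-spectrum
reference, integer index-shift alignment, apex-window quantification, a
second log with pseudo-count for variance stabilization, and finally
averaging of technical replicates.  ANOVA downstream assumes the output
is homoscedastic — variance independent of mean intensity — which the
double log achieves under multiplicative error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy.ndimage import grey_opening
from scipy.signal import argrelmax
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from maldianova.spectrum import Spectrum, Stage

__all__ = [
    "PeakSet", "AlignmentShift", "IntensityMatrix", "VarianceDiagnostic",
    "log_transform", "median_smooth", "tophat_baseline", "cwt_pick_peaks",
    "compute_reference_peaks", "align_shift", "apply_shift",
    "quantify_peaks", "stabilize_variance", "variance_diagnostic",
    "average_technical_replicates", "preprocess_dataset",
]


@dataclass
class PeakSet:
    """Apex indices (strictly increasing) picked from one spectrum."""

    spectrum_id: str
    apex_indices: np.ndarray
    snr: np.ndarray

    def __post_init__(self) -> None:
        self.apex_indices = np.asarray(self.apex_indices, dtype=int)
        self.snr = np.asarray(self.snr, dtype=float)
        if len(self.apex_indices) > 1 and np.any(np.diff(self.apex_indices) <= 0):
            raise ValueError("apex indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.apex_indices)


@dataclass
class AlignmentShift:
    """Signed integer index shift of one spectrum versus the reference."""

    spectrum_id: str
    shift: int
    n_matched: int
    zero_match: bool = False


@dataclass
class IntensityMatrix:
    """Peaks x profiles table of intensities.

    ``data`` is a DataFrame with one row per peak (index: peak m/z) and
    one column per profile (spectrum id at replicate level, sample id
    after averaging).  ``peak_indices`` keeps the axis index of each
    peak for traceability.
    """

    data: pd.DataFrame
    peak_indices: np.ndarray
    level: str = "replicate"            # or "sample-averaged"
    transforms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if len(self.peak_indices) != len(self.data):
            raise ValueError("peak_indices/data length mismatch")
        if self.level == "sample-averaged" and self.data.isna().any().any():
            raise ValueError("missing values after averaging")

    @property
    def peak_mz(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=float)

    @property
    def n_peaks(self) -> int:
        return len(self.data)

    @property
    def n_profiles(self) -> int:
        return self.data.shape[1]


@dataclass
class VarianceDiagnostic:
    """Mean-vs-spread cloud per (peak, replicate group), with fits."""

    means: np.ndarray
    spreads: np.ndarray
    slope: float
    intercept: float
    lowess: np.ndarray  # (k, 2) sorted curve points
    statistic: str = "se"


# ---------------------------------------------------------------- chain

def log_transform(spectrum: Spectrum, c0: float = 1.0) -> Spectrum:
    """First log: ``x -> log(x + c0)``; the guard keeps zeros finite."""
    if spectrum.stage != Stage.RAW:
        raise ValueError("log_transform expects a raw spectrum")
    x = spectrum.intensities
    if np.any(x < 0):
        raise ValueError("negative raw intensities")
    return spectrum.advanced(np.log(x + c0), Stage.LOGGED)


def median_smooth(spectrum: Spectrum, window: int = 9) -> Spectrum:
    """Centered running median; the window shrinks at the edges."""
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    x = spectrum.intensities
    n = len(x)
    if window > n:
        raise ValueError("window larger than spectrum")
    half = window // 2
    out = np.empty(n)
    # interior via a strided sliding window, edges by shrinking
    if n >= window:
        sw = np.lib.stride_tricks.sliding_window_view(x, window)
        out[half:n - half] = np.median(sw, axis=1)
    for i in range(half):
        out[i] = np.median(x[:i + half + 1])
        out[n - 1 - i] = np.median(x[n - 1 - i - half:])
    return spectrum.advanced(out, Stage.SMOOTHED)


def tophat_baseline(spectrum: Spectrum, struct_width: int = 151) -> Spectrum:
    """Subtract the morphological opening (flat structuring element).

    Removes baseline components wider than ``struct_width`` while
    preserving narrower peaks; the result is non-negative.
    """
    if struct_width % 2 == 0:
        raise ValueError("struct_width must be odd")
    if struct_width < 3:
        raise ValueError("struct_width below peak-resolving minimum (3)")
    if spectrum.stage != Stage.SMOOTHED:
        raise ValueError("tophat expects a smoothed spectrum")
    x = spectrum.intensities
    opened = grey_opening(x, size=struct_width, mode="nearest")
    return spectrum.advanced(x - opened, Stage.BASELINED)


def _cwt_ridges(coefs: np.ndarray, scales: np.ndarray,
                gap_thresh: int = 2) -> list[list[tuple[int, int]]]:
    """Track ridge lines from coarse to fine scale.

    A ridge links local maxima of adjacent scale rows that lie within
    one scale-width of each other; a ridge survives up to ``gap_thresh``
    rows with no matching maximum.
    """
    nrow = coefs.shape[0]
    maxima = [argrelmax(coefs[i], order=max(1, int(scales[i])))[0]
              for i in range(nrow)]
    active: list[list[tuple[int, int]]] = [
        [(nrow - 1, int(c))] for c in maxima[-1]]
    gaps = [0] * len(active)
    done: list[list[tuple[int, int]]] = []
    for row in range(nrow - 2, -1, -1):
        cols = list(maxima[row])
        used: set[int] = set()
        for k, ridge in enumerate(active):
            prev = ridge[-1][1]
            win = max(1, int(scales[row]))
            cand = [c for c in cols if abs(c - prev) <= win and c not in used]
            if cand:
                c = min(cand, key=lambda c: (abs(c - prev), c))
                used.add(c)
                ridge.append((row, int(c)))
                gaps[k] = 0
            else:
                gaps[k] += 1
        for c in cols:
            if c not in used:
                active.append([(row, int(c))])
                gaps.append(0)
        nxt_a, nxt_g = [], []
        for ridge, g in zip(active, gaps):
            if g > gap_thresh:
                done.append(ridge)
            else:
                nxt_a.append(ridge)
                nxt_g.append(g)
        active, gaps = nxt_a, nxt_g
    done.extend(active)
    return done


def cwt_pick_peaks(
    spectrum: Spectrum | np.ndarray,
    scale_min: int = 3,
    scale_max: int = 16,
    length_min: int = 7,
    noise_quantile: float = 0.95,
    min_snr: float = 3.0,
    refine_window: int = 8,
    spectrum_id: str = "<anonymous>",
) -> PeakSet:
    """Mexican-hat CWT peak picking via ridge-line tracking.

    The transform is taken over integer scales ``scale_min..scale_max``;
    ridge lines shorter than ``length_min`` rows are discarded, as are
    ridges whose maximal coefficient falls below ``min_snr`` times the
    noise level (the ``noise_quantile`` quantile of the absolute
    finest-scale coefficients).  Apexes are reported at the finest scale
    a ridge reaches, refined to the intensity centroid within
    ``±refine_window`` indices — a deterministic, translation-equivariant
    estimate that is stabler under noise than the raw ridge end.
    Picking is invariant to rescaling the intensities.
    """
    if isinstance(spectrum, Spectrum):
        if spectrum.stage < Stage.BASELINED:
            raise ValueError("peak picking expects a baselined spectrum")
        y = spectrum.intensities
        spectrum_id = spectrum.spectrum_id
    else:
        y = np.asarray(spectrum, dtype=float)
    if len(y) < 4 * scale_max:
        raise ValueError("spectrum shorter than minimum CWT support")
    scales = np.arange(scale_min, scale_max + 1)
    coefs, _ = pywt.cwt(y, scales, "mexh")
    ridges = _cwt_ridges(coefs, scales)
    noise = float(np.quantile(np.abs(coefs[0]), noise_quantile))
    noise = max(noise, 1e-12)
    picks: dict[int, float] = {}
    for ridge in ridges:
        if len(ridge) < length_min:
            continue
        snr = max(coefs[r, c] for r, c in ridge) / noise
        if snr < min_snr:
            continue
        apex = ridge[-1][1]
        if refine_window > 0:
            for _ in range(3):       # re-center until the window is symmetric
                lo = max(0, apex - refine_window)
                hi = min(len(y), apex + refine_window + 1)
                w = np.clip(y[lo:hi], 0.0, None)
                if w.sum() <= 0:
                    break
                new = int(round(float((w * np.arange(lo, hi)).sum()
                                      / w.sum())))
                if new == apex:
                    break
                apex = new
        picks[apex] = max(snr, picks.get(apex, 0.0))
    apices = np.array(sorted(picks), dtype=int)
    snrs = np.array([picks[a] for a in apices])
    return PeakSet(spectrum_id, apices, snrs)


def compute_reference_peaks(spectra: list[Spectrum], **cwt_kwargs) -> PeakSet:
    """Pick reference peaks from the point-wise mean of baselined spectra."""
    if not spectra:
        raise ValueError("no spectra")
    n = len(spectra[0])
    for s in spectra:
        if len(s) != n:
            raise ValueError("spectra length mismatch")
        if s.stage < Stage.BASELINED:
            raise ValueError("reference peaks need baselined spectra")
    mean = np.mean([s.intensities for s in spectra], axis=0)
    ps = cwt_pick_peaks(mean, spectrum_id="<mean spectrum>", **cwt_kwargs)
    return ps


def align_shift(peakset: PeakSet, reference: PeakSet,
                window: int = 30) -> AlignmentShift:
    """Estimate one integer shift from apex distances to reference peaks.

    For every reference apex the nearest observed apex within ±window
    contributes its signed distance (observed − reference); the shift is
    the rounded mean of those distances (half away from zero).  With no
    matches the shift is 0 and the result is flagged.
    """
    distances = []
    obs = peakset.apex_indices
    for ref in reference.apex_indices:
        if len(obs) == 0:
            break
        j = int(np.argmin(np.abs(obs - ref)))
        d = int(obs[j]) - int(ref)
        if abs(d) <= window:
            distances.append(d)
    if not distances:
        return AlignmentShift(peakset.spectrum_id, 0, 0, zero_match=True)
    m = float(np.mean(distances))
    shift = int(math.copysign(math.floor(abs(m) + 0.5), m))
    return AlignmentShift(peakset.spectrum_id, shift, len(distances))


def apply_shift(spectrum: Spectrum, shift: int) -> Spectrum:
    """Translate intensities by −shift indices onto reference coordinates.

    The vacated edge is filled with the boundary value.  A zero shift
    still advances the stage to ``aligned``.
    """
    if abs(shift) >= len(spectrum):
        raise ValueError("|shift| must be smaller than the spectrum")
    x = spectrum.intensities
    out = np.empty_like(x)
    if shift == 0:
        out[:] = x
    elif shift > 0:                      # features sit late; pull them back
        out[:-shift] = x[shift:]
        out[-shift:] = x[-1]
    else:
        out[-shift:] = x[:shift]
        out[:-shift] = x[0]
    return spectrum.advanced(out, Stage.ALIGNED)


def quantify_peaks(spectrum: Spectrum, reference: PeakSet,
                   q: int = 4) -> np.ndarray:
    """Per reference apex: maximum intensity within ±q indices (clipped)."""
    if spectrum.stage != Stage.ALIGNED:
        raise ValueError("quantification expects an aligned spectrum")
    x = spectrum.intensities
    n = len(x)
    vals = np.empty(len(reference))
    for i, a in enumerate(reference.apex_indices):
        lo, hi = max(0, a - q), min(n, a + q + 1)
        vals[i] = x[lo:hi].max()
    return vals


def stabilize_variance(matrix: IntensityMatrix, pseudo_count: float = 0.1,
                       offset: float = 0.0) -> IntensityMatrix:
    """Second log with pseudo-count: ``v -> log(v + 0.1) + offset``.

    Applied element-wise at replicate level; turns the residual
    multiplicative error of quantified peak intensities into an additive
    one so downstream ANOVA sees homoscedastic data.
    """
    if matrix.level != "replicate":
        raise ValueError("stabilization applies at replicate level")
    v = matrix.data.to_numpy()
    if np.any(v + pseudo_count <= 0):
        raise ValueError("values <= -pseudo_count cannot be logged")
    out = np.log(v + pseudo_count) + offset
    return IntensityMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        matrix.peak_indices, matrix.level,
        matrix.transforms + [f"log(v+{pseudo_count})", f"offset+{offset}"],
    )


def variance_diagnostic(
    matrix: IntensityMatrix,
    replicate_groups: pd.Series | dict,
    statistic: str = "se",
    lowess_frac: float = 2.0 / 3.0,
) -> VarianceDiagnostic:
    """Mean-vs-spread diagnostic per (peak, replicate group).

    ``replicate_groups`` maps profile id -> group label (typically the
    sample id); groups with fewer than two replicates are excluded.
    ``statistic`` is ``"se"`` (standard error of the mean, as in the
    classic error plots) or ``"sd"``.  Returns the least-squares line
    and a lowess curve through the (mean, spread) cloud.
    """
    groups = pd.Series(replicate_groups)
    cols = matrix.data.columns
    missing = [c for c in cols if c not in groups.index]
    if missing:
        raise KeyError(f"profiles without replicate group: {missing[:3]}")
    means, spreads = [], []
    for _, sub in matrix.data.T.groupby(groups.loc[cols]):
        if len(sub) < 2:
            continue
        m = sub.mean(axis=0).to_numpy()
        sd = sub.std(axis=0, ddof=1).to_numpy()
        if statistic == "se":
            sd = sd / np.sqrt(len(sub))
        elif statistic != "sd":
            raise ValueError("statistic must be 'se' or 'sd'")
        means.append(m)
        spreads.append(sd)
    if not means:
        raise ValueError("no replicate group with >= 2 members")
    x = np.concatenate(means)
    y = np.concatenate(spreads)
    slope, intercept = np.polyfit(x, y, 1)
    curve = sm_lowess(y, x, frac=lowess_frac, return_sorted=True)
    return VarianceDiagnostic(x, y, float(slope), float(intercept),
                              curve, statistic)


def average_technical_replicates(matrix: IntensityMatrix,
                                 sample_sheet: pd.DataFrame) -> IntensityMatrix:
    """One profile per biological sample: the mean of its replicates.

    Technical replicates are not independent observations and would
    inflate ANOVA degrees of freedom, so they are averaged (on the
    stabilized scale) before any statistics.
    """
    if matrix.level != "replicate":
        raise ValueError("matrix already averaged")
    mapping = sample_sheet.set_index("spectrum_id")["sample_id"]
    unmapped = [c for c in matrix.data.columns if c not in mapping.index]
    if unmapped:
        raise KeyError(f"profiles missing from sample sheet: {unmapped[:3]}")
    # preserve first-appearance sample order from the sheet
    order = pd.unique(mapping.loc[matrix.data.columns])
    avg = matrix.data.T.groupby(mapping.loc[matrix.data.columns]).mean().T
    avg = avg[order]
    return IntensityMatrix(avg, matrix.peak_indices, "sample-averaged",
                           matrix.transforms + ["replicate-mean"])


# ------------------------------------------------------------- pipeline

def preprocess_dataset(
    spectra: list[Spectrum],
    sample_sheet: pd.DataFrame,
    c0: float = 1.0,
    smooth_window: int = 9,
    struct_width: int = 151,
    align: bool = True,
    align_window: int = 30,
    quant_window: int = 4,
    pseudo_count: float = 0.1,
    offset: float = 0.0,
    cwt_kwargs: dict | None = None,
) -> tuple[IntensityMatrix, IntensityMatrix, dict]:
    """Run the full chain on a dataset.

    Returns ``(replicate_matrix, sample_matrix, info)`` where ``info``
    holds reference peaks, per-spectrum shifts and warnings.  With
    ``align=False`` the per-spectrum CWT/alignment pass is skipped and
    every shift is taken as zero (appropriate for drift-free data).
    """
    cwt_kwargs = cwt_kwargs or {}
    baselined = []
    for s in spectra:
        b = tophat_baseline(median_smooth(log_transform(s, c0), smooth_window),
                            struct_width)
        baselined.append(b)
    reference = compute_reference_peaks(baselined, **cwt_kwargs)
    if len(reference) == 0:
        raise ValueError("no reference peaks found in the mean spectrum")

    shifts: dict[str, AlignmentShift] = {}
    warn: list[str] = []
    aligned = []
    for b in baselined:
        if align:
            ps = cwt_pick_peaks(b, **cwt_kwargs)
            sh = align_shift(ps, reference, window=align_window)
            if sh.zero_match:
                warn.append(f"no reference match for {b.spectrum_id}")
        else:
            sh = AlignmentShift(b.spectrum_id, 0, 0)
        shifts[b.spectrum_id] = sh
        aligned.append(apply_shift(b, sh.shift))

    axis = spectra[0].axis
    mz = axis[reference.apex_indices]
    cols = {a.spectrum_id: quantify_peaks(a, reference, q=quant_window)
            for a in aligned}
    rep = IntensityMatrix(
        pd.DataFrame(cols, index=pd.Index(mz, name="mz")),
        reference.apex_indices, "replicate",
        [f"log(x+{c0})", f"median{smooth_window}", f"tophat{struct_width}",
         "aligned" if align else "unaligned", f"max±{quant_window}"],
    )
    rep = stabilize_variance(rep, pseudo_count, offset)
    sample = average_technical_replicates(rep, sample_sheet)
    info = {"reference": reference, "shifts": shifts, "warnings": warn}
    if warn:
        warnings.warn(f"{len(warn)} spectra had no reference match",
                      stacklevel=2)
    return rep, sample, info
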
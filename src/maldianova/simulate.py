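"""Synthetic multi-factorial MALDI-TOF profile datasets with ground truth.

The generator emulates plasma profiling data from a multi-strain,
multi-diet, multi-week mouse study: correlated peak families derived
from common parent proteins, log-normal (multiplicative) intensity
noise, slowly varying chemical baselines, and small per-spectrum integer
drifts of the sampling index.  Every random choice is recorded in a
:class:`SyntheticTruth` object so each downstream stage can be tested
against what was planted.

Model, per peak ``j`` of family ``f`` and biological sample ``s``::

    log A_{s,j} = base_f + effect_f(s)
                  + sigma_bio * (sqrt(rho_f) u_{s,f} + sqrt(1-rho_f) v_{s,j})

``u`` is shared within the family (the parent protein's abundance), ``v``
is peak specific, so ``rho_f`` sets the within-family correlation of
log-abundances.  Each technical replicate ``r`` then observes

    A_{s,j} * exp(sigma_tech * e_{r,j})

i.e. multiplicative noise whose raw-scale standard deviation grows
linearly with the mean — the error structure that motivates the second
log transform in the pre-processing chain.  Peaks are rendered as
Gaussians in index space on top of a non-negative baseline (decaying
exponential plus a slow sinusoid), then the whole trace is jittered
point-wise by a small multiplicative factor and shifted by the
spectrum's planted integer drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from maldianova.design import StudyDesign
from maldianova.spectrum import Spectrum, Stage

MZ_MIN = 700.0
MZ_MAX = 10_000.0
REPLICATES_PER_PREPARATION = 4

FACTORS = ("genotype", "diet", "week", "genotype:diet")


@dataclass
class PeakFamily:
    """Peaks sharing a parent protein, hence correlated abundances."""

    family_id: str
    apex_indices: list[int]
    base_log_intensity: float
    within_family_correlation: float

    def __post_init__(self) -> None:
        idx = list(self.apex_indices)
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("apex indices must be strictly increasing")
        if not 0.0 <= self.within_family_correlation <= 1.0:
            raise ValueError("correlation must be in [0, 1]")


@dataclass
class PlantedEffect:
    """A log-intensity shift tied to levels of one experimental factor.

    ``level_shifts`` maps a level (or a ``"genotype|diet"`` pair for the
    interaction) to the shift added to every peak of the family.
    """

    family_id: str
    factor: str
    level_shifts: dict[str, float]

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise ValueError(f"unknown factor {self.factor!r}")
        for v in self.level_shifts.values():
            if not np.isfinite(v):
                raise ValueError("shifts must be finite")

    def shift_for(self, genotype: str, diet: str, week: int) -> float:
        if self.factor == "genotype":
            return self.level_shifts.get(genotype, 0.0)
        if self.factor == "diet":
            return self.level_shifts.get(diet, 0.0)
        if self.factor == "week":
            return self.level_shifts.get(str(week), 0.0)
        return self.level_shifts.get(f"{genotype}|{diet}", 0.0)


@dataclass
class NoiseParams:
    """Noise magnitudes, all on the natural-log intensity scale except
    the baseline terms (raw intensity units) and the drift (indices)."""

    technical_sigma: float = 0.5
    biological_sigma: float = 0.4
    point_sigma: float = 0.03
    baseline_amplitude: float = 60.0
    baseline_decay: float = 5.0       # e-folds across the axis
    baseline_wave_amplitude: float = 20.0
    baseline_wave_periods: float = 2.5
    max_index_shift: int = 10
    peak_width_sd: float = 3.0        # Gaussian peak sd, in indices


@dataclass
class SyntheticTruth:
    """Everything that was planted, keyed for recovery tests."""

    seed: int
    axis_length: int
    index_shifts: dict[str, int]            # spectrum_id -> drift
    peak_apices: list[int]                  # true apex index per peak
    peak_families: dict[str, str]           # "peak@index" -> family_id
    effects: list[PlantedEffect]
    noise: NoiseParams

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        d["effects"] = [PlantedEffect(**e) for e in d["effects"]]
        d["noise"] = NoiseParams(**d["noise"])
        d["index_shifts"] = {k: int(v) for k, v in d["index_shifts"].items()}
        return cls(**d)


@dataclass
class SimulatedDataset:
    spectra: list[Spectrum]
    sample_sheet: pd.DataFrame
    truth: SyntheticTruth


def default_families(
    axis_length: int,
    n_families: int = 5,
    peaks_per_family: int = 4,
    n_singletons: int = 10,
    correlation: float = 0.9,
    seed: int = 0,
) -> list[PeakFamily]:
    """A plausible peak catalogue: correlated families plus singleton peaks.

    Apex positions are drawn without replacement on a coarse grid with a
    guard margin so neighbouring peaks stay resolvable; base log
    intensities are uniform in [5, 9] (raw heights roughly 150-8000).
    """
    rng = np.random.default_rng(seed)
    n_peaks = n_families * peaks_per_family + n_singletons
    margin = max(30, axis_length // 100)
    grid = np.arange(margin, axis_length - margin, 2 * margin)
    if len(grid) < n_peaks:
        raise ValueError("axis too short for requested peak count")
    pos = np.sort(rng.choice(grid, size=n_peaks, replace=False))
    rng.shuffle(pos)
    families = []
    k = 0
    for i in range(n_families):
        apices = sorted(int(p) for p in pos[k:k + peaks_per_family])
        k += peaks_per_family
        families.append(PeakFamily(
            family_id=f"fam{i + 1}",
            apex_indices=apices,
            base_log_intensity=float(rng.uniform(5.0, 9.0)),
            within_family_correlation=correlation,
        ))
    for i in range(n_singletons):
        families.append(PeakFamily(
            family_id=f"solo{i + 1}",
            apex_indices=[int(pos[k + i])],
            base_log_intensity=float(rng.uniform(5.0, 9.0)),
            within_family_correlation=1.0,
        ))
    return families


def _allocate_replicates(n_spectra: int, n_samples: int) -> list[int]:
    """Spread spectra over samples as evenly as possible (max 8 each)."""
    base, extra = divmod(n_spectra, n_samples)
    counts = [base + (1 if i < extra else 0) for i in range(n_samples)]
    if max(counts) > 2 * REPLICATES_PER_PREPARATION:
        raise ValueError("more than 8 technical replicates per sample")
    return counts


def _baseline(n: int, noise: NoiseParams, phase: float) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)
    decay = noise.baseline_amplitude * np.exp(-noise.baseline_decay * t)
    wave = noise.baseline_wave_amplitude * 0.5 * (
        1.0 + np.sin(2.0 * np.pi * noise.baseline_wave_periods * t + phase))
    return decay + wave


def simulate_dataset(
    design: StudyDesign,
    families: list[PeakFamily],
    effects: list[PlantedEffect] | None = None,
    noise: NoiseParams | None = None,
    axis_length: int = 4000,
    seed: int = 0,
) -> SimulatedDataset:
    """Simulate raw spectra plus sample sheet for a whole study design.

    Identical arguments (including ``seed``) give bit-identical output.
    Empty design cells are skipped; the sample sheet has one row per
    spectrum with columns ``spectrum_id, spectrum_file, sample_id,
    genotype, diet, week, preparation, replicate``.
    """
    effects = list(effects or [])
    noise = noise or NoiseParams()
    fam_by_id = {f.family_id: f for f in families}
    for e in effects:
        if e.family_id not in fam_by_id:
            raise ValueError(f"effect references unknown family {e.family_id!r}")
    max_apex = max((i for f in families for i in f.apex_indices), default=0)
    margin = 5 * noise.peak_width_sd + noise.max_index_shift
    if max_apex + margin > axis_length:
        raise ValueError("axis_length too short for the peak catalogue")

    rng = np.random.default_rng(seed)
    axis = np.linspace(MZ_MIN, MZ_MAX, axis_length)
    half_profiles = {
        f.family_id: [np.exp(-0.5 * ((np.arange(axis_length) - a)
                                     / noise.peak_width_sd) ** 2)
                      for a in f.apex_indices]
        for f in families
    }

    spectra: list[Spectrum] = []
    rows: list[dict] = []
    index_shifts: dict[str, int] = {}

    for (g, d, w), cell in design.cells():
        if cell.n_samples == 0:
            continue
        rep_counts = _allocate_replicates(cell.n_spectra, cell.n_samples)
        for s_idx, n_rep in enumerate(rep_counts, start=1):
            sample_id = f"{g}_{d}_w{w}_s{s_idx}"
            # biological draw, shared by all technical replicates
            amplitudes: list[tuple[np.ndarray, float]] = []
            for fam in families:
                shift = sum(e.shift_for(g, d, w) for e in effects
                            if e.family_id == fam.family_id)
                u = rng.standard_normal()
                rho = fam.within_family_correlation
                for j, prof in enumerate(half_profiles[fam.family_id]):
                    v = rng.standard_normal()
                    log_amp = (fam.base_log_intensity + shift
                               + noise.biological_sigma
                               * (np.sqrt(rho) * u + np.sqrt(1.0 - rho) * v))
                    amplitudes.append((prof, log_amp))
            for r_idx in range(n_rep):
                prep = r_idx // REPLICATES_PER_PREPARATION + 1
                repl = r_idx % REPLICATES_PER_PREPARATION + 1
                spectrum_id = f"{sample_id}_p{prep}r{repl}"
                trace = _baseline(axis_length, noise,
                                  phase=float(rng.uniform(0, 2 * np.pi)))
                for prof, log_amp in amplitudes:
                    tech = noise.technical_sigma * rng.standard_normal()
                    trace = trace + np.exp(log_amp + tech) * prof
                if noise.point_sigma > 0:
                    trace = trace * np.exp(
                        noise.point_sigma * rng.standard_normal(axis_length))
                # drawn unconditionally so runs differing only in
                # max_index_shift stay pairable draw-for-draw
                drift = int(rng.integers(-noise.max_index_shift,
                                         noise.max_index_shift + 1))
                if drift:
                    shifted = np.empty_like(trace)
                    if drift > 0:
                        shifted[drift:] = trace[:-drift]
                        shifted[:drift] = trace[0]
                    else:
                        shifted[:drift] = trace[-drift:]
                        shifted[drift:] = trace[-1]
                    trace = shifted
                index_shifts[spectrum_id] = drift
                spectra.append(Spectrum(spectrum_id, axis, trace, Stage.RAW))
                rows.append({
                    "spectrum_id": spectrum_id,
                    "spectrum_file": f"{spectrum_id}.csv",
                    "sample_id": sample_id,
                    "genotype": g, "diet": d, "week": w,
                    "preparation": prep, "replicate": repl,
                })

    sheet = pd.DataFrame(rows)
    peak_apices = [a for f in families for a in f.apex_indices]
    peak_families = {f"peak@{a}": f.family_id
                     for f in families for a in f.apex_indices}
    truth = SyntheticTruth(
        seed=int(seed),
        axis_length=int(axis_length),
        index_shifts=index_shifts,
        peak_apices=sorted(peak_apices),
        peak_families=peak_families,
        effects=effects,
        noise=noise,
    )
    return SimulatedDataset(spectra, sheet, truth)
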
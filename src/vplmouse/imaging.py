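"""Intrinsic-signal optical imaging: synthesis and analysis.

Synthesis.  ``synth_cortex`` renders reflectance movies of a model V1 patch.
In periodic mode a bar sweeps the visual field at 0.1 Hz and every
responsive pixel modulates sinusoidally at the stimulus frequency with a
phase that varies linearly across the cortex (retinotopy).  In episodic
mode drifting gratings of one spatial frequency are shown for 4 s per trial
with a 1 s pre-stimulus baseline and a 7 s gray gap; the evoked reflectance
decrease scales linearly with SF down to zero at the animal's true cut-off.

Analysis mirrors the standard single-condition pipeline: per-trial delta-R/R
maps (response window minus blank, divided by blank), trial averaging,
circular-disk smoothing (3 px = 51 um radius), ROI tuning curves (response
magnitude positive), and the cut-off SF as the zero crossing of a linear
fit.  Retinotopy quality is quantified by the phase scatter of the map at
the stimulus frequency.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import linregress
from skimage.morphology import disk

__all__ = [
    "StimulusSchedule",
    "FrameStack",
    "RetinotopyMap",
    "ConditionMap",
    "CutoffFit",
    "CortexTruth",
    "cortex_truth",
    "synth_cortex",
    "fourier_map",
    "condition_map",
    "trial_maps",
    "smooth_map",
    "default_roi",
    "roi_tuning",
    "cutoff_sf",
    "map_scatter",
    "analyze_sf_series",
    "simulate_cutoff_animal",
    "save_stack",
    "load_stack",
    "DEFAULT_SF_CONDITIONS",
]

DEFAULT_FRAME_RATE = 5.0            # frames per second
DEFAULT_PIXEL_SIZE_UM = 17.0
DEFAULT_SF_CONDITIONS = tuple(np.round(np.arange(0.05, 0.501, 0.05), 3))


@dataclass(frozen=True)
class StimulusSchedule:
    """Stimulus timing for one acquisition.

    mode "periodic": a bar sweeping at ``frequency_hz`` for ``duration_s``.
    mode "episodic": per-trial boxcar gratings; times in seconds, the
    response window is measured from stimulus onset.
    """

    mode: str = "episodic"
    # periodic mode
    frequency_hz: float = 0.1
    duration_s: float = 600.0
    # episodic mode
    baseline_s: float = 1.0
    stim_s: float = 4.0
    window_s: tuple[float, float] = (2.0, 6.0)
    gap_s: float = 7.0
    n_trials: int = 32
    sf_cpd: float | None = None

    def __post_init__(self):
        if self.mode not in ("periodic", "episodic"):
            raise ValueError("mode must be 'periodic' or 'episodic'")
        if self.mode == "episodic":
            lo, hi = self.window_s
            if not 0 <= lo < hi <= self.stim_s + self.gap_s:
                raise ValueError("analysis window outside trial bounds")

    @property
    def trial_s(self) -> float:
        return self.baseline_s + self.stim_s + self.gap_s


@dataclass
class FrameStack:
    """Reflectance movie (time, height, width) with acquisition metadata."""

    frames: np.ndarray
    frame_interval_s: float
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    schedule: StimulusSchedule = field(default_factory=StimulusSchedule)

    def __post_init__(self):
        if self.frames.ndim != 3 or min(self.frames.shape) < 1:
            raise ValueError("frames must be a (time, height, width) array")
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.frame_interval_s

    @property
    def times(self) -> np.ndarray:
        """Frame-centre times in seconds."""
        return (np.arange(self.frames.shape[0]) + 0.5) * self.frame_interval_s


@dataclass(frozen=True)
class RetinotopyMap:
    magnitude: np.ndarray       # response strength at the stimulus frequency
    phase: np.ndarray           # radians in (-pi, pi], maps to eccentricity


@dataclass(frozen=True)
class ConditionMap:
    """Signed delta-R/R image for one SF condition (negative = response)."""

    data: np.ndarray
    sf_cpd: float | None = None
    smoothed: bool = False
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM


@dataclass(frozen=True)
class CutoffFit:
    """Linear SF-response fit and its zero crossing (the cut-off SF)."""

    sfs: np.ndarray
    responses: np.ndarray
    slope: float
    intercept: float
    cutoff: float
    valid: bool
    fitted_mask: np.ndarray     # which points entered the fit


# ---------------------------------------------------------------------------
# synthesis

@dataclass(frozen=True)
class CortexTruth:
    """Ground truth of a synthetic cortical patch.

    The SF response declines linearly to zero at ``cutoff_cpd`` (and stays
    zero beyond); ``amplitude`` is the peak fractional reflectance decrease
    as SF -> 0.  Noise is white Gaussian per pixel and frame; drift is a
    slow global reflectance oscillation.  Retinotopic phase advances
    linearly along the horizontal axis within the responsive blob.
    """

    cutoff_cpd: float = 0.39
    amplitude: float = 2e-3
    noise_sd: float = 2e-3
    drift_amplitude: float = 1e-3
    drift_period_s: float = 137.0
    blob_center: tuple[float, float] = (0.5, 0.5)   # fractional image coords
    blob_sigma: float = 0.22                        # fraction of image size
    phase_span: float = 1.5 * math.pi               # retinotopy across blob
    baseline: float = 1.0

    def sf_response(self, sf: float) -> float:
        """Fractional reflectance decrease evoked by a grating of this SF."""
        if sf <= 0:
            raise ValueError("spatial frequency must be positive")
        return self.amplitude * max(0.0, 1.0 - sf / self.cutoff_cpd)


_TRUTH_PRESETS = {
    "trained": 0.39,            # NSFT group cut-off
    "untrained": 0.27,          # control group cut-off
    "naive": 0.27,
}


def cortex_truth(profile: str, **overrides) -> CortexTruth:
    """Preset ground truths for trained / untrained (control) cortices."""
    try:
        cutoff = _TRUTH_PRESETS[profile]
    except KeyError:
        raise ValueError(f"unknown cortex profile {profile!r}; available: "
                         f"{', '.join(sorted(_TRUTH_PRESETS))}") from None
    return CortexTruth(cutoff_cpd=cutoff, **overrides)


def _blob(shape: tuple[int, int], truth: CortexTruth) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = truth.blob_center[0] * h, truth.blob_center[1] * w
    s = truth.blob_sigma * max(h, w)
    return np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s)))


def _hemo(t_post_onset: np.ndarray) -> np.ndarray:
    """Normalized hemodynamic time course: ramps over 2 s, plateaus at 1
    through 6 s post-onset (the analysis window), then decays."""
    h = np.clip(t_post_onset / 2.0, 0.0, 1.0)
    h = np.where(t_post_onset > 6.0,
                 np.exp(-(t_post_onset - 6.0) / 2.0), h)
    return np.where(t_post_onset < 0, 0.0, h)


def synth_cortex(truth: CortexTruth, schedule: StimulusSchedule,
                 rng: np.random.Generator, shape: tuple[int, int] = (64, 64),
                 frame_rate: float = DEFAULT_FRAME_RATE) -> FrameStack:
    """Render a synthetic reflectance movie under the given schedule."""
    dt = 1.0 / frame_rate
    blob = _blob(shape, truth)
    if schedule.mode == "periodic":
        n = int(round(schedule.duration_s * frame_rate))
        t = (np.arange(n) + 0.5) * dt
        _, w = shape
        phase = (np.arange(w) / max(w - 1, 1) - 0.5) * truth.phase_span
        carrier = np.cos(2 * math.pi * schedule.frequency_hz * t[:, None, None]
                         - phase[None, None, :])
        signal = truth.amplitude * blob[None, :, :] * carrier
        frames = truth.baseline * (1.0 + signal)
    else:
        per_trial = int(round(schedule.trial_s * frame_rate))
        n = per_trial * schedule.n_trials
        t = (np.arange(n) + 0.5) * dt
        t_in_trial = t % schedule.trial_s
        r = truth.sf_response(schedule.sf_cpd if schedule.sf_cpd else 1e9)
        h = _hemo(t_in_trial - schedule.baseline_s)
        frames = truth.baseline * (
            1.0 - r * h[:, None, None] * blob[None, :, :])
    drift = truth.drift_amplitude * np.sin(
        2 * math.pi * t / truth.drift_period_s
        + rng.uniform(0, 2 * math.pi))
    frames = frames + drift[:, None, None]
    if truth.noise_sd > 0:
        frames = frames + rng.normal(0.0, truth.noise_sd, size=frames.shape)
    return FrameStack(frames=frames.astype(np.float32),
                      frame_interval_s=dt, schedule=schedule)


# ---------------------------------------------------------------------------
# Fourier retinotopy

def fourier_map(stack: FrameStack, f_stim: float) -> RetinotopyMap:
    """Per-pixel complex amplitude at the stimulus frequency.

    A pure cosine of amplitude A and phase phi returns magnitude A and
    phase phi.  The frequency must be resolvable: positive and at or below
    the Nyquist frequency of the acquisition.
    """
    if f_stim <= 0:
        raise ValueError("stimulus frequency must be positive")
    nyquist = stack.frame_rate / 2.0
    if f_stim > nyquist:
        raise ValueError(f"{f_stim} Hz above Nyquist ({nyquist} Hz)")
    x = stack.frames.astype(np.float64)
    x = x - x.mean(axis=0, keepdims=True)
    n = x.shape[0]
    t = stack.times
    basis = np.exp(-2j * math.pi * f_stim * t)
    coef = np.tensordot(basis, x, axes=(0, 0)) * (2.0 / n)
    return RetinotopyMap(magnitude=np.abs(coef), phase=np.angle(coef))


def map_scatter(rmap: RetinotopyMap, magnitude_threshold: float,
                radius: int = 3) -> float:
    """Phase scatter of a retinotopic map: mean absolute circular deviation
    of each suprathreshold pixel's phase from the local (disk) mean phase.
    Lower is cleaner; a perfectly smooth gradient scores near zero."""
    mask = rmap.magnitude > magnitude_threshold
    if not mask.any():
        raise ValueError("no pixels above the magnitude threshold")
    unit = np.exp(1j * rmap.phase) * mask
    kernel = disk(radius).astype(float)
    num = ndimage.convolve(unit.real, kernel, mode="constant") \
        + 1j * ndimage.convolve(unit.imag, kernel, mode="constant")
    cnt = ndimage.convolve(mask.astype(float), kernel, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        local = np.angle(num / np.maximum(cnt, 1e-12))
    diff = np.angle(np.exp(1j * (rmap.phase - local)))
    return float(np.mean(np.abs(diff[mask])))


# ---------------------------------------------------------------------------
# single-condition maps

def _window_slices(stack: FrameStack) -> tuple[np.ndarray, np.ndarray, int]:
    sched = stack.schedule
    if sched.mode != "episodic":
        raise ValueError("single-condition analysis needs an episodic schedule")
    fr = stack.frame_rate
    per_trial = int(round(sched.trial_s * fr))
    if stack.frames.shape[0] < per_trial * sched.n_trials:
        raise ValueError("stack shorter than the scheduled trials")
    t_in = (np.arange(per_trial) + 0.5) / fr
    base_idx = np.nonzero(t_in < sched.baseline_s)[0]
    lo, hi = sched.window_s
    win_idx = np.nonzero((t_in >= sched.baseline_s + lo)
                         & (t_in < sched.baseline_s + hi))[0]
    if base_idx.size == 0 or win_idx.size == 0:
        raise ValueError("baseline or analysis window contains no frames")
    return base_idx, win_idx, per_trial


def trial_maps(stack: FrameStack) -> np.ndarray:
    """Per-trial delta-R/R maps: (window mean - blank) / blank, pixelwise."""
    base_idx, win_idx, per_trial = _window_slices(stack)
    sched = stack.schedule
    x = stack.frames[:per_trial * sched.n_trials].astype(np.float64)
    x = x.reshape(sched.n_trials, per_trial, *x.shape[1:])
    blank = x[:, base_idx].mean(axis=1)
    if np.any(blank == 0):
        raise ValueError("division by zero baseline")
    resp = x[:, win_idx].mean(axis=1)
    return (resp - blank) / blank


def condition_map(stack: FrameStack,
                  schedule: StimulusSchedule | None = None) -> ConditionMap:
    """Trial-averaged single-condition delta-R/R map (unsmoothed)."""
    if schedule is not None:
        stack = replace_schedule(stack, schedule)
    maps = trial_maps(stack)
    return ConditionMap(data=maps.mean(axis=0),
                        sf_cpd=stack.schedule.sf_cpd,
                        pixel_size_um=stack.pixel_size_um)


def replace_schedule(stack: FrameStack, schedule: StimulusSchedule) -> FrameStack:
    return FrameStack(frames=stack.frames,
                      frame_interval_s=stack.frame_interval_s,
                      pixel_size_um=stack.pixel_size_um, schedule=schedule)


def smooth_map(cmap: ConditionMap, radius_px: int = 3) -> ConditionMap:
    """Circular averaging filter (default 3 px = 51 um radius).

    Border pixels average over the partial disk that remains inside the
    image (renormalised kernel), so a constant map is exactly preserved.
    """
    if radius_px < 1:
        raise ValueError("radius must be >= 1 pixel")
    kernel = disk(radius_px).astype(float)
    num = ndimage.convolve(cmap.data.astype(np.float64), kernel,
                           mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(cmap.data, dtype=np.float64), kernel,
                           mode="constant", cval=0.0)
    return ConditionMap(data=num / den, sf_cpd=cmap.sf_cpd, smoothed=True,
                        pixel_size_um=cmap.pixel_size_um)


def default_roi(reference: ConditionMap, quantile: float = 0.9) -> np.ndarray:
    """ROI: pixels in the top decile of response magnitude of a reference
    (lowest-SF) condition map."""
    resp = -reference.data          # reflectance decrease -> positive
    thr = np.quantile(resp, quantile)
    mask = resp >= thr
    if not mask.any():
        raise ValueError("empty ROI")
    return mask


def roi_tuning(maps: Sequence[tuple[float, ConditionMap]],
               roi: np.ndarray) -> list[tuple[float, float]]:
    """Mean response magnitude in the ROI per SF condition.

    Responses are reported positive (reflectance decreases negated).
    """
    if not np.asarray(roi).any():
        raise ValueError("empty ROI")
    out = []
    for sf, cmap in maps:
        if roi.shape != cmap.data.shape:
            raise ValueError("ROI shape does not match the map")
        out.append((float(sf), float(-cmap.data[roi].mean())))
    return sorted(out)


def cutoff_sf(tuning: Sequence[tuple[float, float]],
              noise_floor: float | None = None) -> CutoffFit:
    """Cut-off SF: zero crossing of an ordinary least-squares line through
    the (SF, response) points.

    With a ``noise_floor``, only conditions whose response exceeds it plus
    the first subthreshold condition enter the fit, mirroring a
    zero-crossing extrapolation of the declining limb; without one all
    points are fit.  A non-declining fit raises; a crossing far beyond the
    tested range is flagged invalid.
    """
    pts = sorted((float(s), float(r)) for s, r in tuning)
    if len(pts) < 3:
        raise ValueError("need at least 3 (SF, response) points")
    sfs = np.array([p[0] for p in pts])
    resp = np.array([p[1] for p in pts])
    mask = np.ones(sfs.size, dtype=bool)
    if noise_floor is not None:
        above = resp > noise_floor
        mask = above.copy()
        below = np.nonzero(~above)[0]
        if below.size:
            mask[below[0]] = True       # first subthreshold condition
        if mask.sum() < 3:
            mask = np.ones(sfs.size, dtype=bool)
    fit = linregress(sfs[mask], resp[mask])
    if fit.slope >= 0:
        raise ValueError("no declining tuning; cutoff undefined")
    cutoff = -fit.intercept / fit.slope
    valid = sfs.min() < cutoff <= 2 * sfs.max()
    return CutoffFit(sfs=sfs, responses=resp, slope=float(fit.slope),
                     intercept=float(fit.intercept), cutoff=float(cutoff),
                     valid=bool(valid), fitted_mask=mask)


# ---------------------------------------------------------------------------
# pipeline

def analyze_sf_series(stacks: Iterable[FrameStack],
                      roi: np.ndarray | str = "auto",
                      smooth_radius_px: int = 3) -> dict:
    """Full single-condition pipeline over a series of SF conditions.

    For each stack: per-trial delta-R/R maps, trial average, smoothing.
    The ROI is the top decile of the lowest-SF condition unless given.  The
    noise floor for the cut-off fit is twice the median across conditions
    of the SEM of per-trial ROI responses.

    Returns a dict with the tuning curve, the CutoffFit, the ROI mask and
    the smoothed condition maps.
    """
    per_sf: list[tuple[float, ConditionMap, np.ndarray]] = []
    for stack in stacks:
        sf = stack.schedule.sf_cpd
        if sf is None:
            raise ValueError("each stack needs schedule.sf_cpd set")
        tm = trial_maps(stack)
        cm = smooth_map(ConditionMap(tm.mean(axis=0), sf_cpd=sf,
                                     pixel_size_um=stack.pixel_size_um),
                        smooth_radius_px)
        per_sf.append((float(sf), cm, tm))
    if not per_sf:
        raise ValueError("no stacks to analyze")
    per_sf.sort(key=lambda x: x[0])
    if isinstance(roi, str):
        roi_mask = default_roi(per_sf[0][1])
    else:
        roi_mask = np.asarray(roi, dtype=bool)
    tuning = roi_tuning([(sf, cm) for sf, cm, _ in per_sf], roi_mask)
    sems = []
    for sf, _, tm in per_sf:
        trial_resp = -tm[:, roi_mask].mean(axis=1)
        sems.append(trial_resp.std(ddof=1) / math.sqrt(trial_resp.shape[0]))
    floor = 2.0 * float(np.median(sems))
    fit = cutoff_sf(tuning, noise_floor=floor)
    return {"tuning": tuning, "fit": fit, "roi": roi_mask,
            "noise_floor": floor,
            "maps": [(sf, cm) for sf, cm, _ in per_sf]}


def simulate_cutoff_animal(truth: CortexTruth, rng: np.random.Generator,
                           sfs: Sequence[float] = DEFAULT_SF_CONDITIONS,
                           shape: tuple[int, int] = (64, 64),
                           n_trials: int = 32,
                           frame_rate: float = DEFAULT_FRAME_RATE) -> dict:
    """Synthesise one animal's SF series and run the full analysis.

    Conditions are generated and analysed one at a time to bound memory.
    """
    def gen():
        for sf in sfs:
            sched = StimulusSchedule(mode="episodic", sf_cpd=float(sf),
                                     n_trials=n_trials)
            yield synth_cortex(truth, sched, rng, shape=shape,
                               frame_rate=frame_rate)
    return analyze_sf_series(gen())


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF + JSON sidecar

def save_stack(stack: FrameStack, path) -> None:
    """Write frames as a multi-page TIFF with a JSON metadata sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    meta = {
        "frame_interval_s": stack.frame_interval_s,
        "pixel_size_um": stack.pixel_size_um,
        "schedule": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in vars(stack.schedule).items()},
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_stack(path) -> FrameStack:
    import tifffile

    path = Path(path)
    frames = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    sched_kwargs = dict(meta["schedule"])
    if "window_s" in sched_kwargs:
        sched_kwargs["window_s"] = tuple(sched_kwargs["window_s"])
    return FrameStack(frames=np.asarray(frames, dtype=np.float32),
                      frame_interval_s=float(meta["frame_interval_s"]),
                      pixel_size_um=float(meta["pixel_size_um"]),
                      schedule=StimulusSchedule(**sched_kwargs))
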
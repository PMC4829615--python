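"""Synthetic resting-state cohort generator with planted networks.

The generator emulates a four-group cross-sectional cohort (young
healthy, old healthy, stroke within 7 days, stroke at 1-6 months) of
~10-minute scans at TR = 2.6 s.  Each scan is a linear mixture of five
planted intrinsic connectivity networks — three default-mode
subcomponents (pDMN, aDMN, vDMN) plus primary visual and sensorimotor —
each a fixed non-negative spatial map (sums of Gaussian blobs on a small
grid) multiplied by a band-structured component time course, plus white
voxel noise.

A component time course is the sum of

* random-phase sinusoids at every Fourier frequency inside slow-5
  (0.01-0.027 Hz), jointly scaled so the slow-5 part has standard
  deviation ``slow5_amp``;
* the same construction for slow-4 (0.027-0.073 Hz) with ``slow4_amp``;
* white Gaussian noise with standard deviation ``broadband_amp``.

Group structure is parameterised by *generative slow-5 fALFF targets*:
for each component and group the (slow5, slow4) amplitude pair is solved
so that the analytically expected slow-5 fALFF of the time course equals
a target value, under a constraint on total low-frequency power
(slow5_amp^2 + slow4_amp^2).  The default targets encode the two
qualitative group patterns the analysis layer is meant to recover:

* late-stage stroke vs. old: slow-5 amplitude lowered in all five
  components with slow-4 raised so total LF power is unchanged
  (spectral power reallocation, not loss);
* old vs. young: DMN slow-5 and total LF power lowered (resource
  decline), while the task-positive visual/motor components show the
  inverted pattern — slow-5 raised and slow-4 lowered at constant LF
  power;
* early-stage stroke is spectrally indistinguishable from the old group.

Every stochastic quantity is drawn from one seeded generator, so a fixed
seed fixes every output byte; full ground truth (maps, time courses,
per-subject jittered amplitudes and analytic fALFF targets) is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import hyp1f1

from .bands import Band, BandScheme, make_band_scheme
from .exceptions import ParameterError, ValidationError

__all__ = [
    "PlantedComponent",
    "GroundTruthSpec",
    "CohortScan",
    "GroundTruth",
    "synth_component_timecourse",
    "synth_motion_track",
    "simulate_cohort",
    "default_spec",
    "default_components",
    "expected_band_amplitude_sums",
    "generative_falff",
    "amplitudes_for_falff_target",
]

GROUP_LABELS = ("young", "old", "stroke_early", "stroke_late")
COMPONENT_LABELS = ("pDMN", "aDMN", "vDMN", "visual", "motor")

# Generative slow-5 fALFF targets per component and group.  Old and
# stroke-late values follow the published component fALFF means
# (pDMN 0.383->0.329, aDMN 0.401->0.335, vDMN 0.349->0.305,
# visual 0.429->0.385, motor 0.437->0.376); stroke-early equals old;
# young is old +0.05 in the DMN and old -0.05 in visual/motor.
DEFAULT_FALFF_TARGETS: dict[str, dict[str, float]] = {
    "pDMN": {"young": 0.433, "old": 0.383, "stroke_early": 0.383, "stroke_late": 0.329},
    "aDMN": {"young": 0.451, "old": 0.401, "stroke_early": 0.401, "stroke_late": 0.335},
    "vDMN": {"young": 0.399, "old": 0.349, "stroke_early": 0.349, "stroke_late": 0.305},
    "visual": {"young": 0.379, "old": 0.429, "stroke_early": 0.429, "stroke_late": 0.385},
    "motor": {"young": 0.387, "old": 0.437, "stroke_early": 0.437, "stroke_late": 0.376},
}

# Total low-frequency generative power (slow5_amp^2 + slow4_amp^2), in
# units of broadband noise variance.  Constant across old / stroke-early /
# stroke-late (reallocation, not loss); the young DMN gets 20% more
# (aging depletes DMN resting power) while young visual/motor stay equal.
DEFAULT_LF_POWER = 30.0
DEFAULT_YOUNG_DMN_LF_FACTOR = 1.2

DEFAULT_GROUP_SIZES = {"young": 43, "old": 42, "stroke_early": 14, "stroke_late": 16}

DEFAULT_GRID = (20, 24, 20)

# Blob centres (voxels) on the default grid; pairwise distances keep
# map cross-correlations well below 0.3.
_BLOBS: dict[str, list[tuple[tuple[float, float, float], float]]] = {
    "pDMN": [((10.0, 19.0, 9.0), 2.5), ((10.0, 16.0, 13.0), 2.0)],
    "aDMN": [((10.0, 5.0, 10.0), 2.5)],
    "vDMN": [((14.5, 12.0, 4.0), 2.2), ((5.5, 12.0, 4.0), 2.2)],
    "visual": [((10.0, 21.0, 16.0), 2.3)],
    "motor": [((4.0, 10.0, 16.0), 2.2), ((16.0, 10.0, 16.0), 2.2)],
}


@dataclass(frozen=True)
class PlantedComponent:
    """One synthetic network: a spatial map plus per-group band amplitudes."""

    label: str
    spatial_map: np.ndarray  # non-negative 3D weight field
    band_amplitude_per_group: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        if np.any(self.spatial_map < 0):
            raise ValidationError(f"component {self.label}: spatial map must be >= 0")
        for g, amps in self.band_amplitude_per_group.items():
            if any(a < 0 for a in amps):
                raise ValidationError(f"component {self.label}, group {g}: amplitudes must be >= 0")


@dataclass
class GroundTruthSpec:
    """Full description of a synthetic cohort; the generator's contract."""

    n_subjects_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_volumes: int = 230
    tr_seconds: float = 2.6
    components: Sequence[PlantedComponent] = ()
    noise_sd: float = 1.0
    amp_jitter_sd: float = 0.4  # yields per-subject fALFF SD ~= 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes * self.tr_seconds <= 0:
            raise ParameterError("scan duration must be positive")
        # slow-5 must contain at least 3 Fourier frequencies
        df = 1.0 / (self.n_volumes * self.tr_seconds)
        n_slow5 = np.sum(Band("slow5", 0.01, 0.027).mask(np.arange(1, self.n_volumes // 2 + 1) * df))
        if n_slow5 < 3:
            raise ParameterError(
                f"scan too short: only {n_slow5} Fourier frequencies in slow-5"
            )
        if not self.components:
            self.components = default_components(self.n_volumes, self.tr_seconds)

    @property
    def nyquist(self) -> float:
        return 0.5 / self.tr_seconds

    @property
    def group_labels(self) -> list[str]:
        return list(self.n_subjects_per_group)


@dataclass
class CohortScan:
    """One subject's scan: voxels x time matrix plus acquisition metadata."""

    subject_id: str
    group: str
    data: np.ndarray  # (voxels, time) or 4D (x, y, z, time)
    tr_seconds: float
    motion: np.ndarray | None = None  # (time, 6): x, y, z mm; roll, pitch, yaw deg
    shape3d: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.data.ndim == 4:
            self.shape3d = self.data.shape[:3]
            self.data = self.data.reshape(-1, self.data.shape[-1])
        if np.any(~np.isfinite(self.data)):
            raise ValidationError(f"{self.subject_id}: data contains missing samples")
        if self.motion is not None and self.motion.shape != (self.n_volumes, 6):
            raise ValidationError(
                f"{self.subject_id}: motion track shape {self.motion.shape} "
                f"!= ({self.n_volumes}, 6)"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    def volume(self) -> np.ndarray:
        """Data as a 4D array (requires a known 3D grid)."""
        if self.shape3d is None:
            raise ValidationError(f"{self.subject_id}: no 3D grid recorded")
        return self.data.reshape(*self.shape3d, -1)


@dataclass
class GroundTruth:
    """Everything the generator knew: recovered-vs-planted comparisons key off this."""

    spec: GroundTruthSpec
    maps: dict[str, np.ndarray]  # component -> flattened spatial map
    timecourses: dict[str, dict[str, np.ndarray]]  # subject -> component -> series
    subject_amplitudes: dict[str, dict[str, tuple[float, float, float]]]
    falff_targets: dict[str, dict[str, float]]  # analytic slow-5 fALFF per subject x component
    groups: dict[str, str]

    def to_json_dict(self) -> dict:
        return {
            "group_sizes": dict(self.spec.n_subjects_per_group),
            "n_volumes": self.spec.n_volumes,
            "tr_seconds": self.spec.tr_seconds,
            "noise_sd": self.spec.noise_sd,
            "amp_jitter_sd": self.spec.amp_jitter_sd,
            "seed": self.spec.seed,
            "groups": self.groups,
            "subject_amplitudes": {
                s: {c: list(a) for c, a in comps.items()}
                for s, comps in self.subject_amplitudes.items()
            },
            "falff_targets": self.falff_targets,
        }


# ---------------------------------------------------------------------------
# analytic spectral expectations

def _band_freq_count(band: Band, n_volumes: int, tr: float) -> int:
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    return int(band.mask(freqs[1:]).sum())  # DC excluded


def expected_band_amplitude_sums(
    amps: tuple[float, float, float],
    n_volumes: int,
    tr: float,
    scheme: BandScheme | None = None,
    sigma_bins: float = 2.0,
) -> dict[str, float]:
    """Expected one-sided |FFT| mass per band for a generated time course.

    A sinusoid of amplitude A at an on-grid frequency contributes A*T/2
    to its bin.  White noise of standard deviation sigma contributes a
    complex-Gaussian term of variance sigma^2*T per interior bin; the
    magnitude of sinusoid-plus-noise is Rice distributed, whose mean is
    evaluated via the confluent hypergeometric function.  Because the
    analysis chain smooths spectra before fALFF and smoothing is linear,
    the same Gaussian kernel (``sigma_bins``, reflect boundaries) is
    applied to the expected amplitudes; pass ``sigma_bins=0`` for the
    raw-spectrum expectation.  This is the independent analytic oracle
    for the measured fALFF of generated series.
    """
    slow5_amp, slow4_amp, broadband = amps
    if scheme is None:
        scheme = make_band_scheme(0.5 / tr)
    T = n_volumes
    freqs = np.fft.rfftfreq(T, d=tr)
    per_freq_amp = np.zeros_like(freqs)
    for band_label, amp in (("slow5", slow5_amp), ("slow4", slow4_amp)):
        band = scheme[band_label]
        mask = band.mask(freqs)
        mask[0] = False
        m = int(mask.sum())
        if m and amp > 0:
            a_sin = amp * np.sqrt(2.0 / m)  # per-sinusoid amplitude for band sd = amp
            per_freq_amp[mask] = a_sin * T / 2.0
    # Rice mean: |A + N|, N complex Gaussian with E|N|^2 = sigma^2 * T
    sigma2 = broadband**2 * T / 2.0  # per real/imag component
    if sigma2 > 0:
        s = np.sqrt(sigma2)
        x = -(per_freq_amp**2) / (2.0 * sigma2)
        mean_amp = s * np.sqrt(np.pi / 2.0) * hyp1f1(-0.5, 1.0, x)
    else:
        mean_amp = per_freq_amp.copy()
    mean_amp[0] = 0.0  # series is demeaned
    if sigma_bins > 0:
        from scipy.ndimage import gaussian_filter1d

        mean_amp = gaussian_filter1d(mean_amp, sigma=sigma_bins, mode="reflect")
    return {
        b.label: float(mean_amp[b.mask(freqs)].sum()) for b in scheme.bands
    }


def generative_falff(
    amps: tuple[float, float, float],
    n_volumes: int,
    tr: float,
    numerator: str = "slow5",
    denominator: str = "full",
    scheme: BandScheme | None = None,
    sigma_bins: float = 2.0,
) -> float:
    """Analytically expected band fALFF (smoothed-spectrum convention)."""
    sums = expected_band_amplitude_sums(amps, n_volumes, tr, scheme, sigma_bins)
    return sums[numerator] / sums[denominator]


def amplitudes_for_falff_target(
    target_slow5_falff: float,
    lf_power: float,
    broadband: float,
    n_volumes: int,
    tr: float,
) -> tuple[float, float]:
    """Solve (slow5_amp, slow4_amp) with slow5^2 + slow4^2 = lf_power whose
    analytic slow-5 fALFF equals the target."""

    def f(a5: float) -> float:
        a4 = np.sqrt(max(lf_power - a5**2, 0.0))
        return (
            generative_falff((a5, a4, broadband), n_volumes, tr) - target_slow5_falff
        )

    hi = np.sqrt(lf_power)
    lo_val, hi_val = f(1e-9), f(hi * (1 - 1e-9))
    if lo_val > 0 or hi_val < 0:
        raise ParameterError(
            f"slow-5 fALFF target {target_slow5_falff} unreachable with "
            f"lf_power={lf_power}, broadband={broadband}"
        )
    a5 = brentq(f, 1e-9, hi * (1 - 1e-9), xtol=1e-12)
    a4 = float(np.sqrt(lf_power - a5**2))
    return float(a5), a4


# ---------------------------------------------------------------------------
# component construction

def _gaussian_blob(grid: tuple[int, int, int], center, sigma: float) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*(np.arange(n) for n in grid), indexing="ij")
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


def _spatial_map(label: str, grid: tuple[int, int, int]) -> np.ndarray:
    # blob geometry is defined on the reference grid and scaled with it
    scale = np.array(grid) / np.array(DEFAULT_GRID)
    m = np.zeros(grid)
    for center, sigma in _BLOBS[label]:
        m += _gaussian_blob(grid, np.array(center) * scale, sigma * scale.mean())
    return m


def check_map_correlations(components: Sequence[PlantedComponent], limit: float = 0.3) -> None:
    """Enforce pairwise spatial correlation < limit between planted maps."""
    flat = [c.spatial_map.ravel() for c in components]
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            r = np.corrcoef(flat[i], flat[j])[0, 1]
            if abs(r) >= limit:
                raise ValidationError(
                    f"maps {components[i].label} and {components[j].label} "
                    f"correlate at {r:.3f} >= {limit}"
                )


def default_components(
    n_volumes: int = 230,
    tr: float = 2.6,
    grid: tuple[int, int, int] = DEFAULT_GRID,
    falff_targets: Mapping[str, Mapping[str, float]] | None = None,
    lf_power: float = DEFAULT_LF_POWER,
    young_dmn_lf_factor: float = DEFAULT_YOUNG_DMN_LF_FACTOR,
    broadband: float = 1.0,
) -> list[PlantedComponent]:
    """Build the five standard planted networks with calibrated amplitudes."""
    if falff_targets is None:
        falff_targets = DEFAULT_FALFF_TARGETS
    comps = []
    for label in COMPONENT_LABELS:
        amps: dict[str, tuple[float, float, float]] = {}
        for group, target in falff_targets[label].items():
            p = lf_power
            if group == "young" and label in ("pDMN", "aDMN", "vDMN"):
                p = lf_power * young_dmn_lf_factor
            a5, a4 = amplitudes_for_falff_target(target, p, broadband, n_volumes, tr)
            amps[group] = (a5, a4, broadband)
        comps.append(
            PlantedComponent(
                label=label,
                spatial_map=_spatial_map(label, grid),
                band_amplitude_per_group=amps,
            )
        )
    check_map_correlations(comps)
    return comps


def default_spec(**overrides) -> GroundTruthSpec:
    """The standard study-condition cohort spec; keyword overrides allowed."""
    spec = GroundTruthSpec(**{k: v for k, v in overrides.items() if k != "components"})
    if "components" in overrides:
        spec.components = overrides["components"]
    return spec


# ---------------------------------------------------------------------------
# generators

def synth_component_timecourse(
    amps: tuple[float, float, float],
    n_volumes: int,
    tr: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Band-structured component time course (zero mean).

    Sum of random-phase sinusoids spanning every Fourier frequency inside
    slow-5 (scaled to standard deviation ``amps[0]``), the same for
    slow-4 (``amps[1]``), and white noise of sd ``amps[2]``.  Each
    sinusoid gets its own phase, avoiding phase-locked degeneracy.
    """
    slow5_amp, slow4_amp, broadband = amps
    if any(a < 0 for a in amps):
        raise ParameterError("band amplitudes must be non-negative")
    if n_volumes < 64:
        raise ParameterError("need at least 64 volumes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(n_volumes) * tr
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    series = np.zeros(n_volumes)
    scheme = make_band_scheme(0.5 / tr)
    for band_label, amp in (("slow5", slow5_amp), ("slow4", slow4_amp)):
        mask = scheme[band_label].mask(freqs)
        mask[0] = False
        band_freqs = freqs[mask]
        m = len(band_freqs)
        phases = rng.uniform(0.0, 2.0 * np.pi, m)
        if m == 0 or amp == 0:
            continue
        a_sin = amp * np.sqrt(2.0 / m)
        series += a_sin * np.cos(
            2.0 * np.pi * band_freqs[:, None] * t[None, :] + phases[:, None]
        ).sum(axis=0)
    if broadband > 0:
        series = series + rng.normal(0.0, broadband, n_volumes)
    else:
        rng.normal(0.0, 1.0, n_volumes)  # keep stream alignment across amp choices
    return series - series.mean()


def synth_motion_track(
    n_volumes: int,
    rms_mm: float,
    seed: int | np.random.Generator = 0,
    rotation_radius_mm: float = 50.0,
) -> np.ndarray:
    """Smooth mean-reverting 6-parameter motion track (x,y,z mm; roll,pitch,yaw deg).

    Frame-to-frame increments are drawn i.i.d. per parameter, lightly
    smoothed (3-frame moving average), and accumulated with a weak pull
    back toward the reference position — head motion wanders but stays
    bounded, unlike a pure random walk.  The finished track is rescaled
    so the mean per-frame Euclidean-norm displacement (rotations
    converted to mm on a 50-mm radius) equals ``rms_mm``.
    """
    if rms_mm < 0:
        raise ParameterError("rms_mm must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rms_mm == 0:
        rng.normal(size=(n_volumes - 1, 6))
        return np.zeros((n_volumes, 6))
    steps = rng.normal(size=(n_volumes - 1, 6))
    kernel = np.ones(3) / 3.0
    for j in range(6):
        steps[:, j] = np.convolve(steps[:, j], kernel, mode="same")
    track = np.zeros((n_volumes, 6))
    reversion = 0.9  # pull toward the reference position each frame
    for t in range(1, n_volumes):
        track[t] = reversion * track[t - 1] + steps[t - 1]
    enorm = np.sqrt((np.diff(track, axis=0) ** 2).sum(axis=1))
    track *= rms_mm / enorm.mean()
    # express rotational columns in degrees
    deg_per_mm = 180.0 / (np.pi * rotation_radius_mm)
    track[:, 3:] *= deg_per_mm
    return track


def simulate_cohort(
    gt: GroundTruthSpec, make_volumes: bool = True, motion_rms_mm: float = 0.15
) -> tuple[list[CohortScan], GroundTruth]:
    """Generate the cohort: scans (maps x time courses + voxel noise) + truth.

    ``make_volumes=False`` skips spatial mixing and voxel noise, returning
    scans whose data rows are the planted component time courses
    themselves — useful when only the spectral/statistical chain is under
    study.
    """
    check_map_correlations(list(gt.components))
    rng = np.random.default_rng(gt.seed)
    scans: list[CohortScan] = []
    maps = {c.label: c.spatial_map.ravel() for c in gt.components}
    grid = gt.components[0].spatial_map.shape if gt.components else None
    timecourses: dict[str, dict[str, np.ndarray]] = {}
    subject_amps: dict[str, dict[str, tuple[float, float, float]]] = {}
    falff_targets: dict[str, dict[str, float]] = {}
    groups: dict[str, str] = {}
    for group, n_subj in gt.n_subjects_per_group.items():
        for i in range(n_subj):
            sid = f"{group}_{i:03d}"
            groups[sid] = group
            tcs: dict[str, np.ndarray] = {}
            amps_here: dict[str, tuple[float, float, float]] = {}
            targets_here: dict[str, float] = {}
            for comp in gt.components:
                a5, a4, bb = comp.band_amplitude_per_group[group]
                # per-subject multiplicative amplitude jitter (between-
                # subject variability of band power)
                j5 = max(1.0 + rng.normal(0.0, gt.amp_jitter_sd), 0.05)
                j4 = max(1.0 + rng.normal(0.0, gt.amp_jitter_sd), 0.05)
                amps = (a5 * j5, a4 * j4, bb)
                amps_here[comp.label] = amps
                tcs[comp.label] = synth_component_timecourse(
                    amps, gt.n_volumes, gt.tr_seconds, rng
                )
                targets_here[comp.label] = generative_falff(
                    amps, gt.n_volumes, gt.tr_seconds
                )
            timecourses[sid] = tcs
            subject_amps[sid] = amps_here
            falff_targets[sid] = targets_here
            motion = synth_motion_track(gt.n_volumes, motion_rms_mm, rng)
            if make_volumes:
                data = np.zeros((len(maps[next(iter(maps))]), gt.n_volumes))
                for comp in gt.components:
                    data += np.outer(maps[comp.label], tcs[comp.label])
                data += rng.normal(0.0, gt.noise_sd, data.shape)
            else:
                data = np.vstack([tcs[c.label] for c in gt.components])
            scans.append(
                CohortScan(
                    subject_id=sid,
                    group=group,
                    data=data,
                    tr_seconds=gt.tr_seconds,
                    motion=motion,
                    shape3d=grid if make_volumes else None,
                )
            )
    truth = GroundTruth(
        spec=gt,
        maps=maps,
        timecourses=timecourses,
        subject_amplitudes=subject_amps,
        falff_targets=falff_targets,
        groups=groups,
    )
    return scans, truth
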
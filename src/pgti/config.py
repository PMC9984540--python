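"""Experiment configuration: accelerator, beam delivery, geometry, detectors.

A full :class:`ExperimentConfig` describes one irradiation campaign — the
accelerator time structure, the slab phantom along the beam axis, the beam
monitor and the prompt-gamma detector modules — plus the analysis settings
(binning, windows, bootstrap spec).  Configurations round-trip through YAML,
and two bundled presets describe the experimental setups the synthetic data
generator emulates: a 63 MeV cyclotron beam on a thin+thick PMMA target pair
(``medicyc_63mev``) and a 148 MeV synchro-cyclotron beam on PMMA targets
viewed by detectors at two angles (``s2c2_148mev``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .errors import ConfigurationError
from .physics import RangeEnergyModel, Slab


@dataclass
class AcceleratorStructure:
    """Periodic beam micro/macro time structure.

    bunch_period/bunch_width in ns; optional pulse macro-structure
    (synchro-cyclotron) in us / ms.
    """

    bunch_period_ns: float
    bunch_width_ns: float
    pulse_width_us: float | None = None
    pulse_period_ms: float | None = None

    def __post_init__(self):
        if self.bunch_width_ns > self.bunch_period_ns:
            raise ConfigurationError(
                "accelerator.bunch_width_ns exceeds bunch_period_ns")
        if (self.pulse_width_us is None) != (self.pulse_period_ms is None):
            raise ConfigurationError(
                "accelerator pulse_width_us and pulse_period_ms must be set together")
        if self.pulse_width_us is not None and \
                self.pulse_width_us * 1e-3 > self.pulse_period_ms:
            raise ConfigurationError(
                "accelerator.pulse_width_us exceeds pulse_period_ms")

    @property
    def bunch_rate_hz(self):
        """Raw micro-bunch repetition rate."""
        return 1e9 / self.bunch_period_ns

    @property
    def duty_cycle(self):
        """Fraction of wall-clock time with beam (1.0 for a CW cyclotron)."""
        if self.pulse_width_us is None:
            return 1.0
        return (self.pulse_width_us * 1e-6) / (self.pulse_period_ms * 1e-3)

    @property
    def effective_bunch_rate_hz(self):
        """Duty-cycle-weighted bunch rate (bunches per wall-clock second)."""
        return self.bunch_rate_hz * self.duty_cycle

    @property
    def bunch_sigma_ns(self):
        """Standard deviation of a uniform bunch of the configured width."""
        return self.bunch_width_ns / math.sqrt(12.0)


@dataclass
class BeamDelivery:
    """Mean bunch occupancy seen by the monitor and its beam coverage."""

    mean_protons_per_bunch: float  # Poisson lambda at the monitor
    monitor_coverage: float = 1.0  # fraction of the beam the monitor sees

    def __post_init__(self):
        if self.mean_protons_per_bunch < 0:
            raise ConfigurationError("delivery.mean_protons_per_bunch must be >= 0")
        if not 0 < self.monitor_coverage <= 1:
            raise ConfigurationError("delivery.monitor_coverage must be in (0, 1]")


@dataclass
class EfficiencyCurve:
    """Sigmoid + linear intrinsic detection efficiency versus gamma energy.

    p(E) = amplitude / (1 + exp(-(E - center)/width)) + slope * E, clipped to
    [0, 1] and forced to 0 below ``min_energy`` (no detectable interaction).
    """

    amplitude: float
    center: float  # MeV
    width: float   # MeV
    slope: float   # 1/MeV
    min_energy: float = 0.1  # MeV

    @classmethod
    def from_anchor(cls, anchor_energy, anchor_prob, center, width, slope,
                    min_energy=0.1):
        """Fix the sigmoid amplitude so the curve passes through an anchor."""
        sig = 1.0 / (1.0 + math.exp(-(anchor_energy - center) / width))
        amplitude = (anchor_prob - slope * anchor_energy) / sig
        return cls(amplitude, center, width, slope, min_energy)

    def __call__(self, energy):
        e = np.asarray(energy, dtype=float)
        sig = 1.0 / (1.0 + np.exp(-(e - self.center) / self.width))
        p = self.amplitude * sig + self.slope * e
        p = np.clip(p, 0.0, 1.0)
        p = np.where(e < self.min_energy, 0.0, p)
        return float(p) if np.isscalar(energy) else p


def default_efficiency_curves():
    """Per-threshold efficiency curves for a ~1 cm^3 Cherenkov module.

    The 6 p.e. curve is anchored at 5% efficiency for 2 MeV gammas; the 3 and
    9 p.e. curves bracket it (lower thresholds are uniformly more efficient).
    """
    return {
        3: EfficiencyCurve(amplitude=0.35, center=3.0, width=1.2, slope=0.005),
        6: EfficiencyCurve.from_anchor(2.0, 0.05, center=4.0, width=1.2,
                                       slope=0.004),
        9: EfficiencyCurve(amplitude=0.18, center=5.0, width=1.2, slope=0.003),
    }


@dataclass
class DetectorModule:
    """One prompt-gamma detection module.

    The position is specified as an angle from the beam direction plus a
    distance from a named anchor (target entrance or Bragg-peak depth) and
    resolved to a 3-vector once the geometry is known.
    """

    id: str
    angle_deg: float
    distance_cm: float
    anchor: str = "bragg_peak"  # or "entrance"
    face_area_cm2: float = 1.0
    time_resolution_fwhm_ps: float = 276.0
    threshold_pe: int = 6
    dark_count_rate_hz: float = 302.0
    efficiency: dict = field(default_factory=default_efficiency_curves)

    def __post_init__(self):
        if self.time_resolution_fwhm_ps <= 0:
            raise ConfigurationError(
                f"detector {self.id!r}: time_resolution_fwhm_ps must be > 0")
        if self.threshold_pe < 0:
            raise ConfigurationError(
                f"detector {self.id!r}: threshold_pe must be >= 0")
        if self.anchor not in ("entrance", "bragg_peak"):
            raise ConfigurationError(
                f"detector {self.id!r}: anchor must be 'entrance' or 'bragg_peak'")

    def position(self, bragg_peak_x):
        """Resolve to a 3-vector in cm (beam along +x, detector in the xy plane)."""
        x0 = 0.0 if self.anchor == "entrance" else bragg_peak_x
        th = math.radians(self.angle_deg)
        return np.array([x0 + self.distance_cm * math.cos(th),
                         self.distance_cm * math.sin(th),
                         0.0])

    def detection_probability(self, energy, threshold_pe=None):
        """Intrinsic detection probability at the (default: own) threshold."""
        th = self.threshold_pe if threshold_pe is None else threshold_pe
        curve = self.efficiency.get(th)
        if curve is None:
            raise ConfigurationError(
                f"detector {self.id!r}: no efficiency curve for threshold "
                f"{th} p.e.")
        return curve(energy)


@dataclass
class BeamMonitor:
    """Diamond-based beam monitor providing the proton time tag."""

    time_resolution_fwhm_ps: float = 156.0

    def __post_init__(self):
        if self.time_resolution_fwhm_ps <= 0:
            raise ConfigurationError("monitor.time_resolution_fwhm_ps must be > 0")


@dataclass
class EmissionModel:
    """Parametric prompt-gamma emission model (spectrum + depth profile).

    The energy spectrum is a mixture of a decaying continuum on
    [continuum_lo, continuum_hi] MeV and discrete de-excitation lines
    (4.44 MeV from carbon, 6.13 MeV from oxygen by default).  The depth
    profile is a plateau with a linear distal ramp of ``falloff_ramp_cm``
    ending where the proton energy drops below ``production_threshold_mev``.
    """

    continuum_lo: float = 2.0
    continuum_hi: float = 7.0
    continuum_decay_mev: float = 2.0
    continuum_weight: float = 0.60
    line_energies: tuple = (4.44, 6.13)
    line_weights: tuple = (0.25, 0.15)
    production_threshold_mev: float = 2.5
    falloff_ramp_cm: float = 0.3
    plateau_rise: float = 0.3  # fractional rise of the plateau toward the Bragg peak

    def __post_init__(self):
        w = self.continuum_weight + sum(self.line_weights)
        if not math.isclose(w, 1.0, rel_tol=1e-9):
            raise ConfigurationError(
                f"emission mixture weights must sum to 1, got {w}")


@dataclass
class BackgroundModel:
    """Parameters for the three synthetic background classes."""

    coincidence_window_ns: float = 20.0      # 2*tau of the DAQ coincidence
    random_coincidence_rate_hz: float = 0.0  # bunch-correlated untagged-proton rate
    bunch_sigma_ns: float | None = None      # override of the accelerator bunch sigma
    scatter_bump: bool = False               # monitor->module scattered protons
    scatter_rate_hz: float = 0.0
    scatter_sigma_ps: float = 150.0


@dataclass
class BootstrapSpec:
    """Subsample sizes and toy counts for the fall-off error extrapolation."""

    n_toys: int = 5000
    subsample_sizes: tuple = tuple(range(30, 136, 15))
    target_n: int = 600

    def __post_init__(self):
        if self.n_toys < 100:
            raise ConfigurationError("bootstrap.n_toys must be >= 100")
        if len(self.subsample_sizes) == 0:
            raise ConfigurationError("bootstrap.subsample_sizes must be non-empty")


@dataclass
class AnalysisSettings:
    """Histogram binning, analysis windows and the bootstrap spec."""

    time_bin_ps: float = 50.0
    space_bin_cm: float = 0.5
    tof_window_ps: tuple | None = None       # auto from geometry if None
    off_signal_fraction: float = 0.2         # trailing fraction used as off-window
    bootstrap: BootstrapSpec = field(default_factory=BootstrapSpec)


@dataclass
class ExperimentConfig:
    """Complete description of one (synthetic) experiment."""

    name: str
    beam_energy_mev: float
    accelerator: AcceleratorStructure
    delivery: BeamDelivery
    slabs: list                       # list of Slab
    gap_index: int | None             # index of the air gap widened by a range shift
    monitor: BeamMonitor
    detectors: list                   # list of DetectorModule
    emission: EmissionModel = field(default_factory=EmissionModel)
    backgrounds: BackgroundModel = field(default_factory=BackgroundModel)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    range_model: RangeEnergyModel = field(
        default_factory=RangeEnergyModel.calibrated)
    seed: int = 0

    def __post_init__(self):
        if not self.detectors:
            raise ConfigurationError("at least one detector module is required")
        if self.gap_index is not None:
            if not 0 <= self.gap_index < len(self.slabs):
                raise ConfigurationError("geometry.gap_index out of range")
            if not self.range_model.material(
                    self.slabs[self.gap_index].material).lossless:
                raise ConfigurationError(
                    "geometry.gap_index must point at an air (lossless) slab")
        for slab in self.slabs:
            self.range_model.material(slab.material)  # raises if undefined
        ids = [d.id for d in self.detectors]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("detector ids must be unique")

    def shifted(self, shift_cm):
        """Copy of this config with the air gap widened by ``shift_cm``."""
        if shift_cm == 0:
            return self
        if self.gap_index is None:
            raise ConfigurationError(
                "this geometry has no air gap to shift (gap_index unset)")
        slabs = list(self.slabs)
        g = slabs[self.gap_index]
        slabs[self.gap_index] = Slab(g.material, g.thickness + shift_cm)
        return dataclasses.replace(self, slabs=slabs)

    def config_hash(self):
        """Stable hash of the physical configuration, for run manifests."""
        payload = json.dumps(_to_plain(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _require(mapping, key, context):
    try:
        return mapping[key]
    except (KeyError, TypeError):
        raise ConfigurationError(
            f"missing required config field {context}.{key}") from None


def config_from_dict(raw):
    """Build a validated ExperimentConfig from a plain nested mapping."""
    acc_raw = _require(raw, "accelerator", "config")
    accelerator = AcceleratorStructure(
        bunch_period_ns=_require(acc_raw, "bunch_period_ns", "accelerator"),
        bunch_width_ns=_require(acc_raw, "bunch_width_ns", "accelerator"),
        pulse_width_us=acc_raw.get("pulse_width_us"),
        pulse_period_ms=acc_raw.get("pulse_period_ms"),
    )
    dl_raw = _require(raw, "delivery", "config")
    delivery = BeamDelivery(
        mean_protons_per_bunch=_require(dl_raw, "mean_protons_per_bunch",
                                        "delivery"),
        monitor_coverage=dl_raw.get("monitor_coverage", 1.0),
    )
    rm_raw = raw.get("range_model", {})
    range_model = RangeEnergyModel.calibrated(
        anchor_energy=rm_raw.get("anchor_energy_mev", 148.0),
        anchor_range=rm_raw.get("anchor_range_cm", 13.4),
        alpha=rm_raw.get("alpha", 0.0022),
        p=rm_raw.get("p", 1.77),
        pmma_density=rm_raw.get("pmma_density", 1.19),
    )
    geo_raw = _require(raw, "geometry", "config")
    slabs = [Slab(_require(s, "material", "geometry.slabs"),
                  _require(s, "thickness_cm", "geometry.slabs"))
             for s in _require(geo_raw, "slabs", "geometry")]
    detectors = []
    for d in _require(raw, "detectors", "config"):
        kwargs = dict(
            id=str(_require(d, "id", "detectors")),
            angle_deg=_require(d, "angle_deg", "detectors"),
            distance_cm=_require(d, "distance_cm", "detectors"),
            anchor=d.get("anchor", "bragg_peak"),
            face_area_cm2=d.get("face_area_cm2", 1.0),
            time_resolution_fwhm_ps=d.get("time_resolution_fwhm_ps", 276.0),
            threshold_pe=d.get("threshold_pe", 6),
            dark_count_rate_hz=d.get("dark_count_rate_hz", 302.0),
        )
        detectors.append(DetectorModule(**kwargs))
    mon_raw = raw.get("monitor", {})
    monitor = BeamMonitor(
        time_resolution_fwhm_ps=mon_raw.get("time_resolution_fwhm_ps", 156.0))
    em_raw = raw.get("emission", {})
    emission = EmissionModel(**em_raw) if em_raw else EmissionModel()
    bg_raw = raw.get("backgrounds", {})
    backgrounds = BackgroundModel(**bg_raw) if bg_raw else BackgroundModel()
    an_raw = raw.get("analysis", {})
    bs_raw = an_raw.get("bootstrap", {})
    bootstrap = BootstrapSpec(
        n_toys=bs_raw.get("n_toys", 5000),
        subsample_sizes=tuple(bs_raw.get("subsample_sizes",
                                         list(range(30, 136, 15)))),
        target_n=bs_raw.get("target_n", 600),
    )
    analysis = AnalysisSettings(
        time_bin_ps=an_raw.get("time_bin_ps", 50.0),
        space_bin_cm=an_raw.get("space_bin_cm", 0.5),
        tof_window_ps=(tuple(an_raw["tof_window_ps"])
                       if an_raw.get("tof_window_ps") else None),
        off_signal_fraction=an_raw.get("off_signal_fraction", 0.2),
        bootstrap=bootstrap,
    )
    return ExperimentConfig(
        name=_require(raw, "name", "config"),
        beam_energy_mev=_require(raw, "beam_energy_mev", "config"),
        accelerator=accelerator,
        delivery=delivery,
        slabs=slabs,
        gap_index=geo_raw.get("gap_index"),
        monitor=monitor,
        detectors=detectors,
        emission=emission,
        backgrounds=backgrounds,
        analysis=analysis,
        range_model=range_model,
        seed=raw.get("seed", 0),
    )


def load_config(path):
    """Load and validate an ExperimentConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} did not parse to a mapping")
    return config_from_dict(raw)


def load_preset(name):
    """Load one of the bundled presets: 'medicyc_63mev' or 's2c2_148mev'."""
    ref = resources.files("pgti").joinpath(f"presets/{name}.yaml")
    try:
        raw = yaml.safe_load(ref.read_text())
    except FileNotFoundError:
        raise ConfigurationError(f"unknown preset {name!r}") from None
    return config_from_dict(raw)
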
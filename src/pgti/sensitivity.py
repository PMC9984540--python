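"""Bootstrap fall-off uncertainty, counting-statistics formulas and the
end-to-end range-shift sensitivity scan.

The statistical error on the fall-off shift at a given PG statistics N is
estimated by subsampling: many small toy profiles are drawn without
replacement from the measured event sample, the shift statistic is computed
for each, and the spread sigma(N) over toys is fitted with the k/sqrt(N)
law and extrapolated to the full sample size.  Subsample sizes are kept
well below the sample size to limit the statistical dependency between
toys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import BootstrapSpec
from .physics import inverse_speed, proton_time_map
from .profiles import Histogram1D, ShiftResult, distal_maximum, falloff_shift
from .reconstruction import build_reference_map, reconstruct_dataset
from .synthetic import _auto_tof_window, generate_dataset, pg_emission_profile


# ---------------------------------------------------------------------------
# counting-statistics formulas

def poisson_lambda(count_zero, count_one):
    """Mean bunch occupancy from empty/single-proton bunch counts.

    For Poisson-delivered bunches P(1)/P(0) = lambda, so the ratio of the
    observed counts estimates the mean protons per bunch.
    """
    if count_zero <= 0:
        raise ValueError("lambda estimate undefined without empty bunches")
    return count_one / count_zero


def random_coincidence_rate(f_dia_hz, dcr_sipm_hz, window_2tau_s):
    """Random-coincidence rate f_dia x DCR_SiPM x 2tau (Hz)."""
    if min(f_dia_hz, dcr_sipm_hz, window_2tau_s) < 0:
        raise ValueError("rate factors must be non-negative")
    return f_dia_hz * dcr_sipm_hz * window_2tau_s


def spr_delivery_time(n_protons, bunch_rate_hz, lam):
    """Wall-clock time to deliver n protons in single-proton regime.

    Protons are only usable when their bunch is non-empty and taggable, so
    the effective delivery rate is bunch_rate x P(occupied) = rate(1-e^-lam).
    For a pulsed machine pass the duty-cycle-weighted bunch rate.
    """
    if bunch_rate_hz <= 0 or lam <= 0:
        raise ValueError("bunch rate and lambda must be positive")
    return n_protons / (bunch_rate_hz * (1.0 - math.exp(-lam)))


def quadratic_difference(total_fwhm, component_fwhm):
    """Quadrature decomposition sqrt(total^2 - component^2) of a resolution."""
    if not total_fwhm > component_fwhm >= 0:
        raise ValueError("need total > component >= 0 for a real remainder")
    return math.sqrt(total_fwhm ** 2 - component_fwhm ** 2)


# ---------------------------------------------------------------------------
# bootstrap machinery

@dataclass
class BootstrapResult:
    """sigma(N) table, fitted k and the extrapolated errors at target_n."""

    sigma1: float
    sigma2: float
    k: float
    target_n: int
    sizes: np.ndarray
    sigmas: np.ndarray


def bootstrap_shift_error(samples, reference, spec=None, seed=0,
                          x_ref=None, with_replacement=False, robust=False):
    """Subsampling estimate of the fall-off shift error versus statistics.

    For each subsample size, ``n_toys`` toys are drawn (without replacement
    by default) from ``samples`` (raw TOF or vertex values), histogrammed on
    the reference binning and compared to the reference with the integral
    shift statistic.  The per-size spreads are fitted with sigma = k/sqrt(N)
    through the origin and evaluated at ``target_n``.

    Returns a BootstrapResult; sigma2 is exactly twice sigma1.
    """
    if spec is None:
        spec = BootstrapSpec()
    samples = np.asarray(samples, dtype=float)
    n_avail = len(samples)
    max_size = max(spec.subsample_sizes)
    if not with_replacement and n_avail <= max_size:
        raise ValueError(
            f"need more than {max_size} events for subsampling, "
            f"got {n_avail}")
    rng = np.random.default_rng(seed)
    if x_ref is None:
        x_ref = distal_maximum(reference)
    f_ref = reference.cumulative()
    y_ref = float(np.interp(x_ref, reference.bin_edges, f_ref))
    edges = reference.bin_edges

    sizes = np.asarray(spec.subsample_sizes)
    sigmas = np.empty(len(sizes))
    for j, size in enumerate(sizes):
        ds = np.empty(spec.n_toys)
        for i in range(spec.n_toys):
            sub = rng.choice(samples, size=size,
                             replace=with_replacement)
            counts, _ = np.histogram(sub, bins=edges)
            cum = np.concatenate([[0.0], np.cumsum(counts)]) / counts.sum()
            ds[i] = np.interp(y_ref, cum, edges) - x_ref
        if robust:
            sigmas[j] = 1.4826 * np.median(np.abs(ds - np.median(ds)))
        else:
            sigmas[j] = ds.std(ddof=1)

    x = 1.0 / np.sqrt(sizes)
    k = float(np.sum(sigmas * x) / np.sum(x * x))
    sigma1 = k / math.sqrt(spec.target_n)
    return BootstrapResult(sigma1=sigma1, sigma2=2.0 * sigma1, k=k,
                           target_n=spec.target_n, sizes=sizes, sigmas=sigmas)


# ---------------------------------------------------------------------------
# end-to-end sensitivity scan

def pgt_conversion_ps_per_cm(config):
    """Time-to-range conversion slope for PGT shifts.

    A range shift implemented by widening the air gap delays every post-gap
    TOF by the shift times the inverse speed of protons entering the gap, so
    the slope equals 1/(beta c) at the exit energy of the slab upstream of
    the gap.
    """
    if config.gap_index is None or config.gap_index == 0:
        raise ValueError("geometry has no upstream slab + air gap pair")
    e = config.beam_energy_mev
    for slab in config.slabs[:config.gap_index]:
        e = config.range_model.energy_at_depth(e, slab.thickness,
                                               slab.material)
    return inverse_speed(e)


def _reference_histograms(config, n_reference, seed, mode):
    """High-statistics simulated reference profile (and maps for PGTI)."""
    time_map = proton_time_map(config.slabs, config.beam_energy_mev,
                               config.range_model)
    ref_events, _ = generate_dataset(config, n_reference, seed=seed,
                                     time_map=time_map)
    window = _auto_tof_window(config)
    bw_t = config.analysis.time_bin_ps
    if mode == "PGT":
        ref_hist = Histogram1D.from_samples(ref_events["tof_ps"], bw_t,
                                            window=window)
        return ref_hist, None, window, time_map
    maps = {d.id: build_reference_map(config, d, time_map=time_map)
            for d in config.detectors}
    rec = reconstruct_dataset(ref_events, maps)
    x_max = max(m.grid_positions[-1] for m in maps.values())
    bw_x = config.analysis.space_bin_cm
    # boundary-assigned (out-of-range) events stay in the edge bins so the
    # cumulative keeps its total mass; dropping them would renormalize the
    # cumulative and bias the shift statistic toward zero
    ref_hist = Histogram1D.from_samples(
        rec["x_rec_cm"], bw_x, window=(0.0, x_max))
    return ref_hist, maps, window, time_map


def sensitivity_scan(config, shifts_cm, n_events_per_shift, mode="PGT",
                     seed=0, n_reference=20000, bootstrap_spec=None,
                     return_details=False):
    """Measure the fall-off shift (with bootstrap errors) for each range shift.

    For every implemented shift the air gap of the reference geometry is
    widened, a dataset of accepted PG events is generated, its profile (TOF
    for PGT, reconstructed vertex for PGTI; PGTI always uses the REFERENCE
    maps) is compared to a high-statistics simulated reference, and the
    statistical errors are extrapolated with the k/sqrt(N) bootstrap law.

    Returns a DataFrame with columns implemented_shift, measured_d, sigma1,
    sigma2, n_events, k, units (ps for PGT, cm for PGTI).
    """
    mode = mode.upper()
    if mode not in ("PGT", "PGTI"):
        raise ValueError("mode must be 'PGT' or 'PGTI'")
    if 0.0 not in [float(s) for s in shifts_cm]:
        raise ValueError("the shift list must include 0 (reference geometry)")
    if bootstrap_spec is None:
        bootstrap_spec = BootstrapSpec(
            n_toys=config.analysis.bootstrap.n_toys,
            subsample_sizes=config.analysis.bootstrap.subsample_sizes,
            target_n=min(config.analysis.bootstrap.target_n,
                         int(n_events_per_shift)),
        )
    ss = np.random.SeedSequence(seed)
    ref_seed, *shift_seeds = ss.spawn(len(list(shifts_cm)) + 1)

    ref_hist, maps, window, _ = _reference_histograms(
        config, n_reference, ref_seed, mode)
    x_ref = distal_maximum(ref_hist)
    # lab-frame detector positions from the reference geometry
    ref_profile = pg_emission_profile(config)
    det_positions = {d.id: d.position(ref_profile.falloff_x)
                     for d in config.detectors}

    rows = []
    details = []
    for s, sub_seed in zip(shifts_cm, shift_seeds):
        shifted = config.shifted(float(s))
        events, _ = generate_dataset(shifted, n_events_per_shift,
                                     seed=sub_seed,
                                     detector_positions=det_positions)
        if mode == "PGT":
            samples = events["tof_ps"].to_numpy()
        else:
            rec = reconstruct_dataset(events, maps)
            samples = rec["x_rec_cm"].to_numpy()
        hist = Histogram1D.from_samples(
            samples, ref_hist.bin_edges[1] - ref_hist.bin_edges[0],
            window=(ref_hist.bin_edges[0], ref_hist.bin_edges[-1]))
        shift = falloff_shift(hist, ref_hist, x_ref=x_ref)
        boot = bootstrap_shift_error(
            samples, ref_hist, spec=bootstrap_spec,
            seed=np.random.default_rng(sub_seed).integers(2 ** 31),
            x_ref=x_ref)
        rows.append({
            "implemented_shift_cm": float(s),
            "measured_d": shift.d,
            "sigma1": boot.sigma1,
            "sigma2": boot.sigma2,
            "n_events": len(samples),
            "k": boot.k,
            "units": "ps" if mode == "PGT" else "cm",
        })
        details.append((events, hist, boot))
    table = pd.DataFrame(rows)
    if return_details:
        return table, ref_hist, details
    return table
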
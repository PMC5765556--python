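"""Compression-test analysis and simple structural models of a fang.

Converts load–displacement records to engineering stress–strain (stress from
the cross-sectional area at the failure location, strain from the total fang
length), extracts the structural modulus from an automatically detected
linear region and the yield point by the 0.2% strain-offset convention, and
connects structure to material:

* ``theoretical_rod_stress`` — the stress a straight rod of the fang's
  mid-radius and material volume fraction would see under the same force,
  neglecting curvature and taper;
* ``foam_material_modulus`` — Gibson–Ashby open-cell-foam scaling
  ``E_s = E_eff / (BV/TV)²``, inverting the structural modulus to a material
  modulus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

logger = logging.getLogger("fangmech")

__all__ = [
    "StressStrainCurve",
    "MechanicalSummary",
    "read_compression_record",
    "to_stress_strain",
    "linear_modulus",
    "yield_point",
    "theoretical_rod_stress",
    "foam_material_modulus",
    "effective_from_material",
    "summarize_test",
]


class LinearRegionError(ValueError):
    """No linear region could be identified on the stress-strain curve."""


@dataclass
class StressStrainCurve:
    """Engineering stress–strain series with the geometry used to form it."""

    strain: np.ndarray             # dimensionless
    stress: np.ndarray             # Pa
    area_at_failure: float         # μm²
    gauge_length: float            # μm

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, float)
        self.stress = np.asarray(self.stress, float)
        if self.strain.shape != self.stress.shape:
            raise ValueError("strain and stress series differ in length")


@dataclass
class MechanicalSummary:
    yield_force: float             # N
    yield_stress: float            # Pa
    effective_modulus: float       # Pa
    material_modulus_estimate: float  # Pa
    yield_flagged: bool = False    # True when yield fell back to the maximum

    def to_dict(self) -> dict:
        return asdict(self)


def read_compression_record(path: str) -> np.ndarray:
    """Read a 2-column delimited text record: displacement (mm), load (N).

    A single header line is auto-detected and skipped.  Displacement is
    converted to micrometres.
    """
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    try:
        [float(tok) for tok in first.replace(",", " ").split()]
    except ValueError:
        skip = 1
    rec = np.loadtxt(path, skiprows=skip, delimiter=None if "," not in first else ",",
                     ndmin=2)
    rec = rec[:, :2].astype(float)
    rec[:, 0] *= 1000.0  # mm -> um
    return rec


def to_stress_strain(record: np.ndarray, area_at_failure: float,
                     gauge_length: float) -> StressStrainCurve:
    """Engineering stress–strain from a (displacement μm, load N) record.

    stress = load / area_at_failure, strain = displacement / gauge_length.
    """
    if area_at_failure <= 0 or gauge_length <= 0:
        raise ValueError("area and gauge length must be positive")
    record = np.asarray(record, float)
    strain = record[:, 0] / gauge_length
    stress = record[:, 1] / (area_at_failure * 1e-12)  # N / m^2
    return StressStrainCurve(strain=strain, stress=stress,
                             area_at_failure=area_at_failure,
                             gauge_length=gauge_length)


# ---------------------------------------------------------------------------
# Modulus and yield extraction
# ---------------------------------------------------------------------------

def _local_slopes(eps: np.ndarray, sig: np.ndarray) -> np.ndarray:
    """Local dσ/dε by Savitzky–Golay differentiation (noise-robust)."""
    from scipy.signal import savgol_filter

    n = len(eps)
    w = max(11, (n // 10) | 1)
    if w >= n:
        return np.gradient(sig) / np.gradient(eps)
    dsig = savgol_filter(sig, w, polyorder=2, deriv=1, delta=1.0)
    deps = np.gradient(eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        return dsig / np.where(deps == 0, np.nan, deps)


def linear_modulus(curve: StressStrainCurve, slope_band: float = 0.10,
                   min_window: int = 10, return_window: bool = False):
    """Slope of the pre-yield linear region (Pa).

    Local slopes are estimated by Savitzky–Golay differentiation; the linear
    region is the longest contiguous run of samples (before the stress
    maximum) whose local slope stays within ``slope_band`` of the run's
    median slope (the reference slope is refined iteratively from an initial
    median over rising samples).  The least-squares slope over that window
    is returned; with ``return_window`` also the (start, stop) indices.
    """
    eps, sig = curve.strain, curve.stress
    if len(eps) < min_window:
        raise LinearRegionError(f"need >= {min_window} pre-yield samples")
    peak = int(np.argmax(sig)) + 1
    eps_pre, sig_pre = eps[:peak], sig[:peak]
    if len(eps_pre) < min_window:
        raise LinearRegionError("too few samples before the stress maximum")

    slopes = _local_slopes(eps_pre, sig_pre)
    rising = slopes[np.isfinite(slopes) & (slopes > 0)]
    if rising.size == 0:
        raise LinearRegionError("no rising region on the curve")

    # the window median depends on the window: seed the reference slope from
    # several percentiles of the rising slopes, refine each, and keep the
    # longest self-consistent run
    best = None
    for q in (50.0, 70.0, 85.0, 95.0):
        ref = float(np.percentile(rising, q))
        run = None
        for _ in range(3):
            ok = np.abs(slopes - ref) <= slope_band * ref
            run = _longest_run(ok)
            if run is None or run[1] - run[0] < min_window:
                run = None
                break
            ref = float(np.nanmedian(slopes[run[0]:run[1]]))
        if run is not None and (best is None or run[1] - run[0] > best[1] - best[0]):
            best = run
    if best is None:
        raise LinearRegionError("no linear region of sufficient length")
    start, stop = best
    slope = float(np.polyfit(eps_pre[start:stop], sig_pre[start:stop], 1)[0])
    logger.info("linear region: samples [%d, %d), modulus %.4g Pa", start, stop, slope)
    if return_window:
        return slope, (start, stop)
    return slope


def _longest_run(ok: np.ndarray):
    best, cur_start, best_len = None, None, 0
    for i, flag in enumerate(np.append(ok, False)):
        if flag and cur_start is None:
            cur_start = i
        elif not flag and cur_start is not None:
            if i - cur_start > best_len:
                best, best_len = (cur_start, i), i - cur_start
            cur_start = None
    return best


def yield_point(curve: StressStrainCurve, offset: float = 0.002,
                ) -> tuple[float, float, bool]:
    """Yield by the 0.2% strain-offset convention.

    Intersects the curve with the linear fit shifted by ``offset`` strain.
    If no intersection occurs before the stress maximum the curve maximum is
    returned instead, flagged.  Returns (yield_stress Pa, yield_force N,
    flagged).
    """
    E, (start, stop) = linear_modulus(curve, return_window=True)
    eps, sig = curve.strain, curve.stress
    # intercept of the fitted line (toe correction)
    b = float(np.polyfit(eps[start:stop], sig[start:stop], 1)[1])
    # detect the intersection on a smoothed copy so single-sample noise
    # excursions across the offset line are ignored
    from scipy.signal import savgol_filter

    w = max(11, (len(sig) // 15) | 1)
    sig_s = savgol_filter(sig, w, polyorder=2) if w < len(sig) else sig
    offset_line = E * (eps - offset) + b
    diff = sig_s - offset_line
    peak = int(np.argmax(sig_s))
    crossing = np.where((diff[:-1] > 0) & (diff[1:] <= 0))[0]
    # the offset intersection lies beyond the proportional limit; crossings
    # inside the linear window are artefacts
    crossing = crossing[(crossing <= peak) & (crossing >= stop - 1)]
    flagged = False
    if len(crossing):
        i = int(crossing[0])
        t = diff[i] / (diff[i] - diff[i + 1])
        y_stress = float(sig_s[i] + t * (sig_s[i + 1] - sig_s[i]))
    else:
        y_stress = float(sig_s[peak])
        flagged = True
    y_force = y_stress * curve.area_at_failure * 1e-12
    return y_stress, y_force, flagged


# ---------------------------------------------------------------------------
# Structural models
# ---------------------------------------------------------------------------

def theoretical_rod_stress(force: float, mid_radius: float, bvtv: float) -> float:
    """Stress in an equivalent straight rod: F / (π r² · BV/TV).

    The rod has the fang's mid-radius (μm) and its cross-section is corrected
    for the material volume fraction; curvature and taper are neglected.
    Returns Pa for ``force`` in newtons.
    """
    if force < 0 or mid_radius <= 0:
        raise ValueError("force must be >= 0 and mid_radius > 0")
    if not 0 < bvtv <= 1:
        raise ValueError("bvtv must lie in (0, 1]")
    area_m2 = np.pi * (mid_radius * 1e-6) ** 2 * bvtv
    return force / area_m2


def foam_material_modulus(effective_modulus: float, bvtv: float,
                          exponent: float = 2.0) -> float:
    """Material modulus from the structural one, open-cell-foam scaling.

    Gibson–Ashby: ``E_eff / E_s = (BV/TV)^exponent`` with exponent 2 for an
    open-cell foam, so ``E_s = E_eff / (BV/TV)²``.
    """
    if not 0 < bvtv <= 1:
        raise ValueError("bvtv must lie in (0, 1]")
    return effective_modulus / bvtv ** exponent


def effective_from_material(material_modulus: float, bvtv: float,
                            exponent: float = 2.0) -> float:
    """Inverse of :func:`foam_material_modulus`."""
    if not 0 < bvtv <= 1:
        raise ValueError("bvtv must lie in (0, 1]")
    return material_modulus * bvtv ** exponent


def summarize_test(curve: StressStrainCurve, bvtv: float) -> MechanicalSummary:
    """Modulus, yield and foam-inverted material modulus for one record."""
    E_eff = linear_modulus(curve)
    y_stress, y_force, flagged = yield_point(curve)
    return MechanicalSummary(
        yield_force=y_force,
        yield_stress=y_stress,
        effective_modulus=E_eff,
        material_modulus_estimate=foam_material_modulus(E_eff, bvtv),
        yield_flagged=flagged,
    )
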
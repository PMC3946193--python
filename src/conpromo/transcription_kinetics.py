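"""Single-round mixed-transcription kinetics.

In the mixed assay, a test and a reference template are preincubated with
holoenzyme for increasing times; heparin then restricts transcription to
open complexes formed during preincubation, so the RNA yield as a function
of preincubation time traces open-complex accumulation.  The observable is
modelled as the saturating exponential

    y(t) = A (1 - exp(-k t))

where the plateau A (parameter I) reports holoenzyme binding to the
promoter and the approach rate k sets parameter II, the reciprocal time to
reach the plateau.  Band intensities from the radiolabelled gel are first
converted to molar units by dividing by the transcript's U count, since
label incorporation is proportional to the number of U residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

DEFAULT_TIME_GRID = (0.5, 1.0, 2.5, 5.0, 7.5, 10.0, 15.0)


@dataclass(frozen=True)
class TimeCourse:
    times: np.ndarray  # minutes, strictly increasing, positive
    signal: np.ndarray  # corrected molar RNA units
    template_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.size != y.size:
            raise ValueError("times and signal must have equal length")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be positive and strictly increasing")
        if np.any(y < 0):
            raise ValueError("signal must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", y)


@dataclass(frozen=True)
class KineticFit:
    amplitude: float  # parameter I: plateau RNA level (binding)
    rate: float  # k, per minute
    residual_norm: float
    status: str = "ok"  # "ok" | "saturated" | "failed"
    plateau_frac: float = 0.95

    @property
    def param_II(self) -> float:
        return parameter_II(self, self.plateau_frac)

    @property
    def ok(self) -> bool:
        return self.status in ("ok", "saturated")


def u_correct(band_intensity: float, transcript_seq: str) -> float:
    """Convert a band intensity to molar units by dividing by the number of
    U residues in the transcript (T counts as U for DNA-written input)."""
    if band_intensity < 0:
        raise ValueError("band intensity must be non-negative")
    n_u = transcript_seq.upper().count("U") + transcript_seq.upper().count("T")
    if n_u == 0:
        raise ValueError("transcript contains no U: intensity cannot be calibrated")
    return band_intensity / n_u


def _model(t, amplitude, rate):
    return amplitude * (1.0 - np.exp(-rate * t))


def fit_single_round(
    tc: TimeCourse, plateau_frac: float = 0.95, saturation_factor: float = 0.99
) -> KineticFit:
    """Least-squares fit of y(t) = A (1 - exp(-k t)) to one time course.

    Gel-band noise is multiplicative (it scales with band intensity), so
    residuals are weighted relative to the observed signal (sigma
    proportional to y, floored at 1e-3 of the maximum to keep near-zero
    early points from dominating).  Initialization: A0 = max(signal);
    k0 = ln 2 / (earliest time at which the
    signal reaches A0/2).  A fit whose rate puts the curve above
    ``saturation_factor`` of its plateau already at the first time point is
    flagged "saturated": k is then only bounded below by the grid, not
    resolved by it.  Failures (non-convergence, non-positive estimates) are
    returned flagged, never raised.
    """
    t, y = tc.times, tc.signal
    if t.size < 4:
        raise ValueError("need at least 4 time points to fit")
    a0 = float(y.max())
    if a0 <= 0:
        return KineticFit(np.nan, np.nan, np.nan, status="failed",
                          plateau_frac=plateau_frac)
    half_idx = np.flatnonzero(y >= a0 / 2.0)
    k0 = np.log(2.0) / t[half_idx[0]] if half_idx.size else 1.0 / t[-1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sigma = np.maximum(y, 1e-3 * a0)
            popt, _ = curve_fit(
                _model,
                t,
                y,
                p0=(a0, k0),
                sigma=sigma,
                absolute_sigma=False,
                bounds=((0.0, 0.0), (np.inf, np.inf)),
                maxfev=10_000,
            )
    except (RuntimeError, ValueError):
        return KineticFit(np.nan, np.nan, np.nan, status="failed",
                          plateau_frac=plateau_frac)
    amplitude, rate = float(popt[0]), float(popt[1])
    if not np.isfinite(amplitude) or not np.isfinite(rate) or amplitude <= 0 or rate <= 0:
        return KineticFit(amplitude, rate, np.nan, status="failed",
                          plateau_frac=plateau_frac)
    residual = float(np.linalg.norm(y - _model(t, amplitude, rate)))
    # rate unresolvable when the curve is already at plateau by the first point
    k_ceiling = -np.log(1.0 - saturation_factor) / t[0]
    status = "saturated" if rate >= k_ceiling else "ok"
    return KineticFit(amplitude, rate, residual, status=status,
                      plateau_frac=plateau_frac)


def parameter_II(fit: KineticFit, plateau_frac: float = 0.95) -> float:
    """Reciprocal of the time the fitted curve needs to reach
    ``plateau_frac`` of its plateau: 1 / t_p with t_p = ln(1/(1-f)) / k,
    i.e. k / ln(1/(1-f)).  Monotone in k, independent of A."""
    if not np.isfinite(fit.rate) or fit.rate <= 0:
        raise ValueError("parameter II requires a successful fit with k > 0")
    if not (0 < plateau_frac < 1):
        raise ValueError("plateau_frac must lie strictly between 0 and 1")
    return fit.rate / np.log(1.0 / (1.0 - plateau_frac))


def relative_activity(test_fit: KineticFit, reference_fit: KineticFit,
                      which: str = "I") -> float:
    """Ratio of parameter I (plateau) or II (opening rate) between a test
    and a reference fit."""
    if not (test_fit.ok and reference_fit.ok):
        raise ValueError("both fits must be successful")
    if which == "I":
        num, den = test_fit.amplitude, reference_fit.amplitude
    elif which == "II":
        num, den = test_fit.param_II, reference_fit.param_II
    else:
        raise ValueError("which must be 'I' or 'II'")
    if den == 0:
        raise ZeroDivisionError("reference parameter is zero")
    return num / den


def normalize_to_best(fits: dict[str, KineticFit], which: str = "I") -> dict[str, float]:
    """Within a template set, activities relative to the most active
    template, so exactly one template reports 1.0."""
    if not fits:
        raise ValueError("empty fit set")
    values = {
        tid: (f.amplitude if which == "I" else f.param_II) for tid, f in fits.items()
    }
    best = max(values.values())
    if best <= 0:
        raise ValueError("no positive activities to normalize against")
    return {tid: v / best for tid, v in values.items()}


def fit_table(
    timecourses: pd.DataFrame,
    transcripts: dict[str, str] | None = None,
    plateau_frac: float = 0.95,
) -> pd.DataFrame:
    """Fit every template in a long-format table (template_id, time_min,
    intensity); intensities are U-corrected when transcript sequences are
    supplied.  Returns one row per template with A, k, parameter II,
    activities relative to the set's best template, and fit status."""
    rows = []
    fits: dict[str, KineticFit] = {}
    for tid, grp in timecourses.groupby("template_id", sort=True):
        grp = grp.sort_values("time_min")
        y = grp["intensity"].to_numpy(dtype=float)
        if transcripts is not None:
            y = np.array([u_correct(v, transcripts[tid]) for v in y])
        tc = TimeCourse(grp["time_min"].to_numpy(dtype=float), y, template_id=str(tid))
        fits[str(tid)] = fit_single_round(tc, plateau_frac=plateau_frac)
    good = {tid: f for tid, f in fits.items() if f.ok}
    rel_I = normalize_to_best(good, "I") if good else {}
    rel_II = normalize_to_best(good, "II") if good else {}
    for tid, f in fits.items():
        rows.append(
            {
                "template_id": tid,
                "amplitude": f.amplitude,
                "rate": f.rate,
                "param_II": f.param_II if f.ok else np.nan,
                "rel_param_I": rel_I.get(tid, np.nan),
                "rel_param_II": rel_II.get(tid, np.nan),
                "residual_norm": f.residual_norm,
                "status": f.status,
            }
        )
    return pd.DataFrame(rows)
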
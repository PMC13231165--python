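"""Plate-reader curve fits: anisotropy binding, beacon kinetics, metal
activation and thermal melts.

Four assay models used to characterize Rep (HUH-endonuclease) variants:

* fluorescence polarization / anisotropy titrations fit to the
  ligand-depletion **quadratic binding isotherm** — required because the
  labelled probe concentration (10 nM) is comparable to the dissociation
  constants being measured, so free protein cannot be approximated by total
  protein;
* **molecular beacon** cleavage progress curves summarized as initial
  rates (fluorophore/quencher separation on cleavage gives a fluorescence
  increase proportional to reaction progress);
* cleavage rate versus Mn²⁺ fit to a **single-site hyperbolic activation**
  model, giving an apparent metal dissociation constant;
* differential scanning fluorimetry (DSF) melts, with T_m read from the
  maximum of the **first derivative** dF/dT.

All fits are deterministic given identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

__all__ = [
    "TitrationSeries",
    "FitResult",
    "polarization_from_intensities",
    "quadratic_binding",
    "hyperbolic_activation",
    "melt_sigmoid",
    "beacon_progress",
    "fit_quadratic_binding",
    "beacon_initial_rate",
    "fit_exponential_progress",
    "fit_metal_activation",
    "dsf_tm",
]


# --- Model functions ------------------------------------------------------

def quadratic_binding(pt, kd, amax, amin, dt):
    """Ligand-depletion quadratic binding isotherm.

    A([Pt]) = Amin + (Amax − Amin) ·
              (([Pt]+[Dt]+K_D) − sqrt(([Pt]+[Dt]+K_D)² − 4[Pt][Dt])) / (2[Dt])

    with [Pt] total protein, [Dt] total labelled probe (same units as K_D).
    Reduces to the hyperbolic Langmuir isotherm as [Dt] → 0 and to Amin at
    [Pt] = 0.
    """
    pt = np.asarray(pt, dtype=float)
    b = pt + dt + kd
    disc = np.maximum(b * b - 4.0 * pt * dt, 0.0)
    bound_frac = (b - np.sqrt(disc)) / (2.0 * dt)
    return amin + (amax - amin) * bound_frac


def hyperbolic_activation(conc, vmax, kapp, hill=1.0):
    """Single-site saturation: v = vmax·[M]^h / (K_app^h + [M]^h), h=1 default."""
    conc = np.asarray(conc, dtype=float)
    ch = np.power(conc, hill)
    return vmax * ch / (np.power(kapp, hill) + ch)


def melt_sigmoid(temp, tm, width, f_low, f_high):
    """Two-state thermal unfolding: F(T) = f_low + (f_high−f_low)/(1+e^{−(T−Tm)/width})."""
    temp = np.asarray(temp, dtype=float)
    return f_low + (f_high - f_low) / (1.0 + np.exp(-(temp - tm) / width))


def beacon_progress(t, rate_k, f0, f_inf):
    """Single-exponential progress curve: F(t) = F∞ − (F∞ − F₀)·e^{−kt}."""
    t = np.asarray(t, dtype=float)
    return f_inf - (f_inf - f0) * np.exp(-rate_k * t)


def polarization_from_intensities(ipar, iper):
    """Anisotropy-form polarization, (Ipar − Iper)/(Ipar + 2·Iper).

    Undefined (NaN) when both intensities are zero.  Accepts scalars or
    arrays; intensities must be non-negative.
    """
    ipar = np.asarray(ipar, dtype=float)
    iper = np.asarray(iper, dtype=float)
    if (ipar < 0).any() or (iper < 0).any():
        raise ValueError("intensities must be non-negative")
    denom = ipar + 2.0 * iper
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, (ipar - iper) / denom, np.nan)
    return float(out) if out.ndim == 0 else out


# --- Domain types ---------------------------------------------------------

_X_KINDS = ("protein_nM", "metal_uM", "temperature_C", "time_s")


@dataclass
class TitrationSeries:
    """One titration / time course: x grid, signal, optional replicate labels.

    ``x_kind`` tags the axis (protein nM, metal µM, temperature °C, time s).
    Concentration axes must be non-negative; temperature/time axes strictly
    increasing.  ``dt_nM`` is the fixed labelled-probe concentration for
    binding fits.
    """

    x: np.ndarray
    y: np.ndarray
    x_kind: str = "protein_nM"
    replicate: np.ndarray | None = None
    dt_nM: float | None = None
    series_id: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same shape")
        if self.x_kind not in _X_KINDS:
            raise ValueError(f"unknown x_kind {self.x_kind!r}; one of {_X_KINDS}")
        if self.x_kind in ("protein_nM", "metal_uM"):
            if (self.x < 0).any():
                raise ValueError("concentrations must be non-negative")
        else:
            if self.replicate is None and not (np.diff(self.x) > 0).all():
                raise ValueError(f"{self.x_kind} axis must be strictly increasing")
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)
            if self.replicate.shape != self.x.shape:
                raise ValueError("replicate labels must match x")

    def split_replicates(self) -> list["TitrationSeries"]:
        if self.replicate is None:
            return [self]
        out = []
        for label in pd.unique(self.replicate):
            m = self.replicate == label
            out.append(
                TitrationSeries(
                    self.x[m], self.y[m], self.x_kind, None, self.dt_nM,
                    series_id=f"{self.series_id}/{label}",
                )
            )
        return out


@dataclass
class FitResult:
    """Parameter estimates with uncertainties and fit diagnostics."""

    model: str
    params: dict[str, float]
    stderr: dict[str, float]
    r_squared: float
    converged: bool
    n_points: int
    flags: list[str] = field(default_factory=list)
    per_replicate: list["FitResult"] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {"model": self.model, "converged": self.converged,
               "r_squared": self.r_squared, "n_points": self.n_points,
               "flags": ";".join(self.flags)}
        for name, val in self.params.items():
            row[name] = val
            row[f"{name}_se"] = self.stderr.get(name, np.nan)
        return row


def _failed(model: str, names: list[str], n: int, reason: str) -> FitResult:
    nan = {p: np.nan for p in names}
    return FitResult(model, dict(nan), dict(nan), np.nan, False, n,
                     flags=[f"not_converged: {reason}"])


def _r_squared(y, fitted) -> float:
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan


# --- Fits -----------------------------------------------------------------

def fit_quadratic_binding(
    series: TitrationSeries,
    dt_nM: float | None = None,
    mode: str = "replicate_mean",
) -> FitResult:
    """Fit the quadratic binding isotherm; returns K_D, Amax, Amin.

    ``mode="replicate_mean"`` (default) fits each replicate day separately
    and reports the mean K_D across per-replicate fits, mirroring K_D
    averaging over independent reactions; ``mode="pooled"`` fits all points
    jointly.  Initialization: Amin = min(y), Amax = max(y), K_D = the
    protein concentration closest to half-signal.  Requires at least 6
    distinct protein concentrations and a positive probe concentration.
    """
    dt = dt_nM if dt_nM is not None else series.dt_nM
    if dt is None or dt <= 0:
        raise ValueError("probe concentration [Dt] must be positive")
    if len(np.unique(series.x)) < 6:
        raise ValueError("need at least 6 distinct protein concentrations")
    if mode not in ("replicate_mean", "pooled"):
        raise ValueError(f"unknown fit mode {mode!r}")

    def fit_one(x, y) -> FitResult:
        amin0, amax0 = float(np.min(y)), float(np.max(y))
        half = 0.5 * (amin0 + amax0)
        kd0 = max(float(x[np.argmin(np.abs(y - half))]), 1e-3)
        try:
            popt, pcov = optimize.curve_fit(
                lambda p, kd, amax, amin: quadratic_binding(p, kd, amax, amin, dt),
                x, y, p0=[kd0, amax0, amin0],
                bounds=([1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            return _failed("quadratic_binding", ["kd_nM", "amax", "amin"],
                           len(x), str(exc))
        se = np.sqrt(np.diag(pcov))
        fitted = quadratic_binding(x, *popt, dt)
        return FitResult(
            model="quadratic_binding",
            params={"kd_nM": popt[0], "amax": popt[1], "amin": popt[2]},
            stderr={"kd_nM": se[0], "amax": se[1], "amin": se[2]},
            r_squared=_r_squared(y, fitted),
            converged=True,
            n_points=len(x),
        )

    if mode == "pooled" or series.replicate is None:
        result = fit_one(series.x, series.y)
        result.extra["mode"] = "pooled"
        return result
    per_rep = [fit_one(s.x, s.y) for s in series.split_replicates()]
    good = [r for r in per_rep if r.converged]
    if not good:
        out = _failed("quadratic_binding", ["kd_nM", "amax", "amin"],
                      len(series.x), "no replicate converged")
        out.per_replicate = per_rep
        return out
    params = {p: float(np.mean([r.params[p] for r in good]))
              for p in ("kd_nM", "amax", "amin")}
    stderr = {p: float(np.std([r.params[p] for r in good], ddof=1))
              if len(good) > 1 else np.nan for p in params}
    out = FitResult(
        model="quadratic_binding", params=params, stderr=stderr,
        r_squared=float(np.mean([r.r_squared for r in good])),
        converged=True, n_points=len(series.x), per_replicate=per_rep,
        extra={"mode": "replicate_mean", "n_replicates": len(per_rep)},
    )
    if len(good) < len(per_rep):
        out.flags.append(f"{len(per_rep) - len(good)} replicate fits failed")
    return out


def beacon_initial_rate(
    t,
    fluorescence,
    window_s: float = 60.0,
    dead_time_s: float = 0.0,
    saturation_level: float | None = None,
) -> FitResult:
    """Initial-rate summary of a beacon cleavage progress curve.

    Ordinary least-squares slope of F(t) over the initial window after the
    dead time (default 60 s), with R² as a linearity diagnostic.  Rates are
    relative (signal units per second).  If ``saturation_level`` is given
    and the curve starts near it with negligible slope, the reaction is
    flagged too fast to measure rather than reported as slow.
    """
    t = np.asarray(t, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    m = (t >= dead_time_s) & (t <= dead_time_s + window_s)
    if m.sum() < 5:
        raise ValueError("need at least 5 points in the initial window")
    res = stats.linregress(t[m], f[m])
    flags = []
    if saturation_level is not None:
        span = abs(saturation_level)
        if span > 0 and f[m][0] > 0.8 * saturation_level and \
                abs(res.slope) * window_s < 0.05 * span:
            flags.append("too_fast_to_measure")
    return FitResult(
        model="beacon_initial_rate",
        params={"rate_au_per_s": float(res.slope),
                "intercept": float(res.intercept)},
        stderr={"rate_au_per_s": float(res.stderr)},
        r_squared=float(res.rvalue) ** 2,
        converged=True,
        n_points=int(m.sum()),
        flags=flags,
    )


def fit_exponential_progress(t, fluorescence) -> FitResult:
    """Single-exponential fit F(t) = F∞ − (F∞−F₀)e^{−kt} as an alternative
    rate summary for curves that saturate within the acquisition."""
    t = np.asarray(t, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    f0, finf = float(f[0]), float(f.max())
    span = max(finf - f0, 1e-12)
    # crude k0 from time to reach ~63% of the span
    above = np.nonzero(f - f0 >= 0.63 * span)[0]
    k0 = 1.0 / max(float(t[above[0]]), 1e-6) if above.size else 1.0 / max(t[-1], 1e-6)
    try:
        popt, pcov = optimize.curve_fit(
            beacon_progress, t, f, p0=[k0, f0, finf],
            bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return _failed("exponential_progress", ["k_per_s", "f0", "f_inf"],
                       len(t), str(exc))
    se = np.sqrt(np.diag(pcov))
    return FitResult(
        model="exponential_progress",
        params={"k_per_s": popt[0], "f0": popt[1], "f_inf": popt[2]},
        stderr={"k_per_s": se[0], "f0": se[1], "f_inf": se[2]},
        r_squared=_r_squared(f, beacon_progress(t, *popt)),
        converged=True,
        n_points=len(t),
    )


def fit_metal_activation(
    conc_uM, rates, fit_hill: bool = False
) -> FitResult:
    """Fit rate vs [Mn²⁺] to single-site hyperbolic activation.

    v = v_max·[Mn]/(K_app + [Mn]); K_app is the apparent metal dissociation
    constant.  A Hill coefficient can optionally be fit (default fixed at 1).
    Requires ≥ 4 concentrations; flags a wide-confidence warning when the
    data do not reach saturation (max [Mn] < 2·K_app estimate).
    """
    conc = np.asarray(conc_uM, dtype=float)
    v = np.asarray(rates, dtype=float)
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 metal concentrations")
    vmax0 = float(v.max())
    half = 0.5 * vmax0
    kapp0 = max(float(conc[np.argmin(np.abs(v - half))]), 1e-6)
    names = ["vmax", "kapp_uM"] + (["hill"] if fit_hill else [])
    try:
        if fit_hill:
            popt, pcov = optimize.curve_fit(
                hyperbolic_activation, conc, v, p0=[vmax0, kapp0, 1.0],
                bounds=([0, 1e-9, 0.1], [np.inf, np.inf, 10.0]), maxfev=20000,
            )
        else:
            popt, pcov = optimize.curve_fit(
                lambda c, vm, ka: hyperbolic_activation(c, vm, ka),
                conc, v, p0=[vmax0, kapp0],
                bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=20000,
            )
    except (RuntimeError, ValueError) as exc:
        return _failed("hyperbolic_activation", names, len(conc), str(exc))
    se = np.sqrt(np.diag(pcov))
    params = dict(zip(names, popt))
    result = FitResult(
        model="hyperbolic_activation",
        params={k: float(v_) for k, v_ in params.items()},
        stderr={k: float(s) for k, s in zip(names, se)},
        r_squared=_r_squared(v, hyperbolic_activation(conc, *popt)),
        converged=True,
        n_points=len(conc),
    )
    if conc.max() < 2.0 * params["kapp_uM"]:
        result.flags.append("no_saturation_in_range: K_app poorly constrained")
    return result


def dsf_tm(
    temperature_C,
    fluorescence,
    smoothing_window: int = 11,
    edge_exclude_C: float = 2.0,
) -> FitResult:
    """Melting temperature from the first derivative of a DSF melt curve.

    F(T) is smoothed with a Savitzky–Golay filter (local polynomial, window
    in grid points), dF/dT taken numerically, and T_m read as the
    temperature of the interior derivative maximum, refined by parabolic
    interpolation around the peak.  The first and last ``edge_exclude_C``
    degrees are excluded to avoid edge artifacts.  Multiple comparable
    peaks (prominence ≥ 50% of the largest) are all reported with the
    largest flagged primary; curves with no transition (e.g. linear drift)
    return NaN with a no-transition flag.
    """
    t = np.asarray(temperature_C, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if not (np.diff(t) > 0).all():
        raise ValueError("temperatures must be strictly increasing")
    window = min(smoothing_window, len(f) if len(f) % 2 else len(f) - 1)
    if window >= 5:
        f_s = signal.savgol_filter(f, window_length=window, polyorder=3)
    else:
        f_s = f
    dfdt = np.gradient(f_s, t)
    interior = (t >= t[0] + edge_exclude_C) & (t <= t[-1] - edge_exclude_C)
    d_in = dfdt[interior]
    t_in = t[interior]
    ptp = float(np.ptp(d_in))
    scale = float(np.ptp(f)) / max(float(np.ptp(t)), 1e-12)
    min_prom = max(0.05 * ptp, 1e-9 * max(scale, 1e-12))
    peaks, props = signal.find_peaks(d_in, prominence=min_prom)
    if peaks.size == 0:
        out = _failed("dsf_first_derivative", ["tm_C"], len(t), "no transition")
        out.flags = ["no_transition"]
        return out

    def refine(i: int) -> float:
        # parabolic interpolation through the peak and its neighbours
        if 0 < i < len(d_in) - 1:
            y0, y1, y2 = d_in[i - 1], d_in[i], d_in[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                delta = 0.5 * (y0 - y2) / denom
                step = t_in[min(i + 1, len(t_in) - 1)] - t_in[i]
                return float(t_in[i] + np.clip(delta, -1, 1) * step)
        return float(t_in[i])

    prominences = props["prominences"]
    order = np.argsort(prominences)[::-1]
    comparable = [peaks[j] for j in order
                  if prominences[j] >= 0.5 * prominences[order[0]]]
    all_tms = [refine(int(i)) for i in comparable]
    primary = all_tms[0]
    result = FitResult(
        model="dsf_first_derivative",
        params={"tm_C": primary},
        stderr={"tm_C": np.nan},
        r_squared=np.nan,
        converged=True,
        n_points=len(t),
        extra={"all_tm_C": all_tms,
               "peak_dfdt": float(d_in[comparable[0]])},
    )
    if len(all_tms) > 1:
        result.flags.append(f"{len(all_tms)} comparable transitions; "
                            "largest reported as primary")
    return result
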
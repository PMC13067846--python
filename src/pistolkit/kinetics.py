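"""Cleavage kinetics and cellular dose-response fitting.

Fraction-cleaved time courses are fitted to the single-exponential
first-order model

    F(t) = F_inf * (1 - exp(-k_obs * t))

with ``k_obs`` in min^-1 and an optionally fitted plateau ``F_inf`` (gels
rarely reach 100% cleavage; fixing F_inf = 1 is available for comparison
with analyses that assume complete cleavage).  Dose-response data are
fitted with a four-parameter log-logistic (4PL) model

    R(c) = bottom + (top - bottom) / (1 + (ic50 / c)^hill)

with concentrations in nM and responses in percent inhibition.  Both fits
use derivative-based least squares with analytic Jacobians and fixed,
data-derived initialisation, so identical inputs give bit-identical
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigError, NonIdentifiableError

__all__ = [
    "TimeCourse",
    "KineticFit",
    "DoseResponseCurve",
    "Ic50Fit",
    "MetalComparison",
    "fraction_from_bands",
    "predict_fraction",
    "fit_kobs",
    "compare_metals",
    "fit_ic50",
]

_MAX_ITER = 500
_XTOL = 1e-10


@dataclass(frozen=True)
class Condition:
    """Reaction condition metadata for a time course."""

    ion: str = "Mg2+"
    ion_concentration_m: float = 1e-3
    ph: float = 7.0
    temperature_c: float = 37.0


@dataclass
class TimeCourse:
    """Fraction-cleaved observations over time (minutes)."""

    times: np.ndarray
    fraction_cleaved: np.ndarray
    condition: Condition = field(default_factory=Condition)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fraction_cleaved = np.asarray(self.fraction_cleaved, dtype=float)
        if self.times.shape != self.fraction_cleaved.shape:
            raise ConfigError("times and fraction_cleaved lengths differ")
        if self.times.size < 4:
            raise ConfigError("a time course needs at least 4 points")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ConfigError("times must be non-negative and strictly increasing")
        if np.any((self.fraction_cleaved < 0) | (self.fraction_cleaved > 1)):
            raise ConfigError("fraction_cleaved values must lie in [0, 1]")


@dataclass(frozen=True)
class KineticFit:
    k_obs: float
    plateau: float
    residual_sum: float
    stderr_k: float
    n_points: int
    converged: bool
    plateau_mode: str
    condition: Condition = Condition()


@dataclass
class DoseResponseCurve:
    """Concentration (nM) vs percent-inhibition observations."""

    concentrations: np.ndarray
    response: np.ndarray
    replicate_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentrations.shape != self.response.shape:
            raise ConfigError("concentrations and response lengths differ")
        if self.concentrations.size < 5:
            raise ConfigError("a dose-response curve needs at least 5 concentrations")
        if np.any(self.concentrations <= 0):
            raise ConfigError("concentrations must be positive")


@dataclass(frozen=True)
class Ic50Fit:
    ic50: float
    hill: float
    top: float
    bottom: float
    converged: bool
    extrapolated: bool
    residual_sum: float


@dataclass(frozen=True)
class MetalComparison:
    """Pairwise k_obs ratios between ions at shared concentrations."""

    fits: dict
    ratios: dict  # ((ion_a, ion_b), concentration) -> k_a / k_b


def fraction_from_bands(substrate_intensity: float, product_intensities: list[float],
                        lengths: tuple[int, ...] | None = None,
                        normalize_by_length: bool = False) -> float:
    """Fraction cleaved from gel band intensities.

    Default is the raw-intensity fraction ``P / (P + S)`` with ``P`` the
    summed product intensities.  With ``normalize_by_length`` (for
    mass-proportional stains), intensities are converted to molar amounts
    by dividing by fragment length (``lengths`` = substrate length followed
    by product lengths) and the product amount is the mean over fragments,
    since one cleavage event yields one of each.
    """
    s = float(substrate_intensity)
    prods = [float(p) for p in product_intensities]
    if s < 0 or any(p < 0 for p in prods):
        raise ConfigError("band intensities must be non-negative")
    if s == 0 and not any(prods):
        raise NonIdentifiableError("all band intensities are zero")
    if normalize_by_length:
        if lengths is None or len(lengths) != 1 + len(prods):
            raise ConfigError("lengths must give substrate then one length per product band")
        s = s / lengths[0]
        molar = [p / L for p, L in zip(prods, lengths[1:])]
        p_total = sum(molar) / len(molar)
    else:
        p_total = sum(prods)
    return p_total / (p_total + s)


def predict_fraction(k_obs: float, t, plateau: float = 1.0):
    """F(t) = F_inf (1 - e^(-k t)); monotone nondecreasing in t and k."""
    if k_obs < 0:
        raise ConfigError("k_obs must be non-negative")
    t = np.asarray(t, dtype=float)
    out = plateau * (-np.expm1(-k_obs * t))
    return float(out) if out.ndim == 0 else out


def _init_kobs(times: np.ndarray, fracs: np.ndarray, plateau0: float) -> float:
    """Log-linear initial rate from the early, pre-plateau points."""
    mask = (times > 0) & (fracs < 0.95 * plateau0) & (fracs > 0)
    if mask.sum() >= 2:
        y = -np.log1p(-np.clip(fracs[mask] / plateau0, 0.0, 1.0 - 1e-12))
        t = times[mask]
        k0 = float(np.dot(t, y) / np.dot(t, t))  # through-origin regression
        if k0 > 0 and math.isfinite(k0):
            return k0
    t_mid = float(np.median(times[times > 0])) if np.any(times > 0) else 1.0
    return 1.0 / t_mid


def fit_kobs(tc: TimeCourse, plateau_mode: str = "fitted") -> KineticFit:
    """Nonlinear least-squares fit of the single-exponential model.

    ``plateau_mode="fitted"`` (default) estimates F_inf in (0, 1];
    ``"fixed_1"`` pins it at 1.  Raises :class:`NonIdentifiableError` on a
    flat-zero response.
    """
    if plateau_mode not in ("fitted", "fixed_1"):
        raise ConfigError(f"unknown plateau_mode {plateau_mode!r}")
    t, f = tc.times, tc.fraction_cleaved
    if not np.any(f > 0):
        raise NonIdentifiableError("flat-zero time course: k_obs is not identifiable")

    if plateau_mode == "fixed_1":
        plateau0 = 1.0

        def resid(params):
            return predict_fraction(params[0], t) - f

        def jac(params):
            return (t * np.exp(-params[0] * t)).reshape(-1, 1)

        x0 = [_init_kobs(t, f, plateau0)]
        bounds = ([0.0], [np.inf])
    else:
        plateau0 = min(1.0, max(float(f.max()), 1e-3))

        def resid(params):
            k, fin = params
            return fin * (-np.expm1(-k * t)) - f

        def jac(params):
            k, fin = params
            e = np.exp(-k * t)
            return np.column_stack([fin * t * e, -np.expm1(-k * t)])

        x0 = [_init_kobs(t, f, plateau0), plateau0]
        bounds = ([0.0, 1e-9], [np.inf, 1.0])

    res = least_squares(resid, x0, jac=jac, bounds=bounds,
                        xtol=_XTOL, ftol=_XTOL, gtol=_XTOL, max_nfev=_MAX_ITER)
    k = float(res.x[0])
    plateau = float(res.x[1]) if plateau_mode == "fitted" else 1.0
    rss = float(np.sum(res.fun**2))
    dof = max(t.size - res.x.size, 1)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * (rss / dof)
        stderr_k = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        stderr_k = float("nan")
    converged = bool(res.success) and math.isfinite(k) and k >= 0
    return KineticFit(k_obs=k, plateau=plateau, residual_sum=rss, stderr_k=stderr_k,
                      n_points=int(t.size), converged=converged,
                      plateau_mode=plateau_mode, condition=tc.condition)


def compare_metals(fits: list[KineticFit]) -> MetalComparison:
    """Pairwise k_obs ratios between ions sharing a concentration.

    Ratios satisfy ratio(a, b) * ratio(b, a) = 1 whenever both are finite;
    ion pairs without a shared concentration are omitted.
    """
    keyed = {(f.condition.ion, f.condition.ion_concentration_m): f for f in fits}
    ratios = {}
    keys = sorted(keyed)
    for ion_a, conc in keys:
        for ion_b, conc_b in keys:
            if ion_a == ion_b or conc != conc_b:
                continue
            kb = keyed[(ion_b, conc)].k_obs
            ratios[((ion_a, ion_b), conc)] = keyed[(ion_a, conc)].k_obs / kb if kb else math.inf
    return MetalComparison(fits=keyed, ratios=ratios)


def _fourpl(c: np.ndarray, top: float, bottom: float, log_ic50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (log_ic50 - np.log(c))))


def fit_ic50(dr: DoseResponseCurve) -> Ic50Fit:
    """Four-parameter log-logistic fit; IC50 reported in nM.

    Initialisation is deterministic: top/bottom from the response extremes,
    IC50 from linear interpolation of the half-maximal response, hill = 1.
    ``extrapolated`` flags an IC50 outside the tested concentration span.
    """
    c, r = dr.concentrations, dr.response
    if np.log10(c.max() / c.min()) < 1.0:
        raise ConfigError("concentrations must span at least one log10 unit")
    if float(r.max() - r.min()) < 1e-9:
        raise NonIdentifiableError("flat dose-response: IC50 is not identifiable")

    order = np.argsort(c)
    cs, rs = c[order], r[order]
    top0, bottom0 = float(r.max()), float(r.min())
    half = 0.5 * (top0 + bottom0)
    ic50_0 = float(np.interp(half, rs, cs)) if rs[0] < rs[-1] else float(np.interp(half, rs[::-1], cs[::-1]))
    ic50_0 = min(max(ic50_0, cs[0]), cs[-1])
    x0 = [top0, bottom0, math.log(ic50_0), 1.0]

    def resid(params):
        return _fourpl(c, *params) - r

    def jac(params):
        top, bottom, log_ic50, hill = params
        z = np.exp(hill * (log_ic50 - np.log(c)))
        denom = (1.0 + z) ** 2
        d_top = 1.0 / (1.0 + z)
        d_bottom = z / (1.0 + z)
        d_log = -(top - bottom) * hill * z / denom
        d_hill = -(top - bottom) * (log_ic50 - np.log(c)) * z / denom
        return np.column_stack([d_top, d_bottom, d_log, d_hill])

    res = least_squares(resid, x0, jac=jac, xtol=_XTOL, ftol=_XTOL, gtol=_XTOL,
                        max_nfev=_MAX_ITER)
    top, bottom, log_ic50, hill = (float(v) for v in res.x)
    if bottom > top:  # re-express with top >= bottom (sign of hill flips)
        top, bottom, hill = bottom, top, -hill
    ic50 = math.exp(log_ic50)
    converged = bool(res.success) and math.isfinite(ic50)
    extrapolated = not (c.min() <= ic50 <= c.max())
    return Ic50Fit(ic50=ic50, hill=hill, top=top, bottom=bottom, converged=converged,
                   extrapolated=extrapolated, residual_sum=float(np.sum(res.fun**2)))
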
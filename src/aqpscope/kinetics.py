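"""Stopped-flow and yeast-assay kinetics.

Single-exponential rate fitting of stopped-flow traces (light scattering for
water, internal fluorescence for ammonia), rate-versus-gradient regression,
Henderson-Hasselbalch free-NH3 gradients, empty-vector background correction
(clipped at zero), ammonia/water specificity ratios with first-order error
propagation, and construct classification against a reference channel.

Units follow the assay convention: ammonia rates are tabulated in units of
1e-2 s^-1 and water rates in s^-1, so the printed specificity ratio
("ammonia/water x 1e-2") is numerically ammonia_rate / water_rate in those
table units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .errors import DomainError, FitError

#: Default pKa of the ammonium/ammonia equilibrium at 25 C.
NH4_PKA = 9.25

#: Relative half-width of the "similar ratio" band for the reference-like call.
LIKE_BAND = 0.25

#: A corrected rate is insignificant when below max(3*se, floor) in table units.
SIGNIFICANCE_FLOOR = 0.1


@dataclass
class Trace:
    """A stopped-flow recording."""

    times: np.ndarray
    signal: np.ndarray
    channel: str = "scattering"  # scattering | fluorescence
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.times) != len(self.signal):
            raise DomainError("times and signal must have equal length")
        if len(self.times) < 10:
            raise DomainError("trace needs at least 10 points")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")


@dataclass
class RateFit:
    k: float
    amplitude: float
    offset: float
    k_stderr: float
    r_squared: float
    direction: str = "rising"
    flagged: bool = False


@dataclass
class ConstructRates:
    construct: str
    filter_code: str | None
    ammonia_rate: float      # x 1e-2 s^-1
    ammonia_se: float
    water_rate: float        # s^-1
    water_se: float


@dataclass
class SpecificityRow:
    construct: str
    filter_code: str | None
    corrected_ammonia: float     # x 1e-2 s^-1
    corrected_ammonia_se: float
    corrected_water: float       # s^-1
    corrected_water_se: float
    ratio: float | None          # x 1e-2 (None when NA or infinite)
    ratio_se: float | None
    call: str                    # Water | Ammonia | reference-like | NA
    infinite_ratio: bool = False


# ---------------------------------------------------------------------------
# Exponential fitting
# ---------------------------------------------------------------------------

def _rising(t, a, k, c):
    return a * (1.0 - np.exp(-k * t)) + c


def _falling(t, a, k, c):
    return a * np.exp(-k * t) + c


def fit_single_exponential(trace: Trace, dead_time: float = 0.0) -> RateFit:
    """Least-squares single-exponential fit with auto-detected direction.

    Rising traces are fit as ``A (1 - exp(-k t)) + c``, falling traces as
    ``A exp(-k t) + c``; points before ``dead_time`` are excluded.  A trace
    whose amplitude is indistinguishable from its noise is returned flagged
    with k ~ 0 and a large standard error rather than raising.
    """
    mask = trace.times >= dead_time
    t = trace.times[mask] - trace.times[mask][0]
    s = trace.signal[mask]
    if len(t) < 10:
        raise DomainError("fewer than 10 points after dead-time exclusion")
    span = s.max() - s.min()
    rising = s[-3:].mean() >= s[:3].mean()
    if span == 0:
        return RateFit(k=0.0, amplitude=0.0, offset=float(s[0]), k_stderr=np.inf,
                       r_squared=0.0, direction="rising" if rising else "falling",
                       flagged=True)
    # initial k from the time to cover ~63% of the signal span
    target = s[0] + (0.632 if rising else -0.632) * (s[-1] - s[0])
    reached = np.nonzero((s >= target) if rising else (s <= target))[0]
    t63 = t[reached[0]] if len(reached) and t[reached[0]] > 0 else t[-1] / 3
    k0 = 1.0 / max(t63, 1e-12)
    model = _rising if rising else _falling
    if rising:
        p0 = [s[-1] - s[0], k0, s[0]]
    else:
        p0 = [s[0] - s[-1], k0, s[-1]]
    try:
        popt, pcov = curve_fit(
            model, t, s, p0=p0,
            bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        resid = float(np.sum((s - model(t, *p0)) ** 2))
        raise FitError(f"exponential fit failed: {exc}",
                       diagnostics={"residual_ss": resid, "p0": p0}) from exc
    a, k, c = popt
    perr = np.sqrt(np.diag(pcov))
    fitted = model(t, *popt)
    ss_res = float(np.sum((s - fitted) ** 2))
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    flagged = not np.isfinite(perr[1]) or (
        abs(a) < 3 * np.sqrt(ss_res / max(len(s) - 3, 1))
    )
    return RateFit(k=float(k), amplitude=float(a), offset=float(c),
                   k_stderr=float(perr[1]), r_squared=r2,
                   direction="rising" if rising else "falling", flagged=flagged)


def rate_vs_gradient(points) -> tuple[float, float, float]:
    """OLS of mean rate against concentration gradient.

    ``points`` is a sequence of (gradient, k) or (gradient, k, sd) tuples
    (sd is carried for presentation only).  Returns (slope, intercept, r).
    """
    pts = [tuple(p) for p in points]
    if len(pts) < 3:
        raise DomainError("rate-vs-gradient regression needs >= 3 points")
    g = np.array([p[0] for p in pts], dtype=float)
    k = np.array([p[1] for p in pts], dtype=float)
    if np.allclose(g, g[0]):
        raise DomainError("all gradients equal: singular design")
    res = linregress(g, k)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def nh3_gradient(total_ammonium: float, pH: float, pKa: float = NH4_PKA) -> float:
    """Free-NH3 concentration from total ammonium via Henderson-Hasselbalch."""
    if total_ammonium <= 0:
        raise DomainError("total ammonium must be positive")
    if not 0 < pH < 14:
        raise DomainError("pH must be in (0, 14)")
    return total_ammonium / (1.0 + 10.0 ** (pKa - pH))


# ---------------------------------------------------------------------------
# Background correction and specificity
# ---------------------------------------------------------------------------

def background_correct(rate: float, background: float) -> float:
    """Subtract the empty-vector rate; negative results clip to zero."""
    if not (np.isfinite(rate) and np.isfinite(background)):
        raise DomainError("rates must be finite")
    if rate < 0 or background < 0:
        raise DomainError("rates must be non-negative")
    return max(rate - background, 0.0)


def corrected_se(rate_se: float, background_se: float) -> float:
    """SE of a background-corrected rate (quadrature of fit and background SE)."""
    return math.hypot(rate_se, background_se)


def _significant(value: float, se: float,
                 floor: float = SIGNIFICANCE_FLOOR) -> bool:
    return value >= max(3.0 * se, floor)


def specificity_ratio(
    corr_ammonia: float,
    se_ammonia: float,
    corr_water: float,
    se_water: float,
    floor: float = SIGNIFICANCE_FLOOR,
):
    """Ammonia/water specificity ratio with propagated SE (table units, x 1e-2).

    Returns ``(ratio, se, infinite)``.  ratio is None (NA) when both
    corrected rates are insignificant; when water is exactly zero but
    ammonia is significant, the infinite-ratio flag is set and the numeric
    ratio is None.
    """
    if corr_ammonia < 0 or corr_water < 0:
        raise DomainError("corrected rates must be non-negative")
    water_ok = _significant(corr_water, se_water, floor)
    ammonia_ok = _significant(corr_ammonia, se_ammonia, floor)
    if corr_water == 0:
        return (None, None, True) if ammonia_ok else (None, None, False)
    if not water_ok and not ammonia_ok:
        return None, None, False
    if corr_ammonia == 0:
        return 0.0, 0.0, False
    ratio = corr_ammonia / corr_water
    se = ratio * math.sqrt(
        (se_ammonia / corr_ammonia) ** 2 + (se_water / corr_water) ** 2
    )
    return float(ratio), float(se), False


def classify_construct(
    ratio: float | None,
    reference_ratio: float,
    infinite: bool = False,
    like_band: float = LIKE_BAND,
    reference_name: str = "AtTIP2;1",
) -> str:
    """Classify by comparing the specificity ratio to the reference channel.

    Ratios within ``like_band`` (relative) of the reference are
    reference-like; higher means ammonia specificity, lower (including zero)
    water specificity; NA when the ratio is undefined.
    """
    if reference_ratio <= 0:
        raise DomainError("reference ratio must be positive")
    if infinite:
        return "Ammonia"
    if ratio is None:
        return "NA"
    if abs(ratio - reference_ratio) <= like_band * reference_ratio:
        return f"{reference_name}-like"
    return "Ammonia" if ratio > reference_ratio else "Water"


def build_specificity_table(
    rates: list[ConstructRates] | pd.DataFrame,
    background: str,
    reference: str,
    like_band: float = LIKE_BAND,
    floor: float = SIGNIFICANCE_FLOOR,
) -> pd.DataFrame:
    """Full background-corrected specificity table for a construct panel.

    ``rates`` carries raw per-construct rates (ammonia in 1e-2 s^-1, water in
    s^-1) with standard errors; the row named ``background`` supplies the
    empty-vector rates and is excluded from the output; ``reference`` names
    the channel whose ratio anchors the classification.
    """
    if isinstance(rates, pd.DataFrame):
        rows = [
            ConstructRates(
                construct=r.construct,
                filter_code=getattr(r, "filter_code", None),
                ammonia_rate=float(r.ammonia_rate),
                ammonia_se=float(r.ammonia_se),
                water_rate=float(r.water_rate),
                water_se=float(r.water_se),
            )
            for r in rates.itertuples(index=False)
        ]
    else:
        rows = list(rates)
    by_name = {r.construct: r for r in rows}
    if background not in by_name:
        raise DomainError(f"background construct {background!r} not in table")
    if reference not in by_name:
        raise DomainError(f"reference construct {reference!r} not in table")
    bg = by_name[background]

    def corrected(r: ConstructRates):
        ca = background_correct(r.ammonia_rate, bg.ammonia_rate)
        cw = background_correct(r.water_rate, bg.water_rate)
        return (ca, corrected_se(r.ammonia_se, bg.ammonia_se),
                cw, corrected_se(r.water_se, bg.water_se))

    ref_ca, ref_sa, ref_cw, ref_sw = corrected(by_name[reference])
    ref_ratio, _, _ = specificity_ratio(ref_ca, ref_sa, ref_cw, ref_sw, floor)

    out = []
    for r in rows:
        if r.construct == background:
            continue
        ca, sa, cw, sw = corrected(r)
        ratio, ratio_se, infinite = specificity_ratio(ca, sa, cw, sw, floor)
        if ref_ratio is None or ref_ratio <= 0:
            call = "NA"  # no anchor: the reference shows no transport
        else:
            call = classify_construct(ratio, ref_ratio, infinite, like_band,
                                      reference_name=reference)
        out.append(
            SpecificityRow(
                construct=r.construct,
                filter_code=r.filter_code,
                corrected_ammonia=ca,
                corrected_ammonia_se=sa,
                corrected_water=cw,
                corrected_water_se=sw,
                ratio=ratio,
                ratio_se=ratio_se,
                call=call,
                infinite_ratio=infinite,
            )
        )
    return pd.DataFrame([row.__dict__ for row in out])


def round_sig(x: float, sig: int) -> float:
    """Round to the given number of significant figures (table presentation)."""
    if x == 0 or not np.isfinite(x):
        return x
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1)))
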
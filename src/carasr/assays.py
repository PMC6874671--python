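"""Quantitative enzyme characterization: initial rates, Michaelis–Menten and
substrate-inhibition kinetics, the bell-shaped pH–activity model, thermal
A50, half-life, DSF melting temperature, and activity significance calls.

The assay readout throughout is NADPH depletion followed by absorbance at
340 nm: traces are blank-subtracted, converted to µM NADPH through a
standard curve, and the initial linear window's slope gives the rate in
µM·min⁻¹.  Rates over a substrate dilution series are fitted to

    v = Vmax·S/(KM + S)              (Michaelis–Menten), or
    v = Vmax·S/(KM + S·(1 + S/Ki))   (substrate inhibition),

with kcat = Vmax/[E].  The pH dependence of activity follows the diprotic
bell model v = V100 / (h/K1 + 1 + K2/h) with h the proton concentration;
K1 and K2 are the proton concentrations where activity falls to 50% on the
acidic and alkaline flanks (pK = −log10 K).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


class FitError(RuntimeError):
    """Raised when a curve fit cannot be performed or does not converge."""


# ---------------------------------------------------------------------------
# traces and standard curve
# ---------------------------------------------------------------------------


@dataclass
class PlateTrace:
    """One well's absorbance-versus-time trace at 340 nm."""

    time_s: np.ndarray
    a340: np.ndarray
    substrate: str = ""
    concentration: float = 0.0
    enzyme_uM: float = 0.0
    replicate: int = 0
    blank: bool = False

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.a340 = np.asarray(self.a340, dtype=float)
        if self.time_s.shape != self.a340.shape:
            raise ValueError("time and absorbance tracks differ in length")
        if self.time_s.size < 4:
            raise ValueError("a trace needs at least 4 points")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time points must be strictly increasing")


@dataclass
class StandardCurve:
    """Linear NADPH standard curve: A340 = slope·[NADPH] + intercept."""

    slope: float  # absorbance per µM NADPH
    intercept: float
    r_squared: float

    def to_concentration(self, a340: np.ndarray) -> np.ndarray:
        return (np.asarray(a340) - self.intercept) / self.slope


def fit_standard_curve(concentrations, absorbances) -> StandardCurve:
    """Ordinary least-squares standard curve over >= 3 distinct concentrations."""
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if np.unique(c).size < 3:
        raise ValueError("standard curve needs at least 3 distinct concentrations")
    if np.ptp(c) == 0:
        raise ValueError("zero variance in concentrations")
    res = stats.linregress(c, a)
    if res.slope <= 0:
        raise FitError("standard curve slope must be positive")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


@dataclass
class InitialRate:
    """Initial NADPH-consumption rate with the window actually used."""

    rate: float  # µM·min⁻¹, positive when NADPH is consumed
    window: tuple[int, int]
    r_squared: float
    low_confidence: bool = False


def initial_rate(
    trace: PlateTrace,
    curve: StandardCurve,
    blank: PlateTrace | None = None,
    min_points: int = 4,
    r2_floor: float = 0.98,
) -> InitialRate:
    """Slope of the initial linear window of a blank-subtracted trace.

    The default window policy considers every prefix of at least
    ``min_points`` points whose linear fit reaches R² >= ``r2_floor`` and
    uses the most linear one (maximal R², longer prefix on ties) — short,
    near-perfectly-linear windows win on curved progress traces, long ones
    on noisy linear traces.  If no prefix qualifies, the first quarter of
    the points (at least ``min_points``) is used and the result flagged
    low-confidence.  The sign is flipped so that NADPH consumption is a
    positive rate.
    """
    a = trace.a340
    if blank is not None:
        lo = max(trace.time_s[0], blank.time_s[0])
        hi = min(trace.time_s[-1], blank.time_s[-1])
        if lo > hi:
            raise ValueError("trace and blank time ranges do not overlap")
        a = a - np.interp(trace.time_s, blank.time_s, blank.a340)
    conc = (a - curve.intercept) / curve.slope if blank is None else a / curve.slope
    t_min = trace.time_s / 60.0

    n = conc.size
    best = None
    for end in range(min_points, n + 1):
        res = stats.linregress(t_min[:end], conc[:end])
        r2 = res.rvalue**2 if np.ptp(conc[:end]) > 0 else 1.0
        if r2 >= r2_floor and (best is None or r2 >= best[2]):
            best = (end, res, r2)
    if best is not None:
        end, res, r2 = best
        slope = res.slope if np.ptp(conc[:end]) > 0 else 0.0
        return InitialRate(rate=-float(slope), window=(0, end), r_squared=float(r2))
    end = max(min_points, int(np.ceil(n * 0.25)))
    res = stats.linregress(t_min[:end], conc[:end])
    return InitialRate(
        rate=-float(res.slope),
        window=(0, end),
        r_squared=float(res.rvalue**2),
        low_confidence=True,
    )


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


@dataclass
class KineticDataset:
    """Initial rates over a substrate dilution series.

    Concentrations carry their unit (µM or mM); rates are µM NADPH·min⁻¹;
    replicate rates at one concentration are kept, not pre-averaged.
    """

    concentrations: np.ndarray
    rates: np.ndarray
    enzyme_uM: float
    unit: str = "µM"
    substrate: str = ""

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.concentrations.shape != self.rates.shape:
            raise ValueError("concentrations and rates differ in length")
        if (self.concentrations < 0).any():
            raise ValueError("concentrations must be >= 0")
        if not self.enzyme_uM > 0:
            raise ValueError("enzyme concentration must be positive")


def michaelis_menten(S, Vmax, KM):
    return Vmax * S / (KM + S)


def substrate_inhibition(S, Vmax, KM, Ki):
    return Vmax * S / (KM + S * (1.0 + S / Ki))


@dataclass
class KineticFit:
    """Fitted kinetic constants with fit-covariance standard errors."""

    model: str  # 'MM' or 'MM+SI'
    Vmax: float
    kcat: float  # min⁻¹
    KM: float
    Ki: float | None
    efficiency: float  # kcat / KM, min⁻¹ · unit⁻¹
    unit: str
    se: dict = field(default_factory=dict)
    trimmed: list[float] = field(default_factory=list)


def catalytic_efficiency(kcat: float, KM: float) -> float:
    """kcat / KM in min⁻¹ per concentration unit of KM."""
    if kcat <= 0 or KM <= 0:
        raise ValueError("kcat and KM must be positive")
    return kcat / KM


def _mm_initial_values(S, v):
    Vmax0 = float(np.max(v))
    half = Vmax0 / 2.0
    order = np.argsort(S)
    Ss, vs = S[order], v[order]
    KM0 = float(Ss[np.argmin(np.abs(vs - half))])
    above = np.where(vs >= half)[0]
    if above.size and above[0] > 0:
        i = above[0]
        f = (half - vs[i - 1]) / (vs[i] - vs[i - 1])
        KM0 = float(Ss[i - 1] + f * (Ss[i] - Ss[i - 1]))
    return Vmax0, max(KM0, np.min(Ss[Ss > 0], initial=1e-6))


def _trim_inhibited_points(S, v, trimmed, min_distinct=5, depression=0.03):
    """Drop substrate-inhibited concentrations; record them in ``trimmed``.

    Primary criterion: fit the substrate-inhibition model to the full series
    and drop concentrations where the inhibition term lowers the rate by
    more than ``depression`` relative to Michaelis–Menten with the same
    Vmax/KM.  Fallback when that fit is unavailable: drop everything above
    the empirical rate peak.  Either way a residual-based guard then drops
    the top concentration while its mean residual under the plain fit is
    negative and beyond 2x the residual SD.  Never trims below
    ``min_distinct`` distinct concentrations.
    """
    si_done = False
    if np.unique(S).size >= 6:
        try:
            p0 = _mm_initial_values(S, v) + (float(np.max(S)),)
            (Vm, KM, Ki), _ = optimize.curve_fit(
                substrate_inhibition, S, v, p0=p0, maxfev=40000
            )
            if Ki > 0 and KM > 0:
                ratio = (KM + S) / (KM + S * (1.0 + S / Ki))
                keep = ratio >= 1.0 - depression
                while np.unique(S[keep]).size < min_distinct:
                    keep |= S == np.min(S[~keep])
                trimmed.extend(sorted(set(S[~keep]), reverse=True))
                S, v = S[keep], v[keep]
                si_done = True
        except RuntimeError:
            pass
    if not si_done:
        means = {s: float(np.mean(v[S == s])) for s in np.unique(S)}
        peak = max(means, key=means.get)
        keep = S <= peak
        while np.unique(S[keep]).size < min_distinct and (~keep).any():
            keep |= S == np.min(S[~keep])
        trimmed.extend(sorted(set(S[~keep]), reverse=True))
        S, v = S[keep], v[keep]
    while np.unique(S).size > min_distinct:
        try:
            popt, _ = optimize.curve_fit(
                michaelis_menten, S, v, p0=_mm_initial_values(S, v), maxfev=20000
            )
        except RuntimeError:
            break
        resid = v - michaelis_menten(S, *popt)
        sd = float(np.std(resid, ddof=2)) if resid.size > 2 else 0.0
        top = float(np.max(S))
        top_resid = float(np.mean(resid[S == top]))
        if sd > 0 and top_resid < 0 and abs(top_resid) > 2.0 * sd:
            trimmed.append(top)
            keepm = S < top
            S, v = S[keepm], v[keepm]
        else:
            break
    return S, v


def fit_kinetics(
    data: KineticDataset,
    model: str = "MM",
    trim_inhibited: bool = False,
) -> KineticFit:
    """Nonlinear least-squares fit of a dilution-series rate dataset.

    ``trim_inhibited`` removes concentrations that show substrate inhibition
    before the (plain) fit: a substrate-inhibition pre-fit identifies
    concentrations where the fitted inhibition term depresses the rate by
    more than 3%, which are dropped (never below 5 distinct concentrations);
    when the pre-fit is unavailable, concentrations above the empirical rate
    peak are dropped instead, and a residual-based guard then iteratively
    drops the top concentration while its mean residual under the
    Michaelis–Menten fit is negative and exceeds twice the residual SD.
    """
    if model not in ("MM", "MM+SI"):
        raise ValueError("model must be 'MM' or 'MM+SI'")
    S = data.concentrations.copy()
    v = data.rates.copy()
    if np.all(v == 0):
        raise ValueError("all rates are zero; nothing to fit")
    min_conc = 5 if model == "MM" else 6
    trimmed: list[float] = []

    def distinct(S_):
        return np.unique(S_).size

    if distinct(S) < min_conc:
        raise ValueError(
            f"{model} fit needs >= {min_conc} distinct concentrations, got {distinct(S)}"
        )

    def mm_fit(S_, v_):
        p0 = _mm_initial_values(S_, v_)
        popt, pcov = optimize.curve_fit(
            michaelis_menten, S_, v_, p0=p0, maxfev=20000
        )
        return popt, pcov

    if trim_inhibited:
        S, v = _trim_inhibited_points(S, v, trimmed)

    try:
        if model == "MM":
            popt, pcov = mm_fit(S, v)
            Vmax, KM = popt
            Ki = None
        else:
            Vmax0, KM0 = _mm_initial_values(S, v)
            p0 = (Vmax0, KM0, float(np.max(S)))
            popt, pcov = optimize.curve_fit(
                substrate_inhibition, S, v, p0=p0, maxfev=40000
            )
            Vmax, KM, Ki = popt
    except RuntimeError as exc:
        raise FitError(
            f"kinetic fit did not converge (model={model}, n={S.size}, "
            f"initial values from max rate / half-max interpolation): {exc}"
        ) from exc
    if Vmax <= 0 or KM <= 0:
        raise FitError(f"non-physical fit: Vmax={Vmax:.3g}, KM={KM:.3g}")

    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    kcat = Vmax / data.enzyme_uM
    se = dict(Vmax=float(perr[0]), KM=float(perr[1]), kcat=float(perr[0] / data.enzyme_uM))
    if Ki is not None:
        se["Ki"] = float(perr[2])
    return KineticFit(
        model=model,
        Vmax=float(Vmax),
        kcat=float(kcat),
        KM=float(KM),
        Ki=None if Ki is None else float(Ki),
        efficiency=catalytic_efficiency(kcat, float(KM)),
        unit=data.unit,
        se=se,
        trimmed=trimmed,
    )


# ---------------------------------------------------------------------------
# pH profile
# ---------------------------------------------------------------------------


def ph_rate_model(pH, V100, pK1, pK2):
    """Diprotic bell: v = V100 / (h/K1 + 1 + K2/h) with h = 10^(−pH)."""
    return V100 / (10.0 ** (pK1 - np.asarray(pH)) + 1.0 + 10.0 ** (np.asarray(pH) - pK2))


@dataclass
class PHFit:
    """Fitted bell-model parameters; pK = −log10 of a proton concentration."""

    V100: float
    pK1: float
    pK2: float
    se: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def K1(self) -> float:
        return 10.0**-self.pK1

    @property
    def K2(self) -> float:
        return 10.0**-self.pK2


def _half_crossings(pH, act):
    """Interpolated pH values where activity crosses half its maximum."""
    order = np.argsort(pH)
    x, y = np.asarray(pH, float)[order], np.asarray(act, float)[order]
    half = y.max() / 2.0
    peak = int(np.argmax(y))
    left = right = None
    for i in range(peak, 0, -1):
        if (y[i] - half) * (y[i - 1] - half) <= 0 and y[i] >= half:
            f = (half - y[i - 1]) / (y[i] - y[i - 1])
            left = x[i - 1] + f * (x[i] - x[i - 1])
            break
    for i in range(peak, len(y) - 1):
        if (y[i] - half) * (y[i + 1] - half) <= 0 and y[i] >= half:
            f = (y[i] - half) / (y[i] - y[i + 1])
            right = x[i] + f * (x[i + 1] - x[i])
            break
    return left, right


def fit_ph_profile(pH, activities) -> PHFit:
    """Fit the diprotic bell model to a pH–relative-activity profile.

    Initial values come from the interpolated half-maximum crossings.  A
    flank that shows essentially no decline within the sampled range (the
    extreme point still >= 90% of the maximum) leaves its pK unidentifiable:
    the fit is one-sided and that pK is reported at the corresponding pH
    bound with a warning.  A flank that declines without crossing 50% is
    still fitted (mild model-based extrapolation).
    """
    pH = np.asarray(pH, dtype=float)
    act = np.asarray(activities, dtype=float)
    if pH.size < 6:
        raise ValueError("pH profile needs at least 6 points")
    warns: list[str] = []
    if np.ptp(act) == 0:
        return PHFit(
            V100=float(act[0] if act.size else 0.0),
            pK1=float(pH.min()),
            pK2=float(pH.max()),
            warnings=["flat profile: pKs unidentifiable, reported at the pH bounds"],
        )
    left, right = _half_crossings(pH, act)
    order = np.argsort(pH)
    amax = act.max()
    acid_missing = act[order][0] >= 0.9 * amax
    alk_missing = act[order][-1] >= 0.9 * amax
    if acid_missing:
        warns.append("acidic flank shows no decline: pK1 reported as lower bound")
    if alk_missing:
        warns.append("alkaline flank shows no decline: pK2 reported as upper bound")
    pK1_0 = left if left is not None else float(pH.min()) - 1.0
    pK2_0 = right if right is not None else float(pH.max()) + 1.0
    p0 = (float(act.max()), pK1_0, pK2_0)
    try:
        popt, pcov = optimize.curve_fit(ph_rate_model, pH, act, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"pH-profile fit did not converge (p0={p0}): {exc}") from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    fit = PHFit(
        V100=float(popt[0]),
        pK1=float(popt[1]),
        pK2=float(popt[2]),
        se=dict(V100=float(perr[0]), pK1=float(perr[1]), pK2=float(perr[2])),
        warnings=warns,
    )
    if acid_missing:
        fit.pK1 = float(pH.min())
    if alk_missing:
        fit.pK2 = float(pH.max())
    return fit


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------


@dataclass
class StabilityResult:
    """A50/C50/half-life/Tm with the method used and an unbounded marker.

    ``value`` is None when the 50% level is never reached; ``marker`` then
    carries the ``"> max condition"``-style bound.
    """

    kind: str  # 'A50', 'C50', 'half-life', 'Tm'
    value: float | None
    method: str
    marker: str | None = None
    meta: dict = field(default_factory=dict)


def activity_threshold(
    conditions, activities, level: float = 50.0, kind: str = "A50"
) -> StabilityResult:
    """Interpolated condition at which activity falls to ``level`` percent.

    Points are sorted by condition; the crossing searched for is the first
    decreasing pass through ``level`` at or after the condition of maximal
    activity.  Multiple crossings are flagged; a profile that never reaches
    the level returns an unbounded ``"> max"`` marker instead of a number.
    """
    x = np.asarray(conditions, dtype=float)
    y = np.asarray(activities, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 condition points")
    order = np.argsort(x)
    x, y = x[order], y[order]
    crossings = [
        i for i in range(x.size - 1) if (y[i] - level) * (y[i + 1] - level) <= 0
        and (y[i] - level) != (y[i + 1] - level)
    ]
    peak = int(np.argmax(y))
    usable = [i for i in crossings if i >= peak and y[i] >= level >= y[i + 1]]
    if not usable:
        return StabilityResult(
            kind=kind,
            value=None,
            method="interpolation",
            marker=f">{x.max():g}",
            meta=dict(level=level),
        )
    i = usable[0]
    f = (y[i] - level) / (y[i] - y[i + 1])
    value = float(x[i] + f * (x[i + 1] - x[i]))
    return StabilityResult(
        kind=kind,
        value=value,
        method="interpolation",
        meta=dict(level=level, multiple_crossings=len(usable) > 1),
    )


def half_life(times, activities, method: str = "exponential") -> StabilityResult:
    """Time to 50% residual activity, in the units of ``times``.

    ``exponential`` fits A(t) = 100·exp(−k·t) and returns ln2/k;
    ``interpolation`` brackets the 50% crossing linearly.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(activities, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    order = np.argsort(t)
    t, a = t[order], a[order]
    if t[0] != 0:
        raise ValueError("half-life profiles must include the t=0 reference point")
    fit_slope = stats.linregress(t, a).slope
    if fit_slope >= 0:
        raise FitError("activity does not decay over time; no half-life")
    if method == "interpolation":
        res = activity_threshold(t, a, level=50.0, kind="half-life")
        res.method = "interpolation"
        return res
    if method != "exponential":
        raise ValueError("method must be 'exponential' or 'interpolation'")

    def decay(t_, k):
        return 100.0 * np.exp(-k * t_)

    k0 = 0.693 / max(t[-1] / 2.0, 1e-9)
    popt, pcov = optimize.curve_fit(decay, t, a, p0=(k0,), maxfev=20000)
    k = float(popt[0])
    if k <= 0:
        raise FitError("fitted decay constant is non-positive")
    se_k = float(np.sqrt(max(pcov[0, 0], 0.0)))
    return StabilityResult(
        kind="half-life",
        value=float(np.log(2.0) / k),
        method="exponential fit",
        meta=dict(k=k, se_k=se_k),
    )


def dsf_tm(temperatures, fluorescence, smooth_window: int = 5) -> StabilityResult:
    """Melting temperature from the derivative peak of a DSF melt curve.

    The fluorescence track is smoothed by a centered moving average, the
    first derivative dF/dT taken, and the temperature of its interior
    maximum refined by a three-point quadratic.  A curve whose derivative
    has no interior maximum (e.g. a linear ramp) raises :class:`FitError`.
    """
    T = np.asarray(temperatures, dtype=float)
    F = np.asarray(fluorescence, dtype=float)
    if T.size < 20:
        raise ValueError("DSF needs at least 20 points over the ramp")
    if not (np.all(np.diff(T) > 0) or np.all(np.diff(T) < 0)):
        raise ValueError("temperature ramp must be monotone")
    if np.all(np.diff(T) < 0):
        T, F = T[::-1], F[::-1]
    w = max(1, int(smooth_window))
    if w > 1:
        kernel = np.ones(w) / w
        pad = w // 2
        Fp = np.pad(F, pad, mode="edge")
        F = np.convolve(Fp, kernel, mode="valid")[: T.size]
    dF = np.gradient(F, T)
    interior = slice(1, T.size - 1)
    i = 1 + int(np.argmax(dF[interior]))
    prominence = dF[i] - np.median(dF)
    if i <= 1 or i >= T.size - 2 or prominence <= 0.05 * max(np.ptp(dF), 1e-30):
        raise FitError("melt-curve derivative has no interior maximum")
    y0, y1, y2 = dF[i - 1], dF[i], dF[i + 1]
    denom = y0 - 2 * y1 + y2
    tm = T[i]
    if denom < 0:
        h = (T[i + 1] - T[i - 1]) / 2.0
        tm = T[i] - 0.5 * h * (y2 - y0) / denom
    return StabilityResult(
        kind="Tm",
        value=float(tm),
        method="derivative peak",
        meta=dict(window=w, peak_index=i),
    )


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

#: Significance bands used on activity-screen figures: (upper p bound, stars).
STAR_BANDS = (
    (1e-6, "****"),
    (1e-5, "***"),
    (1e-4, "**"),
    (1e-3, "*"),
)


def significance_stars(p: float) -> str:
    for bound, stars in STAR_BANDS:
        if p <= bound:
            return stars
    return "ns"


@dataclass
class SignificanceResult:
    t: float
    p: float
    stars: str


def activity_significance(sample_rates, control_rates) -> SignificanceResult:
    """Welch two-sample t-test of enzyme rates against no-enzyme controls.

    Star bands: **** P <= 1e-6; *** 1e-6 < P <= 1e-5; ** 1e-5 < P <= 1e-4;
    * 1e-4 < P <= 1e-3; ns above 1e-3.  Two identical zero-variance groups
    return p = 1 rather than raising.
    """
    a = np.asarray(sample_rates, dtype=float)
    b = np.asarray(control_rates, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 replicates in each group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return SignificanceResult(t=0.0, p=1.0, stars="ns")
        return SignificanceResult(t=np.inf if a[0] > b[0] else -np.inf, p=0.0, stars="****")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return SignificanceResult(t=float(t), p=float(p), stars=significance_stars(float(p)))
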
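"""Kinetic parameter extraction from oxygen-uptake traces.

Given a test trace, an antioxidant-free control and a reference trace
(or a known initiation rate), this module produces the standard
report of an inhibited-autoxidation experiment: the pre-injection
rate R_ox1, the inhibited rate R_inh, the post-inhibition rate R_ox2,
the induction period tau, the initiation rate Ri (calibrated from the
reference antioxidant via tau = n [AoxH]0 / Ri), kinetic chain
lengths nu = R/Ri, the stoichiometric factor n, and k_inh from the
integrated inhibited rate law (oxygen uptake regressed against
-ln(1 - t/tau)).  A rule-based classifier labels each compound as
reference / antioxidant / retarder / inactive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from lipoxkin.chain_kinetics import (
    ChainParams,
    chain_length,
    format_chain_length,
    stoichiometric_n,
)
from lipoxkin.oximetry_sim import OxTrace


class AnalysisError(RuntimeError):
    """A trace-analysis stage could not produce its estimate."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the extraction pipeline.

    ``eq2_window`` is the fractional range of tau used for the
    integrated-rate-law regression; the defaults avoid the injection
    transient and the logarithmic divergence near tau.
    ``kinh_ratio_min`` encodes the classification rule that an active
    antioxidant needs k_inh well above the propagation rate constant
    (k_inh >= 100 kp); ``retard_frac`` labels a compound a retarder
    when its inhibited rate is at most that fraction of the control
    rate.  ``tau_slope_ratio_min`` is the minimum steep/inhibited
    slope ratio for an induction period to count as detected.
    """

    smooth_window: int = 5
    rate_window_frac: tuple[float, float] = (0.3, 0.8)
    eq2_window: tuple[float, float] = (0.10, 0.80)
    tau_method: str = "tangent_intersection"
    kinh_ratio_min: float = 100.0
    retard_frac: float = 0.90
    #: weak antioxidants show only a slight inflection (steep/inhibited
    #: slope ratio ~2.5) while true retarders sit near 1.1; 2.0 splits
    #: the two regimes.
    tau_slope_ratio_min: float = 2.0
    min_r2: float = 0.99
    #: subtract the constant initiation O2 uptake (Ri * t) before the
    #: integrated-rate-law regression, when the trace metadata says it
    #: was recorded; without it k_inh is biased low whenever the
    #: inhibited chain rate is comparable to Ri.
    subtract_initiation_uptake: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.eq2_window
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("eq2_window bounds must satisfy 0 < lo < hi < 1")
        if self.tau_method not in ("tangent_intersection", "second_derivative"):
            raise ValueError(f"unknown tau_method {self.tau_method!r}")
        if min(self.kinh_ratio_min, self.retard_frac,
               self.tau_slope_ratio_min) <= 0:
            raise ValueError("classification thresholds must be positive")


@dataclass(frozen=True)
class InductionEstimate:
    """Detected induction period; ``tau`` is None when no induction
    (retardation or control behaviour)."""

    tau: float | None
    method: str
    window: tuple[float, float] | None = None
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Eq2Fit:
    """OLS fit of O2 uptake vs -ln(1 - t/tau): slope = kp[LH]/k_inh."""

    slope: float
    intercept: float
    r2: float
    kinh: float
    window: tuple[float, float]
    reliable: bool


@dataclass
class KineticReport:
    """Table-shaped kinetic summary for one compound.

    Rates in M/s; tau in s; None marks a quantity the trace does not
    support (no induction period -> no tau, n, k_inh).
    """

    compound: str
    Rox1: float
    Rinh: float | None
    Rox2: float | None
    tau: float | None
    Ri: float
    nu_ox1: float | None = None
    nu_inh: float | None = None
    nu_ox2: float | None = None
    n_stoich: float | None = None
    kinh: float | None = None
    classification: str = "inactive"
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-ready dict with boundary units (nM/s, min)."""
        def nms(x):
            return None if x is None else round(x * 1e9, 3)
        return {
            "compound": self.compound,
            "Rox1_nM_s": nms(self.Rox1),
            "Rinh_nM_s": nms(self.Rinh),
            "Rox2_nM_s": nms(self.Rox2),
            "tau_min": None if self.tau is None else round(self.tau / 60.0, 2),
            "Ri_nM_s": nms(self.Ri),
            "nu_ox1": None if self.nu_ox1 is None else float(
                format_chain_length(self.nu_ox1)),
            "nu_inh": None if self.nu_inh is None else float(
                format_chain_length(self.nu_inh)),
            "nu_ox2": None if self.nu_ox2 is None else float(
                format_chain_length(self.nu_ox2)),
            "n_stoich": None if self.n_stoich is None else round(
                self.n_stoich, 2),
            "kinh_M_s": None if self.kinh is None else float(
                f"{self.kinh:.3g}"),
            "classification": self.classification,
            "provenance": self.provenance,
        }


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, r^2 of y on t."""
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def estimate_rate(trace: OxTrace, window: tuple[float, float]) -> float:
    """O2-uptake rate, M/s: negated least-squares slope of O2 vs time
    over the window, clipped at zero."""
    t_lo, t_hi = window
    sel = (trace.times >= t_lo) & (trace.times <= t_hi)
    if sel.sum() < 5:
        raise AnalysisError(
            f"rate window [{t_lo}, {t_hi}] s contains {int(sel.sum())} "
            "samples; need >= 5"
        )
    slope, _, _ = _ols(trace.times[sel], trace.o2[sel])
    return max(-slope, 0.0)


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    out = np.convolve(ypad, kernel, mode="same")[pad:pad + y.size]
    return out


def _eq2_r2(t: np.ndarray, u: np.ndarray, tau: float) -> float:
    x = -np.log1p(-t / tau)
    _, _, r2 = _ols(x, u)
    return r2


def _refine_tau_eq2(t: np.ndarray, u: np.ndarray, tau0: float,
                    config: AnalysisConfig) -> float:
    """Refine tau by maximizing the linearity (r^2) of uptake against
    -ln(1 - t/tau) over the configured induction-phase window.

    Line intersections locate the slope break only to within the
    radical-pool relaxation time; the induction-phase data itself
    pins tau much more sharply because the divergence of the
    integrated rate law is sensitive to it.  The refinement window
    deliberately reaches closer to the divergence (0.2-0.92 tau) than
    the k_inh regression window does: the near-divergence samples
    carry most of the information about tau.
    """
    lo, hi = 0.2, 0.92
    tau = tau0
    for _ in range(3):  # re-window and re-optimize; converges fast
        w = (t >= lo * tau) & (t <= hi * tau)
        if w.sum() < 8:
            return tau
        tw, uw = t[w], u[w]
        t_max = tw[-1]
        grid = np.linspace(t_max * 1.02, max(2.5 * tau, t_max * 1.5), 60)
        r2s = [_eq2_r2(tw, uw, g) for g in grid]
        i = int(np.argmax(r2s))
        if i == grid.size - 1:
            # monotone landscape: the uptake carries no logarithmic
            # curvature (e.g. a linear inhibited phase), so the
            # linearity criterion cannot localize tau
            return tau0
        # golden-section polish around the best grid point
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, grid.size - 1)]
        gr = (math.sqrt(5) - 1) / 2
        c1, c2 = b - gr * (b - a), a + gr * (b - a)
        f1, f2 = _eq2_r2(tw, uw, c1), _eq2_r2(tw, uw, c2)
        for _ in range(40):
            if f1 < f2:
                a, c1, f1 = c1, c2, f2
                c2 = a + gr * (b - a)
                f2 = _eq2_r2(tw, uw, c2)
            else:
                b, c2, f2 = c2, c1, f1
                c1 = b - gr * (b - a)
                f1 = _eq2_r2(tw, uw, c1)
        tau_new = (a + b) / 2
        if abs(tau_new - tau) < 1e-3 * tau:
            return float(tau_new)
        tau = float(tau_new)
    return float(tau)


def detect_tau(trace: OxTrace, config: AnalysisConfig | None = None) -> InductionEstimate:
    """Locate the induction period on a post-injection trace.

    The detector first checks that the record shows a genuine slope
    break: the steep-phase slope (last quarter before O2 exhaustion)
    must exceed the inhibited-phase slope (first stretch after the
    injection) by at least ``config.tau_slope_ratio_min``; otherwise
    the behaviour is retardation and tau is absent.  A provisional
    breakpoint is the last upward crossing of the smoothed uptake
    rate through the midpoint of the two slopes.  tau itself is then
    the intersection abscissa of the inhibited and steep tangent
    lines (``tangent_intersection``) or the maximum-curvature point
    (``second_derivative``), refined in both cases by maximizing the
    linearity of uptake against -ln(1 - t/tau) over the
    induction-phase window — the integrated rate law pins tau more
    sharply than the smeared slope break does.
    """
    config = config or AnalysisConfig()
    if trace.t_aox is None:
        return InductionEstimate(None, "none", diagnostics={
            "reason": "no antioxidant injection on trace"})

    sel = trace.times >= trace.t_aox
    t = trace.times[sel] - trace.t_aox
    o2 = _smooth(trace.o2[sel], config.smooth_window)
    if t.size < 20:
        return InductionEstimate(None, config.tau_method, diagnostics={
            "reason": "too few post-injection samples"})
    span = t[-1]
    u = o2[0] - o2
    if trace.meta.get("include_initiation_uptake") and \
            config.subtract_initiation_uptake:
        ri_meta = trace.meta.get("Ri")
        if ri_meta:
            u = u - float(ri_meta) * t

    # steep-phase slope from the last quarter of the record
    late = t >= 0.75 * span
    m2, b2, _ = _ols(t[late], u[late])
    # inhibited-phase slope from the earliest post-injection stretch,
    # past any injection transient
    early = (t >= 0.03 * span) & (t <= 0.18 * span)
    m1_probe, _, _ = _ols(t[early], u[early])
    s1p, s2 = max(m1_probe, 0.0), max(m2, 0.0)
    ratio = s2 / s1p if s1p > 0 else math.inf
    diag = {"slope_inhibited_probe": s1p, "slope_steep": s2, "ratio": ratio}
    if ratio < config.tau_slope_ratio_min:
        return InductionEstimate(None, config.tau_method, diagnostics=diag)

    # provisional breakpoint: last upward crossing of the rate through
    # the midpoint of the inhibited and steep slopes (robust against
    # the radical-pool transient right after each injection).  The
    # rate scan needs smoothing scaled to the record length or
    # electrode noise swamps the slope signal.
    w_scan = max(config.smooth_window, t.size // 40)
    rate = _smooth(np.gradient(_smooth(u, w_scan), t), w_scan)
    mid = 0.5 * (s1p + s2)
    above = rate >= mid
    crossings = np.flatnonzero(~above[:-1] & above[1:])
    if crossings.size == 0:
        return InductionEstimate(None, config.tau_method, diagnostics={
            "reason": "rate never crosses slope midpoint", **diag})
    tau0 = float(t[crossings[-1] + 1])
    if not 0.02 * span < tau0 < 0.97 * span:
        return InductionEstimate(None, config.tau_method, diagnostics={
            "reason": "O2 exhausted before inflection", **diag})
    diag["tau_midpoint"] = tau0

    if config.tau_method == "second_derivative":
        curv = _smooth(np.gradient(rate, t), max(config.smooth_window, 5))
        zone = (t >= 0.4 * tau0) & (t <= min(1.6 * tau0, span))
        tau_raw = float(t[zone][np.argmax(curv[zone])])
        method = "second_derivative"
        window = (float(trace.t_aox + 0.4 * tau0),
                  float(trace.t_aox + min(1.6 * tau0, span)))
    else:
        lo, hi = config.eq2_window
        w1 = (t >= lo * tau0) & (t <= hi * tau0)
        if w1.sum() < 5:
            return InductionEstimate(None, "tangent_intersection", diagnostics={
                "reason": "inhibited phase too short", **diag})
        m1, b1, _ = _ols(t[w1], u[w1])
        if m2 <= m1:
            return InductionEstimate(None, "tangent_intersection", diagnostics={
                "reason": "no slope break at candidate point", **diag})
        tau_raw = (b2 - b1) / (m1 - m2)
        if not tau_raw > 0:
            return InductionEstimate(None, "tangent_intersection", diagnostics={
                "reason": "intersection behind injection", **diag})
        method = "tangent_intersection"
        window = (float(trace.t_aox + lo * tau0), float(trace.t_aox + span))
    diag["tau_raw"] = float(tau_raw)

    # refine on the smoothed uptake: the r^2 landscape in tau is
    # shallow, so electrode noise must be averaged down first
    tau = _refine_tau_eq2(t, _smooth(u, w_scan), float(tau_raw), config)
    # the linearity refinement is only trusted near the tangent
    # estimate; weak traps violate the integrated rate law enough to
    # let an unconstrained r^2 search drift far
    if not 0.7 * tau_raw <= tau <= 1.4 * tau_raw:
        diag["tau_refined_rejected"] = float(tau)
        tau = float(tau_raw)
    return InductionEstimate(float(tau), method + "+eq2_refine",
                             window=window, diagnostics=diag)


def calibrate_Ri(reference_trace: OxTrace, n_ref: float, conc0: float,
                 config: AnalysisConfig | None = None) -> float:
    """Initiation rate from the reference antioxidant's induction
    period: Ri = n [AoxH]0 / tau."""
    est = detect_tau(reference_trace, config)
    if est.tau is None:
        raise AnalysisError(
            "reference trace shows no induction period; cannot calibrate Ri "
            f"({est.diagnostics.get('reason', 'no inflection')})"
        )
    return n_ref * conc0 / est.tau


def fit_eq2(trace: OxTrace, tau: float, params: ChainParams,
            config: AnalysisConfig | None = None) -> Eq2Fit:
    """Extract k_inh from the integrated inhibited rate law.

    Regresses the post-injection uptake U(t) = [O2]_inj - [O2]_t on
    x = -ln(1 - (t - t_aox)/tau) over the configured fraction of the
    induction period; slope = kp [LH] / k_inh.
    """
    config = config or AnalysisConfig()
    if trace.t_aox is None:
        raise AnalysisError("trace has no antioxidant injection")
    if not tau > 0:
        raise AnalysisError("tau must be positive")
    lo, hi = config.eq2_window
    rel = trace.times - trace.t_aox
    sel = (rel >= lo * tau) & (rel <= hi * tau)
    if sel.sum() < 5:
        raise AnalysisError("integrated-rate-law window contains < 5 samples")
    o2_inj = float(np.interp(trace.t_aox, trace.times, trace.o2))
    u = o2_inj - trace.o2[sel]
    if config.subtract_initiation_uptake and trace.meta.get(
            "include_initiation_uptake"):
        u = u - float(trace.meta.get("Ri", params.Ri)) * rel[sel]
    x = -np.log1p(-rel[sel] / tau)
    slope, intercept, r2 = _ols(x, u)
    if slope <= 0:
        raise AnalysisError("non-positive uptake slope; not an inhibited phase")
    kinh = params.kp * params.LH0 / slope
    return Eq2Fit(slope=slope, intercept=intercept, r2=r2, kinh=kinh,
                  window=(lo * tau, hi * tau), reliable=r2 >= config.min_r2)


def classify(*, tau: float | None, kinh: float | None, Rinh: float | None,
             Rox1_control: float, kp: float, is_reference: bool = False,
             config: AnalysisConfig | None = None) -> str:
    """Label a compound's kinetic behaviour.

    reference: the designated calibration standard.  antioxidant: an
    induction period is present and k_inh >= kinh_ratio_min * kp.
    retarder: no induction period but the inhibited rate is at most
    retard_frac of the control rate.  inactive otherwise.  Boundary
    equalities resolve toward the stronger class.
    """
    config = config or AnalysisConfig()
    if not Rox1_control > 0:
        raise AnalysisError("control rate Rox1 is required for classification")
    if is_reference:
        return "reference"
    if tau is not None and kinh is not None and kinh >= config.kinh_ratio_min * kp:
        return "antioxidant"
    if Rinh is not None and Rinh <= config.retard_frac * Rox1_control:
        return "retarder"
    return "inactive"


def _pre_injection_rate(trace: OxTrace, config: AnalysisConfig) -> tuple[float, tuple[float, float]]:
    """R_ox1: slope of the uninhibited phase between initiation and
    antioxidant injection (or over the configured fraction of the
    whole post-initiation record for a control)."""
    t_end = trace.t_aox if trace.t_aox is not None else trace.times[-1]
    lo_f, hi_f = config.rate_window_frac
    span = t_end - trace.t_init
    window = (trace.t_init + lo_f * span, trace.t_init + hi_f * span)
    return estimate_rate(trace, window), window


def analyze_trace(
    test: OxTrace,
    control: OxTrace,
    reference: OxTrace | float,
    params: ChainParams,
    config: AnalysisConfig | None = None,
    *,
    is_reference: bool = False,
    reference_n: float = 2.0,
    reference_conc0: float = 1e-6,
) -> KineticReport:
    """Full extraction pipeline for one compound.

    ``reference`` is either the reference-antioxidant trace (Ri is
    calibrated from its induction period) or a known Ri in M/s.
    """
    config = config or AnalysisConfig()
    if isinstance(reference, OxTrace):
        Ri = calibrate_Ri(reference, reference_n, reference_conc0, config)
    else:
        Ri = float(reference)
    if not Ri > 0:
        raise AnalysisError("initiation rate Ri must be positive")

    Rox1_control, ctrl_window = _pre_injection_rate(control, config)
    prov: dict = {"Ri_source": "reference trace" if isinstance(reference, OxTrace)
                  else "given", "control_rate_window_s": list(ctrl_window),
                  "config": {"eq2_window": list(config.eq2_window),
                             "tau_method": config.tau_method,
                             "smooth_window": config.smooth_window}}

    Rox1, w = _pre_injection_rate(test, config)
    prov["Rox1_window_s"] = list(w)

    tau = None
    Rinh = Rox2 = kinh = n_st = None
    if test.t_aox is not None:
        est = detect_tau(test, config)
        tau = est.tau
        prov["tau_method"] = est.method
        prov["tau_diagnostics"] = {k: v for k, v in est.diagnostics.items()
                                   if k != "reason"} | (
            {"reason": est.diagnostics["reason"]}
            if "reason" in est.diagnostics else {})
        t0 = test.t_aox
        t_end = test.times[-1]
        if tau is not None:
            lo, hi = config.eq2_window
            Rinh = estimate_rate(test, (t0 + lo * tau, t0 + hi * tau))
            prov["Rinh_window_s"] = [t0 + lo * tau, t0 + hi * tau]
            post_lo = t0 + 1.15 * tau
            if post_lo < t_end:
                Rox2 = estimate_rate(test, (post_lo, t_end))
                prov["Rox2_window_s"] = [post_lo, t_end]
            fit = fit_eq2(test, tau, params, config)
            kinh = fit.kinh
            prov["eq2_fit"] = {"slope_M": fit.slope, "r2": fit.r2,
                               "reliable": fit.reliable}
            conc0 = test.meta.get("aox_conc0_M")
            if conc0:
                n_st = stoichiometric_n(Ri, tau, conc0)
        else:
            # retarded process: slope over the first half of the
            # post-injection record
            mid = t0 + 0.5 * (t_end - t0)
            Rinh = estimate_rate(test, (t0, mid))
            prov["Rinh_window_s"] = [t0, mid]
            Rox2 = estimate_rate(test, (mid, t_end))
            prov["Rox2_window_s"] = [mid, t_end]
    else:
        # control analyzed as test: the whole record is uninhibited
        Rinh = Rox1

    label = classify(tau=tau, kinh=kinh, Rinh=Rinh, Rox1_control=Rox1_control,
                     kp=params.kp, is_reference=is_reference, config=config)
    report = KineticReport(
        compound=test.label, Rox1=Rox1, Rinh=Rinh, Rox2=Rox2, tau=tau, Ri=Ri,
        nu_ox1=chain_length(Rox1, Ri),
        nu_inh=None if Rinh is None else chain_length(Rinh, Ri),
        nu_ox2=None if Rox2 is None else chain_length(Rox2, Ri),
        n_stoich=n_st, kinh=kinh, classification=label, provenance=prov,
    )
    return report
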
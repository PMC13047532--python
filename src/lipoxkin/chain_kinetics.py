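"""Closed-form kinetics of inhibited lipid peroxidation.

The chain mechanism (azo-initiator decomposition, O2 addition,
H-abstraction propagation, peroxyl self-termination, and trapping of
peroxyl radicals by an antioxidant AoxH) admits simple steady-state
rate laws that anchor every other stage of the pipeline:

* uninhibited rate       R_ox  = kp [LH] sqrt(Ri / 2 kt)
* inhibited rate         R_inh = kp [LH] Ri / (n k_inh [AoxH]0)
* induction period       tau   = n [AoxH]0 / Ri
* integrated uptake law  -d[O2]_t = (kp [LH] / k_inh) ln(1 - t/tau)

All quantities are SI internally (M, s, M^-1 s^-1).  Reporting layers
convert to nM/s and minutes at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class ParameterError(ValueError):
    """A kinetic parameter is outside its physical domain."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ParameterError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class ChainParams:
    """Rate constants and concentrations of the peroxidation chain.

    Parameters
    ----------
    kp : float
        Propagation rate constant LOO* + LH, M^-1 s^-1 (41 for the
        linoleate/liposome system).
    kt : float
        Peroxyl self-termination rate constant 2 LOO* ->, M^-1 s^-1.
    Ri : float
        Radical initiation rate, M s^-1.
    LH0 : float
        Initial oxidizable substrate (methyl linoleate), M.
    O2_0 : float
        Initial dissolved oxygen, M.
    kO2 : float
        O2 addition rate constant to carbon radicals, M^-1 s^-1.
        Informational: it must be fast enough (>= 1e3 kp) that O2
        addition is never rate limiting.
    """

    kp: float
    kt: float
    Ri: float
    LH0: float
    O2_0: float = 217e-6
    kO2: float = 3e9

    def __post_init__(self) -> None:
        _require_positive(
            kp=self.kp, kt=self.kt, Ri=self.Ri, LH0=self.LH0,
            O2_0=self.O2_0, kO2=self.kO2,
        )
        if self.kO2 < 1e3 * self.kp:
            raise ParameterError(
                "kO2 must be >= 1e3*kp (fast O2-addition regime), "
                f"got kO2={self.kO2}, kp={self.kp}"
            )


@dataclass(frozen=True)
class AntioxidantSpec:
    """One compound's peroxyl-trapping parameters.

    ``n_stoich`` is the number of radicals trapped per antioxidant
    molecule (2.0 for the tocopherol analogue PMHC; fractional values
    indicate back reactions or stable-adduct formation).
    """

    name: str
    conc0: float
    kinh: float
    n_stoich: float

    def __post_init__(self) -> None:
        if self.conc0 < 0:
            raise ParameterError(f"conc0 must be >= 0, got {self.conc0!r}")
        if self.kinh < 0:
            raise ParameterError(f"kinh must be >= 0, got {self.kinh!r}")
        _require_positive(n_stoich=self.n_stoich)


def uninhibited_rate(params: ChainParams) -> float:
    """Steady-state oxidation rate without antioxidant, M s^-1.

    Propagation is rate determining and peroxyl self-termination
    closes the chain: R_ox = kp [LH] sqrt(Ri / 2 kt).
    """
    return params.kp * params.LH0 * math.sqrt(params.Ri / (2.0 * params.kt))


def inhibited_rate(params: ChainParams, aox: AntioxidantSpec) -> float:
    """Instantaneous inhibited chain rate at the initial antioxidant
    concentration, M s^-1.

    Assumes antioxidant trapping dominates termination:
    R_inh = kp [LH] Ri / (n k_inh [AoxH]0).  Initiation uptake is
    excluded.  Note this is the t=0 rate; a window-averaged slope over
    the induction period is larger because [AoxH] is consumed.
    """
    if aox.conc0 <= 0 or aox.kinh <= 0:
        raise ParameterError(
            "inhibited_rate requires conc0 > 0 and kinh > 0; "
            "use uninhibited_rate for the antioxidant-free system"
        )
    return (params.kp * params.LH0 * params.Ri
            / (aox.n_stoich * aox.kinh * aox.conc0))


def induction_period(aox: AntioxidantSpec, Ri: float) -> float:
    """Induction period tau = n [AoxH]0 / Ri, s."""
    _require_positive(Ri=Ri)
    return aox.n_stoich * aox.conc0 / Ri


def initiation_rate(aox: AntioxidantSpec, tau: float) -> float:
    """Initiation rate from a measured induction period:
    Ri = n [AoxH]0 / tau (Eq-1 inversion, the reference-antioxidant
    calibration)."""
    _require_positive(tau=tau)
    return aox.n_stoich * aox.conc0 / tau


def stoichiometric_n(Ri: float, tau: float, conc0: float) -> float:
    """Stoichiometric factor n = Ri tau / [AoxH]0, dimensionless.

    Inverse of the induction-period relation; tau = 0 gives n = 0.
    """
    _require_positive(Ri=Ri, conc0=conc0)
    if tau < 0:
        raise ParameterError(f"tau must be >= 0, got {tau!r}")
    return Ri * tau / conc0


def eq2_uptake(t: float, tau: float, params: ChainParams, kinh: float) -> float:
    """Cumulative O2 consumed during the induction period, M.

    Integrated inhibited rate law:
    U(t) = (kp [LH] / k_inh) * (-ln(1 - t/tau)), valid for 0 <= t < tau.
    U is the positive amount of O2 consumed ([O2]_0 - [O2]_t).
    """
    _require_positive(tau=tau, kinh=kinh)
    if t < 0 or t >= tau:
        raise ParameterError(
            f"t must lie in [0, tau); got t={t!r}, tau={tau!r}"
        )
    return -(params.kp * params.LH0 / kinh) * math.log1p(-t / tau)


def chain_length(R: float, Ri: float) -> float:
    """Kinetic chain length nu = R / Ri: propagation cycles per
    initiating radical."""
    _require_positive(Ri=Ri)
    if R < 0:
        raise ParameterError(f"R must be >= 0, got {R!r}")
    return R / Ri


def format_chain_length(nu: float) -> str:
    """Display convention: nearest integer for nu >= 10, one decimal
    below 10."""
    if nu >= 10:
        return f"{nu:.0f}"
    return f"{nu:.1f}"


def calibrate_kt(Rox_observed: float, kp: float, LH0: float, Ri: float) -> float:
    """Invert the uninhibited rate law for the termination constant.

    kt = Ri (kp [LH] / R_ox)^2 / 2.  The termination constant of a
    microheterogeneous liposome system is rarely tabulated; it is
    fixed here so that the simulated control slope reproduces an
    observed uninhibited rate.
    """
    _require_positive(Rox_observed=Rox_observed, kp=kp, LH0=LH0, Ri=Ri)
    return Ri * (kp * LH0 / Rox_observed) ** 2 / 2.0


def estimate_kinh_retarder(
    Rinh: float, params: ChainParams, conc0: float, n_assumed: float = 1.0
) -> float:
    """Order-of-magnitude k_inh estimate for a retarder from its
    retarded rate, M^-1 s^-1.

    Inverts the inhibited rate law, k_inh = kp [LH] Ri / (n R_inh
    [AoxH]0).  For weak traps the neglected peroxyl self-termination
    carries part of the chain, so treat the result as an upper-bound
    scale, not a fitted constant.
    """
    _require_positive(Rinh=Rinh, conc0=conc0, n_assumed=n_assumed)
    return params.kp * params.LH0 * params.Ri / (n_assumed * Rinh * conc0)
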
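"""Flight energetics and the maximum-detour (barrier-avoidance) model.

The core question: how long a detour around a high-altitude barrier is
energetically worthwhile for a bird that would otherwise have to cross
the barrier in costly flapping flight, when the detour can be flown by
cheap thermal soaring?  With transport costs C1 (flapping, J/m) and C2
(soaring, J/m) and a barrier of along-route extent Yb, the maximal
economical extra distance is

    D_max = Yb * (C1 / C2 - 1).

C1 = Pmr / Vmr comes from a fixed-wing power curve: chemical power is
U-shaped in airspeed, the maximum-range speed Vmr is where the tangent
from the origin touches the curve, and Pmr is the power there.
C2 = Ps / Vcc uses soaring power Ps = 4 x basal metabolic rate and the
classic thermal cross-country speed Vcc (climb at rate c, glide at the
speed maximising average progress v*c / (c + s(v)) on the glide polar).

Power-curve terms follow Pennycuick's fixed-wing aerodynamic model:
induced power ~ (m g)^2 / (2 rho v Sd), parasite power
~ 1/2 rho v^3 Sb CDb, profile power a fixed multiple (8.4 / aspect
ratio) of the absolute minimum of the first two.  Chemical power is
mechanical power times a respiration factor, divided by the muscle
conversion efficiency, plus basal metabolism.  The conversion
efficiency default is calibrated once (see docs/methods.md) so that
the study morphometrics reproduce the published transport costs; all
aerodynamic constants keep their standard published values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

from scipy.optimize import minimize_scalar

from .errors import NumericalError, ValidationError

KCAL_J = 4186.8         # thermochemical kilocalorie
DAY_S = 86400.0


@dataclass(frozen=True)
class Morphometrics:
    mass_kg: float
    wingspan_m: float
    wing_area_m2: float

    def __post_init__(self):
        if min(self.mass_kg, self.wingspan_m, self.wing_area_m2) <= 0:
            raise ValidationError("morphometrics must be strictly positive")
        if not 4.0 <= self.aspect_ratio <= 20.0:
            raise ValidationError(
                f"aspect ratio {self.aspect_ratio:.2f} outside sane range 4-20")

    @property
    def aspect_ratio(self) -> float:
        return self.wingspan_m ** 2 / self.wing_area_m2


#: the study species (Montagu's Harrier, Circus pygargus)
HARRIER = Morphometrics(mass_kg=0.291, wingspan_m=1.09, wing_area_m2=0.135)


@dataclass(frozen=True)
class FlightConstants:
    """Physical and physiological constants of the power-curve model.

    ``muscle_conversion_efficiency`` and ``default_climb_rate_ms`` are
    calibration constants frozen against the study species' published
    transport costs; everything else is a standard published value.
    """
    air_density: float = 1.225            # kg/m3, sea level ISA
    gravity: float = 9.81                 # m/s2
    induced_power_factor: float = 1.2     # k
    body_drag_coefficient: float = 0.1    # CDb
    profile_power_constant: float = 8.4   # X1; profile = X1/AR * P_am
    muscle_conversion_efficiency: float = 0.113   # calibrated, frozen
    respiration_factor: float = 1.1
    include_bmr_in_chemical: bool = True
    basal_multiplier_soaring: float = 4.0
    bmr_coefficient: float = 78.3         # kcal/day per kg^exponent
    bmr_exponent: float = 0.723           # non-passerine allometry
    default_climb_rate_ms: float = 2.29   # calibrated, frozen
    speed_bracket_ms: tuple = (1.0, 60.0)

    def __post_init__(self):
        if self.air_density <= 0:
            raise ValidationError("air density must be positive")
        if not 0 < self.muscle_conversion_efficiency < 1:
            raise ValidationError("efficiency must lie in (0, 1)")


DEFAULT_CONSTANTS = FlightConstants()


@dataclass(frozen=True)
class FlightPerformance:
    bmr_w: float
    ps_w: float
    vmp_ms: float
    vmr_ms: float
    pmr_w: float
    vcc_ms: float
    climb_rate_ms: float


@dataclass(frozen=True)
class TransportCosts:
    c1_j_per_m: float
    c2_j_per_m: float

    @property
    def ratio(self) -> float:
        return self.c1_j_per_m / self.c2_j_per_m


@dataclass(frozen=True)
class DetourAssessment:
    yb_km: float
    dmax_km: float
    observed_detour_km: float

    @property
    def optimal(self) -> bool:
        return self.observed_detour_km <= self.dmax_km


def bmr(mass_kg: float,
        constants: FlightConstants = DEFAULT_CONSTANTS) -> float:
    """Basal metabolic rate (W) from the non-passerine allometry
    BMR[kcal/day] = a * M^b."""
    if mass_kg <= 0:
        raise ValidationError("mass must be positive")
    kcal_day = constants.bmr_coefficient * mass_kg ** constants.bmr_exponent
    return kcal_day * KCAL_J / DAY_S


def soaring_power(mass_kg: float,
                  constants: FlightConstants = DEFAULT_CONSTANTS) -> float:
    """Soaring power Ps = multiplier x BMR (default multiplier 4)."""
    return constants.basal_multiplier_soaring * bmr(mass_kg, constants)


def _body_frontal_area(mass_kg: float) -> float:
    # Pennycuick's allometry for body frontal area
    return 0.00813 * mass_kg ** 0.666


def _power_terms(v: float, morph: Morphometrics,
                 c: FlightConstants) -> tuple[float, float]:
    """(induced, parasite) mechanical power terms at airspeed v."""
    if v <= 0:
        raise ValidationError("airspeed must be positive")
    weight = morph.mass_kg * c.gravity
    disc_area = math.pi * morph.wingspan_m ** 2 / 4.0
    induced = c.induced_power_factor * weight ** 2 \
        / (2.0 * c.air_density * v * disc_area)
    parasite = 0.5 * c.air_density * v ** 3 \
        * _body_frontal_area(morph.mass_kg) * c.body_drag_coefficient
    return induced, parasite


def _absolute_minimum_power(morph: Morphometrics, c: FlightConstants) -> float:
    """Closed-form minimum of induced+parasite (induced = 3 x parasite)."""
    weight = morph.mass_kg * c.gravity
    disc_area = math.pi * morph.wingspan_m ** 2 / 4.0
    a = c.induced_power_factor * weight ** 2 / (2.0 * c.air_density * disc_area)
    b = 0.5 * c.air_density * _body_frontal_area(morph.mass_kg) \
        * c.body_drag_coefficient
    v_star = (a / (3.0 * b)) ** 0.25
    return a / v_star + b * v_star ** 3


def mechanical_power(v: float, morph: Morphometrics,
                     constants: FlightConstants = DEFAULT_CONSTANTS) -> float:
    """Mechanical power (W) to fly at airspeed v: induced + parasite +
    profile, the last a fixed fraction (X1 / aspect ratio) of the
    absolute minimum of the first two."""
    induced, parasite = _power_terms(v, morph, constants)
    profile = (constants.profile_power_constant / morph.aspect_ratio) \
        * _absolute_minimum_power(morph, constants)
    return induced + parasite + profile


def chemical_power(v: float, morph: Morphometrics,
                   constants: FlightConstants = DEFAULT_CONSTANTS) -> float:
    """Chemical (metabolic) power: respiration-factored mechanical
    power over the muscle conversion efficiency, plus BMR when the
    additive-basal convention is enabled."""
    p = constants.respiration_factor * mechanical_power(v, morph, constants) \
        / constants.muscle_conversion_efficiency
    if constants.include_bmr_in_chemical:
        p += bmr(morph.mass_kg, constants)
    return p


def _bounded_argmin(fn, lo: float, hi: float, what: str) -> float:
    res = minimize_scalar(fn, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:
        raise NumericalError(f"failed to solve {what}")
    x = float(res.x)
    if not lo + 1e-6 < x < hi - 1e-6:
        raise NumericalError(f"no interior optimum for {what} in "
                             f"[{lo}, {hi}] (hit {x:.3f})")
    return x


def minimum_power_speed(power_fn, bracket: tuple[float, float]) -> float:
    """argmin of a U-shaped power curve (Vmp for the chemical curve)."""
    return _bounded_argmin(power_fn, *bracket, what="minimum-power speed")


def maximum_range_speed(power_fn, bracket: tuple[float, float]) -> float:
    """Speed minimising power per unit distance, P(v)/v — the point
    where the tangent from the origin touches the power curve."""
    return _bounded_argmin(lambda v: power_fn(v) / v, *bracket,
                           what="maximum-range speed")


def characteristic_speeds(
        morph: Morphometrics,
        constants: FlightConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float, float]:
    """(Vmp, Vmr, Pmr) of the chemical power curve, solved numerically
    on the configured speed bracket."""
    fn = lambda v: chemical_power(v, morph, constants)
    vmp = minimum_power_speed(fn, constants.speed_bracket_ms)
    vmr = maximum_range_speed(fn, (vmp, constants.speed_bracket_ms[1]))
    return vmp, vmr, fn(vmr)


def glide_sink_rate(v: float, morph: Morphometrics,
                    constants: FlightConstants = DEFAULT_CONSTANTS) -> float:
    """Sink rate s(v) = P_mech(v) / (m g) of the gliding polar, m/s."""
    return mechanical_power(v, morph, constants) \
        / (morph.mass_kg * constants.gravity)


def cross_country_speed(morph: Morphometrics,
                        constants: FlightConstants = DEFAULT_CONSTANTS,
                        climb_rate: float | None = None) -> float:
    """Thermal cross-country speed: climb at rate c, glide at the speed
    maximising average ground progress v * c / (c + s(v)).  Returns the
    maximised average speed; for very strong climbs the optimum glides
    at the upper edge of the speed bracket."""
    c = constants.default_climb_rate_ms if climb_rate is None else climb_rate
    if c <= 0:
        raise ValidationError("climb rate must be positive")
    lo, hi = constants.speed_bracket_ms

    def neg_vcc(v):
        return -v * c / (c + glide_sink_rate(v, morph, constants))

    res = minimize_scalar(neg_vcc, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success or not math.isfinite(res.fun):
        raise NumericalError("cross-country optimisation failed")
    return -float(res.fun)


def flight_performance(morph: Morphometrics = HARRIER,
                       constants: FlightConstants = DEFAULT_CONSTANTS,
                       climb_rate: float | None = None) -> FlightPerformance:
    """All characteristic speeds and powers for one bird."""
    vmp, vmr, pmr = characteristic_speeds(morph, constants)
    c = constants.default_climb_rate_ms if climb_rate is None else climb_rate
    return FlightPerformance(
        bmr_w=bmr(morph.mass_kg, constants),
        ps_w=soaring_power(morph.mass_kg, constants),
        vmp_ms=vmp, vmr_ms=vmr, pmr_w=pmr,
        vcc_ms=cross_country_speed(morph, constants, c),
        climb_rate_ms=c)


def transport_costs(perf: FlightPerformance) -> TransportCosts:
    """C1 = Pmr/Vmr (flapping) and C2 = Ps/Vcc (soaring), J/m."""
    if perf.vmr_ms <= 0 or perf.vcc_ms <= 0:
        raise ValidationError("speeds must be positive")
    return TransportCosts(c1_j_per_m=perf.pmr_w / perf.vmr_ms,
                          c2_j_per_m=perf.ps_w / perf.vcc_ms)


def max_detour(yb_km: float, costs: TransportCosts) -> float:
    """Maximal economical detour D = Yb * (C1/C2 - 1), km."""
    if yb_km <= 0:
        raise ValidationError("barrier distance must be positive")
    if costs.ratio < 1.0:
        warnings.warn("cost ratio < 1: soaring costlier than flapping, "
                      "no detour is economical", stacklevel=2)
    return yb_km * (costs.ratio - 1.0)


def assess_detour(observed_km: float, dmax_km: float,
                  yb_km: float = float("nan")) -> DetourAssessment:
    """Compare an observed detour distance against the model maximum."""
    if observed_km < 0 or dmax_km < 0:
        raise ValidationError("distances must be non-negative")
    return DetourAssessment(yb_km=yb_km, dmax_km=dmax_km,
                            observed_detour_km=observed_km)
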
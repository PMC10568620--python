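"""Four-genotype exponential growth–mutation model under a fixed drug regimen.

The model tracks four genotypes of an EGFR-mutant NSCLC tumor under
EGFR-tyrosine-kinase-inhibitor therapy:

* **Type-W** — driver mutation only (e.g. L858R, del-19); sensitive to both
  drug generations.
* **Type-X** — T790M; resistant to first/second-generation TKIs ("DrugA"),
  sensitive to osimertinib ("DrugB").
* **Type-Y** — C797S; sensitive to DrugA, resistant to DrugB.
* **Type-Z** — T790M + C797S; resistant to both.

Under a constant regimen the dynamics are a triangular linear ODE system
(mutation is irreversible, so W feeds X, Y, Z; X and Y feed Z)::

    dw/dt = a w
    dx/dt = g w + b x
    dy/dt = h w + c y
    dz/dt = k w + p x + q y + f z

with per-day net growth rates ``a, b, c, f`` (negative under an effective
drug) and per-day mutation rates ``g, h, k, p, q >= 0``.  The triangular
structure admits a closed-form solution by a divided-difference cascade
(:func:`closed_form_state`); an adaptive high-accuracy ODE integration
(:func:`numeric_reference_state`) serves as an independent oracle and as the
fallback for degenerate (near-equal-rate) parameter sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml
from scipy.integrate import solve_ivp

logger = logging.getLogger(__name__)

__all__ = [
    "RegimenParameters",
    "TumorState",
    "InvalidCompositionError",
    "IntegrationFailureError",
    "REGIMEN_LABELS",
    "GROWTH_RATE_NAMES",
    "MUTATION_RATE_NAMES",
    "RATE_NAMES",
    "DEGENERACY_THRESHOLD",
    "default_parameter_table",
    "load_parameter_table",
    "standard_initial_state",
    "closed_form_state",
    "numeric_reference_state",
    "degeneracy_fallback_count",
    "reset_degeneracy_fallback_count",
]

REGIMEN_LABELS = ("A", "B", "C")
GROWTH_RATE_NAMES = ("a", "b", "c", "f")
MUTATION_RATE_NAMES = ("g", "h", "k", "p", "q")
RATE_NAMES = GROWTH_RATE_NAMES + MUTATION_RATE_NAMES

#: Relative threshold below which a growth-rate difference counts as
#: degenerate (repeated eigenvalue) and the closed form defers to the
#: numerical oracle.
DEGENERACY_THRESHOLD = 1e-8


class InvalidCompositionError(ValueError):
    """Initial cell counts that exceed or exhaust the stated total."""


class IntegrationFailureError(RuntimeError):
    """The adaptive ODE integrator failed to converge."""


@dataclass(frozen=True)
class RegimenParameters:
    """The nine rate constants (per day) of one drug regimen.

    ``label`` identifies the regimen: ``"A"`` (erlotinib-class), ``"B"``
    (osimertinib) or ``"C"`` (combination).  Growth rates may be negative
    (net decay under drug); mutation rates must be non-negative.
    """

    label: str
    a: float
    b: float
    c: float
    f: float
    g: float
    h: float
    k: float
    p: float
    q: float

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"rate {name!r} must be finite, got {value!r}")
        for name in MUTATION_RATE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(
                    f"mutation rate {name!r} must be >= 0, got {getattr(self, name)!r}"
                )

    @property
    def growth_rates(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.f)

    @property
    def mutation_rates(self) -> tuple[float, float, float, float, float]:
        return (self.g, self.h, self.k, self.p, self.q)

    def rate_differences(self) -> tuple[float, ...]:
        """The growth-rate differences the closed-form cascade divides by."""
        a, b, c, f = self.growth_rates
        return (a - b, a - c, a - f, b - f, c - f)

    def is_degenerate(self, threshold: float = DEGENERACY_THRESHOLD) -> bool:
        """True when any cascade denominator is within ``threshold`` (relative
        to the largest growth-rate magnitude) of zero."""
        scale = max(abs(r) for r in self.growth_rates)
        if scale == 0.0:
            return True
        return any(abs(d) < threshold * scale for d in self.rate_differences())

    def replace(self, **changes: float) -> "RegimenParameters":
        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RATE_NAMES}

    @classmethod
    def from_dict(cls, label: str, rates: dict[str, float]) -> "RegimenParameters":
        unknown = set(rates) - set(RATE_NAMES)
        if unknown:
            raise ValueError(f"unknown rate name(s) {sorted(unknown)} for regimen {label!r}")
        missing = set(RATE_NAMES) - set(rates)
        if missing:
            raise ValueError(f"missing rate(s) {sorted(missing)} for regimen {label!r}")
        return cls(label=label, **{k: float(v) for k, v in rates.items()})


@dataclass(frozen=True)
class TumorState:
    """Cell counts of the four genotypes at time ``t`` (days).

    Counts are continuous non-negative reals — the model is deterministic
    and fractional counts are meaningful as expectations.
    """

    w: float
    x: float
    y: float
    z: float
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("w", "x", "y", "z"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"cell count {name!r} must be finite and >= 0, got {value!r}")

    def total(self) -> float:
        return self.w + self.x + self.y + self.z

    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, counts, t: float = 0.0) -> "TumorState":
        w, x, y, z = (float(v) for v in counts)
        return cls(w=w, x=x, y=y, z=z, t=float(t))


def _load_table_from_mapping(mapping: dict) -> dict[str, RegimenParameters]:
    return {
        label: RegimenParameters.from_dict(label, dict(rates))
        for label, rates in mapping.items()
    }


def load_parameter_table(path) -> dict[str, RegimenParameters]:
    """Read a per-regimen rate table from a YAML (or JSON) file.

    The file maps regimen labels to the nine rate names, either at top level
    or under a ``parameters`` key.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"parameter file {path!s} must contain a mapping")
    mapping = raw.get("parameters", raw)
    return _load_table_from_mapping(mapping)


_DEFAULT_TABLE_CACHE: dict[str, RegimenParameters] | None = None


def _load_bundled_defaults() -> dict:
    text = resources.files("tkiswitch.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def default_parameter_table() -> dict[str, RegimenParameters]:
    """The bundled published rate table for regimens A, B and C.

    Growth rates come from genome-edited cell-line measurements under
    erlotinib and osimertinib; all five mutation rates are 1e-7 per day in
    every regimen.  Returns a fresh dict each call (values are frozen).
    """
    global _DEFAULT_TABLE_CACHE
    if _DEFAULT_TABLE_CACHE is None:
        _DEFAULT_TABLE_CACHE = _load_table_from_mapping(
            _load_bundled_defaults()["parameters"]
        )
    return dict(_DEFAULT_TABLE_CACHE)


def standard_initial_state(
    total: float = 1e9, x0: float = 1e4, y0: float = 1e4, z0: float = 10.0
) -> TumorState:
    """Initial tumor of ``total`` cells with given resistant seeds, W the rest.

    The default is the standard clinical-detection-size tumor: 1e9 cells
    (about 1 cm diameter) seeded with 1e4 Type-X, 1e4 Type-Y and 10 Type-Z.
    """
    if min(x0, y0, z0) < 0:
        raise InvalidCompositionError("resistant-cell counts must be >= 0")
    rest = total - (x0 + y0 + z0)
    if rest <= 0:
        raise InvalidCompositionError(
            f"resistant counts ({x0} + {y0} + {z0}) exhaust the total {total}"
        )
    return TumorState(w=rest, x=x0, y=y0, z=z0, t=0.0)


_degeneracy_fallbacks = 0


def degeneracy_fallback_count() -> int:
    """Number of closed-form calls that deferred to the numerical oracle."""
    return _degeneracy_fallbacks


def reset_degeneracy_fallback_count() -> None:
    global _degeneracy_fallbacks
    _degeneracy_fallbacks = 0


def closed_form_state(
    initial: TumorState, params: RegimenParameters, dt: float
) -> TumorState:
    """Advance a tumor state by ``dt`` days under constant rates, exactly.

    The triangular system solves by cascade.  Writing ``E(r) = exp(r*dt)``
    and ``D(r, s) = (E(r) - E(s)) / (r - s)`` (the divided difference of the
    exponential, always >= 0)::

        w(dt) = W0 E(a)
        x(dt) = X0 E(b) + g W0 D(a, b)
        y(dt) = Y0 E(c) + h W0 D(a, c)
        z(dt) = Z0 E(f) + A D(a, f) + B D(b, f) + C D(c, f)

    where the inflow into Type-Z groups by eigenvalue::

        A = W0 (k + g p / (a - b) + h q / (a - c))   # e^{at} inflow,
                                                     # incl. W→X→Z and W→Y→Z
        B = p (X0 - g W0 / (a - b))                  # e^{bt} inflow
        C = q (Y0 - h W0 / (a - c))                  # e^{ct} inflow

    When any cascade denominator is near zero (repeated eigenvalue) the
    computation falls back to :func:`numeric_reference_state` at rel_tol
    1e-12 and logs the event; such parameter sets never occur at the
    published defaults.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    if dt == 0:
        return replace(initial, t=initial.t)
    if params.is_degenerate():
        global _degeneracy_fallbacks
        _degeneracy_fallbacks += 1
        logger.warning(
            "near-equal growth rates in regimen %s (%s); deferring to the "
            "numerical oracle",
            params.label,
            params.growth_rates,
        )
        return numeric_reference_state(initial, params, dt, rel_tol=1e-12)

    a, b, c, f = params.growth_rates
    g, h, k, p, q = params.mutation_rates
    W0, X0, Y0, Z0 = initial.w, initial.x, initial.y, initial.z

    ea = math.exp(a * dt)
    eb = math.exp(b * dt)
    ec = math.exp(c * dt)
    ef = math.exp(f * dt)

    w = W0 * ea
    x = X0 * eb + g * W0 * (ea - eb) / (a - b)
    y = Y0 * ec + h * W0 * (ea - ec) / (a - c)

    coef_a = W0 * (k + g * p / (a - b) + h * q / (a - c))
    coef_b = p * (X0 - g * W0 / (a - b))
    coef_c = q * (Y0 - h * W0 / (a - c))
    z = (
        Z0 * ef
        + coef_a * (ea - ef) / (a - f)
        + coef_b * (eb - ef) / (b - f)
        + coef_c * (ec - ef) / (c - f)
    )

    # The grouped-coefficient form can round a mathematically non-negative
    # sum a few ulp below zero; clamp so downstream states stay valid.
    return TumorState(
        w=max(w, 0.0), x=max(x, 0.0), y=max(y, 0.0), z=max(z, 0.0), t=initial.t + dt
    )


def numeric_reference_state(
    initial: TumorState,
    params: RegimenParameters,
    dt: float,
    rel_tol: float = 1e-10,
    abs_tol: float = 1e-250,
) -> TumorState:
    """Advance a state by adaptive high-order ODE integration (DOP853).

    Serves as the independent oracle for :func:`closed_form_state`.  The
    absolute tolerance defaults far below any attainable cell count so that
    error control is purely relative: every component is a non-negative sum
    of exponentials and never crosses zero, which keeps relative control
    well-defined even for counts that decay through hundreds of orders of
    magnitude.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    if rel_tol <= 0:
        raise ValueError(f"rel_tol must be > 0, got {rel_tol}")
    if dt == 0:
        return replace(initial, t=initial.t)

    a, b, c, f = params.growth_rates
    g, h, k, p, q = params.mutation_rates

    def rhs(_t: float, s: np.ndarray) -> list[float]:
        w, x, y, z = s
        return [a * w, g * w + b * x, h * w + c * y, k * w + p * x + q * y + f * z]

    sol = solve_ivp(
        rhs,
        (0.0, dt),
        initial.as_array(),
        method="DOP853",
        rtol=rel_tol,
        atol=abs_tol,
    )
    if not sol.success:
        raise IntegrationFailureError(
            f"ODE integration failed over dt={dt}: {sol.message}"
        )
    counts = np.maximum(sol.y[:, -1], 0.0)
    return TumorState.from_array(counts, t=initial.t + dt)
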
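"""Sex- and age-specific penetrance from incidence tables.

Cancer risk for carriers of a dominant pathogenic variant and for the
general (non-carrier) population is summarised as age-specific incidence
rates per 5-year age group, in the style of the Prospective Lynch Syndrome
Database (carriers) and Cancer Incidence in Five Continents (population).
This module converts such tables into cumulative penetrance curves via the
piecewise-constant-hazard survival model

    F(end of group k) = 1 - exp(-sum_{j<=k} lambda_j * width_j),

optionally after a pre-smoothing step: penalized Poisson spline regression
of event counts on age-group midpoints with a log person-years offset
(P-spline with difference penalty; penalty weight chosen by generalized
cross-validation).

Conventions (documented choices, see package docs):
  * age groups are half-open intervals [lo, hi);
  * the regression covariate is the group midpoint;
  * cumulative risk is indexed at the end of the group containing an age;
  * beyond the last tabulated group the hazard is held constant at the last
    group's rate;
  * the penetrance class for unknown age is the unweighted mean of the
    cumulative risks across age groups (person-year weighting available).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .errors import DataFormatError

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

__all__ = [
    "IncidenceTable",
    "PenetranceModel",
    "smooth_incidence",
    "incidence_to_penetrance",
    "MALE",
    "FEMALE",
]


# ---------------------------------------------------------------------------
# Incidence tables
# ---------------------------------------------------------------------------

@dataclass
class IncidenceTable:
    """Age-specific incidence for one sex.

    Rates are events per person-year within half-open age groups
    ``[age_lo, age_hi)``.  ``events``/``person_years`` may be absent when
    only rates are known (they are required for the Poisson pre-smoothing).
    """

    sex: str
    age_lo: np.ndarray
    age_hi: np.ndarray
    rate: np.ndarray
    events: np.ndarray | None = None
    person_years: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.age_lo = np.asarray(self.age_lo, dtype=float)
        self.age_hi = np.asarray(self.age_hi, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.events is not None:
            self.events = np.asarray(self.events, dtype=float)
        if self.person_years is not None:
            self.person_years = np.asarray(self.person_years, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise DataFormatError(f"unknown sex {self.sex!r}")
        n = self.age_lo.size
        if n == 0:
            raise DataFormatError("incidence table has no age groups")
        if self.age_hi.size != n or self.rate.size != n:
            raise DataFormatError("incidence table column lengths differ")
        if np.any(self.age_hi <= self.age_lo):
            raise DataFormatError("age groups must have positive width")
        if np.any(self.age_lo[1:] != self.age_hi[:-1]):
            raise DataFormatError("age groups must be contiguous and ascending")
        if np.any(self.rate < 0):
            raise DataFormatError("negative incidence rate")
        if (self.events is None) != (self.person_years is None):
            raise DataFormatError("events and person_years must come together")
        if self.events is not None:
            if np.any(self.person_years <= 0):
                raise DataFormatError("person_years must be positive")
            implied = self.events / self.person_years
            if not np.allclose(implied, self.rate, rtol=1e-6, atol=1e-12):
                raise DataFormatError("rate != events / person_years")

    @property
    def width(self) -> np.ndarray:
        return self.age_hi - self.age_lo

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.age_lo + self.age_hi)

    def scaled(self, factor: float) -> "IncidenceTable":
        """Return a copy with all rates (and events) multiplied by ``factor``."""
        if factor < 0:
            raise DataFormatError("scale factor must be non-negative")
        ev = None if self.events is None else self.events * factor
        return IncidenceTable(self.sex, self.age_lo.copy(), self.age_hi.copy(),
                              self.rate * factor, ev,
                              None if self.person_years is None
                              else self.person_years.copy())

    def with_rates(self, rate: np.ndarray) -> "IncidenceTable":
        """Copy of the table with new rates (events kept consistent)."""
        rate = np.asarray(rate, dtype=float)
        ev = None if self.person_years is None else rate * self.person_years
        return IncidenceTable(self.sex, self.age_lo.copy(), self.age_hi.copy(),
                              rate, ev,
                              None if self.person_years is None
                              else self.person_years.copy())

    def same_grid(self, other: "IncidenceTable") -> bool:
        return (self.age_lo.size == other.age_lo.size
                and np.array_equal(self.age_lo, other.age_lo)
                and np.array_equal(self.age_hi, other.age_hi))


# ---------------------------------------------------------------------------
# Penalized Poisson spline pre-smoothing
# ---------------------------------------------------------------------------

def _bspline_basis(x: np.ndarray, k: int) -> np.ndarray:
    """B-spline design matrix with ``k`` basis functions on the range of x.

    Degree is min(3, k - 1); interior knots at quantiles of x.  The basis is
    a partition of unity, which makes the difference penalty's null space
    contain the constant fit and preserves the total fitted event count.
    """
    x = np.asarray(x, dtype=float)
    deg = min(3, k - 1)
    n_interior = k - deg - 1
    lo, hi = float(x.min()), float(x.max())
    if n_interior > 0:
        interior = np.quantile(x, np.linspace(0.0, 1.0, n_interior + 2)[1:-1])
    else:
        interior = np.array([])
    knots = np.r_[[lo] * (deg + 1), interior, [hi] * (deg + 1)]
    return BSpline.design_matrix(x, knots, deg, extrapolate=True).toarray()


def _poisson_irls(B: np.ndarray, P: np.ndarray, y: np.ndarray,
                  offset: np.ndarray, lam: float):
    """Penalized Poisson IRLS with canonical log link.

    Returns (fitted mean, effective df, deviance).
    """
    n, p = B.shape
    beta = np.full(p, np.log(max(float(y.sum()), 0.5))
                   - np.log(float(np.exp(offset).sum())))
    A = None
    for _ in range(200):
        eta = np.clip(B @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        w = np.maximum(mu, 1e-10)
        z = (eta - offset) + (y - mu) / w
        A = B.T @ (w[:, None] * B) + lam * P + 1e-9 * np.eye(p)
        step = np.linalg.solve(A, B.T @ (w * z)) - beta
        mx = float(np.max(np.abs(step)))
        if mx > 5.0:
            step *= 5.0 / mx
        beta = beta + step
        if mx < 1e-10:
            break
    eta = np.clip(B @ beta + offset, -30.0, 30.0)
    mu = np.exp(eta)
    w = np.maximum(mu, 1e-10)
    edf = float(np.trace(B @ np.linalg.solve(A, (B * w[:, None]).T)))
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = 2.0 * float(np.sum(np.where(y > 0,
                                          y * np.log(np.maximum(y, 1e-300) / mu),
                                          0.0) - (y - mu)))
    return mu, edf, dev


def smooth_incidence(table: IncidenceTable, basis_dimension: int = 3,
                     penalty: float | None = None) -> IncidenceTable:
    """Pre-smooth an incidence table by penalized Poisson spline regression.

    Event counts are regressed on age-group midpoints with a log
    person-years offset; the spline has ``basis_dimension`` basis functions
    and a second-order difference penalty whose weight is chosen by GCV
    unless ``penalty`` is given (``penalty=0`` disables it).
    """
    if table.events is None or table.person_years is None:
        raise DataFormatError("smoothing requires events and person_years")
    if basis_dimension < 3:
        raise DataFormatError("basis_dimension must be >= 3")
    if basis_dimension > table.age_lo.size:
        raise DataFormatError("fewer age groups than basis dimension")
    if np.all(table.person_years == 0):
        raise DataFormatError("all-zero person_years")

    x = table.midpoint
    y = table.events
    offset = np.log(table.person_years)
    B = _bspline_basis(x, basis_dimension)
    p = B.shape[1]
    D = np.diff(np.eye(p), 2, axis=0) if p >= 3 else np.zeros((0, p))
    P = D.T @ D

    if penalty is not None:
        mu, _, _ = _poisson_irls(B, P, y, offset, float(penalty))
    else:
        n = x.size
        best = None
        for lam in np.r_[0.0, np.logspace(-6, 6, 25)]:
            mu_l, edf, dev = _poisson_irls(B, P, y, offset, lam)
            gcv = n * dev / max(n - edf, 1e-8) ** 2
            if best is None or gcv < best[0]:
                best = (gcv, mu_l)
        mu = best[1]

    fitted_rate = np.maximum(mu / table.person_years, 0.0)
    return table.with_rates(fitted_rate)


# ---------------------------------------------------------------------------
# Penetrance model
# ---------------------------------------------------------------------------

@dataclass
class PenetranceModel:
    """Cumulative disease risk by liability class (sex x age group x carrier).

    ``cumulative[(sex, carrier)]`` holds F at the *end* of each age group;
    ``hazard[(sex, carrier)]`` the per-year rates used to build it (also used
    to extend risk beyond the tabulated ages at the last group's rate).
    ``average[(sex, carrier)]`` is the class assigned to unknown ages.
    """

    age_lo: np.ndarray
    age_hi: np.ndarray
    cumulative: dict = field(default_factory=dict)
    hazard: dict = field(default_factory=dict)
    average: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.age_lo = np.asarray(self.age_lo, dtype=float)
        self.age_hi = np.asarray(self.age_hi, dtype=float)
        for key, F in self.cumulative.items():
            F = np.asarray(F, dtype=float)
            self.cumulative[key] = F
            if np.any(F < 0) or np.any(F > 1):
                raise DataFormatError(f"penetrance outside [0, 1] for {key}")
            if np.any(np.diff(F) < -1e-12):
                raise DataFormatError(f"penetrance decreasing in age for {key}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_cumulative(cls, age_lo, age_hi, curves: dict,
                        average_weights=None) -> "PenetranceModel":
        """Build from cumulative curves ``{(sex, carrier): F array}``.

        Hazards are recovered from consecutive survival ratios so that risk
        can be extended beyond the last group.
        """
        age_lo = np.asarray(age_lo, dtype=float)
        age_hi = np.asarray(age_hi, dtype=float)
        width = age_hi - age_lo
        hazard = {}
        average = {}
        for key, F in curves.items():
            F = np.minimum(np.asarray(F, dtype=float), 1.0 - 1e-12)
            S = 1.0 - F
            S_prev = np.r_[1.0, S[:-1]]
            hazard[key] = np.log(S_prev / S) / width
            if average_weights is None:
                average[key] = float(np.mean(F))
            else:
                w = np.asarray(average_weights, dtype=float)
                average[key] = float(np.sum(w * F) / np.sum(w))
        return cls(age_lo, age_hi, dict(curves), hazard, average)

    @classmethod
    def constant(cls, f_carrier: float, f_noncarrier: float) -> "PenetranceModel":
        """Flat penetrance: one broad age class, both sexes (toy models)."""
        curves = {}
        for sex in SEXES:
            curves[(sex, True)] = np.array([f_carrier], dtype=float)
            curves[(sex, False)] = np.array([f_noncarrier], dtype=float)
        return cls.from_cumulative(np.array([0.0]), np.array([130.0]), curves)

    # -- lookup ------------------------------------------------------------

    def risk(self, sex: str, age, carrier: bool) -> float:
        """Cumulative risk for the liability class containing (sex, age).

        ``age=None`` returns the average class.  Risk is indexed at the end
        of the 5-year group containing the age; ages past the table are
        extended with the last group's hazard held constant.
        """
        key = (sex, bool(carrier))
        if key not in self.cumulative:
            raise DataFormatError(f"no penetrance class for {key}")
        if age is None:
            return self.average[key]
        age = float(age)
        F = self.cumulative[key]
        if age < self.age_hi[-1]:
            idx = int(np.searchsorted(self.age_hi, age, side="right"))
            idx = min(idx, F.size - 1)
            return float(F[idx])
        # constant-hazard extension past the table, in table-width steps
        lam = self.hazard[key][-1]
        width = float(self.age_hi[-1] - self.age_lo[-1])
        n_extra = int(np.floor((age - self.age_hi[-1]) / width)) + 1
        S_last = 1.0 - F[-1]
        return float(1.0 - S_last * np.exp(-lam * width * n_extra))

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "age_lo": self.age_lo.tolist(),
            "age_hi": self.age_hi.tolist(),
            "classes": [
                {"sex": sex, "carrier": carrier,
                 "cumulative": self.cumulative[(sex, carrier)].tolist(),
                 "hazard": self.hazard[(sex, carrier)].tolist(),
                 "average": self.average[(sex, carrier)]}
                for (sex, carrier) in sorted(self.cumulative)
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PenetranceModel":
        payload = json.loads(text)
        cumulative, hazard, average = {}, {}, {}
        for entry in payload["classes"]:
            key = (entry["sex"], bool(entry["carrier"]))
            cumulative[key] = np.asarray(entry["cumulative"], dtype=float)
            hazard[key] = np.asarray(entry["hazard"], dtype=float)
            average[key] = float(entry["average"])
        return cls(np.asarray(payload["age_lo"], dtype=float),
                   np.asarray(payload["age_hi"], dtype=float),
                   cumulative, hazard, average)


def _as_table_map(tables) -> dict:
    if isinstance(tables, IncidenceTable):
        tables = [tables]
    out = {}
    for t in tables:
        if t.sex in out:
            raise DataFormatError(f"duplicate incidence table for sex {t.sex}")
        out[t.sex] = t
    return out


def incidence_to_penetrance(carrier, noncarrier,
                            average_weighting: str = "uniform") -> PenetranceModel:
    """Convert carrier and non-carrier incidence tables into penetrance.

    ``carrier``/``noncarrier`` are IncidenceTables (or iterables of them, one
    per sex) on a common age grid.  Cumulative risk at the end of group k is
    ``1 - exp(-sum_{j<=k} rate_j * width_j)``.  ``average_weighting`` is
    ``"uniform"`` (default: unweighted mean of F over groups) or
    ``"person_years"``.
    """
    carrier_map = _as_table_map(carrier)
    noncarrier_map = _as_table_map(noncarrier)
    if set(carrier_map) != set(noncarrier_map):
        raise DataFormatError("carrier and non-carrier tables cover different sexes")

    ref = next(iter(carrier_map.values()))
    curves, hazard, average = {}, {}, {}
    for sex, is_carrier, table in (
            [(s, True, t) for s, t in carrier_map.items()]
            + [(s, False, t) for s, t in noncarrier_map.items()]):
        if not table.same_grid(ref):
            raise DataFormatError("incidence tables are on different age grids")
        if np.any(table.rate < 0):
            raise DataFormatError("negative incidence rate")
        cumhaz = np.cumsum(table.rate * table.width)
        F = 1.0 - np.exp(-cumhaz)
        key = (sex, is_carrier)
        curves[key] = F
        hazard[key] = table.rate.copy()
        if average_weighting == "uniform":
            average[key] = float(np.mean(F))
        elif average_weighting == "person_years":
            if table.person_years is None:
                raise DataFormatError("person_years weighting needs person_years")
            average[key] = float(np.sum(table.person_years * F)
                                 / np.sum(table.person_years))
        else:
            raise DataFormatError(f"unknown weighting {average_weighting!r}")

    return PenetranceModel(ref.age_lo.copy(), ref.age_hi.copy(),
                           curves, hazard, average)
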
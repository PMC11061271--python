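"""Full-likelihood Bayes factor (FLB) co-segregation analysis.

The FLB quantifies how much better a family's joint phenotype and
carrier-test data are explained by the hypothesis that the variant causes
the disease than by the hypothesis that it is neutral:

    FLB = [ P(data | causal) / P(proband data | causal) ]
          / [ P(data | neutral) / P(proband data | neutral) ]

Both terms condition on the proband's own observations (affected, confirmed
carrier) to correct for ascertainment: the family was collected *because*
of the proband, so the proband's data carry no segregation evidence.  A
singleton pedigree therefore always gives FLB = 1.

Evidence thresholds follow the common translation to variant-classification
language: FLB > 8 counts as supporting and FLB > 16 as strong evidence of
pathogenicity.  Independent families multiply.

The sensitivity analysis re-derives penetrance over a grid of perturbed
incidence assumptions: non-carrier rates scaled by a factor f in
[0.50, 1.50], and carrier rates replaced by the weighted average
(1 - e) * (scaled non-carrier rates) + e * (original carrier rates) for an
"excess" weight e in [0, 1].  At e = 0 carriers and non-carriers coincide,
so FLB = 1 identically; (f, e) = (1, 1) reproduces the unperturbed result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import DataFormatError, PedigreeError
from .pedigree import (AFFECTED, CARRIER, CAUSAL, NEUTRAL, UNKNOWN, UNTESTED,
                       DiseaseModel, Pedigree, pedigree_loglik)
from .penetrance import IncidenceTable, incidence_to_penetrance

SUPPORTING_THRESHOLD = 8.0
STRONG_THRESHOLD = 16.0

__all__ = [
    "FLBResult", "SensitivityGrid",
    "compute_flb", "combine_flb", "sensitivity_analysis", "flb_contour",
    "evidence_level", "SUPPORTING_THRESHOLD", "STRONG_THRESHOLD",
]


def evidence_level(flb: float, supporting: float = SUPPORTING_THRESHOLD,
                   strong: float = STRONG_THRESHOLD) -> str:
    if flb > strong:
        return "strong"
    if flb > supporting:
        return "supporting"
    return "none"


@dataclass(frozen=True)
class FLBResult:
    flb: float
    log_flb: float
    family_id: str
    evidence_level: str

    @classmethod
    def from_log(cls, log_flb: float, family_id: str,
                 supporting: float = SUPPORTING_THRESHOLD,
                 strong: float = STRONG_THRESHOLD) -> "FLBResult":
        flb = math.exp(log_flb)
        return cls(flb, log_flb, family_id, evidence_level(flb, supporting, strong))

    def to_dict(self) -> dict:
        return {"family_id": self.family_id, "flb": self.flb,
                "log_flb": self.log_flb, "evidence_level": self.evidence_level}


def _strip_to_proband(ped: Pedigree) -> Pedigree:
    """Keep only the proband's evidence; everyone else becomes uninformative."""
    updates = {m.id: {"affected": UNKNOWN, "carrier_status": UNTESTED}
               for m in ped.members if not m.is_proband}
    return ped.replaced(updates=updates)


def compute_flb(ped: Pedigree, model: DiseaseModel,
                supporting: float = SUPPORTING_THRESHOLD,
                strong: float = STRONG_THRESHOLD) -> FLBResult:
    """FLB for one family, conditioning on the proband's observed data."""
    probands = ped.probands
    if len(probands) != 1:
        raise PedigreeError(
            f"family {ped.family_id}: co-segregation analysis needs exactly one "
            f"proband, found {len(probands)}")
    proband = probands[0]
    if proband.carrier_status != CARRIER or proband.affected != AFFECTED:
        raise PedigreeError(
            f"family {ped.family_id}: proband {proband.id} must be an affected, "
            f"confirmed carrier")

    stripped = _strip_to_proband(ped)
    log_num = pedigree_loglik(ped, model, CAUSAL) \
        - pedigree_loglik(stripped, model, CAUSAL)
    log_den = pedigree_loglik(ped, model, NEUTRAL) \
        - pedigree_loglik(stripped, model, NEUTRAL)
    if not math.isfinite(log_den):
        raise PedigreeError(
            f"family {ped.family_id}: zero likelihood under the neutral "
            f"hypothesis (inconsistent observations)")
    return FLBResult.from_log(log_num - log_den, ped.family_id,
                              supporting, strong)


def combine_flb(results: list[FLBResult],
                supporting: float = SUPPORTING_THRESHOLD,
                strong: float = STRONG_THRESHOLD) -> FLBResult:
    """Product of per-family FLBs (families assumed independent)."""
    if not results:
        raise DataFormatError("cannot combine an empty list of FLB results")
    log_total = sum(r.log_flb for r in results)
    family_id = "+".join(r.family_id for r in results)
    return FLBResult.from_log(log_total, family_id, supporting, strong)


# ---------------------------------------------------------------------------
# Sensitivity analysis (penetrance robustness surface)
# ---------------------------------------------------------------------------

@dataclass
class SensitivityGrid:
    factors: np.ndarray          # non-carrier incidence scale factors
    excess_fractions: np.ndarray  # carrier excess weights in [0, 1]
    flb_values: np.ndarray       # shape (len(factors), len(excess_fractions))
    baseline: tuple = (1.0, 1.0)

    def baseline_flb(self) -> float:
        i = int(np.argmin(np.abs(self.factors - self.baseline[0])))
        j = int(np.argmin(np.abs(self.excess_fractions - self.baseline[1])))
        return float(self.flb_values[i, j])

    def interpolate(self, factor: float, excess: float) -> float:
        """Bilinear interpolation of the FLB surface."""
        return _bilinear(self.factors, self.excess_fractions,
                         self.flb_values, factor, excess)


def _bilinear(xs, ys, Z, x, y) -> float:
    i = int(np.clip(np.searchsorted(xs, x, side="right") - 1, 0, xs.size - 2))
    j = int(np.clip(np.searchsorted(ys, y, side="right") - 1, 0, ys.size - 2))
    tx = (x - xs[i]) / (xs[i + 1] - xs[i])
    ty = (y - ys[j]) / (ys[j + 1] - ys[j])
    return float((1 - tx) * (1 - ty) * Z[i, j] + tx * (1 - ty) * Z[i + 1, j]
                 + (1 - tx) * ty * Z[i, j + 1] + tx * ty * Z[i + 1, j + 1])


def perturbed_model(carrier_tables, noncarrier_tables, factor: float,
                    excess: float, allele_frequency: float,
                    weight_scaled: bool = True) -> DiseaseModel:
    """Disease model with perturbed incidence assumptions.

    Non-carrier rates are scaled by ``factor``; carrier rates become the
    weighted average ``(1 - excess) * noncarrier + excess * carrier`` where
    the non-carrier component is the *scaled* rates when ``weight_scaled``
    (default) and the original ones otherwise.
    """
    if isinstance(carrier_tables, IncidenceTable):
        carrier_tables = [carrier_tables]
    if isinstance(noncarrier_tables, IncidenceTable):
        noncarrier_tables = [noncarrier_tables]
    nc_by_sex = {t.sex: t for t in noncarrier_tables}
    new_nc, new_c = [], []
    for ct in carrier_tables:
        nc = nc_by_sex[ct.sex]
        scaled_nc = nc.scaled(factor)
        base_nc = scaled_nc if weight_scaled else nc
        mixed = (1.0 - excess) * base_nc.rate + excess * ct.rate
        new_nc.append(scaled_nc)
        new_c.append(ct.with_rates(mixed))
    pen = incidence_to_penetrance(new_c, new_nc)
    return DiseaseModel(penetrance=pen, allele_frequency=allele_frequency)


def sensitivity_analysis(peds, carrier_tables, noncarrier_tables,
                         allele_frequency: float = 0.001,
                         factor_grid=None, excess_grid=None,
                         weight_scaled: bool = True) -> SensitivityGrid:
    """FLB surface over perturbed penetrance assumptions (one or more families)."""
    if isinstance(peds, Pedigree):
        peds = [peds]
    factors = np.linspace(0.5, 1.5, 21) if factor_grid is None \
        else np.asarray(factor_grid, dtype=float)
    excesses = np.linspace(0.0, 1.0, 21) if excess_grid is None \
        else np.asarray(excess_grid, dtype=float)
    if factors.min() < 0.5 - 1e-9 or factors.max() > 1.5 + 1e-9:
        raise DataFormatError("factor grid must lie within [0.50, 1.50]")
    if excesses.min() < -1e-9 or excesses.max() > 1.0 + 1e-9:
        raise DataFormatError("excess grid must lie within [0, 1]")

    Z = np.empty((factors.size, excesses.size))
    for i, f in enumerate(factors):
        for j, e in enumerate(excesses):
            model = perturbed_model(carrier_tables, noncarrier_tables,
                                    float(f), float(e), allele_frequency,
                                    weight_scaled)
            log_flb = sum(compute_flb(p, model).log_flb for p in peds)
            Z[i, j] = math.exp(log_flb)
    return SensitivityGrid(factors, excesses, Z)


# ---------------------------------------------------------------------------
# Iso-level contour of the FLB surface (marching squares)
# ---------------------------------------------------------------------------

def flb_contour(grid: SensitivityGrid, level: float) -> list[list[tuple]]:
    """Piecewise-linear iso-contour of the FLB surface at ``level``.

    Returns a list of polylines, each a list of (factor, excess) points; the
    surface is interpolated bilinearly, so every returned point lies on a
    cell edge where linear interpolation along the edge equals ``level``.
    Empty when the surface never crosses the level.
    """
    if level <= 0:
        raise DataFormatError("contour level must be positive")
    xs, ys, Z = grid.factors, grid.excess_fractions, grid.flb_values
    if xs.size < 2 or ys.size < 2:
        raise DataFormatError("degenerate grid: need at least 2 points per axis")

    # nudge corners lying exactly on the level (simulation-of-simplicity),
    # so every crossing is a strict sign change
    eps = max(abs(level), 1.0) * 1e-12
    Z = np.where(Z == level, level + eps, Z)

    segments = []
    for i in range(xs.size - 1):
        for j in range(ys.size - 1):
            corners = [
                (xs[i], ys[j], Z[i, j]),
                (xs[i + 1], ys[j], Z[i + 1, j]),
                (xs[i + 1], ys[j + 1], Z[i + 1, j + 1]),
                (xs[i], ys[j + 1], Z[i, j + 1]),
            ]
            pts = []
            for a in range(4):
                x1, y1, z1 = corners[a]
                x2, y2, z2 = corners[(a + 1) % 4]
                if (z1 - level) * (z2 - level) < 0:
                    t = (level - z1) / (z2 - z1)
                    pts.append((float(x1 + t * (x2 - x1)),
                                float(y1 + t * (y2 - y1))))
            pts = list(dict.fromkeys(pts))
            if len(pts) == 2:
                segments.append((pts[0], pts[1]))
            elif len(pts) == 4:
                # saddle cell: pair crossings by edge order
                segments.append((pts[0], pts[1]))
                segments.append((pts[2], pts[3]))

    return _chain_segments(segments)


def _chain_segments(segments) -> list[list[tuple]]:
    """Connect unordered segments into polylines by matching endpoints."""
    def key(p):
        return (round(p[0], 9), round(p[1], 9))

    unused = list(segments)
    polylines = []
    while unused:
        a, b = unused.pop()
        line = [a, b]
        grew = True
        while grew:
            grew = False
            for idx, (p, q) in enumerate(unused):
                if key(p) == key(line[-1]):
                    line.append(q)
                elif key(q) == key(line[-1]):
                    line.append(p)
                elif key(p) == key(line[0]):
                    line.insert(0, q)
                elif key(q) == key(line[0]):
                    line.insert(0, p)
                else:
                    continue
                unused.pop(idx)
                grew = True
                break
        polylines.append(line)
    return polylines
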
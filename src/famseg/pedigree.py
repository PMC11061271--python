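"""Pedigree data model and single-locus likelihood engine.

The likelihood is for a biallelic autosomal locus under a dominant disease
model.  Genotypes are coded by risk-allele dosage g in {0, 1, 2}; founders
follow Hardy-Weinberg proportions at the model allele frequency, offspring
follow Mendelian transmission, and each individual contributes a phenotype
term from their liability class (sex x age group, carrier vs non-carrier
penetrance).  Under the ``causal`` hypothesis the phenotype term depends on
genotype (dosage >= 1 uses carrier penetrance — dominance); under
``neutral`` every individual uses the non-carrier penetrance regardless of
genotype.  Carrier-test results enter as hard evidence restricting the
genotype state space.

Likelihoods are computed by variable elimination on the pedigree's factor
graph (Elston-Stewart-style peeling, generalised by a greedy elimination
order so that small marriage loops are handled exactly), with running
rescaling so that the result is accumulated in log space.  Pedigrees whose
elimination would blow up fall back to exhaustive genotype enumeration when
at most 12 members are untyped, otherwise they are rejected.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ComplexityError, PedigreeError

MALE = "male"
FEMALE = "female"
AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"
CARRIER = "carrier"
NON_CARRIER = "non_carrier"
UNTESTED = "untested"

CAUSAL = "causal"
NEUTRAL = "neutral"

__all__ = [
    "Individual", "Pedigree", "DiseaseModel",
    "pedigree_likelihood", "pedigree_loglik", "validate_pedigree",
    "MALE", "FEMALE", "AFFECTED", "UNAFFECTED", "UNKNOWN",
    "CARRIER", "NON_CARRIER", "UNTESTED", "CAUSAL", "NEUTRAL",
]


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``age`` is age at diagnosis for affected individuals and age at last
    observation otherwise; ``None`` means unknown (assigned the average
    liability class).
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = MALE
    affected: str = UNKNOWN
    age: int | None = None
    carrier_status: str = UNTESTED
    is_proband: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    family_id: str
    members: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {m.id: i for i, m in enumerate(self.members)}
        if len(self._index) != len(self.members):
            raise PedigreeError(f"duplicate individual ids in family {self.family_id}")

    def member(self, ind_id: str) -> Individual:
        return self.members[self._index[ind_id]]

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._index

    def __len__(self) -> int:
        return len(self.members)

    @property
    def probands(self) -> list[Individual]:
        return [m for m in self.members if m.is_proband]

    def replaced(self, **per_member_updates) -> "Pedigree":
        """Copy with per-member field updates: {id: {field: value}}."""
        updates = per_member_updates.get("updates", {})
        new = [replace(m, **updates.get(m.id, {})) for m in self.members]
        return Pedigree(self.family_id, new)


@dataclass
class DiseaseModel:
    """Autosomal dominant single-locus disease model.

    ``penetrance`` is any object with a ``risk(sex, age, carrier) -> float``
    method (see :mod:`famseg.penetrance`).
    """

    penetrance: object
    allele_frequency: float = 0.001
    inheritance: str = "autosomal_dominant"

    def __post_init__(self) -> None:
        if not (0.0 < self.allele_frequency < 1.0):
            raise PedigreeError("allele frequency must be in (0, 1)")
        if self.inheritance != "autosomal_dominant":
            raise PedigreeError(f"unsupported inheritance {self.inheritance!r}")

    def founder_prior(self) -> np.ndarray:
        p = self.allele_frequency
        return np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_pedigree(ped: Pedigree) -> list[str]:
    """Return human-readable descriptions of invariant violations (never raises)."""
    problems: list[str] = []
    for m in ped.members:
        has_f, has_m = m.father_id is not None, m.mother_id is not None
        if has_f != has_m:
            problems.append(f"{m.id}: has exactly one parent (needs none or both)")
        for pid, role, want in ((m.father_id, "father", MALE),
                                (m.mother_id, "mother", FEMALE)):
            if pid is None:
                continue
            if pid not in ped:
                problems.append(f"{m.id}: {role} {pid!r} not in pedigree")
            elif ped.member(pid).sex != want:
                problems.append(f"{m.id}: {role} {pid} is not {want}")
        if m.sex not in (MALE, FEMALE):
            problems.append(f"{m.id}: invalid sex {m.sex!r}")

    # ancestor cycles (includes self-parenthood)
    colour: dict[str, int] = {}

    def visit(ind_id: str, stack: list[str]) -> None:
        colour[ind_id] = 1
        stack.append(ind_id)
        m = ped.member(ind_id)
        for pid in (m.father_id, m.mother_id):
            if pid is None or pid not in ped:
                continue
            if colour.get(pid, 0) == 1:
                cycle = stack[stack.index(pid):] + [pid]
                problems.append(
                    f"{ind_id}: ancestor cycle {' -> '.join(cycle)}")
            elif colour.get(pid, 0) == 0:
                visit(pid, stack)
        stack.pop()
        colour[ind_id] = 2

    for m in ped.members:
        if colour.get(m.id, 0) == 0:
            visit(m.id, [])

    probands = ped.probands
    if len(probands) > 1:
        problems.append(
            "multiple probands: " + ", ".join(p.id for p in probands)
            + " (co-segregation analysis conditions on a unique proband)")
    for p in probands:
        if p.carrier_status != CARRIER:
            problems.append(f"{p.id}: proband must be a confirmed carrier")
    return problems


def _check_structure(ped: Pedigree) -> None:
    problems = validate_pedigree(ped)
    structural = [p for p in problems if "proband" not in p]
    if structural:
        raise PedigreeError("; ".join(structural))


# ---------------------------------------------------------------------------
# Factors
# ---------------------------------------------------------------------------

def _transmission_tensor() -> np.ndarray:
    """T[gc, gf, gm] = P(child dosage | father dosage, mother dosage)."""
    T = np.zeros((3, 3, 3))
    for gf in range(3):
        for gm in range(3):
            pf, pm = gf / 2.0, gm / 2.0
            T[0, gf, gm] = (1 - pf) * (1 - pm)
            T[1, gf, gm] = pf * (1 - pm) + (1 - pf) * pm
            T[2, gf, gm] = pf * pm
    return T


_TRANS = _transmission_tensor()


def _evidence_vector(ind: Individual, model: DiseaseModel,
                     hypothesis: str) -> np.ndarray:
    """P(phenotype, carrier-test | genotype) over dosages 0,1,2."""
    v = np.ones(3)
    if ind.carrier_status == CARRIER:
        v[0] = 0.0
    elif ind.carrier_status == NON_CARRIER:
        v[1] = v[2] = 0.0
    if ind.affected != UNKNOWN:
        for g in range(3):
            carrier = (g > 0) if hypothesis == CAUSAL else False
            F = model.penetrance.risk(ind.sex, ind.age, carrier)
            v[g] *= F if ind.affected == AFFECTED else 1.0 - F
    return v


def _build_factors(ped: Pedigree, model: DiseaseModel, hypothesis: str):
    """(scope tuple of member indices, table) factors for the pedigree."""
    idx = {m.id: i for i, m in enumerate(ped.members)}
    prior = model.founder_prior()
    factors = []
    for i, m in enumerate(ped.members):
        if m.is_founder:
            factors.append(((i,), prior.copy()))
        else:
            fi, mi = idx[m.father_id], idx[m.mother_id]
            factors.append(((i, fi, mi), _TRANS.copy()))
        factors.append(((i,), _evidence_vector(m, model, hypothesis)))
    return factors


# ---------------------------------------------------------------------------
# Variable elimination with log rescaling
# ---------------------------------------------------------------------------

def _multiply(f1, f2):
    s1, t1 = f1
    s2, t2 = f2
    scope = tuple(dict.fromkeys(s1 + s2))  # ordered union
    return scope, _align(s1, t1, scope) * _align(s2, t2, scope)


def _align(scope_from, table, scope_to):
    """Broadcast ``table`` (axes ``scope_from``) into the axes of ``scope_to``."""
    order = sorted(range(len(scope_from)),
                   key=lambda ax: scope_to.index(scope_from[ax]))
    t = np.transpose(table, order)
    shape = tuple(3 if v in scope_from else 1 for v in scope_to)
    return t.reshape(shape)


def _eliminate_all(factors, n_vars: int, max_scope: int = 10) -> float:
    """Sum out every variable; return log of the total sum.

    Raises ComplexityError if an intermediate factor would exceed
    ``max_scope`` variables.
    """
    log_scale = 0.0
    factors = [(tuple(s), np.asarray(t, dtype=float)) for s, t in factors]
    remaining = set(range(n_vars))

    while remaining:
        # greedy: eliminate the variable whose merged factor is smallest
        best_var, best_scope = None, None
        for v in remaining:
            scope: dict = {}
            for s, _ in factors:
                if v in s:
                    for u in s:
                        scope[u] = None
            merged = tuple(scope)
            if best_scope is None or len(merged) < len(best_scope):
                best_var, best_scope = v, merged
        if len(best_scope) > max_scope:
            raise ComplexityError(
                f"elimination scope of {len(best_scope)} variables exceeds "
                f"supported size {max_scope}")
        v = best_var
        involved = [f for f in factors if v in f[0]]
        rest = [f for f in factors if v not in f[0]]
        prod_scope, prod = involved[0]
        prod = prod.copy()
        cur = (prod_scope, prod)
        for f in involved[1:]:
            cur = _multiply(cur, f)
        scope, table = cur
        table = table.sum(axis=scope.index(v))
        scope = tuple(u for u in scope if u != v)
        mx = float(table.max()) if table.size else 0.0
        if mx <= 0.0:
            return -math.inf
        table = table / mx
        log_scale += math.log(mx)
        rest.append((scope, table))
        factors = rest
        remaining.discard(v)

    total = 1.0
    for _, t in factors:  # every remaining factor is scalar by now
        total *= float(np.asarray(t).reshape(()))
    if total <= 0.0:
        return -math.inf
    return log_scale + math.log(total)


def _allowed_states(ind: Individual) -> tuple[int, ...]:
    if ind.carrier_status == CARRIER:
        return (1, 2)
    if ind.carrier_status == NON_CARRIER:
        return (0,)
    return (0, 1, 2)


def _enumerate_loglik(ped: Pedigree, model: DiseaseModel, hypothesis: str) -> float:
    """Exhaustive sum over genotype vectors (fallback for small looped pedigrees)."""
    n = len(ped.members)
    idx = {m.id: i for i, m in enumerate(ped.members)}
    prior = model.founder_prior()
    evid = [_evidence_vector(m, model, hypothesis) for m in ped.members]
    states = [_allowed_states(m) for m in ped.members]
    total = 0.0
    for combo in itertools.product(*states):
        p = 1.0
        for i, m in enumerate(ped.members):
            g = combo[i]
            if m.is_founder:
                p *= prior[g]
            else:
                p *= _TRANS[g, combo[idx[m.father_id]], combo[idx[m.mother_id]]]
            p *= evid[i][g]
            if p == 0.0:
                break
        total += p
    if total <= 0.0:
        return -math.inf
    return math.log(total)


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def pedigree_loglik(ped: Pedigree, model: DiseaseModel,
                    hypothesis: str) -> float:
    """Log P(phenotypes, carrier tests | hypothesis) for the whole pedigree.

    Returns ``-inf`` when the observed data are impossible under the model
    (e.g. a carrier child of two confirmed non-carriers).
    """
    if hypothesis not in (CAUSAL, NEUTRAL):
        raise PedigreeError(f"unknown hypothesis {hypothesis!r}")
    _check_structure(ped)
    factors = _build_factors(ped, model, hypothesis)
    try:
        return _eliminate_all(factors, len(ped.members))
    except ComplexityError:
        n_untyped = sum(1 for m in ped.members
                        if m.carrier_status == UNTESTED)
        if n_untyped <= 12:
            return _enumerate_loglik(ped, model, hypothesis)
        raise


def pedigree_likelihood(ped: Pedigree, model: DiseaseModel,
                        hypothesis: str) -> float:
    """P(phenotypes, carrier tests | hypothesis); see :func:`pedigree_loglik`."""
    ll = pedigree_loglik(ped, model, hypothesis)
    return math.exp(ll) if ll > -math.inf else 0.0
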
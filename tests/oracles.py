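"""Independent reference implementations used as test oracles.

Everything here recomputes quantities from first principles (exhaustive
enumeration, quadratic recounts, closed forms) without touching the
package's own algorithmic paths.
"""

import itertools

import numpy as np

from famseg import DiseaseModel, Individual, Pedigree, PenetranceModel
from famseg.pedigree import (AFFECTED, CARRIER, FEMALE, MALE, NON_CARRIER,
                             UNAFFECTED, UNKNOWN, UNTESTED)

# Mendelian transmission table, written out independently
_TRANS = np.zeros((3, 3, 3))
for _gf in range(3):
    for _gm in range(3):
        _pf, _pm = _gf / 2.0, _gm / 2.0
        _TRANS[0, _gf, _gm] = (1 - _pf) * (1 - _pm)
        _TRANS[1, _gf, _gm] = _pf * (1 - _pm) + (1 - _pf) * _pm
        _TRANS[2, _gf, _gm] = _pf * _pm


def brute_force_likelihood(ped: Pedigree, model: DiseaseModel,
                           hypothesis: str) -> float:
    """Sum over all 3^n genotype vectors of the joint probability."""
    members = ped.members
    idx = {m.id: i for i, m in enumerate(members)}
    p = model.allele_frequency
    prior = [(1 - p) ** 2, 2 * p * (1 - p), p * p]
    total = 0.0
    for combo in itertools.product(range(3), repeat=len(members)):
        pr = 1.0
        for i, m in enumerate(members):
            g = combo[i]
            if m.father_id is None:
                pr *= prior[g]
            else:
                pr *= _TRANS[g, combo[idx[m.father_id]], combo[idx[m.mother_id]]]
            if m.carrier_status == CARRIER and g == 0:
                pr = 0.0
            elif m.carrier_status == NON_CARRIER and g > 0:
                pr = 0.0
            if pr == 0.0:
                break
            if m.affected != UNKNOWN:
                carrier = (g > 0) if hypothesis == "causal" else False
                F = model.penetrance.risk(m.sex, m.age, carrier)
                pr *= F if m.affected == AFFECTED else 1.0 - F
        total += pr
    return total


def brute_force_flb(ped: Pedigree, model: DiseaseModel) -> float:
    """FLB by enumeration: data likelihood over proband-only likelihood,
    causal over neutral."""
    from dataclasses import replace

    stripped = Pedigree(ped.family_id, [
        m if m.is_proband else replace(m, affected=UNKNOWN,
                                       carrier_status=UNTESTED)
        for m in ped.members])
    num = (brute_force_likelihood(ped, model, "causal")
           / brute_force_likelihood(stripped, model, "causal"))
    den = (brute_force_likelihood(ped, model, "neutral")
           / brute_force_likelihood(stripped, model, "neutral"))
    return num / den


def random_pedigree(rng: np.random.Generator, n: int,
                    consistent_genotypes: bool = False) -> Pedigree:
    """Random pedigree of n members (founder couples plus children).

    With ``consistent_genotypes`` the carrier observations come from a
    gene-dropped genotype vector, so the likelihood can never be zero.
    """
    males, females, rows = [], [], []
    for k in range(n):
        iid = f"i{k}"
        sex = MALE if rng.random() < 0.5 else FEMALE
        if rows and males and females and rng.random() < 0.6:
            fa = males[int(rng.integers(len(males)))]
            mo = females[int(rng.integers(len(females)))]
        else:
            fa = mo = None
        (males if sex == MALE else females).append(iid)
        rows.append((iid, fa, mo, sex))

    geno = {}
    for iid, fa, mo, _sex in rows:
        if fa is None:
            geno[iid] = int(rng.choice(3, p=[0.49, 0.42, 0.09]))
        else:
            geno[iid] = int((rng.random() < geno[fa] / 2.0)
                            + (rng.random() < geno[mo] / 2.0))

    members = []
    for iid, fa, mo, sex in rows:
        affected = [AFFECTED, UNAFFECTED, UNKNOWN][int(rng.integers(3))]
        age = None if rng.random() < 0.2 else int(rng.integers(20, 85))
        if consistent_genotypes:
            if rng.random() < 0.7:
                status = CARRIER if geno[iid] > 0 else NON_CARRIER
            else:
                status = UNTESTED
        else:
            status = [CARRIER, NON_CARRIER, UNTESTED][int(rng.integers(3))]
        members.append(Individual(iid, fa, mo, sex, affected, age, status))
    return Pedigree("RAND", members)


def random_disease_model(rng: np.random.Generator) -> DiseaseModel:
    """Random two-age-group penetrance model for both sexes."""
    age_lo = np.array([0.0, 40.0])
    age_hi = np.array([40.0, 130.0])
    curves = {}
    for sex in (MALE, FEMALE):
        for car in (True, False):
            curves[(sex, car)] = np.sort(rng.uniform(0.02, 0.95, 2))
    pen = PenetranceModel.from_cumulative(age_lo, age_hi, curves)
    return DiseaseModel(penetrance=pen,
                        allele_frequency=float(rng.uniform(0.001, 0.3)))


def quadratic_w(sites, radius_bp: int = 1_000_000,
                include_self: bool = True) -> np.ndarray:
    """O(n^2) recount of the IBS=0 neighbourhood fraction."""
    n = len(sites)
    out = np.zeros(n)
    ibs0 = [2 - abs(s.genotypes[0] - s.genotypes[1]) == 0 for s in sites]
    for i in range(n):
        cnt = tot = 0
        for j in range(n):
            if sites[j].chrom != sites[i].chrom:
                continue
            if abs(sites[j].pos - sites[i].pos) > radius_bp:
                continue
            if j == i and not include_self:
                continue
            tot += 1
            cnt += ibs0[j]
        out[i] = cnt / tot if tot else 0.0
    return out


def bilinear_eval(xs, ys, Z, x, y) -> float:
    """Independent bilinear interpolation on a rectilinear grid."""
    i = int(np.clip(np.searchsorted(xs, x) - 1, 0, len(xs) - 2))
    j = int(np.clip(np.searchsorted(ys, y) - 1, 0, len(ys) - 2))
    tx = (x - xs[i]) / (xs[i + 1] - xs[i])
    ty = (y - ys[j]) / (ys[j + 1] - ys[j])
    return ((1 - tx) * (1 - ty) * Z[i, j] + tx * (1 - ty) * Z[i + 1, j]
            + (1 - tx) * ty * Z[i, j + 1] + tx * ty * Z[i + 1, j + 1])
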
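"""Synthetic inputs for every stage of the pipeline.

Three generators, all deterministic under a fixed seed:

* :func:`simulate_pedigree` — gene dropping on a family template: founder
  genotypes from Hardy-Weinberg (optionally forcing a carrier founder),
  Mendelian transmission, and affection status sampled from the liability
  class given genotype under the ``causal`` hypothesis or from the
  non-carrier class under ``neutral``.  The proband is a randomly chosen
  affected carrier.

* :func:`simulate_pair` — paired diploid genotypes along one chromosome.
  Outside planted segments the samples' genotypes are independent
  Hardy-Weinberg draws per site; inside a planted segment the two samples
  share exactly one haplotype (which forbids opposite homozygotes, the
  IBS = 0 signal the w-statistic detects, up to genotyping error).  Errors
  flip a dosage to an adjacent value with the given probability, applied
  independently to both samples.  DP/GQ/FILTER are drawn so that a
  realistic minority of sites fails the hard quality filter.

* :func:`make_incidence` — 5-year age-group incidence tables with events
  and person-years, log-linear in age by default (a good description of
  adult "any cancer" incidence), with optional Poisson noise.  Default
  parameter sets emulate a high-risk mismatch-repair carrier cohort and a
  Nordic general population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataFormatError, FamsegError
from .ibd import GeneticMap, VariantSite
from .pedigree import (AFFECTED, CARRIER, FEMALE, MALE, NON_CARRIER,
                       UNAFFECTED, UNTESTED, CAUSAL, NEUTRAL,
                       DiseaseModel, Individual, Pedigree)
from .penetrance import IncidenceTable

__all__ = [
    "PedigreeSimSpec", "PairSimSpec",
    "simulate_pedigree", "simulate_pair", "make_incidence",
    "default_carrier_incidence", "default_population_incidence",
    "default_disease_model",
]


# ---------------------------------------------------------------------------
# Pedigree simulation (gene dropping)
# ---------------------------------------------------------------------------

#: structure rows: (id, father, mother, sex, generation index)
_TEMPLATES = {
    "nuclear": [
        ("F1", None, None, MALE, 0), ("F2", None, None, FEMALE, 0),
        ("C1", "F1", "F2", MALE, 1), ("C2", "F1", "F2", FEMALE, 1),
        ("C3", "F1", "F2", MALE, 1), ("C4", "F1", "F2", FEMALE, 1),
    ],
    "three_generation": [
        ("G1", None, None, MALE, 0), ("G2", None, None, FEMALE, 0),
        ("P1", "G1", "G2", MALE, 1), ("S1", None, None, FEMALE, 1),
        ("P2", "G1", "G2", FEMALE, 1), ("S2", None, None, MALE, 1),
        ("P3", "G1", "G2", FEMALE, 1), ("S3", None, None, MALE, 1),
        ("K1", "P1", "S1", MALE, 2), ("K2", "P1", "S1", FEMALE, 2),
        ("K3", "S2", "P2", FEMALE, 2), ("K4", "S2", "P2", MALE, 2),
        ("K5", "S3", "P3", MALE, 2), ("K6", "S3", "P3", FEMALE, 2),
    ],
}

_DEFAULT_AGE_RANGES = ((65, 90), (40, 65), (15, 40), (5, 15))


@dataclass
class PedigreeSimSpec:
    """Conditions for one simulated family."""

    model: DiseaseModel
    template: str | list = "three_generation"
    hypothesis: str = CAUSAL
    founder_carrier: bool = True
    typing_probability: float = 0.9
    age_ranges: tuple = _DEFAULT_AGE_RANGES
    family_id: str = "SIM1"
    seed: int = 0
    max_retries: int = 1000

    def structure(self) -> list:
        if isinstance(self.template, str):
            try:
                return _TEMPLATES[self.template]
            except KeyError:
                raise DataFormatError(
                    f"unknown template {self.template!r}; "
                    f"choose from {sorted(_TEMPLATES)} or pass rows") from None
        return list(self.template)


def _drop_genotypes(rows, rng, p, founder_carrier):
    geno = {}
    founders = [r for r in rows if r[1] is None]
    forced = founders[0][0] if founder_carrier and founders else None
    for iid, fa, mo, _sex, _gen in rows:
        if fa is None:
            if iid == forced:
                geno[iid] = 1
            else:
                geno[iid] = int(rng.choice(3, p=[(1 - p) ** 2,
                                                 2 * p * (1 - p), p * p]))
        else:
            gf, gm = geno[fa], geno[mo]
            geno[iid] = int((rng.random() < gf / 2.0)
                            + (rng.random() < gm / 2.0))
    return geno


def simulate_pedigree(spec: PedigreeSimSpec) -> Pedigree:
    """Gene-drop a family and sample phenotypes; proband = affected carrier.

    Raises FamsegError when no affected carrier arises within the retry cap
    (e.g. when carrier penetrance is zero).
    """
    if not 0.0 <= spec.typing_probability <= 1.0:
        raise DataFormatError("typing_probability must be in [0, 1]")
    if spec.hypothesis not in (CAUSAL, NEUTRAL):
        raise DataFormatError(f"unknown hypothesis {spec.hypothesis!r}")
    rows = spec.structure()
    rng = np.random.default_rng(spec.seed)
    model = spec.model

    for _attempt in range(spec.max_retries):
        geno = _drop_genotypes(rows, rng, model.allele_frequency,
                               spec.founder_carrier)
        members = []
        affected_carriers = []
        for iid, fa, mo, sex, gen in rows:
            lo, hi = spec.age_ranges[min(gen, len(spec.age_ranges) - 1)]
            age = int(rng.integers(lo, hi))
            carrier = geno[iid] > 0
            use_carrier_class = carrier if spec.hypothesis == CAUSAL else False
            risk = model.penetrance.risk(sex, age, use_carrier_class)
            affected = AFFECTED if rng.random() < risk else UNAFFECTED
            typed = rng.random() < spec.typing_probability
            status = (CARRIER if carrier else NON_CARRIER) if typed else UNTESTED
            members.append(Individual(iid, fa, mo, sex, affected, age,
                                      status, False))
            if affected == AFFECTED and carrier:
                affected_carriers.append(len(members) - 1)
        if affected_carriers:
            k = int(rng.choice(affected_carriers))
            pb = members[k]
            members[k] = Individual(pb.id, pb.father_id, pb.mother_id, pb.sex,
                                    pb.affected, pb.age, CARRIER, True)
            return Pedigree(spec.family_id, members)

    raise FamsegError(
        f"no affected carrier arose in {spec.max_retries} attempts; "
        f"check that carrier penetrance is non-zero")


# ---------------------------------------------------------------------------
# Paired genotypes with planted IBD segments
# ---------------------------------------------------------------------------

@dataclass
class PairSimSpec:
    """Conditions for one simulated two-sample genotype comparison."""

    chrom: str = "2"
    chrom_length_bp: int = 50_000_000
    variant_density: float = 0.001          # variants per bp (~1/kb)
    allele_freq_range: tuple = (0.05, 0.5)
    planted_segments: tuple = ()            # ((start_bp, length_cm), ...)
    genotype_error_rate: float = 0.002
    dp_mean: float = 30.0
    gq_high: int = 99
    gq_high_prob: float = 0.9
    pass_prob: float = 0.98
    gmap: GeneticMap = field(default_factory=GeneticMap.uniform)
    seed: int = 0


def _segment_spans_bp(spec: PairSimSpec) -> list:
    spans = []
    for start_bp, length_cm in spec.planted_segments:
        start_cm = float(spec.gmap.cm_at(spec.chrom, start_bp))
        end_bp = float(spec.gmap.pos_at(spec.chrom, start_cm + length_cm))
        if start_bp < 1 or end_bp > spec.chrom_length_bp:
            raise DataFormatError(
                f"planted segment {start_bp}+{length_cm}cM exceeds chromosome")
        spans.append((float(start_bp), end_bp))
    spans.sort()
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise DataFormatError("planted segments overlap")
    return spans


def _apply_dosage_errors(dos: np.ndarray, rng, rate: float) -> np.ndarray:
    """Flip dosages to an adjacent value with probability ``rate``."""
    err = rng.random(dos.size) < rate
    direction = np.where(dos == 0, 1, np.where(dos == 2, -1,
                         np.where(rng.random(dos.size) < 0.5, -1, 1)))
    return np.where(err, dos + direction, dos)


def simulate_pair(spec: PairSimSpec) -> list:
    """Simulate the paired genotype data of two distantly related samples."""
    if spec.variant_density <= 0:
        raise DataFormatError("variant density must be positive")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.chrom_length_bp * spec.variant_density))
    pos = np.unique(rng.integers(1, spec.chrom_length_bp + 1,
                                 size=int(n * 1.1)))
    if pos.size > n:
        pos = np.sort(rng.choice(pos, size=n, replace=False))

    lo, hi = spec.allele_freq_range
    p = rng.uniform(lo, hi, size=pos.size)

    h1a = (rng.random(pos.size) < p).astype(np.int8)
    h1b = (rng.random(pos.size) < p).astype(np.int8)
    h2a = (rng.random(pos.size) < p).astype(np.int8)
    h2b = (rng.random(pos.size) < p).astype(np.int8)

    shared = np.zeros(pos.size, dtype=bool)
    for s_bp, e_bp in _segment_spans_bp(spec):
        shared |= (pos >= s_bp) & (pos <= e_bp)
    h2a[shared] = h1a[shared]  # one haplotype identical by descent

    g1 = _apply_dosage_errors(h1a + h1b, rng, spec.genotype_error_rate)
    g2 = _apply_dosage_errors(h2a + h2b, rng, spec.genotype_error_rate)

    dp1 = rng.poisson(spec.dp_mean, pos.size)
    dp2 = rng.poisson(spec.dp_mean, pos.size)
    gq1 = np.where(rng.random(pos.size) < spec.gq_high_prob, spec.gq_high,
                   rng.integers(0, 100, pos.size))
    gq2 = np.where(rng.random(pos.size) < spec.gq_high_prob, spec.gq_high,
                   rng.integers(0, 100, pos.size))
    filt = np.where(rng.random(pos.size) < spec.pass_prob, "PASS", "LowQual")

    refs = rng.choice(np.array(list("ACGT")), size=pos.size)
    alt_offset = rng.integers(1, 4, size=pos.size)
    bases = np.array(list("ACGT"))
    base_idx = np.searchsorted(bases, refs)
    alts = bases[(base_idx + alt_offset) % 4]

    return [VariantSite(chrom=spec.chrom, pos=int(pos[i]),
                        genotypes=(int(g1[i]), int(g2[i])),
                        filter=str(filt[i]),
                        depth=(int(dp1[i]), int(dp2[i])),
                        genotype_quality=(int(gq1[i]), int(gq2[i])),
                        ref=str(refs[i]), alt=str(alts[i]))
            for i in range(pos.size)]


# ---------------------------------------------------------------------------
# Incidence tables
# ---------------------------------------------------------------------------

def make_incidence(shape: str = "log_linear", sex: str = FEMALE,
                   age_max: int = 85, base_rate: float = 2e-4,
                   slope: float = 0.06, person_years: float = 1e5,
                   rates=None, poisson_noise: bool = False,
                   seed: int = 0) -> IncidenceTable:
    """Synthesise a 5-year-age-group incidence table.

    ``log_linear``: rate(age) = base_rate * exp(slope * midpoint) — the
    standard log-linear age trend of adult cancer incidence.  ``table``
    uses the explicitly supplied ``rates``.  Events are rate x person-years,
    Poisson-resampled when ``poisson_noise`` (rates then recomputed from
    the noisy counts).
    """
    age_lo = np.arange(0, age_max, 5, dtype=float)
    age_hi = age_lo + 5
    mid = age_lo + 2.5
    if shape == "log_linear":
        if base_rate < 0 or person_years <= 0:
            raise DataFormatError("negative parameters")
        rate = base_rate * np.exp(slope * mid)
    elif shape == "table":
        if rates is None:
            raise DataFormatError("shape='table' requires rates")
        rate = np.asarray(rates, dtype=float)
        if rate.size != age_lo.size:
            raise DataFormatError("rates length does not match the age grid")
        if np.any(rate < 0):
            raise DataFormatError("negative rates")
    else:
        raise DataFormatError(f"unknown incidence shape {shape!r}")

    py = np.full(age_lo.size, float(person_years))
    events = rate * py
    if poisson_noise:
        rng = np.random.default_rng(seed)
        events = rng.poisson(events).astype(float)
        rate = events / py
    return IncidenceTable(sex=sex, age_lo=age_lo, age_hi=age_hi,
                          rate=rate, events=events, person_years=py)


def default_carrier_incidence(sex: str) -> IncidenceTable:
    """Any-cancer incidence emulating a high-risk MSH2 carrier cohort
    (cumulative risk ~80-85% by age 70)."""
    return make_incidence(sex=sex, base_rate=1e-3, slope=0.07)


def default_population_incidence(sex: str) -> IncidenceTable:
    """Any-cancer incidence emulating a Nordic general population
    (cumulative risk ~25-30% by age 70)."""
    return make_incidence(sex=sex, base_rate=1.8e-4, slope=0.07)


def default_disease_model(allele_frequency: float = 0.001) -> DiseaseModel:
    """Disease model built from the default carrier/population tables."""
    from .penetrance import incidence_to_penetrance
    pen = incidence_to_penetrance(
        [default_carrier_incidence(s) for s in (MALE, FEMALE)],
        [default_population_incidence(s) for s in (MALE, FEMALE)])
    return DiseaseModel(penetrance=pen, allele_frequency=allele_frequency)
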
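"""Pairwise IBD-segment detection from two-sample genotypes.

Identity-by-descent segments between two individuals are inferred from
identity-by-state (IBS) along the genome, PLINK-style.  After a hard
quality filter (FILTER = PASS, both depths > 10, both genotype qualities
> 50, both genotypes called, biallelic SNV), each site's IBS state
(0, 1 or 2 shared alleles) is recorded together with w, the fraction of
sites with IBS = 0 within 1 Mb up- and downstream.  Maximal runs of
consecutive sites with w <= 0.5% that contain at least 100 variants and
span at least 1 cM are reported as IBD segments.

Genetic positions come from linear interpolation of a HapMap-style map
(chrom, bp, cM); with no map a uniform 1 cM/Mb is assumed (the genome-wide
average rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataFormatError

DEFAULT_RADIUS_BP = 1_000_000
DEFAULT_W_THRESHOLD = 0.005
DEFAULT_MIN_VARIANTS = 100
DEFAULT_MIN_CM = 1.0

__all__ = [
    "VariantSite", "IBDSegment", "GeneticMap",
    "filter_sites", "ibs_state", "neighborhood_w", "neighborhood_w_all",
    "call_segments", "interpolate_cm",
    "DEFAULT_RADIUS_BP", "DEFAULT_W_THRESHOLD",
    "DEFAULT_MIN_VARIANTS", "DEFAULT_MIN_CM",
]


@dataclass(slots=True)
class VariantSite:
    """One biallelic SNV with the two samples' genotypes and quality fields.

    Genotypes are risk-allele dosages 0/1/2 (``None`` = missing call);
    ``cm`` is the interpolated genetic position, filled by
    :func:`interpolate_cm`.
    """

    chrom: str
    pos: int
    genotypes: tuple
    filter: str = "PASS"
    depth: tuple = (0, 0)
    genotype_quality: tuple = (0, 0)
    ref: str = "A"
    alt: str = "C"
    cm: float | None = None


@dataclass(frozen=True)
class IBDSegment:
    chrom: str
    start_pos: int
    end_pos: int
    start_cm: float
    end_cm: float
    length_cm: float
    n_variants: int
    max_w: float

    def to_dict(self) -> dict:
        return {"chrom": self.chrom, "start_pos": self.start_pos,
                "end_pos": self.end_pos, "start_cm": self.start_cm,
                "end_cm": self.end_cm, "length_cm": self.length_cm,
                "n_variants": self.n_variants, "max_w": self.max_w}

    def midpoint_cm(self) -> float:
        return 0.5 * (self.start_cm + self.end_cm)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Piecewise-linear bp -> cM map per chromosome.

    ``points[chrom] = (pos_bp ascending, cm non-decreasing)``.  Outside the
    mapped range, positions are extrapolated with the terminal interval's
    recombination rate held constant.  ``uniform_rate`` (cM/Mb) makes the
    map defined for every chromosome.
    """

    points: dict = field(default_factory=dict)
    uniform_rate: float | None = None

    def __post_init__(self) -> None:
        for chrom, (pos, cm) in self.points.items():
            pos = np.asarray(pos, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if pos.size < 2:
                raise DataFormatError(f"map for {chrom}: need >= 2 points")
            if np.any(np.diff(pos) <= 0):
                raise DataFormatError(f"map for {chrom}: positions not ascending")
            if np.any(np.diff(cm) < 0):
                raise DataFormatError(f"map for {chrom}: cM decreasing")
            self.points[chrom] = (pos, cm)

    @classmethod
    def uniform(cls, rate_cm_per_mb: float = 1.0) -> "GeneticMap":
        return cls(points={}, uniform_rate=rate_cm_per_mb)

    def _table(self, chrom: str):
        if chrom in self.points:
            return self.points[chrom]
        if self.uniform_rate is not None:
            return None
        raise DataFormatError(f"chromosome {chrom!r} absent from genetic map")

    def cm_at(self, chrom: str, pos) -> np.ndarray:
        """Genetic position(s) in cM for physical position(s) in bp."""
        pos = np.asarray(pos, dtype=float)
        table = self._table(chrom)
        if table is None:
            return pos * self.uniform_rate / 1e6
        mp, mc = table
        cm = np.interp(pos, mp, mc)
        left_rate = (mc[1] - mc[0]) / (mp[1] - mp[0])
        right_rate = (mc[-1] - mc[-2]) / (mp[-1] - mp[-2])
        below = pos < mp[0]
        above = pos > mp[-1]
        cm = np.where(below, mc[0] - (mp[0] - pos) * left_rate, cm)
        cm = np.where(above, mc[-1] + (pos - mp[-1]) * right_rate, cm)
        return cm

    def pos_at(self, chrom: str, cm) -> np.ndarray:
        """Inverse lookup: physical position(s) for genetic position(s)."""
        cm = np.asarray(cm, dtype=float)
        table = self._table(chrom)
        if table is None:
            return cm / self.uniform_rate * 1e6
        mp, mc = table
        return np.interp(cm, mc, mp)


def interpolate_cm(sites: list, gmap: GeneticMap) -> list:
    """Fill each site's ``cm`` field from the genetic map (in place)."""
    by_chrom: dict = {}
    for i, s in enumerate(sites):
        by_chrom.setdefault(s.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        pos = np.array([sites[i].pos for i in idxs], dtype=float)
        cms = gmap.cm_at(chrom, pos)
        for i, c in zip(idxs, cms):
            sites[i].cm = float(c)
    return sites


# ---------------------------------------------------------------------------
# Filtering and IBS
# ---------------------------------------------------------------------------

def filter_sites(sites: list, min_dp: int = 10, min_gq: int = 50) -> list:
    """Keep sites with FILTER=PASS, both DP > min_dp, both GQ > min_gq,
    both genotypes called and a biallelic single-nucleotide ref/alt."""
    kept = []
    for s in sites:
        if s.filter != "PASS":
            continue
        if not (s.depth[0] > min_dp and s.depth[1] > min_dp):
            continue
        if not (s.genotype_quality[0] > min_gq and s.genotype_quality[1] > min_gq):
            continue
        if s.genotypes[0] is None or s.genotypes[1] is None:
            continue
        if len(s.ref) != 1 or len(s.alt) != 1 or s.ref == s.alt:
            continue
        kept.append(s)
    return kept


def ibs_state(g1, g2) -> int:
    """Number of alleles shared by state between two dosage genotypes."""
    if g1 is None or g2 is None:
        raise DataFormatError("IBS undefined for missing genotypes")
    if g1 not in (0, 1, 2) or g2 not in (0, 1, 2):
        raise DataFormatError(f"invalid dosages ({g1}, {g2})")
    return 2 - abs(g1 - g2)


def _check_sorted(sites: list) -> None:
    for a, b in zip(sites, sites[1:]):
        if a.chrom == b.chrom and b.pos < a.pos:
            raise DataFormatError("sites must be sorted by (chrom, pos)")


def neighborhood_w_all(sites: list, radius_bp: int = DEFAULT_RADIUS_BP,
                       include_self: bool = True) -> np.ndarray:
    """w for every site: fraction of sites within ±radius (same chromosome)
    whose IBS state is 0.  The site itself is included unless
    ``include_self=False``."""
    _check_sorted(sites)
    n = len(sites)
    w = np.empty(n)
    chroms = [s.chrom for s in sites]
    start = 0
    while start < n:
        end = start
        while end < n and chroms[end] == chroms[start]:
            end += 1
        pos = np.array([s.pos for s in sites[start:end]], dtype=np.int64)
        ibs0 = np.array([ibs_state(*s.genotypes) == 0
                         for s in sites[start:end]], dtype=np.float64)
        cum = np.r_[0.0, np.cumsum(ibs0)]
        lo = np.searchsorted(pos, pos - radius_bp, side="left")
        hi = np.searchsorted(pos, pos + radius_bp, side="right")
        counts = cum[hi] - cum[lo]
        totals = (hi - lo).astype(float)
        if not include_self:
            counts -= ibs0
            totals -= 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            w[start:end] = np.where(totals > 0, counts / totals, 0.0)
        start = end
    return w


def neighborhood_w(sites: list, index: int,
                   radius_bp: int = DEFAULT_RADIUS_BP,
                   include_self: bool = True) -> float:
    """w for a single site (see :func:`neighborhood_w_all`)."""
    if not 0 <= index < len(sites):
        raise DataFormatError(f"site index {index} out of range")
    return float(neighborhood_w_all(sites, radius_bp, include_self)[index])


# ---------------------------------------------------------------------------
# Segment calling
# ---------------------------------------------------------------------------

def call_segments(sites: list,
                  w_threshold: float = DEFAULT_W_THRESHOLD,
                  min_variants: int = DEFAULT_MIN_VARIANTS,
                  min_cm: float = DEFAULT_MIN_CM,
                  radius_bp: int = DEFAULT_RADIUS_BP,
                  include_self: bool = True) -> list:
    """Call IBD segments as maximal low-w runs on filtered, sorted,
    cM-annotated sites.

    A run is a maximal stretch of consecutive same-chromosome sites with
    w <= ``w_threshold``; it is reported iff it contains at least
    ``min_variants`` sites and spans at least ``min_cm`` centimorgans.
    """
    if not sites:
        return []
    for s in sites:
        if s.cm is None:
            raise DataFormatError(
                f"site {s.chrom}:{s.pos} has no genetic position; "
                f"run interpolate_cm first")
    w = neighborhood_w_all(sites, radius_bp, include_self)
    chroms = [s.chrom for s in sites]
    ok = w <= w_threshold

    segments = []
    i, n = 0, len(sites)
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1] and chroms[j + 1] == chroms[i]:
            j += 1
        run = sites[i:j + 1]
        span = run[-1].cm - run[0].cm
        if len(run) >= min_variants and span >= min_cm:
            segments.append(IBDSegment(
                chrom=run[0].chrom,
                start_pos=run[0].pos, end_pos=run[-1].pos,
                start_cm=run[0].cm, end_cm=run[-1].cm,
                length_cm=span, n_variants=len(run),
                max_w=float(np.max(w[i:j + 1]))))
        i = j + 1
    return segments
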
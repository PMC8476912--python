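"""Trait statistics and single-marker association for inbred panels.

Implements the statistical layer of the pipeline: per-trait summaries
(min/max/median/mean/SD/CV), trait-trait Pearson correlation, one-way
ANOVA of year (environment) effects, the single-marker general linear
model scan with marker R-squared and the 1/M significance threshold,
multi-year co-detection of marker-trait correlations, Wilcoxon rank-sum
haplotype comparison, and pairwise LD r-squared.

Genotypes are coded as additive alt-allele dosages (0/1/2); for a selfed
inbred panel the dosage is effectively two-valued {0, 2}, making the OLS
fit on dosage identical to a two-group ANOVA.  Missing phenotypes or
genotypes are dropped per test (pairwise-complete deletion).  The scan
threshold is 1/M at full precision, where M is the number of
analysis-eligible markers; no further multiple-testing correction is
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from mirvar.config import ScoringConfig, DEFAULT_CONFIG
from mirvar.errors import ValidationError

_EPS = 1e-12


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Accession x trait x year quantitative phenotypes (long format)."""

    df: pd.DataFrame  # columns: accession, trait, year, value

    REQUIRED = ("accession", "trait", "year", "value")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"trait table lacks columns {missing}")

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "TraitTable":
        """Build from a long table, averaging replicate measurements.

        Multiple rows for one (accession, trait, year) — e.g. field
        replicates — are averaged into a single value.
        """
        g = (df.groupby(["accession", "trait", "year"], as_index=False)
               ["value"].mean())
        return cls(g)

    @property
    def traits(self) -> list:
        return sorted(self.df["trait"].unique())

    @property
    def years(self) -> list:
        return sorted(self.df["year"].unique())

    @property
    def accessions(self) -> list:
        return sorted(self.df["accession"].unique())

    def values(self, trait: str, year) -> pd.Series:
        """Phenotype values for one trait-year, indexed by accession."""
        sub = self.df[(self.df["trait"] == trait) & (self.df["year"] == year)]
        return sub.set_index("accession")["value"]


@dataclass(frozen=True)
class TraitSummary:
    """Descriptive summary of one trait-year distribution."""

    n: int
    min: float
    max: float
    median: float
    mean: float
    sd: float  # sample SD, n-1 denominator
    cv: Optional[float]  # SD / mean; None when mean == 0

    def rounded(self, ndigits: int = 2) -> dict:
        """Tabular rendering (2-decimal convention); internals stay exact."""
        out = {k: round(getattr(self, k), ndigits)
               for k in ("min", "max", "median", "mean", "sd")}
        out["n"] = self.n
        out["cv"] = None if self.cv is None else round(self.cv, ndigits)
        return out


@dataclass(frozen=True)
class GLMFit:
    """Core of a single-marker OLS fit."""

    n: int
    effect: Optional[float]  # slope per alt-allele dosage unit
    r2: Optional[float]
    p: Optional[float]
    untestable: bool = False


@dataclass(frozen=True)
class AssociationResult:
    """One (variant, trait, year) test from the correlation scan."""

    variant_key: str
    trait: str
    year: object
    n: int
    effect: Optional[float]
    r2: Optional[float]
    p: Optional[float]
    significant: bool
    untestable: bool = False


@dataclass
class CorrelationScan:
    """All results of one scan plus the threshold that was applied."""

    results: List[AssociationResult]
    threshold: float  # full-precision 1/M
    m_markers: int

    @property
    def threshold_display(self) -> float:
        """The threshold as reported in text (3-decimal rounding)."""
        return round(self.threshold, 3)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variant": r.variant_key,
                    "trait": r.trait,
                    "year": r.year,
                    "n": r.n,
                    "effect": r.effect,
                    "r2": r.r2,
                    "p": r.p,
                    "significant": r.significant,
                }
                for r in self.results
            ]
        )


@dataclass(frozen=True)
class CoDetection:
    """Multi-year consistency of one (variant, trait) correlation."""

    variant_key: str
    trait: str
    years_significant: frozenset
    co_detected: bool
    neglog10_p: tuple  # per year, in year order
    r2_range: tuple  # (min, max) across years


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def trait_summary(values: Sequence[float]) -> TraitSummary:
    """n / min / max / median / mean / sample SD / CV of a trait vector.

    Missing values are dropped first; at least two non-missing values are
    required.  CV = SD/mean is undefined (None) for a zero mean.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValidationError(
            f"trait summary needs >= 2 values, got {v.size}")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    cv = None if mean == 0 else sd / mean
    return TraitSummary(
        n=int(v.size),
        min=float(v.min()),
        max=float(v.max()),
        median=float(np.median(v)),
        mean=mean,
        sd=sd,
        cv=cv,
    )


def summary_table(traits: TraitTable) -> pd.DataFrame:
    """Per (trait, year) summary table with the 2-decimal CV convention."""
    rows = []
    for trait in traits.traits:
        for year in traits.years:
            vals = traits.values(trait, year).dropna()
            if len(vals) < 2:
                continue
            s = trait_summary(vals.to_numpy()).rounded()
            rows.append({"trait": trait, "year": year, **s})
    return pd.DataFrame(rows)


def pairwise_trait_correlation(x, y):
    """Pearson correlation of two trait vectors with its t-test P.

    Pairwise-complete cases only (n >= 3 required); zero variance in
    either vector yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[m], y[m]
    if x.size < 3:
        raise ValidationError("pairwise-complete n must be >= 3")
    if x.std() <= _EPS or y.std() <= _EPS:
        return (float("nan"), float("nan"))
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def anova_year_effect(groups: Sequence[Sequence[float]]):
    """One-way ANOVA of year (environment) effects: returns (F, P)."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    arrs = [a[~np.isnan(a)] for a in arrs]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValidationError(
            "year-effect ANOVA needs >= 2 groups with >= 2 values each")
    f, p = sps.f_oneway(*arrs)
    return float(f), float(p)


def wilcoxon_rank_sum(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) P for two haplotype groups.

    Exact enumeration when the pooled sample is small (n_a + n_b <= 20)
    and tie-free; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue)


def ld_r2(dosages_1, dosages_2) -> float:
    """Pairwise LD as the squared Pearson correlation of dosage vectors."""
    x = np.asarray(dosages_1, dtype=float)
    y = np.asarray(dosages_2, dtype=float)
    m = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[m], y[m]
    if x.size < 2:
        raise ValidationError("pairwise-complete n must be >= 2")
    if x.std() <= _EPS or y.std() <= _EPS:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# single-marker GLM
# ---------------------------------------------------------------------------

def glm_single_marker(dosages, phenotypes) -> GLMFit:
    """OLS of phenotype on alt-allele dosage (intercept + slope).

    P comes from the F test with (1, n-2) degrees of freedom; marker
    R-squared is 1 - SSE/SST.  Pairwise-complete cases only.  A marker
    monomorphic after deletion (fewer than two distinct dosage values),
    or a constant phenotype, is flagged untestable rather than raising.
    """
    g = np.asarray(dosages, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    if g.shape != y.shape:
        raise ValidationError("dosage and phenotype vectors differ in length")
    m = ~np.isnan(g) & ~np.isnan(y)
    g, y = g[m], y[m]
    n = g.size
    if n < 3:
        return GLMFit(n=n, effect=None, r2=None, p=None, untestable=True)
    cxx = float(((g - g.mean()) ** 2).sum())
    cyy = float(((y - y.mean()) ** 2).sum())
    cxy = float(((g - g.mean()) * (y - y.mean())).sum())
    if cxx <= _EPS or cyy <= _EPS:
        return GLMFit(n=n, effect=None, r2=None, p=None, untestable=True)
    slope = cxy / cxx
    r2 = cxy * cxy / (cxx * cyy)
    r2 = min(r2, 1.0)
    if r2 >= 1.0:
        p = 0.0
    else:
        f = r2 * (n - 2) / (1.0 - r2)
        p = float(sps.f.sf(f, 1, n - 2))
    return GLMFit(n=n, effect=slope, r2=r2, p=p)


def correlation_scan(
    genotypes,
    traits: TraitTable,
    eligible: Optional[Sequence[str]] = None,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> CorrelationScan:
    """Scan every eligible marker against every trait-year.

    `genotypes` is a GenotypeMatrix; `eligible` lists the marker keys
    admitted to the scan (when omitted, eligibility — MAF above threshold
    with sufficient integrity — is computed from the matrix itself).  The
    significance threshold is 1/M at full precision, M being the number
    of eligible markers; the conventional display value rounds to three
    decimals.
    """
    if eligible is None:
        st = genotypes.stats(config)
        eligible = [k for k in genotypes.variant_keys
                    if bool(st.loc[k, "analysis_eligible"])]
    eligible = list(eligible)
    m_markers = len(eligible)
    if m_markers < 1:
        raise ValidationError("no analysis-eligible markers")
    threshold = 1.0 / m_markers

    df = genotypes.df[eligible]
    acc_index = df.index
    G = df.to_numpy(dtype=float)
    results: List[AssociationResult] = []
    for trait in traits.traits:
        for year in traits.years:
            y = traits.values(trait, year).reindex(acc_index).to_numpy(
                dtype=float)
            valid = (~np.isnan(G)) & (~np.isnan(y))[:, None]
            gv = np.where(valid, G, 0.0)
            yv = np.where(valid, y[:, None], 0.0)
            nk = valid.sum(axis=0).astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                sx, sy = gv.sum(0), yv.sum(0)
                cxx = (gv ** 2).sum(0) - sx * sx / nk
                cyy = (yv ** 2).sum(0) - sy * sy / nk
                cxy = (gv * yv).sum(0) - sx * sy / nk
                slope = cxy / cxx
                r2 = np.clip(cxy * cxy / (cxx * cyy), 0.0, 1.0)
                fstat = r2 * (nk - 2) / (1.0 - r2)
            bad = (nk < 3) | (cxx <= _EPS) | (cyy <= _EPS)
            pvals = np.full(G.shape[1], np.nan)
            ok = ~bad
            exact = ok & (r2 >= 1.0)
            approx = ok & (r2 < 1.0)
            pvals[approx] = sps.f.sf(fstat[approx], 1, nk[approx] - 2)
            pvals[exact] = 0.0
            for j, key in enumerate(eligible):
                if bad[j]:
                    results.append(AssociationResult(
                        variant_key=key, trait=trait, year=year,
                        n=int(nk[j]), effect=None, r2=None, p=None,
                        significant=False, untestable=True))
                else:
                    results.append(AssociationResult(
                        variant_key=key, trait=trait, year=year,
                        n=int(nk[j]), effect=float(slope[j]),
                        r2=float(r2[j]), p=float(pvals[j]),
                        significant=bool(pvals[j] <= threshold)))
    return CorrelationScan(results=results, threshold=threshold,
                           m_markers=m_markers)


def co_detect(
    results: Sequence[AssociationResult], years: Sequence
) -> List[CoDetection]:
    """Aggregate scan results into multi-year co-detections.

    A (variant, trait) pair is co-detected when it is significant in
    every analyzed year.  Reports per-year -log10(P) (in year order) and
    the min-max marker R-squared range across years.
    """
    years = sorted(years)
    grouped: Dict[tuple, dict] = {}
    for r in results:
        grouped.setdefault((r.variant_key, r.trait), {})[r.year] = r
    out = []
    for (key, trait) in sorted(grouped):
        per_year = grouped[(key, trait)]
        sig_years = frozenset(y for y in years
                              if y in per_year and per_year[y].significant)
        nlp = tuple(
            (-math.log10(per_year[y].p)
             if y in per_year and per_year[y].p not in (None, 0) else
             (math.inf if y in per_year and per_year[y].p == 0 else None))
            for y in years
        )
        r2s = [per_year[y].r2 for y in years
               if y in per_year and per_year[y].r2 is not None]
        r2_range = (min(r2s), max(r2s)) if r2s else (None, None)
        out.append(CoDetection(
            variant_key=key,
            trait=trait,
            years_significant=sig_years,
            co_detected=sig_years == frozenset(years),
            neglog10_p=nlp,
            r2_range=r2_range,
        ))
    return out
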
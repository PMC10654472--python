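"""Gene-level farmed-vs-wild statistics for candidate-gene genotypes.

Operates on individual diploid genotypes collected per population, where
each population carries an origin label (farmed / wild) and a collection
period (2004-2007 / 2012-2016).  Implements the statistical track used
for the *vgll3* / *six6* candidate-gene comparison:

* per-population allele and genotype frequencies;
* a two-sided Wilcoxon rank-sum test of farmed vs wild per-population
  frequencies (exact permutation enumeration at small n, normal
  approximation with tie correction otherwise);
* Hardy-Weinberg equilibrium tests per origin group (exact conditional
  test by default, chi-square optional);
* binomial logistic GLMs of per-population allele counts on origin and
  collection period, with stepwise AIC model selection over the lattice
  {1, origin, time, origin+time, origin x time}.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

logger = logging.getLogger(__name__)

__all__ = [
    "GENOTYPE_COLUMNS",
    "read_genotype_table",
    "write_genotype_table",
    "FreqTable",
    "compute_frequencies",
    "wilcoxon_origin_test",
    "wilcoxon_by_locus",
    "hwe_test",
    "hwe_by_origin",
    "GlmFit",
    "ModelSelectionResult",
    "reference_allele",
    "fit_origin_time_glm",
    "stepwise_aic",
]

GENOTYPE_COLUMNS = ["individual", "population", "origin", "period", "locus", "allele1", "allele2"]

MODEL_SCOPE = ("1", "origin", "time", "origin + time", "origin * time")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genotype_table(path) -> pd.DataFrame:
    """Read a tab-separated genotype table (one row per individual x locus)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"genotype table missing columns: {missing}")
    bad_origin = set(df["origin"]) - {"farmed", "wild"}
    if bad_origin:
        raise ValueError(f"unknown origin labels: {sorted(bad_origin)}")
    return df[GENOTYPE_COLUMNS]


def write_genotype_table(df: pd.DataFrame, path) -> None:
    df[GENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

@dataclass
class FreqTable:
    """Per population x locus allele and genotype counts and frequencies.

    ``allele_freqs`` columns: population, origin, period, locus, allele,
    count, freq, n (diploid individuals).  ``genotype_freqs`` columns:
    population, origin, period, locus, genotype (sorted "X/Y"), count, freq.
    """

    allele_freqs: pd.DataFrame
    genotype_freqs: pd.DataFrame


def compute_frequencies(table: pd.DataFrame, allele_set: set[str] | None = None) -> FreqTable:
    """Tabulate allele and genotype frequencies per population x locus.

    Rows with a missing allele are dropped; a population x locus cell left
    empty after that is excluded with a logged warning.  ``allele_set``
    optionally declares the legal allele symbols per check.
    """
    if table.empty:
        raise ValueError("empty genotype table")
    df = table.copy()
    na_mask = df["allele1"].isna() | df["allele2"].isna()
    if na_mask.any():
        dropped = df[na_mask]
        for (pop, locus), grp in dropped.groupby(["population", "locus"]):
            logger.warning("dropping %d genotypes with missing alleles in %s/%s", len(grp), pop, locus)
        df = df[~na_mask]
    if df.empty:
        raise ValueError("no callable genotypes after filtering")
    if allele_set is not None:
        seen = set(df["allele1"]) | set(df["allele2"])
        unknown = seen - set(allele_set)
        if unknown:
            raise ValueError(f"unknown allele symbols: {sorted(unknown)}")

    meta = df.groupby("population", sort=True)[["origin", "period"]].first()

    allele_rows, geno_rows = [], []
    for (pop, locus), grp in df.groupby(["population", "locus"], sort=True):
        n = len(grp)
        alleles = pd.concat([grp["allele1"], grp["allele2"]])
        counts = alleles.value_counts().sort_index()
        for allele, cnt in counts.items():
            allele_rows.append(
                dict(population=pop, origin=meta.loc[pop, "origin"], period=meta.loc[pop, "period"],
                     locus=locus, allele=allele, count=int(cnt), freq=cnt / (2 * n), n=n)
            )
        genos = grp.apply(lambda r: "/".join(sorted((r["allele1"], r["allele2"]))), axis=1)
        for geno, cnt in genos.value_counts().sort_index().items():
            geno_rows.append(
                dict(population=pop, origin=meta.loc[pop, "origin"], period=meta.loc[pop, "period"],
                     locus=locus, genotype=geno, count=int(cnt), freq=cnt / n, n=n)
            )
    return FreqTable(pd.DataFrame(allele_rows), pd.DataFrame(geno_rows))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum on per-population frequencies
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    return st.rankdata(values, method="average")


def wilcoxon_origin_test(
    farmed: np.ndarray | list,
    wild: np.ndarray | list,
    exact_limit: int = 12,
) -> float:
    """Two-sided rank-sum p for farmed vs wild per-population values.

    Uses exact permutation enumeration of all C(n, n1) group assignments
    (midranks, so ties are handled) when the combined sample size is at
    most ``exact_limit``; otherwise the normal approximation with tie
    correction.  Symmetric in its two arguments.
    """
    x = np.asarray(farmed, dtype=float)
    y = np.asarray(wild, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both origin groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    n = n1 + n2
    ranks = _midranks(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    if n <= exact_limit:
        dev_obs = abs(w_obs - mu)
        hits = total = 0
        for idx in itertools.combinations(range(n), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev_obs - 1e-9:
                hits += 1
        return hits / total
    if np.all(pooled == pooled[0]):
        return 1.0
    res = st.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def wilcoxon_by_locus(
    table: pd.DataFrame,
    locus: str,
    mode: str = "allele",
    level: str | None = None,
    exact_limit: int = 12,
) -> float:
    """Farmed-vs-wild Wilcoxon test on per-population frequencies at a locus.

    ``mode='allele'`` compares per-population frequencies of one allele
    (default: the farmed-reference allele); ``mode='genotype'`` compares
    frequencies of one genotype class (default: the reference homozygote).
    """
    sub = table[table["locus"] == locus]
    if sub.empty:
        raise ValueError(f"locus {locus!r} not present")
    freqs = compute_frequencies(sub)
    ref = level
    if mode == "allele":
        if ref is None:
            ref = reference_allele(sub, locus)
        af = freqs.allele_freqs
        origin = af.groupby("population")["origin"].first()
        per_pop = pd.DataFrame({"origin": origin})
        hit = af[af["allele"] == ref].set_index("population")["freq"]
        # populations lacking the allele entirely have frequency zero
        per_pop["freq"] = hit.reindex(per_pop.index).fillna(0.0)
    elif mode == "genotype":
        if ref is None:
            a = reference_allele(sub, locus)
            ref = f"{a}/{a}"
        gf = freqs.genotype_freqs
        origin = gf.groupby("population")["origin"].first()
        per_pop = pd.DataFrame({"origin": origin, "freq": 0.0})
        hit = gf[gf["genotype"] == ref].set_index("population")["freq"]
        per_pop.loc[hit.index, "freq"] = hit
    else:
        raise ValueError("mode must be 'allele' or 'genotype'")
    farmed = per_pop.loc[per_pop["origin"] == "farmed", "freq"].to_numpy()
    wild = per_pop.loc[per_pop["origin"] == "wild", "freq"].to_numpy()
    return wilcoxon_origin_test(farmed, wild, exact_limit=exact_limit)


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

def hwe_test(counts, method: str = "exact") -> float:
    """P-value for departure from Hardy-Weinberg proportions.

    ``counts`` is ``(n_AA, n_Aa, n_aa)``.  The default is the exact
    conditional test (sum of probabilities of heterozygote counts no more
    likely than the observed one, given the allele counts); ``method=
    'chisq'`` gives the 1-df chi-square test on expected HW counts.
    """
    n_hom1, n_het, n_hom2 = (int(c) for c in counts)
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_hom1 + n_het
    n_b = 2 * n_hom2 + n_het
    if n_a == 0 or n_b == 0:
        return 1.0  # monomorphic: HW trivially satisfied
    if method == "chisq":
        p = n_a / (2 * n)
        exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        obs = np.array([n_hom1, n_het, n_hom2], dtype=float)
        stat = float(((obs - exp) ** 2 / exp).sum())
        return float(st.chi2.sf(stat, df=1))
    if method != "exact":
        raise ValueError("method must be 'exact' or 'chisq'")
    n_minor = min(n_a, n_b)

    def log_prob(het: int) -> float:
        hom_minor = (n_minor - het) // 2
        hom_major = n - het - hom_minor
        return (
            math.lgamma(n + 1)
            - math.lgamma(hom_major + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_minor + 1)
            + het * math.log(2.0)
            + math.lgamma(n_a + 1)
            + math.lgamma(n_b + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = range(n_minor % 2, n_minor + 1, 2)
    logs = {h: log_prob(h) for h in hets}
    obs_lp = logs[n_het]
    total = sum(math.exp(lp) for lp in logs.values())
    p_val = sum(math.exp(lp) for lp in logs.values() if lp <= obs_lp + 1e-9) / total
    return min(1.0, p_val)


def hwe_by_origin(table: pd.DataFrame, locus: str, method: str = "exact") -> dict[str, float]:
    """HWE p-value per origin group, genotype counts pooled over populations."""
    sub = table[table["locus"] == locus]
    if sub.empty:
        raise ValueError(f"locus {locus!r} not present")
    alleles = sorted(set(sub["allele1"]) | set(sub["allele2"]))
    if len(alleles) > 2:
        raise ValueError(f"HWE test needs a biallelic locus, found {alleles}")
    a = alleles[0]
    out = {}
    for origin, grp in sub.groupby("origin"):
        n_a_hom = int(((grp["allele1"] == a) & (grp["allele2"] == a)).sum())
        n_het = int((grp["allele1"] != grp["allele2"]).sum())
        n_b_hom = len(grp) - n_a_hom - n_het
        out[origin] = hwe_test((n_a_hom, n_het, n_b_hom), method=method)
    return out


# ---------------------------------------------------------------------------
# Binomial GLM with stepwise AIC
# ---------------------------------------------------------------------------

@dataclass
class GlmFit:
    """One binomial logistic fit of per-population allele counts."""

    formula: str
    params: pd.Series
    bse: pd.Series
    log_likelihood: float
    npar: int
    separation: bool = False

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.npar


@dataclass
class ModelSelectionResult:
    """Stepwise-AIC outcome: every fitted candidate plus the search trace."""

    fits: dict[str, GlmFit]
    selected: str
    trace: list[dict] = field(default_factory=list)

    @property
    def selected_fit(self) -> GlmFit:
        return self.fits[self.selected]


def reference_allele(table: pd.DataFrame, locus: str) -> str:
    """Most frequent allele among the farmed populations (ties: first)."""
    sub = table[(table["locus"] == locus) & (table["origin"] == "farmed")]
    if sub.empty:
        raise ValueError("no farmed populations for reference-level choice")
    counts = pd.concat([sub["allele1"], sub["allele2"]]).value_counts()
    top = counts.max()
    tied = sorted(counts[counts == top].index)
    if len(tied) > 1:
        logger.info("reference-allele tie at %s, using %s", locus, tied[0])
    return tied[0]


def _population_counts(table: pd.DataFrame, locus: str) -> pd.DataFrame:
    """Aggregate per-population (reference count, other count) for a locus."""
    sub = table[table["locus"] == locus]
    if sub.empty:
        raise ValueError(f"locus {locus!r} not present")
    if set(sub["origin"]) != {"farmed", "wild"}:
        raise ValueError("both origins must be present")
    ref = reference_allele(table, locus)
    rows = []
    for pop, grp in sub.groupby("population", sort=True):
        alleles = pd.concat([grp["allele1"], grp["allele2"]])
        ref_n = int((alleles == ref).sum())
        rows.append(
            dict(population=pop, origin=grp["origin"].iloc[0], period=grp["period"].iloc[0],
                 ref_count=ref_n, other_count=len(alleles) - ref_n)
        )
    return pd.DataFrame(rows)


def _design_matrix(pops: pd.DataFrame, formula: str) -> tuple[np.ndarray, list[str]]:
    wild = (pops["origin"] == "wild").astype(float).to_numpy()
    periods = sorted(pops["period"].unique())
    late = (pops["period"] == periods[-1]).astype(float).to_numpy() if len(periods) > 1 else np.zeros(len(pops))
    cols = [np.ones(len(pops))]
    names = ["Intercept"]
    if "origin" in formula:
        cols.append(wild)
        names.append("origin[wild]")
    if "time" in formula:
        cols.append(late)
        names.append("time[late]")
    if "*" in formula:
        cols.append(wild * late)
        names.append("origin[wild]:time[late]")
    return np.column_stack(cols), names


def fit_origin_time_glm(table: pd.DataFrame, locus: str, formula: str = "origin * time") -> GlmFit:
    """Binomial logistic fit of reference-allele counts on origin/time.

    The response per population is ``(reference count, other count)`` with
    the reference level the most frequent allele in the farmed populations.
    ``formula`` is one of ``'1', 'origin', 'time', 'origin + time',
    'origin * time'``.  Complete separation is flagged in the result but
    the fit is still returned.
    """
    import statsmodels.api as sm

    if formula not in MODEL_SCOPE:
        raise ValueError(f"formula must be one of {MODEL_SCOPE}")
    pops = _population_counts(table, locus)
    endog = pops[["ref_count", "other_count"]].to_numpy()
    exog, names = _design_matrix(pops, formula)
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        res = model.fit(maxiter=200)
    mu = res.fittedvalues
    separation = bool(np.any((mu < 1e-8) | (mu > 1 - 1e-8)) or np.any(np.abs(res.params) > 15))
    if separation:
        logger.warning("possible separation in GLM fit (%s) at locus %s", formula, locus)
    return GlmFit(
        formula=formula,
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        log_likelihood=float(res.llf),
        npar=len(names),
        separation=separation,
    )


_NEIGHBOURS = {
    "1": ("origin", "time"),
    "origin": ("1", "origin + time"),
    "time": ("1", "origin + time"),
    "origin + time": ("origin", "time", "origin * time"),
    "origin * time": ("origin + time",),
}


def stepwise_aic(table: pd.DataFrame, locus: str, start: str = "origin * time",
                 scope: tuple[str, ...] = MODEL_SCOPE) -> ModelSelectionResult:
    """Bidirectional stepwise AIC search over the origin/time model lattice.

    Starts from the full interaction model and repeatedly moves to the
    neighbouring model (one term added or dropped) with the lowest AIC,
    stopping when no neighbour improves.  AIC ties are broken toward the
    model with fewer parameters.
    """
    if start not in scope:
        raise ValueError("start model must be inside the scope")
    fits: dict[str, GlmFit] = {}

    def fit(name: str) -> GlmFit:
        if name not in fits:
            fits[name] = fit_origin_time_glm(table, locus, name)
        return fits[name]

    current = start
    trace: list[dict] = []
    fit(current)
    while True:
        neighbours = [m for m in _NEIGHBOURS.get(current, ()) if m in scope]
        candidates = [current] + neighbours
        for m in candidates:
            fit(m)
        best = min(candidates, key=lambda m: (round(fits[m].aic, 12), fits[m].npar))
        trace.append(
            {"current": current, "candidates": {m: fits[m].aic for m in candidates}, "chosen": best}
        )
        if best == current:
            break
        current = best
    selected = min(fits, key=lambda m: (round(fits[m].aic, 12), fits[m].npar))
    return ModelSelectionResult(fits=fits, selected=selected, trace=trace)
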
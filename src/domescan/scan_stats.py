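"""Per-SNP farmed-vs-wild differentiation statistics and track building.

Given biallelic SNPs with per-pool major/minor read counts and a manifest
assigning each pool an origin (farmed / wild), this module computes the
chromosome-scan statistics:

* pooled nucleotide diversity pi = (1 - p^2 - q^2) * C/(C-1) with read
  frequencies p, q and read depth C (the finite-depth correction used by
  Pool-Seq FST estimators);
* pairwise FST = (pi_T - mean(pi_A, pi_B)) / pi_T, reported both as the
  mean over all farmed x wild pool pairs and from counts combined per
  origin ("combined-pool", the headline column);
* Fisher's exact test on summed farmed vs wild allele counts;
* the Cochran-Mantel-Haenszel chi-square over farmed/wild pool pairs as
  strata (continuity-corrected by default);
* Benjamini-Hochberg adjustment, rolling-average tracks over a window of
  SNPs, peak detection with significance stars, and gene-neighbourhood
  annotation from GFF3.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from ._exact import fisher_exact_2x2, fisher_exact_many
from .poolseq_core import snp_pool_ids

logger = logging.getLogger(__name__)

__all__ = [
    "pool_pi",
    "pairwise_fst",
    "fisher_scan",
    "cmh_scan",
    "bh_adjust",
    "RollingTrack",
    "rolling_average",
    "PeakReport",
    "find_peaks",
    "read_gff3_genes",
    "genes_near",
    "compute_scan",
]


# ---------------------------------------------------------------------------
# Pooled diversity and FST
# ---------------------------------------------------------------------------

def pool_pi(major, minor):
    """Pooled heterozygosity (1 - p^2 - q^2) * C/(C-1) from read counts.

    Undefined (NaN) below depth 2.  Accepts scalars or arrays.
    """
    maj = np.asarray(major, dtype=float)
    mnr = np.asarray(minor, dtype=float)
    depth = maj + mnr
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(depth > 0, maj / depth, np.nan)
        het = 1.0 - p**2 - (1.0 - p) ** 2
        pi = np.where(depth >= 2, het * depth / (depth - 1.0), np.nan)
    return pi if pi.shape else float(pi)


def pairwise_fst(a_major, a_minor, b_major, b_minor):
    """Pool-pair FST: (pi_T - mean(pi_A, pi_B)) / pi_T.

    ``pi_T`` is computed from the two pools' summed read counts.  Sites
    monomorphic across both pools (pi_T = 0) are undefined and return NaN.
    Symmetric in its pool arguments; small negative values are legitimate
    finite-sample outcomes and are not clamped here.
    """
    pi_a = np.asarray(pool_pi(a_major, a_minor), dtype=float)
    pi_b = np.asarray(pool_pi(b_major, b_minor), dtype=float)
    pi_t = np.asarray(
        pool_pi(np.asarray(a_major) + np.asarray(b_major),
                np.asarray(a_minor) + np.asarray(b_minor)),
        dtype=float,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(pi_t > 0, (pi_t - 0.5 * (pi_a + pi_b)) / np.where(pi_t > 0, pi_t, 1.0),
                       np.nan)
    return fst if fst.ndim else float(fst)


# ---------------------------------------------------------------------------
# Per-SNP tests
# ---------------------------------------------------------------------------

def fisher_scan(farmed_major, farmed_minor, wild_major, wild_minor) -> np.ndarray:
    """Two-sided Fisher exact p per SNP on summed farmed vs wild counts."""
    return fisher_exact_many(farmed_major, farmed_minor, wild_major, wild_minor)


def cmh_scan(a, b, c, d, continuity: bool = True):
    """Cochran-Mantel-Haenszel chi-square over stratified 2x2 tables.

    ``a, b`` are the first row (e.g. farmed major/minor counts) and
    ``c, d`` the second row of each stratum's table; each has shape
    ``(K,)`` for one SNP or ``(K, n_snps)`` for a scan.  The statistic is
    ``(|sum_k (a_k - E a_k)| - corr)^2 / sum_k V_k`` with expectation and
    variance from the hypergeometric null; ``corr = 0.5`` unless
    ``continuity=False``.  Returns ``(statistic, p)`` with p from the
    1-df chi-square.  Strata with zero margins contribute nothing; if all
    variance vanishes the p-value is 1 with a warning.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    c = np.atleast_1d(np.asarray(c, dtype=float))
    d = np.atleast_1d(np.asarray(d, dtype=float))
    squeeze = a.ndim == 1
    if squeeze:
        a, b, c, d = (x[:, None] for x in (a, b, c, d))
    n = a + b + c + d
    r1, c1 = a + b, a + c
    r2, c2 = c + d, b + d
    with np.errstate(invalid="ignore", divide="ignore"):
        e_a = np.where(n > 0, r1 * c1 / n, 0.0)
        v_a = np.where(n > 1, r1 * r2 * c1 * c2 / (n**2 * (n - 1.0)), 0.0)
    num = np.abs((a - e_a).sum(axis=0))
    if continuity:
        # R's mantelhaen.test convention: no clamping at zero
        num = num - 0.5
    var = v_a.sum(axis=0)
    zero = var <= 0
    if zero.any():
        warnings.warn("CMH: zero variance in all strata for some SNPs; p set to 1")
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(zero, 0.0, num**2 / np.where(zero, 1.0, var))
    p = np.where(zero, 1.0, st.chi2.sf(stat, df=1))
    if squeeze:
        return float(stat[0]), float(p[0])
    return stat, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out.reshape(np.shape(pvalues))


# ---------------------------------------------------------------------------
# Tracks and peaks
# ---------------------------------------------------------------------------

@dataclass
class RollingTrack:
    """Centred moving average of a per-SNP statistic over a SNP-count window."""

    positions: np.ndarray
    values: np.ndarray
    window: int
    statistic: str = ""


def rolling_average(positions, values, window: int = 5000, statistic: str = "") -> RollingTrack:
    """Centred rolling mean over a window counted in SNPs (not bp).

    Edge windows are truncated to the available SNPs and NaN (masked)
    values are skipped.  A window longer than the series collapses to the
    single global mean, with a warning.
    """
    pos = np.asarray(positions)
    vals = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if pos.shape != vals.shape:
        raise ValueError("positions and values must align")
    if window > vals.size:
        warnings.warn("window exceeds number of SNPs; returning the global mean")
        mean = float(np.nanmean(vals)) if vals.size else float("nan")
        centre = pos[vals.size // 2 : vals.size // 2 + 1]
        return RollingTrack(positions=centre, values=np.array([mean]), window=window,
                            statistic=statistic)
    track = (
        pd.Series(vals)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return RollingTrack(positions=pos.copy(), values=track, window=window, statistic=statistic)


@dataclass
class PeakReport:
    """Summit of a rolling track plus its most extreme member SNP."""

    peak_pos: int | None
    peak_value: float | None
    window: int
    best_snp_pos: int | None = None
    best_snp_value: float | None = None
    best_snp_adj_p: float | None = None
    stars: str = ""
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def empty(self) -> bool:
        return self.peak_pos is None


def _star_string(p: float | None) -> str:
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def find_peaks(
    track: RollingTrack,
    snp_positions,
    snp_values,
    snp_adj_p=None,
    annotations: pd.DataFrame | None = None,
    flank: int = 50_000,
) -> PeakReport:
    """Locate the global maximum of a rolling track and its top SNP.

    Within the winning window, the SNP maximising the per-SNP statistic is
    reported together with its BH-adjusted p-value (significance stars at
    0.05 / 0.01 / 0.001) and, when ``annotations`` is given, the genes
    within ``flank`` bp on each side of the peak.
    """
    vals = np.asarray(track.values, dtype=float)
    if vals.size == 0 or np.all(np.isnan(vals)):
        return PeakReport(peak_pos=None, peak_value=None, window=track.window)
    i_peak = int(np.nanargmax(vals))
    peak_pos = int(np.asarray(track.positions)[i_peak])

    snp_pos = np.asarray(snp_positions)
    snp_vals = np.asarray(snp_values, dtype=float)
    half = track.window // 2
    lo = max(0, i_peak - half)
    hi = min(snp_pos.size, i_peak + half + 1)
    if track.positions.shape != snp_pos.shape:
        # collapsed track (global mean): search every SNP
        lo, hi = 0, snp_pos.size
    window_vals = snp_vals[lo:hi]
    best_pos = best_val = best_p = None
    if window_vals.size and not np.all(np.isnan(window_vals)):
        j = lo + int(np.nanargmax(window_vals))
        best_pos = int(snp_pos[j])
        best_val = float(snp_vals[j])
        if snp_adj_p is not None:
            best_p = float(np.asarray(snp_adj_p, dtype=float)[j])
    genes = pd.DataFrame()
    if annotations is not None and not annotations.empty:
        genes = genes_near(peak_pos, annotations, flank=flank)
    return PeakReport(
        peak_pos=peak_pos,
        peak_value=float(vals[i_peak]),
        window=track.window,
        best_snp_pos=best_pos,
        best_snp_value=best_val,
        best_snp_adj_p=best_p,
        stars=_star_string(best_p),
        genes=genes,
    )


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_gff3_genes(source) -> pd.DataFrame:
    """Read gene features from GFF3 text or a file path.

    Returns ``chrom, start, end, strand, gene_id, name`` (1-based
    inclusive coordinates).  Only ``gene`` features are kept.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        if "\n" in s or s.startswith("##gff"):
            text = s
        else:
            with open(s) as fh:
                text = fh.read()
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"GFF3 line {lineno}: expected 9 fields, got {len(fields)}")
        if fields[2] != "gene":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
        )
        rows.append(
            dict(
                chrom=fields[0],
                start=int(fields[3]),
                end=int(fields[4]),
                strand=fields[6],
                gene_id=attrs.get("ID", ""),
                name=attrs.get("Name", attrs.get("ID", "")),
            )
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id", "name"])


def genes_near(pos: int, genes: pd.DataFrame, flank: int = 50_000,
               chrom: str | None = None) -> pd.DataFrame:
    """Genes whose span intersects ``[pos - flank, pos + flank]``.

    Coordinates are 1-based inclusive on both sides; ``chrom`` restricts
    the annotation to one sequence when the frame covers several.
    """
    if genes.empty:
        return genes.copy()
    df = genes
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    lo, hi = pos - flank, pos + flank
    hit = df[(df["end"] >= lo) & (df["start"] <= hi)]
    return hit.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Full scan
# ---------------------------------------------------------------------------

def compute_scan(
    snps: pd.DataFrame,
    manifest: pd.DataFrame,
    pairing: str = "index",
    continuity: bool = True,
    include_fisher: bool = True,
    clamp_fst: bool = False,
) -> pd.DataFrame:
    """Per-SNP farmed-vs-wild statistics for a biallelic SNP table.

    ``manifest`` maps ``pool_id`` to ``origin`` (farmed / wild).  Emits
    one row per SNP with the mean pairwise FST over all farmed x wild pool
    pairs, the combined-pool FST (counts summed per origin; the headline
    column), the Fisher exact p on the summed counts, the CMH statistic
    and p over pool-pair strata, and BH-adjusted p-values (computed across
    all SNPs in the frame, i.e. per chromosome scan).

    CMH strata pair the i-th farmed with the i-th wild pool after sorting
    pool ids (``pairing='index'``); ``pairing='manifest'`` uses an
    explicit integer ``stratum`` column in the manifest instead.
    """
    if pairing not in ("index", "manifest"):
        raise ValueError("pairing must be 'index' or 'manifest'")
    pool_ids = snp_pool_ids(snps)
    manifest = manifest.set_index("pool_id") if "pool_id" in manifest.columns else manifest
    origins = {}
    for pid in pool_ids:
        if pid not in manifest.index:
            raise ValueError(f"pool {pid!r} missing from manifest")
        origins[pid] = manifest.loc[pid, "origin"]
    farmed = sorted(p for p in pool_ids if origins[p] == "farmed")
    wild = sorted(p for p in pool_ids if origins[p] == "wild")
    if not farmed or not wild:
        raise ValueError("manifest must contain both farmed and wild pools")

    maj = {p: snps[f"{p}_major"].to_numpy(float) for p in pool_ids}
    mnr = {p: snps[f"{p}_minor"].to_numpy(float) for p in pool_ids}

    # mean pairwise FST over farmed x wild pairs (NaN pairs skipped per SNP)
    pair_stack = np.stack(
        [pairwise_fst(maj[f], mnr[f], maj[w], mnr[w]) for f in farmed for w in wild]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_fst = np.nanmean(pair_stack, axis=0)

    f_maj = sum(maj[p] for p in farmed)
    f_mnr = sum(mnr[p] for p in farmed)
    w_maj = sum(maj[p] for p in wild)
    w_mnr = sum(mnr[p] for p in wild)
    comb_fst = pairwise_fst(f_maj, f_mnr, w_maj, w_mnr)
    if clamp_fst:
        mean_fst = np.clip(mean_fst, 0.0, 1.0)
        comb_fst = np.clip(comb_fst, 0.0, 1.0)

    if pairing == "index":
        k = min(len(farmed), len(wild))
        strata = list(zip(farmed[:k], wild[:k]))
    else:
        if "stratum" not in manifest.columns:
            raise ValueError("pairing='manifest' needs a 'stratum' manifest column")
        by_stratum: dict[int, dict[str, str]] = {}
        for pid in pool_ids:
            s = int(manifest.loc[pid, "stratum"])
            by_stratum.setdefault(s, {})[origins[pid]] = pid
        strata = [
            (d["farmed"], d["wild"]) for s, d in sorted(by_stratum.items())
            if "farmed" in d and "wild" in d
        ]
        if not strata:
            raise ValueError("no complete farmed/wild strata in manifest")
    a = np.stack([maj[f] for f, _ in strata])
    b = np.stack([mnr[f] for f, _ in strata])
    c = np.stack([maj[w] for _, w in strata])
    d = np.stack([mnr[w] for _, w in strata])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmh_stat, cmh_p = cmh_scan(a, b, c, d, continuity=continuity)

    out = snps[["chrom", "pos"]].copy()
    out["mean_pairwise_fst"] = mean_fst
    out["combined_fst"] = comb_fst
    if include_fisher:
        fisher_p = fisher_scan(
            f_maj.astype(int), f_mnr.astype(int), w_maj.astype(int), w_mnr.astype(int)
        )
        out["fisher_p"] = fisher_p
        out["fisher_q"] = bh_adjust(fisher_p)
    out["cmh_stat"] = cmh_stat
    out["cmh_p"] = cmh_p
    out["cmh_q"] = bh_adjust(cmh_p)
    return out
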
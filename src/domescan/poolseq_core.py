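"""Pooled pileup ingestion, replicate merging and biallelic SNP calling.

The Pool-Seq track starts from per-position base counts produced upstream
(reads mapped, filtered, counted per pool).  Two text dialects are read
and written:

* ``readcount`` — bam-readcount style: tab-separated
  ``chrom pos ref depth base:count[:extra...]`` tokens, extra per-base
  fields ignored;
* ``sync`` — PoPoolation2 synchronized format: ``chrom pos ref`` then one
  ``A:T:C:G:N:del`` column per pool (N and deletion counts parsed but
  excluded from allele calling).

Technical replicates of a pool are merged by summing base counts per
position.  Biallelic SNPs are then called under a minimum per-pool read
depth (default 25, justified by the depth-calibration resampling) and a
minimum allele frequency (default 1%, guarding against sequencing error).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BASES",
    "PILEUP_COLUMNS",
    "FilterConfig",
    "read_pileup",
    "write_pileup",
    "merge_replicates",
    "call_biallelic",
    "write_snps",
    "read_snps",
]

BASES = ("A", "C", "G", "T")
PILEUP_COLUMNS = ["chrom", "pos", "ref", "A", "C", "G", "T", "N", "DEL"]

_SYNC_ORDER = ("A", "T", "C", "G", "N", "DEL")  # sync column order A:T:C:G:N:del


@dataclass(frozen=True)
class FilterConfig:
    """SNP-calling filters.

    min_depth
        Minimum total read depth per pool at a site (reads covering the
        position); sites under-covered in any compared pool are dropped by
        default.
    min_allele_freq
        Minimum allele frequency for a base to count as a real allele,
        computed on counts pooled across populations by default.
    """

    min_depth: int = 25
    min_allele_freq: float = 0.01

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.0 <= self.min_allele_freq < 0.5:
            raise ValueError("min_allele_freq must be in [0, 0.5)")


# ---------------------------------------------------------------------------
# Parsing / writing
# ---------------------------------------------------------------------------

def _parse_error(path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


def read_pileup(path, dialect: str = "readcount", pool_index: int = 0) -> pd.DataFrame:
    """Read one pool's per-position base counts.

    Returns a frame with columns ``chrom, pos, ref, A, C, G, T, N, DEL``
    in coordinate order.  For multi-pool sync files, ``pool_index``
    selects the pool column.  Malformed lines and coordinate-unsorted
    input raise ``ValueError`` with the offending line number.
    """
    if dialect not in ("readcount", "sync"):
        raise ValueError("dialect must be 'readcount' or 'sync'")
    rows = []
    last: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "readcount" and " " in line and len(fields) < 4:
                fields = line.split()
            try:
                chrom, pos_s, ref = fields[0], fields[1], fields[2]
                pos = int(pos_s)
            except (IndexError, ValueError):
                raise _parse_error(path, lineno, f"malformed line: {line!r}") from None
            if pos < 1:
                raise _parse_error(path, lineno, f"position must be >= 1, got {pos}")
            if chrom in last and pos <= last[chrom]:
                raise _parse_error(path, lineno, f"input not sorted at {chrom}:{pos}")
            last[chrom] = pos
            counts = dict.fromkeys(("A", "C", "G", "T", "N", "DEL"), 0)
            if dialect == "readcount":
                if len(fields) < 4:
                    raise _parse_error(path, lineno, "readcount line needs >= 4 fields")
                for token in fields[4:]:
                    parts = token.split(":")
                    if len(parts) < 2:
                        raise _parse_error(path, lineno, f"malformed base token {token!r}")
                    base = parts[0].upper()
                    try:
                        cnt = int(parts[1])
                    except ValueError:
                        raise _parse_error(path, lineno, f"malformed count in {token!r}") from None
                    if cnt < 0:
                        raise _parse_error(path, lineno, f"negative count in {token!r}")
                    key = base if base in ("A", "C", "G", "T", "N") else "DEL"
                    counts[key] += cnt
            else:
                pools = fields[3:]
                if pool_index >= len(pools):
                    raise _parse_error(path, lineno, f"sync line has no pool column {pool_index}")
                parts = pools[pool_index].split(":")
                if len(parts) != 6:
                    raise _parse_error(path, lineno, f"malformed sync token {pools[pool_index]!r}")
                try:
                    vals = [int(p) for p in parts]
                except ValueError:
                    raise _parse_error(path, lineno, f"malformed sync token {pools[pool_index]!r}") from None
                if min(vals) < 0:
                    raise _parse_error(path, lineno, "negative count in sync token")
                counts.update(dict(zip(_SYNC_ORDER, vals)))
            rows.append({"chrom": chrom, "pos": pos, "ref": ref.upper(), **counts})
    df = pd.DataFrame(rows, columns=PILEUP_COLUMNS)
    if df.empty:
        return pd.DataFrame(columns=PILEUP_COLUMNS).astype({"pos": int})
    return df


def write_pileup(df: pd.DataFrame, path, dialect: str = "readcount") -> None:
    """Write a single-pool pileup in either supported dialect."""
    if dialect not in ("readcount", "sync"):
        raise ValueError("dialect must be 'readcount' or 'sync'")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            if dialect == "readcount":
                depth = sum(getattr(row, b) for b in ("A", "C", "G", "T", "N")) + row.DEL
                tokens = [f"{b}:{getattr(row, b)}" for b in ("A", "C", "G", "T", "N")]
                fh.write(f"{row.chrom}\t{row.pos}\t{row.ref}\t{depth}\t" + "\t".join(tokens) + "\n")
            else:
                token = ":".join(str(getattr(row, b)) for b in _SYNC_ORDER)
                fh.write(f"{row.chrom}\t{row.pos}\t{row.ref}\t{token}\n")


# ---------------------------------------------------------------------------
# Replicate merging
# ---------------------------------------------------------------------------

def merge_replicates(replicates: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum per-base counts across technical replicates of one pool.

    Positions are outer-joined (a position absent from a replicate
    contributes zero counts); conflicting reference bases at a shared
    position raise ``ValueError``.
    """
    if not replicates:
        raise ValueError("no replicates to merge")
    frames = [df for df in replicates if not df.empty]
    if not frames:
        return replicates[0].copy()
    count_cols = ["A", "C", "G", "T", "N", "DEL"]
    cat = pd.concat(frames, ignore_index=True)
    refs = cat.groupby(["chrom", "pos"])["ref"].nunique()
    conflicts = refs[refs > 1]
    if len(conflicts):
        chrom, pos = conflicts.index[0]
        raise ValueError(f"conflicting reference base at {chrom}:{pos}")
    merged = (
        cat.groupby(["chrom", "pos"], sort=True)
        .agg({"ref": "first", **{c: "sum" for c in count_cols}})
        .reset_index()
    )
    return merged[PILEUP_COLUMNS]


# ---------------------------------------------------------------------------
# Biallelic SNP calling
# ---------------------------------------------------------------------------

def call_biallelic(
    pools: dict[str, pd.DataFrame],
    filters: FilterConfig | None = None,
    maf_mode: str = "pooled",
    depth_mode: str = "drop_site",
    return_stats: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, int]]:
    """Call biallelic SNPs across a set of population pools.

    Per site: the site is dropped when any pool's total read depth (A+C+G+T)
    is below ``min_depth`` (``depth_mode='drop_site'``, the default) or the
    under-covered pool's counts are masked to zero with the site kept while
    at least two pools remain (``'mask_pool'``).  Base frequencies are then
    computed from counts summed over all pools (``maf_mode='pooled'``) or a
    base is retained when it reaches the threshold in at least one pool
    (``'per_pool'``); bases below ``min_allele_freq`` are discarded and the
    site is emitted iff exactly two bases survive.  The major allele is the
    more frequent base overall (ties broken alphabetically, logged).

    Returns a frame with columns ``chrom, pos, major, minor`` plus, per
    pool, ``{pool}_major, {pool}_minor, {pool}_depth, {pool}_freq`` where
    depth counts the two retained alleles and freq is the major-allele
    read frequency.
    """
    if filters is None:
        filters = FilterConfig()
    if maf_mode not in ("pooled", "per_pool"):
        raise ValueError("maf_mode must be 'pooled' or 'per_pool'")
    if depth_mode not in ("drop_site", "mask_pool"):
        raise ValueError("depth_mode must be 'drop_site' or 'mask_pool'")
    if not pools:
        raise ValueError("no pools supplied")

    pool_ids = list(pools)
    stats = {"input_sites": 0, "depth_pass": 0, "polymorphic": 0, "biallelic": 0}

    def _ret(df: pd.DataFrame):
        return (df, stats) if return_stats else df

    indexed = {}
    for pid, df in pools.items():
        if df.empty:
            return _ret(_empty_snp_frame(pool_ids))
        indexed[pid] = df.set_index(["chrom", "pos"])

    idx = indexed[pool_ids[0]].index
    for pid in pool_ids[1:]:
        idx = idx.union(indexed[pid].index)
    idx = idx.sortlevel([0, 1])[0] if idx.nlevels == 2 else idx

    # counts[b] has one column per pool, one row per site
    counts = {}
    for b in BASES:
        counts[b] = np.column_stack(
            [indexed[pid][b].reindex(idx, fill_value=0).to_numpy() for pid in pool_ids]
        ).astype(float)
    depth = sum(counts[b] for b in BASES)  # (n_sites, n_pools)

    stats["input_sites"] = int(depth.shape[0])

    under = depth < filters.min_depth
    if depth_mode == "drop_site":
        keep = ~under.any(axis=1)
    else:
        for b in BASES:
            counts[b][under] = 0.0
        depth = sum(counts[b] for b in BASES)
        keep = (~under).sum(axis=1) >= 2
    stats["depth_pass"] = int(keep.sum())
    if not keep.any():
        return _ret(_empty_snp_frame(pool_ids))
    idx = idx[keep]
    for b in BASES:
        counts[b] = counts[b][keep]
    depth = depth[keep]

    total = np.stack([counts[b].sum(axis=1) for b in BASES], axis=1)  # (n_sites, 4)
    grand = total.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        if maf_mode == "pooled":
            freq = np.where(grand > 0, total / grand, 0.0)
            retained = freq >= filters.min_allele_freq
        else:
            pool_tot = depth[:, :, None].transpose(0, 2, 1)  # (sites, 1, pools)
            per_pool = np.stack([counts[b] for b in BASES], axis=1)  # (sites, 4, pools)
            pf = np.where(pool_tot > 0, per_pool / pool_tot, 0.0)
            retained = (pf >= filters.min_allele_freq).any(axis=2)
        retained &= total > 0

    stats["polymorphic"] = int(((total > 0).sum(axis=1) >= 2).sum())
    biallelic = retained.sum(axis=1) == 2
    stats["biallelic"] = int(biallelic.sum())
    if not biallelic.any():
        return _ret(_empty_snp_frame(pool_ids))

    idx = idx[biallelic]
    total = total[biallelic]
    retained = retained[biallelic]
    for b in BASES:
        counts[b] = counts[b][biallelic]

    base_arr = np.array(BASES)
    rows_major, rows_minor = [], []
    for i in range(retained.shape[0]):
        pair = base_arr[retained[i]]
        c = total[i][retained[i]]
        if c[0] == c[1]:
            logger.info("major-allele tie at %s:%s, using alphabetical order", *idx[i])
            order = np.argsort(pair)
        else:
            order = np.argsort(-c, kind="stable")
        rows_major.append(pair[order[0]])
        rows_minor.append(pair[order[1]])

    out = pd.DataFrame(
        {"chrom": [t[0] for t in idx], "pos": [t[1] for t in idx],
         "major": rows_major, "minor": rows_minor}
    )
    base_lookup = {b: counts[b] for b in BASES}
    maj_idx = np.array([BASES.index(m) for m in rows_major])
    min_idx = np.array([BASES.index(m) for m in rows_minor])
    site_range = np.arange(len(out))
    stacked = np.stack([base_lookup[b] for b in BASES], axis=1)  # (sites, 4, pools)
    for j, pid in enumerate(pool_ids):
        maj = stacked[site_range, maj_idx, j]
        mnr = stacked[site_range, min_idx, j]
        dep = maj + mnr
        with np.errstate(invalid="ignore", divide="ignore"):
            frq = np.where(dep > 0, maj / dep, np.nan)
        out[f"{pid}_major"] = maj.astype(int)
        out[f"{pid}_minor"] = mnr.astype(int)
        out[f"{pid}_depth"] = dep.astype(int)
        out[f"{pid}_freq"] = frq
    return _ret(out.sort_values(["chrom", "pos"], ignore_index=True))


def _empty_snp_frame(pool_ids: list[str]) -> pd.DataFrame:
    cols = ["chrom", "pos", "major", "minor"]
    for pid in pool_ids:
        cols += [f"{pid}_major", f"{pid}_minor", f"{pid}_depth", f"{pid}_freq"]
    return pd.DataFrame(columns=cols)


def snp_pool_ids(snps: pd.DataFrame) -> list[str]:
    """Pool identifiers encoded in a biallelic SNP frame's columns."""
    return [c[: -len("_major")] for c in snps.columns if c.endswith("_major")]


def write_snps(snps: pd.DataFrame, path) -> None:
    """Write biallelic SNPs as TSV: chrom, pos, major, minor, then one
    ``major:minor`` count column per pool."""
    pools = snp_pool_ids(snps)
    out = snps[["chrom", "pos", "major", "minor"]].copy()
    for pid in pools:
        out[pid] = snps[f"{pid}_major"].astype(str) + ":" + snps[f"{pid}_minor"].astype(str)
    out.to_csv(path, sep="\t", index=False)


def read_snps(path) -> pd.DataFrame:
    """Read the TSV written by :func:`write_snps` back into the wide form."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    pools = [c for c in df.columns if c not in ("chrom", "pos", "major", "minor")]
    out = df[["chrom", "pos", "major", "minor"]].copy()
    for pid in pools:
        parts = df[pid].str.split(":", expand=True).astype(int)
        out[f"{pid}_major"] = parts[0]
        out[f"{pid}_minor"] = parts[1]
        out[f"{pid}_depth"] = parts[0] + parts[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"{pid}_freq"] = np.where(
                out[f"{pid}_depth"] > 0, out[f"{pid}_major"] / out[f"{pid}_depth"], np.nan
            )
    return out
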
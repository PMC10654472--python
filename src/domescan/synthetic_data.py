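"""Synthetic data with the statistical structure the scans assume.

Two generators make the whole pipeline testable offline:

* :func:`generate_gene_level` emulates the candidate-gene design —
  farmed and wild populations of a handful of individuals each, sampled
  in two collection periods, genotypes drawn as two Hardy-Weinberg draws
  from the population's allele frequency.  Farmed frequencies can be a
  fixed value or produced by one Wright-Fisher bottleneck pass per farmed
  population (independent hatchery bottlenecks).

* :func:`generate_poolseq` emulates pooled whole-genome sequencing of
  farmed and wild population pools on one chromosome: per-SNP wild
  frequencies from a Beta prior, farmed frequencies produced by a shared
  drift pass (or kept identical for pure-null data), an optional selected
  region where the farmed frequency is shifted by ``delta``, binomial
  sampling of pool chromosomes and of reads at a negative-binomial depth,
  and a split of each pool's reads over technical replicates.  A truth
  table and a minimal GFF3 annotation accompany the pileups.

Neither generator models linkage disequilibrium, sequencing error or
read-level artefacts; see the methods note for what that implies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bottleneck_sim import wf_trajectory
from .gene_level import GENOTYPE_COLUMNS, write_genotype_table
from .poolseq_core import PILEUP_COLUMNS, write_pileup

__all__ = [
    "GeneLevelSimConfig",
    "PoolSeqSimConfig",
    "PoolSeqSim",
    "generate_gene_level",
    "generate_poolseq",
    "write_poolseq",
    "load_config",
]

# Default gene-level layout: the gilthead seabream vgll3 design
# (11 wild populations totalling 54 individuals, 9 farmed totalling 37;
# the first 6 wild / 4 farmed populations belong to the 2004-2007 period).
_WILD_SIZES = (5, 5, 5, 5, 5, 5, 5, 5, 5, 4, 5)
_FARMED_SIZES = (4, 4, 3, 5, 5, 2, 4, 5, 5)
_WILD_EARLY = 6
_FARMED_EARLY = 4


@dataclass(frozen=True)
class GeneLevelSimConfig:
    """Gene-level genotype simulation parameters.

    ``wild_allele_freq`` / ``farmed_allele_freq`` are frequencies of the
    alternate allele (``alleles[1]``); ``farmed_allele_freq='drift'``
    derives each farmed population's frequency by an independent
    Wright-Fisher bottleneck pass (``nb`` diploids for ``generations``
    rounds) from the wild frequency.
    """

    wild_pop_sizes: tuple[int, ...] = _WILD_SIZES
    farmed_pop_sizes: tuple[int, ...] = _FARMED_SIZES
    wild_allele_freq: float = 0.5
    farmed_allele_freq: float | str = "drift"
    nb: int = 100
    generations: int = 8
    n_early_wild: int = _WILD_EARLY
    n_early_farmed: int = _FARMED_EARLY
    periods: tuple[str, str] = ("2004-2007", "2012-2016")
    alleles: tuple[str, str] = ("A", "G")
    locus_id: str = "locus1"
    seed: int | None = None

    def __post_init__(self) -> None:
        for sizes in (self.wild_pop_sizes, self.farmed_pop_sizes):
            if not sizes or any(int(s) < 1 for s in sizes):
                raise ValueError("population sizes must be positive")
        if not 0.0 <= self.wild_allele_freq <= 1.0:
            raise ValueError("wild_allele_freq must be in [0, 1]")
        if self.farmed_allele_freq != "drift" and not 0.0 <= float(self.farmed_allele_freq) <= 1.0:
            raise ValueError("farmed_allele_freq must be in [0, 1] or 'drift'")
        if len(self.alleles) != 2 or self.alleles[0] == self.alleles[1]:
            raise ValueError("alleles must be two distinct symbols")


def generate_gene_level(config: GeneLevelSimConfig | None = None, **kwargs) -> pd.DataFrame:
    """Simulate an individual-level genotype table.

    Each individual's two alleles are independent draws from its
    population's alternate-allele frequency (Hardy-Weinberg).  Output is
    a frame with the standard genotype-table columns; identical seeds
    give identical tables.
    """
    cfg = config if config is not None else GeneLevelSimConfig(**kwargs)
    rng = np.random.default_rng(cfg.seed)
    ref, alt = cfg.alleles
    rows = []

    def emit(origin: str, sizes, n_early: int, freqs) -> None:
        for i, (size, p) in enumerate(zip(sizes, freqs)):
            pop = f"{origin}_{i + 1}"
            period = cfg.periods[0] if i < n_early else cfg.periods[1]
            draws = rng.binomial(1, p, size=(int(size), 2))
            for j in range(int(size)):
                a1 = alt if draws[j, 0] else ref
                a2 = alt if draws[j, 1] else ref
                rows.append((f"{pop}_ind{j + 1}", pop, origin, period, cfg.locus_id, a1, a2))

    wild_freqs = [cfg.wild_allele_freq] * len(cfg.wild_pop_sizes)
    if cfg.farmed_allele_freq == "drift":
        farmed_freqs = [
            wf_trajectory(cfg.wild_allele_freq, nb=cfg.nb, generations=cfg.generations, rng=rng)
            for _ in cfg.farmed_pop_sizes
        ]
    else:
        farmed_freqs = [float(cfg.farmed_allele_freq)] * len(cfg.farmed_pop_sizes)

    emit("wild", cfg.wild_pop_sizes, cfg.n_early_wild, wild_freqs)
    emit("farmed", cfg.farmed_pop_sizes, cfg.n_early_farmed, farmed_freqs)
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


# ---------------------------------------------------------------------------
# Pool-Seq simulation
# ---------------------------------------------------------------------------

_DEFAULT_POOLS = tuple(
    [(f"farm{i + 1}", "farmed", 25, 2) for i in range(4)]
    + [(f"wild{i + 1}", "wild", 25, 2) for i in range(4)]
)


@dataclass(frozen=True)
class PoolSeqSimConfig:
    """Pool-Seq simulation parameters.

    pools
        ``(pool_id, origin, n_individuals, n_replicates)`` per pool;
        defaults to 4 farmed + 4 wild pools of 25 individuals with 2
        technical replicates each (the deposited pools' typical layout).
    mean_depth / depth_dispersion
        Negative-binomial read depth per pool and site: mean ``mu`` and
        dispersion ``k`` (variance ``mu + mu^2/k``).
    wild_freq_prior
        Beta(a, b) prior of per-SNP wild alternate-allele frequencies.
    selected_region
        ``(start, end, delta)``: inside ``[start, end]`` the farmed
        frequency is the wild frequency shifted by ``delta`` toward the
        more distant boundary (so the truth-table divergence is
        ``delta`` exactly).
    farmed_null
        Outside the region: ``'drift'`` passes the wild frequency through
        one shared bottleneck (realistic null noise), ``'identical'``
        copies it (pure null).
    """

    chrom: str = "chr1"
    chrom_length: int = 20_000_000
    n_snps: int = 20_000
    pools: tuple[tuple[str, str, int, int], ...] = _DEFAULT_POOLS
    mean_depth: float = 60.0
    depth_dispersion: float = 5.0
    wild_freq_prior: tuple[float, float] = (0.8, 0.8)
    selected_region: tuple[int, int, float] | None = None
    farmed_null: str = "drift"
    nb: int = 100
    generations: int = 8
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        if self.n_snps > self.chrom_length:
            raise ValueError("more SNPs than positions on the chromosome")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        if any(a <= 0 for a in self.wild_freq_prior):
            raise ValueError("Beta prior parameters must be positive")
        if self.selected_region is not None:
            start, end, delta = self.selected_region
            if not (1 <= start <= end <= self.chrom_length):
                raise ValueError("selected_region must lie inside the chromosome")
            if not 0.0 <= delta <= 1.0:
                raise ValueError("delta must be in [0, 1]")
        if self.farmed_null not in ("drift", "identical"):
            raise ValueError("farmed_null must be 'drift' or 'identical'")
        if not self.pools:
            raise ValueError("at least one pool is required")
        for pid, origin, n, reps in self.pools:
            if origin not in ("farmed", "wild"):
                raise ValueError(f"pool {pid!r}: origin must be farmed/wild")
            if n < 1 or reps < 1:
                raise ValueError(f"pool {pid!r}: sizes and replicates must be >= 1")


@dataclass
class PoolSeqSim:
    """Simulated Pool-Seq dataset: pileups per (pool, replicate), truth
    table, GFF3 annotation text and a pool manifest."""

    config: PoolSeqSimConfig
    pileups: dict[tuple[str, int], pd.DataFrame] = field(repr=False)
    truth: pd.DataFrame = field(repr=False)
    gff3: str = field(repr=False)
    manifest: pd.DataFrame = field(repr=False)


def _sample_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct 1-based positions, sorted, without materialising arange(length)."""
    pos = np.array([], dtype=np.int64)
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=2 * (n - pos.size) + 8)
        pos = np.unique(np.concatenate([pos, extra]))
    if pos.size > n:
        keep = rng.choice(pos.size, size=n, replace=False)
        pos = np.sort(pos[keep])
    return pos


def _shift_toward_divergence(p: np.ndarray, delta: float) -> np.ndarray:
    """Shift each frequency by delta toward its more distant boundary."""
    up = p <= 0.5
    return np.clip(np.where(up, p + delta, p - delta), 0.0, 1.0)


def generate_poolseq(config: PoolSeqSimConfig | None = None, **kwargs) -> PoolSeqSim:
    """Simulate pooled pileups, the underlying truth, and annotations.

    Per SNP: the wild alternate-allele frequency is Beta-distributed; the
    farmed frequency equals the wild one passed through a shared
    bottleneck (or copied), except inside the selected region where it is
    the wild frequency shifted by ``delta``.  Each pool then draws its
    sampled chromosome frequency binomially (2n chromosomes), a total
    read depth from the negative-binomial distribution, alternate-read
    counts binomially at the sampled frequency, and splits reads
    uniformly over its technical replicates (replicate depths sum to the
    pool depth exactly).
    """
    cfg = config if config is not None else PoolSeqSimConfig(**kwargs)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps

    pos = _sample_positions(rng, cfg.chrom_length, n)
    bases = np.array(["A", "C", "G", "T"])
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4

    a, b = cfg.wild_freq_prior
    wild_freq = rng.beta(a, b, size=n)
    if cfg.farmed_null == "drift":
        farmed_freq = wf_trajectory(wild_freq, nb=cfg.nb, generations=cfg.generations, rng=rng)
    else:
        farmed_freq = wild_freq.copy()
    in_region = np.zeros(n, dtype=bool)
    if cfg.selected_region is not None:
        start, end, delta = cfg.selected_region
        in_region = (pos >= start) & (pos <= end)
        farmed_freq = np.where(in_region, _shift_toward_divergence(wild_freq, delta), farmed_freq)

    truth = pd.DataFrame(
        {"chrom": cfg.chrom, "pos": pos, "wild_freq": wild_freq,
         "farmed_freq": farmed_freq, "in_selected_region": in_region}
    )

    # negative binomial with mean mu and dispersion k: n=k, p=k/(k+mu)
    k = cfg.depth_dispersion
    p_nb = k / (k + cfg.mean_depth) if cfg.mean_depth > 0 else 1.0

    pileups: dict[tuple[str, int], pd.DataFrame] = {}
    for pid, origin, n_ind, n_rep in cfg.pools:
        freq = farmed_freq if origin == "farmed" else wild_freq
        sample_freq = rng.binomial(2 * n_ind, freq) / (2 * n_ind)
        depth = rng.negative_binomial(k, p_nb, size=n) if cfg.mean_depth > 0 else np.zeros(n, int)
        alt_reads = rng.binomial(depth, sample_freq)
        ref_reads = depth - alt_reads

        # split reads uniformly over replicates; totals are conserved
        rem_alt, rem_ref = alt_reads.copy(), ref_reads.copy()
        for r in range(n_rep):
            if r == n_rep - 1:
                alt_r, ref_r = rem_alt, rem_ref
            else:
                frac = 1.0 / (n_rep - r)
                alt_r = rng.binomial(rem_alt, frac)
                ref_r = rng.binomial(rem_ref, frac)
                rem_alt = rem_alt - alt_r
                rem_ref = rem_ref - ref_r
            counts = np.zeros((n, 4), dtype=np.int64)
            counts[np.arange(n), ref_idx] += ref_r
            counts[np.arange(n), alt_idx] += alt_r
            df = pd.DataFrame(
                {"chrom": cfg.chrom, "pos": pos, "ref": bases[ref_idx],
                 "A": counts[:, 0], "C": counts[:, 1], "G": counts[:, 2], "T": counts[:, 3],
                 "N": 0, "DEL": 0}
            )[PILEUP_COLUMNS]
            pileups[(pid, r + 1)] = df

    manifest = pd.DataFrame(
        [(pid, origin, n_ind, n_rep) for pid, origin, n_ind, n_rep in cfg.pools],
        columns=["pool_id", "origin", "n_individuals", "n_replicates"],
    )
    gff3 = _synthetic_gff3(cfg)
    return PoolSeqSim(config=cfg, pileups=pileups, truth=truth, gff3=gff3, manifest=manifest)


def _synthetic_gff3(cfg: PoolSeqSimConfig) -> str:
    """Minimal synthetic gene annotation: a few evenly spaced genes, plus a
    gene centred in the selected region when one is configured."""
    lines = ["##gff-version 3"]
    n_genes = 5
    span = cfg.chrom_length // (n_genes + 1)
    for i in range(n_genes):
        start = (i + 1) * span
        end = min(start + 20_000, cfg.chrom_length)
        name = f"gene{i + 1}"
        lines.append(
            f"{cfg.chrom}\tdomescan_sim\tgene\t{start}\t{end}\t.\t+\t.\tID=gene:{name};Name={name}"
        )
    if cfg.selected_region is not None:
        start, end, _ = cfg.selected_region
        mid = (start + end) // 2
        g_start, g_end = max(1, mid - 10_000), min(cfg.chrom_length, mid + 10_000)
        lines.append(
            f"{cfg.chrom}\tdomescan_sim\tgene\t{g_start}\t{g_end}\t.\t+\t.\t"
            "ID=gene:sel_gene;Name=sel_gene"
        )
    return "\n".join(lines) + "\n"


def write_poolseq(sim: PoolSeqSim, outdir, dialect: str = "readcount") -> dict[str, str]:
    """Write a simulated Pool-Seq dataset to a directory.

    Emits one pileup file per pool x replicate, the truth table
    (``truth.tsv``), the annotation (``genes.gff3``) and the pool manifest
    (``manifest.tsv``).  Returns the written paths keyed by role.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ext = "sync" if dialect == "sync" else "readcount.tsv"
    paths: dict[str, str] = {}
    for (pid, rep), df in sim.pileups.items():
        p = out / f"{pid}.rep{rep}.{ext}"
        write_pileup(df, p, dialect=dialect)
        paths[f"pileup:{pid}:rep{rep}"] = str(p)
    truth_p = out / "truth.tsv"
    sim.truth.to_csv(truth_p, sep="\t", index=False)
    paths["truth"] = str(truth_p)
    gff_p = out / "genes.gff3"
    gff_p.write_text(sim.gff3)
    paths["gff3"] = str(gff_p)
    man_p = out / "manifest.tsv"
    sim.manifest.to_csv(man_p, sep="\t", index=False)
    paths["manifest"] = str(man_p)
    return paths


def load_config(path):
    """Load a simulation config mapping from a YAML or JSON file."""
    text = Path(path).read_text()
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        import yaml

        return yaml.safe_load(text)
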
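"""Read-depth calibration for pooled sequencing.

In Pool-Seq, each read at a position is drawn from one of the pooled
individuals, so a site's read depth bounds how many distinct individuals
can contribute to its allele-frequency estimate.  This module implements
the resampling simulation behind the minimum-depth filter: draw ``depth``
reads uniformly with replacement from a pool of ``pool_size`` individuals,
count how many distinct individuals were sampled, and summarise the
distribution over many replicates.  For a pool of 25 individuals a depth
of 25 reads samples on average P(1-(1-1/P)^D) ~ 16 individuals, with a
lower 95% confidence limit of at least 13 — the basis of the depth-25
site filter used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DepthCalibConfig",
    "DepthCalibResult",
    "expected_distinct",
    "distinct_individuals",
    "choose_min_depth",
]


@dataclass(frozen=True)
class DepthCalibConfig:
    """Parameters of the distinct-individuals resampling experiment.

    pool_size
        Diploid individuals in the pool (reads are drawn over individuals,
        not chromosomes).
    depth
        Reads drawn per replicate, uniformly with replacement.
    replicates
        Resampling replicates.
    ci_level
        Confidence level; the reported lower bound is the (1-ci_level)/2
        quantile (two-sided convention), or the (1-ci_level) quantile when
        ``one_sided``.
    """

    pool_size: int = 25
    depth: int = 25
    replicates: int = 1_000_000
    ci_level: float = 0.95
    one_sided: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class DepthCalibResult:
    """Distribution summary of distinct individuals per replicate."""

    config: DepthCalibConfig
    mean: float
    lower_ci: float
    quantiles: dict[float, float]
    histogram: dict[int, int] = field(repr=False)

    @property
    def max_possible(self) -> int:
        return min(self.config.pool_size, self.config.depth)


def expected_distinct(pool_size: int, depth: int) -> float:
    """Closed-form expectation P(1 - (1 - 1/P)^D) of the distinct count."""
    p = float(pool_size)
    return p * (1.0 - (1.0 - 1.0 / p) ** depth)


def _simulate_counts(cfg: DepthCalibConfig, rng: np.random.Generator) -> np.ndarray:
    """Distinct-individual counts per replicate, chunked to bound memory."""
    counts = np.empty(cfg.replicates, dtype=np.int32)
    chunk = max(1, min(cfg.replicates, 4_000_000 // cfg.depth))
    done = 0
    while done < cfg.replicates:
        m = min(chunk, cfg.replicates - done)
        draws = rng.integers(0, cfg.pool_size, size=(m, cfg.depth))
        draws.sort(axis=1)
        counts[done : done + m] = 1 + (np.diff(draws, axis=1) != 0).sum(axis=1)
        done += m
    return counts


def distinct_individuals(config: DepthCalibConfig | None = None, **kwargs) -> DepthCalibResult:
    """Simulate the number of distinct pooled individuals hit by the reads.

    Each replicate draws ``depth`` reads uniformly with replacement over the
    ``pool_size`` individuals and counts the distinct ones.  Returns the
    mean, the lower confidence-limit quantile, a small set of quantiles and
    the full histogram.
    """
    cfg = config if config is not None else DepthCalibConfig(**kwargs)
    rng = np.random.default_rng(cfg.seed)
    counts = _simulate_counts(cfg, rng)
    alpha = 1.0 - cfg.ci_level
    lower_q = alpha if cfg.one_sided else alpha / 2.0
    qs = sorted({lower_q, 0.05, 0.25, 0.5, 0.75, 0.95})
    quantiles = {q: float(np.quantile(counts, q)) for q in qs}
    values, freqs = np.unique(counts, return_counts=True)
    return DepthCalibResult(
        config=cfg,
        mean=float(counts.mean()),
        lower_ci=quantiles[lower_q],
        quantiles=quantiles,
        histogram=dict(zip(values.tolist(), freqs.tolist())),
    )


def choose_min_depth(
    pool_size: int,
    target_fraction: float = 0.5,
    ci_level: float = 0.95,
    replicates: int = 100_000,
    seed: int | None = None,
    one_sided: bool = False,
    max_depth: int | None = None,
) -> int:
    """Smallest read depth whose lower-CI distinct count covers the target.

    Scans depths upward until the lower confidence bound of the simulated
    distinct-individual count reaches ``ceil(target_fraction * pool_size)``.
    """
    if not 0.0 < target_fraction <= 1.0:
        raise ValueError("target_fraction must be in (0, 1]")
    target = int(np.ceil(target_fraction * pool_size))
    if target > pool_size:
        raise ValueError("target exceeds pool size")
    ss = np.random.SeedSequence(seed)
    if max_depth is None:
        max_depth = max(20 * pool_size, 100)
    for depth in range(target, max_depth + 1):
        res = distinct_individuals(
            DepthCalibConfig(
                pool_size=pool_size,
                depth=depth,
                replicates=replicates,
                ci_level=ci_level,
                one_sided=one_sided,
                seed=int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)),
            )
        )
        if res.lower_ci >= target:
            return depth
    raise RuntimeError(f"no depth <= {max_depth} reaches the target coverage")
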
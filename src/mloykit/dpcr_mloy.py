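"""Digital-PCR mLOY estimation from partition counts.

A dPCR run partitions a gDNA sample into ~26k compartments and amplifies a
Y target (AMELY, FAM channel) and its X homologue (AMELX, VIC channel).
The mean copies per partition ``lambda`` comes from the Poisson void
probability, ``lambda = -ln(1 - positive fraction)``, and mLOY is the
copy-ratio statistic ``(1 - lambda_Y / lambda_X) * 100%``. Partition
volume cancels in the ratio, so concentrations are used per-partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "PartitionPlate",
    "DpcrMloyResult",
    "poisson_lambda",
    "compute_mloy_dpcr",
    "mloy_ci",
    "categorize_dpcr",
    "estimate_plate",
]


@dataclass
class PartitionPlate:
    """Per-sample dPCR positive/total partition counts for both channels."""

    sample_id: str
    n_partitions: int
    positives_y: int
    positives_x: int
    partition_volume: Optional[float] = None  # microlitres, reporting only

    def __post_init__(self) -> None:
        if self.n_partitions <= 0:
            raise ValueError("n_partitions must be > 0")
        for name in ("positives_y", "positives_x"):
            v = getattr(self, name)
            if not 0 <= v <= self.n_partitions:
                raise ValueError(
                    f"{name}={v} outside [0, n_partitions={self.n_partitions}]"
                )


@dataclass
class DpcrMloyResult:
    sample_id: str
    lambda_y: float
    lambda_x: float
    mloy_percent: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    high: bool = False
    negative_estimate: bool = False


def poisson_lambda(positives: int, n_partitions: int) -> float:
    """Mean copies per partition: ``-ln(1 - positives/n_partitions)``."""
    if positives > n_partitions:
        raise ValueError("positives exceed n_partitions (malformed input)")
    if positives == n_partitions:
        raise ValueError("plate saturated: positives == n_partitions")
    if positives < 0:
        raise ValueError("positives must be >= 0")
    return -math.log1p(-positives / n_partitions)


def compute_mloy_dpcr(lambda_y: float, lambda_x: float) -> float:
    """mLOY percent: ``(1 - lambda_y/lambda_x) * 100``. Not clamped."""
    if lambda_x <= 0:
        raise ValueError("lambda_x must be > 0 (undefined ratio)")
    if lambda_y < 0:
        raise ValueError("lambda_y must be >= 0")
    return (1.0 - lambda_y / lambda_x) * 100.0


def mloy_ci(
    plate: PartitionPlate,
    confidence: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mLOY percent.

    Both channels are resampled as binomials at their observed positive
    fractions and pushed through the Poisson inversion and copy-ratio
    formula; deterministic given ``seed``. Saturated bootstrap replicates
    are clipped to ``n_partitions - 1`` positives (the estimator is
    otherwise undefined there).
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    n = plate.n_partitions
    # raise on already-saturated observed data
    poisson_lambda(plate.positives_y, n)
    poisson_lambda(plate.positives_x, n)
    rng = np.random.default_rng(seed)
    py = plate.positives_y / n
    px = plate.positives_x / n
    ky = np.minimum(rng.binomial(n, py, size=n_boot), n - 1)
    kx = np.minimum(rng.binomial(n, px, size=n_boot), n - 1)
    lam_y = -np.log1p(-ky / n)
    lam_x = -np.log1p(-kx / n)
    ok = lam_x > 0
    if not np.any(ok):
        raise ValueError("all bootstrap X-channel replicates empty")
    pct = (1.0 - lam_y[ok] / lam_x[ok]) * 100.0
    alpha = 1.0 - confidence
    lo, hi = np.quantile(pct, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def categorize_dpcr(mloy_percent: float, cutoff: float = 40.0) -> bool:
    """High-mLOY flag at the given cutoff (boundary inclusive)."""
    return bool(mloy_percent >= cutoff)


def estimate_plate(
    plate: PartitionPlate,
    cutoff: float = 40.0,
    confidence: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
    floor_at_zero: bool = False,
) -> DpcrMloyResult:
    """Point estimate + bootstrap CI + categorical flag for one plate."""
    lam_y = poisson_lambda(plate.positives_y, plate.n_partitions)
    lam_x = poisson_lambda(plate.positives_x, plate.n_partitions)
    pct = compute_mloy_dpcr(lam_y, lam_x)
    negative = pct < 0
    if floor_at_zero and negative:
        pct = 0.0
    lo, hi = mloy_ci(plate, confidence=confidence, n_boot=n_boot, seed=seed)
    return DpcrMloyResult(
        sample_id=plate.sample_id,
        lambda_y=lam_y,
        lambda_x=lam_x,
        mloy_percent=pct,
        ci_low=lo,
        ci_high=hi,
        high=categorize_dpcr(pct, cutoff),
        negative_estimate=negative,
    )
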
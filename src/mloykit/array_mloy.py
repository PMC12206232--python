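"""SNP-array mLOY quantification.

The pipeline takes per-probe log-R ratios (LRR) for male subjects and
produces per-subject estimates of the fraction of blood leukocytes lacking
chromosome Y:

1. ``compute_mlrr`` — per-subject medians of X- and Y-probe LRR
   (mLRRX / mLRRY).
2. ``compute_dlrs`` — derivative log-ratio spread on chromosome-1 probes,
   a per-sample noise metric.
3. ``qc_filter_dlrs`` — remove samples whose DLRS exceeds Q3 + 1.5 IQR.
4. ``flag_sex_aneuploidy`` — exclude XXY-like / XYY-like / female-like
   profiles so only mosaic Y loss remains.
5. ``batch_adjust`` — subtract the per-batch median mLRRY of eligible
   subjects.
6. ``mlrr_to_percent`` — ideal single-copy transformation
   ``100 * (1 - 2**(mLRRY / slope))``.
7. ``derive_detection_threshold`` — detection limit from the lower tail of
   the experimental-noise confidence interval (default 99%).
8. ``categorize_mloy`` — detectable / high (default 40%) categorical flags.

``estimate_cohort`` runs the whole chain on a long probe table and is fully
vectorised; the per-profile operations mirror it one subject at a time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityProfile",
    "MloyEstimate",
    "DetectionThreshold",
    "AneuploidyBounds",
    "compute_mlrr",
    "compute_dlrs",
    "qc_filter_dlrs",
    "flag_sex_aneuploidy",
    "batch_adjust",
    "mlrr_to_percent",
    "percent_to_mlrr",
    "derive_detection_threshold",
    "categorize_mloy",
    "estimate_cohort",
    "profiles_to_frame",
    "read_probe_csv",
]

VALID_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])


@dataclass
class IntensityProfile:
    """One subject's per-probe log-R ratios.

    ``probe_ids``, ``chroms`` and ``lrr`` are parallel arrays; probes are
    assumed to be in genomic order within each chromosome (required for
    DLRS).
    """

    subject_id: str
    probe_ids: np.ndarray
    chroms: np.ndarray
    lrr: np.ndarray
    batch_id: str = "batch0"

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids)
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.lrr = np.asarray(self.lrr, dtype=float)
        if self.lrr.size == 0:
            raise ValueError("probes must be non-empty")
        if not (len(self.probe_ids) == len(self.chroms) == len(self.lrr)):
            raise ValueError("probe_ids, chroms and lrr must be parallel")
        if not np.all(np.isfinite(self.lrr)):
            raise ValueError("lrr values must be finite")
        bad = set(map(str, self.chroms)) - VALID_CHROMS
        if bad:
            raise ValueError(f"unknown chromosome labels: {sorted(bad)}")


@dataclass
class MloyEstimate:
    subject_id: str
    mlrrx: float
    mlrry: float
    batch_id: str = "batch0"
    mlrry_adjusted: float = float("nan")
    dlrs_chr1: float = float("nan")
    percent_loy: float = float("nan")
    qc_pass: bool = True
    aneuploidy_flag: str = "none"
    detectable: bool = False
    high: bool = False


@dataclass
class DetectionThreshold:
    """Detection limit derived from the experimental-noise distribution."""

    threshold_percent: float
    noise_sd: float
    confidence: float = 0.99
    n_reference: int = 0
    method: str = "mirrored-right-half MAD"

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must be in (0, 1)")
        if self.noise_sd > 0 and self.threshold_percent <= 0:
            raise ValueError("threshold_percent must be > 0 for noise_sd > 0")


@dataclass
class AneuploidyBounds:
    """mLRRX / mLRRY bounds separating euploid males from other karyotypes.

    Defaults are deliberately wide (+/- 0.3 in log2-ratio space) and are
    configurable; the original inspection was done on a scatter plot without
    published numeric cut-offs.
    """

    x_gain: float = 0.3
    y_gain: float = 0.3
    x_female: float = -0.3


def compute_mlrr(profile: IntensityProfile) -> tuple[float, float]:
    """Median LRR over X probes and over Y probes (mLRRX, mLRRY).

    Even-length medians are the mean of the two middle order statistics.
    """
    chroms = np.asarray(profile.chroms, dtype=str)
    x = profile.lrr[chroms == "X"]
    y = profile.lrr[chroms == "Y"]
    if x.size == 0 or y.size == 0:
        raise ValueError(
            f"profile {profile.subject_id!r} lacks "
            f"{'X' if x.size == 0 else 'Y'} probes"
        )
    return float(np.median(x)), float(np.median(y))


def compute_dlrs(profile: IntensityProfile, chromosome: str = "1") -> float:
    """Derivative log-ratio spread: sd of successive LRR differences / sqrt(2)."""
    chroms = np.asarray(profile.chroms, dtype=str)
    vals = profile.lrr[chroms == str(chromosome)]
    if vals.size < 3:
        raise ValueError(
            f"need >= 3 probes on chromosome {chromosome} "
            f"(got {vals.size}) for DLRS"
        )
    d = np.diff(vals)
    return float(np.std(d, ddof=1) / math.sqrt(2.0))


def qc_filter_dlrs(
    estimates: Sequence[MloyEstimate],
) -> tuple[list[MloyEstimate], list[MloyEstimate], float]:
    """Flag samples with DLRS above Q3 + 1.5 IQR of the cohort distribution.

    Quantiles use linear interpolation between order statistics ("type 7").
    Returns (kept, removed, cutoff); ``qc_pass`` is updated in place.
    """
    dlrs = np.array([e.dlrs_chr1 for e in estimates], dtype=float)
    finite = dlrs[np.isfinite(dlrs)]
    if finite.size < 4:
        raise ValueError("need >= 4 finite DLRS values to derive a cutoff")
    q1, q3 = np.quantile(finite, [0.25, 0.75])  # linear interpolation
    cutoff = float(q3 + 1.5 * (q3 - q1))
    kept, removed = [], []
    for e in estimates:
        if np.isfinite(e.dlrs_chr1) and e.dlrs_chr1 > cutoff:
            e.qc_pass = False
            removed.append(e)
        else:
            kept.append(e)
    return kept, removed, cutoff


def flag_sex_aneuploidy(
    mlrrx: float, mlrry: float, bounds: AneuploidyBounds | None = None
) -> str:
    """Classify a profile as none / XXY-like / XYY-like / other."""
    bounds = bounds or AneuploidyBounds()
    if not (np.isfinite(mlrrx) and np.isfinite(mlrry)):
        raise ValueError("mlrrx and mlrry must be finite")
    if mlrrx > bounds.x_gain:
        return "XXY-like"
    if mlrry > bounds.y_gain:
        return "XYY-like"
    if mlrrx < bounds.x_female:
        return "other"
    return "none"


def batch_adjust(estimates: Sequence[MloyEstimate]) -> list[MloyEstimate]:
    """Subtract each batch's median mLRRY (eligible subjects only).

    Eligible = qc-passing, aneuploidy-free. Batches with no eligible
    subjects fall back to the grand median (logged).
    """
    eligible = [
        e for e in estimates if e.qc_pass and e.aneuploidy_flag == "none"
    ]
    if not eligible:
        raise ValueError("no eligible subjects for batch adjustment")
    grand_median = float(np.median([e.mlrry for e in eligible]))
    by_batch: dict[str, list[float]] = {}
    for e in eligible:
        by_batch.setdefault(e.batch_id, []).append(e.mlrry)
    medians = {b: float(np.median(v)) for b, v in by_batch.items()}
    for e in estimates:
        if e.batch_id not in medians:
            logger.warning(
                "batch %r has no eligible subjects; using grand median",
                e.batch_id,
            )
        e.mlrry_adjusted = e.mlrry - medians.get(e.batch_id, grand_median)
    return list(estimates)


def mlrr_to_percent(mlrry_adjusted: float, response_slope: float = 1.0) -> float:
    """Percent of cells with Y loss under the ideal single-copy model.

    ``100 * (1 - 2**(mLRRY / slope))``; exceeds 100 never, may be negative
    from noise (preserved, not clamped).
    """
    if response_slope <= 0:
        raise ValueError("response_slope must be positive")
    out = 100.0 * (1.0 - np.exp2(np.asarray(mlrry_adjusted, dtype=float) / response_slope))
    return float(out) if out.ndim == 0 else out


def percent_to_mlrr(percent_loy: float, response_slope: float = 1.0) -> float:
    """Inverse of :func:`mlrr_to_percent` (valid for percent < 100)."""
    f = np.asarray(percent_loy, dtype=float) / 100.0
    out = response_slope * np.log2(1.0 - f)
    return float(out) if out.ndim == 0 else out


def derive_detection_threshold(
    reference_mlrry: Iterable[float],
    confidence: float = 0.99,
    method: str = "mirrored",
    response_slope: float = 1.0,
    min_reference: int = 100,
) -> DetectionThreshold:
    """Detection limit from the lower tail of the experimental noise.

    The noise sd is a robust estimate (1.4826 x MAD about 0). With
    ``method="mirrored"`` (default, for cohorts without known LOY-free
    subjects) only values >= 0 are used, mirrored about 0 — the right half
    of the mLRRY distribution is noise-dominated since Y loss only pushes
    values left. ``method="direct"`` uses all supplied values as-is and is
    meant for references known to be LOY-free.

    The mLRRY-space bound is ``-z_{(1+confidence)/2} * noise_sd`` and is
    mapped to percent with :func:`mlrr_to_percent`; a subject is
    *detectable* when ``percent_loy >= threshold_percent``.
    """
    vals = np.asarray(list(reference_mlrry), dtype=float)
    vals = vals[np.isfinite(vals)]
    if method == "mirrored":
        vals = vals[vals >= 0]
        used_method = "mirrored-right-half MAD"
    elif method == "direct":
        used_method = "direct MAD"
    else:
        raise ValueError(f"unknown method {method!r}")
    if vals.size < min_reference:
        raise ValueError(
            f"need >= {min_reference} reference values (got {vals.size})"
        )
    # MAD about 0 of the (implicitly) symmetric set {v, -v} is median(|v|).
    noise_sd = 1.4826 * float(np.median(np.abs(vals)))
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    bound = -z * noise_sd
    threshold_percent = float(mlrr_to_percent(bound, response_slope))
    return DetectionThreshold(
        threshold_percent=threshold_percent,
        noise_sd=noise_sd,
        confidence=confidence,
        n_reference=int(vals.size),
        method=used_method,
    )


def categorize_mloy(
    percent_loy: float,
    threshold: DetectionThreshold,
    high_cutoff: float = 40.0,
    strict: bool = False,
) -> tuple[bool, bool]:
    """(detectable, high) flags; boundaries inclusive unless ``strict``."""
    if strict:
        return (
            bool(percent_loy > threshold.threshold_percent),
            bool(percent_loy > high_cutoff),
        )
    return (
        bool(percent_loy >= threshold.threshold_percent),
        bool(percent_loy >= high_cutoff),
    )


# ---------------------------------------------------------------------------
# Cohort pipeline (vectorised)
# ---------------------------------------------------------------------------

def profiles_to_frame(profiles: Sequence[IntensityProfile]) -> pd.DataFrame:
    """Long probe table: subject_id, probe_id, chrom, lrr, batch_id."""
    sizes = np.array([p.lrr.size for p in profiles])
    subj = np.repeat(np.array([p.subject_id for p in profiles], dtype=object), sizes)
    batch = np.repeat(np.array([p.batch_id for p in profiles], dtype=object), sizes)
    return pd.DataFrame(
        {
            "subject_id": subj,
            "probe_id": np.concatenate([p.probe_ids for p in profiles]),
            "chrom": np.concatenate(
                [np.asarray(p.chroms, dtype=object) for p in profiles]
            ),
            "lrr": np.concatenate([p.lrr for p in profiles]),
            "batch_id": batch,
        }
    )


def read_probe_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"chrom": str})
    required = {"subject_id", "probe_id", "chrom", "lrr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"probe CSV missing columns: {sorted(missing)}")
    if "batch_id" not in df.columns:
        df["batch_id"] = "batch0"
    return df


def estimate_cohort(
    probes: pd.DataFrame | Sequence[IntensityProfile],
    confidence: float = 0.99,
    high_cutoff: float = 40.0,
    response_slope: float = 1.0,
    bounds: AneuploidyBounds | None = None,
    dlrs_chrom: str = "1",
    threshold: DetectionThreshold | None = None,
    adjust_batches: bool = True,
    min_reference: int = 100,
) -> tuple[pd.DataFrame, DetectionThreshold, float]:
    """Full mLOY pipeline on a cohort.

    Parameters
    ----------
    probes
        Long probe table (``subject_id, probe_id, chrom, lrr, batch_id``)
        or a sequence of :class:`IntensityProfile`.
    threshold
        Pre-derived detection threshold; derived from this cohort's
        adjusted mLRRY values (mirrored-MAD) when omitted.

    Returns
    -------
    (estimates, threshold, dlrs_cutoff)
        ``estimates`` is one row per subject with mlrrx, mlrry,
        mlrry_adjusted, dlrs, qc/aneuploidy flags, percent_loy and the
        detectable/high categories.
    """
    if not isinstance(probes, pd.DataFrame):
        probes = profiles_to_frame(probes)
    bounds = bounds or AneuploidyBounds()

    probes = probes[["subject_id", "probe_id", "chrom", "lrr", "batch_id"]]
    if probes["chrom"].dtype != object:
        probes = probes.assign(chrom=probes["chrom"].astype(str))
    med = (
        probes.groupby(["subject_id", "chrom"], sort=False, observed=True)["lrr"]
        .median()
        .unstack("chrom")
    )
    for c in ("X", "Y"):
        if c not in med.columns or med[c].isna().any():
            raise ValueError(f"every subject needs >= 1 chromosome-{c} probe")

    chr1 = probes[probes["chrom"] == dlrs_chrom]
    grp = chr1.groupby("subject_id", sort=False)
    diffs = grp["lrr"].diff()
    dlrs = diffs.groupby(chr1["subject_id"], sort=False).std(ddof=1) / math.sqrt(2)

    batch = probes.groupby("subject_id", sort=False)["batch_id"].first()
    df = pd.DataFrame(
        {
            "subject_id": med.index,
            "batch_id": batch.reindex(med.index).values,
            "mlrrx": med["X"].values,
            "mlrry": med["Y"].values,
            "dlrs_chr1": dlrs.reindex(med.index).values,
        }
    ).reset_index(drop=True)

    # DLRS QC: Q3 + 1.5 IQR (type-7 quantiles)
    finite = df["dlrs_chr1"].dropna().values
    if finite.size >= 4:
        q1, q3 = np.quantile(finite, [0.25, 0.75])
        dlrs_cutoff = float(q3 + 1.5 * (q3 - q1))
    else:
        dlrs_cutoff = float("inf")
    df["qc_pass"] = ~(df["dlrs_chr1"] > dlrs_cutoff)

    # sex-aneuploidy flags
    flag = np.full(len(df), "none", dtype=object)
    flag[df["mlrrx"].values > bounds.x_gain] = "XXY-like"
    mask = (flag == "none") & (df["mlrry"].values > bounds.y_gain)
    flag[mask] = "XYY-like"
    mask = (flag == "none") & (df["mlrrx"].values < bounds.x_female)
    flag[mask] = "other"
    df["aneuploidy_flag"] = flag

    # batch adjustment on eligible subjects. The batch median estimates the
    # technical offset, which presumes most subjects carry ~0% LOY (true in
    # population cohorts); disable for cohorts where that fails.
    if adjust_batches:
        eligible = df[(df["qc_pass"]) & (df["aneuploidy_flag"] == "none")]
        if eligible.empty:
            raise ValueError("no eligible subjects for batch adjustment")
        grand = float(eligible["mlrry"].median())
        med_by_batch = eligible.groupby("batch_id")["mlrry"].median()
        offsets = df["batch_id"].map(med_by_batch).fillna(grand)
        df["mlrry_adjusted"] = df["mlrry"] - offsets
    else:
        df["mlrry_adjusted"] = df["mlrry"]

    df["percent_loy"] = 100.0 * (
        1.0 - np.exp2(df["mlrry_adjusted"].values / response_slope)
    )

    if threshold is None:
        ref = df.loc[
            (df["qc_pass"]) & (df["aneuploidy_flag"] == "none"),
            "mlrry_adjusted",
        ]
        threshold = derive_detection_threshold(
            ref,
            confidence=confidence,
            response_slope=response_slope,
            min_reference=min_reference,
        )

    usable = (df["qc_pass"]) & (df["aneuploidy_flag"] == "none")
    df["detectable"] = usable & (
        df["percent_loy"] >= threshold.threshold_percent
    )
    df["high"] = df["percent_loy"] >= high_cutoff
    return df, threshold, dlrs_cutoff
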
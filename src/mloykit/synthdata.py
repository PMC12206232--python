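"""Seeded synthetic-data generators for every pipeline stage.

Each generator returns its artifact together with a ground-truth sidecar so
recovery tests can compare estimates to the generating parameters. All
randomness flows through an explicit ``seed`` argument (no global state);
identical seeds and parameters give byte-identical output.

Generators
----------
``gen_array_cohort``
    SNP-array intensity profiles: Y-probe log-R ratios around the ideal
    signal ``slope * log2(1 - f)`` for true LOY fraction ``f``, X/autosomal
    probes around 0, plus per-batch offsets and Gaussian probe noise.
``gen_dpcr_run``
    Digital-PCR partition counts: channel positives are binomial with
    Poisson-occupancy probabilities ``1 - exp(-lambda)`` (X) and
    ``1 - exp(-lambda * (1 - f))`` (Y).
``gen_sc_cohort``
    Droplet scRNA-seq counts with donor structure, cell-type mixtures,
    depth-scaled Poisson rates, all-or-none MSY zeroing in LOY cells, and
    optional LOY-coupled up-regulation of designated profibrotic genes.
``gen_epi_cohort``
    Subject-level outcome tables from an exponential proportional-hazards
    model with a per-percent-mLOY log-hazard effect, optional covariate
    effects, and administrative censoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .array_mloy import IntensityProfile
from .dpcr_mloy import PartitionPlate
from .sc_loy import CellDataset

__all__ = [
    "ArrayTruth",
    "ScTruth",
    "EpiTruth",
    "gen_array_cohort",
    "gen_dpcr_run",
    "gen_sc_cohort",
    "gen_epi_cohort",
    "draw_fractions",
    "write_array_cohort",
    "write_epi_cohort",
    "echo_config",
]

DistSpec = "float | tuple | Callable[[np.random.Generator, int], np.ndarray]"


@dataclass
class ArrayTruth:
    subject_id: str
    true_loy_fraction: float
    batch_id: str
    age: float


@dataclass
class ScTruth:
    cell_id: str
    donor_id: str
    condition: str
    cell_type: str
    is_loy: bool
    depth: int


@dataclass
class EpiTruth:
    subject_id: str
    sex: str
    mloy_percent: float
    age: float
    smoking: str
    event: bool
    time_to_event_or_censor: float


def draw_fractions(spec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw ``n`` values in [0, 1] from a distribution spec.

    Accepted specs: a scalar (constant), ``("constant", f)``,
    ``("beta", a, b)``, ``("uniform", lo, hi)``, or a callable
    ``(rng, n) -> array``.
    """
    if callable(spec):
        vals = np.asarray(spec(rng, n), dtype=float)
    elif np.isscalar(spec):
        vals = np.full(n, float(spec))
    else:
        kind, *params = spec
        params = [float(p) for p in params]
        if not all(np.isfinite(params)):
            raise ValueError("distribution parameters must be finite")
        if kind == "constant":
            vals = np.full(n, params[0])
        elif kind == "beta":
            if params[0] <= 0 or params[1] <= 0:
                raise ValueError("beta parameters must be positive")
            vals = rng.beta(params[0], params[1], size=n)
        elif kind == "uniform":
            vals = rng.uniform(params[0], params[1], size=n)
        else:
            raise ValueError(f"unknown distribution kind {kind!r}")
    if vals.shape != (n,):
        raise ValueError("distribution spec produced wrong shape")
    if not np.all(np.isfinite(vals)) or vals.min() < 0 or vals.max() > 1:
        raise ValueError("fractions must be finite and within [0, 1]")
    return vals


# ---------------------------------------------------------------------------
# SNP-array cohorts
# ---------------------------------------------------------------------------

def gen_array_cohort(
    n: int,
    loy_dist=0.0,
    noise_sd: float = 0.05,
    n_batches: int = 1,
    batch_sd: float = 0.0,
    probes_per_chrom: int = 25,
    seed: int = 0,
    chromosomes: Optional[Sequence[str]] = None,
    response_slope: float = 1.0,
    age_range: tuple[float, float] = (40.0, 70.0),
) -> tuple[list[IntensityProfile], list[ArrayTruth]]:
    """Synthetic SNP-array cohort with known per-subject LOY fractions.

    Y-probe LRR are centred on ``response_slope * log2(1 - f)``; X and
    autosomal probes on 0. Every probe receives the subject's batch offset
    (drawn once per batch from N(0, batch_sd)) plus N(0, noise_sd) probe
    noise. Fractions are capped just below 1 so the ideal signal stays
    finite. Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd < 0 or batch_sd < 0:
        raise ValueError("noise_sd and batch_sd must be >= 0")
    if probes_per_chrom < 2:
        raise ValueError("probes_per_chrom must be >= 2")
    if chromosomes is None:
        chromosomes = [str(i) for i in range(1, 23)] + ["X", "Y"]
    chromosomes = [str(c) for c in chromosomes]
    for req in ("1", "X", "Y"):
        if req not in chromosomes:
            raise ValueError(f"chromosomes must include {req!r}")

    rng = np.random.default_rng(seed)
    fracs = draw_fractions(loy_dist, rng, n)
    fracs_safe = np.minimum(fracs, 1.0 - 1e-12)
    batch_ids = rng.integers(0, n_batches, size=n)
    batch_offsets = rng.normal(0.0, batch_sd, size=n_batches) if batch_sd > 0 else np.zeros(n_batches)
    ages = rng.uniform(*age_range, size=n)

    k = probes_per_chrom
    n_chrom = len(chromosomes)
    ideal = np.zeros((n, n_chrom, k))
    y_idx = chromosomes.index("Y")
    ideal[:, y_idx, :] = (response_slope * np.log2(1.0 - fracs_safe))[:, None]
    noise = rng.normal(0.0, noise_sd, size=ideal.shape) if noise_sd > 0 else 0.0
    lrr = ideal + noise + batch_offsets[batch_ids][:, None, None]

    probe_ids = np.array(
        [f"chr{c}_p{j}" for c in chromosomes for j in range(k)], dtype=object
    )
    chrom_arr = np.array([c for c in chromosomes for _ in range(k)], dtype=object)

    profiles, truths = [], []
    for i in range(n):
        sid = f"S{i:06d}"
        bid = f"B{batch_ids[i]:03d}"
        profiles.append(
            IntensityProfile(
                subject_id=sid,
                probe_ids=probe_ids,
                chroms=chrom_arr,
                lrr=lrr[i].ravel(),
                batch_id=bid,
            )
        )
        truths.append(
            ArrayTruth(
                subject_id=sid,
                true_loy_fraction=float(fracs[i]),
                batch_id=bid,
                age=float(ages[i]),
            )
        )
    return profiles, truths


# ---------------------------------------------------------------------------
# Digital PCR
# ---------------------------------------------------------------------------

def gen_dpcr_run(
    true_f: float,
    n_partitions: int = 26000,
    mean_copies_per_partition: float = 1.0,
    seed: int = 0,
    sample_id: str = "sample0",
) -> PartitionPlate:
    """Synthetic dPCR plate for a sample with LOY fraction ``true_f``.

    X-channel positives ~ Binomial(n, 1 - exp(-lambda));
    Y-channel positives ~ Binomial(n, 1 - exp(-lambda * (1 - true_f))).
    """
    if not 0.0 <= true_f <= 1.0:
        raise ValueError("true_f must be in [0, 1]")
    if n_partitions < 100:
        raise ValueError("n_partitions must be >= 100")
    lam = float(mean_copies_per_partition)
    if lam <= 0:
        raise ValueError("mean_copies_per_partition must be > 0")
    rng = np.random.default_rng(seed)
    p_x = 1.0 - np.exp(-lam)
    p_y = 1.0 - np.exp(-lam * (1.0 - true_f))
    return PartitionPlate(
        sample_id=sample_id,
        n_partitions=n_partitions,
        positives_y=int(rng.binomial(n_partitions, p_y)),
        positives_x=int(rng.binomial(n_partitions, p_x)),
    )


# ---------------------------------------------------------------------------
# Single-cell cohorts
# ---------------------------------------------------------------------------

_DEFAULT_MSY_MEANS = {
    "RPS4Y1": 3.0,
    "DDX3Y": 1.5,
    "UTY": 0.8,
    "KDM5D": 0.8,
    "EIF1AY": 1.2,
    "USP9Y": 0.5,
}
_MITO_GENES = ["MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-CYB"]


def gen_sc_cohort(
    n_donors_per_condition: Mapping[str, int],
    cells_per_donor: int,
    celltype_props: Mapping[str, float],
    loy_frac_by_condition_and_type: Mapping[str, Mapping[str, float]],
    msy_gene_means: Optional[Mapping[str, float]] = None,
    profib_effect: float = 0.0,
    profib_genes: Sequence[str] = ("FN1", "SPP1"),
    profib_types: Sequence[str] = ("macrophage",),
    depth_dist=("lognormal", np.log(6000.0), 0.25),
    seed: int = 0,
    marker_table: Optional[Mapping[str, Sequence[str]]] = None,
    marker_strength: float = 4.0,
    marker_base_mean: float = 2.0,
    n_background_genes: int = 50,
    nominal_depth: float = 6000.0,
    mito_total_mean: float = 300.0,
    profib_base_mean: float = 5.0,
    overdispersion: Optional[float] = None,
) -> tuple[CellDataset, pd.DataFrame]:
    """Droplet scRNA-seq cohort with cell-level Y-loss ground truth.

    Gene means are expressed as expected counts in a cell of depth
    ``nominal_depth``; per cell, a target depth is drawn from
    ``depth_dist`` and every gene's Poisson rate is the mean scaled by
    ``depth / nominal_depth``. LOY is assigned per cell (all-or-none,
    before count sampling) from ``loy_frac_by_condition_and_type``; LOY
    cells have every MSY rate set to 0 and, in ``profib_types``, their
    ``profib_genes`` rates multiplied by ``exp(profib_effect)``. Marker
    genes (one implicit panel per type unless ``marker_table`` is given)
    are ``marker_strength`` times stronger in their own type. With
    ``overdispersion`` set, rates get a Gamma(1/d, d) multiplier
    (negative-binomial counts); the default Poisson keeps the MSY
    void-probability oracle closed-form.

    Returns the :class:`~mloykit.sc_loy.CellDataset` (metadata recomputed
    from the emitted matrix) and a ground-truth DataFrame with one row per
    cell (``cell_id, donor_id, condition, cell_type, is_loy, depth``).
    """
    if cells_per_donor < 1:
        raise ValueError("cells_per_donor must be >= 1")
    props = pd.Series(celltype_props, dtype=float)
    if (props < 0).any() or not np.isclose(props.sum(), 1.0):
        raise ValueError("celltype_props must be a simplex over labels")
    types = list(props.index)
    for cond, table in loy_frac_by_condition_and_type.items():
        unknown = set(table) - set(types)
        if unknown:
            raise ValueError(
                f"unknown cell-type labels in loy table for {cond!r}: "
                f"{sorted(unknown)}"
            )
    msy_means = dict(msy_gene_means or _DEFAULT_MSY_MEANS)
    if any(v < 0 for v in msy_means.values()) or not any(
        v > 0 for v in msy_means.values()
    ):
        raise ValueError("msy_gene_means must be >= 0 with at least one > 0")

    if marker_table is None:
        marker_table = {t: [f"MARKER_{t}"] for t in types}

    # gene panel and baseline means (expected counts at nominal depth)
    gene_means: dict[str, float] = {}
    gene_means.update(msy_means)
    for g in _MITO_GENES:
        gene_means[g] = mito_total_mean / len(_MITO_GENES)
    for t, markers in marker_table.items():
        for g in markers:
            gene_means.setdefault(g, marker_base_mean)
    for g in profib_genes:
        gene_means.setdefault(g, profib_base_mean)
    reserved = sum(gene_means.values())
    if reserved >= nominal_depth:
        raise ValueError("gene means exceed nominal depth; reduce means")
    bg_mean = (nominal_depth - reserved) / n_background_genes
    for j in range(n_background_genes):
        gene_means[f"BG{j:04d}"] = bg_mean

    genes = list(gene_means)
    gene_idx = {g: i for i, g in enumerate(genes)}
    base = np.array([gene_means[g] for g in genes])
    msy_rows = np.array([gene_idx[g] for g in msy_means])
    profib_rows = np.array([gene_idx[g] for g in profib_genes])

    rng = np.random.default_rng(seed)
    cell_rows = []
    for cond in sorted(n_donors_per_condition):
        loy_table = loy_frac_by_condition_and_type.get(cond, {})
        for d in range(n_donors_per_condition[cond]):
            donor = f"{cond}_D{d:02d}"
            ct = rng.choice(types, size=cells_per_donor, p=props.values)
            for i, t in enumerate(ct):
                frac = float(loy_table.get(t, 0.0))
                is_loy = bool(rng.random() < frac)
                cell_rows.append((f"{donor}_C{i:04d}", donor, cond, t, is_loy))
    meta = pd.DataFrame(
        cell_rows, columns=["cell_id", "donor_id", "condition", "cell_type", "is_loy"]
    )
    n_cells = len(meta)

    if callable(depth_dist):
        depths = np.asarray(depth_dist(rng, n_cells), dtype=float)
    else:
        kind, *params = depth_dist
        if kind == "lognormal":
            depths = rng.lognormal(params[0], params[1], size=n_cells)
        elif kind == "constant":
            depths = np.full(n_cells, float(params[0]))
        else:
            raise ValueError(f"unknown depth distribution {kind!r}")
    if np.any(depths <= 0):
        raise ValueError("depths must be positive")

    rates = np.tile(base[:, None], (1, n_cells)) * (depths / nominal_depth)[None, :]
    # type-specific marker boost
    type_arr = meta["cell_type"].values
    for t, markers in marker_table.items():
        cols = np.flatnonzero(type_arr == t)
        rows = [gene_idx[g] for g in markers if g in gene_idx]
        if len(cols) and rows:
            rates[np.ix_(rows, cols)] *= marker_strength
    loy_cols = np.flatnonzero(meta["is_loy"].values)
    rates[np.ix_(msy_rows, loy_cols)] = 0.0
    if profib_effect != 0.0:
        target = loy_cols[np.isin(type_arr[loy_cols], list(profib_types))]
        if len(target):
            rates[np.ix_(profib_rows, target)] *= np.exp(profib_effect)

    if overdispersion is not None and overdispersion > 0:
        rates = rates * rng.gamma(
            1.0 / overdispersion, overdispersion, size=rates.shape
        )
    counts = rng.poisson(rates)

    gene_df = pd.DataFrame(index=pd.Index(genes, name="gene"))
    gene_df["is_msy"] = gene_df.index.isin(msy_means)
    gene_df["is_mito"] = gene_df.index.isin(_MITO_GENES)
    cells = meta.set_index("cell_id")[["donor_id", "condition", "cell_type"]].copy()
    cells["sex"] = "M"
    dataset = CellDataset(counts=counts, genes=gene_df, cells=cells)

    truth = meta.copy()
    truth["depth"] = dataset.cells["depth"].values
    return dataset, truth


# ---------------------------------------------------------------------------
# Epidemiological cohorts
# ---------------------------------------------------------------------------

def _default_mloy_by_age(age: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Age-dependent mLOY percent: mean rises ~0.5 %/year past 40."""
    mean = 0.5 * np.maximum(age - 40.0, 0.0)
    return np.maximum(rng.normal(mean, 4.0), 0.0)


def gen_epi_cohort(
    n: int,
    frac_female: float = 0.5,
    mloy_dist_by_age: Optional[Callable] = None,
    hr_per_percent: float = 1.013,
    baseline_hazard: float = 0.001,
    covariate_effects: Optional[Mapping[str, float]] = None,
    max_followup: float = 15.0,
    seed: int = 0,
    smoking_probs: Sequence[float] = (0.55, 0.30, 0.15),
    smoking_mloy_shift: float = 0.0,
    fvc_high_mloy_deficit: float = 0.0,
    exposure_missing_frac: float = 0.0,
) -> pd.DataFrame:
    """Subject-level cohort with events from an exponential PH model.

    The log-hazard linear predictor is
    ``log(hr_per_percent) * mloy_percent + sum(covariate_effects)``;
    event times are exponential given the subject hazard, with
    administrative censoring at ``max_followup``. ``smoking_mloy_shift``
    adds that many mLOY percentage points to ever-smokers (a built-in
    smoking -> mLOY -> outcome chain for mediation tests);
    ``fvc_high_mloy_deficit`` subtracts litres of FVC for subjects with
    mLOY >= 40%. Female subjects have mLOY 0. Deterministic given ``seed``.
    """
    if hr_per_percent <= 0:
        raise ValueError("hr_per_percent must be > 0")
    if baseline_hazard < 0:
        raise ValueError("baseline_hazard must be >= 0")
    if max_followup < 0:
        raise ValueError("follow-up horizon must be >= 0")
    rng = np.random.default_rng(seed)
    sex = np.where(rng.random(n) < frac_female, "F", "M")
    age = rng.uniform(40.0, 70.0, size=n)
    smoking = rng.choice(
        ["never", "previous", "current"], size=n, p=list(smoking_probs)
    )
    mloy_fn = mloy_dist_by_age or _default_mloy_by_age
    mloy = mloy_fn(age, rng)
    mloy = np.asarray(mloy, dtype=float)
    if smoking_mloy_shift:
        mloy = mloy + smoking_mloy_shift * (smoking != "never")
    mloy = np.clip(mloy, 0.0, 100.0)
    mloy[sex == "F"] = 0.0

    packyears = np.where(
        smoking == "never", 0.0, rng.gamma(2.0, 10.0, size=n)
    )
    lp = np.log(hr_per_percent) * mloy
    covariate_effects = covariate_effects or {}
    frame_cov = {
        "age": age - 55.0,
        "smoking_previous": (smoking == "previous").astype(float),
        "smoking_current": (smoking == "current").astype(float),
        "packyears": packyears,
    }
    for name, beta in covariate_effects.items():
        if name not in frame_cov:
            raise ValueError(f"unknown covariate {name!r}")
        lp = lp + beta * frame_cov[name]

    hazard = baseline_hazard * np.exp(lp)
    with np.errstate(divide="ignore"):
        t_event = np.where(
            hazard > 0, rng.exponential(1.0, size=n) / np.maximum(hazard, 1e-300), np.inf
        )
    event = t_event <= max_followup
    time = np.minimum(t_event, max_followup)

    fvc = 4.6 - 0.02 * (age - 40.0) + rng.normal(0.0, 0.5, size=n)
    if fvc_high_mloy_deficit:
        fvc = fvc - fvc_high_mloy_deficit * (mloy >= 40.0)

    exposures = {
        f"pollutant_{k}": rng.lognormal(2.0, 0.3, size=n) for k in range(3)
    }
    df = pd.DataFrame(
        {
            "subject_id": [f"P{i:06d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "smoking": smoking,
            "packyears": packyears,
            "mloy_percent": mloy,
            "event": event.astype(int),
            "time": time,
            "fvc": fvc,
            **exposures,
        }
    )
    if exposure_missing_frac > 0:
        for col in exposures:
            miss = rng.random(n) < exposure_missing_frac
            df.loc[miss, col] = np.nan
    return df


# ---------------------------------------------------------------------------
# Writers / provenance
# ---------------------------------------------------------------------------

def write_array_cohort(
    profiles: Sequence[IntensityProfile],
    truths: Sequence[ArrayTruth],
    outdir,
) -> None:
    """Write probes as CSV (sample, probe, chrom, lrr, batch) + truth sidecar."""
    from .array_mloy import profiles_to_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles_to_frame(profiles).to_csv(outdir / "probes.csv", index=False)
    pd.DataFrame([t.__dict__ for t in truths]).to_csv(
        outdir / "truth.csv", index=False
    )


def write_epi_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def echo_config(config: Mapping, path) -> None:
    """Echo generator parameters into the output directory for provenance."""
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
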
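"""Synthetic datasets with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes --
a log-linear fossil-count process driven by research effort and
environmental predictors, a spatially autocorrelated continental
richness surface, and a logistic species-description curve -- without
attempting to mimic real geography. Every generator is a pure function
of its parameters and seed, and the generating coefficients are returned
as a :class:`GroundTruth` so downstream estimators can be tested for
parameter recovery without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from darkbirds import data_prep
from darkbirds.data_prep import INTERACTION

#: Predictor transforms used both when generating and when refitting.
DEFAULT_TRANSFORMS = {
    "research_effort": "log1p",
    "total_area": "log",
    "sd_area": "log",
    "isolation_distance": "log",
    "surrounding_landmass": "log",
    "elevation": "log",
    "precipitation": "log",
    "plant_richness": "log",
    "n_endemic": "log1p",
}

#: The twelve predictors retained after the default collinearity screen
#: (sd_area and surrounding_landmass are generated collinear with
#: total_area and isolation_distance and get dropped).
RETAINED_PREDICTORS = [
    "research_effort",
    "total_area",
    "isolation_distance",
    "elevation",
    "temperature",
    "precipitation",
    "temperature_variability",
    "precipitation_variability",
    "plant_richness",
    "native_rodents",
    "arrival_year",
    "n_endemic",
]

#: Generating coefficients on the standardized log(count + 1) scale.
#: Research effort dominates (it proxies fossil-record completeness),
#: with area and the area-by-effort interaction next, mirroring the
#: relative importance structure the fossil model is designed to detect.
DEFAULT_LM_COEFFICIENTS = {
    "intercept": 1.0,
    "research_effort": 0.7,
    "total_area": 0.45,
    "isolation_distance": 0.25,
    "elevation": 0.2,
    "temperature": -0.15,
    "precipitation": 0.1,
    "temperature_variability": 0.0,
    "precipitation_variability": 0.0,
    "plant_richness": 0.15,
    "native_rodents": -0.25,
    "arrival_year": -0.35,
    "n_endemic": 0.2,
    INTERACTION: 0.3,
}

DEFAULT_GRID_COEFFICIENTS = {
    "intercept": 5.8,
    "elevation": 0.15,
    "temperature": 0.35,
    "precipitation": 0.3,
    "temperature_variability": -0.15,
    "precipitation_variability": -0.05,
}

REALMS = ["Australasia", "Nearctic", "Neotropic", "IndoMalay", "Palearctic"]


@dataclass
class GroundTruth:
    """Generating parameters stored alongside each synthetic dataset."""

    lm_coefficients: dict = field(default_factory=dict)
    lm_sigma: float = 0.75
    grid_coefficients: dict = field(default_factory=dict)
    grid_autocorr: float = 0.0
    grid_overdispersion: float = 0.0
    logistic_truth: tuple | None = None
    seed: int | None = None

    def to_yaml(self, path) -> None:
        def plain(v):
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [plain(x) for x in v]
            if isinstance(v, np.generic):
                return v.item()
            return v

        Path(path).write_text(yaml.safe_dump(plain(asdict(self)), sort_keys=False))


def generate_archipelago_dataset(
    n_archipelagos: int = 69,
    reference_effort: float = 343.0,
    coefficients: dict | None = None,
    lm_sigma: float = 0.75,
    count_process: str = "lognormal",
    integer_counts: bool = True,
    transforms: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate an archipelago table from a log-linear fossil-count process.

    Raw predictors are drawn from right-skewed distributions typical of
    island data (areas and isolation over several orders of magnitude);
    ``sd_area`` and ``surrounding_landmass`` are built collinear with
    ``total_area`` and ``isolation_distance`` so the collinearity screen
    has real work to do. Fossil counts arise as
    ``max(round(exp(X beta + eps) - 1), 0)`` on the standardized design
    (``count_process="lognormal"``, under which the linear model of
    log(count + 1) is correctly specified) or, with
    ``count_process="poisson"``, from a Poisson with the same log-mean
    (a deliberately misspecified probe). Exactly one archipelago -- the
    one with maximum research effort, fixed at ``reference_effort`` --
    is flagged as the reference.
    """
    coefficients = dict(coefficients or DEFAULT_LM_COEFFICIENTS)
    transforms = dict(transforms or DEFAULT_TRANSFORMS)
    n_pred = len(RETAINED_PREDICTORS)
    if n_archipelagos < n_pred + 2:
        raise ValueError(
            f"n_archipelagos={n_archipelagos} cannot identify a model with {n_pred} predictors"
        )
    if count_process not in ("lognormal", "poisson"):
        raise ValueError("count_process must be 'lognormal' or 'poisson'")
    rng = np.random.default_rng(seed)
    n = n_archipelagos

    # Non-reference efforts stay strictly below the reference maximum.
    effort = np.clip(np.round(np.exp(rng.normal(3.0, 1.2, n))), 1, 0.8 * reference_effort)
    ref = int(np.argmax(effort))
    effort[ref] = reference_effort

    isolation = np.exp(rng.normal(5.5, 1.0, n))  # km
    # surrounding landmass declines linearly with isolation (raw-scale
    # Pearson r ~ -0.95), so the collinearity screen must arbitrate
    surrounding = np.maximum(6.5e6 - 1300.0 * isolation, 5.0e5) + np.abs(rng.normal(0, 2.0e5, n))  # km^2
    total_area = np.exp(rng.normal(6.5, 2.0, n))  # km^2
    sd_area = total_area * np.exp(rng.normal(-1.5, 0.4, n))
    elevation = np.exp(rng.normal(6.3, 1.0, n))  # m
    temperature = rng.normal(21.0, 6.0, n)
    precipitation = np.exp(rng.normal(7.2, 0.6, n))  # mm
    temp_var = np.abs(rng.normal(1.0, 0.4, n)) + 0.1
    precip_var = np.abs(rng.normal(1.0, 0.4, n)) + 0.1
    plant_richness = np.round(np.exp(rng.normal(6.0, 1.0, n))).astype(int) + 10
    native_rodents = rng.random(n) < 1.0 / 3.0
    # Arrival spans the Holocene peopling of islands; the reference was
    # colonized late (ca. 1250 CE) with tight bounds.
    lo = rng.uniform(-3000, 1100, n)
    hi = lo + rng.uniform(50, 400, n)
    lo[ref], hi[ref] = 1230.0, 1280.0
    n_endemic = rng.poisson(np.exp(rng.normal(2.0, 1.0, n))) + 1
    is_pacific = rng.random(n) < 0.55
    is_pacific[ref] = True

    df = pd.DataFrame(
        {
            "archipelago_id": [f"A{i:03d}" for i in range(n)],
            "name": [f"Synthetic Archipelago {i}" for i in range(n)],
            "n_fossil": 0,
            "n_observed": 0,
            "n_extant": 0,
            "n_endemic": n_endemic,
            "research_effort": effort.astype(int),
            "isolation_distance": isolation,
            "surrounding_landmass": surrounding,
            "elevation": elevation,
            "temperature": temperature,
            "precipitation": precipitation,
            "temperature_variability": temp_var,
            "precipitation_variability": precip_var,
            "plant_richness": plant_richness,
            "total_area": total_area,
            "sd_area": sd_area,
            "native_rodents": native_rodents,
            "arrival_year_lo": lo,
            "arrival_year_hi": hi,
            "is_pacific": is_pacific,
            "is_reference": np.arange(n) == ref,
        }
    )
    df = data_prep.validate_archipelagos(df)
    design = data_prep.prepare_design(df, RETAINED_PREDICTORS, transforms)
    beta = np.array([coefficients.get("intercept", 0.0)] + [coefficients.get(c, 0.0) for c in design.columns])
    X = np.column_stack([np.ones(n), design.values.to_numpy(float)])
    eta = X @ beta
    if count_process == "lognormal":
        eps = rng.normal(0.0, lm_sigma, n) if lm_sigma > 0 else np.zeros(n)
        latent = np.expm1(eta + eps)
        # integer rounding and the zero floor (the realistic data product)
        # mildly censor the smallest counts; calibration studies use the
        # exact latent instead, which may dip into (-1, 0)
        counts = np.maximum(np.round(latent), 0).astype(int) if integer_counts else latent
    else:
        counts = rng.poisson(np.expm1(np.maximum(eta, 0)) + 1e-9)
    df["n_fossil"] = counts
    # Observed (post-1500) extinctions and extant richness scale with the
    # same latent suitability but are not modelled; realistic magnitudes
    # only (global observed total on the order of 2e2, extant 1e4).
    df["n_observed"] = rng.poisson(np.maximum(0.25 * (counts + 1), 0.5))
    df["n_extant"] = rng.poisson(20 + 0.05 * plant_richness)
    truth = GroundTruth(
        lm_coefficients={"intercept": beta[0], **dict(zip(design.columns, beta[1:]))},
        lm_sigma=lm_sigma,
        seed=seed,
    )
    return df, truth


def _smooth_lattice(field: np.ndarray, strength: float, n_passes: int = 2) -> np.ndarray:
    """Mix each cell with its queen-neighbourhood mean, ``n_passes`` times."""
    if strength <= 0:
        return field
    f = field.copy()
    for _ in range(n_passes):
        padded = np.pad(f, 1, mode="edge")
        acc = np.zeros_like(f)
        cnt = np.zeros_like(f)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if dx == dy == 0:
                    continue
                acc += padded[1 + dx : 1 + dx + f.shape[0], 1 + dy : 1 + dy + f.shape[1]]
                cnt += 1
        f = (1 - strength) * f + strength * acc / cnt
    return f


def generate_grid_dataset(
    nx: int = 30,
    ny: int = 30,
    coefficients: dict | None = None,
    autocorr: float = 0.6,
    latent_sd: float = 0.5,
    overdispersion: float = 0.15,
    archipelago_ids: list[str] | None = None,
    cells_per_archipelago: tuple[int, int] = (1, 5),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a continental richness grid and an archipelago-cell mapping.

    Richness is drawn from an overdispersed count process with a log link
    on five environmental predictors plus a spatially smooth latent field
    (white noise mixed with its first-order neighbourhood mean with
    weight ``autocorr``). The default 30 x 30 lattice is the desk-scale
    stand-in for the full 10,600-cell continental grid, which remains
    available by configuration.
    """
    coefficients = dict(coefficients or DEFAULT_GRID_COEFFICIENTS)
    rng = np.random.default_rng(seed)
    n = nx * ny
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    preds = {
        "elevation": _smooth_lattice(rng.normal(0, 1, (nx, ny)), 0.5).ravel(),
        "temperature": _smooth_lattice(rng.normal(0, 1, (nx, ny)), 0.5).ravel(),
        "precipitation": _smooth_lattice(rng.normal(0, 1, (nx, ny)), 0.5).ravel(),
        "temperature_variability": rng.normal(0, 1, n),
        "precipitation_variability": rng.normal(0, 1, n),
    }
    latent = (
        _smooth_lattice(rng.normal(0, latent_sd, (nx, ny)), autocorr).ravel()
        if latent_sd > 0
        else np.zeros(n)
    )
    eta = coefficients["intercept"] + latent
    for name, vals in preds.items():
        eta = eta + coefficients.get(name, 0.0) * vals
    if overdispersion > 0:
        eta = eta + rng.normal(0, overdispersion, n)
    richness = rng.poisson(np.exp(eta))
    grid = pd.DataFrame(
        {"cell_id": [f"C{i:05d}" for i in range(n)], "x": xs.ravel(), "y": ys.ravel(), "richness": richness, **preds}
    )
    if archipelago_ids is None:
        archipelago_ids = [f"A{i:03d}" for i in range(69)]
    lo, hi = cells_per_archipelago
    rows = []
    for aid in archipelago_ids:
        k = int(rng.integers(lo, hi + 1))
        for cid in rng.choice(grid["cell_id"].to_numpy(), size=k, replace=False):
            rows.append((aid, cid))
    mapping = pd.DataFrame(rows, columns=["archipelago_id", "cell_id"])
    truth = GroundTruth(
        grid_coefficients=coefficients,
        grid_autocorr=autocorr,
        grid_overdispersion=overdispersion,
        seed=seed,
    )
    return grid, mapping, truth


def generate_species_register(
    archipelagos: pd.DataFrame,
    n_possibly_extinct: int = 46,
    n_continental_fossil: int = 98,
    n_observed_missing_last_record: int = 17,
    p_extinct_beta: tuple[float, float] = (4.0, 1.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a species register reconciling exactly with the table counts.

    One record per fossil and observed species of every archipelago, plus
    possibly-extinct species (with an extinction probability and a last
    record year) and continental fossil species spread over the five
    biogeographic realms. Indo-Malayan and Palearctic continental fossils
    carry a minimum fossil age earlier than 1500 CE, as required by their
    uniform dating rule.
    """
    rng = np.random.default_rng(seed)
    rows = []
    k = 0

    def add(**kw):
        nonlocal k
        rows.append(
            {
                "species_id": f"S{k:05d}",
                "category": kw["category"],
                "region_id": kw["region_id"],
                "region_type": kw.get("region_type", "archipelago"),
                "realm": kw.get("realm", ""),
                "last_record_year": kw.get("last_record_year", np.nan),
                "p_extinct": kw.get("p_extinct", np.nan),
                "min_fossil_age": kw.get("min_fossil_age", np.nan),
                "description_year": kw.get("description_year", np.nan),
            }
        )
        k += 1

    observed_missing = n_observed_missing_last_record
    total_observed = int(archipelagos["n_observed"].sum())
    if observed_missing > total_observed:
        raise ValueError("more observed species without last records than observed species")
    missing_flags = np.zeros(total_observed, dtype=bool)
    missing_flags[rng.choice(total_observed, size=observed_missing, replace=False)] = True
    obs_i = 0
    for _, rec in archipelagos.iterrows():
        for _ in range(int(rec["n_fossil"])):
            add(
                category="fossil",
                region_id=rec["archipelago_id"],
                description_year=float(np.round(rng.uniform(1843, 2017))),
            )
        for _ in range(int(rec["n_observed"])):
            year = np.nan if missing_flags[obs_i] else float(np.round(rng.uniform(1500, 2019)))
            add(category="observed", region_id=rec["archipelago_id"], last_record_year=year)
            obs_i += 1
    pacific_ids = archipelagos.loc[archipelagos["is_pacific"], "archipelago_id"].to_numpy()
    for _ in range(n_possibly_extinct):
        add(
            category="possibly_extinct",
            region_id=str(rng.choice(pacific_ids if len(pacific_ids) else archipelagos["archipelago_id"])),
            p_extinct=float(rng.beta(*p_extinct_beta)),
            last_record_year=float(np.round(rng.uniform(1900, 2019))),
        )
    realm_of = rng.choice(REALMS, size=n_continental_fossil)
    for realm in realm_of:
        kw = dict(category="fossil", region_id=realm, region_type="continental_realm", realm=realm)
        if realm in ("IndoMalay", "Palearctic"):
            kw["min_fossil_age"] = float(np.round(rng.uniform(-20000, 1000)))
        add(**kw)
    return data_prep.validate_species(pd.DataFrame(rows))


def generate_description_series(
    logistic_truth: tuple[float, float, float, float] = (522.0, 1950.0, 0.05, 5.0),
    years: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Cumulative species-description counts from a noisy logistic curve.

    ``logistic_truth`` is (maximum, midpoint year, growth rate per year,
    noise sd). Counts are the logistic mean plus Gaussian noise, rounded
    and made non-decreasing; with zero noise the rounded logistic itself.
    """
    maximum, midpoint, rate, noise_sd = logistic_truth
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    years = np.arange(1843, 2018) if years is None else np.asarray(years)
    rng = np.random.default_rng(seed)
    mean = maximum / (1.0 + np.exp(-rate * (years - midpoint)))
    noisy = mean + (rng.normal(0, noise_sd, len(years)) if noise_sd > 0 else 0.0)
    counts = np.maximum.accumulate(np.round(np.maximum(noisy, 0.0)))
    return pd.DataFrame({"year": years, "n_described": counts.astype(int)})


def write_dataset(
    outdir,
    archipelagos: pd.DataFrame,
    truth: GroundTruth,
    grid: pd.DataFrame | None = None,
    mapping: pd.DataFrame | None = None,
    species: pd.DataFrame | None = None,
    description: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write a synthetic dataset in the CSV schemas ``data_prep`` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    cols = [c for c in data_prep.ARCHIPELAGO_COLUMNS]
    archipelagos[cols].to_csv(outdir / "archipelagos.csv", index=False)
    paths["archipelagos"] = outdir / "archipelagos.csv"
    for name, df in (("grid", grid), ("mapping", mapping), ("species", species), ("description", description)):
        if df is not None:
            df.to_csv(outdir / f"{name}.csv", index=False)
            paths[name] = outdir / f"{name}.csv"
    truth.to_yaml(outdir / "ground_truth.yaml")
    paths["ground_truth"] = outdir / "ground_truth.yaml"
    return paths
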
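"""Reading, validation, filtering and standardization of the tabular inputs.

Three tables drive the analysis:

* an island table (one row per island) used only to decide which islands
  are eligible to contribute to an archipelago,
* an archipelago table (one row per archipelago) with fossil / observed /
  extant / endemic species counts, fossil-record research effort, and the
  environmental predictors of the fossil-count models,
* a continental grid table plus an archipelago-to-cell mapping used by the
  upper-bound richness model, and a species register used by the
  chronology machinery.

All predictors enter the models transformed (where configured), centred
and scaled to zero mean and unit variance; the constants of that mapping
are retained in a :class:`PredictorMatrix` so that new raw values (for
example, the reference archipelago's research effort) can be projected
into model space exactly as at fit time.

Calendar years use astronomical numbering throughout (a year 0 exists,
so 124,050 BCE is -124049).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is missing or a table-level invariant is violated."""


class ParseError(ValueError):
    """A cell could not be interpreted (e.g. a non-numeric count)."""


#: Columns every archipelago table must provide.
ARCHIPELAGO_COLUMNS = [
    "archipelago_id",
    "name",
    "n_fossil",
    "n_observed",
    "n_extant",
    "n_endemic",
    "research_effort",
    "isolation_distance",
    "surrounding_landmass",
    "elevation",
    "temperature",
    "precipitation",
    "temperature_variability",
    "precipitation_variability",
    "plant_richness",
    "total_area",
    "sd_area",
    "native_rodents",
    "arrival_year_lo",
    "arrival_year_hi",
    "is_pacific",
    "is_reference",
]

ISLAND_COLUMNS = [
    "island_id",
    "archipelago_id",
    "area",
    "isolated_from_mainland",
    "glaciated_lgm",
    "settled_pre1500",
]

GRID_COLUMNS = [
    "cell_id",
    "x",
    "y",
    "richness",
    "elevation",
    "temperature",
    "precipitation",
    "temperature_variability",
    "precipitation_variability",
]

SPECIES_COLUMNS = [
    "species_id",
    "category",
    "region_id",
    "region_type",
    "realm",
    "last_record_year",
    "p_extinct",
    "min_fossil_age",
    "description_year",
]

#: The fourteen candidate predictors of the fossil-count models, in
#: priority order for collinearity screening (earlier names win).
CANDIDATE_PREDICTORS = [
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
    "sd_area",
    "surrounding_landmass",
]

COUNT_COLUMNS = {
    "n_fossil",
    "n_observed",
    "n_extant",
    "n_endemic",
    "research_effort",
    "plant_richness",
    "richness",
}

#: Name given to the area-by-effort interaction column of the design.
INTERACTION = "total_area_x_research_effort"

_TRANSFORMS = {
    "identity": (lambda x: x, lambda y: y),
    "log": (np.log, np.exp),
    "log1p": (np.log1p, np.expm1),
    "sqrt": (np.sqrt, np.square),
}


def _require(df: pd.DataFrame, columns: list[str], table: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing required column(s): {missing}")
    extra = [c for c in df.columns if c not in columns]
    if extra:
        logger.warning("%s table: ignoring unknown column(s) %s", table, extra)
    return df[columns].copy()


def _coerce_counts(df: pd.DataFrame, table: str) -> None:
    for col in df.columns.intersection(COUNT_COLUMNS):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise ParseError(f"{table}.{col}: non-numeric count at row(s) {list(bad[:5])}")
        if (vals < 0).any():
            raise SchemaError(f"{table}.{col}: negative count")
        df[col] = vals.astype(int)


def validate_archipelagos(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise an archipelago table.

    Enforces the table invariants: non-negative counts, ordered arrival
    bounds, strictly boolean flags, and exactly one reference archipelago.
    Adds the derived ``arrival_year`` predictor (midpoint of the arrival
    bounds, astronomical years).
    """
    df = _require(df, ARCHIPELAGO_COLUMNS, "archipelago")
    _coerce_counts(df, "archipelago")
    for col in ("native_rodents", "is_pacific", "is_reference"):
        df[col] = df[col].astype(bool)
    if (df["arrival_year_lo"] > df["arrival_year_hi"]).any():
        raise SchemaError("archipelago: arrival_year_lo > arrival_year_hi")
    n_ref = int(df["is_reference"].sum())
    if n_ref != 1:
        raise SchemaError(f"archipelago: expected exactly one reference archipelago, found {n_ref}")
    df["arrival_year"] = 0.5 * (df["arrival_year_lo"] + df["arrival_year_hi"])
    logger.info("archipelago table: %d records", len(df))
    return df


def validate_islands(df: pd.DataFrame) -> pd.DataFrame:
    df = _require(df, ISLAND_COLUMNS, "island")
    if (pd.to_numeric(df["area"], errors="coerce") <= 0).any():
        raise SchemaError("island: area must be > 0")
    for col in ("isolated_from_mainland", "glaciated_lgm", "settled_pre1500"):
        df[col] = df[col].astype(bool)
    return df


def validate_grid(df: pd.DataFrame) -> pd.DataFrame:
    df = _require(df, GRID_COLUMNS, "grid")
    _coerce_counts(df, "grid")
    if not np.isfinite(df[GRID_COLUMNS[4:]].to_numpy(float)).all():
        raise SchemaError("grid: non-finite predictor value")
    return df


def validate_species(df: pd.DataFrame) -> pd.DataFrame:
    df = _require(df, SPECIES_COLUMNS, "species")
    ok = df["category"].isin(["fossil", "observed", "possibly_extinct", "undiscovered"])
    if not ok.all():
        raise SchemaError(f"species: unknown category {sorted(df.loc[~ok, 'category'].unique())}")
    pe = df["category"] == "possibly_extinct"
    p = pd.to_numeric(df.loc[pe, "p_extinct"], errors="coerce")
    if p.isna().any() or (p < 0).any() or (p > 1).any():
        raise SchemaError("species: possibly_extinct records need p_extinct in [0, 1]")
    return df


def read_tables(
    archipelago_path,
    island_path=None,
    grid_path=None,
    mapping_path=None,
    species_path=None,
):
    """Read and validate the delimited input tables.

    Only the archipelago table is mandatory; the others are returned as
    ``None`` when no path is given. Unknown columns are dropped with a
    logged warning; missing required columns raise :class:`SchemaError`.
    """
    archipelagos = validate_archipelagos(pd.read_csv(archipelago_path))
    islands = validate_islands(pd.read_csv(island_path)) if island_path else None
    grid = validate_grid(pd.read_csv(grid_path)) if grid_path else None
    mapping = pd.read_csv(mapping_path) if mapping_path else None
    if mapping is not None:
        mapping = _require(mapping, ["archipelago_id", "cell_id"], "mapping")
    species = validate_species(pd.read_csv(species_path)) if species_path else None
    return archipelagos, islands, grid, mapping, species


def filter_islands(
    islands: pd.DataFrame, min_area: float = 5.0, reference_year: int = 1500
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the four island-eligibility rules.

    An island contributes to its archipelago only if it (1) has area
    strictly greater than ``min_area`` km^2, (2) was isolated from the
    mainland at the last-glacial-maximum sea level, (3) was not glaciated
    at the last glacial maximum, and (4) was settled by humans before
    written observational records began (``reference_year``, 1500 CE).

    Returns the eligible subset and a tally of how many islands each rule
    excluded (an island failing several rules is counted in each).
    """
    if min_area <= 0:
        raise ValueError("min_area must be > 0")
    islands = validate_islands(islands) if len(islands) else islands
    rules = {
        "area": islands["area"] > min_area if len(islands) else pd.Series(dtype=bool),
        "isolation": islands["isolated_from_mainland"] if len(islands) else pd.Series(dtype=bool),
        "glaciation": ~islands["glaciated_lgm"] if len(islands) else pd.Series(dtype=bool),
        "settlement": islands["settled_pre1500"] if len(islands) else pd.Series(dtype=bool),
    }
    tally = {name: int((~passed).sum()) for name, passed in rules.items()}
    if not len(islands):
        return islands, tally
    keep = np.logical_and.reduce([p.to_numpy() for p in rules.values()])
    return islands.loc[keep].copy(), tally


def screen_collinearity(
    archipelagos: pd.DataFrame,
    predictors: list[str] | None = None,
    threshold: float = 0.8,
    priority: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop one member of every highly correlated predictor pair.

    For each pair with \\|Pearson r\\| >= ``threshold``, the member ranked
    lower in ``priority`` (default :data:`CANDIDATE_PREDICTORS` order) is
    dropped. Returns the retained names and the full pairwise correlation
    matrix.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    predictors = list(predictors or CANDIDATE_PREDICTORS)
    priority = list(priority or CANDIDATE_PREDICTORS)
    X = archipelagos[predictors].astype(float)
    sd = X.std(ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()]
    if len(constant):
        raise ValueError(f"constant column(s) make correlation undefined: {list(constant)}")
    corr = X.corr(method="pearson")

    def rank(name: str) -> int:
        return priority.index(name) if name in priority else len(priority)

    dropped: set[str] = set()
    for i, a in enumerate(predictors):
        for b in predictors[i + 1 :]:
            if a in dropped or b in dropped:
                continue
            r = corr.loc[a, b]
            hit = abs(r) >= threshold if threshold < 1 else abs(r) == 1
            if hit:
                loser = b if rank(a) <= rank(b) else a
                dropped.add(loser)
                logger.info("collinearity screen: |r(%s, %s)| = %.3f, dropping %s", a, b, abs(r), loser)
    retained = [p for p in predictors if p not in dropped]
    return retained, corr


@dataclass
class PredictorMatrix:
    """Standardized design matrix plus the constants to reproduce it.

    ``values`` holds one row per archipelago (indexed by id) with every
    non-interaction column transformed, centred and scaled to unit sample
    (n-1) standard deviation. The interaction column is the product of
    the two scaled main-effect columns and is deliberately left unscaled,
    so its coefficient reads as effect modification per SD.
    """

    values: pd.DataFrame
    transform_spec: dict[str, dict] = field(default_factory=dict)
    interaction: tuple[str, str] | None = ("total_area", "research_effort")

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def to_model_space(self, column: str, raw) -> np.ndarray | float:
        """Map a raw predictor value into the fitted model space."""
        spec = self.transform_spec[column]
        fwd = _TRANSFORMS[spec["transform"]][0]
        return (fwd(np.asarray(raw, dtype=float)) - spec["center"]) / spec["scale"]

    def from_model_space(self, column: str, z) -> np.ndarray | float:
        """Inverse of :meth:`to_model_space`."""
        spec = self.transform_spec[column]
        inv = _TRANSFORMS[spec["transform"]][1]
        return inv(np.asarray(z, dtype=float) * spec["scale"] + spec["center"])


def prepare_design(
    archipelagos: pd.DataFrame,
    retained: list[str],
    transform_spec: dict[str, str] | None = None,
    interaction: tuple[str, str] | None = ("total_area", "research_effort"),
) -> PredictorMatrix:
    """Build the standardized design matrix for the fossil-count models.

    ``transform_spec`` maps predictor names to a monotone transform
    (``identity``, ``log``, ``log1p`` or ``sqrt``; unnamed columns use
    identity) applied before centring and scaling. Standardization uses
    the sample (n-1) standard deviation; the constants are stored so raw
    values round-trip exactly.
    """
    transform_spec = dict(transform_spec or {})
    out = {}
    spec_out: dict[str, dict] = {}
    X = archipelagos.set_index("archipelago_id") if "archipelago_id" in archipelagos else archipelagos
    for col in retained:
        name = transform_spec.get(col, "identity")
        if name not in _TRANSFORMS:
            raise ValueError(f"unknown transform {name!r} for column {col!r}")
        raw = X[col].astype(float)
        if name == "log" and (raw <= 0).any():
            bad = raw.index[raw <= 0][0]
            raise ValueError(f"log transform of non-positive value in column {col!r} at row {bad!r}")
        if name in ("log1p", "sqrt") and (raw < 0).any():
            bad = raw.index[raw < 0][0]
            raise ValueError(f"{name} transform of negative value in column {col!r} at row {bad!r}")
        t = _TRANSFORMS[name][0](raw)
        center, scale = float(t.mean()), float(t.std(ddof=1))
        if scale == 0:
            raise ValueError(f"column {col!r} is constant after transform; cannot scale")
        out[col] = (t - center) / scale
        spec_out[col] = {"transform": name, "center": center, "scale": scale, "sd_convention": "sample(n-1)"}
    values = pd.DataFrame(out, index=X.index)
    if interaction is not None:
        a, b = interaction
        if a not in values or b not in values:
            raise ValueError(f"interaction columns {interaction} must both be retained")
        values[INTERACTION] = values[a] * values[b]
    return PredictorMatrix(values=values, transform_spec=spec_out, interaction=interaction)


def compute_vif(design: PredictorMatrix | pd.DataFrame) -> pd.Series:
    """Variance inflation factor per design column.

    VIF_j = 1 / (1 - R^2_j) with R^2_j from regressing column j on all
    other columns (plus an intercept). Exact collinearity reports +inf.
    """
    X = design.values if isinstance(design, PredictorMatrix) else design
    if X.shape[1] < 2 or X.shape[0] <= X.shape[1]:
        raise ValueError("VIF needs >= 2 columns and more rows than columns")
    arr = X.to_numpy(float)
    n = arr.shape[0]
    vifs = {}
    for j, col in enumerate(X.columns):
        y = arr[:, j]
        others = np.column_stack([np.ones(n), np.delete(arr, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0
        vifs[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(vifs, name="vif")
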
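"""Constraining and combining extinction components into totals.

Undiscovered-extinction draws that exceed their archipelago's
island-biogeography upper bound are rejected and replaced by fresh
draw/bound pairs resampled from the posterior ensembles (with a capped
number of retries, after which the draw is truncated to the bound), so a
fixed-size accepted ensemble always results. Accepted undiscovered
draws, the fixed fossil counts, and binomially resampled observed
extinctions (confirmed observed species plus probabilistic inclusion of
possibly-extinct species) are then summed draw-wise into global,
Pacific, and non-Pacific totals with equal-tailed credible intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RejectionReport:
    rates: pd.Series  # per-archipelago fraction of proposals rejected
    truncation_events: int

    @property
    def median_rate(self) -> float:
        return float(self.rates.median())

    @property
    def mean_rate(self) -> float:
        return float(self.rates.mean())


@dataclass
class TotalsSummary:
    """Draw-wise component sums and their summaries per stratum."""

    components: dict  # stratum -> component -> {median, lo, hi}
    derived: dict = field(default_factory=dict)
    draws: dict | None = None  # stratum -> component -> np.ndarray

    def to_dict(self) -> dict:
        return {"components": self.components, "derived": self.derived}


def _as_array(obj) -> np.ndarray:
    return np.asarray(getattr(obj, "draws", obj), dtype=float)


def rejection_sample(
    undiscovered_draws: dict,
    bound_draws: dict,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> tuple[dict[str, np.ndarray], RejectionReport]:
    """Enforce the upper bounds by rejection with resampled replacements.

    For each archipelago and draw index, a (estimate, bound) pair with
    estimate > bound is rejected and both members are redrawn from their
    respective ensembles until accepted or ``max_retries`` is exhausted,
    at which point the estimate is truncated to the bound and the event
    logged. The per-archipelago rejection rate is the fraction of all
    proposals rejected.
    """
    if max_retries < 1:
        raise ValueError("max_retries must be >= 1")
    accepted: dict[str, np.ndarray] = {}
    rates = {}
    truncations = 0
    for aid, est in undiscovered_draws.items():
        est = _as_array(est)
        bnd = _as_array(bound_draws[aid]) if aid in bound_draws else np.full_like(est, np.inf)
        n = len(est)
        if len(bnd) != n:
            raise ValueError(f"draw-count mismatch for {aid}: {n} estimates vs {len(bnd)} bounds")
        out = est.copy()
        proposals = n
        rejected = 0
        bad = np.nonzero(out > bnd)[0]
        current_bnd = bnd.copy()
        for i in bad:
            rejected += 1  # the original proposal
            ok = False
            for _ in range(max_retries):
                j, k = rng.integers(0, n, size=2)
                proposals += 1
                if est[j] <= bnd[k]:
                    out[i], current_bnd[i] = est[j], bnd[k]
                    ok = True
                    break
                rejected += 1
            if not ok:
                k = int(rng.integers(0, n))
                out[i] = min(out[i], np.floor(bnd[k]))
                current_bnd[i] = bnd[k]
                truncations += 1
        accepted[aid] = np.maximum(out, 0.0)
        # all rejected proposals over all proposals, first pass included
        rates[aid] = rejected / proposals if proposals else 0.0
    report = RejectionReport(rates=pd.Series(rates, name="rejection_rate"), truncation_events=truncations)
    return accepted, report


def observed_component_draws(
    register: pd.DataFrame,
    n_draws: int,
    rng: np.random.Generator,
    strata: pd.Series | None = None,
) -> pd.DataFrame:
    """Draw-wise observed-extinction totals.

    Each draw counts every confirmed observed extinction once and each
    possibly-extinct species with probability equal to its assessed
    extinction probability. When ``strata`` labels the register rows,
    per-stratum columns are returned alongside ``global``; the stratum
    columns share one inclusion realization, so they sum to the global
    column exactly.
    """
    obs = register.loc[register["category"] == "observed"]
    poss = register.loc[register["category"] == "possibly_extinct"]
    p = poss["p_extinct"].to_numpy(float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("extinction probabilities must lie in [0, 1]")
    include = rng.random((n_draws, len(p))) < p  # (n_draws, n_poss)
    out = {"global": np.full(n_draws, len(obs), dtype=float) + include.sum(axis=1)}
    if strata is not None:
        for label in strata.dropna().unique():
            obs_n = int((strata.loc[obs.index] == label).sum())
            mask = (strata.loc[poss.index] == label).to_numpy()
            out[str(label)] = obs_n + include[:, mask].sum(axis=1)
    return pd.DataFrame(out)


def credible_interval(draws, level: float = 0.95, hdi: bool = False) -> tuple[float, float]:
    """Equal-tailed (default) or highest-density interval of the draws."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty draws")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if not hdi:
        alpha = (1.0 - level) / 2.0
        return float(np.quantile(draws, alpha)), float(np.quantile(draws, 1.0 - alpha))
    x = np.sort(draws)
    m = int(np.ceil(level * len(x)))
    if m >= len(x):
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: len(x) - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


def assemble_totals(
    accepted: dict[str, np.ndarray],
    archipelagos: pd.DataFrame,
    observed_draws: pd.DataFrame,
    extant_present: int = 10865,
    n_continental_fossil: int = 0,
    level: float = 0.95,
    hdi: bool = False,
    keep_draws: bool = False,
) -> TotalsSummary:
    """Assemble stratum totals with credible intervals.

    Fossil counts are fixed data (archipelago fossils plus continental
    fossils, the latter assigned to the non-Pacific stratum); observed
    and undiscovered components vary across draws. Per draw the Pacific
    and non-Pacific totals sum exactly to the global total.
    """
    if "is_pacific" not in archipelagos:
        raise ValueError("archipelago table must carry the is_pacific flag")
    arch = archipelagos.set_index("archipelago_id")
    n_draws = len(observed_draws)
    strata = {"global": None, "pacific": True, "non_pacific": False}
    draws: dict[str, dict[str, np.ndarray]] = {}
    for name, flag in strata.items():
        if flag is None:
            ids = arch.index
        else:
            ids = arch.index[arch["is_pacific"] == flag]
        fossil = float(arch.loc[ids, "n_fossil"].sum())
        if flag in (None, False):
            fossil += n_continental_fossil
        undiscovered = np.zeros(n_draws)
        for aid in ids:
            if aid in accepted:
                undiscovered = undiscovered + np.asarray(accepted[aid], dtype=float)
        observed = observed_draws[name].to_numpy(float) if name in observed_draws else observed_draws["global"].to_numpy(float) * 0.0
        draws[name] = {
            "fossil": np.full(n_draws, fossil),
            "observed": observed,
            "undiscovered": undiscovered,
            "total": fossil + observed + undiscovered,
        }
    components = {
        name: {
            comp: {
                "median": float(np.median(vals)),
                "lo": credible_interval(vals, level, hdi)[0],
                "hi": credible_interval(vals, level, hdi)[1],
            }
            for comp, vals in comps.items()
        }
        for name, comps in draws.items()
    }
    g = components["global"]
    p = components["pacific"]

    def ratio(num, den):
        return num / den if den else float("nan")

    derived = {
        "percent_undiscovered": 100.0 * ratio(g["undiscovered"]["median"], g["total"]["median"]),
        "percent_total_pacific": 100.0 * ratio(p["total"]["median"], g["total"]["median"]),
        "percent_undiscovered_pacific": 100.0
        * ratio(p["undiscovered"]["median"], g["undiscovered"]["median"]),
        "percent_of_all_birds_extinct": 100.0
        * ratio(g["total"]["median"], g["total"]["median"] + extant_present),
        "pacific_undiscovered_to_total_ratio": ratio(p["undiscovered"]["median"], p["total"]["median"]),
    }
    return TotalsSummary(components=components, derived=derived, draws=draws if keep_draws else None)
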
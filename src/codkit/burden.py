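"""Years of life lost, age-standardised rates, hierarchy aggregation, and
change metrics.

YLLs value each death by the standard life expectancy at its age:
YLL(a) = deaths(a) x SLE(a).  The packaged standard life table is a
synthetic stand-in anchored at SLE(birth) = 86.6 years and strictly
decreasing with age; the standard population used for age standardisation
is likewise a synthetic, time-invariant weight set summing to 1.  Both are
plain two-column files, so externally supplied reference tables can be
dropped in.

All operations act draw-wise when given a :class:`DrawCube`, so uncertainty
propagates into YLLs, standardised rates, and change metrics unchanged.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .codcorrect import point_and_ui, significant_change
from .cube import DrawCube
from .hierarchy import CauseHierarchy

PER = 100_000.0


def _packaged(name: str) -> pd.DataFrame:
    with importlib.resources.files("codkit.data").joinpath(name).open() as f:
        return pd.read_csv(f)


def load_standard_life_table(path=None) -> pd.Series:
    """Standard life expectancy by age-group index (synthetic stand-in by
    default)."""
    df = pd.read_csv(path) if path is not None else _packaged(
        "synthetic_standard_life_table.csv")
    s = df.set_index("age")["sle"]
    if not (s.diff().dropna() < 0).all():
        raise ValueError("standard life expectancy must strictly decrease with age")
    return s


def load_standard_population(path=None) -> pd.Series:
    """Standard population weights by age-group index; sums to 1."""
    df = pd.read_csv(path) if path is not None else _packaged(
        "synthetic_standard_population.csv")
    s = df.set_index("age")["weight"]
    if (s < 0).any() or abs(s.sum() - 1.0) > 1e-9:
        raise ValueError("standard population weights must be >= 0 and sum to 1")
    return s


def ylls(deaths, life_table: pd.Series):
    """Years of life lost.

    * Series of deaths indexed by age -> (YLL Series by age, total).
    * DrawCube of deaths -> DrawCube of YLLs (draw-wise).
    """
    if isinstance(deaths, DrawCube):
        ages = deaths.index["age"]
        missing = set(ages.unique()) - set(life_table.index)
        if missing:
            raise ValueError(f"ages outside life table: {sorted(missing)}")
        sle = ages.map(life_table).to_numpy(float)[:, None]
        return DrawCube(deaths.index.copy(), deaths.draws * sle)
    deaths = pd.Series(deaths)
    missing = set(deaths.index) - set(life_table.index)
    if missing:
        raise ValueError(f"ages outside life table: {sorted(missing)}")
    by_age = deaths * life_table.reindex(deaths.index)
    return by_age, float(by_age.sum())


def age_standardise(rates, std_pop: pd.Series) -> float | np.ndarray:
    """Age-standardised rate: sum over ages of w(a) x rate(a).

    ``rates`` may be a Series (age -> rate) or a DataFrame / 2-D array of
    per-draw rates indexed by age (rows); pass rates per 100 000 to get the
    standardised rate per 100 000.  Age sets must match the standard
    population exactly; the weights sum to 1, so a constant rate
    standardises to itself.
    """
    if isinstance(rates, pd.DataFrame):
        idx = rates.index
        vals = rates.to_numpy(float)
    else:
        rates = pd.Series(rates)
        idx = rates.index
        vals = rates.to_numpy(float)
    if set(idx) != set(std_pop.index):
        raise ValueError("age groups of rates and standard population differ")
    w = std_pop.reindex(idx).to_numpy(float)
    out = vals.T @ w
    return float(out) if np.ndim(out) == 0 else out


def cube_rates(cube: DrawCube, population: pd.DataFrame) -> DrawCube:
    """Convert a deaths cube to rates using a population table
    (location, year, age, sex, population)."""
    merged = cube.index.merge(population, on=["location", "year", "age", "sex"],
                              how="left")
    if merged["population"].isna().any():
        raise ValueError("population missing for some cells")
    return DrawCube(cube.index.copy(),
                    cube.draws / merged["population"].to_numpy(float)[:, None])


def aggregate_hierarchy(cube: DrawCube, hierarchy: CauseHierarchy) -> DrawCube:
    """Sum most-detailed draws up the cause tree, per draw.

    Returns a cube holding every cause (leaves plus all internal nodes).
    The Level-1 causes partition the total, so their sum per cell-draw is
    the all-cause total.
    """
    leaves = set(hierarchy.most_detailed())
    present = set(cube.index["cause"].unique())
    orphans = present - set(hierarchy.cause_ids)
    if orphans:
        raise ValueError(f"causes not in hierarchy: {sorted(orphans)}")
    not_leaf = present - leaves
    if not_leaf:
        raise ValueError(
            f"input draws must be on most-detailed causes only; got {sorted(not_leaf)}"
        )
    pieces = [cube]
    frame = cube.index
    for node in hierarchy.internal_nodes():
        node_leaves = [l for l in hierarchy.most_detailed()
                       if node in hierarchy.ancestors(l) or l == node]
        sel = frame["cause"].isin(node_leaves).to_numpy()
        if not sel.any():
            continue
        sub_idx = frame[sel]
        codes, cells = DrawCube(sub_idx, cube.draws[sel]).cell_groups()
        sums = np.zeros((len(cells), cube.n_draws))
        np.add.at(sums, codes, cube.draws[sel])
        idx = cells.copy()
        idx["cause"] = node
        pieces.append(DrawCube(idx, sums))
    index = pd.concat([p.index for p in pieces], ignore_index=True)
    draws = np.vstack([p.draws for p in pieces])
    return DrawCube(index, draws)


def change_metrics(values_t1, values_t2, years: float) -> dict:
    """Percent change and annualised rate of change (ARC) with uncertainty.

    Per draw: percent change = 100 (v2 - v1)/v1; ARC = 100 ln(v2/v1)/years
    (log-ratio per year).  Draws with v1 = 0 are treated as missing and
    excluded from the summaries; their count is reported.  Significance
    follows the 95%-of-draws rule on the raw values.
    """
    if years <= 0:
        raise ValueError("years must be positive")
    v1 = np.asarray(values_t1, dtype=float)
    v2 = np.asarray(values_t2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("draw vectors must be matched")
    ok = v1 != 0
    n_missing = int((~ok).sum())
    if not ok.any():
        raise ValueError("v1 is zero in every draw")
    pct = 100.0 * (v2[ok] - v1[ok]) / v1[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        arc = 100.0 * np.log(v2[ok] / v1[ok]) / years
    out = {
        "percent_change": point_and_ui(pct),
        "arc": point_and_ui(arc[np.isfinite(arc)]) if np.isfinite(arc).sum() >= 2
        else (float("nan"),) * 3,
        "significance": significant_change(v1, v2),
        "n_missing_draws": n_missing,
    }
    return out
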
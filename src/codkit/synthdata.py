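"""Synthetic truth and its distorted observation.

The generator produces a latent cause-specific mortality surface ("truth")
driven by an SDI-linked epidemiological transition — log death rates are
linear in SDI, with steeply negative slopes for CMNN causes, shallow slopes
for NCDs, and intermediate slopes for injuries — and then pushes that truth
through the defects real cause-of-death data carry: incomplete registration,
age-dependent garbage coding, cause-list aggregation by source, and verbal
autopsy misclassification.

Every downstream stage (quality rating, redistribution, ensemble modelling,
envelope rescaling, burden, SDI curves) is tested against this generator, so
its observation model is deliberately the simplest one consistent with count
data: Poisson counts, thinned binomially for completeness, reallocated
multinomially for garbage coding and misclassification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cube import EnvelopeDraws
from .hierarchy import CauseHierarchy, toy_hierarchy

N_AGE_GROUPS = 23

#: 0-based age-group index -> label; intervals are closed-open in days/years.
AGE_GROUP_LABELS = (
    ["0-6 days", "7-27 days", "28-364 days", "1-4 years"]
    + [f"{a}-{a + 4} years" for a in range(5, 95, 5)]
    + ["95 plus"]
)

#: Midpoint age in years per group, used for life-table interpolation.
AGE_GROUP_MIDPOINTS = np.array(
    [0.01, 0.05, 0.54, 3.0] + [a + 2.5 for a in range(5, 95, 5)] + [97.5]
)

SOURCE_VR = "VR"
SOURCE_VA = "VA"
SOURCE_SUBNATIONAL_VA = "subnational_VA"
SOURCE_NONE = "none"

# Group-level SDI slopes on the log-rate scale: CMNN falls steeply with
# development, NCDs are nearly flat, injuries in between.
DEFAULT_GROUP_SLOPES = {"cmnn": -3.0, "ncd": -0.4, "injury": -1.2}
DEFAULT_GROUP_INTERCEPTS = {"cmnn": -5.2, "ncd": -6.0, "injury": -7.0}


def default_age_offsets() -> np.ndarray:
    """U-shaped log-rate age pattern: elevated in infancy, minimum in late
    childhood, rising roughly Gompertz-like (log-linearly) to the terminal
    group."""
    idx = np.arange(N_AGE_GROUPS)
    child = np.where(idx < 4, 2.2 - 0.95 * idx, 0.0)
    adult = np.where(idx >= 4, -1.6 + 0.26 * (idx - 4.0), 0.0)
    return child + adult


def default_population_shares() -> np.ndarray:
    """Age distribution of person-years, young-heavy like a mid-transition
    population; sums to 1 over the 23 groups."""
    w = np.concatenate(
        [
            [0.0004, 0.0012, 0.018, 0.07],
            0.07 * np.exp(-0.09 * np.arange(18)),
            [0.004],
        ]
    )
    return w / w.sum()


@dataclass
class SimConfig:
    """Study conditions for the synthetic world.

    Defaults give 20 locations observed 1990-2016 over a three-group,
    nine-leaf cause tree — a desk-scale rendering of the 195-location,
    23-age-group study design the pipeline targets.
    """

    n_locations: int = 20
    year_start: int = 1990
    year_end: int = 2016
    hierarchy: CauseHierarchy = field(default_factory=toy_hierarchy)
    # epidemiological transition: log rate = intercept + slope * SDI + offsets
    group_slopes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SLOPES))
    group_intercepts: dict = field(
        default_factory=lambda: dict(DEFAULT_GROUP_INTERCEPTS)
    )
    cause_spread: float = 0.5  # leaf-to-leaf intercept spread within a group
    age_offsets: np.ndarray = field(default_factory=default_age_offsets)
    sex_offsets: dict = field(default_factory=lambda: {"male": 0.15, "female": -0.15})
    location_noise_sd: float = 0.3  # per location-cause log-rate noise
    # SDI trajectories: linear per location
    sdi_start: np.ndarray | None = None  # default linspace(0.15, 0.85)
    sdi_annual_gain: float = 0.005
    # demography
    base_population: float = 2_000_000.0
    population_shares: np.ndarray = field(default_factory=default_population_shares)
    # observation model
    completeness: pd.DataFrame | None = None  # columns location, year, completeness
    garbage_p_max: float = 0.25
    garbage_age_midpoint: float = 14.0  # age-group index of the logistic midpoint
    garbage_age_steepness: float = 0.25
    garbage_code_weights: dict | None = None  # code -> weight; default favours major
    va_diag: float = 0.7  # on-diagonal mass of the VA misclassification matrix
    va_misclassification: np.ndarray | None = None  # overrides va_diag if given
    source_types: np.ndarray | None = None  # per location; default from SDI
    seed: int = 0

    # -- derived defaults ------------------------------------------------
    def locations(self) -> np.ndarray:
        return np.arange(self.n_locations)

    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def sdi(self) -> pd.DataFrame:
        """SDI per location-year, clipped to [0, 1]."""
        start = self.sdi_start
        if start is None:
            start = np.linspace(0.15, 0.85, self.n_locations)
        start = np.asarray(start, dtype=float)
        years = self.years()
        grid = start[:, None] + self.sdi_annual_gain * (years - self.year_start)[None, :]
        grid = np.clip(grid, 0.0, 1.0)
        return pd.DataFrame(
            {
                "location": np.repeat(self.locations(), len(years)),
                "year": np.tile(years, self.n_locations),
                "sdi": grid.ravel(),
            }
        )

    def source_by_location(self) -> np.ndarray:
        if self.source_types is not None:
            out = np.asarray(self.source_types, dtype=object)
            if len(out) != self.n_locations:
                raise ValueError("source_types must have one entry per location")
            return out
        # VR where development is high, VA in the middle, none at the bottom
        start = self.sdi_start
        if start is None:
            start = np.linspace(0.15, 0.85, self.n_locations)
        start = np.asarray(start, dtype=float)
        out = np.where(
            start >= 0.5, SOURCE_VR, np.where(start >= 0.25, SOURCE_VA, SOURCE_NONE)
        ).astype(object)
        return out

    def completeness_table(self) -> pd.DataFrame:
        """Completeness per location-year; defaults rise with SDI."""
        if self.completeness is not None:
            t = self.completeness
            bad = t[(t["completeness"] < 0) | (t["completeness"] > 1)]
            if len(bad):
                raise ValueError("completeness outside [0,1]")
            return t
        sdi = self.sdi()
        c = np.clip(1.35 * sdi["sdi"] - 0.08, 0.0, 1.0)
        return sdi.assign(completeness=c)[["location", "year", "completeness"]]

    def garbage_probability(self, age_index: np.ndarray) -> np.ndarray:
        """Logistic-in-age garbage-coding probability (rises with age)."""
        z = self.garbage_age_steepness * (np.asarray(age_index) - self.garbage_age_midpoint)
        return self.garbage_p_max / (1.0 + np.exp(-z))

    def misclassification_matrix(self) -> np.ndarray:
        leaves = self.hierarchy.most_detailed()
        k = len(leaves)
        if self.va_misclassification is not None:
            m = np.asarray(self.va_misclassification, dtype=float)
            if m.shape != (k, k):
                raise ValueError("va_misclassification must be (n_leaves, n_leaves)")
            if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("va_misclassification rows must be probabilities summing to 1")
            return m
        off = (1.0 - self.va_diag) / (k - 1) if k > 1 else 0.0
        m = np.full((k, k), off)
        np.fill_diagonal(m, self.va_diag if k > 1 else 1.0)
        return m

    def validate(self) -> None:
        for name in ("garbage_p_max", "garbage_age_midpoint", "garbage_age_steepness",
                     "location_noise_sd", "sdi_annual_gain", "base_population",
                     "cause_spread"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite parameter: {name}")
        for label, d in (("group_slopes", self.group_slopes),
                         ("group_intercepts", self.group_intercepts),
                         ("sex_offsets", self.sex_offsets)):
            for k, v in d.items():
                if not np.isfinite(v):
                    raise ValueError(f"non-finite parameter: {label}[{k!r}]")
        if not np.all(np.isfinite(self.age_offsets)):
            raise ValueError("non-finite parameter: age_offsets")
        if len(self.age_offsets) != N_AGE_GROUPS:
            raise ValueError(f"age_offsets must have {N_AGE_GROUPS} entries")
        if not (0.0 <= self.garbage_p_max <= 1.0):
            raise ValueError("garbage_p_max must lie in [0,1]")
        if self.location_noise_sd < 0:
            raise ValueError("location_noise_sd must be >= 0")
        self.completeness_table()
        self.misclassification_matrix()


def simulate_truth(config: SimConfig) -> pd.DataFrame:
    """Latent cause-specific mortality: one row per
    location-year-age-sex-cause with the true rate and expected deaths.

    log rate = group intercept + leaf offset + group slope x SDI
               + age offset + sex offset + location-cause noise.
    """
    config.validate()
    hier = config.hierarchy
    leaves = hier.most_detailed()
    rng = np.random.default_rng(config.seed)

    slopes, intercepts = [], []
    for j, leaf in enumerate(leaves):
        g = hier.group_of(leaf)
        if g not in config.group_slopes:
            raise ValueError(f"no slope configured for group {g!r}")
        slopes.append(config.group_slopes[g])
        # deterministic leaf spread around the group intercept
        k = sum(1 for l in leaves if hier.group_of(l) == g)
        rank = [l for l in leaves if hier.group_of(l) == g].index(leaf)
        offs = (rank - (k - 1) / 2) * (config.cause_spread / max(k - 1, 1) * 2)
        intercepts.append(config.group_intercepts[g] + offs)
    slopes = np.array(slopes)
    intercepts = np.array(intercepts)

    loc_noise = rng.normal(0.0, config.location_noise_sd,
                           size=(config.n_locations, len(leaves)))

    sdi = config.sdi()
    sexes = list(config.sex_offsets)
    pop_by_age = config.base_population * config.population_shares / len(sexes)

    frames = []
    n_years = len(config.years())
    loc_idx = sdi["location"].to_numpy()
    sdi_vals = sdi["sdi"].to_numpy()
    for s in sexes:
        for a in range(N_AGE_GROUPS):
            # (n_locyears, n_leaves)
            log_rate = (
                intercepts[None, :]
                + slopes[None, :] * sdi_vals[:, None]
                + config.age_offsets[a]
                + config.sex_offsets[s]
                + loc_noise[loc_idx, :]
            )
            rate = np.exp(log_rate)
            frames.append(
                pd.DataFrame(
                    {
                        "location": np.repeat(loc_idx, len(leaves)),
                        "year": np.repeat(sdi["year"].to_numpy(), len(leaves)),
                        "age": a,
                        "sex": s,
                        "cause": np.tile(np.asarray(leaves, dtype=object),
                                         len(sdi)),
                        "sdi": np.repeat(sdi_vals, len(leaves)),
                        "population": pop_by_age[a],
                        "rate": rate.ravel(),
                    }
                )
            )
    truth = pd.concat(frames, ignore_index=True)
    truth["deaths"] = truth["rate"] * truth["population"]
    return truth.sort_values(["location", "year", "age", "sex", "cause"],
                             ignore_index=True)


def observe(truth: pd.DataFrame, config: SimConfig,
            hierarchy: CauseHierarchy | None = None) -> pd.DataFrame:
    """Push truth through the observation model.

    Poisson counts -> binomial thinning by completeness -> garbage-coding
    moves (probability logistic in age) -> VA misclassification for VA-source
    locations.  Returns a death-record table with columns location, year,
    age, sex, source, code, deaths; strata with no registration (source
    ``none`` or completeness 0) yield no records.
    """
    hier = hierarchy or config.hierarchy
    config.validate()
    leaves = hier.most_detailed()
    for c in truth["cause"].unique():
        if c not in hier:
            raise ValueError(f"truth cause {c!r} not in hierarchy")
    garbage_codes = list(hier.garbage_codes)
    if config.garbage_code_weights is not None:
        gw = np.array([config.garbage_code_weights.get(c, 0.0) for c in garbage_codes],
                      dtype=float)
        if gw.sum() <= 0:
            raise ValueError("garbage_code_weights must have positive total weight")
    else:
        # major codes receive most of the ill-defined deaths
        gw = np.array([3.0 if hier.is_major_garbage(c) else 1.0 for c in garbage_codes])
    gw = gw / gw.sum()

    rng = np.random.default_rng(config.seed + 1)
    comp = config.completeness_table()
    src = config.source_by_location()

    df = truth.merge(comp, on=["location", "year"], how="left")
    if df["completeness"].isna().any():
        raise ValueError("completeness missing for some location-years in truth")
    df["source"] = src[df["location"].to_numpy()]
    df = df[df["source"] != SOURCE_NONE].reset_index(drop=True)
    if not len(df):
        return pd.DataFrame(
            columns=["location", "year", "age", "sex", "source", "code", "deaths"]
        )

    counts = rng.poisson(df["deaths"].to_numpy())
    counts = rng.binomial(counts, df["completeness"].to_numpy())
    g_p = config.garbage_probability(df["age"].to_numpy())
    to_garbage = rng.binomial(counts, g_p)
    kept = counts - to_garbage

    # reallocate garbage deaths across garbage codes
    garbage_mat = rng.multinomial(to_garbage, gw) if len(garbage_codes) else None

    # VA misclassification on the kept cause-coded deaths
    is_va = df["source"].isin([SOURCE_VA, SOURCE_SUBNATIONAL_VA]).to_numpy()
    if is_va.any():
        m = config.misclassification_matrix()
        leaf_pos = {c: j for j, c in enumerate(leaves)}
        rows = np.flatnonzero(is_va)
        true_j = df.loc[rows, "cause"].map(leaf_pos).to_numpy()
        out = np.zeros((len(rows), len(leaves)), dtype=int)
        for j in range(len(leaves)):
            sel = true_j == j
            if sel.any():
                out[sel] = rng.multinomial(kept[rows[sel]], m[j])
        va_records = pd.DataFrame(out, columns=leaves)
        va_records[["location", "year", "age", "sex", "source"]] = (
            df.loc[rows, ["location", "year", "age", "sex", "source"]].to_numpy()
        )
        va_long = va_records.melt(
            id_vars=["location", "year", "age", "sex", "source"],
            var_name="code", value_name="deaths",
        )
        kept = kept.copy()
        kept[rows] = 0  # moved into va_long
    else:
        va_long = None

    records = df[["location", "year", "age", "sex", "source"]].copy()
    records["code"] = df["cause"].to_numpy()
    records["deaths"] = kept

    pieces = [records]
    if va_long is not None:
        pieces.append(va_long)
    if garbage_mat is not None:
        g = pd.DataFrame(garbage_mat, columns=garbage_codes)
        g[["location", "year", "age", "sex", "source"]] = (
            df[["location", "year", "age", "sex", "source"]].to_numpy()
        )
        pieces.append(
            g.melt(id_vars=["location", "year", "age", "sex", "source"],
                   var_name="code", value_name="deaths")
        )
    out = pd.concat(pieces, ignore_index=True)
    out = (
        out[out["deaths"] > 0]
        .groupby(["location", "year", "age", "sex", "source", "code"], as_index=False)
        ["deaths"].sum()
    )
    out["deaths"] = out["deaths"].astype(float)
    return out.sort_values(["location", "year", "age", "sex", "code"],
                           ignore_index=True)


def true_envelope(truth: pd.DataFrame, n_draws: int, cv: float = 0.0,
                  seed: int = 0) -> EnvelopeDraws:
    """All-cause envelope draws from the truth cube.

    With ``cv`` > 0 the draws are lognormal around the true all-cause deaths
    with that coefficient of variation, emulating envelope uncertainty; with
    ``cv`` = 0 every draw equals the truth.
    """
    cells = (
        truth.groupby(["location", "year", "age", "sex"], as_index=False)["deaths"]
        .sum()
    )
    mu = cells["deaths"].to_numpy()[:, None]
    if cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(cv**2))
        noise = rng.lognormal(-sigma**2 / 2, sigma, size=(len(cells), n_draws))
        draws = mu * noise
    else:
        draws = np.repeat(mu, n_draws, axis=1)
    return EnvelopeDraws(cells[["location", "year", "age", "sex"]], draws)


def write_records(records: pd.DataFrame, path) -> None:
    """Death-record table as delimited text (documented header)."""
    records.to_csv(path, index=False)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)
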
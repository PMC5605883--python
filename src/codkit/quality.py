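"""Data-quality metrics and the 0-5 star rating.

A location's cause-of-death data quality is summarised by its percent of
deaths "well certified": the product of registration completeness C, the
fraction of deaths not assigned to major garbage codes (1 - G), and the
fraction assigned to detailed causes D, expressed as a percentage.  Verbal
autopsy data are discounted by the published chance-corrected concordance of
physician-certified VA against medical certification (0.64), and subnational
VA by a further factor of 0.10.  The full-period percent well certified maps
to a star rating through fixed bins: >=85% five stars, 65-<85% four,
35-<65% three, 10-<35% two, >0-<10% one, exactly 0% zero.

The packaged reference table (one row per country: printed star rating,
maximum percent well certified per interval, and the 1980-2016 figure) ships
as ``data/table1_quality.csv``; UK subnational rows are flagged so country
counts can exclude them.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .hierarchy import CauseHierarchy

VA_CONCORDANCE = 0.64
SUBNATIONAL_VA_FACTOR = 0.10
#: star bin lower edges (left-closed): >=85 -> 5, >=65 -> 4, >=35 -> 3, >=10 -> 2
STAR_EDGES = (85.0, 65.0, 35.0, 10.0)

INTERVALS = (
    ("1980-84", 1980, 1984),
    ("1985-89", 1985, 1989),
    ("1990-94", 1990, 1994),
    ("1995-99", 1995, 1999),
    ("2000-04", 2000, 2004),
    ("2005-09", 2005, 2009),
    ("2010-16", 2010, 2016),
)

SOURCE_FACTORS = {
    "VR": 1.0,
    "VA": VA_CONCORDANCE,
    "subnational_VA": VA_CONCORDANCE * SUBNATIONAL_VA_FACTOR,
}


def well_certified_fraction(completeness, major_garbage, detailed, source_type):
    """Percent of deaths well certified, W in [0, 100].

    W = 100 x C x (1 - G) x D, then x 0.64 for any verbal autopsy source and
    a further x 0.10 for subnational VA.  ``source_type`` 'none' gives 0.
    Scalar or array inputs.
    """
    c = np.asarray(completeness, dtype=float)
    g = np.asarray(major_garbage, dtype=float)
    d = np.asarray(detailed, dtype=float)
    for name, v in (("completeness", c), ("major_garbage", g), ("detailed", d)):
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{name} outside [0,1]")
    if np.ndim(source_type) == 0:
        if source_type == "none":
            factor = 0.0
        elif source_type in SOURCE_FACTORS:
            factor = SOURCE_FACTORS[source_type]
        else:
            raise ValueError(f"unknown source type {source_type!r}")
    else:
        st = pd.Series(np.asarray(source_type, dtype=object))
        unknown = st[~st.isin(list(SOURCE_FACTORS) + ["none"])]
        if len(unknown):
            raise ValueError(f"unknown source types: {sorted(set(unknown))}")
        factor = st.map({**SOURCE_FACTORS, "none": 0.0}).to_numpy(float)
    w = 100.0 * c * (1.0 - g) * d * factor
    return float(w) if np.ndim(w) == 0 else w


def star_rating(w):
    """Star rating (0-5) for a percent-well-certified value in [0, 100].

    Bins are left-closed at 85/65/35/10; any positive value below 10 earns
    one star; exactly 0 earns zero stars.  Scalar or array input.
    """
    arr = np.asarray(w, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("percent well certified outside [0,100]")
    stars = np.ones_like(arr, dtype=int)  # >0 and <10
    stars[arr == 0.0] = 0
    for s, edge in zip((2, 3, 4, 5), reversed(STAR_EDGES)):
        stars[arr >= edge] = s
    return int(stars) if np.ndim(w) == 0 else stars


def fraction_major_garbage(records: pd.DataFrame,
                           hierarchy: CauseHierarchy) -> pd.DataFrame:
    """Deaths on major-garbage codes / all recorded deaths, per location-year.

    Location-years with no records are simply absent from the output (no
    zero is invented for empty strata).  Unresolvable codes raise.
    """
    kinds = hierarchy.resolve(records["code"])
    bad = records.loc[kinds == "unknown", "code"].unique()
    if len(bad):
        raise ValueError(f"unresolvable codes: {sorted(bad)}")
    df = records.assign(
        major=records["code"].map(hierarchy.is_major_garbage).astype(float)
    )
    g = df.groupby(["location", "year"]).apply(
        lambda x: np.average(x["major"], weights=x["deaths"])
        if x["deaths"].sum() > 0 else np.nan,
        include_groups=False,
    )
    return g.rename("major_garbage_fraction").reset_index()


def detailed_cause_fraction(records: pd.DataFrame,
                            hierarchy: CauseHierarchy) -> pd.DataFrame:
    """Deaths coded to Level-3/4 causes / all recorded deaths, per
    location-year.  Garbage deaths count in the denominator only."""
    kinds = hierarchy.resolve(records["code"])
    bad = records.loc[kinds == "unknown", "code"].unique()
    if len(bad):
        raise ValueError(f"unresolvable codes: {sorted(bad)}")
    detailed = records["code"].map(
        lambda c: (not hierarchy.is_garbage(c)) and hierarchy.level(c) >= 3
    )
    df = records.assign(detailed=detailed.astype(float))
    g = df.groupby(["location", "year"]).apply(
        lambda x: np.average(x["detailed"], weights=x["deaths"])
        if x["deaths"].sum() > 0 else np.nan,
        include_groups=False,
    )
    return g.rename("detailed_fraction").reset_index()


def interval_of_year(year) -> pd.Series:
    """Map calendar years to the seven reporting intervals (terminal one is
    seven years, 2010-16)."""
    y = pd.Series(np.asarray(year))
    out = pd.Series(pd.NA, index=y.index, dtype="object")
    for label, lo, hi in INTERVALS:
        out[(y >= lo) & (y <= hi)] = label
    return out


def quality_profiles(records: pd.DataFrame, completeness: pd.DataFrame,
                     hierarchy: CauseHierarchy) -> pd.DataFrame:
    """Per location-year quality metrics and W.

    ``completeness`` has columns location, year, completeness.  Source type
    is taken from the records (one source per location-year assumed).
    Returns columns: location, year, interval, completeness,
    major_garbage_fraction, detailed_fraction, source, well_certified,
    deaths.
    """
    g = fraction_major_garbage(records, hierarchy)
    d = detailed_cause_fraction(records, hierarchy)
    totals = records.groupby(["location", "year"], as_index=False).agg(
        deaths=("deaths", "sum"), source=("source", "first")
    )
    prof = totals.merge(g, on=["location", "year"]).merge(d, on=["location", "year"])
    prof = prof.merge(completeness, on=["location", "year"], how="left")
    if prof["completeness"].isna().any():
        missing = prof.loc[prof["completeness"].isna(),
                           ["location", "year"]].drop_duplicates()
        raise ValueError(f"completeness missing for {len(missing)} location-years")
    prof["interval"] = interval_of_year(prof["year"]).to_numpy()
    prof = prof.dropna(subset=["interval"])
    prof["well_certified"] = well_certified_fraction(
        prof["completeness"], prof["major_garbage_fraction"],
        prof["detailed_fraction"], prof["source"],
    )
    return prof


def rate_location_series(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-location report: maximum W per interval, full-period W, stars.

    The full-period figure is the deaths-weighted mean of yearly W values
    (equal weights where the deaths column is absent); intervals with no
    data contribute 0 to the interval columns, mirroring the reference
    table's convention that absent data prints as 0.
    """
    labels = [i[0] for i in INTERVALS]
    unknown = set(profiles["interval"]) - set(labels)
    if unknown:
        raise ValueError(f"unknown interval labels: {sorted(unknown)}")
    rows = []
    for loc, grp in profiles.groupby("location"):
        row = {"location": loc}
        for label in labels:
            sub = grp[grp["interval"] == label]
            row[label] = sub["well_certified"].max() if len(sub) else 0.0
        if "deaths" in grp and grp["deaths"].sum() > 0:
            full = np.average(grp["well_certified"], weights=grp["deaths"])
        else:
            full = grp["well_certified"].mean()
        row["full_period"] = full
        row["stars"] = star_rating(full)
        rows.append(row)
    return pd.DataFrame(rows)


# -- packaged reference table -------------------------------------------


def load_reference_table() -> pd.DataFrame:
    """The packaged country quality table: printed star rating, interval
    maxima of percent well certified, and the 1980-2016 value, with UK
    subnational rows flagged."""
    with importlib.resources.files("codkit.data").joinpath(
        "table1_quality.csv"
    ).open() as f:
        return pd.read_csv(f)


def assign_stars(full_period_percent, printed_stars=None,
                 rounding_unit: float = 0.1):
    """Star ratings for printed full-period percents, resolving rounding.

    A percent printed at one decimal can hide a value up to half a printing
    unit away, which matters exactly at the bin edges: 0.0 can hide a small
    positive value (one star, not zero) and 65.0 can hide 64.96 (three
    stars, not four).  Where ``printed_stars`` is given, the printed rating
    is used for a row whenever the binning of the printed value disagrees
    with it but some unrounded value within half a printing unit would earn
    the printed rating.  A printed rating inconsistent with any such value
    raises.
    """
    w = np.atleast_1d(np.asarray(full_period_percent, dtype=float))
    stars = np.atleast_1d(star_rating(w))
    if printed_stars is not None:
        printed = np.atleast_1d(np.asarray(printed_stars, dtype=int))
        half = rounding_unit / 2.0
        for i in np.flatnonzero(stars != printed):
            lo = max(w[i] - half, 0.0 if w[i] > 0 else np.nextafter(0.0, 1.0))
            hi = min(w[i] + half, 100.0)
            if star_rating(lo) <= printed[i] <= star_rating(hi):
                stars[i] = printed[i]
            else:
                raise ValueError(
                    f"printed rating {printed[i]} inconsistent with printed "
                    f"percent {w[i]} even allowing for rounding"
                )
    return int(stars[0]) if np.ndim(full_period_percent) == 0 else stars


def star_counts(table: pd.DataFrame | None = None,
                national_only: bool = True) -> pd.Series:
    """Countries per star level from the packaged reference table, rating
    each country by its printed full-period percent."""
    t = load_reference_table() if table is None else table
    if national_only and "subnational" in t:
        t = t[t["subnational"] == 0]
    stars = assign_stars(t["pct_1980_2016"].to_numpy(), t["stars"].to_numpy())
    return pd.Series(stars).value_counts().reindex(range(6), fill_value=0)
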
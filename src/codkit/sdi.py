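"""Socio-demographic Index and SDI-expected burden.

SDI summarises development as the geometric mean of three indices rescaled
to [0, 1]: lag-dependent income per capita (LDI), mean educational
attainment in the population aged 15+, and total fertility rate (TFR,
inverted — higher fertility maps to a lower index).  Locations are grouped
into quintiles on a reference year's SDI distribution, with membership held
fixed over time.

The epidemiological-transition machinery fits, for each cause-age-sex, a
Gaussian-process regression of log death rate on SDI (squared-exponential
kernel plus nugget, hyperparameters by marginal-likelihood maximisation).
The posterior mean defines the burden *expected* from development alone;
the ratio of observed to expected YLLs, aggregated over ages before
dividing, flags locations doing better or worse than their development
predicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

RATE_FLOOR = 1e-12
QUINTILE_LABELS = ("low", "low-middle", "middle", "high-middle", "high")


@dataclass
class SDIAnchors:
    """Min/max used to rescale each component onto [0, 1].

    LDI is rescaled on the log scale (income effects are proportional).
    TFR is inverted after rescaling.  Values above/below the anchors clip.
    """

    ldi: tuple = (250.0, 60_000.0)
    education: tuple = (0.0, 17.0)
    tfr: tuple = (1.0, 8.0)

    def validate(self):
        for name in ("ldi", "education", "tfr"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"anchor min >= max for {name}")


def _rescale(x, lo, hi, log=False):
    x = np.asarray(x, dtype=float)
    if log:
        x, lo, hi = np.log(x), np.log(lo), np.log(hi)
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def compute_sdi(components: pd.DataFrame,
                anchors: SDIAnchors | None = None) -> pd.DataFrame:
    """SDI per location-year.

    ``components`` columns: location, year, ldi, education, tfr (all
    positive).  Returns the input plus the three rescaled indices and
    ``sdi`` = geometric mean of the indices, in [0, 1].
    """
    anchors = anchors or SDIAnchors()
    anchors.validate()
    for c in ("ldi", "education", "tfr"):
        if c not in components:
            raise ValueError(f"missing component column {c!r}")
        if (components[c] < 0).any():
            raise ValueError(f"negative values in component {c!r}")
    out = components.copy()
    out["index_ldi"] = _rescale(components["ldi"], *anchors.ldi, log=True)
    out["index_edu"] = _rescale(components["education"], *anchors.education)
    out["index_tfr"] = 1.0 - _rescale(components["tfr"], *anchors.tfr)
    out["sdi"] = np.clip(
        (out["index_ldi"] * out["index_edu"] * out["index_tfr"]) ** (1.0 / 3.0),
        0.0, 1.0,
    )
    return out


def geometric_mean_sdi(index_ldi, index_edu, index_tfr):
    """SDI from already-rescaled indices (geometric mean, clipped)."""
    out = (np.asarray(index_ldi, float) * np.asarray(index_edu, float)
           * np.asarray(index_tfr, float)) ** (1.0 / 3.0)
    return np.clip(out, 0.0, 1.0)


def sdi_quintiles(sdi: pd.DataFrame, reference_year: int) -> pd.Series:
    """Quintile label per location from the reference-year SDI distribution.

    Cut-points are the 20/40/60/80th percentiles of that year's SDI across
    locations; membership is time-invariant.  A value tying a cut-point
    falls in the lower quintile.
    """
    ref = sdi[sdi["year"] == reference_year]
    if ref["location"].nunique() < 5:
        raise ValueError("need at least 5 locations to form quintiles")
    vals = ref.set_index("location")["sdi"]
    if vals.nunique() == 1:
        raise ValueError("degenerate SDI distribution: all locations equal")
    cuts = np.percentile(vals.to_numpy(), [20, 40, 60, 80])
    idx = np.searchsorted(cuts, vals.to_numpy(), side="left")
    return pd.Series([QUINTILE_LABELS[i] for i in idx],
                     index=vals.index, name="sdi_quintile")


@dataclass
class ExpectedCurve:
    """GP posterior of log death rate over SDI in [0, 1] for one
    cause-age-sex."""

    grid: np.ndarray
    mean_log_rate: np.ndarray
    sd_log_rate: np.ndarray

    def expected_rate(self, sdi):
        """Posterior-median expected rate at the given SDI value(s)."""
        mu = np.interp(np.asarray(sdi, float), self.grid, self.mean_log_rate)
        return np.exp(mu)

    def band(self, sdi, z: float = 1.96):
        mu = np.interp(np.asarray(sdi, float), self.grid, self.mean_log_rate)
        sd = np.interp(np.asarray(sdi, float), self.grid, self.sd_log_rate)
        return np.exp(mu - z * sd), np.exp(mu + z * sd)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sdi": self.grid,
            "mean_log_rate": self.mean_log_rate,
            "sd_log_rate": self.sd_log_rate,
        })


def fit_expected_curve(rates, sdi, rate_floor: float = RATE_FLOOR,
                       grid_size: int = 101, seed: int = 0,
                       n_restarts: int = 2,
                       length_scale_bounds=(0.05, 2.0)) -> ExpectedCurve:
    """GP regression of log rate on SDI.

    Squared-exponential kernel with an amplitude term plus a white-noise
    nugget; hyperparameters by marginal-likelihood maximisation with a
    fixed number of restarts under a fixed seed, so results are
    deterministic given data and configuration.  Non-positive rates are
    floored before the log transform.
    """
    r = np.asarray(rates, dtype=float)
    s = np.asarray(sdi, dtype=float)
    ok = np.isfinite(r) & np.isfinite(s)
    r, s = r[ok], s[ok]
    if len(r) == 0:
        raise ValueError("no usable (SDI, rate) pairs")
    if len(r) < 10:
        raise ValueError(f"need at least 10 (SDI, rate) pairs, got {len(r)}")
    y = np.log(np.maximum(r, rate_floor))
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e4))
        * RBF(length_scale=0.3, length_scale_bounds=length_scale_bounds)
        + WhiteKernel(noise_level=0.1, noise_level_bounds=(1e-10, 1e2))
    )
    gp = GaussianProcessRegressor(
        kernel=kernel, normalize_y=True, n_restarts_optimizer=n_restarts,
        random_state=seed,
    )
    gp.fit(s.reshape(-1, 1), y)
    grid = np.linspace(0.0, 1.0, grid_size)
    mu, sd = gp.predict(grid.reshape(-1, 1), return_std=True)
    return ExpectedCurve(grid, mu, sd)


def expected_deaths_by_age(curves: dict, sdi_value: float,
                           population: pd.Series) -> pd.Series:
    """Expected deaths per age group: curve rate at the location's SDI times
    the age group's population.  ``curves`` maps age -> ExpectedCurve."""
    missing = set(population.index) - set(curves)
    if missing:
        raise ValueError(f"no expected curve for ages {sorted(missing)}")
    return pd.Series(
        {a: float(curves[a].expected_rate(sdi_value)) * population[a]
         for a in population.index}
    )


def observed_expected_ratio(observed: pd.Series, expected: pd.Series) -> float:
    """Observed / expected burden, aggregated over ages before the ratio.

    Both series are indexed by age (YLLs or deaths on the same support).
    Returns NaN when the expected total is 0 (logged by the caller).
    """
    if set(observed.index) != set(expected.index):
        raise ValueError("observed and expected must share the same age support")
    tot_exp = float(expected.sum())
    if tot_exp == 0:
        return float("nan")
    return float(observed.sum()) / tot_exp
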
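"""Envelope-consistent draws, YLLs, age-standardised rates, and 2006-16
change metrics for the simulated world.

Turns the completeness-corrected record table into a draw cube (lognormal
observation uncertainty around each cell), rescales the draws to the
all-cause envelope, aggregates up the cause tree, values deaths in years of
life lost with the packaged standard life table, and summarises deaths,
age-standardised rates and percent change 2006-16 per cause group in a
results table.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from codkit.burden import (
    age_standardise,
    aggregate_hierarchy,
    change_metrics,
    load_standard_life_table,
    load_standard_population,
    ylls,
)
from codkit.codcorrect import point_and_ui, rescale_draws
from codkit.cube import DrawCube, EnvelopeDraws
from codkit.hierarchy import toy_hierarchy
from codkit.synthdata import true_envelope

OUT = Path(__file__).resolve().parents[1] / "results"
STRATUM = ["location", "year", "age", "sex"]
N_DRAWS = 500
SEED = 5


def main() -> None:
    corrected = pd.read_csv(OUT / "records_corrected.csv")
    truth = pd.read_csv(OUT / "truth.csv")
    hier = toy_hierarchy()
    rng = np.random.default_rng(SEED)

    index = corrected.rename(columns={"code": "cause"})[
        ["location", "year", "age", "sex", "cause"]]
    mu = corrected["deaths"].to_numpy()[:, None]
    draws = mu * rng.lognormal(-0.05**2 / 2, 0.05, (len(mu), N_DRAWS))
    cube = DrawCube(index, draws)

    observed_cells = index[STRATUM].drop_duplicates()
    env_all = true_envelope(truth, N_DRAWS, cv=0.03, seed=SEED + 1)
    keep = pd.MultiIndex.from_frame(env_all.index[STRATUM]).isin(
        pd.MultiIndex.from_frame(observed_cells))
    env = EnvelopeDraws(env_all.index[keep], env_all.draws[keep])

    corrected_cube = rescale_draws(cube, env)
    agg = aggregate_hierarchy(corrected_cube, hier)
    life_table = load_standard_life_table()
    std_pop = load_standard_population()
    yll_cube = ylls(agg, life_table)

    pop = truth.groupby(STRATUM, as_index=False)["population"].sum()
    frame = agg.to_frame().merge(pop, on=STRATUM)
    yframe = yll_cube.to_frame().merge(pop, on=STRATUM)
    draw_cols = [f"draw_{i}" for i in range(N_DRAWS)]

    def asr_by_cause_year(df, year):
        """Age-standardised rate per 100k, per draw, by cause (both sexes)."""
        sub = df[df["year"] == year]
        out = {}
        for cause, g in sub.groupby("cause"):
            cells = g.groupby("age")[draw_cols + ["population"]].sum()
            rates = cells[draw_cols].div(cells["population"], axis=0) * 1e5
            out[cause] = age_standardise(rates, std_pop)
        return out

    rows = []
    asr_2006 = asr_by_cause_year(frame, 2006)
    asr_2016 = asr_by_cause_year(frame, 2016)
    yll_2016 = yframe[yframe["year"] == 2016].groupby("cause")[draw_cols].sum()
    deaths_2016 = frame[frame["year"] == 2016].groupby("cause")[draw_cols].sum()
    for cause in ("cmnn", "ncd", "injury"):
        d_mean, d_lo, d_hi = point_and_ui(deaths_2016.loc[cause].to_numpy())
        y_mean, y_lo, y_hi = point_and_ui(yll_2016.loc[cause].to_numpy())
        chg = change_metrics(asr_2006[cause], asr_2016[cause], years=10)
        rows.append({
            "cause": cause,
            "deaths_2016": d_mean, "deaths_lo": d_lo, "deaths_hi": d_hi,
            "ylls_2016": y_mean, "ylls_lo": y_lo, "ylls_hi": y_hi,
            "asr_2016_per_100k": float(np.mean(asr_2016[cause])),
            "asr_pct_change_2006_16": chg["percent_change"][0],
            "asr_arc_2006_16": chg["arc"][0],
            "significance": chg["significance"],
        })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "burden_2016.csv", index=False)
    print(table.to_string(index=False,
                          float_format=lambda v: f"{v:,.1f}"))
    share = deaths_2016.loc[["cmnn", "ncd", "injury"]].mean(axis=1)
    share = share / share.sum()
    print("\nshare of 2016 deaths by group:",
          {c: f"{share[c]:.1%}" for c in ('cmnn', 'ncd', 'injury')})


if __name__ == "__main__":
    main()
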
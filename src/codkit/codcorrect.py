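"""Envelope rescaling (CoDCorrect) and draw-based summaries.

Cause-specific models are fit independently, so within a demographic cell
their draws need not sum to the all-cause mortality envelope.  CoDCorrect
restores coherence: within every location-year-age-sex cell and for each
draw index, every most-detailed cause is multiplied by
envelope / sum-of-causes.  Draws are paired positionally (cause draw i with
envelope draw i), which propagates the correlation structure into all
downstream quantities.

Point estimates are draw means; 95% uncertainty intervals are the 2.5th and
97.5th percentiles (linear interpolation between order statistics).  A
change over time is significant when at least 95% of paired draws moved in
the same direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cube import CELL_KEYS, DrawCube, EnvelopeDraws

INCREASE = "increase"
DECREASE = "decrease"
NOT_SIGNIFICANT = "not significant"
SIGNIFICANCE_THRESHOLD = 0.95


def rescale_draws(cause_draws: DrawCube, envelope: EnvelopeDraws) -> DrawCube:
    """Proportionally rescale cause draws to the all-cause envelope.

    Raises if any cell has a positive envelope draw while every cause model
    predicts zero — there is no defensible way to split the envelope, so no
    silent imputation is attempted.
    """
    if cause_draws.n_draws != envelope.n_draws:
        raise ValueError(
            f"draw counts differ: causes {cause_draws.n_draws}, "
            f"envelope {envelope.n_draws}"
        )
    codes, cells = cause_draws.cell_groups()
    sums = np.zeros((len(cells), cause_draws.n_draws))
    np.add.at(sums, codes, cause_draws.draws)

    env = cells.merge(
        pd.concat([envelope.index,
                   pd.DataFrame({"_row": np.arange(len(envelope.index))})], axis=1),
        on=CELL_KEYS, how="left",
    )
    if env["_row"].isna().any():
        cell = env.loc[env["_row"].isna(), CELL_KEYS].iloc[0].to_dict()
        raise ValueError(f"no envelope draws for cell {cell}")
    env_draws = envelope.draws[env["_row"].to_numpy(int)]

    zero_bad = (sums == 0) & (env_draws > 0)
    if zero_bad.any():
        i = int(np.argwhere(zero_bad.any(axis=1))[0][0])
        raise ValueError(
            "all cause models predict zero but envelope is positive in cell "
            f"{cells.iloc[i].to_dict()}"
        )
    with np.errstate(invalid="ignore"):
        factor = np.where(sums > 0, env_draws / np.where(sums > 0, sums, 1.0), 0.0)
    return DrawCube(cause_draws.index.copy(), cause_draws.draws * factor[codes])


def point_and_ui(draws) -> tuple[float, float, float]:
    """(mean, 2.5th percentile, 97.5th percentile) of a draw vector."""
    arr = np.asarray(draws, dtype=float)
    if arr.size == 0:
        raise ValueError("empty draw vector")
    if arr.size < 2:
        raise ValueError("need at least 2 draws")
    lower, upper = np.percentile(arr, [2.5, 97.5])
    return float(arr.mean()), float(lower), float(upper)


def significant_change(draws_t1, draws_t2) -> str:
    """Direction of change between two draw-matched periods.

    'increase' if at least 95% of draws rose, 'decrease' if at least 95%
    fell, otherwise 'not significant'.  The 95% boundary is inclusive.
    """
    a = np.asarray(draws_t1, dtype=float)
    b = np.asarray(draws_t2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"mismatched draw counts: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty draw vectors")
    p_up = np.mean(b > a)
    p_down = np.mean(b < a)
    if p_up >= SIGNIFICANCE_THRESHOLD:
        return INCREASE
    if p_down >= SIGNIFICANCE_THRESHOLD:
        return DECREASE
    return NOT_SIGNIFICANT
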
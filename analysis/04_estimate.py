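"""Validate the ensemble estimator by parameter recovery, and demonstrate
the negative-binomial family on a rare-cause series.

Runs the full chain — pool enumeration, sign/significance screening,
out-of-sample scoring on levels and trends, rank-exponential weighting,
draw generation, envelope rescaling — on panel data generated from a known
pool member, then checks that the corrected 95% intervals cover truth at
their nominal rate and that the ensemble beats the median single model out
of sample.  Writes the recovery summary under results/.
"""

import json
from pathlib import Path

import numpy as np

from codkit.ensemble import fit_negative_binomial
from codkit.experiments import ensemble_recovery_experiment

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 11


def main() -> None:
    OUT.mkdir(exist_ok=True)
    out = ensemble_recovery_experiment(seed=SEED)
    (OUT / "ensemble_recovery.json").write_text(json.dumps(out, indent=2))
    print(f"corrected 95% interval coverage of truth: "
          f"{out['coverage']:.3f} over {out['n_cells']} cells "
          f"(nominal 0.95)")
    print(f"ensemble held-out level RMSE {out['ensemble_rmse']:.4f} vs "
          f"pool-median {out['pool_median_rmse']:.4f}")

    # rare cause: overdispersed counts with known mean rate 2e-6
    rng = np.random.default_rng(SEED)
    exposure = 1e6
    lam = rng.gamma(shape=0.8, scale=2.5 / 0.8, size=300)  # mean 2.5, od
    counts = rng.poisson(lam)
    fit = fit_negative_binomial(counts, exposure, n_draws=1000, seed=SEED)
    lo, hi = np.percentile(fit["draws"], [2.5, 97.5])
    print(f"negative-binomial rare-cause fit: rate {fit['rate']:.3e} "
          f"(95% UI {lo:.3e}-{hi:.3e}; truth 2.5e-06), "
          f"dispersion {fit['dispersion']:.2f}")


if __name__ == "__main__":
    main()
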
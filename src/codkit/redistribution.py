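"""Source filtering, garbage-code redistribution, and completeness correction.

Deaths certified to ICD codes that cannot be underlying causes of death
(ill-defined, intermediate, or unspecified codes — "garbage codes") are
reassigned to plausible true causes before modelling.  Three redistribution
methods are supported, chosen per garbage code by a :class:`GarbageMap`:

``proportional``
    split garbage deaths across the target causes in proportion to the
    observed target-cause deaths within the same location-year-age-sex
    stratum (uniform over targets when all observed targets are zero);
``fixed``
    split by stated fixed proportions (also covers fractional reassignment
    of multi-cause records, whose per-cause fractions are fixed proportions);
``regression``
    predict stratum-specific target shares from a log-linear model of share
    on age, sex and an optional covariate, fitted across strata, then
    normalise.

Redistribution conserves total deaths within every stratum.  After
redistribution, cause fractions are rescaled to the all-cause envelope,
which corrects retained under-registered sources to 100% completeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchy import CauseHierarchy

STRATUM = ["location", "year", "age", "sex"]

COMPLETENESS_EXCLUDE = 0.5
GARBAGE_EXCLUDE = 0.5
NON_REPRESENTATIVE_RANGE = (0.5, 0.7)


@dataclass
class GarbageMapEntry:
    code: str
    level: int  # hierarchy span the code redistributes across (1-4)
    method: str  # proportional | fixed | regression
    targets: tuple
    proportions: tuple | None = None  # method == fixed only

    def __post_init__(self):
        if self.method not in ("proportional", "fixed", "regression"):
            raise ValueError(f"unknown redistribution method {self.method!r}")
        if not self.targets:
            raise ValueError(f"garbage code {self.code!r} has no targets")
        if self.method == "fixed":
            if self.proportions is None or len(self.proportions) != len(self.targets):
                raise ValueError(
                    f"fixed method for {self.code!r} needs one proportion per target"
                )
            p = np.asarray(self.proportions, dtype=float)
            if np.any(p < 0):
                raise ValueError(f"negative proportions for {self.code!r}")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"fixed proportions for {self.code!r} sum to {p.sum()}, not 1"
                )


class GarbageMap:
    """Per-garbage-code redistribution instructions."""

    def __init__(self, entries):
        self.entries = {e.code: e for e in entries}

    def __contains__(self, code):
        return code in self.entries

    def __getitem__(self, code) -> GarbageMapEntry:
        return self.entries[code]

    def validate(self, hierarchy: CauseHierarchy) -> None:
        for e in self.entries.values():
            for t in e.targets:
                if t not in hierarchy:
                    raise ValueError(
                        f"garbage code {e.code!r} targets unknown cause {t!r}"
                    )

    @classmethod
    def proportional_default(cls, hierarchy: CauseHierarchy) -> "GarbageMap":
        """Every garbage code redistributed proportionally across all
        most-detailed causes."""
        leaves = tuple(hierarchy.most_detailed())
        return cls(
            GarbageMapEntry(code, lvl, "proportional", leaves)
            for code, lvl in hierarchy.garbage_codes.items()
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries.values():
            rows.append({
                "code": e.code, "level": e.level, "method": e.method,
                "targets": "|".join(e.targets),
                "proportions": "|".join(map(str, e.proportions)) if e.proportions else "",
            })
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GarbageMap":
        entries = []
        for r in df.itertuples():
            props = tuple(float(x) for x in str(r.proportions).split("|")) \
                if getattr(r, "proportions", "") else None
            entries.append(GarbageMapEntry(
                r.code, int(r.level), r.method, tuple(r.targets.split("|")), props))
        return cls(entries)


def exclude_low_quality(records: pd.DataFrame, completeness: pd.DataFrame,
                        garbage_fractions: pd.DataFrame):
    """Drop unusable location-years and flag marginal ones.

    VR location-years under 50% complete are excluded (selection bias), as
    are location-years with over 50% of deaths on major garbage codes.
    VR completeness in [0.5, 0.7) is retained but flagged non-representative
    (downweighted downstream via variance inflation).  Location-years with
    no completeness estimate follow VA rules: no completeness exclusion,
    logged.  Returns (retained records, exclusion log, flags) — the log and
    flags are DataFrames keyed by location-year.
    """
    meta = records.groupby(["location", "year"], as_index=False).agg(
        source=("source", "first")
    )
    meta = meta.merge(completeness, on=["location", "year"], how="left")
    meta = meta.merge(garbage_fractions, on=["location", "year"], how="left")
    gcol = "major_garbage_fraction"

    log_rows, flag_rows = [], []
    excluded = set()
    for r in meta.itertuples():
        key = (r.location, r.year)
        is_vr = r.source == "VR"
        comp = r.completeness
        if pd.isna(comp):
            log_rows.append({"location": r.location, "year": r.year,
                             "action": "retained",
                             "reason": "no completeness estimate; VA rules applied"})
            comp = None
        if is_vr and comp is not None and comp < COMPLETENESS_EXCLUDE:
            excluded.add(key)
            log_rows.append({"location": r.location, "year": r.year,
                             "action": "excluded", "reason": "completeness"})
            continue
        gf = getattr(r, gcol)
        if not pd.isna(gf) and gf > GARBAGE_EXCLUDE:
            excluded.add(key)
            log_rows.append({"location": r.location, "year": r.year,
                             "action": "excluded", "reason": "garbage"})
            continue
        non_rep = (is_vr and comp is not None
                   and NON_REPRESENTATIVE_RANGE[0] <= comp < NON_REPRESENTATIVE_RANGE[1])
        flag_rows.append({"location": r.location, "year": r.year,
                          "non_representative": bool(non_rep)})
        if non_rep:
            log_rows.append({"location": r.location, "year": r.year,
                             "action": "flagged", "reason": "non-representative"})

    key = pd.MultiIndex.from_frame(records[["location", "year"]])
    retained = records[~key.isin(excluded)].reset_index(drop=True)
    return (retained,
            pd.DataFrame(log_rows, columns=["location", "year", "action", "reason"]),
            pd.DataFrame(flag_rows, columns=["location", "year", "non_representative"]))


def _regression_shares(records, entry, covariate):
    """Fitted target shares per stratum for a regression-method code.

    Log share of each target (within the target set) is modelled linearly in
    age-group index, a male indicator, and the covariate, across strata with
    positive target deaths; predictions are exponentiated and renormalised.
    """
    tgt = records[records["code"].isin(entry.targets)]
    wide = (
        tgt.pivot_table(index=STRATUM, columns="code", values="deaths",
                        aggfunc="sum", fill_value=0.0)
        .reindex(columns=list(entry.targets), fill_value=0.0)
    )
    totals = wide.sum(axis=1)
    obs = wide[totals > 0]
    shares = obs.div(obs.sum(axis=1), axis=0)
    idx = wide.index.to_frame(index=False)
    x_cov = np.zeros(len(idx)) if covariate is None else (
        idx.merge(covariate, on=[c for c in covariate.columns if c != "value"],
                  how="left")["value"].fillna(0.0).to_numpy()
    )
    X_all = np.column_stack([
        np.ones(len(idx)),
        idx["age"].to_numpy(float),
        (idx["sex"] == "male").to_numpy(float),
        x_cov,
    ])
    in_obs = totals.to_numpy() > 0
    X_obs = X_all[in_obs]
    eps = 1e-6
    pred = np.zeros((len(idx), len(entry.targets)))
    for j, t in enumerate(entry.targets):
        y = np.log(shares[t].to_numpy() + eps)
        beta, *_ = np.linalg.lstsq(X_obs, y, rcond=None)
        pred[:, j] = np.exp(X_all @ beta)
    pred /= pred.sum(axis=1, keepdims=True)
    return pd.DataFrame(pred, index=wide.index, columns=list(entry.targets))


def redistribute(records: pd.DataFrame, garbage_map: GarbageMap,
                 hierarchy: CauseHierarchy,
                 covariate: pd.DataFrame | None = None) -> pd.DataFrame:
    """Move all garbage-coded deaths onto true causes.

    Total deaths are conserved within every location-year-age-sex stratum;
    the output carries no mass on garbage codes.  ``covariate`` (optional,
    columns matching stratum keys plus ``value``) feeds the regression
    method.
    """
    garbage_map.validate(hierarchy)
    kinds = hierarchy.resolve(records["code"])
    bad = records.loc[kinds == "unknown", "code"].unique()
    if len(bad):
        raise ValueError(f"unresolvable codes: {sorted(bad)}")
    is_garbage = kinds == "garbage"
    missing = records.loc[is_garbage & ~records["code"].isin(garbage_map.entries),
                          "code"].unique()
    if len(missing):
        raise ValueError(f"garbage codes absent from map: {sorted(missing)}")

    base = records[~is_garbage].copy()
    garbage = records[is_garbage]
    if not len(garbage) or garbage["deaths"].sum() == 0:
        return records[~is_garbage].reset_index(drop=True)

    moved = []
    extra_cols = [c for c in records.columns
                  if c not in STRATUM + ["code", "deaths"]]
    for code, grp in garbage.groupby("code"):
        entry = garbage_map[code]
        if entry.method == "fixed":
            p = np.asarray(entry.proportions, dtype=float)
            for j, t in enumerate(entry.targets):
                if p[j] == 0:
                    continue
                add = grp.copy()
                add["code"] = t
                add["deaths"] = grp["deaths"] * p[j]
                moved.append(add)
            continue
        if entry.method == "proportional":
            tgt = base[base["code"].isin(entry.targets)]
            wide = (
                tgt.pivot_table(index=STRATUM, columns="code", values="deaths",
                                aggfunc="sum", fill_value=0.0)
                .reindex(columns=list(entry.targets), fill_value=0.0)
            )
            shares = wide.div(wide.sum(axis=1).replace(0.0, np.nan), axis=0)
            shares = shares.fillna(1.0 / len(entry.targets))  # uniform fallback
        else:  # regression
            shares = _regression_shares(base, entry, covariate)
        gs = grp.set_index(STRATUM)
        sh = shares.reindex(gs.index).fillna(1.0 / len(entry.targets))
        for t in entry.targets:
            add = gs.reset_index()[STRATUM + extra_cols].copy()
            add["code"] = t
            add["deaths"] = gs["deaths"].to_numpy() * sh[t].to_numpy()
            moved.append(add)

    out = pd.concat([base] + moved, ignore_index=True)
    out = out[out["deaths"] > 0]
    group_cols = STRATUM + extra_cols + ["code"]
    out = out.groupby(group_cols, as_index=False)["deaths"].sum()
    return out.sort_values(group_cols, ignore_index=True)


def completeness_correct(records: pd.DataFrame,
                         envelope: pd.DataFrame) -> pd.DataFrame:
    """Rescale cause fractions to the all-cause envelope.

    adjusted deaths(cause) = (deaths(cause) / sum of deaths) x envelope,
    per location-year-age-sex cell — i.e. sources are corrected to 100%
    completeness while preserving their cause composition.  ``envelope`` has
    stratum columns plus ``envelope``.
    """
    totals = records.groupby(STRATUM)["deaths"].transform("sum")
    merged = records.merge(envelope, on=STRATUM, how="left")
    env = merged["envelope"]
    if env.isna().any():
        cell = merged.loc[env.isna(), STRATUM].iloc[0].to_dict()
        raise ValueError(f"no envelope for cell {cell}")
    zero_env = (env.to_numpy() == 0) & (records["deaths"].to_numpy() > 0)
    if zero_env.any():
        cell = merged.loc[zero_env, STRATUM].iloc[0].to_dict()
        raise ValueError(f"envelope is zero but deaths recorded in cell {cell}")
    out = records.copy()
    out["deaths"] = records["deaths"] / totals.to_numpy() * env.to_numpy()
    return out
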
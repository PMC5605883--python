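"""Cause hierarchy: a 4-level, mutually exclusive and collectively exhaustive
cause tree with ICD-style garbage codes attached.

Level 1 holds the three broad groups (CMNN diseases, non-communicable
diseases, injuries); Level 2 holds cause groups; Levels 3-4 hold the
most-detailed causes at which deaths are recorded and modelled.  Garbage
codes are not causes: each carries a *redistribution level*, the shallowest
hierarchy level its deaths spread across.  Codes with redistribution level
1 or 2 are "major garbage" — their deaths could land almost anywhere in the
tree, which is why the quality rating penalises them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROOT = "all_cause"
MAJOR_GARBAGE_MAX_LEVEL = 2


@dataclass(frozen=True)
class Cause:
    cause_id: str
    parent: str | None
    level: int  # 1..4; root is level 0
    group: str | None = None  # Level-1 group label (cmnn / ncd / injury)


class CauseHierarchy:
    """Cause tree plus the garbage-code register.

    Parameters
    ----------
    causes
        Iterable of :class:`Cause`.  The root (``all_cause``, level 0) is
        implicit and must not be listed.
    garbage_codes
        Mapping ``code -> redistribution level`` (1-4).
    """

    def __init__(self, causes, garbage_codes: dict[str, int] | None = None):
        self._causes: dict[str, Cause] = {}
        for c in causes:
            if c.cause_id in self._causes:
                raise ValueError(f"duplicate cause id {c.cause_id!r}")
            if c.cause_id == ROOT:
                raise ValueError("the all-cause root is implicit")
            self._causes[c.cause_id] = c
        self.garbage_codes: dict[str, int] = dict(garbage_codes or {})
        for code, lvl in self.garbage_codes.items():
            if code in self._causes:
                raise ValueError(f"garbage code {code!r} collides with a cause id")
            if not 1 <= lvl <= 4:
                raise ValueError(f"garbage code {code!r} has level {lvl}, want 1-4")
        self._children: dict[str, list[str]] = {ROOT: []}
        for c in self._causes.values():
            self._children.setdefault(c.cause_id, [])
        for c in self._causes.values():
            parent = c.parent if c.parent is not None else ROOT
            if parent != ROOT and parent not in self._causes:
                raise ValueError(f"cause {c.cause_id!r} has unknown parent {parent!r}")
            self._children[parent].append(c.cause_id)
        self._validate_levels()

    def _validate_levels(self) -> None:
        for c in self._causes.values():
            parent_level = 0 if c.parent in (None, ROOT) else self._causes[c.parent].level
            if c.level != parent_level + 1:
                raise ValueError(
                    f"cause {c.cause_id!r} at level {c.level} under parent at level {parent_level}"
                )

    # -- queries ---------------------------------------------------------
    def __contains__(self, cause_id: str) -> bool:
        return cause_id in self._causes

    def cause(self, cause_id: str) -> Cause:
        return self._causes[cause_id]

    @property
    def cause_ids(self) -> list[str]:
        return list(self._causes)

    def children(self, cause_id: str) -> list[str]:
        return list(self._children[cause_id])

    def most_detailed(self) -> list[str]:
        """Leaf causes — the level at which deaths are recorded and modelled."""
        return [cid for cid in self._causes if not self._children[cid]]

    def level(self, cause_id: str) -> int:
        return self._causes[cause_id].level

    def group_of(self, cause_id: str) -> str | None:
        """Level-1 group label (cmnn / ncd / injury) of any cause."""
        cid = cause_id
        while True:
            c = self._causes[cid]
            if c.level == 1:
                return c.group or c.cause_id
            cid = c.parent

    def ancestors(self, cause_id: str) -> list[str]:
        """Chain from the cause's parent up to (excluding) the root."""
        out = []
        cid = self._causes[cause_id].parent
        while cid not in (None, ROOT):
            out.append(cid)
            cid = self._causes[cid].parent
        return out

    def internal_nodes(self) -> list[str]:
        return [cid for cid in self._causes if self._children[cid]]

    def is_garbage(self, code: str) -> bool:
        return code in self.garbage_codes

    def is_major_garbage(self, code: str) -> bool:
        return self.garbage_codes.get(code, 99) <= MAJOR_GARBAGE_MAX_LEVEL

    def resolve(self, codes) -> pd.Series:
        """Classify codes as 'cause', 'garbage' or 'unknown' (vectorised)."""
        codes = pd.Series(codes)
        out = pd.Series("unknown", index=codes.index)
        out[codes.isin(self._causes)] = "cause"
        out[codes.isin(self.garbage_codes)] = "garbage"
        return out

    # -- serialisation ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cause_id": c.cause_id, "parent": c.parent or ROOT, "level": c.level,
             "group": c.group or ""}
            for c in self._causes.values()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, causes: pd.DataFrame, garbage: pd.DataFrame | None = None):
        cs = [
            Cause(r.cause_id, None if r.parent in (ROOT, "", None) else r.parent,
                  int(r.level), r.group or None)
            for r in causes.itertuples()
        ]
        gmap = {}
        if garbage is not None:
            gmap = dict(zip(garbage["code"], garbage["level"].astype(int)))
        return cls(cs, gmap)


def toy_hierarchy(n_leaves_per_group: int = 3) -> CauseHierarchy:
    """Small three-group hierarchy with two garbage codes per redistribution level.

    Used by the synthetic-data generator and throughout the tests.  Leaves sit
    at Level 3 under one Level-2 group per Level-1 branch, mirroring the real
    cause list's shape at desk scale.
    """
    causes = []
    for g in ("cmnn", "ncd", "injury"):
        causes.append(Cause(g, None, 1, group=g))
        l2 = f"{g}_grp"
        causes.append(Cause(l2, g, 2, group=g))
        for i in range(n_leaves_per_group):
            causes.append(Cause(f"{g}_{i}", l2, 3, group=g))
    garbage = {"gb_major_1": 1, "gb_major_2": 2, "gb_minor_3": 3, "gb_minor_4": 4}
    return CauseHierarchy(causes, garbage)
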
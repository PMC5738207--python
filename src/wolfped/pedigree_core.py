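"""Pedigree data structure, legality checks and identity-by-descent
coefficients.

A pedigree maps each individual to a (dam, sire) pair.  A parental slot
may name a sampled individual, or hold one of two tokens:

* ``UNSAMPLED`` — an anonymous individual outside the genotyped set
  (treated as a distinct unrelated founder per offspring); individuals
  with both parents unsampled are interpreted as immigrants.
* ``UNKNOWN`` — no assignment made.

Kinship follows the standard recursion
phi(x, x) = (1 + F_x) / 2, phi(a, b) = (phi(dam_a, b) + phi(sire_a, b)) / 2
with a chosen as a non-ancestor of b; unsampled/unknown parents are
unrelated founders.  The production path is memoised recursion; the
additive-relationship (tabular) method is kept as an internal oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "UNSAMPLED",
    "UNKNOWN",
    "Pedigree",
    "CohortInfo",
    "is_legal",
    "kinship",
    "inbreeding_coefficient",
    "relatedness",
    "kinship_tabular",
    "infer_birth_years",
    "merge_unsampled_parents",
]

UNSAMPLED = "UNSAMPLED"
UNKNOWN = "UNKNOWN"
_TOKENS = (UNSAMPLED, UNKNOWN)


def _is_token(parent: str | None) -> bool:
    return parent is None or parent in _TOKENS


@dataclass
class Pedigree:
    """Per-individual (dam, sire) assignments with optional link support.

    ``parents[x] = (dam, sire)`` where each slot is an individual id or
    a token.  ``link_prob[x] = (dam_prob, sire_prob)`` carries posterior
    support when the pedigree came out of an estimation run.
    """

    parents: dict[str, tuple[str, str]] = field(default_factory=dict)
    link_prob: dict[str, tuple[float, float]] = field(default_factory=dict)
    sexes: dict[str, str] = field(default_factory=dict)  # id -> M | F | UNKNOWN
    flags: list[str] = field(default_factory=list)

    @property
    def individuals(self) -> list[str]:
        ids = set(self.parents)
        for d, s in self.parents.values():
            if not _is_token(d):
                ids.add(d)
            if not _is_token(s):
                ids.add(s)
        return sorted(ids)

    def dam(self, x: str) -> str:
        return self.parents.get(x, (UNKNOWN, UNKNOWN))[0]

    def sire(self, x: str) -> str:
        return self.parents.get(x, (UNKNOWN, UNKNOWN))[1]

    def sampled_parents(self, x: str) -> list[str]:
        return [p for p in self.parents.get(x, ()) if not _is_token(p)]

    def children_map(self) -> dict[str, list[str]]:
        ch: dict[str, list[str]] = {}
        for o, (d, s) in self.parents.items():
            for p in (d, s):
                if not _is_token(p):
                    ch.setdefault(p, []).append(o)
        return ch

    def copy(self) -> "Pedigree":
        return Pedigree(
            parents=dict(self.parents),
            link_prob=dict(self.link_prob),
            sexes=dict(self.sexes),
            flags=list(self.flags),
        )

    # -- serialisation (TSV, lossless round trip) --
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for x in sorted(self.parents):
            d, s = self.parents[x]
            dp, sp = self.link_prob.get(x, (float("nan"), float("nan")))
            rows.append({"id": x, "dam": d, "sire": s, "dam_prob": dp, "sire_prob": sp})
        return pd.DataFrame(rows, columns=["id", "dam", "sire", "dam_prob", "sire_prob"])

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, sexes: Mapping[str, str] | None = None
    ) -> "Pedigree":
        ped = cls(sexes=dict(sexes or {}))
        for row in df.itertuples(index=False):
            ped.parents[str(row.id)] = (str(row.dam), str(row.sire))
            dp, sp = float(row.dam_prob), float(row.sire_prob)
            if not (pd.isna(dp) and pd.isna(sp)):
                ped.link_prob[str(row.id)] = (dp, sp)
        return ped


def is_legal(pedigree: Pedigree) -> tuple[bool, str | None]:
    """Check acyclicity of the parent relation and sex-role consistency.

    Returns (True, None) or (False, description of the first violation).
    """
    for x, (d, s) in pedigree.parents.items():
        if not _is_token(d):
            sex = pedigree.sexes.get(d, "UNKNOWN")
            if sex == "M":
                return False, f"dam of {x} is male ({d})"
            if d == x:
                return False, f"{x} is its own dam"
        if not _is_token(s):
            sex = pedigree.sexes.get(s, "UNKNOWN")
            if sex == "F":
                return False, f"sire of {x} is female ({s})"
            if s == x:
                return False, f"{x} is its own sire"
    g = nx.DiGraph()
    g.add_nodes_from(pedigree.individuals)
    for x, (d, s) in pedigree.parents.items():
        for p in (d, s):
            if not _is_token(p):
                g.add_edge(p, x)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return True, None
    nodes = [u for u, _ in cycle]
    return False, f"ancestry cycle: {' -> '.join(nodes + nodes[:1])}"


class _KinshipCache:
    def __init__(self, pedigree: Pedigree):
        ok, why = is_legal(pedigree)
        if not ok:
            raise ValueError(f"illegal pedigree: {why}")
        self.ped = pedigree
        self.memo: dict[tuple[str, str], float] = {}
        # generation depth: founders 0, child = max(parents) + 1
        self.depth: dict[str, float] = {}
        for x in nx.topological_sort(self._graph()):
            ps = pedigree.sampled_parents(x)
            self.depth[x] = max((self.depth[p] for p in ps), default=-1) + 1

    def _graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.ped.individuals)
        for x, (d, s) in self.ped.parents.items():
            for p in (d, s):
                if not _is_token(p):
                    g.add_edge(p, x)
        return g

    def phi(self, a: str, b: str) -> float:
        if _is_token(a) or _is_token(b):
            return 0.0
        key = (a, b) if a <= b else (b, a)
        if key in self.memo:
            return self.memo[key]
        if a == b:
            d, s = self.ped.parents.get(a, (UNKNOWN, UNKNOWN))
            val = 0.5 * (1.0 + self.phi(d, s))
        else:
            # recurse on the deeper individual: it cannot be an
            # ancestor of the shallower one
            if self.depth.get(a, 0) < self.depth.get(b, 0):
                a, b = b, a
            d, s = self.ped.parents.get(a, (UNKNOWN, UNKNOWN))
            val = 0.5 * (self.phi(d, b) + self.phi(s, b))
        self.memo[key] = val
        return val


def kinship(pedigree: Pedigree, a: str, b: str) -> float:
    """Kinship coefficient phi(a, b) by memoised recursion."""
    return _KinshipCache(pedigree).phi(a, b)


def inbreeding_coefficient(pedigree: Pedigree, x: str) -> float:
    """F_x = kinship of x's parents (0 if either is unsampled/unknown)."""
    d, s = pedigree.parents.get(x, (UNKNOWN, UNKNOWN))
    if _is_token(d) or _is_token(s):
        return 0.0
    return _KinshipCache(pedigree).phi(d, s)


def relatedness(pedigree: Pedigree, a: str, b: str) -> float:
    """r(a, b) = 2 phi(a, b) / sqrt((1 + F_a)(1 + F_b))."""
    cache = _KinshipCache(pedigree)
    fa = cache.phi(a, a) * 2 - 1
    fb = cache.phi(b, b) * 2 - 1
    return 2 * cache.phi(a, b) / ((1 + fa) * (1 + fb)) ** 0.5


def kinship_tabular(pedigree: Pedigree) -> pd.DataFrame:
    """Full kinship matrix by the additive-relationship (tabular) method.

    Internal oracle for the recursive path: builds the numerator
    relationship matrix A in topological order and returns A / 2.
    """
    ok, why = is_legal(pedigree)
    if not ok:
        raise ValueError(f"illegal pedigree: {why}")
    g = nx.DiGraph()
    ids = pedigree.individuals
    g.add_nodes_from(ids)
    for x, (d, s) in pedigree.parents.items():
        for p in (d, s):
            if not _is_token(p):
                g.add_edge(p, x)
    order = list(nx.topological_sort(g))
    pos = {x: i for i, x in enumerate(order)}
    import numpy as np

    n = len(order)
    a = np.zeros((n, n))
    for i, x in enumerate(order):
        d, s = pedigree.parents.get(x, (UNKNOWN, UNKNOWN))
        di = pos.get(d) if not _is_token(d) else None
        si = pos.get(s) if not _is_token(s) else None
        for j in range(i):
            val = 0.0
            if di is not None:
                val += 0.5 * a[di, j]
            if si is not None:
                val += 0.5 * a[si, j]
            a[i, j] = a[j, i] = val
        a[i, i] = 1.0 + (0.5 * a[di, si] if di is not None and si is not None else 0.0)
    out = pd.DataFrame(a / 2.0, index=order, columns=order)
    return out.loc[sorted(order), sorted(order)]


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortInfo:
    """Inferred birth years and age constraints for pedigree members.

    ``birth_year[x]`` is None where undetermined; ``upper_bound[x]`` is
    the first-detection year (an individual cannot be born after it is
    first seen).  Litters are annual, so cohorts are calendar years.
    """

    birth_year: dict[str, int | None] = field(default_factory=dict)
    upper_bound: dict[str, int | None] = field(default_factory=dict)
    death_year: dict[str, int] = field(default_factory=dict)
    known_age_at_death: dict[str, int] = field(default_factory=dict)
    min_breeding_age: int = 2
    conflicts: list[str] = field(default_factory=list)

    def effective_birth(self, x: str) -> int | None:
        """Assigned birth year, falling back to the first-seen bound."""
        b = self.birth_year.get(x)
        return b if b is not None else self.upper_bound.get(x)

    def excluded_as_parent(self, x: str) -> bool:
        """True when x is known to have died below the minimum breeding age."""
        age = self.known_age_at_death.get(x)
        return age is not None and age < self.min_breeding_age


def infer_birth_years(
    pedigree: Pedigree,
    first_seen: Mapping[str, date | int],
    death_dates: Mapping[str, date | int] | None = None,
    known_age_at_death: Mapping[str, int] | None = None,
    min_breeding_age: int = 2,
) -> CohortInfo:
    """Infer litter birth years from sibling-group detections.

    Siblings (same parent pair with at least one sampled parent) share a
    birth year: the earliest year consistent with every member's first
    detection and with each sampled parent reaching the minimum breeding
    age (a parent's own birth year falls back to its first-seen year
    when not inferred).  Individuals with no sampled parents keep an
    undetermined birth year bounded above by first detection.
    Conflicting constraints are flagged, not fatal.
    """

    def _year(v: date | int) -> int:
        return v.year if isinstance(v, date) else int(v)

    info = CohortInfo(min_breeding_age=min_breeding_age)
    for x in pedigree.individuals:
        info.upper_bound[x] = _year(first_seen[x]) if x in first_seen else None
        info.birth_year[x] = None
    for x, v in (death_dates or {}).items():
        info.death_year[x] = _year(v)
    info.known_age_at_death.update(known_age_at_death or {})

    # sibling groups keyed by parent pair (>=1 sampled parent)
    groups: dict[tuple[str, str], list[str]] = {}
    for x, (d, s) in pedigree.parents.items():
        if not _is_token(d) or not _is_token(s):
            groups.setdefault((d, s), []).append(x)

    # propagate top-down: parents appear in shallower groups
    for _ in range(len(groups) + 1):
        changed = False
        for (d, s), members in groups.items():
            lower = None
            for p in (d, s):
                if _is_token(p):
                    continue
                pb = info.effective_birth(p)
                if pb is not None:
                    cand = pb + min_breeding_age
                    lower = cand if lower is None else max(lower, cand)
            uppers = [info.upper_bound[m] for m in members if info.upper_bound.get(m) is not None]
            upper = min(uppers) if uppers else None
            if lower is None:
                continue
            if upper is not None and lower > upper:
                msg = f"litter of ({d}, {s}): earliest feasible year {lower} after first detection {upper}"
                if msg not in info.conflicts:
                    info.conflicts.append(msg)
                continue
            for m in members:
                if info.birth_year[m] != lower:
                    info.birth_year[m] = lower
                    changed = True
        if not changed:
            break
    return info


def merge_unsampled_parents(
    pedigree: Pedigree,
    offspring_ids: Iterable[str],
    role: str,
    merged_id: str,
    sex: str | None = None,
) -> Pedigree:
    """Replace the UNSAMPLED ``role`` ('dam'|'sire') slot of the given
    offspring with a shared anonymous founder id (manual curation of an
    unsampled breeding pair).  Returns a new pedigree."""
    if role not in ("dam", "sire"):
        raise ValueError("role must be 'dam' or 'sire'")
    out = pedigree.copy()
    for x in offspring_ids:
        d, s = out.parents[x]
        if role == "dam":
            if d != UNSAMPLED:
                raise ValueError(f"dam of {x} is not UNSAMPLED")
            out.parents[x] = (merged_id, s)
        else:
            if s != UNSAMPLED:
                raise ValueError(f"sire of {x} is not UNSAMPLED")
            out.parents[x] = (d, merged_id)
    if sex:
        out.sexes[merged_id] = sex
    ok, why = is_legal(out)
    if not ok:
        raise ValueError(f"merge would create an illegal pedigree: {why}")
    return out
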
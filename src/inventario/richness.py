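"""Incidence summaries, the small-sample Chao2 estimator and completeness.

The sampling unit is one day at one place; an *event* is one unique
species x date combination within a unit (grid cell, hotspot or named
locality).  From the incidence frequencies of a unit —

- ``N``      total events,
- ``S_obs``  species recorded,
- ``a``      species recorded exactly once (singletons),
- ``b``      species recorded exactly twice (doubletons),

the expected richness is the small-sample-adjusted Chao2 estimator

    S_exp = S_obs + ((N - 1) / N) * (a * (a - 1)) / (2 * (b + 1))

and the inventory completeness index is ``C = S_obs / S_exp``.  Chao2 is a
lower-bound-type estimator: it asks how many species remain undetected given
how many are still being seen only once or twice.  With no singletons
(``a = 0``) the inventory is judged complete, ``C = 1``.

Selection of well-inventoried units applies the study thresholds: units with
``N < 200`` are discarded as too thinly sampled to judge, and tiers are
decided on ``C`` rounded to two decimals (``C >= 0.9`` excellent,
``0.8 <= C < 0.9`` good).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

__all__ = [
    "IncidenceSummary",
    "SelectionCriteria",
    "summarize_incidence",
    "summarize_by_unit",
    "chao2",
    "completeness",
    "add_estimates",
    "select_well_inventoried",
]


@dataclass(frozen=True)
class IncidenceSummary:
    """Incidence frequencies and derived richness estimates for one unit."""

    unit_id: object
    N: int
    S_obs: int
    a: int
    b: int
    S_exp: float | None = None
    C: float | None = None

    def with_estimates(self) -> "IncidenceSummary":
        s_exp = chao2(self.N, self.S_obs, self.a, self.b)
        return replace(self, S_exp=s_exp, C=self.S_obs / s_exp)


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds for designating a unit as well-inventoried."""

    min_N: int = 200
    c_good: float = 0.8
    c_excellent: float = 0.9
    decimals: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.c_good <= self.c_excellent <= 1):
            raise ValueError("need 0 < c_good <= c_excellent <= 1")


def chao2(N: int, S_obs: int, a: int, b: int) -> float:
    """Small-sample-adjusted Chao2 expected species richness.

    Raises ``ValueError`` for ``N < 1`` (the estimator is undefined on an
    empty unit) or inconsistent frequencies.
    """
    if N < 1:
        raise ValueError("Chao2 requires at least one event (N >= 1)")
    if min(S_obs, a, b) < 0 or a + b > S_obs or S_obs > N:
        raise ValueError(f"inconsistent incidence summary (N={N}, S_obs={S_obs}, a={a}, b={b})")
    return S_obs + ((N - 1) / N) * (a * (a - 1)) / (2 * (b + 1))


def completeness(N: int, S_obs: int, a: int, b: int) -> float:
    """Inventory completeness C = S_obs / S_exp, in (0, 1]."""
    return S_obs / chao2(N, S_obs, a, b)


def summarize_incidence(events: pd.DataFrame, unit_id: object) -> IncidenceSummary | None:
    """Tally incidence frequencies for the events of one unit.

    ``events`` must already be unique species x date combinations within the
    unit.  Returns ``None`` for an empty unit (no summary is emitted).
    """
    if len(events) == 0:
        return None
    per_species = events.groupby("taxon", sort=False).size()
    return IncidenceSummary(
        unit_id=unit_id,
        N=int(len(events)),
        S_obs=int(per_species.size),
        a=int((per_species == 1).sum()),
        b=int((per_species == 2).sum()),
    ).with_estimates()


def summarize_by_unit(events: pd.DataFrame, by: str = "place_key") -> pd.DataFrame:
    """Incidence summary table over all units in an event frame.

    Returns a frame with columns ``unit_id, N, S_obs, a, b, S_exp, C``,
    one row per unit, sorted by unit id.
    """
    rows = []
    for unit_id, unit_events in events.groupby(by, sort=True):
        summary = summarize_incidence(unit_events, unit_id)
        if summary is not None:
            rows.append(summary)
    return pd.DataFrame(
        [
            {
                "unit_id": s.unit_id,
                "N": s.N,
                "S_obs": s.S_obs,
                "a": s.a,
                "b": s.b,
                "S_exp": s.S_exp,
                "C": s.C,
            }
            for s in rows
        ],
        columns=["unit_id", "N", "S_obs", "a", "b", "S_exp", "C"],
    )


def add_estimates(summaries: pd.DataFrame) -> pd.DataFrame:
    """Vectorized S_exp and C over a frame with N, S_obs, a, b columns."""
    out = summaries.copy()
    N = out["N"].to_numpy(float)
    if (N < 1).any():
        raise ValueError("Chao2 requires N >= 1 in every row")
    S_obs = out["S_obs"].to_numpy(float)
    a = out["a"].to_numpy(float)
    b = out["b"].to_numpy(float)
    out["S_exp"] = S_obs + ((N - 1) / N) * (a * (a - 1)) / (2 * (b + 1))
    out["C"] = S_obs / out["S_exp"]
    return out


def select_well_inventoried(
    summaries: pd.DataFrame, criteria: SelectionCriteria = SelectionCriteria()
) -> dict[str, pd.DataFrame]:
    """Tier units into excellent / good inventories.

    Units with ``N < min_N`` are excluded before thresholding.  Tier
    membership is decided on ``C`` rounded to ``criteria.decimals`` — the
    reporting precision — so a unit whose raw C is 0.8969 counts as 0.90.
    The returned frames carry a ``C_rounded`` column.
    """
    eligible = summaries.loc[summaries["N"] >= criteria.min_N].copy()
    eligible["C_rounded"] = eligible["C"].round(criteria.decimals)
    excellent = eligible.loc[eligible["C_rounded"] >= criteria.c_excellent]
    good = eligible.loc[
        (eligible["C_rounded"] >= criteria.c_good)
        & (eligible["C_rounded"] < criteria.c_excellent)
    ]
    return {"excellent": excellent.copy(), "good": good.copy()}
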
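"""Surveillance statistics: age-specific incidence rates and prevalence trends.

Incidence rates (IR) are first-event rates: a person is at risk for a term
until the calendar year of their first event of that term (inclusive), and
the event is counted in the age group of that year.  IR = events /
person-years x 100,000, computed per (term, age group) over a calendar
period (default 2010-2021), with age = event year - birth year at annual
granularity.  Within each term the age-group IRs are mapped to quantile
categories (default 5) for heat-strip display.

Prevalence trends come from aggregate tables (yearly affected counts plus
population denominators), scaled per 1,000 persons or as a percentage.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import AGE_BANDS

__all__ = [
    "incidence_rates",
    "quantile_categorize",
    "prevalence_trend",
    "age_band_label",
]


def age_band_label(band: tuple[int, int]) -> str:
    return f"{band[0]}-{band[1]}"


def incidence_rates(
    events: pd.DataFrame,
    census: pd.DataFrame,
    terms: Sequence[str],
    period: tuple[int, int] = (2010, 2021),
    age_groups: Sequence[tuple[int, int]] = AGE_BANDS,
    recurrent: bool = False,
    token_column: str = "code",
) -> pd.DataFrame:
    """Age-specific incidence rates per 100,000 person-years.

    ``events`` needs columns person_id, year and ``token_column``; ``census``
    needs person_id and birth_year for everyone under observation (also
    persons without events, who contribute person-years only).  For each
    (term, age group) cell within ``period``:

    * events — persons whose first-ever event of the term (or any event,
      with ``recurrent=True``) falls in that age group and period,
    * person-years — whole calendar years at risk; risk for a term ends
      after the year of the first event (no exit with ``recurrent=True``).

    Cells with zero person-years get IR = NaN and ``ir_defined = False``
    (undefined, not zero).
    """
    start, end = period
    if start > end:
        raise ValueError("inverted period")
    if census.empty:
        raise ValueError("empty census")
    birth = dict(zip(census["person_id"], census["birth_year"]))

    max_age = max(hi for _, hi in age_groups)
    band_of = {}
    for b, (lo, hi) in enumerate(age_groups):
        for a in range(lo, hi + 1):
            band_of[a] = b

    # first event year per (person, term)
    ev = events[events[token_column].isin(set(terms))]
    first = (
        ev.groupby(["person_id", token_column])["year"].min()
        if not recurrent
        else None
    )

    n_bands = len(age_groups)
    results = []
    for term in terms:
        events_per_band = np.zeros(n_bands, dtype=int)
        py_per_band = np.zeros(n_bands, dtype=float)
        if recurrent:
            term_events = ev[ev[token_column] == term]
            counted = term_events[
                (term_events["year"] >= start) & (term_events["year"] <= end)
            ]
            for _, row in counted.iterrows():
                age = int(row["year"]) - int(birth[row["person_id"]])
                if age in band_of:
                    events_per_band[band_of[age]] += 1
            exit_year = {}
        else:
            term_first = (
                first.xs(term, level=token_column)
                if term in first.index.get_level_values(token_column)
                else pd.Series(dtype=int)
            )
            exit_year = term_first.to_dict()
            for pid, fy in exit_year.items():
                if start <= fy <= end:
                    age = int(fy) - int(birth[pid])
                    if age in band_of:
                        events_per_band[band_of[age]] += 1

        for pid, by in birth.items():
            last = end if recurrent else min(end, exit_year.get(pid, end))
            lo_year = max(start, by)
            for year in range(lo_year, last + 1):
                age = year - by
                if 0 <= age <= max_age and age in band_of:
                    py_per_band[band_of[age]] += 1.0

        for b, band in enumerate(age_groups):
            py = py_per_band[b]
            n_ev = int(events_per_band[b])
            ir = n_ev / py * 100_000 if py > 0 else float("nan")
            results.append(
                (term, age_band_label(band), n_ev, py, ir, py > 0)
            )

    return pd.DataFrame(
        results,
        columns=["term", "age_group", "events", "person_years", "ir_per_100k", "ir_defined"],
    )


def quantile_categorize(table: pd.DataFrame, q: int = 5) -> pd.DataFrame:
    """Within-term quantile categories (1..q) of the age-group IRs.

    Rank-then-bin: with n defined IRs in a term, an IR of min-rank r gets
    category ceil(q * r / n).  Monotone (a higher IR never gets a lower
    category), invariant under strictly monotone IR transformations; ties
    share a category, and all-identical IRs collapse to a single category.
    Undefined IRs get no category (NA).
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    out = table.copy()
    out["quantile"] = pd.array([pd.NA] * len(out), dtype="Int64")
    for term, group in out.groupby("term"):
        defined = group[group["ir_defined"]]
        if defined.empty:
            raise ValueError(f"term {term!r} has no defined IR")
        n = len(defined)
        ranks = defined["ir_per_100k"].rank(method="min")
        cats = np.ceil(q * ranks / n).astype(int)
        out.loc[defined.index, "quantile"] = cats
    return out


def prevalence_trend(
    aggregate: pd.DataFrame,
    scale: str = "per-1000",
) -> pd.DataFrame:
    """Yearly prevalence per indicator from aggregate count tables.

    ``aggregate`` needs columns year, (code or indicator), affected,
    population.  ``scale`` is ``"per-1000"`` (rate per 1,000 persons) or
    ``"percent"``; rows with zero population raise.
    """
    factors = {"per-1000": 1000.0, "percent": 100.0}
    if scale not in factors:
        raise ValueError(f"scale must be one of {sorted(factors)}")
    key = "indicator" if "indicator" in aggregate.columns else "code"
    df = aggregate.copy()
    if (df["population"] <= 0).any():
        raise ValueError("zero or negative population in aggregate table")
    df["rate"] = df["affected"] / df["population"] * factors[scale]
    df["scale"] = scale
    return (
        df[["year", key, "affected", "population", "rate", "scale"]]
        .rename(columns={key: "indicator"})
        .sort_values(["indicator", "year"], kind="stable")
        .reset_index(drop=True)
    )
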
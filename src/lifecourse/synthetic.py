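"""Synthetic register cohorts with planted co-occurrence structure.

Real nationwide register data (multi-decade event histories of diagnoses,
prescriptions, procedures and childhood adversities) are access-restricted,
so every downstream stage of the pipeline is exercised on simulated cohorts
with known ground truth instead.  The generator emulates the features the
embedding pipeline exploits:

* per-person event streams spanning birth to a fixed observation end year,
* four code systems (ICD-10-style diagnoses, ATC-style medications,
  SKS-style procedures, and childhood-adversity indicators),
* age-dependent event rates via per-code age profiles over 5-year bands,
* adversity events restricted to ages below a cutoff (default 16),
* planted "communities" of codes that co-occur within persons at a boosted
  rate — the ground truth that embedding/clustering stages must recover.

The generative model is deliberately simple: for each person-year the number
of events is Poisson with rate ``background_rate`` scaled by the mean age
weight of the vocabulary, and each event's code is drawn with probability
proportional to its age-profile weight, multiplied by the community boost
for codes sharing a community with a code the person has already accrued.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CodeDef",
    "Community",
    "CohortSpec",
    "AGE_BANDS",
    "generate_cohort",
    "generate_aggregate_counts",
    "cohort_census",
    "default_cohort_spec",
    "write_events_tsv",
    "read_events_tsv",
    "write_aggregate_tsv",
]

CODE_SYSTEMS = ("diagnosis", "medication", "procedure", "adversity")

#: 5-year age bands 0-4 ... 40-44, matching the study's 0-42 age span.
AGE_BANDS: tuple[tuple[int, int], ...] = tuple((lo, lo + 4) for lo in range(0, 45, 5))

ADVERSITY_AGE_CUTOFF = 16


def _age_band_index(age: int) -> int:
    return min(age // 5, len(AGE_BANDS) - 1)


@dataclass(frozen=True)
class CodeDef:
    """One vocabulary code: identity, system and relative incidence by age.

    ``age_profile`` holds non-negative weights over the 9 five-year age bands
    0-4 ... 40-44; it need not be normalized.  Adversity codes carry
    ``adversity_only_before`` (default 16): no event is generated at or above
    that age regardless of the profile.
    """

    code: str
    system: str
    age_profile: tuple[float, ...] = field(default=tuple([1.0] * len(AGE_BANDS)))
    adversity_only_before: Optional[int] = None

    def __post_init__(self) -> None:
        if self.system not in CODE_SYSTEMS:
            raise ValueError(f"unknown code system: {self.system!r}")
        profile = tuple(float(w) for w in self.age_profile)
        if len(profile) != len(AGE_BANDS):
            raise ValueError(
                f"age_profile must have {len(AGE_BANDS)} weights, got {len(profile)}"
            )
        if any(w < 0 for w in profile) or sum(profile) <= 0:
            raise ValueError("age_profile weights must be >= 0 and sum to > 0")
        object.__setattr__(self, "age_profile", profile)
        if self.system == "adversity" and self.adversity_only_before is None:
            object.__setattr__(self, "adversity_only_before", ADVERSITY_AGE_CUTOFF)


@dataclass(frozen=True)
class Community:
    """Planted group of codes that co-occur within persons at a boosted rate."""

    member_codes: tuple[str, ...]
    co_occurrence_boost: float

    def __post_init__(self) -> None:
        members = tuple(self.member_codes)
        if len(members) < 2:
            raise ValueError("a community needs at least 2 member codes")
        if self.co_occurrence_boost <= 1:
            raise ValueError("co_occurrence_boost must be > 1")
        object.__setattr__(self, "member_codes", members)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic register cohort."""

    n_individuals: int
    birth_year_range: tuple[int, int] = (1980, 2015)
    observation_end_year: int = 2022
    vocabulary: tuple[CodeDef, ...] = ()
    communities: tuple[Community, ...] = ()
    background_rate: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be > 0")
        lo, hi = self.birth_year_range
        if lo > hi:
            raise ValueError(f"inverted birth_year_range: {self.birth_year_range}")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        object.__setattr__(self, "vocabulary", tuple(self.vocabulary))
        object.__setattr__(self, "communities", tuple(self.communities))
        known = {c.code for c in self.vocabulary}
        for comm in self.communities:
            missing = set(comm.member_codes) - known
            if missing:
                raise ValueError(f"community references unknown codes: {sorted(missing)}")

    def replace(self, **kwargs) -> "CohortSpec":
        return dataclasses.replace(self, **kwargs)


def _validate_for_generation(spec: CohortSpec) -> None:
    if not spec.vocabulary:
        raise ValueError("empty vocabulary")
    lo, hi = spec.birth_year_range
    if hi > spec.observation_end_year:
        raise ValueError("birth_year_range extends past observation_end_year")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate the event table for one cohort.

    Returns a DataFrame with columns ``person_id, birth_year, year, code,
    system``, sorted by person and year.  Bit-identical across calls with the
    same spec (the spec's ``seed`` drives a dedicated PCG64 generator).
    """
    _validate_for_generation(spec)
    rng = np.random.default_rng(spec.seed)
    vocab = spec.vocabulary
    n_codes = len(vocab)
    # profile[b, j] = weight of code j in age band b
    profile = np.array([c.age_profile for c in vocab], dtype=float).T
    cutoff = np.array(
        [c.adversity_only_before if c.adversity_only_before is not None else 10_000
         for c in vocab],
        dtype=int,
    )
    community_of = np.full(n_codes, -1, dtype=int)
    code_index = {c.code: j for j, c in enumerate(vocab)}
    boosts = np.ones(len(spec.communities), dtype=float)
    for ci, comm in enumerate(spec.communities):
        boosts[ci] = comm.co_occurrence_boost
        for code in comm.member_codes:
            community_of[code_index[code]] = ci

    # Mean age weight normalizes so background_rate is events/person-year
    # for an average code mix.
    band_mean = profile.mean(axis=1)
    band_total = profile.sum(axis=1)

    lo, hi = spec.birth_year_range
    birth_years = rng.integers(lo, hi + 1, size=spec.n_individuals)

    persons: list[int] = []
    births: list[int] = []
    years: list[int] = []
    codes: list[int] = []
    for pid in range(spec.n_individuals):
        birth = int(birth_years[pid])
        seen_comm = np.zeros(len(spec.communities), dtype=bool)
        for year in range(birth, spec.observation_end_year + 1):
            age = year - birth
            band = _age_band_index(age)
            if band_total[band] <= 0:
                continue
            rate = spec.background_rate * band_mean[band] / max(band_mean.mean(), 1e-12)
            n_events = rng.poisson(rate)
            for _ in range(n_events):
                w = profile[band].copy()
                w[age >= cutoff] = 0.0
                if seen_comm.any():
                    boosted = seen_comm[community_of] & (community_of >= 0)
                    w[boosted] *= boosts[community_of[boosted]]
                total = w.sum()
                if total <= 0:
                    continue
                j = int(rng.choice(n_codes, p=w / total))
                if community_of[j] >= 0:
                    seen_comm[community_of[j]] = True
                persons.append(pid)
                births.append(birth)
                years.append(year)
                codes.append(j)

    events = pd.DataFrame(
        {
            "person_id": np.array(persons, dtype=int),
            "birth_year": np.array(births, dtype=int),
            "year": np.array(years, dtype=int),
            "code": [vocab[j].code for j in codes],
            "system": [vocab[j].system for j in codes],
        }
    )
    events = events.sort_values(["person_id", "year"], kind="stable").reset_index(drop=True)
    return events


def cohort_census(spec: CohortSpec) -> pd.DataFrame:
    """Person-level census (person_id, birth_year) matching generate_cohort.

    Uses the same seed stream head, so birth years agree with the event table.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.birth_year_range
    birth_years = rng.integers(lo, hi + 1, size=spec.n_individuals)
    return pd.DataFrame(
        {"person_id": np.arange(spec.n_individuals), "birth_year": birth_years.astype(int)}
    )


def generate_aggregate_counts(
    spec: CohortSpec,
    codes: Sequence[str],
    years: Sequence[int],
    age_band: tuple[int, int],
) -> pd.DataFrame:
    """Yearly affected counts and population denominators for given codes.

    Emulates public aggregate extracts (yearly counts of residents purchasing
    a medication / receiving a diagnosis, plus census denominators).
    ``affected`` counts distinct persons in the age band with >= 1 event of
    the code that year; ``population`` counts persons alive and in the band.
    Consistent with :func:`generate_cohort` under the same spec.
    """
    years = list(years)
    if not years:
        raise ValueError("empty year list")
    bad = [y for y in years if y > spec.observation_end_year]
    if bad:
        raise ValueError(f"years outside observation window: {bad}")
    lo_age, hi_age = age_band
    events = generate_cohort(spec)
    census = cohort_census(spec)

    rows = []
    for year in years:
        ages = year - census["birth_year"]
        in_band = (ages >= lo_age) & (ages <= hi_age) & (census["birth_year"] <= year)
        population = int(in_band.sum())
        year_events = events[events["year"] == year]
        for code in codes:
            sub = year_events[year_events["code"] == code]
            sub_ages = sub["year"] - sub["birth_year"]
            affected = sub.loc[(sub_ages >= lo_age) & (sub_ages <= hi_age), "person_id"].nunique()
            rows.append((year, code, int(affected), population))
    return pd.DataFrame(rows, columns=["year", "code", "affected", "population"])


# ---------------------------------------------------------------------------
# Default study-style cohort: 60 codes, 3 planted communities, boost 20
# ---------------------------------------------------------------------------

#: Childhood-adversity indicators across the three dimensions
#: (material deprivation / loss or threat of loss / familial dysfunction).
ADVERSITY_LABELS = (
    "poverty",
    "parental_unemployment",
    "parental_death",
    "sibling_death",
    "parental_severe_disease",
    "parental_divorce",
    "foster_care",
    "sibling_psychiatric_illness",
    "parental_psychiatric_illness",
    "parental_alcohol_abuse",
)

_CHILD_PROFILE = (3.0, 3.0, 2.0, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0)
_ADULT_PROFILE = (0.2, 0.3, 0.5, 1.0, 1.5, 2.0, 2.0, 1.8, 1.5)
_FLAT_PROFILE = tuple([1.0] * len(AGE_BANDS))
_YOUTH_PROFILE = (1.0, 2.0, 3.0, 3.0, 2.0, 1.0, 0.5, 0.3, 0.2)


def default_cohort_spec(
    n_individuals: int = 5000,
    boost: float = 20.0,
    seed: int = 7,
    background_rate: float = 0.6,
) -> CohortSpec:
    """Study-condition cohort: 60 codes in 3 planted communities.

    Community layout (20 codes each):

    * ``sleep`` — the sleep-problem query codes (nonorganic F51.x and organic
      G47.x diagnoses, melatonin/benzodiazepine-related/promethazine ATC
      groups), sleep-adjacent procedures, and three familial-dysfunction
      adversities (sibling psychiatric illness, foster care, parental
      divorce), mirroring the adversity-sleep neighborhood under study.
    * ``cardio`` — cardiometabolic diagnoses/medications/procedures plus
      material-deprivation adversities.
    * ``msk`` — musculoskeletal/injury codes plus loss-related adversities.
    """
    sleep_codes = [
        CodeDef("F510", "diagnosis", _ADULT_PROFILE),   # nonorganic insomnia
        CodeDef("F512", "diagnosis", _YOUTH_PROFILE),   # sleep-wake rhythm disorder
        CodeDef("F514", "diagnosis", _CHILD_PROFILE),   # sleep terrors
        CodeDef("F515", "diagnosis", _CHILD_PROFILE),   # nightmares
        CodeDef("F519", "diagnosis", _YOUTH_PROFILE),   # nonorganic sleep disorder UNS
        CodeDef("G470", "diagnosis", _ADULT_PROFILE),   # insomnia, organic
        CodeDef("G473", "diagnosis", _ADULT_PROFILE),   # sleep apnea
        CodeDef("G474", "diagnosis", _YOUTH_PROFILE),   # narcolepsy
        CodeDef("N05CH", "medication", _ADULT_PROFILE),  # melatonin receptor agonists
        CodeDef("N05CF", "medication", _ADULT_PROFILE),  # benzodiazepine-related
        CodeDef("R06AD", "medication", _ADULT_PROFILE),  # phenothiazine derivatives
        CodeDef("N06AB", "medication", _ADULT_PROFILE),  # SSRIs (comorbid)
        CodeDef("ZZ7610", "procedure", _ADULT_PROFILE),  # polysomnography-style
        CodeDef("ZZ4171", "procedure", _ADULT_PROFILE),  # CPAP-style
        CodeDef("BRXA1", "procedure", _YOUTH_PROFILE),
        CodeDef("F411", "diagnosis", _ADULT_PROFILE),    # anxiety (comorbid)
        CodeDef("F320", "diagnosis", _ADULT_PROFILE),    # depressive episode
        CodeDef("sibling_psychiatric_illness", "adversity", _CHILD_PROFILE),
        CodeDef("foster_care", "adversity", _CHILD_PROFILE),
        CodeDef("parental_divorce", "adversity", _CHILD_PROFILE),
    ]
    cardio_codes = [
        CodeDef("I109", "diagnosis", _ADULT_PROFILE),
        CodeDef("I209", "diagnosis", _ADULT_PROFILE),
        CodeDef("I489", "diagnosis", _ADULT_PROFILE),
        CodeDef("E119", "diagnosis", _ADULT_PROFILE),
        CodeDef("E669", "diagnosis", _ADULT_PROFILE),
        CodeDef("J459", "diagnosis", _YOUTH_PROFILE),
        CodeDef("C10AA", "medication", _ADULT_PROFILE),
        CodeDef("C07AB", "medication", _ADULT_PROFILE),
        CodeDef("C09AA", "medication", _ADULT_PROFILE),
        CodeDef("A10BA", "medication", _ADULT_PROFILE),
        CodeDef("R03AC", "medication", _YOUTH_PROFILE),
        CodeDef("UXKC8", "procedure", _ADULT_PROFILE),
        CodeDef("KFNG0", "procedure", _ADULT_PROFILE),
        CodeDef("UXRC8", "procedure", _ADULT_PROFILE),
        CodeDef("ZZ0149", "procedure", _FLAT_PROFILE),
        CodeDef("E039", "diagnosis", _ADULT_PROFILE),
        CodeDef("I259", "diagnosis", _ADULT_PROFILE),
        CodeDef("poverty", "adversity", _CHILD_PROFILE),
        CodeDef("parental_unemployment", "adversity", _CHILD_PROFILE),
        CodeDef("parental_alcohol_abuse", "adversity", _CHILD_PROFILE),
    ]
    msk_codes = [
        CodeDef("M545", "diagnosis", _ADULT_PROFILE),
        CodeDef("M179", "diagnosis", _ADULT_PROFILE),
        CodeDef("M255", "diagnosis", _FLAT_PROFILE),
        CodeDef("S525", "diagnosis", _YOUTH_PROFILE),
        CodeDef("S934", "diagnosis", _YOUTH_PROFILE),
        CodeDef("T784", "diagnosis", _FLAT_PROFILE),
        CodeDef("M02AA", "medication", _ADULT_PROFILE),
        CodeDef("N02BE", "medication", _FLAT_PROFILE),
        CodeDef("N02AA", "medication", _ADULT_PROFILE),
        CodeDef("M03BX", "medication", _ADULT_PROFILE),
        CodeDef("H02AB", "medication", _ADULT_PROFILE),
        CodeDef("KNGF2", "procedure", _ADULT_PROFILE),
        CodeDef("KNBJ6", "procedure", _YOUTH_PROFILE),
        CodeDef("UXRG0", "procedure", _FLAT_PROFILE),
        CodeDef("BWAA1", "procedure", _FLAT_PROFILE),
        CodeDef("M796", "diagnosis", _ADULT_PROFILE),
        CodeDef("G560", "diagnosis", _ADULT_PROFILE),
        CodeDef("parental_death", "adversity", _CHILD_PROFILE),
        CodeDef("sibling_death", "adversity", _CHILD_PROFILE),
        CodeDef("parental_severe_disease", "adversity", _CHILD_PROFILE),
    ]
    vocabulary = tuple(sleep_codes + cardio_codes + msk_codes)
    communities = (
        Community(tuple(c.code for c in sleep_codes), boost),
        Community(tuple(c.code for c in cardio_codes), boost),
        Community(tuple(c.code for c in msk_codes), boost),
    )
    return CohortSpec(
        n_individuals=n_individuals,
        birth_year_range=(1980, 2015),
        observation_end_year=2022,
        vocabulary=vocabulary,
        communities=communities,
        background_rate=background_rate,
        seed=seed,
    )


def planted_labels(spec: CohortSpec) -> dict[str, int]:
    """Map code -> planted community index (codes outside communities absent)."""
    labels: dict[str, int] = {}
    for ci, comm in enumerate(spec.communities):
        for code in comm.member_codes:
            labels[code] = ci
    return labels


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"code": str, "system": str})


def write_aggregate_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
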
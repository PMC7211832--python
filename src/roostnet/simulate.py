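"""Synthetic roost-capture data with known social and genetic structure.

The generator emulates the sampling situation the analysis assumes:
two closed, genetically distinct populations of bats; female
philopatry with male natal dispersal (dispersing males leave the study
area); fission-fusion roost switching among nearby roosts;
kin-biased co-roosting in females; partner preference in both sexes;
a tendency toward single-male/multi-female groups; and imperfect
per-event capture.  Ground truth (pedigree, daily group memberships)
is retained so every pipeline stage can be checked against known
structure, and so the null-model machinery can be calibrated on data
generated with *no* social preference.

Group assembly is sequential-greedy with random arrival order: each
day, bats in random order join the open roost maximising

    score = pi * mean past association with current members
          + kappa * mean relatedness to current female members (female choosers)
          - male_avoidance * number of males already present (males only)
          - crowding_penalty * number of members already present
          + Gumbel(0, 1) noise

The crowding term models limited roost capacity; without it,
preference reinforcement collapses every population into a single
permanent group instead of fission-fusion subgroups.

With ``kappa = pi = male_avoidance = 0`` the Gumbel-noise argmax
reduces exactly to a uniform-random roost choice — the calibration
null of the permutation machinery.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from roostnet.records import (
    CAPTURE_COLUMNS,
    CaptureDataset,
    RelatednessMatrix,
    RoostRegistry,
    write_captures,
    write_roosts,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "Pedigree",
    "RoostingTruth",
    "SimulationBundle",
    "simulate_pedigree",
    "pedigree_relatedness",
    "simulate_roosting",
    "sample_captures",
    "simulate_dataset",
]

POPULATIONS = ("west", "east")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic roosting study.

    Defaults are set to the scale of a six-year, two-population
    roost-capture study (~150 marked bats, ~100 group captures) with
    female philopatry, strong male natal dispersal, fission-fusion
    roost switching at the 0.1-0.5 km roost spacing scale, female
    kin-biased association, partner preference in both sexes, and a
    single-male/multi-female group tendency.  Social-preference
    strengths are in units of the Gumbel(0, 1) choice noise.
    """

    n_founders: int = 60
    n_years: int = 6
    n_roosts_per_population: int = 16
    pup_rate: float = 0.5
    male_dispersal_prob: float = 0.85
    female_dispersal_prob: float = 0.0
    male_immigrants_per_year: float = 3.0  # Poisson, per population per year
    kin_bias_strength: float = 4.0  # kappa; female choosers, female members
    partner_preference_strength: float = 4.0  # pi; both sexes
    male_avoidance: float = 3.5  # per male already in the group; males only
    crowding_penalty: float = 0.6  # per member already in the group
    roost_switch_prob: float = 0.15  # per group per day
    groups_per_day: int = 8  # open roosts per population per day
    capture_events_per_year: int = 18
    detection_prob: float = 0.7
    relatedness_noise_sd: float = 0.05  # estimator noise on observed r
    seed: int | None = None
    # demographic / bookkeeping details
    adult_survival: float = 0.88  # annual, adults only
    days_per_year: int = 60  # simulated roosting days per year
    maturity_years: int = 1
    repro_male_prob: float = 0.6  # P(adult male is scrotal in a given year)
    roost_span_m: float = 450.0  # extent of each population's roost cluster
    population_separation_m: float = 2000.0

    def __post_init__(self) -> None:
        probs = {
            "pup_rate": self.pup_rate,
            "male_dispersal_prob": self.male_dispersal_prob,
            "female_dispersal_prob": self.female_dispersal_prob,
            "roost_switch_prob": self.roost_switch_prob,
            "detection_prob": self.detection_prob,
            "adult_survival": self.adult_survival,
            "repro_male_prob": self.repro_male_prob,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.kin_bias_strength < 0 or self.partner_preference_strength < 0:
            raise ValueError("kappa and pi must be >= 0")
        if self.male_avoidance < 0:
            raise ValueError("male_avoidance must be >= 0")
        if self.crowding_penalty < 0:
            raise ValueError("crowding_penalty must be >= 0")
        if self.male_immigrants_per_year < 0:
            raise ValueError("male_immigrants_per_year must be >= 0")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.groups_per_day > self.n_roosts_per_population:
            raise ValueError("groups_per_day cannot exceed roosts per population")

    def null(self, **overrides) -> "SimulationConfig":
        """Copy with all social-preference terms zeroed (random assembly)."""
        params = asdict(self)
        params.update(
            kin_bias_strength=0.0,
            partner_preference_strength=0.0,
            male_avoidance=0.0,
            crowding_penalty=0.0,
        )
        params.update(overrides)
        return SimulationConfig(**params)


@dataclass
class Pedigree:
    """Simulated parentage with per-individual demographic fate.

    ``table`` columns: id, sex, mother_id, father_id, birth_year,
    population, death_year (NaN = alive at end), dispersal_year
    (NaN = never dispersed), arrival_year (NaN for natives; the year
    an immigrant male entered the study area as an adult).  Founders
    are established adults born before the study with no recorded
    parents.  Bats never change
    population.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        ids = set(t["id"])
        sex = dict(zip(t["id"], t["sex"]))
        by = dict(zip(t["id"], t["birth_year"]))
        for _, row in t.iterrows():
            for parent, want in ((row["mother_id"], "female"), (row["father_id"], "male")):
                if parent is None or (isinstance(parent, float) and np.isnan(parent)):
                    continue
                if parent not in ids:
                    raise ValueError(f"unknown parent {parent!r} of {row['id']!r}")
                if sex[parent] != want:
                    raise ValueError(f"parent {parent!r} of {row['id']!r} has wrong sex")
                if by[parent] >= row["birth_year"]:
                    raise ValueError(
                        f"parent {parent!r} not older than offspring {row['id']!r}"
                    )
        self.table = t

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def sex_of(self) -> pd.Series:
        return self.table.set_index("id")["sex"]

    def adult_from(self, maturity_years: int) -> pd.Series:
        return self.table.set_index("id")["birth_year"] + maturity_years

    def present(self, year: int, maturity_years: int = 1) -> pd.DataFrame:
        """Individuals in the study area in ``year`` (adults and pups of the year)."""
        t = self.table
        alive = t["death_year"].isna() | (t["death_year"] > year)
        here = t["dispersal_year"].isna() | (t["dispersal_year"] > year)
        born = t["birth_year"] <= year
        arrived = (
            t["arrival_year"].isna() | (t["arrival_year"] <= year)
            if "arrival_year" in t.columns
            else True
        )
        return t[alive & here & born & arrived]

    def present_adults(self, year: int, maturity_years: int = 1) -> pd.DataFrame:
        p = self.present(year, maturity_years)
        return p[p["birth_year"] + maturity_years <= year]


def simulate_pedigree(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> Pedigree:
    """Simulate an overlapping-generations two-population pedigree.

    Founders (birth year -1, unknown parents) are split evenly across
    the two populations with a balanced sex ratio.  Each year, adults
    die with probability ``1 - adult_survival``; juveniles reaching
    maturity emigrate (are removed) with the sex-specific dispersal
    probability; each resident adult female produces at most one pup
    (probability ``pup_rate``) sired by a random resident adult male
    of her population.  Populations are closed to each other.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rows: list[dict] = []
    counter = 0

    def new_bat(sex, mother, father, birth_year, population, arrival_year=np.nan):
        nonlocal counter
        counter += 1
        rows.append(
            {
                "id": f"B{counter:04d}",
                "sex": sex,
                "mother_id": mother,
                "father_id": father,
                "birth_year": birth_year,
                "population": population,
                "death_year": np.nan,
                "dispersal_year": np.nan,
                "arrival_year": arrival_year,
            }
        )
        return rows[-1]

    # founders are established adults: born before the study so the
    # maturity/dispersal step never applies to them
    founder_birth = -1 - cfg.maturity_years
    per_pop = cfg.n_founders // 2
    for pop in POPULATIONS:
        n_pop = per_pop if pop == POPULATIONS[0] else cfg.n_founders - per_pop
        for k in range(n_pop):
            sex = "female" if k < n_pop / 2 else "male"
            new_bat(sex, None, None, founder_birth, pop)

    def resident(row, year):
        return (
            (np.isnan(row["death_year"]) or row["death_year"] > year)
            and (np.isnan(row["dispersal_year"]) or row["dispersal_year"] > year)
            and (np.isnan(row["arrival_year"]) or row["arrival_year"] <= year)
        )

    for year in range(cfg.n_years):
        # adult mortality
        for row in rows:
            if row["birth_year"] + cfg.maturity_years <= year and resident(row, year):
                if rng.random() > cfg.adult_survival:
                    row["death_year"] = year
        # natal dispersal: locally born bats face an annual emigration
        # hazard from maturity until they leave, so few natal males
        # remain as older adults
        for row in rows:
            if (
                row["mother_id"] is not None
                and row["birth_year"] + cfg.maturity_years <= year
                and resident(row, year)
            ):
                p = (
                    cfg.male_dispersal_prob
                    if row["sex"] == "male"
                    else cfg.female_dispersal_prob
                )
                if rng.random() < p:
                    row["dispersal_year"] = year
        # immigrant adult males (floaters replacing dispersing sons)
        for pop in POPULATIONS:
            for _ in range(int(rng.poisson(cfg.male_immigrants_per_year))):
                new_bat(
                    "male", None, None,
                    year - cfg.maturity_years, pop, arrival_year=year,
                )
        # births (<= 1 pup per female per year)
        for pop in POPULATIONS:
            adults = [
                r for r in rows
                if r["population"] == pop
                and r["birth_year"] + cfg.maturity_years <= year
                and resident(r, year)
            ]
            mothers = [r for r in adults if r["sex"] == "female"]
            fathers = [r for r in adults if r["sex"] == "male"]
            for mom in mothers:
                if rng.random() < cfg.pup_rate:
                    dad = fathers[rng.integers(len(fathers))] if fathers else None
                    sex = "female" if rng.random() < 0.5 else "male"
                    new_bat(sex, mom["id"], dad["id"] if dad else None, year, pop)
        n_resident = sum(1 for r in rows if resident(r, year))
        if n_resident == 0:
            warnings.warn(
                f"population extinct in year {year}; returning partial pedigree",
                stacklevel=2,
            )
            break
    return Pedigree(pd.DataFrame(rows))


def pedigree_relatedness(
    ped: Pedigree,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> RelatednessMatrix:
    """Dyadic relatedness r = 2 * kinship from the pedigree.

    Kinship is computed with the standard recursive (tabular)
    algorithm: phi(i, i) = 0.5 * (1 + phi(mother_i, father_i)) and,
    for j born no later than i, phi(i, j) = 0.5 * (phi(mother_i, j) +
    phi(father_i, j)), unknown parents contributing zero.  Optional
    zero-mean Gaussian noise (sd ``noise_sd``) is added symmetrically
    off-diagonal and clamped to [0, 1], emulating estimation error of
    a marker-based relatedness estimator.
    """
    t = ped.table.sort_values("birth_year", kind="mergesort").reset_index(drop=True)
    ids = list(t["id"])
    index = {b: i for i, b in enumerate(ids)}
    n = len(ids)
    mother = np.array(
        [index.get(m, -1) if isinstance(m, str) else -1 for m in t["mother_id"]]
    )
    father = np.array(
        [index.get(f, -1) if isinstance(f, str) else -1 for f in t["father_id"]]
    )
    K = np.zeros((n, n))
    for i in range(n):
        mi, fi = mother[i], father[i]
        if i > 0:
            row_m = K[mi, :i] if mi >= 0 else 0.0
            row_f = K[fi, :i] if fi >= 0 else 0.0
            K[i, :i] = 0.5 * (row_m + row_f)
            K[:i, i] = K[i, :i]
        K[i, i] = 0.5 * (1.0 + (K[mi, fi] if (mi >= 0 and fi >= 0) else 0.0))
    r = 2.0 * K
    # inbred pedigrees can push 2*phi above 1; the dyadic relatedness
    # contract (and marker-based estimators) are bounded by [0, 1]
    r = np.clip(r, 0.0, 1.0)
    np.fill_diagonal(r, 1.0)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        noise = rng.normal(0.0, noise_sd, size=(n, n))
        noise = np.triu(noise, k=1)
        noise = noise + noise.T
        r = np.clip(r + noise, 0.0, 1.0)
        np.fill_diagonal(r, 1.0)
    # return in pedigree id order
    order = np.array([index[b] for b in ped.ids])
    return RelatednessMatrix(ped.ids, r[np.ix_(order, order)])


@dataclass
class RoostingTruth:
    """True daily group memberships plus the roost registry.

    ``groups`` has one row per occupied roost-day: year, day, date,
    population, roost_id, members (tuple of bat ids, adults plus
    attached pups of the year).
    """

    groups: pd.DataFrame
    registry: RoostRegistry
    config: SimulationConfig = field(repr=False, default=None)


def _make_registry(cfg: SimulationConfig, rng: np.random.Generator) -> RoostRegistry:
    rows = []
    k = 0
    for p_idx, pop in enumerate(POPULATIONS):
        for _ in range(cfg.n_roosts_per_population):
            k += 1
            rows.append(
                {
                    "roost_id": f"R{k:03d}",
                    "population": pop,
                    "x": p_idx * cfg.population_separation_m
                    + rng.uniform(0.0, cfg.roost_span_m),
                    "y": rng.uniform(0.0, 100.0),
                }
            )
    return RoostRegistry(pd.DataFrame(rows), coordinates="planar")


def _dates_for(cfg: SimulationConfig, year: int) -> pd.DatetimeIndex:
    base = pd.Timestamp(year=2013 + year, month=1, day=1)
    step = max(1, 350 // max(1, cfg.days_per_year))
    return pd.DatetimeIndex([base + pd.Timedelta(days=int(d * step)) for d in range(cfg.days_per_year)])


def simulate_roosting(
    ped: Pedigree,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    registry: RoostRegistry | None = None,
    relatedness: RelatednessMatrix | None = None,
) -> RoostingTruth:
    """Simulate daily fission-fusion roosting for every study year.

    Each population keeps ``groups_per_day`` roosts open; every day
    each open roost relocates wholesale to an unused roost with
    probability ``roost_switch_prob``, then resident adults re-assort
    among the open roosts by the sequential-greedy score rule (see
    module docstring).  Pups of the year roost with their mother.
    Past association (the pi term) is the running fraction of days a
    dyad has co-roosted; the kappa term uses noise-free pedigree
    relatedness.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if registry is None:
        registry = _make_registry(cfg, rng)
    if relatedness is None:
        relatedness = pedigree_relatedness(ped)
    ids = ped.ids
    index = {b: i for i, b in enumerate(ids)}
    R = relatedness.r
    sex_map = ped.sex_of()
    is_male = np.array([sex_map[b] == "male" for b in ids])

    null_assembly = (
        cfg.kin_bias_strength == 0
        and cfg.partner_preference_strength == 0
        and cfg.male_avoidance == 0
        and cfg.crowding_penalty == 0
    )
    C = np.zeros((len(ids), len(ids)))  # co-roosting day counts (adults)
    n_days_total = 0

    roosts_by_pop = {
        pop: [r for r in registry.roost_ids if registry.population_of(r) == pop]
        for pop in POPULATIONS
    }
    open_roosts = {
        pop: list(rng.choice(roosts_by_pop[pop], size=cfg.groups_per_day, replace=False))
        for pop in POPULATIONS
    }

    out_rows = []
    for year in range(cfg.n_years):
        dates = _dates_for(cfg, year)
        present = ped.present(year, cfg.maturity_years)
        adults = ped.present_adults(year, cfg.maturity_years)
        pups = present[present["birth_year"] == year]
        pup_of_mother: dict[str, list[str]] = {}
        for _, row in pups.iterrows():
            if isinstance(row["mother_id"], str):
                pup_of_mother.setdefault(row["mother_id"], []).append(row["id"])
        adults_by_pop = {
            pop: [index[b] for b in adults[adults["population"] == pop]["id"]]
            for pop in POPULATIONS
        }
        for day in range(cfg.days_per_year):
            n_days_total += 1
            for pop in POPULATIONS:
                # wholesale group relocation to an empty roost
                slots = open_roosts[pop]
                for g in range(len(slots)):
                    if rng.random() < cfg.roost_switch_prob:
                        unused = [r for r in roosts_by_pop[pop] if r not in slots]
                        if unused:
                            slots[g] = unused[int(rng.integers(len(unused)))]
                bats = adults_by_pop[pop]
                if not bats:
                    continue
                order = rng.permutation(len(bats))
                G = cfg.groups_per_day
                if null_assembly:
                    choice = rng.integers(0, G, size=len(bats))
                    groups: list[list[int]] = [[] for _ in range(G)]
                    for k, b in enumerate(order):
                        groups[choice[k]].append(bats[b])
                else:
                    groups = [[] for _ in range(G)]
                    denom = max(1, n_days_total - 1)
                    for k in order:
                        b = bats[k]
                        scores = rng.gumbel(0.0, 1.0, size=G)
                        for g in range(G):
                            mem = groups[g]
                            if not mem:
                                continue
                            s = 0.0
                            if cfg.partner_preference_strength > 0:
                                s += cfg.partner_preference_strength * (
                                    C[b, mem].mean() / denom
                                )
                            if cfg.kin_bias_strength > 0 and not is_male[b]:
                                rb = R[b, mem]
                                fem = ~is_male[mem]
                                if fem.any():
                                    s += cfg.kin_bias_strength * rb[fem].mean()
                            if cfg.male_avoidance > 0 and is_male[b]:
                                s -= cfg.male_avoidance * is_male[mem].sum()
                            s -= cfg.crowding_penalty * len(mem)
                            scores[g] += s
                        groups[int(np.argmax(scores))].append(b)
                for g, mem in enumerate(groups):
                    if not mem:
                        continue
                    mem_idx = np.array(mem)
                    C[np.ix_(mem_idx, mem_idx)] += 1
                    member_ids = [ids[m] for m in mem]
                    for b in list(member_ids):
                        for pup in pup_of_mother.get(b, []):
                            member_ids.append(pup)
                    out_rows.append(
                        {
                            "year": 2013 + year,
                            "day": day,
                            "date": dates[day],
                            "population": pop,
                            "roost_id": slots[g],
                            "members": tuple(member_ids),
                        }
                    )
    np.fill_diagonal(C, 0)
    truth = RoostingTruth(pd.DataFrame(out_rows), registry, cfg)
    truth.co_roost_days = C
    truth.bat_ids = ids
    return truth


def sample_captures(
    truth: RoostingTruth,
    ped: Pedigree,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    return_truth: bool = False,
):
    """Sample group captures from the true roosting history.

    Per year, ``capture_events_per_year`` occupied roost-days are
    drawn without replacement; each bat present is recorded
    independently with ``detection_prob`` (bats sometimes escape the
    net).  Empty recorded groups are dropped.  Pups of the year are
    recorded as juveniles, everyone else as adults; reproductive
    status is scrotal for reproductive males (redrawn per year),
    pregnant or lactating for a share of adult females, unknown for
    juveniles.  Returns a :class:`CaptureDataset` in the records_io
    dialect (with the registry attached); with ``return_truth=True``
    also returns the sampled true groups for oracle tests.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sex_map = ped.sex_of()
    birth = ped.table.set_index("id")["birth_year"]
    repro_status: dict[tuple[str, int], str] = {}

    def status_of(bat: str, year_idx: int, age: str) -> str:
        if age == "juvenile":
            return "unknown"
        key = (bat, year_idx)
        if key not in repro_status:
            if sex_map[bat] == "male":
                repro_status[key] = (
                    "scrotal" if rng.random() < cfg.repro_male_prob else "nonreproductive"
                )
            else:
                u = rng.random()
                repro_status[key] = (
                    "pregnant" if u < 0.2 else "lactating" if u < 0.4 else "nonreproductive"
                )
        return repro_status[key]

    records = []
    sampled_rows = []
    groups = truth.groups
    year_iter = [] if groups.empty else groups.groupby("year")
    for cal_year, sub in year_iter:
        n_take = min(cfg.capture_events_per_year, len(sub))
        take = rng.choice(len(sub), size=n_take, replace=False)
        for i in sorted(take):
            row = sub.iloc[i]
            detected = [
                b for b in row["members"] if rng.random() < cfg.detection_prob
            ]
            sampled_rows.append({**row.to_dict(), "detected": tuple(detected)})
            year_idx = int(cal_year) - 2013
            for b in detected:
                age = "juvenile" if birth[b] == year_idx else "adult"
                records.append(
                    {
                        "bat_id": b,
                        "date": row["date"],
                        "roost_id": row["roost_id"],
                        "population": row["population"],
                        "sex": sex_map[b],
                        "age_class": age,
                        "repro_status": status_of(b, year_idx, age),
                    }
                )
    if not records:
        warnings.warn("no bats detected in any sampled capture", stacklevel=2)
    ds = CaptureDataset(
        pd.DataFrame(records, columns=CAPTURE_COLUMNS), registry=truth.registry
    )
    if return_truth:
        return ds, pd.DataFrame(sampled_rows)
    return ds


@dataclass
class SimulationBundle:
    """Everything one simulated study produces."""

    config: SimulationConfig
    pedigree: Pedigree
    relatedness: RelatednessMatrix
    truth: RoostingTruth
    dataset: CaptureDataset
    sampled_truth: pd.DataFrame

    def write(self, outdir) -> None:
        """Emit captures.csv, roosts.csv, relatedness.csv, truth.json."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_captures(self.dataset, out / "captures.csv")
        write_roosts(self.truth.registry, out / "roosts.csv")
        self.relatedness.write(out / "relatedness.csv")
        ped = self.pedigree.table.where(pd.notna(self.pedigree.table), None)
        truth = {
            "config": asdict(self.config),
            "pedigree": ped.to_dict(orient="records"),
            "true_groups": [
                {
                    "date": str(r["date"].date()),
                    "population": r["population"],
                    "roost_id": r["roost_id"],
                    "members": list(r["members"]),
                }
                for _, r in self.truth.groups.iterrows()
            ],
            "notes": {
                "roost_switch_prob": "order-of-magnitude choice; no published rate",
                "burn_in_and_thinning": "see PermutationConfig defaults",
            },
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, default=str)


def simulate_dataset(cfg: SimulationConfig) -> SimulationBundle:
    """Run pedigree -> relatedness -> roosting -> capture sampling end to end.

    A single generator seeded from ``cfg.seed`` drives every stage, so
    identical configs give bit-identical bundles.
    """
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    true_r = pedigree_relatedness(ped)
    truth = simulate_roosting(ped, cfg, rng, relatedness=true_r)
    ds, sampled = sample_captures(truth, ped, cfg, rng, return_truth=True)
    observed_r = (
        true_r
        if cfg.relatedness_noise_sd == 0
        else pedigree_relatedness(ped, cfg.relatedness_noise_sd, rng)
    )
    return SimulationBundle(cfg, ped, observed_r, truth, ds, sampled)
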
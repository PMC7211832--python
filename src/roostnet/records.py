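"""Capture records, roost registries, and relatedness matrices.

The sampling unit throughout is the *group capture*: a single netting
of all catchable occupants of one day roost on one date.  A capture
dataset is a table with one row per individual per group capture;
capture events are derived deterministically by grouping rows on
(date, roost).  Roosts belong to one of two genetically distinct
populations and never change population.

File dialects
-------------
captures.csv
    columns ``bat_id,date,roost_id,population,sex,age_class,repro_status``
    with ISO-8601 dates.
roosts.csv
    first line ``# coordinates: planar`` (metres, Euclidean distance) or
    ``# coordinates: geographic`` (lon/lat, great-circle distance), then
    columns ``roost_id,population,x,y``.
relatedness.csv
    square matrix with bat ids as header row and first column; empty
    cells are missing (ungenotyped) dyads.
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

CAPTURE_COLUMNS = [
    "bat_id",
    "date",
    "roost_id",
    "population",
    "sex",
    "age_class",
    "repro_status",
]

VALID_SEXES = {"female", "male"}
VALID_AGE_CLASSES = {"adult", "juvenile"}
VALID_REPRO_STATUS = {
    "pregnant",
    "lactating",
    "scrotal",
    "nonreproductive",
    "unknown",
}

EARTH_RADIUS_M = 6_371_000.0


class RecordsError(ValueError):
    """Invalid capture, roost, or relatedness input."""


@dataclass
class RoostRegistry:
    """Roost locations and population membership.

    Parameters
    ----------
    table : DataFrame with columns roost_id, population, x, y indexed
        by roost_id.
    coordinates : "planar" (x, y in metres) or "geographic"
        (x=longitude, y=latitude in decimal degrees).
    """

    table: pd.DataFrame
    coordinates: str = "planar"

    def __post_init__(self) -> None:
        if self.coordinates not in ("planar", "geographic"):
            raise RecordsError(
                f"unknown coordinate system {self.coordinates!r}; "
                "expected 'planar' or 'geographic'"
            )
        t = self.table.reset_index(drop=True).copy()
        t["roost_id"] = t["roost_id"].astype(str)
        t["population"] = t["population"].astype(str)
        if t["roost_id"].duplicated().any():
            dup = t.loc[t["roost_id"].duplicated(), "roost_id"].iloc[0]
            raise RecordsError(f"duplicate roost_id {dup!r} in registry")
        self.table = t.set_index("roost_id", drop=False)

    @property
    def roost_ids(self) -> list[str]:
        return list(self.table["roost_id"])

    def population_of(self, roost_id: str) -> str:
        return self.table.at[str(roost_id), "population"]

    def distance_matrix(self, roost_ids: list[str] | None = None) -> pd.DataFrame:
        """Pairwise distances in metres between roosts (symmetric, zero diagonal)."""
        ids = self.roost_ids if roost_ids is None else [str(r) for r in roost_ids]
        sub = self.table.loc[ids]
        xy = sub[["x", "y"]].to_numpy(float)
        if self.coordinates == "planar":
            d = squareform(pdist(xy))
        else:
            d = _haversine_matrix(lon=xy[:, 0], lat=xy[:, 1])
        return pd.DataFrame(d, index=ids, columns=ids)

    def distance(self, a: str, b: str) -> float:
        return float(self.distance_matrix([str(a), str(b)]).iloc[0, 1])


def _haversine_matrix(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lam = np.radians(lon)
    phi = np.radians(lat)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (
        np.sin(dphi / 2.0) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class CaptureDataset:
    """Validated capture records with derived capture events.

    ``records`` has one row per individual per group capture;
    ``events`` is derived by grouping on (date, roost_id) and has
    columns event_id, date, roost_id, population, year, size.
    """

    records: pd.DataFrame
    registry: RoostRegistry | None = None
    events: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.records = _validate_records(self.records, self.registry)
        self.events = _derive_events(self.records)

    # -- descriptive accessors -------------------------------------------------
    @property
    def bats(self) -> list[str]:
        return sorted(self.records["bat_id"].unique())

    @property
    def n_bats(self) -> int:
        return self.records["bat_id"].nunique()

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_roosts(self) -> int:
        return self.records["roost_id"].nunique()

    @property
    def n_observations(self) -> int:
        """Total individual-level observations (rows)."""
        return len(self.records)

    def sighting_counts(self) -> pd.Series:
        """Number of capture events in which each bat appears."""
        return (
            self.records.groupby("bat_id")["event_id"].nunique().sort_index()
        )

    def sex_of(self) -> pd.Series:
        """Sex per bat; error if a bat has conflicting sex records."""
        sexes = self.records.groupby("bat_id")["sex"].agg(set)
        bad = sexes[sexes.map(len) > 1]
        if len(bad):
            raise RecordsError(
                f"conflicting sex records for bat(s) {sorted(bad.index)}"
            )
        return sexes.map(lambda s: next(iter(s))).sort_index()

    def event_members(self) -> pd.Series:
        """event_id -> frozenset of member bat ids."""
        return self.records.groupby("event_id")["bat_id"].agg(frozenset)

    def summary(self) -> dict:
        sizes = self.events["size"]
        return {
            "n_bats": self.n_bats,
            "n_events": self.n_events,
            "n_roosts": self.n_roosts,
            "n_observations": self.n_observations,
            "group_size_min": int(sizes.min()) if len(sizes) else 0,
            "group_size_max": int(sizes.max()) if len(sizes) else 0,
            "group_size_median": float(sizes.median()) if len(sizes) else math.nan,
        }

    def write(self, path) -> None:
        write_captures(self, path)


def _validate_records(
    records: pd.DataFrame, registry: RoostRegistry | None
) -> pd.DataFrame:
    missing = [c for c in CAPTURE_COLUMNS if c not in records.columns and c != "repro_status"]
    if missing:
        raise RecordsError(f"missing required column(s): {missing}")
    df = records.copy().reset_index(drop=True)
    if "repro_status" not in df.columns:
        df["repro_status"] = "unknown"
    df["repro_status"] = df["repro_status"].fillna("unknown")
    for col in ("bat_id", "roost_id", "population", "sex", "age_class", "repro_status"):
        df[col] = df[col].astype(str).str.strip()
    df["sex"] = df["sex"].str.lower()
    df["age_class"] = df["age_class"].str.lower()
    df["repro_status"] = df["repro_status"].str.lower().replace({"nan": "unknown", "": "unknown"})

    bad_sex = ~df["sex"].isin(VALID_SEXES)
    if bad_sex.any():
        row = int(np.flatnonzero(bad_sex.to_numpy())[0])
        raise RecordsError(
            f"row {row}: unknown sex code {df.loc[row, 'sex']!r} "
            f"(expected one of {sorted(VALID_SEXES)})"
        )
    bad_age = ~df["age_class"].isin(VALID_AGE_CLASSES)
    if bad_age.any():
        row = int(np.flatnonzero(bad_age.to_numpy())[0])
        raise RecordsError(
            f"row {row}: unknown age class {df.loc[row, 'age_class']!r} "
            f"(expected one of {sorted(VALID_AGE_CLASSES)})"
        )
    bad_repro = ~df["repro_status"].isin(VALID_REPRO_STATUS)
    if bad_repro.any():
        row = int(np.flatnonzero(bad_repro.to_numpy())[0])
        raise RecordsError(
            f"row {row}: unknown reproductive status {df.loc[row, 'repro_status']!r}"
        )

    try:
        try:
            df["date"] = pd.to_datetime(df["date"], format="ISO8601")
        except (ValueError, TypeError):
            df["date"] = pd.to_datetime(df["date"])
        df["date"] = df["date"].dt.normalize()
    except (ValueError, TypeError) as exc:
        raise RecordsError(f"unparseable date in captures table: {exc}") from exc

    if registry is not None:
        known = set(registry.roost_ids)
        unknown = ~df["roost_id"].isin(known)
        if unknown.any():
            row = int(np.flatnonzero(unknown.to_numpy())[0])
            raise RecordsError(
                f"row {row}: roost_id {df.loc[row, 'roost_id']!r} "
                "not present in roost registry"
            )
        reg_pop = df["roost_id"].map(registry.table["population"])
        mismatch = reg_pop != df["population"]
        if mismatch.any():
            row = int(np.flatnonzero(mismatch.to_numpy())[0])
            raise RecordsError(
                f"row {row}: population {df.loc[row, 'population']!r} disagrees "
                f"with registry population {reg_pop.iloc[row]!r} "
                f"for roost {df.loc[row, 'roost_id']!r}"
            )

    # a roost's population never changes
    pops = df.groupby("roost_id")["population"].nunique()
    if (pops > 1).any():
        roost = pops[pops > 1].index[0]
        raise RecordsError(f"roost {roost!r} assigned to more than one population")

    dup = df.duplicated(subset=["bat_id", "date", "roost_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise RecordsError(
            f"row {row}: bat {df.loc[row, 'bat_id']!r} appears more than once "
            f"in the capture event ({df.loc[row, 'date'].date()}, "
            f"{df.loc[row, 'roost_id']!r})"
        )

    df = df.sort_values(["date", "roost_id", "bat_id"], kind="mergesort").reset_index(drop=True)
    df["event_id"] = (
        df["date"].dt.strftime("%Y-%m-%d") + "@" + df["roost_id"]
    )
    df["year"] = df["date"].dt.year
    return df


def _derive_events(records: pd.DataFrame) -> pd.DataFrame:
    if records.empty:
        return pd.DataFrame(
            columns=["event_id", "date", "roost_id", "population", "year", "size"]
        )
    ev = (
        records.groupby("event_id", sort=False)
        .agg(
            date=("date", "first"),
            roost_id=("roost_id", "first"),
            population=("population", "first"),
            year=("year", "first"),
            size=("bat_id", "size"),
        )
        .reset_index()
        .sort_values(["date", "roost_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return ev


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_captures(path, registry: RoostRegistry | None = None) -> CaptureDataset:
    """Read a captures.csv file into a validated :class:`CaptureDataset`.

    Rows are grouped into capture events on (date, roost_id).  Raises
    :class:`RecordsError` with the offending row for unknown roosts,
    duplicate bats within an event, or unknown sex/age codes.
    """
    df = pd.read_csv(path, dtype=str)
    ds = CaptureDataset(df, registry=registry)
    logger.info(
        "read %s: %d bats, %d events, %d roosts, %d observations",
        path, ds.n_bats, ds.n_events, ds.n_roosts, ds.n_observations,
    )
    return ds


def write_captures(ds: CaptureDataset, path) -> None:
    out = ds.records[CAPTURE_COLUMNS].copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_roosts(path) -> RoostRegistry:
    """Read a roosts.csv file (leading ``# coordinates:`` header line)."""
    with open(path) as fh:
        first = fh.readline().strip()
        rest = fh.read()
    if not first.lower().startswith("# coordinates:"):
        raise RecordsError(
            "roosts.csv must start with a '# coordinates: planar|geographic' line"
        )
    coords = first.split(":", 1)[1].strip().lower()
    df = pd.read_csv(io.StringIO(rest), dtype={"roost_id": str, "population": str})
    required = {"roost_id", "population", "x", "y"}
    if not required.issubset(df.columns):
        raise RecordsError(
            f"roosts.csv needs columns {sorted(required)}, got {list(df.columns)}"
        )
    return RoostRegistry(df, coordinates=coords)


def write_roosts(registry: RoostRegistry, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# coordinates: {registry.coordinates}\n")
        registry.table[["roost_id", "population", "x", "y"]].to_csv(fh, index=False)


@dataclass
class RelatednessMatrix:
    """Symmetric dyadic relatedness in [0, 1]; NaN marks ungenotyped dyads.

    The diagonal is ignored by all analyses.
    """

    ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.ids)
        if self.r.shape != (n, n):
            raise RecordsError(
                f"relatedness matrix shape {self.r.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise RecordsError("duplicate ids in relatedness matrix")
        off = ~np.eye(n, dtype=bool)
        vals = self.r[off]
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise RecordsError("relatedness values must lie in [0, 1]")
        asym = np.nanmax(np.abs(self.r - self.r.T)) if n else 0.0
        if n and not (np.isnan(asym) or asym < 1e-8):
            raise RecordsError("relatedness matrix is not symmetric")

    def subset(self, ids: list[str]) -> "RelatednessMatrix":
        index = {b: i for i, b in enumerate(self.ids)}
        missing = [b for b in ids if str(b) not in index]
        if missing:
            raise RecordsError(f"ids not in relatedness matrix: {missing}")
        idx = np.array([index[str(b)] for b in ids])
        return RelatednessMatrix([str(b) for b in ids], self.r[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.ids, columns=self.ids)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index_label="")


def read_relatedness(path) -> RelatednessMatrix:
    """Read a square relatedness CSV (ids on both axes, empty = missing)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise RecordsError("relatedness.csv row and column ids differ")
    return RelatednessMatrix(list(df.index), df.to_numpy(float))


# ---------------------------------------------------------------------------
# filtering and descriptive summaries
# ---------------------------------------------------------------------------

def filter_dataset(
    ds: CaptureDataset,
    adults_only: bool = True,
    min_sightings: int = 1,
    population: str | None = None,
) -> CaptureDataset:
    """Restrict a dataset to well-sampled bats.

    The adult/population filters are applied to the records first;
    ``min_sightings`` then counts capture events per bat *within the
    retained record set* (e.g. "captured at least four times as an
    adult"), and the dataset is restricted to the surviving bats'
    retained records.  Idempotent for fixed parameters.
    """
    if min_sightings < 1:
        raise RecordsError("min_sightings must be >= 1")
    rec = ds.records
    if adults_only:
        rec = rec[rec["age_class"] == "adult"]
    if population is not None:
        rec = rec[rec["population"] == str(population)]
    counts = rec.groupby("bat_id")["event_id"].nunique()
    keep = set(counts[counts >= min_sightings].index)
    rec = rec[rec["bat_id"].isin(keep)]
    if rec.empty:
        warnings.warn("filter_dataset produced an empty dataset", stacklevel=2)
    out = CaptureDataset(rec[CAPTURE_COLUMNS].copy(), registry=ds.registry)
    logger.info(
        "filter(adults_only=%s, min_sightings=%d, population=%s): %d -> %d bats",
        adults_only, min_sightings, population, ds.n_bats, out.n_bats,
    )
    return out


def sightings_threshold_curve(ds: CaptureDataset) -> pd.DataFrame:
    """Number of bats seen at least N times, for N = 1..max sightings.

    Monotonically non-increasing; the value at N=1 is the total number
    of bats.
    """
    counts = ds.sighting_counts()
    if counts.empty:
        return pd.DataFrame(columns=["N", "n_bats"]).astype(int)
    nmax = int(counts.max())
    rows = [(n, int((counts >= n).sum())) for n in range(1, nmax + 1)]
    return pd.DataFrame(rows, columns=["N", "n_bats"])


def group_composition_summary(ds: CaptureDataset) -> pd.DataFrame:
    """Per-event size, sex composition, and class (all-male/all-female/mixed).

    Class is computed from sex alone; reproductive males are adult
    males recorded as scrotal (with forearm crust).
    """
    rec = ds.records
    if rec.empty:
        return pd.DataFrame(
            columns=[
                "event_id", "date", "roost_id", "population", "size",
                "n_females", "n_males", "n_reproductive_males",
                "n_unknown_repro", "composition",
            ]
        )
    grp = rec.groupby("event_id", sort=False)
    out = grp.agg(
        date=("date", "first"),
        roost_id=("roost_id", "first"),
        population=("population", "first"),
        size=("bat_id", "size"),
        n_females=("sex", lambda s: int((s == "female").sum())),
        n_males=("sex", lambda s: int((s == "male").sum())),
    ).reset_index()
    repro_male = (rec["sex"] == "male") & (rec["repro_status"] == "scrotal")
    out["n_reproductive_males"] = (
        rec.assign(_rm=repro_male).groupby("event_id", sort=False)["_rm"].sum().to_numpy(int)
    )
    out["n_unknown_repro"] = (
        rec.assign(_u=rec["repro_status"] == "unknown")
        .groupby("event_id", sort=False)["_u"].sum().to_numpy(int)
    )
    comp = np.where(
        out["n_females"] == 0,
        "all-male",
        np.where(out["n_males"] == 0, "all-female", "mixed"),
    )
    out["composition"] = comp
    return out.sort_values(["date", "roost_id"], kind="mergesort").reset_index(drop=True)
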
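"""Group-by-individual matrices, simple ratio index, social differentiation.

Two bats are associated when they occupy the same day roost at the
same time, i.e. appear in the same capture event.  Dyadic association
is estimated with the simple ratio index (SRI)

    SRI = x / (x + y_ab + y_a + y_b)

where, over sampling periods, ``x`` counts periods in which the two
bats were in the same group, ``y_ab`` periods in which both were
observed but never together, and ``y_a`` / ``y_b`` periods in which
only one of the pair was observed.  The denominator therefore equals
the number of periods in which at least one of the pair was seen.

The default sampling period is (date, population): two bats captured
the same day in different roosts of one population count as seen
apart, while different populations are never co-sampled.  Setting
``period="event"`` treats every capture event as its own period, in
which case ``y_ab`` is structurally zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from roostnet.records import CaptureDataset

__all__ = [
    "GroupByIndividual",
    "AssociationMatrix",
    "build_gbi",
    "simple_ratio_index",
    "social_differentiation",
]


@dataclass
class GroupByIndividual:
    """Binary incidence matrix of capture events (rows) by bats (columns).

    ``events`` carries per-event metadata (event_id, date, roost_id,
    population, year) in row order; ``bats`` is the column order
    (lexicographic).  Row sums are group sizes, column sums per-bat
    sighting counts.
    """

    bats: list[str]
    events: pd.DataFrame
    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.int8)
        if self.M.shape != (len(self.events), len(self.bats)):
            raise ValueError(
                f"incidence matrix shape {self.M.shape} does not match "
                f"{len(self.events)} events x {len(self.bats)} bats"
            )
        if not np.isin(self.M, (0, 1)).all():
            raise ValueError("incidence matrix entries must be 0 or 1")

    @property
    def n_bats(self) -> int:
        return len(self.bats)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def group_sizes(self) -> np.ndarray:
        return self.M.sum(axis=1)

    def sighting_counts(self) -> np.ndarray:
        return self.M.sum(axis=0)

    def period_index(self, period: str = "date_population") -> np.ndarray:
        """Integer sampling-period label per event row."""
        if period == "event":
            return np.arange(self.n_events)
        if period == "date_population":
            key = (
                self.events["date"].astype(str)
                + "|"
                + self.events["population"].astype(str)
            )
            return pd.factorize(key)[0]
        raise ValueError(f"unknown sampling period {period!r}")


@dataclass
class AssociationMatrix:
    """Symmetric simple-ratio indices with their per-dyad denominators.

    ``sri[i, j]`` is NaN where ``denom[i, j] == 0`` (dyad never
    observed in any shared sampling period); such dyads are excluded
    from downstream statistics via :meth:`defined_mask`.
    """

    bats: list[str]
    sri: np.ndarray
    denom: np.ndarray

    def __post_init__(self) -> None:
        self.sri = np.asarray(self.sri, dtype=float)
        self.denom = np.asarray(self.denom, dtype=float)
        n = len(self.bats)
        if self.sri.shape != (n, n) or self.denom.shape != (n, n):
            raise ValueError("association matrices must be square over bats")

    @property
    def n_bats(self) -> int:
        return len(self.bats)

    def defined_mask(self) -> np.ndarray:
        """Boolean matrix: off-diagonal dyads with a nonzero denominator."""
        m = self.denom > 0
        np.fill_diagonal(m, False)
        return m

    def subset(self, bats: list[str]) -> "AssociationMatrix":
        index = {b: i for i, b in enumerate(self.bats)}
        missing = [b for b in bats if b not in index]
        if missing:
            raise KeyError(f"bats not in association matrix: {missing}")
        idx = np.array([index[b] for b in bats])
        return AssociationMatrix(
            list(bats), self.sri[np.ix_(idx, idx)], self.denom[np.ix_(idx, idx)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sri, index=self.bats, columns=self.bats)

    def write(self, path, denom_path=None) -> None:
        self.to_frame().to_csv(path, index_label="")
        if denom_path is not None:
            pd.DataFrame(self.denom, index=self.bats, columns=self.bats).to_csv(
                denom_path, index_label=""
            )


def build_gbi(ds: CaptureDataset) -> GroupByIndividual:
    """Build the group-by-individual matrix from a capture dataset.

    Events are ordered by (date, roost), bats lexicographically, so
    the construction is deterministic for a given dataset.
    """
    if ds.records.empty:
        raise ValueError("cannot build a group-by-individual matrix from an empty dataset")
    bats = ds.bats
    bat_index = {b: j for j, b in enumerate(bats)}
    events = ds.events[["event_id", "date", "roost_id", "population", "year"]].copy()
    ev_index = {e: i for i, e in enumerate(events["event_id"])}
    M = np.zeros((len(events), len(bats)), dtype=np.int8)
    rows = ds.records["event_id"].map(ev_index).to_numpy()
    cols = ds.records["bat_id"].map(bat_index).to_numpy()
    M[rows, cols] = 1
    return GroupByIndividual(bats, events, M)


def simple_ratio_index(
    gbi: GroupByIndividual, period: str = "date_population"
) -> AssociationMatrix:
    """Compute the simple ratio index for every dyad.

    Vectorised over sampling periods: per period, two bats were
    "together" if they share at least one capture event in it, "seen"
    if they appear in any event in it.
    """
    M = gbi.M.astype(np.int32)
    pidx = gbi.period_index(period)
    n = gbi.n_bats
    n_periods = int(pidx.max()) + 1 if len(pidx) else 0

    together = np.zeros((n, n), dtype=np.int64)
    seen = np.zeros((n_periods, n), dtype=bool)
    for p in range(n_periods):
        Mp = M[pidx == p]
        together += (Mp.T @ Mp) > 0
        seen[p] = Mp.any(axis=0)
    x = together.astype(float)
    seen_f = seen.astype(np.int64)
    both = seen_f.T @ seen_f  # periods with both bats observed
    s = seen_f.sum(axis=0)
    denom = s[:, None] + s[None, :] - both  # >= 1 of the pair observed
    denom_f = denom.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sri = np.where(denom > 0, x / np.where(denom > 0, denom, 1), np.nan)
    np.fill_diagonal(sri, np.nan)
    np.fill_diagonal(denom_f, 0.0)
    return AssociationMatrix(list(gbi.bats), sri, denom_f)


def social_differentiation(
    assoc: AssociationMatrix,
    dyad_mask: np.ndarray | None = None,
    ddof: int = 0,
) -> float:
    """Coefficient of variation of the SRI over defined dyads.

    Each unordered dyad is counted once; dyads with a zero denominator
    (and dyads outside ``dyad_mask``, if given) are excluded.  Uses the
    population standard deviation by default (``ddof=0``); pass
    ``ddof=1`` for the sample-sd convention.  Returns NaN when the mean
    SRI is zero (CV undefined).
    """
    mask = assoc.defined_mask()
    if dyad_mask is not None:
        mask = mask & np.asarray(dyad_mask, dtype=bool)
    iu = np.triu_indices(assoc.n_bats, k=1)
    vals = assoc.sri[iu][mask[iu]]
    if vals.size < 2:
        raise ValueError("social differentiation needs at least 2 defined dyads")
    mean = vals.mean()
    if mean == 0:
        return float("nan")
    return float(vals.std(ddof=ddof) / mean)
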
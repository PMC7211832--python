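"""Constrained datastream (pre-network) permutations and empirical p-values.

Null association networks are generated by repeatedly swapping pairs
of individual bat observations between capture events that share the
same population, roost, and calendar year.  For example, the identity
of bat 1 captured in a roost on day 1 of 2015 may be exchanged with
the identity of bat 3 captured in the same roost on day 4 of 2015.
Each swap preserves, exactly: every event's group size, every bat's
total sighting count, every bat's per-(roost, year, population) visit
counts, and the no-duplicate-within-event rule — so highly associated
dyads arising merely from shared roost preference or shared years
remain associated under the null, and only preference beyond those
confounds is tested.

Sampled networks are emitted on an accepted-swap clock after a burn-in,
and the whole stream is reproducible from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterator

import numpy as np
import pandas as pd

from roostnet.association import (
    AssociationMatrix,
    GroupByIndividual,
    simple_ratio_index,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationConfig",
    "PermutationState",
    "DegenerateStrataError",
    "attempt_swap",
    "generate_null_networks",
    "null_association_matrices",
    "empirical_p",
    "PValue",
]


class DegenerateStrataError(RuntimeError):
    """No valid observation swap exists in any stratum."""


@dataclass
class PermutationConfig:
    """Settings for the datastream permutation null.

    ``n_networks`` defaults to the 5000 networks used for the headline
    tests.  ``burn_in_swaps`` and ``swaps_per_sample`` count *accepted*
    swaps (rejected proposals do not advance the clock) and follow
    common datastream-permutation practice; they are not derived from
    any published value and should be checked against a mixing
    diagnostic for new datasets.
    """

    n_networks: int = 5000
    swaps_per_sample: int = 100
    burn_in_swaps: int = 1000
    seed: int | None = None
    period: str = "date_population"

    def __post_init__(self) -> None:
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")
        if self.swaps_per_sample < 1:
            raise ValueError("swaps_per_sample must be >= 1")
        if self.burn_in_swaps < 0:
            raise ValueError("burn_in_swaps must be >= 0")


class PermutationState:
    """Mutable observation table indexed by (population, roost, year) strata.

    Each observation is one bat-in-event record.  Swaps exchange the
    bat identities of two observations within one stratum; the event
    and stratum of every observation slot never change, so all
    conservation invariants hold by construction.
    """

    def __init__(self, gbi: GroupByIndividual):
        self.bats = list(gbi.bats)
        self.events = gbi.events.reset_index(drop=True)
        rows, cols = np.nonzero(gbi.M)
        self.event_of_obs = rows.astype(np.int64)
        self.bat_of_obs = cols.astype(np.int64)
        key = (
            self.events["population"].astype(str)
            + "|"
            + self.events["roost_id"].astype(str)
            + "|"
            + self.events["year"].astype(str)
        )
        self.stratum_of_event = pd.factorize(key)[0]
        strat_of_obs = self.stratum_of_event[self.event_of_obs]
        n_strata = int(self.stratum_of_event.max()) + 1
        self.stratum_obs = [
            np.flatnonzero(strat_of_obs == s) for s in range(n_strata)
        ]
        self.eligible_strata = np.array(
            [s for s in range(n_strata) if len(self.stratum_obs[s]) >= 2],
            dtype=np.int64,
        )
        self.members: list[set[int]] = [set() for _ in range(len(self.events))]
        for e, b in zip(self.event_of_obs, self.bat_of_obs):
            self.members[e].add(int(b))
        self.n_accepted = 0
        self.n_rejected = 0

    @property
    def n_obs(self) -> int:
        return len(self.bat_of_obs)

    def has_valid_swap(self) -> bool:
        """Whether any stratum admits at least one valid swap."""
        for s in self.eligible_strata:
            obs = self.stratum_obs[s]
            for i in range(len(obs)):
                e1 = self.event_of_obs[obs[i]]
                b1 = int(self.bat_of_obs[obs[i]])
                for j in range(i + 1, len(obs)):
                    e2 = self.event_of_obs[obs[j]]
                    b2 = int(self.bat_of_obs[obs[j]])
                    if (
                        e1 != e2
                        and b1 != b2
                        and b2 not in self.members[e1]
                        and b1 not in self.members[e2]
                    ):
                        return True
        return False

    def incidence(self) -> np.ndarray:
        M = np.zeros((len(self.events), len(self.bats)), dtype=np.int8)
        M[self.event_of_obs, self.bat_of_obs] = 1
        return M

    def to_gbi(self) -> GroupByIndividual:
        return GroupByIndividual(list(self.bats), self.events.copy(), self.incidence())

    def check_invariants(self, reference: GroupByIndividual) -> None:
        """Assert the conservation invariants against the original matrix."""
        M0 = np.asarray(reference.M, dtype=np.int64)
        M = self.incidence().astype(np.int64)
        if not np.array_equal(M.sum(axis=1), M0.sum(axis=1)):
            raise AssertionError("event group sizes not conserved")
        if not np.array_equal(M.sum(axis=0), M0.sum(axis=0)):
            raise AssertionError("per-bat sighting counts not conserved")
        # per-bat visit counts within each (population, roost, year) stratum
        n_strata = int(self.stratum_of_event.max()) + 1
        for s in range(n_strata):
            ev = self.stratum_of_event == s
            if not np.array_equal(M[ev].sum(axis=0), M0[ev].sum(axis=0)):
                raise AssertionError(
                    "per-bat stratum visit counts not conserved"
                )
        for e in range(M.shape[0]):
            if len(self.members[e]) != M[e].sum():
                raise AssertionError("duplicate bat within an event")


def attempt_swap(state: PermutationState, rng: np.random.Generator) -> bool:
    """Propose one observation swap; mutate ``state`` iff it is valid.

    A stratum is chosen uniformly among strata holding >= 2
    observations, then two distinct observations uniformly within it.
    The proposal is accepted iff the observations sit in different
    events, carry different bats, and neither bat already belongs to
    the other's event; otherwise the state is left unchanged and the
    rejection counted.
    """
    n_elig = len(state.eligible_strata)
    if n_elig == 0:
        raise DegenerateStrataError(
            "no stratum holds two observations; the dataset is too small to permute"
        )
    s = state.eligible_strata[rng.integers(n_elig)]
    obs = state.stratum_obs[s]
    m = len(obs)
    k1 = int(rng.integers(m))
    k2 = int(rng.integers(m - 1))
    if k2 >= k1:
        k2 += 1
    o1, o2 = int(obs[k1]), int(obs[k2])
    e1, e2 = int(state.event_of_obs[o1]), int(state.event_of_obs[o2])
    b1, b2 = int(state.bat_of_obs[o1]), int(state.bat_of_obs[o2])
    if e1 == e2 or b1 == b2 or b2 in state.members[e1] or b1 in state.members[e2]:
        state.n_rejected += 1
        return False
    state.bat_of_obs[o1] = b2
    state.bat_of_obs[o2] = b1
    state.members[e1].discard(b1)
    state.members[e1].add(b2)
    state.members[e2].discard(b2)
    state.members[e2].add(b1)
    state.n_accepted += 1
    return True


_MAX_REJECTS_PER_ACCEPT = 100_000


def _advance(state: PermutationState, rng: np.random.Generator, n_accept: int) -> None:
    done = 0
    rejects = 0
    while done < n_accept:
        if attempt_swap(state, rng):
            done += 1
            rejects = 0
        else:
            rejects += 1
            if rejects >= _MAX_REJECTS_PER_ACCEPT:
                raise DegenerateStrataError(
                    "swap acceptance stalled; strata are (nearly) degenerate"
                )


def generate_null_networks(
    gbi: GroupByIndividual,
    cfg: PermutationConfig,
    stat_fn: Callable[[AssociationMatrix], float] | None = None,
    sink=None,
    return_gbi: bool = False,
) -> Iterator[AssociationMatrix | GroupByIndividual]:
    """Stream null association networks from constrained datastream swaps.

    Performs ``cfg.burn_in_swaps`` accepted swaps, then yields one
    network every ``cfg.swaps_per_sample`` accepted swaps,
    ``cfg.n_networks`` times.  Identical (gbi, cfg) and seed give a
    bit-identical stream.  If ``stat_fn`` is given, its value on each
    sampled network is written to ``sink`` (a file-like object) as
    ``network_index,statistic`` lines.

    With ``return_gbi=True`` the permuted group-by-individual matrices
    are yielded instead of association matrices.
    """
    state = PermutationState(gbi)
    if not state.has_valid_swap():
        raise DegenerateStrataError(
            "no valid swap exists in any (population, roost, year) stratum; "
            "the permutation null needs a larger or denser dataset"
        )
    rng = np.random.default_rng(cfg.seed)
    _advance(state, rng, cfg.burn_in_swaps)
    for i in range(cfg.n_networks):
        _advance(state, rng, cfg.swaps_per_sample)
        if return_gbi:
            yield state.to_gbi()
            continue
        net = simple_ratio_index(state.to_gbi(), period=cfg.period)
        if stat_fn is not None and sink is not None:
            sink.write(f"{i},{stat_fn(net)}\n")
        yield net


def null_association_matrices(
    gbi: GroupByIndividual, cfg: PermutationConfig
) -> list[AssociationMatrix]:
    """Materialise the null-network stream as a list."""
    return list(generate_null_networks(gbi, cfg))


@dataclass(frozen=True)
class PValue:
    """Empirical p-value with its permutation count and zero-count bound.

    When the extreme-tail count is zero the p-value is reported as the
    bound "< 1/n" rather than 0, mirroring the convention of printing
    p < 0.0002 for 5000 permutations.
    """

    value: float
    n: int
    bound: bool = False

    def __float__(self) -> float:
        return self.value

    @property
    def reportable(self) -> float:
        """Numeric value for thresholding: 1/n when at the zero-count bound."""
        return 1.0 / self.n if self.bound else self.value

    def __str__(self) -> str:
        if self.bound:
            return f"< {1.0 / self.n:g}"
        return f"{self.value:g}"


def empirical_p(
    observed: float,
    nulls,
    alternative: str = "two-sided-doubled",
) -> PValue:
    """Empirical p-value of an observed statistic against null samples.

    One-sided p is the proportion of null values at least as extreme
    as the observed (ties count as extreme); the two-sided value is
    twice the smaller one-sided p, capped at 1.
    """
    nulls = np.asarray(list(nulls), dtype=float)
    if nulls.size == 0:
        raise ValueError("empirical_p needs at least one null value")
    if np.isnan(observed):
        raise ValueError("observed statistic is NaN")
    nulls = nulls[~np.isnan(nulls)]  # +-inf kept: ordering is well defined
    n = nulls.size
    if n == 0:
        raise ValueError("all null values are NaN")
    kg = int((nulls >= observed).sum())
    kl = int((nulls <= observed).sum())
    if alternative == "greater":
        return PValue(kg / n, n, bound=kg == 0)
    if alternative == "less":
        return PValue(kl / n, n, bound=kl == 0)
    if alternative == "two-sided-doubled":
        kmin = min(kg, kl)
        return PValue(min(1.0, 2.0 * kmin / n), n, bound=kmin == 0)
    raise ValueError(f"unknown alternative {alternative!r}")
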
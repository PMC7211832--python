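"""Permutation tests on per-individual summaries.

Covers sex differences in roost use (number of roosts, roost-switch
rate, spread of the roosts a bat uses), the variance test of
sex-biased philopatry on juvenile-to-adult recapture spans, and the
resampling null for the relatedness of the two reproductive males in
two-male groups.  All inference is by label permutation or resampling
— no parametric t/F reference distributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from roostnet.permutations import PValue, empirical_p
from roostnet.records import CaptureDataset, RelatednessMatrix, RoostRegistry

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationTestResult",
    "roost_use_summaries",
    "permuted_mean_diff_test",
    "permuted_variance_ratio_test",
    "juvenile_recapture_spans",
    "two_male_relatedness_null",
]


@dataclass
class PermutationTestResult:
    """One permutation test: statistic, empirical p, and bookkeeping."""

    statistic: float
    p: PValue
    n: int
    groups: tuple[str, str]
    n_perm: int
    exact: bool = False

    def __str__(self) -> str:
        return (
            f"{self.groups[0]} vs {self.groups[1]}: statistic = "
            f"{self.statistic:.4g}, n = {self.n}, p {self.p}"
        )


def _split_groups(values, labels, group_order=None):
    values = np.asarray(values, dtype=float)
    labels = np.asarray([str(x) for x in labels])
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    uniq = list(dict.fromkeys(labels))
    if group_order is not None:
        group_order = [str(g) for g in group_order]
        if set(group_order) != set(uniq):
            raise ValueError(
                f"group_order {group_order} does not match labels {sorted(uniq)}"
            )
        uniq = group_order
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    g1 = values[labels == uniq[0]]
    g2 = values[labels == uniq[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be non-empty")
    return values, g1, g2, (uniq[0], uniq[1])


def _exhaustible(n, k, limit=400):
    from math import comb

    return comb(n, k) <= limit


def _permutation_pvalue(values, n1, stat_fn, observed, n_perm, seed, exact):
    """Null statistics from label shuffles; exhaustive when requested."""
    n = len(values)
    if exact:
        nulls = np.array(
            [stat_fn(values[list(idx)], np.delete(values, list(idx)))
             for idx in combinations(range(n), n1)]
        )
    else:
        rng = np.random.default_rng(seed)
        nulls = np.empty(n_perm)
        for k in range(n_perm):
            perm = rng.permutation(n)
            nulls[k] = stat_fn(values[perm[:n1]], values[perm[n1:]])
    return empirical_p(observed, nulls), len(nulls)


def permuted_mean_diff_test(
    values,
    labels,
    n_perm: int = 10_000,
    seed: int | None = None,
    group_order=None,
    exact: bool = False,
) -> PermutationTestResult:
    """Permuted t-test analogue: difference of group means under label shuffles.

    The statistic is mean(group1) - mean(group2) in the declared (or
    first-appearance) group order; the p-value is the two-sided-doubled
    empirical proportion over ``n_perm`` random label permutations, or
    over all distinct splits when ``exact`` is set.
    """
    values, g1, g2, groups = _split_groups(values, labels, group_order)
    observed = float(g1.mean() - g2.mean())

    def stat(a, b):
        return a.mean() - b.mean()

    if exact and not _exhaustible(len(values), len(g1)):
        raise ValueError("too many label splits for exact enumeration")
    p, n_used = _permutation_pvalue(values, len(g1), stat, observed, n_perm, seed, exact)
    return PermutationTestResult(observed, p, len(values), groups, n_used, exact)


def permuted_variance_ratio_test(
    values,
    labels,
    n_perm: int = 5_000,
    seed: int | None = None,
    group_order=None,
    exact: bool = False,
) -> PermutationTestResult:
    """Permuted F-test analogue: ratio of group variances under label shuffles.

    F = var(group1) / var(group2) with sample variances (ddof=1) and
    groups in the declared order; the report always states that
    orientation via ``groups``.  A zero-variance denominator flags the
    statistic infinite; the permutation p-value is still defined.
    """
    values, g1, g2, groups = _split_groups(values, labels, group_order)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both groups need >= 2 values for a variance ratio")

    def stat(a, b):
        vb = b.var(ddof=1)
        if vb == 0:
            return np.inf
        return a.var(ddof=1) / vb

    observed = float(stat(g1, g2))
    if not np.isfinite(observed):
        warnings.warn("denominator group has zero variance; F is infinite", stacklevel=2)
    if exact and not _exhaustible(len(values), len(g1)):
        raise ValueError("too many label splits for exact enumeration")
    # rank on log scale so inf/0 tails behave; empirical_p only compares order
    p, n_used = _permutation_pvalue(values, len(g1), stat, observed, n_perm, seed, exact)
    return PermutationTestResult(observed, p, len(values), groups, n_used, exact)


def roost_use_summaries(
    ds: CaptureDataset, registry: RoostRegistry | None = None
) -> pd.DataFrame:
    """Per-bat roost-use table.

    Columns: sex, n_roosts_used, n_visits (capture events),
    switch_rate = n_roosts_used / n_visits, and
    mean_pairwise_distance_m over unordered pairs of distinct roosts
    used (0 for single-roost bats; NaN if coordinates are missing).
    The caller is responsible for any minimum-sightings filter (the
    roost-switching rate is meaningful for bats captured four or more
    times).
    """
    if registry is None:
        registry = ds.registry
    sex = ds.sex_of()
    rows = []
    dist = registry.distance_matrix() if registry is not None else None
    for bat, sub in ds.records.groupby("bat_id"):
        roosts = sorted(sub["roost_id"].unique())
        n_visits = sub["event_id"].nunique()
        if len(roosts) == 1:
            mean_d = 0.0
        elif dist is None or any(r not in dist.index for r in roosts):
            mean_d = np.nan
        else:
            pairs = [dist.at[a, b] for a, b in combinations(roosts, 2)]
            mean_d = float(np.mean(pairs))
        rows.append(
            (bat, sex[bat], len(roosts), n_visits, len(roosts) / n_visits, mean_d)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "bat_id", "sex", "n_roosts_used", "n_visits",
            "switch_rate", "mean_pairwise_distance_m",
        ],
    ).set_index("bat_id")


def juvenile_recapture_spans(ds: CaptureDataset) -> pd.DataFrame:
    """Days between first juvenile capture and last adult capture, per bat.

    Only bats captured as a juvenile *and* later recaptured as an
    adult appear; spans are nonnegative day counts.
    """
    rec = ds.records
    juv = rec[rec["age_class"] == "juvenile"].groupby("bat_id")["date"].min()
    adult = rec[rec["age_class"] == "adult"].groupby("bat_id")["date"].max()
    both = juv.index.intersection(adult.index)
    both = [b for b in both if adult[b] >= juv[b]]
    sex = ds.sex_of()
    out = pd.DataFrame(
        {
            "sex": [sex[b] for b in both],
            "span_days": [int((adult[b] - juv[b]).days) for b in both],
        },
        index=pd.Index(both, name="bat_id"),
    )
    return out.sort_index()


def two_male_relatedness_null(
    ds: CaptureDataset,
    relatedness: RelatednessMatrix,
    n_draws: int = 5000,
    seed: int | None = None,
    pool: str = "population_year",
) -> dict:
    """Resampling null for the relatedness of two-reproductive-male groups.

    Finds capture events containing exactly two reproductive (scrotal)
    males and averages their dyadic relatedness.  The null draws, for
    each such group, two distinct adult males captured in the same
    population and calendar year (``pool="roost"`` narrows to the same
    roost), averages across groups, and repeats ``n_draws`` times; the
    95% CI is the 2.5/97.5 percentile band of the replicate means.
    Groups whose resampling pool holds fewer than two genotyped males
    are skipped with a warning.
    """
    if pool not in ("population_year", "roost"):
        raise ValueError("pool must be 'population_year' or 'roost'")
    rec = ds.records
    rel = relatedness.to_frame()
    known = set(relatedness.ids)

    males = rec[(rec["sex"] == "male") & (rec["age_class"] == "adult")]
    repro = males[males["repro_status"] == "scrotal"]
    two_male_events = [
        e for e, sub in repro.groupby("event_id") if len(sub) == 2
    ]

    observed_pairs = []
    pools = []
    for e in two_male_events:
        pair = sorted(repro.loc[repro["event_id"] == e, "bat_id"])
        ev = rec[rec["event_id"] == e].iloc[0]
        if pool == "roost":
            cand = males[
                (males["roost_id"] == ev["roost_id"]) & (males["year"] == ev["year"])
            ]
        else:
            cand = males[
                (males["population"] == ev["population"]) & (males["year"] == ev["year"])
            ]
        cand_ids = sorted(set(cand["bat_id"]) & known)
        if pair[0] not in known or pair[1] not in known:
            warnings.warn(
                f"event {e}: male pair not fully genotyped; skipped", stacklevel=2
            )
            continue
        if len(cand_ids) < 2:
            warnings.warn(
                f"event {e}: fewer than two genotyped adult males in the "
                "resampling pool; skipped",
                stacklevel=2,
            )
            continue
        r = rel.at[pair[0], pair[1]]
        if not np.isfinite(r):
            warnings.warn(f"event {e}: pair relatedness missing; skipped", stacklevel=2)
            continue
        observed_pairs.append(float(r))
        pools.append(cand_ids)

    if not observed_pairs:
        raise ValueError("no usable two-reproductive-male groups found")

    observed_mean = float(np.mean(observed_pairs))
    rng = np.random.default_rng(seed)
    reps = np.empty(n_draws)
    pool_arrays = [np.array(p) for p in pools]
    for k in range(n_draws):
        vals = []
        for arr in pool_arrays:
            i, j = rng.choice(len(arr), size=2, replace=False)
            v = rel.at[arr[i], arr[j]]
            # redraw around missing dyads rather than biasing toward 0
            tries = 0
            while not np.isfinite(v) and tries < 20:
                i, j = rng.choice(len(arr), size=2, replace=False)
                v = rel.at[arr[i], arr[j]]
                tries += 1
            if np.isfinite(v):
                vals.append(float(v))
        reps[k] = np.mean(vals) if vals else np.nan
    reps = reps[np.isfinite(reps)]
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return {
        "observed_mean": observed_mean,
        "ci_95": (float(lo), float(hi)),
        "n_groups": len(observed_pairs),
        "n_draws": int(reps.size),
        "null_means": reps,
    }
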
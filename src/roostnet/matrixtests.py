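"""Dyadic matrix statistics: Mantel tests and QAP regression.

Both procedures operate on the vectorised lower triangles of aligned
square matrices, restricted to dyads that are defined in every input
(listwise deletion of undefined dyads).  Inference is by permutation:

* Mantel — Pearson correlation between two dyadic matrices, with a
  null built by jointly permuting the row/column labels of the second
  matrix (node permutation).
* QAP regression — ordinary least squares of a response matrix on one
  or more predictor matrices over dyads, with null coefficients from
  either node permutation of the response or, for association
  responses, a *custom* null: re-fitting against each pre-network
  permuted association matrix (see :mod:`roostnet.permutations`),
  which preserves roost/year/population confounds under the null.

Two-sided p-values are twice the smaller one-sided tail proportion
(capped at 1), with zero counts reported as "< 1/n".
"""

from __future__ import annotations

import logging

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from roostnet.association import AssociationMatrix
from roostnet.permutations import PValue, empirical_p
from roostnet.records import RelatednessMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MantelResult",
    "DyadTypeMatrix",
    "QapResult",
    "mantel",
    "dyad_type_matrix",
    "qap_regression",
    "kin_bias_suite",
]

DYAD_TYPES = ("female-female", "male-male", "female-male")


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, AssociationMatrix):
        return m.sri
    if isinstance(m, RelatednessMatrix):
        return m.r
    if isinstance(m, DyadTypeMatrix):
        return m.B.astype(float)
    return np.asarray(m, dtype=float)


def _check_square(mats: Sequence[np.ndarray]) -> int:
    n = mats[0].shape[0]
    for m in mats:
        if m.shape != (n, n):
            raise ValueError("all matrices must be square and share one bat ordering")
    return n


def _defined_mask(mats: Sequence[np.ndarray], mask: np.ndarray | None) -> np.ndarray:
    n = _check_square(mats)
    out = np.ones((n, n), dtype=bool)
    for m in mats:
        out &= np.isfinite(m)
    if mask is not None:
        out &= np.asarray(mask, dtype=bool)
    np.fill_diagonal(out, False)
    # a dyad is kept only if defined in both orientations
    out &= out.T
    return out


def _tri_vector(m: np.ndarray, mask: np.ndarray) -> np.ndarray:
    il = np.tril_indices(m.shape[0], k=-1)
    keep = mask[il]
    return m[il][keep]


@dataclass
class MantelResult:
    r: float
    p: PValue
    n_bats: int
    n_dyads: int
    n_perm: int

    def __str__(self) -> str:
        return f"Mantel r = {self.r:.3g} (n = {self.n_bats} bats, p {self.p})"


def mantel(
    A,
    B,
    n_perm: int = 5000,
    seed: int | None = None,
    mask: np.ndarray | None = None,
    alternative: str = "two-sided-doubled",
) -> MantelResult:
    """Mantel test: Pearson correlation between two dyadic matrices.

    ``r`` is computed over the vectorised lower triangles of the
    defined dyads; the null distribution re-computes r after jointly
    permuting the rows and columns of ``B``.  Matrices must share one
    bat ordering.
    """
    a, b = _as_matrix(A), _as_matrix(B)
    n = _check_square([a, b])
    if n < 3:
        raise ValueError("mantel needs at least 3 individuals")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    m = _defined_mask([a, b], mask)
    va = _tri_vector(a, m)
    if va.size < 3:
        raise ValueError("fewer than 3 defined dyads")
    vb = _tri_vector(b, m)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return MantelResult(float("nan"), PValue(float("nan"), n_perm, False), n, va.size, n_perm)
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)]
        mp = m  # the defined mask follows A's frame; B is fully defined on it or NaNs permute
        vbp = _tri_vector(bp, mp)
        ok = np.isfinite(vbp)
        if ok.all():
            nulls[k] = np.corrcoef(va, vbp)[0, 1]
        else:
            nulls[k] = np.corrcoef(va[ok], vbp[ok])[0, 1]
    p = empirical_p(r_obs, nulls, alternative=alternative)
    return MantelResult(r_obs, p, n, va.size, n_perm)


@dataclass
class DyadTypeMatrix:
    """Binary indicator of one dyad sex combination.

    Over bats of known sex the three type matrices partition all
    off-diagonal dyads: exactly one of female-female, male-male,
    female-male is 1 for every dyad.
    """

    bats: list[str]
    B: np.ndarray
    type: str

    def __post_init__(self) -> None:
        if self.type not in DYAD_TYPES:
            raise ValueError(f"dyad type must be one of {DYAD_TYPES}")
        self.B = np.asarray(self.B, dtype=np.int8)


def dyad_type_matrix(
    sexes: Mapping[str, str] | pd.Series,
    dyad_type: str,
    bats: Sequence[str] | None = None,
) -> DyadTypeMatrix:
    """Indicator matrix for one dyad type (female-female, male-male, female-male).

    ``sexes`` maps bat id -> "female"/"male"; ``bats`` fixes the
    ordering (defaults to sorted ids of ``sexes``).  Unknown sex is an
    error.
    """
    if dyad_type not in DYAD_TYPES:
        raise ValueError(f"dyad type must be one of {DYAD_TYPES}")
    sexes = dict(sexes)
    order = [str(b) for b in (bats if bats is not None else sorted(sexes))]
    sx = []
    for b in order:
        s = sexes.get(b)
        if s not in ("female", "male"):
            raise ValueError(f"bat {b!r} has unknown sex {s!r}")
        sx.append(s)
    female = np.array([s == "female" for s in sx])
    if dyad_type == "female-female":
        B = np.outer(female, female)
    elif dyad_type == "male-male":
        B = np.outer(~female, ~female)
    else:
        B = np.outer(female, ~female) | np.outer(~female, female)
    B = B.astype(np.int8)
    np.fill_diagonal(B, 0)
    return DyadTypeMatrix(order, B, dyad_type)


@dataclass
class QapResult:
    """OLS coefficients over dyads with permutation p-values.

    ``null_source`` records whether the reference distribution came
    from node permutation of the response or from custom (datastream
    permuted) null networks.
    """

    names: list[str]
    beta: np.ndarray
    p: list[PValue]
    null_betas: np.ndarray  # (n_null, n_coef)
    n_bats: int
    n_dyads: int
    null_source: str

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def pvalue(self, name: str) -> PValue:
        return self.p[self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "beta": self.beta,
                "p": [str(pv) for pv in self.p],
                "p_numeric": [pv.reportable for pv in self.p],
                "n_null": [pv.n for pv in self.p],
            }
        )


def _ols_beta(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def _design(
    predictors: Sequence[np.ndarray], mask: np.ndarray, names: Sequence[str],
    standardize: bool,
) -> np.ndarray:
    cols = [np.ones(int(mask[np.tril_indices(mask.shape[0], k=-1)].sum()))]
    for m in predictors:
        v = _tri_vector(m, mask)
        if standardize and v.std() > 0:
            v = (v - v.mean()) / v.std()
        cols.append(v)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        offending = []
        for j in range(1, X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
                offending.append(names[j - 1])
        raise ValueError(
            f"collinear predictor matrices over defined dyads: {offending or list(names)}"
        )
    return X


def qap_regression(
    response,
    predictors,
    null: str | Iterable = "node-permutation",
    n_perm: int = 5000,
    seed: int | None = None,
    mask: np.ndarray | None = None,
    names: Sequence[str] | None = None,
    standardize: bool = False,
) -> QapResult:
    """QAP regression of a dyadic response on dyadic predictors.

    Coefficients are ordinary least squares (intercept included) over
    the vectorised defined lower-triangle dyads, on the raw matrix
    scale unless ``standardize`` is set.  Null coefficients come from

    * ``null="node-permutation"`` — jointly permuting rows/columns of
      the response and re-fitting, ``n_perm`` times; or
    * ``null=<iterable of matrices>`` — re-fitting each supplied
      (e.g. pre-network permuted) association matrix as the response
      against the *unpermuted* predictors.

    p-values per coefficient are two-sided-doubled empirical
    proportions.
    """
    if isinstance(predictors, (np.ndarray, AssociationMatrix, RelatednessMatrix, DyadTypeMatrix)):
        predictors = [predictors]
    pred_mats = [_as_matrix(p) for p in predictors]
    if names is None:
        names = []
        for i, p in enumerate(predictors):
            if isinstance(p, DyadTypeMatrix):
                names.append(p.type)
            elif isinstance(p, RelatednessMatrix):
                names.append("relatedness")
            else:
                names.append(f"x{i + 1}")
    names = list(names)
    y_mat = _as_matrix(response)
    m = _defined_mask([y_mat] + pred_mats, mask)
    n = y_mat.shape[0]
    y = _tri_vector(y_mat, m)
    if y.size <= len(pred_mats) + 1:
        raise ValueError("not enough defined dyads for the regression")
    X = _design(pred_mats, m, names, standardize)
    beta = _ols_beta(y, X)

    if isinstance(null, str):
        if null != "node-permutation":
            raise ValueError(f"unknown null {null!r}")
        rng = np.random.default_rng(seed)
        null_betas = np.empty((n_perm, X.shape[1]))
        for k in range(n_perm):
            perm = rng.permutation(n)
            yp_mat = y_mat[np.ix_(perm, perm)]
            yp = _tri_vector(yp_mat, m)
            ok = np.isfinite(yp)
            if ok.all():
                null_betas[k] = _ols_beta(yp, X)
            else:
                null_betas[k] = _ols_beta(yp[ok], X[ok])
        source = "node-permutation"
    else:
        rows = []
        for net in null:
            nm = _as_matrix(net)
            if nm.shape != (n, n):
                raise ValueError("null network shape does not match the response")
            yp = _tri_vector(nm, m)
            ok = np.isfinite(yp)
            if ok.all():
                rows.append(_ols_beta(yp, X))
            else:
                rows.append(_ols_beta(yp[ok], X[ok]))
        if not rows:
            raise ValueError("custom null iterable is empty")
        null_betas = np.vstack(rows)
        source = "custom"

    pvals = [
        empirical_p(beta[j], null_betas[:, j]) for j in range(X.shape[1])
    ]
    return QapResult(
        names=["intercept"] + names,
        beta=beta,
        p=pvals,
        null_betas=null_betas,
        n_bats=n,
        n_dyads=int(y.size),
        null_source=source,
    )


def kin_bias_suite(
    assoc: AssociationMatrix,
    relatedness: RelatednessMatrix,
    sexes: Mapping[str, str] | pd.Series,
    null_networks: Sequence[AssociationMatrix] | None = None,
    mantel_bats: Sequence[str] | None = None,
    n_perm: int = 5000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Kin-bias test battery over dyad types and sex subsets.

    Runs (i) Mantel tests of each dyad-type indicator against
    relatedness over ``mantel_bats`` (default: all sexed bats in the
    relatedness matrix — typically the full genotyped-adult set);
    (ii) QAP of association on each dyad-type indicator; and (iii) QAP
    of association on relatedness within all bats, females only, and
    males only (dyads rebuilt on each subset).  QAP uses the supplied
    pre-network null networks when given, node permutation otherwise.

    Returns a tidy table (test, subset, n_bats, statistic, p, n_null).
    """
    sexes = {str(k): v for k, v in dict(sexes).items()}
    rows = []

    # (i) dyad-type relatedness structure, Mantel over the genotyped set
    if mantel_bats is None:
        mantel_bats = [b for b in relatedness.ids if sexes.get(b) in ("female", "male")]
    mantel_bats = [str(b) for b in mantel_bats]
    rel_m = relatedness.subset(mantel_bats)
    for i, dt in enumerate(DYAD_TYPES):
        D = dyad_type_matrix(sexes, dt, bats=mantel_bats)
        res = mantel(D, rel_m, n_perm=n_perm, seed=None if seed is None else seed + i)
        rows.append(
            ("mantel:" + dt + "~relatedness", "all", res.n_bats, res.r, str(res.p),
             res.p.reportable, res.n_perm)
        )

    def _nulls_for(bats: list[str]):
        if null_networks is None:
            return "node-permutation"
        return [nn.subset(bats) for nn in null_networks]

    n_null = n_perm if null_networks is None else len(null_networks)

    # (ii) association ~ dyad type, over the association matrix's bats
    abats = list(assoc.bats)
    for i, dt in enumerate(DYAD_TYPES):
        D = dyad_type_matrix(sexes, dt, bats=abats)
        res = qap_regression(
            assoc, [D], null=_nulls_for(abats), n_perm=n_perm,
            seed=None if seed is None else seed + 10 + i, names=[dt],
        )
        rows.append(
            ("qap:association~" + dt, "all", res.n_bats, res.coef(dt),
             str(res.pvalue(dt)), res.pvalue(dt).reportable, n_null)
        )

    # (iii) association ~ relatedness within all / females / males
    subsets = {
        "all": abats,
        "females": [b for b in abats if sexes.get(b) == "female"],
        "males": [b for b in abats if sexes.get(b) == "male"],
    }
    for i, (label, bats) in enumerate(subsets.items()):
        if len(bats) < 3:
            continue
        sub_assoc = assoc.subset(bats)
        sub_rel = relatedness.subset(bats)
        try:
            res = qap_regression(
                sub_assoc, [sub_rel], null=_nulls_for(bats), n_perm=n_perm,
                seed=None if seed is None else seed + 20 + i, names=["relatedness"],
            )
        except ValueError as exc:
            # e.g. constant relatedness within the subset: beta undefined
            logger.info("kin-bias QAP skipped for subset %s: %s", label, exc)
            continue
        rows.append(
            ("qap:association~relatedness", label, res.n_bats,
             res.coef("relatedness"), str(res.pvalue("relatedness")),
             res.pvalue("relatedness").reportable, n_null)
        )

    return pd.DataFrame(
        rows,
        columns=["test", "subset", "n_bats", "statistic", "p", "p_numeric", "n_null"],
    )
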
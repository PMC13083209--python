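"""Community-composition testing on dissimilarity matrices.

Implements the distance-based analysis chain: Bray-Curtis dissimilarity,
the PERMDISP test of homogeneity of multivariate dispersion, and a nested
PERMANOVA with sequential (Type I) sums of squares, denominators derived
from expected mean squares for the random nested design, components of
variation, and p-values by permutation of residuals under the reduced
model.

The partition follows the McArdle-Anderson identity: with ``D`` the
dissimilarity matrix and ``C`` the centring operator, the Gower matrix
``G = -1/2 C D^2 C`` has ``tr(G)`` equal to the total sum of squared
deviations, and the sum of squares attributable to a design subspace with
projection ``H`` is ``tr(H G)``. Sequential terms use differences of
cumulative projections, so the partition is order-dependent exactly as in
a Type I ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

__all__ = [
    "DistanceMatrix",
    "bray_curtis",
    "Permdisp",
    "PermdispResults",
    "Term",
    "NestedPermanova",
    "PermanovaResults",
    "signed_sqrt",
    "variance_components_sqrt",
    "STUDY_TERMS",
]


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample ids."""

    ids: list[str]
    values: np.ndarray
    zero_pairs: list[tuple[str, str]] = dc_field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("ids/values shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def bray_curtis(data: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between rows of a non-negative table.

    ``d(i, j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk)``. A pair whose
    two rows are both all-zero is undefined under the formula and set to 0
    by convention; such pairs are recorded in ``zero_pairs``.

    Raises
    ------
    ValueError
        On any negative input — spatially corrected residuals must first
        go through ``adjust_nonzero``.
    """
    X = data.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError(
            "negative values are not valid Bray-Curtis input; "
            "apply spatial.adjust_nonzero first"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = squareform(pdist(X, metric="braycurtis"))
    ids = list(data.index)
    zero_rows = np.where(X.sum(axis=1) == 0)[0]
    zero_pairs = []
    if len(zero_rows):
        for a in zero_rows:
            for b in zero_rows:
                if a < b:
                    zero_pairs.append((ids[a], ids[b]))
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(ids, d, zero_pairs)


def _gower(dist: np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix G = -1/2 C D^2 C."""
    n = dist.shape[0]
    A = -0.5 * dist**2
    Jm = np.eye(n) - np.ones((n, n)) / n
    return Jm @ A @ Jm


# ---------------------------------------------------------------------------
# PERMDISP


@dataclass
class PermdispResults:
    """One-way test of homogeneity of dispersion for a single factor."""

    statistic: float            # classical one-way F on centroid distances
    p_value: float
    group_sizes: pd.Series
    centroid_distances: pd.Series
    n_permutations: int

    def summary(self) -> str:
        lines = ["PERMDISP: homogeneity of multivariate dispersion",
                 f"F = {self.statistic:.4f}, p_perm = {self.p_value:.4f} "
                 f"({self.n_permutations} permutations)",
                 "group sizes: " + ", ".join(f"{g}={n}" for g, n in self.group_sizes.items())]
        return "\n".join(lines)


class Permdisp:
    """Dispersion-homogeneity model for one grouping factor.

    Distances to group centroids are computed in the principal-coordinate
    embedding with the negative-eigenvalue correction: squared distance to
    the centroid is the real-axis part minus the imaginary-axis part
    (clipped at zero), which preserves the original dissimilarities for
    semi-metric inputs such as Bray-Curtis. The test statistic is the
    classical one-way F on those distances; its null distribution comes
    from permuting group labels.
    """

    def __init__(self, dist: DistanceMatrix, groups: Sequence):
        groups = pd.Series(list(groups), index=dist.ids)
        sizes = groups.value_counts()
        singletons = sizes.index[sizes < 2]
        if len(singletons):
            warnings.warn(f"excluding singleton groups: {list(singletons)}")
            keep = groups[~groups.isin(singletons)].index
            idx = [dist.ids.index(s) for s in keep]
            dist = DistanceMatrix(list(keep), dist.values[np.ix_(idx, idx)])
            groups = groups.loc[keep]
        if groups.nunique() < 2:
            raise ValueError("need >= 2 groups with >= 2 members")
        self.dist = dist
        self.groups = groups

        G = _gower(dist.values)
        evals, evecs = np.linalg.eigh(G)
        pos = evals > 1e-10
        neg = evals < -1e-10
        self._coords_pos = evecs[:, pos] * np.sqrt(evals[pos])
        self._coords_neg = evecs[:, neg] * np.sqrt(-evals[neg])

    def _centroid_distances(self, codes: np.ndarray) -> np.ndarray:
        zpos, zneg = self._coords_pos, self._coords_neg
        d2 = np.zeros(len(codes))
        for g in np.unique(codes):
            m = codes == g
            cp = zpos[m].mean(axis=0)
            d2[m] += ((zpos[m] - cp) ** 2).sum(axis=1)
            if zneg.shape[1]:
                cn = zneg[m].mean(axis=0)
                d2[m] -= ((zneg[m] - cn) ** 2).sum(axis=1)
        return np.sqrt(np.clip(d2, 0.0, None))

    @staticmethod
    def _anova_f(values: np.ndarray, codes: np.ndarray) -> float:
        return float(f_oneway(*(values[codes == g] for g in np.unique(codes))).statistic)

    def fit(self, n_perm: int = 999, seed=0) -> PermdispResults:
        codes, uniques = pd.factorize(self.groups)
        z = self._centroid_distances(codes)
        f_obs = self._anova_f(z, codes)
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            zp = self._centroid_distances(perm)
            if self._anova_f(zp, perm) >= f_obs:
                count += 1
        p = (count + 1) / (n_perm + 1)
        return PermdispResults(
            statistic=f_obs,
            p_value=p,
            group_sizes=self.groups.value_counts(),
            centroid_distances=pd.Series(z, index=self.dist.ids, name="dist_to_centroid"),
            n_permutations=n_perm,
        )


def permdisp(dist: DistanceMatrix, groups, n_perm: int = 999, seed=0) -> PermdispResults:
    """Convenience wrapper: build and fit a :class:`Permdisp` model."""
    return Permdisp(dist, groups).fit(n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# nested PERMANOVA


@dataclass(frozen=True)
class Term:
    """One model term, fitted in order.

    kind: ``fixed`` (categorical), ``continuous`` (1-df covariate), or
    ``random`` (categorical variance component). ``nested_in`` names an
    earlier term whose levels contain this term's levels.
    """

    name: str
    kind: str = "fixed"
    nested_in: str | None = None

    def __post_init__(self):
        if self.kind not in {"fixed", "continuous", "random"}:
            raise ValueError(f"unknown term kind {self.kind!r}")


#: the study model: covariates first, then family and genotype-in-family
STUDY_TERMS = (
    Term("batch", "fixed"),
    Term("soil_pc1", "continuous"),
    Term("family", "random"),
    Term("genotype", "random", nested_in="family"),
)

#: the ancestry variant: ancestry fixed, family nested in ancestry
ANCESTRY_TERMS = (
    Term("batch", "fixed"),
    Term("soil_pc1", "continuous"),
    Term("ancestry", "fixed"),
    Term("family", "random", nested_in="ancestry"),
    Term("genotype", "random", nested_in="family"),
)


def signed_sqrt(value: float) -> float:
    """sign(v) * sqrt(|v|): prints a negative component as negative."""
    return float(np.sign(value) * np.sqrt(abs(value)))


def variance_components_sqrt(table: pd.DataFrame) -> pd.Series:
    """Signed square roots of a PERMANOVA table's components of variation."""
    return table["component_of_variation"].map(signed_sqrt).rename("sqrt_CV")


@dataclass
class PermanovaResults:
    """Sequential PERMANOVA partition with permutation p-values."""

    table: pd.DataFrame
    n_permutations: int
    seed: object

    def summary(self) -> str:
        cols = ["df", "SS", "MS", "pseudo_F", "p_perm", "sqrt_CV"]
        show = self.table[cols].copy()
        out = ["PERMANOVA (Type I SS, permutation of residuals under reduced model)",
               f"{self.n_permutations} permutations"]
        out.append(show.round(4).to_string())
        return "\n".join(out)


class NestedPermanova:
    """Distance-based ANOVA for the clonal-trial nested design.

    Parameters
    ----------
    dist
        Sample dissimilarities.
    metadata
        Per-sample frame (indexed by sample id) holding every term's
        column.
    terms
        Ordered sequence of :class:`Term`; defaults to the study model
        (batch, soil axis, family, genotype within family).

    Notes
    -----
    * Sequential SS: ``SS_j = tr((H_j - H_{j-1}) G)`` with ``H_j`` the
      projection onto the cumulative design span.
    * Denominators: each random term is tested against the next random
      term nested below it (family over genotype-in-family); the deepest
      random term and all fixed terms are tested against the residual.
    * Components of variation: moment (EMS) equations using
      ``tr(P_j Z_r Z_r')`` coefficients, solved from the bottom up;
      negative estimates are retained and reported via signed square
      roots. Fixed-term components use the same moment equation applied
      to the term's own indicator matrix, the distance-based analogue of
      a fixed effect's mean-squared effect size.
    * Permutation of residuals under the reduced model: for term j the
      Gower matrix is double-projected onto the orthocomplement of the
      prior terms' span and its rows/columns permuted; numerator and
      denominator are re-evaluated on the permuted matrix.
    """

    def __init__(
        self,
        dist: DistanceMatrix,
        metadata: pd.DataFrame,
        terms: Sequence[Term] = STUDY_TERMS,
    ):
        missing = [s for s in dist.ids if s not in metadata.index]
        if missing:
            raise ValueError(f"metadata missing samples: {missing[:5]}")
        self.dist = dist
        self.meta = metadata.loc[dist.ids]
        self.terms = list(terms)
        self.n = len(dist.ids)
        self._build_designs()

    # -- design ------------------------------------------------------------

    def _term_matrix(self, term: Term) -> np.ndarray:
        col = self.meta[term.name]
        if term.kind == "continuous":
            v = col.to_numpy(dtype=float)
            return (v - v.mean())[:, None]
        if term.nested_in is not None:
            # nest by combining with the parent labels so levels are unique
            parent = self.meta[term.nested_in].astype(str)
            labels = parent + "/" + col.astype(str)
        else:
            labels = col.astype(str)
        return pd.get_dummies(labels).to_numpy(dtype=float)

    def _build_designs(self) -> None:
        n = self.n
        ones = np.ones((n, 1))
        cum = ones
        H_prev = np.full((n, n), 1.0 / n)
        rank_prev = 1
        self._P: list[np.ndarray] = []      # per-term projection differences
        self._H_before: list[np.ndarray] = []
        self._df: list[int] = []
        self._Z: list[np.ndarray] = []      # raw per-term indicator/column matrices
        for term in self.terms:
            Z = self._term_matrix(term)
            self._Z.append(Z)
            cum = np.hstack([cum, Z])
            U, s, _ = np.linalg.svd(cum, full_matrices=False)
            tol = s.max() * max(cum.shape) * np.finfo(float).eps
            r = int((s > tol).sum())
            H = U[:, s > tol] @ U[:, s > tol].T
            df = r - rank_prev
            if df == 0:
                raise ValueError(
                    f"term {term.name!r} is aliased with earlier terms "
                    "(no additional degrees of freedom)"
                )
            self._H_before.append(H_prev)
            self._P.append(H - H_prev)
            self._df.append(df)
            H_prev, rank_prev = H, r
        self._H_full = H_prev
        self._df_res = n - rank_prev
        if self._df_res <= 0:
            raise ValueError("saturated design: no residual degrees of freedom")
        self._P_res = np.eye(n) - H_prev

    def _exchange_blocks(self, j: int, denom: int | None) -> np.ndarray | None:
        """Exchangeable-unit blocks for term j's permutation, or None (free).

        When a random term is tested against a lower random term (family
        over genotype-in-family), the exchangeable units under the null
        are that denominator term's groups, so whole groups of samples
        are permuted together. This requires equal group sizes; with
        unequal groups the scheme falls back to free permutation of
        sample residuals.
        """
        if denom is None:
            return None
        labels = self.meta[self.terms[denom].name].astype(str)
        parent = self.terms[denom].nested_in
        if parent is not None:
            labels = self.meta[parent].astype(str) + "/" + labels
        codes, _ = pd.factorize(labels)
        sizes = np.bincount(codes)
        if len(set(sizes)) != 1:
            return None
        order = np.argsort(codes, kind="stable")
        return order.reshape(len(sizes), sizes[0])

    def _draw_permutation(self, rng, blocks: np.ndarray | None) -> np.ndarray:
        if blocks is None:
            return rng.permutation(self.n)
        # move whole blocks into the slots of other blocks
        shuffled = blocks[rng.permutation(blocks.shape[0])]
        perm = np.empty(self.n, dtype=int)
        perm[blocks.ravel()] = shuffled.ravel()
        return perm

    def _denominator_index(self, j: int) -> int | None:
        """Index of the denominator term; None means residual MS."""
        term = self.terms[j]
        if term.kind != "random":
            return None
        # next random term nested (directly or transitively) in this one
        for k in range(j + 1, len(self.terms)):
            t = self.terms[k]
            if t.kind != "random":
                continue
            anc = t.nested_in
            while anc is not None:
                if anc == term.name:
                    return k
                anc = next((u.nested_in for u in self.terms if u.name == anc), None)
        return None

    # -- fitting -----------------------------------------------------------

    def fit(self, n_perm: int = 999, seed=0) -> PermanovaResults:
        G = _gower(self.dist.values)
        total_ss = float(np.trace(G))
        k = len(self.terms)
        ss = np.array([float(np.sum(P * G)) for P in self._P])
        ss_res = float(np.sum(self._P_res * G))
        df = np.array(self._df, dtype=float)
        ms = ss / df
        ms_res = ss_res / self._df_res

        denom_idx = [self._denominator_index(j) for j in range(k)]
        denom_ms = np.array([ms[d] if d is not None else ms_res for d in denom_idx])
        pseudo_f = ms / denom_ms

        # permutation of residuals under the reduced model, per term
        rng = np.random.default_rng(seed)
        p_perm = np.full(k, np.nan)
        for j in range(k):
            R = np.eye(self.n) - self._H_before[j]
            Gr = R @ G @ R
            Pnum = self._P[j]
            d = denom_idx[j]
            Pden = self._P[d] if d is not None else self._P_res
            dfden = df[d] if d is not None else self._df_res
            blocks = self._exchange_blocks(j, d)
            count = 0
            for _ in range(n_perm):
                perm = self._draw_permutation(rng, blocks)
                Gp = Gr[np.ix_(perm, perm)]
                f_num = np.sum(Pnum * Gp) / df[j]
                f_den = np.sum(Pden * Gp) / dfden
                stat = f_num / f_den if f_den > 0 else np.inf
                # tolerance keeps tied permutations (identical up to
                # floating jitter) in the exceedance count
                if stat >= pseudo_f[j] - 1e-8 * (abs(pseudo_f[j]) + 1.0):
                    count += 1
            p_perm[j] = (count + 1) / (n_perm + 1)

        cv = self._components_of_variation(ss, ms_res)

        table = pd.DataFrame(
            {
                "df": np.concatenate([df, [self._df_res]]),
                "SS": np.concatenate([ss, [ss_res]]),
                "MS": np.concatenate([ms, [ms_res]]),
                "pseudo_F": np.concatenate([pseudo_f, [np.nan]]),
                "p_perm": np.concatenate([p_perm, [np.nan]]),
                "component_of_variation": np.concatenate([cv, [ms_res]]),
            },
            index=[t.name for t in self.terms] + ["residual"],
        )
        table["sqrt_CV"] = variance_components_sqrt(table)
        assert np.isclose(table["SS"].sum(), total_ss, rtol=1e-8), "SS partition broken"
        return PermanovaResults(table, n_perm, seed)

    def _components_of_variation(self, ss: np.ndarray, ms_res: float) -> np.ndarray:
        """Moment (EMS) estimates of per-term components, solved bottom-up.

        E[SS_j] = sum_r sigma_r^2 tr(P_j Z_r Z_r') + df_j sigma_e^2 over
        the random terms r at or below j; the projections make the system
        triangular because an earlier term's span absorbs its own Z.
        """
        k = len(self.terms)
        coeff = np.zeros((k, k))
        for j in range(k):
            for r in range(j, k):
                Zr = self._Z[r]
                coeff[j, r] = float(np.sum((self._P[j] @ Zr) * Zr))
        cv = np.zeros(k)
        sigma = {}  # random-term variance estimates
        for j in range(k - 1, -1, -1):
            expected_others = sum(
                sigma.get(r, 0.0) * coeff[j, r] for r in range(j + 1, k)
            )
            resid_part = self._df[j] * ms_res
            own = coeff[j, j]
            est = (ss[j] - expected_others - resid_part) / own if own > 0 else np.nan
            cv[j] = est
            if self.terms[j].kind == "random":
                sigma[j] = est
        return cv


def permanova_nested(
    dist: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: Sequence[Term] = STUDY_TERMS,
    n_perm: int = 999,
    seed=0,
) -> PermanovaResults:
    """Convenience wrapper: build and fit a :class:`NestedPermanova`."""
    return NestedPermanova(dist, metadata, terms).fit(n_perm=n_perm, seed=seed)
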
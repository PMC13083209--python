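"""Per-ASV variance components and heritability under the clonal pedigree model.

The model for one ASV's spatially corrected abundance is the linear mixed
model

    y = X b + Za ua + Zf uf + Zc uc + e

with ``ua ~ N(0, A sigma_a^2)`` (additive effects over the pedigree
relationship matrix A), ``uf ~ N(0, I sigma_f^2)`` (full-sib family
effects, which absorb one quarter of dominance variance),
``uc ~ N(0, I sigma_c^2)`` (genotype non-additive effects: the remaining
dominance plus epistasis, identifiable because clonal ramets replicate
each genotype), and ``e ~ N(0, I sigma_e^2)``. Fixed effects are an
intercept, sequencing batch, and the soil covariate axis.

Components are estimated by residual maximum likelihood using
average-information (AI) updates with expectation-maximisation fallback
steps; standard errors come from the inverse AI matrix at the optimum.
Heritabilities are the variance ratios

    H^2 = (sigma_a^2 + sigma_f^2 + sigma_c^2) / total
    h^2 = sigma_a^2 / total

with delta-method standard errors, and a one-sided z threshold of 1.65
(alpha = 0.05) for significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import lapack

from .pedigree import RelationshipMatrix

__all__ = [
    "MixedModelSpec",
    "GeneticMixedModel",
    "VarianceComponents",
    "HeritabilityEstimate",
    "heritability",
    "heritability_scan",
    "Z_THRESHOLD",
    "build_design",
]

#: one-sided standard-normal threshold used for significance (alpha = 0.05)
Z_THRESHOLD = 1.65


# ---------------------------------------------------------------------------
# model specification


def _incidence(labels: Sequence, levels: Sequence) -> np.ndarray:
    pos = {l: k for k, l in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    for r, l in enumerate(labels):
        Z[r, pos[l]] = 1.0
    return Z


@dataclass
class MixedModelSpec:
    """Design for one ASV's mixed model.

    ``X`` must include an intercept column. ``genotype``/``family`` are
    per-sample labels; every genotype must map to exactly one family.
    """

    y: np.ndarray
    X: np.ndarray
    genotype: list
    family: list
    genotype_levels: list = field(default_factory=list)
    family_levels: list = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = len(self.y)
        if self.X.shape[0] != n or len(self.genotype) != n or len(self.family) != n:
            raise ValueError("X, genotype, family must have one row per observation")
        if not self.genotype_levels:
            self.genotype_levels = sorted(set(self.genotype))
        if not self.family_levels:
            self.family_levels = sorted(set(self.family))
        fam_of = {}
        for g, f in zip(self.genotype, self.family):
            if fam_of.setdefault(g, f) != f:
                raise ValueError(f"genotype {g!r} mapped to multiple families")

    @property
    def Za(self) -> np.ndarray:
        return _incidence(self.genotype, self.genotype_levels)

    @property
    def Zf(self) -> np.ndarray:
        return _incidence(self.family, self.family_levels)

    @property
    def Zc(self) -> np.ndarray:
        return self.Za  # same incidence, identity covariance


def build_design(
    metadata: pd.DataFrame,
    batch_col: str = "batch",
    soil_col: str = "soil_pc1",
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design: intercept + batch (reference-coded) + soil axis."""
    n = len(metadata)
    cols = [np.ones(n)]
    names = ["intercept"]
    if batch_col in metadata:
        dummies = pd.get_dummies(metadata[batch_col], drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(f"{batch_col}[{c}]")
    if soil_col in metadata:
        v = metadata[soil_col].to_numpy(dtype=float)
        cols.append(v - v.mean())
        names.append(soil_col)
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# results containers


@dataclass
class VarianceComponents:
    """REML estimates for one response.

    Component order is fixed: additive, family, clone (non-additive),
    residual. ``at_boundary`` flags components pinned at the positivity
    floor; their SEs come from the projected information matrix.
    """

    names: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    covariance: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    at_boundary: np.ndarray
    degenerate: bool = False

    def __getitem__(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    @property
    def total(self) -> float:
        return float(self.estimates.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.estimates, index=self.names)

    def summary(self) -> str:
        rows = [
            f"{n:>10s}  {e:10.5g}  (SE {s:.4g}){'  [boundary]' if b else ''}"
            for n, e, s, b in zip(self.names, self.estimates, self.std_errors, self.at_boundary)
        ]
        head = (
            f"REML variance components  (logL = {self.loglik:.4f}, "
            f"{'converged' if self.converged else 'NOT converged'}, {self.n_iter} iterations)"
        )
        return "\n".join([head] + rows)


@dataclass
class HeritabilityEstimate:
    """Broad- and narrow-sense heritability with delta-method uncertainty."""

    H2: float
    H2_se: float
    H2_z: float
    h2: float
    h2_se: float
    h2_z: float
    significant_H2: bool
    significant_h2: bool
    undefined: bool = False

    def summary(self) -> str:
        flag = lambda s: "*" if s else " "
        return (
            f"H2 = {self.H2:.4f} (SE {self.H2_se:.4f}, z = {self.H2_z:.2f}){flag(self.significant_H2)}\n"
            f"h2 = {self.h2:.4f} (SE {self.h2_se:.4f}, z = {self.h2_z:.2f}){flag(self.significant_h2)}"
        )


# ---------------------------------------------------------------------------
# REML engine


class GeneticMixedModel:
    """REML model for one response under arbitrary variance structures.

    The study model is built with :meth:`from_spec` (additive / family /
    clone / residual); the general constructor accepts any list of named
    PSD covariance structures plus the implicit residual identity, which
    is what the closed-form oracle tests use (e.g. a single genotype
    component with ``A = I``).
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        structures: list[tuple[str, np.ndarray]],
        n_levels: Sequence[int] | None = None,
    ):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        n = len(self.y)
        if self.X.shape[0] != n:
            raise ValueError("X rows must match y")
        for name, G in structures:
            if G.shape != (n, n):
                raise ValueError(f"structure {name!r} must be n x n")
        self.structures = structures
        self.names = [name for name, _ in structures] + ["residual"]
        self._G = [G for _, G in structures] + [np.eye(n)]
        # effect-level counts scale the EM fallback step; default n (conservative)
        if n_levels is None:
            n_levels = [n] * len(structures)
        self._q = list(n_levels) + [n]
        self.n = n
        self.p = np.linalg.matrix_rank(self.X)

    @classmethod
    def from_spec(cls, spec: MixedModelSpec, A: RelationshipMatrix) -> "GeneticMixedModel":
        Asub = A.subset(spec.genotype_levels).values
        Za, Zf, Zc = spec.Za, spec.Zf, spec.Zc
        structures = [
            ("additive", Za @ Asub @ Za.T),
            ("family", Zf @ Zf.T),
            ("clone", Zc @ Zc.T),
        ]
        n_levels = [len(spec.genotype_levels), len(spec.family_levels), len(spec.genotype_levels)]
        return cls(spec.y, spec.X, structures, n_levels=n_levels)

    # -- internals ---------------------------------------------------------

    def _common(self, theta: np.ndarray):
        """V^-1, P (projection), P y, and the REML log-likelihood."""
        V = sum(t * G for t, G in zip(theta, self._G))
        c, info = lapack.dpotrf(V, lower=1)
        if info != 0:
            raise np.linalg.LinAlgError("V not positive definite")
        logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
        Vinv, info = lapack.dpotri(c, lower=1)
        if info != 0:
            raise np.linalg.LinAlgError("V inversion failed")
        Vinv = np.tril(Vinv) + np.tril(Vinv, -1).T
        W = Vinv @ self.X
        XtVX = self.X.T @ W
        sign, logdet_X = np.linalg.slogdet(XtVX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        S = np.linalg.solve(XtVX, W.T)
        P = Vinv - W @ S
        Py = P @ self.y
        loglik = -0.5 * (logdet_V + logdet_X + float(self.y @ Py))
        return P, Py, loglik

    def _score_ai(self, P: np.ndarray, Py: np.ndarray):
        k = len(self._G)
        GPy = [G @ Py for G in self._G]
        PGPy = [P @ v for v in GPy]
        score = np.empty(k)
        for i, G in enumerate(self._G):
            tr_PG = float(np.sum(P * G))  # symmetric: elementwise trace
            score[i] = -0.5 * (tr_PG - float(Py @ GPy[i]))
        AI = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(GPy[i] @ PGPy[j])
        return score, AI, GPy

    def fit(
        self,
        start: np.ndarray | None = None,
        max_iter: int = 100,
        rtol: float = 1e-8,
        verbose: bool = False,
    ) -> VarianceComponents:
        """Maximise the REML log-likelihood.

        AI steps with step-halving; an EM step is taken whenever the AI
        proposal fails (non-finite, likelihood drop). Components are kept
        above a floor of 1e-8 times the total phenotypic variance. A
        constant response short-circuits to a degenerate all-zero result.
        """
        y, X = self.y, self.X
        k = len(self._G)
        vary = float(np.var(y, ddof=1)) if self.n > 1 else 0.0
        if vary <= 0 or not np.isfinite(vary):
            zero = np.zeros(k)
            return VarianceComponents(
                self.names, zero, zero.copy(), np.zeros((k, k)),
                loglik=np.nan, converged=True, n_iter=0,
                at_boundary=np.ones(k, bool), degenerate=True,
            )
        floor = 1e-8 * vary
        theta = np.full(k, vary / k) if start is None else np.asarray(start, float).copy()
        theta = np.maximum(theta, floor)

        P, Py, ll = self._common(theta)
        converged = False
        pinned = np.zeros(k, dtype=bool)
        it = 0
        for it in range(1, max_iter + 1):
            score, AI, GPy = self._score_ai(P, Py)
            # active set: release pinned components whose score pushes inward
            pinned &= ~(score > 0)
            pinned |= (theta <= floor * (1 + 1e-6)) & (score <= 0)
            free = ~pinned
            ll_new = ll
            step_taken = False
            if free.any():
                try:
                    delta = np.zeros(k)
                    delta[free] = np.linalg.solve(AI[np.ix_(free, free)], score[free])
                except np.linalg.LinAlgError:
                    delta = None
                if delta is not None:
                    step = 1.0
                    for _ in range(6):
                        cand = np.maximum(theta + step * delta, floor)
                        cand[pinned] = floor
                        try:
                            P2, Py2, ll2 = self._common(cand)
                        except np.linalg.LinAlgError:
                            step *= 0.5
                            continue
                        if np.isfinite(ll2) and ll2 >= ll - 1e-12:
                            theta, P, Py = cand, P2, Py2
                            ll_new = ll2
                            step_taken = True
                            break
                        step *= 0.5
            if not step_taken:
                # EM-style fallback: guaranteed uphill in the long run and
                # respects positivity by construction
                cand = theta.copy()
                for i, G in enumerate(self._G):
                    if pinned[i]:
                        continue
                    tr_PG = float(np.sum(P * G))
                    cand[i] = theta[i] + theta[i] ** 2 * (float(Py @ GPy[i]) - tr_PG) / self._q[i]
                cand = np.maximum(cand, floor)
                cand[pinned] = floor
                try:
                    P2, Py2, ll_new = self._common(cand)
                except np.linalg.LinAlgError:
                    warnings.warn("REML iteration failed; returning last iterate")
                    break
                theta, P, Py = cand, P2, Py2
            if verbose:
                print(f"iter {it}: logL = {ll_new:.8f}, theta = {theta}")
            if abs(ll_new - ll) < rtol * (abs(ll) + 1.0):
                ll = ll_new
                converged = True
                break
            ll = ll_new

        score, AI, _ = self._score_ai(P, Py)
        at_boundary = theta <= floor * (1 + 1e-6)
        cov = np.full((k, k), np.nan)
        se = np.full(k, np.nan)
        free = ~at_boundary
        if free.any():
            try:
                sub = np.linalg.inv(AI[np.ix_(free, free)])
                cov_free = sub
                cov = np.zeros((k, k))
                cov[np.ix_(free, free)] = cov_free
                se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            except np.linalg.LinAlgError:
                pass
        else:
            cov = np.zeros((k, k))
            se = np.zeros(k)
        if not converged:
            warnings.warn("REML did not converge within max_iter")
        return VarianceComponents(
            self.names, theta, se, cov, loglik=ll, converged=converged,
            n_iter=it, at_boundary=at_boundary,
        )


def reml_fit(
    spec: MixedModelSpec, A: RelationshipMatrix, **options
) -> VarianceComponents:
    """Fit the study's three-random-term model for one response."""
    return GeneticMixedModel.from_spec(spec, A).fit(**options)


# ---------------------------------------------------------------------------
# heritability


def heritability(vc: VarianceComponents) -> HeritabilityEstimate:
    """Broad- and narrow-sense heritability with delta-method SEs.

    Requires the component order (additive, family, clone, residual). A
    zero total variance yields an undefined (flagged) estimate.
    """
    expected = ["additive", "family", "clone", "residual"]
    if vc.names != expected:
        raise ValueError(f"expected components {expected}, got {vc.names}")
    th = vc.estimates
    total = th.sum()
    if total <= 0 or vc.degenerate:
        return HeritabilityEstimate(0.0, np.nan, np.nan, 0.0, np.nan, np.nan,
                                    False, False, undefined=True)
    a, f, c, e = th
    S = a + f + c
    H2 = S / total
    h2 = a / total

    # delta method: gradients of the two ratios w.r.t. (a, f, c, e)
    gH = np.array([e, e, e, -S]) / total**2
    gh = np.array([total - a, -a, -a, -a]) / total**2
    C = np.nan_to_num(vc.covariance, nan=0.0)
    H2_se = float(np.sqrt(max(gH @ C @ gH, 0.0)))
    h2_se = float(np.sqrt(max(gh @ C @ gh, 0.0)))
    H2_z = H2 / H2_se if H2_se > 0 else np.nan
    h2_z = h2 / h2_se if h2_se > 0 else np.nan
    # components pinned at the positivity floor carry no information: a
    # ratio whose numerator is entirely pinned must not be called
    # significant (its projected SE is a boundary artifact)
    genetic_free = ~vc.at_boundary[:3]
    return HeritabilityEstimate(
        H2=float(H2), H2_se=H2_se, H2_z=float(H2_z) if np.isfinite(H2_z) else np.nan,
        h2=float(h2), h2_se=h2_se, h2_z=float(h2_z) if np.isfinite(h2_z) else np.nan,
        significant_H2=bool(
            genetic_free.any() and np.isfinite(H2_z) and abs(H2_z) > Z_THRESHOLD
        ),
        significant_h2=bool(
            genetic_free[0] and np.isfinite(h2_z) and abs(h2_z) > Z_THRESHOLD
        ),
    )


# ---------------------------------------------------------------------------
# per-ASV scan


RESULT_COLUMNS = [
    "sigma_a2", "sigma_f2", "sigma_c2", "sigma_e2",
    "H2", "H2_se", "H2_z", "h2", "h2_se", "h2_z",
    "significant_H2", "significant_h2", "converged",
]


def heritability_scan(
    residuals: pd.DataFrame,
    metadata: pd.DataFrame,
    A: RelationshipMatrix,
    core_asvs: Sequence[str] | None = None,
    batch_col: str = "batch",
    soil_col: str = "soil_pc1",
    genotype_col: str = "genotype",
    family_col: str = "family",
    h2_moderate: float = 0.2,
) -> tuple[pd.DataFrame, dict]:
    """Fit the mixed model to every ASV's spatial residuals.

    Returns a per-ASV results table (sorted by H2, descending) and a
    summary dict with counts of significant and moderately heritable
    (H2 > ``h2_moderate``) ASVs, mean heritabilities of the significant
    sets, and core / non-core strata when ``core_asvs`` is given.
    Per-ASV fitting failures are recorded (``converged = False`` with NaN
    estimates) and never abort the scan.
    """
    if residuals.shape[1] == 0 or residuals.shape[0] == 0:
        return pd.DataFrame(columns=RESULT_COLUMNS), {}

    meta = metadata.loc[residuals.index]
    X, _ = build_design(meta, batch_col=batch_col, soil_col=soil_col)
    genotype = list(meta[genotype_col])
    family = list(meta[family_col])
    genotype_levels = sorted(set(genotype))
    Asub = A.subset(genotype_levels)

    rows = {}
    spec0 = MixedModelSpec(
        np.zeros(len(meta)), X, genotype, family, genotype_levels=genotype_levels
    )
    # structures do not depend on y: build them once
    base = GeneticMixedModel.from_spec(spec0, Asub)
    for asv in residuals.columns:
        y = residuals[asv].to_numpy(float)
        try:
            model = GeneticMixedModel(y, X, base.structures, n_levels=base._q[:-1])
            vc = model.fit()
            est = heritability(vc)
            rows[asv] = dict(
                sigma_a2=vc["additive"], sigma_f2=vc["family"],
                sigma_c2=vc["clone"], sigma_e2=vc["residual"],
                H2=est.H2, H2_se=est.H2_se, H2_z=est.H2_z,
                h2=est.h2, h2_se=est.h2_se, h2_z=est.h2_z,
                significant_H2=est.significant_H2,
                significant_h2=est.significant_h2,
                converged=vc.converged and not vc.degenerate,
            )
        except Exception as err:  # pragma: no cover - defensive
            warnings.warn(f"{asv}: REML failed ({err}); skipped")
            rows[asv] = {c: np.nan for c in RESULT_COLUMNS} | {
                "significant_H2": False, "significant_h2": False, "converged": False,
            }
    table = pd.DataFrame.from_dict(rows, orient="index")[RESULT_COLUMNS]
    table = table.sort_values("H2", ascending=False)

    sig_H = table[table["significant_H2"] == True]  # noqa: E712
    sig_h = table[table["significant_h2"] == True]  # noqa: E712
    summary = {
        "n_asvs": int(len(table)),
        "n_significant_H2": int(len(sig_H)),
        "n_significant_h2": int(len(sig_h)),
        "n_moderate_H2": int((table["H2"] > h2_moderate).sum()),
        "mean_H2_significant": float(sig_H["H2"].mean()) if len(sig_H) else np.nan,
        "mean_h2_significant": float(sig_h["h2"].mean()) if len(sig_h) else np.nan,
    }
    if core_asvs is not None:
        core = table.index.isin(set(core_asvs))
        summary["core"] = {
            "n": int(core.sum()),
            "mean_H2": float(table.loc[core, "H2"].mean()) if core.any() else np.nan,
            "mean_h2": float(table.loc[core, "h2"].mean()) if core.any() else np.nan,
        }
        summary["noncore"] = {
            "n": int((~core).sum()),
            "n_moderate_H2": int((table.loc[~core, "H2"] > h2_moderate).sum()),
            "mean_H2": float(table.loc[~core, "H2"].mean()) if (~core).any() else np.nan,
        }
    return table, summary
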
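"""Thin-plate-spline spatial correction of field-trial count surfaces.

Micro-environmental gradients across a trial (drainage, soil depth,
historical land use) generate smooth spatial trends in ASV abundance that
would otherwise inflate apparent genetic signal, because relatives are not
planted at random distances from each other in any finite layout. Each
ASV's square-root-transformed counts are therefore regressed on a smooth
2-D surface over the planting coordinates; the residuals are the
spatially corrected abundances.

The surface is the classical penalised thin-plate spline: radial basis
``E(r) = r^2 log r`` plus an affine (1, x, y) null space, with roughness
penalty ``lam * w' K w``. The smoothing parameter is chosen by generalised
cross-validation (GCV) by default. Because all ASVs share the trial
coordinates, the expensive eigendecomposition of the penalty is done once
per coordinate set (:class:`ThinPlateSpline`) and reused across ASVs and
candidate ``lam`` values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ThinPlateSpline",
    "SplineFit",
    "AdjustedResiduals",
    "adjust_nonzero",
    "spatial_correct_matrix",
    "SpatialCorrection",
]


def _tps_kernel(sq_dists: np.ndarray) -> np.ndarray:
    """r^2 log r evaluated from squared distances (0 at r = 0)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 * sq_dists * np.log(sq_dists)
    out[~np.isfinite(out)] = 0.0
    return out


@dataclass
class SplineFit:
    """Results of one penalised surface fit."""

    x: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    smoothing: float            # penalty weight lam actually used
    edf: float                  # effective degrees of freedom of the smoother
    gcv: float                  # GCV score at the chosen lam

    @property
    def observed(self) -> np.ndarray:
        return self.fitted + self.residuals


class ThinPlateSpline:
    """Penalised TPS smoother over a fixed set of 2-D coordinates.

    Parameters
    ----------
    x, y
        Planting coordinates. Duplicated coordinates are collapsed by
        averaging the response (with a warning) before fitting; fitted
        values are broadcast back to the duplicates.

    Notes
    -----
    With ``T = [1, x, y]`` (QR: ``T = Q1 R``, null-space basis ``Q2``) and
    kernel matrix ``K``, the penalised solution has residual operator
    ``lam * Q2 (B + lam I)^{-1} Q2'`` where ``B = Q2' K Q2`` is PSD. ``B``
    is eigendecomposed once, so each (response, lam) evaluation costs
    O(n^2); GCV minimisation over a log-spaced grid is nearly free.
    """

    def __init__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(x) < 10:
            raise ValueError("need at least 10 points for a spatial surface")

        coords = np.column_stack([x, y])
        uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
        self._dup = len(uniq) < len(coords)
        if self._dup:
            warnings.warn(
                f"{len(coords) - len(uniq)} duplicate coordinates collapsed by averaging"
            )
        self.x_full, self.y_full = x, y
        self._inverse = inverse
        xu, yu = uniq[:, 0], uniq[:, 1]
        n = len(xu)

        T = np.column_stack([np.ones(n), xu, yu])
        if np.linalg.matrix_rank(T) < 3:
            raise ValueError("coordinates are collinear; a 2-D surface is not identifiable")

        d2 = (xu[:, None] - xu[None, :]) ** 2 + (yu[:, None] - yu[None, :]) ** 2
        K = _tps_kernel(d2)
        Q, _ = np.linalg.qr(T, mode="complete")
        Q2 = Q[:, 3:]
        B = Q2.T @ K @ Q2
        B = (B + B.T) / 2.0
        evals, evecs = np.linalg.eigh(B)
        evals = np.clip(evals, 0.0, None)  # K is conditionally PD on the null space
        self._n = n
        self._U = Q2 @ evecs        # n x (n-3) orthonormal columns
        self._d = evals
        # lam grid spans interpolation to near-affine, scaled by the spectrum
        scale = max(np.mean(evals), np.finfo(float).tiny)
        self._lam_grid = scale * np.logspace(-8, 4, 61)

    def _collapse(self, values: np.ndarray) -> np.ndarray:
        # np.unique sorts the coordinates, so values must always be mapped
        # into unique order (averaging any duplicates)
        sums = np.bincount(self._inverse, weights=values)
        cnts = np.bincount(self._inverse)
        return sums / cnts

    def fit(self, values, smoothing: float | str = "gcv") -> SplineFit:
        """Fit the surface to one response vector.

        ``smoothing`` is either the literal penalty weight (0 gives exact
        interpolation at distinct points) or ``"gcv"`` to minimise the GCV
        score ``n * RSS / (n - edf)^2`` over a log-spaced grid.
        """
        values = np.asarray(values, dtype=float)
        if values.shape != self.x_full.shape:
            raise ValueError("values length must match coordinates")
        v = self._collapse(values)
        n = self._n
        z = self._U.T @ v           # coefficients in the penalised subspace

        def resid_coeffs(lam):
            return (lam / (self._d + lam)) * z if lam > 0 else np.zeros_like(z)

        def edf_of(lam):
            if lam == 0:
                return float(n)
            return 3.0 + float(np.sum(self._d / (self._d + lam)))

        if smoothing in ("gcv", "auto"):
            best = None
            for lam in self._lam_grid:
                rz = resid_coeffs(lam)
                rss = float(rz @ rz)
                edf = edf_of(lam)
                denom = max(n - edf, 1e-10)
                score = n * rss / denom**2
                if best is None or score < best[0]:
                    best = (score, lam)
            gcv_score, lam = best
        else:
            lam = float(smoothing)
            if lam < 0:
                raise ValueError("smoothing must be >= 0")
            rz = resid_coeffs(lam)
            denom = max(n - edf_of(lam), 1e-10)
            gcv_score = n * float(rz @ rz) / denom**2

        resid_u = self._U @ resid_coeffs(lam)
        fitted_u = v - resid_u
        fitted = fitted_u[self._inverse]
        residuals = values - fitted
        return SplineFit(
            x=self.x_full, y=self.y_full, fitted=fitted, residuals=residuals,
            smoothing=float(lam), edf=edf_of(lam), gcv=gcv_score,
        )


def fit_tps(x, y, values, smoothing: float | str = "gcv") -> SplineFit:
    """One-shot convenience wrapper around :class:`ThinPlateSpline`."""
    return ThinPlateSpline(x, y).fit(values, smoothing=smoothing)


@dataclass
class AdjustedResiduals:
    """Residuals shifted to be non-negative for dissimilarity analyses.

    ``values = residuals + shift`` exactly, with
    ``shift = max(0, -min(residuals))`` so the minimum becomes 0 whenever
    any residual was negative. A rigid shift preserves all pairwise
    differences, so it changes nothing but the origin.
    """

    values: np.ndarray
    shift: float


def adjust_nonzero(residuals: np.ndarray) -> AdjustedResiduals:
    """Shift a residual vector so its minimum is zero (if it was negative)."""
    residuals = np.asarray(residuals, dtype=float)
    shift = float(max(0.0, -residuals.min())) if residuals.size else 0.0
    return AdjustedResiduals(residuals + shift, shift)


@dataclass
class SpatialCorrection:
    """Per-ASV spatial correction of a transformed count table."""

    residuals: pd.DataFrame     # unadjusted residuals (heritability input)
    adjusted: pd.DataFrame      # non-negative residuals (community input)
    shifts: pd.Series           # per-ASV shift applied
    smoothing: pd.Series        # per-ASV lam chosen
    edf: pd.Series              # per-ASV effective degrees of freedom


def spatial_correct_matrix(
    sqrt_counts, coordinates: pd.DataFrame, smoothing: float | str = "gcv"
) -> SpatialCorrection:
    """Fit one thin-plate surface per ASV and collect both residual variants.

    Parameters
    ----------
    sqrt_counts
        A ``CountMatrix`` in sqrt state, or a plain DataFrame of
        transformed abundances (samples x ASVs).
    coordinates
        DataFrame indexed by sample id with columns ``x`` and ``y``.

    Raises
    ------
    KeyError
        If any sample in the count table has no coordinates.
    """
    df = getattr(sqrt_counts, "data", sqrt_counts)
    state = getattr(sqrt_counts, "state", "sqrt")
    if state != "sqrt":
        raise ValueError("spatial correction expects the sqrt-transformed matrix")
    missing = [s for s in df.index if s not in coordinates.index]
    if missing:
        raise KeyError(f"samples without coordinates: {missing[:5]}")
    coords = coordinates.loc[df.index]
    tps = ThinPlateSpline(coords["x"].to_numpy(float), coords["y"].to_numpy(float))

    resid, adj, shifts, lams, edfs = {}, {}, {}, {}, {}
    for asv in df.columns:
        fit = tps.fit(df[asv].to_numpy(float), smoothing=smoothing)
        ar = adjust_nonzero(fit.residuals)
        resid[asv] = fit.residuals
        adj[asv] = ar.values
        shifts[asv] = ar.shift
        lams[asv] = fit.smoothing
        edfs[asv] = fit.edf

    return SpatialCorrection(
        residuals=pd.DataFrame(resid, index=df.index),
        adjusted=pd.DataFrame(adj, index=df.index),
        shifts=pd.Series(shifts, name="shift"),
        smoothing=pd.Series(lams, name="smoothing"),
        edf=pd.Series(edfs, name="edf"),
    )
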
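"""Count-table preprocessing: rarefaction, transformation, core microbiome,
and the soil principal-component covariate.

The count table travels through three states: ``raw`` integer counts,
``rarefied`` (every sample subsampled without replacement to a common
depth), and ``sqrt`` (element-wise square root of a rarefied table, which
down-weights dominant ASVs before distance and heritability analyses).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SoilPc1",
    "rarefy",
    "remove_singletons",
    "identify_core",
    "sqrt_transform",
    "soil_pc1",
]


@dataclass
class CountMatrix:
    """A samples x ASVs table with an explicit processing state.

    state: ``raw`` | ``rarefied`` | ``sqrt``. ``depth`` is set once
    rarefied. Values are integers until the sqrt transform.
    """

    data: pd.DataFrame
    state: str = "raw"
    depth: int | None = None

    def __post_init__(self):
        if self.state not in {"raw", "rarefied", "sqrt"}:
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == "rarefied":
            sums = self.data.sum(axis=1)
            if self.depth is None or not (sums == self.depth).all():
                raise ValueError("rarefied state requires every row to sum to depth")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def asvs(self) -> list[str]:
        return list(self.data.columns)


def rarefy(counts: CountMatrix, depth: int, seed=0) -> tuple[CountMatrix, list[str]]:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Each retained sample's counts become a multivariate-hypergeometric draw
    of ``depth`` reads from its observed reads. Samples whose total is
    below ``depth`` are dropped and returned in the second element.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if counts.state != "raw":
        raise ValueError("rarefy expects a raw count matrix")
    rng = np.random.default_rng(seed)
    df = counts.data
    totals = df.sum(axis=1)
    dropped = list(df.index[totals < depth])
    kept = df.loc[totals >= depth]
    out = np.empty_like(kept.to_numpy())
    for r, row in enumerate(kept.to_numpy()):
        if row.sum() == depth:
            out[r] = row
        else:
            out[r] = rng.multivariate_hypergeometric(row, depth)
    rar = pd.DataFrame(out, index=kept.index, columns=kept.columns)
    return CountMatrix(rar, state="rarefied", depth=depth), dropped


def remove_singletons(counts: CountMatrix) -> CountMatrix:
    """Drop ASVs whose total count across all samples is exactly 1."""
    df = counts.data
    keep = df.columns[df.sum(axis=0) != 1]
    return CountMatrix(df[keep], state=counts.state, depth=counts.depth)


def identify_core(
    counts: CountMatrix, prevalence_threshold: float = 0.8
) -> tuple[list[str], float]:
    """Core ASVs: present (count > 0) in at least the threshold fraction of samples.

    Returns the core ASV ids and the mean per-sample relative abundance of
    the core set (mean over samples of core reads / total reads).
    """
    if not (0.0 < prevalence_threshold <= 1.0):
        raise ValueError("prevalence_threshold must be in (0, 1]")
    df = counts.data
    if df.shape[0] == 0:
        return [], float("nan")
    prevalence = (df > 0).mean(axis=0)
    core = list(df.columns[prevalence >= prevalence_threshold])
    totals = df.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = df[core].sum(axis=1) / totals.replace(0, np.nan)
    return core, float(frac.mean()) if core else 0.0


def sqrt_transform(counts: CountMatrix) -> CountMatrix:
    """Element-wise square root of a rarefied table."""
    if counts.state != "rarefied":
        raise ValueError("sqrt_transform expects a rarefied matrix")
    return CountMatrix(np.sqrt(counts.data), state="sqrt", depth=counts.depth)


@dataclass
class SoilPc1:
    """First principal component of the standardised soil covariates."""

    scores: pd.Series              # per sample, standardised units
    loadings: pd.Series            # per variable, unit-norm
    variance_explained: float      # fraction of total standardised variance
    imputed: dict[str, int]        # per variable, number of mean-imputed entries


def soil_pc1(soil: pd.DataFrame, sign_variable: str | None = None) -> SoilPc1:
    """Mean-impute, z-score, and extract PC1 of the soil covariates.

    Missing entries are replaced with the column mean; columns are z-score
    standardised; PC1 comes from the eigendecomposition of the correlation
    matrix. The loading sign is fixed so that ``sign_variable`` (default:
    the first column, pH in the study layout) loads positively.

    Raises
    ------
    ValueError
        If a column has (near-)zero variance after imputation — its
        standardisation is undefined; the error names the column.
    """
    if soil.shape[1] < 2 or soil.shape[0] < 3:
        raise ValueError("need >= 2 variables and >= 3 samples")
    imputed = {c: int(soil[c].isna().sum()) for c in soil.columns}
    filled = soil.fillna(soil.mean())
    sds = filled.std(ddof=1)
    bad = sds.index[(sds == 0) | ~np.isfinite(sds)]
    if len(bad):
        raise ValueError(f"zero-variance soil column(s): {list(bad)}")
    z = (filled - filled.mean()) / sds
    corr = np.cov(z.to_numpy(), rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    top = vecs[:, order[0]]
    sign_variable = sign_variable or soil.columns[0]
    k = list(soil.columns).index(sign_variable)
    if top[k] < 0:
        top = -top
    scores = pd.Series(z.to_numpy() @ top, index=soil.index, name="soil_pc1")
    loadings = pd.Series(top, index=soil.columns, name="pc1_loading")
    var_explained = float(vals[order[0]] / vals.sum())
    return SoilPc1(scores, loadings, var_explained, imputed)
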
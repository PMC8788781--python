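"""Proteome-phenotype integration for single-tubule cohorts.

Given a protein x tubule quantity matrix and a per-tubule phenotype table,
this module computes the correlation structures the study design revolves
around: protein-protein and protein-phenotype Pearson matrices, hierarchical
clustering of correlation profiles (Euclidean distance, average linkage),
PCA of tubules or proteins, per-cell-class chord contributions of positive
and negative correlation mass, and the integration of within-cohort
covariation with knockout regulation.

Phenotype sign convention: correlations are computed on signed values with
V_te = lumen - bath. Because basal V_te is negative, a protein whose
abundance brings the voltage closer to zero shows a *positive* correlation
with V_te. For the amiloride-sensitive voltage the magnitude convention
(``|dVte_amil|``) is available via a flag on the callers that need it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

#: minimum pairwise-complete observations for any reported correlation
DEFAULT_MIN_OBS = 3
#: default minimum fraction of tubules in which a protein must be observed
#: to enter correlation/PCA analyses (under-sampled targets are excluded)
DEFAULT_MIN_VALID_FRACTION = 0.7


def filter_by_completeness(
    m: pd.DataFrame, min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION
) -> pd.DataFrame:
    """Drop proteins observed in too few samples to analyse reliably.

    Proteins quantified in fewer than ``min_valid_fraction`` of the samples
    have insufficient readings for correlation or component analysis and are
    removed before those steps.
    """
    if not 0 < min_valid_fraction <= 1:
        raise ValueError("min_valid_fraction must be in (0, 1]")
    frac = m.notna().mean(axis=1)
    return m.loc[frac >= min_valid_fraction]


def correlation_matrix(
    m: pd.DataFrame,
    phenotypes: pd.DataFrame | None = None,
    min_obs: int = DEFAULT_MIN_OBS,
) -> pd.DataFrame:
    """Pearson correlations over pairwise-complete observations.

    ``m`` is protein x tubule; series are correlated across tubules. With no
    ``phenotypes`` the result is the square protein x protein matrix (unit
    diagonal); with a tubule x phenotype table it is the rectangular
    protein x phenotype grid. Pairs with fewer than ``min_obs`` shared
    observations, or with a zero-variance member, are missing (NaN).
    """
    if min_obs < 3:
        raise ValueError("min_obs must be >= 3 for a meaningful correlation")
    prof = m.T.astype(float)  # tubules x proteins
    if phenotypes is None:
        corr = prof.corr(min_periods=min_obs)
        return corr
    pheno = phenotypes.astype(float).reindex(prof.index)
    corr = pd.DataFrame(index=m.index, columns=pheno.columns, dtype=float)
    for col in pheno.columns:
        corr[col] = prof.corrwith(pheno[col], axis=0)
        # corrwith has no min_periods; enforce the observation floor directly
        n_shared = prof.notna().mul(pheno[col].notna(), axis=0).sum(axis=0)
        corr.loc[n_shared[n_shared < min_obs].index, col] = np.nan
    return corr


def hclust_order(corr: pd.DataFrame) -> tuple[list, np.ndarray]:
    """Average-linkage clustering of correlation profiles.

    Rows of the square correlation matrix are treated as profiles and
    clustered on their Euclidean distances. Labels whose profile still
    contains missing values after symmetric dropping are removed. Returns
    the leaf ordering (labels) and the scipy linkage matrix; ties resolve
    deterministically by input order.
    """
    if corr.shape[0] != corr.shape[1]:
        raise ValueError("hclust_order expects a square correlation matrix")
    c = corr.copy()
    # symmetric drop of labels with missing profile entries
    while c.isna().any().any():
        worst = c.isna().sum(axis=1).idxmax()
        c = c.drop(index=worst, columns=worst)
    if c.shape[0] < 2:
        raise ValueError("need at least 2 items with complete profiles to cluster")
    dist = pdist(c.to_numpy(dtype=float), metric="euclidean")
    link = linkage(dist, method="average")
    order = [c.index[i] for i in leaves_list(link)]
    return order, link


@dataclass
class PCAResult:
    scores: pd.DataFrame            # observations x components
    loadings: pd.DataFrame          # features x components
    variance_fractions: np.ndarray  # sums to 1


def pca(m: pd.DataFrame, axis: str = "tubules") -> PCAResult:
    """Mean-centered SVD principal components.

    ``m`` is protein x tubule. ``axis="tubules"`` treats tubules as the
    observations (proteins as features), matching a per-tubule proteome PCA;
    ``axis="proteins"`` transposes the roles. The matrix must be complete
    (impute first). Component signs are fixed so the largest-magnitude
    loading of each component is positive; degenerate directions simply
    carry zero variance.
    """
    if axis not in ("tubules", "proteins"):
        raise ValueError(f"axis must be 'tubules' or 'proteins', got {axis!r}")
    X = (m.T if axis == "tubules" else m).astype(float)
    if X.isna().any().any():
        raise ValueError("pca requires a complete matrix; impute missing values first")
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 observations and 2 features")
    arr = X.to_numpy()
    arr = arr - arr.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(arr, full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for k in range(len(s)):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    comps = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(u * s, index=X.index, columns=comps),
        loadings=pd.DataFrame(vt.T, index=X.columns, columns=comps),
        variance_fractions=frac,
    )


def chord_contributions(
    corr: pd.DataFrame,
    markers: pd.Series | dict,
    sign: str = "pos",
) -> pd.DataFrame:
    """Per-cell-class contribution of correlation mass to each phenotype.

    For ``sign="pos"`` the mass of class ``c`` toward phenotype ``f`` is the
    sum of ``max(r, 0)`` over that class's proteins (``max(-r, 0)`` for
    ``"neg"``); widths normalize the masses to sum to 1 over all
    (class, phenotype) pairs of that sign — the chord widths of a circos
    plot. Positive and negative masses are kept separate rather than summed
    signed, mirroring paired positive/negative chord panels. Missing
    correlations contribute nothing; an empty class has zero mass.

    Rows are sorted by decreasing mass (link.decreasing presentation parity).
    """
    if sign not in ("pos", "neg"):
        raise ValueError(f"sign must be 'pos' or 'neg', got {sign!r}")
    markers = pd.Series(markers)
    missing = [p for p in corr.index if p not in markers.index]
    if missing:
        raise ValueError(f"proteins absent from the marker map: {missing}")
    vals = corr.astype(float)
    clipped = vals.clip(lower=0) if sign == "pos" else (-vals).clip(lower=0)
    clipped = clipped.fillna(0.0)
    mass = clipped.groupby(markers.reindex(corr.index)).sum()
    long = mass.stack().rename("mass").reset_index()
    long.columns = ["cell_class", "phenotype", "mass"]
    total = long["mass"].sum()
    long["width"] = long["mass"] / total if total > 0 else 0.0
    long["sign"] = sign
    return long.sort_values("mass", ascending=False, kind="stable").reset_index(
        drop=True
    )


@dataclass
class CovariationResult:
    """Covariation-vs-regulation integration output.

    ``table`` pairs each protein's WT covariation with the anchor (``x``,
    Pearson r across tubules) with its knockout response (``y``, log2 fold
    change). ``quadrant_counts`` uses keys like ``"x>0,y<0"``. Permutation
    p-values are one-sided: ``p_r_negative`` for a negative overall r,
    ``p_quadrant_mass`` for excess co-regulation mass (sum of ``x * -y``
    over the ``x>0, y<0`` quadrant) beyond the label-permutation null.
    """

    table: pd.DataFrame
    r: float
    quadrant_counts: dict = field(default_factory=dict)
    p_r_negative: float | None = None
    p_quadrant_mass: float | None = None
    n_permutations: int = 0


def _quadrant_mass(x: np.ndarray, y: np.ndarray) -> float:
    sel = (x > 0) & (y < 0)
    return float(np.sum(x[sel] * -y[sel]))


def covariation_vs_regulation(
    wt: pd.DataFrame,
    anchor_protein: str,
    ko_results: pd.DataFrame,
    min_obs: int = DEFAULT_MIN_OBS,
    n_permutations: int = 0,
    seed: int | None = 0,
) -> CovariationResult:
    """Integrate WT tubule-to-tubule covariation with KO regulation.

    ``x_p`` is the Pearson correlation of protein ``p`` with the anchor
    across WT tubules (pairwise-complete, observation floor ``min_obs``);
    ``y_p`` is the protein's log2 fold change from ``ko_results``. The
    anchor itself is excluded (its self-correlation is degenerate). With
    ``n_permutations > 0`` the x-y pairing is permuted over protein labels
    to test (one-sided) for a negative overall correlation and for excess
    mass in the coexpressed-and-decreased quadrant.
    """
    if anchor_protein not in wt.index:
        raise ValueError(f"anchor protein {anchor_protein!r} absent from WT matrix")
    prof = wt.T.astype(float)
    x = prof.corrwith(prof[anchor_protein])
    n_shared = prof.notna().mul(prof[anchor_protein].notna(), axis=0).sum(axis=0)
    x[n_shared < min_obs] = np.nan
    x = x.drop(index=anchor_protein)
    y = ko_results["log2fc"]
    table = pd.DataFrame({"x": x, "y": y.reindex(x.index)}).dropna()
    if len(table) < 3:
        raise ValueError("need >= 3 proteins shared between WT matrix and KO results")
    xv = table["x"].to_numpy()
    yv = table["y"].to_numpy()
    r = float(np.corrcoef(xv, yv)[0, 1])
    counts = {
        "x>0,y<0": int(np.sum((xv > 0) & (yv < 0))),
        "x>0,y>=0": int(np.sum((xv > 0) & (yv >= 0))),
        "x<=0,y<0": int(np.sum((xv <= 0) & (yv < 0))),
        "x<=0,y>=0": int(np.sum((xv <= 0) & (yv >= 0))),
    }
    result = CovariationResult(table=table, r=r, quadrant_counts=counts)
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        obs_mass = _quadrant_mass(xv, yv)
        perm_r = np.empty(n_permutations)
        perm_mass = np.empty(n_permutations)
        for i in range(n_permutations):
            yp = rng.permutation(yv)
            perm_r[i] = np.corrcoef(xv, yp)[0, 1]
            perm_mass[i] = _quadrant_mass(xv, yp)
        # add-one permutation p-values
        result.p_r_negative = float((1 + np.sum(perm_r <= r)) / (1 + n_permutations))
        result.p_quadrant_mass = float(
            (1 + np.sum(perm_mass >= obs_mass)) / (1 + n_permutations)
        )
        result.n_permutations = n_permutations
    return result
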
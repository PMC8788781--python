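"""Untargeted label-free differential analysis and iBAQ copy-number surrogate.

Protein x sample LFQ-style intensity matrices are log2-transformed and
normalized by per-sample mean subtraction; remaining missing values — which
in nano-scale proteomics are predominantly low-abundance dropouts — are
imputed from a per-sample normal distribution downshifted into the left tail
of the observed intensities. Group differences are then assessed with a
two-sample two-tailed t-test per protein, with Benjamini-Hochberg adjustment
and a combined fold-change / p-value hit flag.

iBAQ values divide a protein's summed intensity by the number of
theoretically observable fully-tryptic peptides of its sequence, giving a
copy-number surrogate comparable across proteins.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: downshift of the imputation distribution, in units of the per-sample SD
DEFAULT_IMPUTE_SHIFT = 1.8
#: width of the imputation distribution, as a fraction of the per-sample SD
DEFAULT_IMPUTE_WIDTH = 0.3
#: default volcano cutoffs: |log2 fold change| >= 1 and p < 0.05
DEFAULT_FC_CUT = 1.0
DEFAULT_P_CUT = 0.05
#: observable tryptic peptide length range for iBAQ
DEFAULT_MIN_PEPTIDE_LEN = 6
DEFAULT_MAX_PEPTIDE_LEN = 30

_VALID_RESIDUES = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYUXBZ]+$")


def log_center(m: pd.DataFrame) -> pd.DataFrame:
    """log2-transform and subtract each sample's (column's) mean.

    Means are over observed entries; missing cells stay missing. Removes
    per-sample loading so columns are comparable; scaling a raw column by any
    constant leaves the output unchanged.
    """
    arr = m.astype(float)
    if (arr <= 0).any().any():
        raise ValueError("all observed intensities must be positive before log2")
    logged = np.log2(arr)
    return logged - logged.mean(axis=0, skipna=True)


def impute_downshift(
    m: pd.DataFrame,
    shift: float = DEFAULT_IMPUTE_SHIFT,
    width: float = DEFAULT_IMPUTE_WIDTH,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Fill missing cells from a downshifted per-sample normal distribution.

    For sample ``s`` with observed mean ``mu_s`` and SD ``sd_s``, missing
    cells are drawn from ``Normal(mu_s - shift*sd_s, (width*sd_s)^2)`` —
    the standard model for intensities absent because they fell below the
    detection limit. Deterministic for a fixed ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = m.astype(float).copy()
    for col in out.columns:
        vals = out[col]
        observed = vals.dropna()
        n_missing = int(vals.isna().sum())
        if n_missing == 0:
            continue
        if len(observed) < 3:
            raise ValueError(
                f"sample {col!r} has {len(observed)} observed values; "
                "need >= 3 to estimate the imputation distribution"
            )
        mu, sd = observed.mean(), observed.std(ddof=1)
        draws = rng.normal(mu - shift * sd, width * sd, size=n_missing)
        out.loc[vals.isna(), col] = draws
    return out


def differential(
    m: pd.DataFrame,
    groups: pd.Series | dict,
    fc_cut: float = DEFAULT_FC_CUT,
    p_cut: float = DEFAULT_P_CUT,
    equal_var: bool = True,
    adjust: bool = True,
) -> pd.DataFrame:
    """Two-sample two-tailed t-test per protein on log2 values.

    ``groups`` maps sample (column) names to the labels ``"WT"`` / ``"KO"``.
    ``log2fc`` is mean(KO) - mean(WT). The default is the Student
    (equal-variance) test; set ``equal_var=False`` for Welch. Proteins with
    zero variance in both groups have an undefined p-value and are flagged
    ``degenerate`` rather than dropped.

    Returns a volcano-ready table with columns ``protein_id, log2fc, t_stat,
    p_value, q_value, hit_flag, degenerate``.
    """
    groups = pd.Series(groups)
    unknown = set(groups.unique()) - {"WT", "KO"}
    if unknown:
        raise ValueError(f"group labels must be WT/KO, got extra {sorted(unknown)}")
    wt_cols = [c for c in m.columns if groups.get(c) == "WT"]
    ko_cols = [c for c in m.columns if groups.get(c) == "KO"]
    if len(wt_cols) < 2 or len(ko_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    wt = m[wt_cols].to_numpy(dtype=float)
    ko = m[ko_cols].to_numpy(dtype=float)
    log2fc = np.nanmean(ko, axis=1) - np.nanmean(wt, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = stats.ttest_ind(
            ko, wt, axis=1, equal_var=equal_var, nan_policy="omit"
        )
    t_stat = np.asarray(t_stat, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    q = np.full_like(p, np.nan)
    if adjust and (~degenerate).any():
        q[~degenerate] = multipletests(p[~degenerate], method="fdr_bh")[1]
    hit = (~degenerate) & (p < p_cut) & (np.abs(log2fc) >= fc_cut)
    return pd.DataFrame(
        {
            "protein_id": m.index,
            "log2fc": log2fc,
            "t_stat": t_stat,
            "p_value": p,
            "q_value": q,
            "hit_flag": hit,
            "degenerate": degenerate,
        }
    ).set_index("protein_id")


def cleave_tryptic(sequence: str) -> list[str]:
    """Fully-tryptic cleavage: cut C-terminal to K or R unless followed by P."""
    if not sequence:
        raise ValueError("empty protein sequence")
    sequence = sequence.upper()
    if not _VALID_RESIDUES.match(sequence):
        raise ValueError("sequence contains characters outside the amino-acid alphabet")
    peptides, start = [], 0
    for i, aa in enumerate(sequence):
        if aa in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            peptides.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        peptides.append(sequence[start:])
    return peptides


def tryptic_digest(
    sequence: str,
    min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
    max_len: int = DEFAULT_MAX_PEPTIDE_LEN,
) -> int:
    """Count theoretically observable fully-tryptic peptides (zero missed
    cleavages, length within ``[min_len, max_len]``) — the iBAQ denominator."""
    return sum(min_len <= len(p) <= max_len for p in cleave_tryptic(sequence))


def ibaq(summed_intensity: float, observable_count: int) -> float:
    """iBAQ value: summed protein intensity / observable peptide count.

    A protein with no observable peptide has no defined iBAQ (NaN), which is
    a missing value rather than an error.
    """
    if observable_count < 1:
        return float("nan")
    return summed_intensity / observable_count


def ibaq_table(
    intensities: pd.Series,
    sequences: dict[str, str],
    min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
    max_len: int = DEFAULT_MAX_PEPTIDE_LEN,
) -> pd.DataFrame:
    """iBAQ values for every protein with a sequence record."""
    rows = []
    for pid, total in intensities.items():
        seq = sequences.get(pid)
        if seq is None:
            continue
        count = tryptic_digest(seq, min_len, max_len)
        rows.append(
            {
                "protein_id": pid,
                "summed_intensity": total,
                "observable_peptides": count,
                "ibaq": ibaq(total, count),
            }
        )
    return pd.DataFrame(rows).set_index("protein_id")
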
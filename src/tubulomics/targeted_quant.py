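"""Targeted (parallel-reaction-monitoring) quantification at MS2 level.

Transition-level chromatogram peaks from an inclusion-list acquisition are
subjected to three quality filters before quantification: a mass-accuracy
filter (strict ``|ppm| < ppm_max``), an acquisition-window filter (the apex
must elute inside the scheduled window), and a coelution requirement (all
transitions of a peptide in a sample must apex within a small retention-time
spread). Surviving transition areas are summed to peptides and peptides to
proteins; protein-level tables are normalized by log2 transformation followed
by subtraction of column (sample) and row (protein) means.

Tables are plain pandas DataFrames, one row per transition, matching a flat
Skyline-style transition report:
``peptide_id, protein_id, fragment_id, apex_rt, rt_window_start,
rt_window_end, mass_error_ppm, area, sample_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: default mass-accuracy cutoff (exclusive), ppm
DEFAULT_PPM_MAX = 10.0
#: default maximum apex retention-time spread among coeluting transitions, min
DEFAULT_COELUTION_TOL = 0.2

TRANSITION_COLUMNS = [
    "peptide_id",
    "protein_id",
    "fragment_id",
    "apex_rt",
    "rt_window_start",
    "rt_window_end",
    "mass_error_ppm",
    "area",
    "sample_id",
]

#: rejection reason codes in precedence order
REASON_PPM = "ppm"
REASON_WINDOW = "window"
REASON_COELUTION = "coelution"
REASON_SINGLETON = "singleton"


@dataclass
class QuantMatrix:
    """Protein x sample intensity grid with explicit missingness.

    ``scale`` is one of ``raw`` (summed areas), ``log2`` or ``centered``
    (log2, column- then row-mean subtracted). ``provenance`` carries filter
    summary counts when the matrix came out of :func:`filter_transitions` /
    :func:`quantify`.
    """

    values: pd.DataFrame
    scale: str = "raw"
    provenance: dict = field(default_factory=dict)


def _validate_transitions(peaks: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRANSITION_COLUMNS if c not in peaks.columns]
    if missing:
        raise ValueError(f"transition table is missing columns: {missing}")
    bad = peaks["rt_window_start"] >= peaks["rt_window_end"]
    if bad.any():
        raise ValueError("rt_window_start must be < rt_window_end for every row")
    if (peaks["area"] < 0).any():
        raise ValueError("transition areas must be >= 0")
    return peaks


def filter_transitions(
    peaks: pd.DataFrame,
    ppm_max: float = DEFAULT_PPM_MAX,
    coelution_tol: float = DEFAULT_COELUTION_TOL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the three transition-quality filters.

    A transition is kept iff

    1. ``|mass_error_ppm| < ppm_max`` (strictly below the cutoff),
    2. its apex elutes inside the scheduled acquisition window, and
    3. it coelutes with the other surviving transitions of its
       (peptide, sample) group: the max pairwise apex spread must not exceed
       ``coelution_tol``, enforced by iteratively dropping the transition
       farthest from the group's median apex (first in input order on ties)
       until the spread condition holds.

    Peptides left with fewer than two transitions in a sample are dropped
    entirely — coelution is undefined for a singleton.

    Returns ``(kept, rejected)``; ``rejected`` carries a ``reason`` column
    with exactly one primary code per row, in the precedence order
    ppm > window > coelution > singleton.
    """
    if ppm_max <= 0 or coelution_tol <= 0:
        raise ValueError("ppm_max and coelution_tol must be positive")
    if peaks.empty:
        empty = peaks.copy()
        rejected = peaks.copy()
        rejected["reason"] = pd.Series(dtype=object)
        return empty, rejected
    peaks = _validate_transitions(peaks).reset_index(drop=True)

    reason = pd.Series(index=peaks.index, dtype=object)
    ppm_fail = peaks["mass_error_ppm"].abs() >= ppm_max
    reason[ppm_fail] = REASON_PPM
    in_window = peaks["apex_rt"].between(
        peaks["rt_window_start"], peaks["rt_window_end"]
    )
    reason[reason.isna() & ~in_window] = REASON_WINDOW

    surviving = reason.isna()
    for (_, _), idx in peaks[surviving].groupby(
        ["peptide_id", "sample_id"], sort=False
    ).groups.items():
        idx = list(idx)
        rts = peaks.loc[idx, "apex_rt"]
        while len(idx) >= 2 and rts.max() - rts.min() > coelution_tol:
            dist = (rts - rts.median()).abs()
            victim = dist.idxmax()  # first max in input order
            reason[victim] = REASON_COELUTION
            idx.remove(victim)
            rts = peaks.loc[idx, "apex_rt"]
        if len(idx) < 2:
            for i in idx:
                reason[i] = REASON_SINGLETON

    kept = peaks[reason.isna()].copy()
    rejected = peaks[reason.notna()].copy()
    rejected["reason"] = reason[reason.notna()]
    return kept, rejected


def quantify(kept: pd.DataFrame) -> QuantMatrix:
    """Sum filtered transition areas to peptide and then protein intensities.

    Cells with no surviving transition are missing (NaN), never zero.
    """
    if kept.empty:
        return QuantMatrix(pd.DataFrame(), scale="raw")
    _validate_transitions(kept)
    peptide = (
        kept.groupby(["protein_id", "peptide_id", "sample_id"], sort=False)["area"]
        .sum()
        .reset_index()
    )
    protein = (
        peptide.groupby(["protein_id", "sample_id"], sort=False)["area"]
        .sum()
        .unstack("sample_id")
    )
    protein.index.name = "protein_id"
    protein.columns.name = "sample_id"
    return QuantMatrix(
        protein,
        scale="raw",
        provenance={"n_transitions": int(len(kept)),
                    "n_peptides": int(peptide["peptide_id"].nunique())},
    )


def double_center(m: QuantMatrix | pd.DataFrame) -> QuantMatrix:
    """log2-transform and subtract column (sample) then row (protein) means.

    Means are taken over observed entries only; for a complete matrix one
    pass of each leaves all row and column means at zero. Removes both
    per-sample loading differences and per-protein baseline abundance, so the
    centered values are relative within-cohort deviations.
    """
    values = m.values if isinstance(m, QuantMatrix) else m
    provenance = dict(m.provenance) if isinstance(m, QuantMatrix) else {}
    if isinstance(m, QuantMatrix) and m.scale != "raw":
        raise ValueError(f"double_center expects a raw matrix, got scale={m.scale!r}")
    arr = values.astype(float)
    if (arr <= 0).any().any():
        raise ValueError("all observed intensities must be positive before log2")
    logged = np.log2(arr)
    centered = logged - logged.mean(axis=0, skipna=True)
    centered = centered.sub(centered.mean(axis=1, skipna=True), axis=0)
    return QuantMatrix(centered, scale="centered", provenance=provenance)
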
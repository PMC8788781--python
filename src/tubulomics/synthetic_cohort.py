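"""Synthetic single-tubule cohort simulator with full ground truth.

Generates cohorts of cortical collecting ducts (CCDs) that emulate the
statistical structure of phenotyped single-tubule proteomics data:

* geometry drawn from the 400-600 um length range of perfusable CCDs;
* a principal/intercalated (PC/IC) cell composition axis whose tubule-to-
  tubule variation is the dominant coherent signal in the marker proteome
  (it drives the first principal component), with the IC fraction coupled
  negatively to tubule length;
* a PC transport-program axis that raises ENaC subunits while lowering
  aquaporins and NEDD4L — tubules adapted for Na+ transport versus water
  transport;
* an IC-B program latent shared by pendrin and its functional partners
  (CLCNKB, BSND, vH+-ATPase C2), giving the anchor co-expression that the
  covariation-vs-regulation integration recovers;
* a ~40-protein marker panel spanning >= 5 orders of magnitude of baseline
  abundance, log-normal biological and measurement noise in log2 space, and
  missing-not-at-random logistic dropout of low intensities;
* electrophysiology forward-simulated through the same physical models the
  analysis inverts: a two-conductance equivalent circuit for the
  transepithelial voltage (transcellular EMF behind conductance g_t,
  paracellular shunt g_p; luminal amiloride sets g_t ~ 0), the sealed-end
  cable model for the current-pulse deflections at 13 nA, and the GHK
  dilution potential at a planted P_Na/P_Cl;
* pendrin-KO cohorts (mouse-level samples of 5 pooled CCDs) with a planted
  down-regulated module and the anchor reduced to the noise floor.

Every generated observable is traceable to a :class:`CohortTruth` entry and
all generators are pure functions of ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .electrophysiology import forward_cable, ghk_dp

# ---------------------------------------------------------------------------
# marker panel: (protein, cell class, log10 baseline abundance at the
# reference tubule: IC fraction 0.28, length 500 um, all latents zero).
# Baselines span 5.1 orders of magnitude, mirroring the dynamic range of a
# CCD proteome profile: Na/K-ATPase and cytoskeleton on top, ENaC subunits
# and ROMK orders of magnitude lower.
DEFAULT_PANEL: tuple[tuple[str, str, float], ...] = (
    ("ACTB", "housekeeping", 7.2),
    ("GAPDH", "housekeeping", 6.9),
    ("ATP1A1", "housekeeping", 6.8),
    ("EEF1A1", "housekeeping", 6.6),
    ("ATP1B1", "housekeeping", 6.5),
    ("ALDOA", "housekeeping", 6.4),
    ("TUBB5", "housekeeping", 6.3),
    ("HSPA8", "housekeeping", 6.2),
    ("PKM", "housekeeping", 6.1),
    ("VIM", "housekeeping", 6.0),
    ("LDHA", "housekeeping", 5.9),
    ("ANXA2", "housekeeping", 5.7),
    ("MYH9", "housekeeping", 5.5),
    ("CLTC", "housekeeping", 5.3),
    ("RAB11A", "housekeeping", 5.0),
    ("CCT2", "housekeeping", 4.8),
    ("AQP2", "PC", 6.2),
    ("AQP3", "PC", 5.8),
    ("AQP4", "PC", 5.2),
    ("HSD11B2", "PC", 4.6),
    ("NEDD4L", "PC", 4.0),
    ("SCNN1A", "PC", 3.4),
    ("SCNN1B", "PC", 3.2),
    ("SCNN1G", "PC", 3.0),
    ("AVPR2", "PC", 2.5),
    ("KCNJ1", "PC", 2.1),
    ("CA2", "IC-A", 5.9),
    ("SLC4A1", "IC-A", 5.8),
    ("ATP6V1B1", "IC-A", 5.6),
    ("ATP6V1A", "IC-A", 5.4),
    ("ATP6V1E1", "IC-A", 5.2),
    ("ATP6V1F", "IC-A", 5.1),
    ("ATP6V0D2", "IC-A", 5.0),
    ("ATP6V0A4", "IC-A", 4.9),
    ("ATP6V1H", "IC-A", 4.7),
    ("CA12", "IC-A", 4.4),
    ("ATP6V1G3", "IC-A", 4.3),
    ("SLC26A4", "IC-B", 4.8),
    ("ATP6V1C2", "IC-B", 4.5),
    ("CLCNKB", "IC-B", 4.2),
    ("BSND", "IC-B", 4.0),
    ("INSRR", "IC-B", 3.6),
)

ENAC_SUBUNITS = ("SCNN1A", "SCNN1B", "SCNN1G")
AQP_CHANNELS = ("AQP2", "AQP3", "AQP4")
#: subunit whose abundance sets the transcellular conductance (beta-ENaC)
CONDUCTANCE_PROTEIN = "SCNN1B"
DEFAULT_ANCHOR = "SLC26A4"
DEFAULT_KO_MODULE = ("CLCNKB", "BSND", "ATP6V1C2", "INSRR")

#: curated marker set for cell-class clustering displays. Proteins whose
#: tubule-to-tubule variation follows the Na+-vs-water transport program
#: rather than cell composition (ENaC subunits, NEDD4L) are not class
#: discriminators and are left out, as are low-abundance targets.
CLUSTER_MARKERS: dict[str, tuple[str, ...]] = {
    "PC": ("AQP2", "AQP3", "AQP4"),
    "IC": (
        "CA2",
        "SLC4A1",
        "ATP6V1B1",
        "ATP6V1A",
        "ATP6V1E1",
        "ATP6V1F",
        "ATP6V0D2",
        "SLC26A4",
        "CLCNKB",
        "BSND",
        "ATP6V1C2",
    ),
    "housekeeping": ("ACTB", "GAPDH", "ALDOA", "TUBB5", "PKM", "LDHA"),
}

#: housekeeping proteins sharing the metabolic/cytoskeletal co-regulation
#: latent (glycolytic enzymes plus the major cytoskeletal proteins); the
#: remaining housekeeping panel varies independently
HK_PROGRAM_SET = ("ACTB", "GAPDH", "ALDOA", "TUBB5", "PKM", "LDHA")


@dataclass(frozen=True)
class Couplings:
    """Planted effect sizes, all in log2 units per latent SD.

    ``enac_dv`` / ``aqp_dv`` / ``nedd4l_dv`` load the PC transport-program
    latent (ENaC up, aquaporins and NEDD4L down); ``icb_module`` loads the
    shared IC-B program latent on the pendrin module; ``hk_program`` is a
    weak shared metabolic/cytoskeletal latent of the housekeeping set;
    ``length_ic`` is the drop of IC fraction per +100 um of tubule length
    (longer tubules reach into the medulla where ICs thin out).
    """

    enac_dv: float = 0.9
    aqp_dv: float = 1.1
    nedd4l_dv: float = 0.7
    icb_module: float = 0.6
    hk_program: float = 0.7
    length_ic: float = 0.03


@dataclass(frozen=True)
class MissingnessParams:
    """MNAR logistic dropout: P(observed) = expit(slope*(log2 I - midpoint))."""

    midpoint_log2: float = 7.5
    slope: float = 2.5
    enabled: bool = True


@dataclass(frozen=True)
class CohortConfig:
    n_tubules: int = 12
    length_range: tuple[float, float] = (400.0, 600.0)   # um
    diameter_range: tuple[float, float] = (18.0, 28.0)   # um
    ic_frac_base: float = 0.28
    # IC fraction is bimodal across a cohort: superficial cortical CCDs are
    # IC-rich, medullary-ray CCDs IC-poor; within-group jitter on top.
    ic_modes: tuple[float, float] = (0.14, 0.52)
    ic_within_sd: float = 0.045
    ic_bounds: tuple[float, float] = (0.05, 0.68)
    noise_sd: float = 0.3        # biological log2 SD per tubule
    meas_sd: float = 0.2         # measurement log2 SD per observation
    emf_mV: float = -60.0        # transcellular EMF of the equivalent circuit
    g_ratio0: float = 0.5        # g_t/g_p at reference ENaC abundance
    rte_mean: float = 160.0      # Ohm cm2
    rte_sd: float = 25.0
    rte_bounds: tuple[float, float] = (60.0, 320.0)
    voltage_noise_mV: float = 0.8
    amil_residual_sd_mV: float = 0.5
    dp_noise_mV: float = 0.3
    beta_median: float = 0.7     # paracellular P_Na/P_Cl, log-normal median
    beta_log_sd: float = 0.3
    rho: float = 60.0            # Ohm cm
    T: float = 310.15            # K
    conc_control: float = 145.0  # mM
    conc_low: float = 30.0       # mM
    I0_nA: float = 13.0
    couplings: Couplings = field(default_factory=Couplings)
    missingness: MissingnessParams = field(default_factory=MissingnessParams)
    panel: tuple[tuple[str, str, float], ...] = DEFAULT_PANEL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tubules < 3:
            raise ValueError("n_tubules must be >= 3")
        for name in ("length_range", "diameter_range", "rte_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an ordered (low, high) pair")
        if not 0 < self.ic_frac_base < 1:
            raise ValueError("ic_frac_base must be in (0, 1)")
        if not all(0 < m < 1 for m in self.ic_modes):
            raise ValueError("ic_modes must be fractions in (0, 1)")
        if not 0 < self.ic_bounds[0] < self.ic_bounds[1] < 1:
            raise ValueError("ic_bounds must be ordered fractions in (0, 1)")
        for name in ("noise_sd", "meas_sd", "ic_within_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CohortTruth:
    """Planted ground truth of a generated cohort.

    ``tubules``: per-tubule geometry, composition, latents and true
    phenotypes. ``proteins``: per-protein class, baseline and planted KO
    effect. ``abundance``: realized true abundances (protein x sample),
    before measurement noise and dropout.
    """

    tubules: pd.DataFrame
    proteins: pd.DataFrame
    abundance: pd.DataFrame
    config: CohortConfig
    seed: int


def marker_map(panel=DEFAULT_PANEL) -> pd.Series:
    """Protein -> cell class mapping for a panel."""
    s = pd.Series({name: cls for name, cls, _ in panel}, name="cell_class")
    s.index.name = "protein_id"
    return s


def _panel_frame(panel) -> pd.DataFrame:
    df = pd.DataFrame(panel, columns=["protein_id", "cell_class", "log10_baseline"])
    if df["protein_id"].duplicated().any():
        raise ValueError("panel contains duplicate protein ids")
    return df.set_index("protein_id")


#: program loading of sibling subunits/channels relative to the primary
#: program proteins (beta-ENaC, AQP2)
SECONDARY_ENAC_LOADING = 0.3
SECONDARY_AQP_LOADING = 0.6


def _program_loadings(proteins: pd.DataFrame, cpl: Couplings) -> pd.Series:
    """log2 loading of each protein on the PC transport-program latent.

    The conductance-setting beta subunit and AQP2 carry the full coupling;
    sibling subunits/channels co-vary with a weaker loading.
    """
    load = pd.Series(0.0, index=proteins.index)
    for p in ENAC_SUBUNITS:
        if p in load.index:
            load[p] = (
                cpl.enac_dv if p == CONDUCTANCE_PROTEIN else SECONDARY_ENAC_LOADING
            )
    for p in AQP_CHANNELS:
        if p in load.index:
            load[p] = -cpl.aqp_dv if p == "AQP2" else -SECONDARY_AQP_LOADING
    if "NEDD4L" in load.index:
        load["NEDD4L"] = -cpl.nedd4l_dv
    return load


def _draw_ic(
    rng: np.random.Generator, cfg: CohortConfig, L: np.ndarray
) -> np.ndarray:
    """Bimodal tubule-level IC fractions, coupled negatively to length."""
    modes = np.asarray(cfg.ic_modes)
    centers = modes[rng.integers(0, len(modes), size=len(L))]
    L_mid = 0.5 * sum(cfg.length_range)
    ic = (
        centers
        + rng.normal(0.0, cfg.ic_within_sd, size=len(L))
        - cfg.couplings.length_ic * (L - L_mid) / 100.0
    )
    return np.clip(ic, *cfg.ic_bounds)


def _composition_log2(proteins: pd.DataFrame, ic_frac: np.ndarray, base: float):
    """log2 composition weight per protein (rows) x sample (cols)."""
    w = np.zeros((len(proteins), len(ic_frac)))
    cls = proteins["cell_class"].to_numpy()
    ic_rows = np.isin(cls, ("IC-A", "IC-B"))
    pc_rows = cls == "PC"
    w[ic_rows, :] = np.log2(ic_frac / base)[None, :]
    w[pc_rows, :] = np.log2((1.0 - ic_frac) / (1.0 - base))[None, :]
    return w


def apply_missingness(
    matrix: pd.DataFrame,
    params: MissingnessParams = MissingnessParams(),
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Drop cells at random with intensity-dependent (MNAR) probability.

    Each cell is observed with probability
    ``expit(slope * (log2 intensity - midpoint))``; lower intensities drop
    out more often, emulating detection-limit censoring of nano-scale
    proteomics. Deterministic under a fixed seed.
    """
    if not params.enabled:
        return matrix.copy()
    if not (np.isfinite(params.slope) and np.isfinite(params.midpoint_log2)):
        raise ValueError("missingness parameters must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = matrix.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        p_obs = expit(params.slope * (np.log2(vals) - params.midpoint_log2))
    keep = rng.random(vals.shape) < p_obs
    out = matrix.copy().astype(float)
    out[~keep] = np.nan
    return out


def calibrate_missingness(
    matrix: pd.DataFrame,
    target_missing: float,
    slope: float = 1.2,
) -> MissingnessParams:
    """Choose the logistic midpoint so the expected missing fraction of a
    matrix equals ``target_missing`` (bisection on the exact expectation)."""
    if not 0 < target_missing < 1:
        raise ValueError("target_missing must be in (0, 1)")
    logs = np.log2(matrix.to_numpy(dtype=float).ravel())
    lo, hi = logs.min() - 20.0, logs.max() + 20.0

    def expected_missing(mid: float) -> float:
        return float(np.mean(1.0 - expit(slope * (logs - mid))))

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected_missing(mid) < target_missing:
            lo = mid
        else:
            hi = mid
    return MissingnessParams(midpoint_log2=0.5 * (lo + hi), slope=slope)


def generate_cohort(
    cfg: CohortConfig = CohortConfig(),
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], CohortTruth]:
    """Generate one perfused-tubule cohort.

    Returns ``(recordings, matrices, truth)`` where ``recordings`` is an
    ElectroRecording table (one row per tubule), ``matrices`` holds the
    ``"complete"`` measured intensity matrix and the MNAR-censored
    ``"observed"`` one, and ``truth`` carries all planted values.
    """
    rng = np.random.default_rng(cfg.seed)
    proteins = _panel_frame(cfg.panel)
    cpl = cfg.couplings
    n = cfg.n_tubules
    ids = [f"T{i + 1:02d}" for i in range(n)]
    L_mid = 0.5 * sum(cfg.length_range)

    L = rng.uniform(*cfg.length_range, size=n)
    diam = rng.uniform(*cfg.diameter_range, size=n)
    ic = _draw_ic(rng, cfg, L)
    z = rng.normal(size=n)   # PC transport-program latent
    f = rng.normal(size=n)   # IC-B program latent
    h = rng.normal(size=n)   # housekeeping metabolic latent

    base_log2 = (proteins["log10_baseline"].to_numpy() * math.log2(10.0))[:, None]
    comp = _composition_log2(proteins, ic, cfg.ic_frac_base)
    length_factor = np.log2(L / L_mid)[None, :]
    prog = _program_loadings(proteins, cpl).to_numpy()[:, None] * z[None, :]
    icb_rows = np.isin(
        proteins.index.to_numpy(), (DEFAULT_ANCHOR,) + DEFAULT_KO_MODULE
    ).astype(float)[:, None]
    icb = icb_rows * cpl.icb_module * f[None, :]
    hk_rows = np.isin(proteins.index.to_numpy(), HK_PROGRAM_SET).astype(float)
    hk = hk_rows[:, None] * cpl.hk_program * h[None, :]
    bio_noise = rng.normal(0.0, cfg.noise_sd, size=comp.shape)

    true_log2 = base_log2 + comp + length_factor + prog + icb + hk + bio_noise
    abundance = pd.DataFrame(2.0**true_log2, index=proteins.index, columns=ids)

    meas = abundance * 2.0 ** rng.normal(0.0, cfg.meas_sd, size=abundance.shape)
    observed = apply_missingness(meas, cfg.missingness, rng)

    # phenotypes through the equivalent circuit + forward physical models
    a_ref = 10.0 ** proteins.loc[CONDUCTANCE_PROTEIN, "log10_baseline"]
    g_rel = cfg.g_ratio0 * abundance.loc[CONDUCTANCE_PROTEIN].to_numpy() / a_ref
    vte_true = cfg.emf_mV * g_rel / (1.0 + g_rel)
    vte_basal = vte_true + rng.normal(0.0, cfg.voltage_noise_mV, size=n)
    vte_amil = rng.normal(0.0, cfg.amil_residual_sd_mV, size=n)
    rte = np.clip(rng.normal(cfg.rte_mean, cfg.rte_sd, size=n), *cfg.rte_bounds)
    beta = np.exp(rng.normal(math.log(cfg.beta_median), cfg.beta_log_sd, size=n))
    vdp_true = np.array(
        [ghk_dp(b, cfg.conc_control, cfg.conc_low, cfg.T) for b in beta]
    )
    vdp = vdp_true + rng.normal(0.0, cfg.dp_noise_mV, size=n)
    deflections = np.array(
        [forward_cable(L[i], diam[i], rte[i], cfg.rho, cfg.I0_nA) for i in range(n)]
    )

    recordings = pd.DataFrame(
        {
            "tubule_id": ids,
            "L": L,
            "I0": cfg.I0_nA,
            "dV0": deflections[:, 0],
            "dVL": deflections[:, 1],
            "Vte_basal": vte_basal,
            "Vte_amil": vte_amil,
            "Vdp": vdp,
            "rho": cfg.rho,
            "T": cfg.T,
            "conc_control": cfg.conc_control,
            "conc_low": cfg.conc_low,
        }
    )
    tub_truth = pd.DataFrame(
        {
            "tubule_id": ids,
            "length_um": L,
            "diameter_um": diam,
            "ic_frac": ic,
            "z_pc_program": z,
            "f_icb_program": f,
            "rte_true": rte,
            "beta_true": beta,
            "vte_basal_true": vte_true,
            "vdp_true": vdp_true,
        }
    ).set_index("tubule_id")
    prot_truth = proteins.copy()
    prot_truth["ko_log2fc"] = 0.0
    truth = CohortTruth(
        tubules=tub_truth,
        proteins=prot_truth,
        abundance=abundance,
        config=cfg,
        seed=cfg.seed,
    )
    return recordings, {"complete": meas, "observed": observed}, truth


#: CCDs pooled into one mouse-level sample of a knockout cohort
KO_TUBULES_PER_MOUSE = 5
#: measurement log2 SD for pooled mouse samples (more material, tighter LFQ)
KO_MEAS_SD = 0.3
#: log10 intensity floor an absent protein's signal collapses to
KO_ANCHOR_FLOOR_LOG10 = 2.3
#: tubule-level IC-fraction SD in the knockout experiment, where a uniform
#: dissection protocol (medullary ray -> cortex) samples a consistent
#: cortico-medullary position, unlike the free heterogeneity of the
#: perfusion cohort
KO_IC_TUBULE_SD = 0.08


def generate_ko_cohort(
    cfg: CohortConfig = CohortConfig(),
    module: tuple[str, ...] = DEFAULT_KO_MODULE,
    effects: float | dict[str, float] = -1.5,
    n_wt: int = 5,
    n_ko: int = 5,
    n_proteins: int = 3630,
    anchor: str = DEFAULT_ANCHOR,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Generate a knockout-vs-littermate untargeted cohort.

    Samples are mice, each a pool of five dissected CCDs, so tubule-level
    biological terms (log2 noise, composition and program latents) shrink by
    ``sqrt(5)``. The untargeted depth is filled with background proteins of
    log-uniform baseline across five orders of magnitude. Module proteins
    carry the planted ``effects`` (log2 fold change) in KO samples; the
    anchor is reduced to the detection noise floor; everything else is
    exchangeable between groups.
    """
    panel = _panel_frame(cfg.panel)
    if anchor not in panel.index:
        raise ValueError(f"anchor {anchor!r} absent from panel")
    missing_mod = [p for p in module if p not in panel.index]
    if missing_mod:
        raise ValueError(f"module proteins absent from panel: {missing_mod}")
    if isinstance(effects, dict):
        eff = pd.Series(0.0, index=panel.index)
        for p, v in effects.items():
            if p not in panel.index:
                raise ValueError(f"effect protein {p!r} absent from panel")
            eff[p] = v
    else:
        eff = pd.Series(0.0, index=panel.index)
        eff[list(module)] = float(effects)

    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n_bg = max(0, n_proteins - len(panel))
    bg = pd.DataFrame(
        {
            "cell_class": "other",
            "log10_baseline": rng.uniform(2.3, 7.3, size=n_bg),
        },
        index=pd.Index([f"BG{i + 1:04d}" for i in range(n_bg)], name="protein_id"),
    )
    proteins = pd.concat([panel[["cell_class", "log10_baseline"]], bg])
    eff = eff.reindex(proteins.index, fill_value=0.0)

    pool = math.sqrt(KO_TUBULES_PER_MOUSE)
    cpl = cfg.couplings
    n_total = n_wt + n_ko
    sample_ids = [f"WT{i + 1}" for i in range(n_wt)] + [
        f"KO{i + 1}" for i in range(n_ko)
    ]
    is_ko = np.array([False] * n_wt + [True] * n_ko)

    # each mouse sample pools five CCDs dissected at a consistent
    # cortico-medullary position: its IC fraction is the mean of five
    # unimodal tubule-level draws, and tubule-level latents average down
    # by sqrt(5)
    ic_center = float(np.mean(cfg.ic_modes))
    tub_ic = rng.normal(
        ic_center, KO_IC_TUBULE_SD, size=(n_total, KO_TUBULES_PER_MOUSE)
    )
    ic = np.clip(tub_ic.mean(axis=1), *cfg.ic_bounds)
    z = rng.normal(0.0, 1.0 / pool, size=n_total)
    f = rng.normal(0.0, 1.0 / pool, size=n_total)

    base_log2 = (proteins["log10_baseline"].to_numpy() * math.log2(10.0))[:, None]
    comp = _composition_log2(proteins, ic, cfg.ic_frac_base)
    prog = (
        _program_loadings(proteins, cpl).reindex(proteins.index, fill_value=0.0)
        .to_numpy()[:, None]
        * z[None, :]
    )
    icb_rows = np.isin(
        proteins.index.to_numpy(), (anchor,) + tuple(module)
    ).astype(float)[:, None]
    icb = icb_rows * cpl.icb_module * f[None, :]
    h = rng.normal(0.0, 1.0 / pool, size=n_total)
    hk_rows = np.isin(proteins.index.to_numpy(), HK_PROGRAM_SET).astype(float)
    hk = hk_rows[:, None] * cpl.hk_program * h[None, :]
    bio = rng.normal(0.0, cfg.noise_sd / pool, size=comp.shape)
    ko_shift = eff.to_numpy()[:, None] * is_ko[None, :].astype(float)

    true_log2 = base_log2 + comp + prog + icb + hk + bio + ko_shift
    # anchor in KO: only a noise-floor signal remains
    a_row = proteins.index.get_loc(anchor)
    floor = KO_ANCHOR_FLOOR_LOG10 * math.log2(10.0)
    true_log2[a_row, is_ko] = floor + rng.normal(0.0, cfg.noise_sd, size=n_ko)

    abundance = pd.DataFrame(2.0**true_log2, index=proteins.index, columns=sample_ids)
    meas = abundance * 2.0 ** rng.normal(0.0, KO_MEAS_SD, size=abundance.shape)
    observed = apply_missingness(meas, cfg.missingness, rng)

    mice = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": np.where(is_ko, "KO", "WT"),
            "ic_frac": ic,
            "z_pc_program": z,
            "f_icb_program": f,
        }
    ).set_index("sample_id")
    prot_truth = proteins.copy()
    prot_truth["ko_log2fc"] = eff
    prot_truth.loc[anchor, "ko_log2fc"] = float(
        floor - proteins.loc[anchor, "log10_baseline"] * math.log2(10.0)
    )
    truth = CohortTruth(
        tubules=mice, proteins=prot_truth, abundance=abundance, config=cfg, seed=seed
    )
    wt = observed[[c for c in sample_ids if c.startswith("WT")]]
    ko = observed[[c for c in sample_ids if c.startswith("KO")]]
    return wt, ko, truth


@dataclass(frozen=True)
class PRMPlan:
    """Planted composition of a PRM transition fixture.

    ``n_clean`` transitions pass every filter (at least two per peptide so
    coelution is defined); the violator counts plant one failure mode each.
    When ``n_ppm >= 1`` the first mass-error violator sits exactly at the
    cutoff (10.0 ppm) to probe the strict inequality.
    """

    n_peptides: int = 2
    n_clean: int = 6
    n_ppm: int = 2
    n_window: int = 1
    n_coelution: int = 1

    def __post_init__(self) -> None:
        if self.n_peptides < 1:
            raise ValueError("need at least one peptide")
        if self.n_clean < 2 * self.n_peptides:
            raise ValueError("need >= 2 clean transitions per peptide")
        for name in ("n_ppm", "n_window", "n_coelution"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def generate_prm_fixture(
    proteins: tuple[str, ...] = ("SLC26A4", "AQP2"),
    plan: PRMPlan = PRMPlan(),
    seed: int = 0,
    ppm_max: float = 10.0,
    coelution_tol: float = 0.2,
    sample_id: str = "S1",
) -> tuple[pd.DataFrame, pd.Series]:
    """Emit a TransitionPeak table with the planned filter outcomes.

    Returns ``(table, planted)`` where ``planted`` labels each row with the
    reason code the filters should assign (``clean`` for keepers). Clean
    transitions of a peptide apex within ``coelution_tol/2``; coelution
    outliers sit 2-4 tolerances from the clean apexes but inside the
    acquisition window; window violators elute after the window closes.
    """
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    centers = rng.uniform(20.0, 80.0, size=plan.n_peptides)
    half_window = 2.5

    def peptide_name(k: int) -> tuple[str, str]:
        prot = proteins[k % len(proteins)]
        return f"{prot}_pep{k + 1}_2+", prot

    def add(kind: str, k: int, frag: int) -> None:
        pep, prot = peptide_name(k)
        c = centers[k]
        jitter = rng.uniform(-coelution_tol / 5, coelution_tol / 5)
        apex = c + jitter
        ppm = rng.uniform(-6.0, 6.0)
        if kind == "ppm":
            first = not any(lab == "ppm" for lab in labels)
            ppm = ppm_max if first else rng.choice([-1, 1]) * rng.uniform(
                ppm_max + 0.5, 2 * ppm_max
            )
        elif kind == "window":
            apex = c + half_window + rng.uniform(0.5, 1.5)
        elif kind == "coelution":
            apex = c + rng.uniform(2.0, 4.0) * coelution_tol
        rows.append(
            {
                "peptide_id": pep,
                "protein_id": prot,
                "fragment_id": f"y{frag + 3}",
                "apex_rt": apex,
                "rt_window_start": c - half_window,
                "rt_window_end": c + half_window,
                "mass_error_ppm": ppm,
                "area": 10.0 ** rng.uniform(3.0, 6.0),
                "sample_id": sample_id,
            }
        )
        labels.append(kind)

    frag_counter = [0] * plan.n_peptides

    def next_frag(k: int) -> int:
        frag_counter[k] += 1
        return frag_counter[k]

    for i in range(plan.n_clean):
        k = i % plan.n_peptides
        add("clean", k, next_frag(k))
    for kind, count in (
        ("ppm", plan.n_ppm),
        ("window", plan.n_window),
        ("coelution", plan.n_coelution),
    ):
        for i in range(count):
            k = i % plan.n_peptides
            add(kind, k, next_frag(k))

    table = pd.DataFrame(rows)
    planted = pd.Series(labels, index=table.index, name="planted_reason")
    return table, planted


def with_seed(cfg: CohortConfig, seed: int) -> CohortConfig:
    """A copy of the config with a different seed (replicate cohorts)."""
    return replace(cfg, seed=seed)
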
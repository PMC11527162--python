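"""Radiolabelled-uptake kinetics: cpm→rate conversion, background
subtraction, wild-type normalization (V%), dose-response fitting
(IC50/Hill) and Cheng-Prusoff Ki.

Assay design assumed throughout: spores of each strain take up a
tritiated substrate at a fixed tracer concentration; scintillation counts
per minute (cpm) over a linear time window are converted to
mol substrate/min/10^8 conidia using the tracer's specific activity;
non-specific uptake measured in a transporter-null strain is subtracted;
mutant rates are expressed as a percentage (V%) of the wild type.
Apparent affinity (K_m/i) comes from homologous competition: the tracer
is competed with increasing unlabelled substrate, the dose-response IC50
is fitted, and Ki = IC50 / (1 + [S]/Km) (Cheng-Prusoff).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

DPM_PER_CI = 2.22e12          # disintegrations/min per Curie
CONIDIA_REFERENCE = 1e8       # rates reported per 10^8 conidia
DEFAULT_SPECIFIC_ACTIVITY = 19.5   # Ci/mmol, tritiated hypoxanthine

#: DataFrame columns for raw uptake observations
OBS_COLUMNS = [
    "strain", "labelled_conc_uM", "competitor", "competitor_conc_uM",
    "cpm", "time_min", "spores", "replicate", "experiment",
]


@dataclass(frozen=True)
class UptakeObservation:
    strain: str
    labelled_conc: float          # µM
    competitor: str | None
    competitor_conc: float        # µM (0 when competitor is None)
    cpm: float
    time_min: float
    spores: float
    replicate_id: str = "r1"
    experiment_id: str = "e1"

    def __post_init__(self) -> None:
        if self.cpm < 0:
            raise ValueError("cpm must be >= 0")
        if self.time_min <= 0:
            raise ValueError("time_min must be > 0")
        if self.spores <= 0:
            raise ValueError("spores must be > 0")


@dataclass
class RateResult:
    strain: str
    rate: float                   # mol substrate/min/10^8 conidia
    background_corrected: bool = False
    negative_flag: bool = False
    sd: float = 0.0
    n: int = 1


def counts_to_rate(
    cpm: float,
    time_min: float = 1.0,
    spores: float = CONIDIA_REFERENCE,
    specific_activity: float = DEFAULT_SPECIFIC_ACTIVITY,
    counting_efficiency: float = 1.0,
) -> float:
    """Convert scintillation counts/min to mol substrate/min/10^8 conidia.

    rate = (cpm / efficiency) / (SA * 2.22e12 dpm/Ci) mmol, converted to
    mol, per minute of uptake, scaled to 10^8 conidia. Linear in cpm and
    inversely linear in counting efficiency.
    """
    if specific_activity <= 0:
        raise ValueError("specific_activity must be > 0")
    if not 0 < counting_efficiency <= 1:
        raise ValueError("counting_efficiency must be in (0, 1]")
    dpm = cpm / counting_efficiency
    mmol = dpm / (specific_activity * DPM_PER_CI)
    mol = mmol * 1e-3
    return mol / time_min * (CONIDIA_REFERENCE / spores)


def rate_to_counts(
    rate: float,
    time_min: float = 1.0,
    spores: float = CONIDIA_REFERENCE,
    specific_activity: float = DEFAULT_SPECIFIC_ACTIVITY,
    counting_efficiency: float = 1.0,
) -> float:
    """Exact inverse of :func:`counts_to_rate` (used by the simulator)."""
    mol = rate * time_min * (spores / CONIDIA_REFERENCE)
    mmol = mol * 1e3
    dpm = mmol * specific_activity * DPM_PER_CI
    return dpm * counting_efficiency


def observation_to_rate(
    obs: UptakeObservation,
    specific_activity: float = DEFAULT_SPECIFIC_ACTIVITY,
    counting_efficiency: float = 1.0,
) -> RateResult:
    return RateResult(
        strain=obs.strain,
        rate=counts_to_rate(
            obs.cpm, obs.time_min, obs.spores,
            specific_activity, counting_efficiency,
        ),
    )


def rates_from_counts(
    obs: pd.DataFrame,
    specific_activity: float = DEFAULT_SPECIFIC_ACTIVITY,
    counting_efficiency: float = 1.0,
) -> pd.DataFrame:
    """Vectorized cpm→rate over an observation table (adds a ``rate``
    column, mol/min/10^8 conidia)."""
    out = obs.copy()
    out["rate"] = [
        counts_to_rate(
            row.cpm, row.time_min, row.spores,
            specific_activity, counting_efficiency,
        )
        for row in obs.itertuples()
    ]
    return out


CONDITION_KEYS = ["labelled_conc_uM", "competitor", "competitor_conc_uM"]


def correct_background(
    rates: pd.DataFrame, background_strain: str = "ΔZAC"
) -> pd.DataFrame:
    """Subtract the background strain's mean rate, matched per condition.

    The background strain itself maps to ~0 (its own mean subtracted).
    Negative corrected rates are retained but flagged, so error
    propagation into V% standard deviations is preserved.
    """
    df = rates.copy()
    df["competitor"] = df["competitor"].fillna("none")
    bg = df[df["strain"] == background_strain]
    if bg.empty:
        raise ValueError(
            f"background strain {background_strain!r} absent from data"
        )
    bg_means = bg.groupby(CONDITION_KEYS)["rate"].mean()
    corrected = []
    flags = []
    for row in df.itertuples():
        key = (row.labelled_conc_uM, row.competitor, row.competitor_conc_uM)
        if key not in bg_means.index:
            raise ValueError(
                f"no background measurement for condition {key}"
            )
        c = row.rate - bg_means.loc[key]
        corrected.append(c)
        flags.append(c < 0)
    df["rate_corrected"] = corrected
    df["negative_flag"] = flags
    return df


def normalize_rates(
    rates: pd.DataFrame,
    reference_strain: str = "PhZwt",
    rate_column: str = "rate_corrected",
) -> pd.DataFrame:
    """Express each strain's mean rate as V%, percent of the reference.

    V%(reference) = 100 exactly; SDs scale by the same factor, so V% is
    invariant to any common rescaling of the rates (e.g. counting
    efficiency).
    """
    g = rates.groupby("strain")[rate_column]
    means, sds, ns = g.mean(), g.std(ddof=1).fillna(0.0), g.size()
    if reference_strain not in means.index:
        raise ValueError(f"reference strain {reference_strain!r} absent")
    ref = means.loc[reference_strain]
    if ref <= 0:
        raise ValueError(
            f"reference strain {reference_strain!r} has non-positive "
            f"mean rate {ref:g}"
        )
    out = pd.DataFrame(
        {
            "strain": means.index,
            "v_percent": 100.0 * means.values / ref,
            "v_sd": 100.0 * sds.values / ref,
            "n": ns.values,
        }
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# dose-response fitting


@dataclass
class DoseResponseFit:
    top: float
    bottom: float
    log10_ic50: float
    ic50: float                   # µM
    hill: float
    rmse: float
    converged: bool
    ki: float | None = None       # µM, filled when [S] supplied
    ki_is_approx: bool = False
    labelled_conc_S: float | None = None
    km_assumed: float | None = None
    message: str = ""


def _logistic(logx: np.ndarray, top: float, bottom: float,
              log_ic50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - logx) * hill))


def fit_dose_response(
    data: list[tuple[float, float]] | pd.DataFrame,
    labelled_conc_S: float | None = None,
    km: float | None = None,
    bottom_nonnegative: bool = True,
    weighting: str = "relative",
) -> DoseResponseFit:
    """Fit the four-parameter variable-slope model
    y = bottom + (top − bottom)/(1 + 10^((log10 IC50 − log10 x)·hill))
    to (competitor concentration µM, rate) points.

    Descending inhibition curves yield hill ≈ −1 under this sign
    convention (a single binding site). Zero-concentration points cannot
    sit on the log grid; they enter instead as direct constraints on the
    ``top`` asymptote (the uninhibited rate), which is what they measure.
    ``weighting="relative"`` (default) divides residuals by the predicted
    value (floored at 0.1% of the data scale), matching the proportional
    error of scintillation counting; ``"absolute"`` is plain least
    squares. When ``labelled_conc_S`` is given, Ki is attached via
    :func:`ic50_to_ki` (Cheng-Prusoff).
    """
    if weighting not in ("relative", "absolute"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if isinstance(data, pd.DataFrame):
        pairs = list(zip(data.iloc[:, 0].to_numpy(), data.iloc[:, 1].to_numpy()))
    else:
        pairs = list(data)
    conc = np.array([c for c, _ in pairs], dtype=float)
    y = np.array([v for _, v in pairs], dtype=float)
    if np.any(conc < 0):
        raise ValueError("negative competitor concentrations")
    zero_mask = conc == 0
    pos_conc, pos_y = conc[~zero_mask], y[~zero_mask]
    if len(np.unique(pos_conc)) < 4:
        raise ValueError(
            "need >= 4 distinct positive competitor concentrations"
        )
    logx = np.log10(pos_conc)

    top0 = float(np.mean(y[zero_mask])) if zero_mask.any() else float(
        np.mean(pos_y[pos_conc == pos_conc.min()])
    )
    bottom0 = max(0.0, float(np.mean(pos_y[pos_conc == pos_conc.max()])))
    span = abs(top0 - bottom0)
    y_scale = float(np.max(np.abs(y)))
    if y_scale == 0 or span < 1e-9 * y_scale:
        return DoseResponseFit(
            top=top0, bottom=bottom0, log10_ic50=math.nan, ic50=math.nan,
            hill=math.nan, rmse=0.0, converged=False,
            message="flat dose-response data: top ≈ bottom",
        )

    # fit in units of the data scale so tolerances behave regardless of
    # whether rates arrive in mol or percent
    ys = pos_y / y_scale
    y0 = y[zero_mask] / y_scale
    lo_mid, hi_mid = logx.min(), logx.max()
    p0 = np.array([top0 / y_scale, bottom0 / y_scale,
                   0.5 * (lo_mid + hi_mid), -1.0])
    lower = np.array(
        [0.0, 0.0 if bottom_nonnegative else -np.inf, lo_mid - 3.0, -5.0]
    )
    upper = np.array([np.inf, np.inf, hi_mid + 3.0, 5.0])
    p0 = np.clip(p0, lower + 1e-12, upper - 1e-12)

    floor = 1e-3  # in scaled units; caps the weight of near-zero predictions

    def resid(p: np.ndarray) -> np.ndarray:
        pred = _logistic(logx, *p)
        r = pred - ys
        if weighting == "relative":
            r = r / np.maximum(np.abs(pred), floor)
        if len(y0):
            # baseline observations measure the uninhibited asymptote
            r0 = p[0] - y0
            if weighting == "relative":
                r0 = r0 / max(abs(p[0]), floor)
            r = np.concatenate([r, r0])
        return r

    sol = least_squares(resid, p0, bounds=(lower, upper),
                        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    top, bottom, log_ic50, hill = sol.x
    rmse = float(
        np.sqrt(np.mean((_logistic(logx, *sol.x) - ys) ** 2))
    ) * y_scale
    top, bottom = top * y_scale, bottom * y_scale
    converged = bool(sol.success) and abs(top - bottom) > 1e-9 * max(
        abs(top), y_scale * 1e-12
    )
    fit = DoseResponseFit(
        top=float(top), bottom=float(bottom),
        log10_ic50=float(log_ic50), ic50=float(10.0 ** log_ic50),
        hill=float(hill), rmse=rmse, converged=converged,
        labelled_conc_S=labelled_conc_S, km_assumed=km,
        message="" if converged else "fit did not converge",
    )
    if converged and labelled_conc_S is not None:
        fit.ki, fit.ki_is_approx = ic50_to_ki(fit.ic50, labelled_conc_S, km)
    return fit


def ic50_to_ki(
    ic50: float, S: float, km: float | None = None
) -> tuple[float, bool]:
    """Cheng-Prusoff: Ki = IC50 / (1 + [S]/Km).

    When Km is unknown the assay regime [S] <= Km/10 bounds the correction
    to <= 1/11 relative, so Ki ≈ IC50 is returned with the approximation
    flagged.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    if S < 0:
        raise ValueError("labelled concentration S must be >= 0")
    if km is None:
        return ic50, True
    if km <= 0:
        raise ValueError("km must be > 0")
    return ic50 / (1.0 + S / km), False


# ---------------------------------------------------------------------------
# competition profiles


@dataclass
class CompetitionProfile:
    strain: str
    percent_remaining: dict[str, float]    # competitor -> V% of own baseline

    def percent_inhibition(self, competitor: str) -> float:
        return 100.0 - self.percent_remaining[competitor]


def competition_profile(
    rates: pd.DataFrame,
    rate_column: str = "rate_corrected",
) -> list[CompetitionProfile]:
    """Percent of each strain's own uninhibited uptake remaining under each
    competitor, normalized against that strain's no-competitor baseline.

    Expects one baseline (competitor == 'none'/NaN) per strain plus rows at
    the competing condition(s). Self-competition with the unlabelled
    substrate serves as the maximum-inhibition control.
    """
    df = rates.copy()
    df["competitor"] = df["competitor"].fillna("none")
    profiles = []
    for strain, sub in df.groupby("strain", sort=False):
        base = sub[sub["competitor"] == "none"][rate_column]
        if base.empty:
            raise ValueError(f"strain {strain!r} has no no-competitor baseline")
        v0 = base.mean()
        if v0 <= 0:
            raise ValueError(
                f"strain {strain!r} baseline rate is non-positive ({v0:g})"
            )
        remaining = {}
        for comp, csub in sub[sub["competitor"] != "none"].groupby("competitor"):
            remaining[comp] = 100.0 * csub[rate_column].mean() / v0
        profiles.append(CompetitionProfile(strain=strain, percent_remaining=remaining))
    return profiles


def competition_matrix(profiles: list[CompetitionProfile]) -> pd.DataFrame:
    competitors = sorted({c for p in profiles for c in p.percent_remaining})
    return pd.DataFrame(
        [
            {"strain": p.strain, **{c: p.percent_remaining.get(c) for c in competitors}}
            for p in profiles
        ]
    )
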
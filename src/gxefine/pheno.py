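"""Phenotype and smoking-exposure derivation applied before association.

Blood-pressure outcomes are systolic (SBP), diastolic (DBP) and pulse
pressure (PP), all in mmHg.  Subjects on antihypertensive medication have
their measured BP adjusted upward by a fixed amount (+15 SBP, +10 DBP) to
approximate untreated values; PP is derived afterwards as SBP - DBP.
Extreme outcome and exposure values are winsorized at mean +/- k*SD.

Smoking exposures: CURSMK (current smoker yes/no), CPD (cigarettes per day,
current smokers only) and pack-years PY = (CPD/20) * years smoked.  The
quantitative exposures are analyzed only in strata with at least
``min_smokers`` current smokers after exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhenoConfig",
    "adjust_bp_for_medication",
    "derive_pp",
    "winsorize",
    "derive_pack_years",
    "exposure_gate",
    "prepare_phenotypes",
]

#: Exposures a stratum may analyze.
ALL_EXPOSURES = ("CURSMK", "CPD", "PY")


@dataclass
class PhenoConfig:
    """Tunable constants of the phenotype pipeline."""

    winsor_k: float = 6.0
    med_adjust_sbp: float = 15.0
    med_adjust_dbp: float = 10.0
    min_smokers: int = 100
    #: adjust medication first, then winsorize (the default order)
    adjust_before_winsorize: bool = True


def adjust_bp_for_medication(
    sbp: np.ndarray, dbp: np.ndarray, on_med: np.ndarray,
    add_sbp: float = 15.0, add_dbp: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Add a fixed offset to treated subjects' SBP/DBP.

    Returns ``(sbp_adj, dbp_adj, valid)`` where ``valid`` is False for rows
    with a missing medication flag or missing BP; those rows are excluded
    downstream rather than guessed.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    med = pd.Series(list(on_med))  # tolerates None/NaN in object or bool input
    missing = med.isna().to_numpy() | ~np.isfinite(sbp) | ~np.isfinite(dbp)
    treated = med.fillna(False).astype(bool).to_numpy() & ~missing
    sbp_adj = np.where(treated, sbp + add_sbp, sbp)
    dbp_adj = np.where(treated, dbp + add_dbp, dbp)
    valid = ~missing
    return sbp_adj, dbp_adj, valid


def derive_pp(sbp_adj: np.ndarray, dbp_adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pulse pressure = adjusted SBP - adjusted DBP.

    Returns ``(pp, valid)``; rows with PP <= 0 (DBP at or above SBP) are
    flagged invalid.
    """
    pp = np.asarray(sbp_adj, dtype=float) - np.asarray(dbp_adj, dtype=float)
    valid = np.isfinite(pp) & (pp > 0)
    return pp, valid


def winsorize(values: np.ndarray, k: float = 6.0) -> np.ndarray:
    """Clamp values beyond mean +/- k*SD to the boundary.

    The mean and SD are computed once on the input (missing values ignored),
    not re-estimated after clamping.  A constant vector (SD = 0) and missing
    values pass through unchanged.
    """
    x = np.asarray(values, dtype=float).copy()
    ok = np.isfinite(x)
    if ok.sum() < 2:
        return x
    mu = x[ok].mean()
    sd = x[ok].std(ddof=1)
    if sd == 0:
        return x
    lo, hi = mu - k * sd, mu + k * sd
    x[ok] = np.clip(x[ok], lo, hi)
    return x


def derive_pack_years(cpd: np.ndarray, smoking_years: np.ndarray) -> np.ndarray:
    """Pack-years = (cigarettes per day / 20) * years smoked.

    Raises on negative inputs; missing values propagate as NaN.
    """
    cpd = np.asarray(cpd, dtype=float)
    yrs = np.asarray(smoking_years, dtype=float)
    if np.any(cpd[np.isfinite(cpd)] < 0) or np.any(yrs[np.isfinite(yrs)] < 0):
        raise ValueError("CPD and smoking years must be non-negative")
    return (cpd / 20.0) * yrs


def exposure_gate(n_current_smokers: int, min_smokers: int = 100) -> tuple[str, ...]:
    """Decide which exposures a stratum may analyze.

    CURSMK is always analyzed; CPD and PY require at least ``min_smokers``
    current smokers after exclusions and winsorization.
    """
    if n_current_smokers >= min_smokers:
        return ALL_EXPOSURES
    return ("CURSMK",)


@dataclass
class PreparedPhenotypes:
    """Output of :func:`prepare_phenotypes`."""

    table: pd.DataFrame
    exposures_enabled: tuple[str, ...]
    n_excluded: int
    exclusion_reasons: dict[str, int] = field(default_factory=dict)


def prepare_phenotypes(
    df: pd.DataFrame, config: PhenoConfig | None = None
) -> PreparedPhenotypes:
    """Run the full derivation pipeline on a subject table.

    Expects columns ``sbp``, ``dbp``, ``on_antihypertensive``, ``cursmk``
    and optionally ``cpd``, ``smoking_years``, ``sex``.  Adds ``sbp_adj``,
    ``dbp_adj``, ``pp`` and (where derivable) ``py``; winsorizes the three
    BP outcomes on the whole sample and CPD/PY separately by sex among
    current smokers.  Rows failing validation are dropped with counted
    reasons.
    """
    cfg = config or PhenoConfig()
    df = df.copy()
    reasons: dict[str, int] = {}

    sbp_adj, dbp_adj, valid_med = adjust_bp_for_medication(
        df["sbp"].to_numpy(), df["dbp"].to_numpy(),
        df["on_antihypertensive"].to_numpy(),
        cfg.med_adjust_sbp, cfg.med_adjust_dbp,
    )
    df["sbp_adj"], df["dbp_adj"] = sbp_adj, dbp_adj
    reasons["missing_bp_or_medication"] = int((~valid_med).sum())

    pp, valid_pp = derive_pp(sbp_adj, dbp_adj)
    df["pp"] = pp
    reasons["nonpositive_pp"] = int((valid_med & ~valid_pp).sum())

    keep = valid_med & valid_pp
    df = df.loc[keep].copy()

    for col in ("sbp_adj", "dbp_adj", "pp"):
        df[col] = winsorize(df[col].to_numpy(), cfg.winsor_k)

    smokers = df["cursmk"] == 1
    if "cpd" in df.columns:
        cpd = df["cpd"].where(smokers)
        if "smoking_years" in df.columns:
            df["py"] = derive_pack_years(
                cpd.to_numpy(), df["smoking_years"].to_numpy()
            )
        # zero or missing CPD/PY excludes the subject from those analyses
        for col in ("cpd", "py"):
            if col in df.columns:
                df.loc[~smokers, col] = np.nan
                df.loc[df[col] == 0, col] = np.nan
        groups = df["sex"] if "sex" in df.columns else pd.Series(0, index=df.index)
        for col in ("cpd", "py"):
            if col in df.columns:
                df[col] = (
                    df[col]
                    .groupby(groups, group_keys=False)
                    .transform(lambda v: winsorize(v.to_numpy(), cfg.winsor_k))
                )

    n_smokers = int(smokers.sum())
    enabled = exposure_gate(n_smokers, cfg.min_smokers)
    return PreparedPhenotypes(
        table=df,
        exposures_enabled=enabled,
        n_excluded=int((~keep).sum()),
        exclusion_reasons=reasons,
    )
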
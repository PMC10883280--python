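"""BRET plate analysis: correction, detection calls, saturation-curve fits.

Raw BRET of a well is the long-wavelength over short-wavelength luminescence
ratio.  The corrected BRET (cBRET) of a test pair subtracts the *maximum* raw
BRET of its two single-tag control pairs (donor with acceptor-tag-only, and
donor-tag-only with acceptor), removing donor bleedthrough, unspecific tag
binding and background; cBRET may be negative.

A protein pair is called detected when, at the configured transfection ratio,
cBRET >= 0.05, the acceptor fluorescence >= 500 units and the total
luminescence >= 50,000 units (all inclusive).

Donor-saturation titrations are fitted with the 1:1 hyperbolic model

    BRET(A/D) = (A/D) * BRETmax / (BRET50 + A/D)

by nonlinear least squares; parameter standard errors come from the
fractional covariance matrix scaled by the residual variance.  BRET50, the
acceptor/donor ratio at half-maximal BRET, proxies binding affinity.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import norm

logger = logging.getLogger("fragscore")

#: Detection thresholds (inclusive >=): cBRET, fluorescence, total luminescence.
CBRET_THRESHOLD = 0.05
FLUORESCENCE_THRESHOLD = 500.0
LUMINESCENCE_THRESHOLD = 50_000.0

#: Default donor:acceptor DNA transfection ratio for detection calls (ng).
DEFAULT_DETECTION_RATIO = (2, 50)


@dataclass
class WellMeasurement:
    """Raw readings of one plate well."""

    pair_id: str
    construct_role: str  # test / control_donor_only / control_acceptor_only / background
    donor_ng: float
    acceptor_ng: float
    fluorescence: float
    total_luminescence: float
    short_wl_lum: float
    long_wl_lum: float
    replicate: str = "1"

    def __post_init__(self) -> None:
        for name in ("fluorescence", "total_luminescence", "short_wl_lum",
                     "long_wl_lum"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TitrationPoint:
    """One titration observation: acceptor/donor expression ratio and cBRET."""

    ad_ratio: float
    cbret: float

    def __post_init__(self) -> None:
        if self.ad_ratio <= 0:
            raise ValueError("ad_ratio must be > 0")


@dataclass
class TitrationFit:
    bretmax: float
    bret50: float
    se_bretmax: float
    se_bret50: float
    residual_variance: float
    converged: bool
    lack_of_fit: bool = False
    n_points: int = 0


def raw_bret(long_wl_lum: float, short_wl_lum: float) -> float:
    """Long-wavelength over short-wavelength luminescence ratio."""
    if short_wl_lum <= 0:
        raise ValueError("short-wavelength luminescence must be > 0")
    return long_wl_lum / short_wl_lum


def corrected_bret(test_bret: float, control_a_bret: float,
                   control_b_bret: float) -> float:
    """cBRET = test - max(control_a, control_b); may be negative."""
    return test_bret - max(control_a_bret, control_b_bret)


def detect_interaction(cbret: float, fluorescence: float,
                       total_luminescence: float,
                       cbret_threshold: float = CBRET_THRESHOLD,
                       fluorescence_threshold: float = FLUORESCENCE_THRESHOLD,
                       luminescence_threshold: float = LUMINESCENCE_THRESHOLD
                       ) -> bool:
    """Detection call: all three thresholds must be met, inclusive."""
    return (cbret >= cbret_threshold
            and fluorescence >= fluorescence_threshold
            and total_luminescence >= luminescence_threshold)


def acceptor_donor_ratio(fluorescence: float, total_luminescence: float,
                         background_fluor: float, background_lum: float,
                         gain_norm: float = 1.0) -> float | None:
    """Acceptor/donor expression ratio from background-corrected readings.

    ratio = gain_norm * (F - F_bg) / (L - L_bg).  A non-positive corrected
    luminescence makes the ratio undefined (None, point excluded with a
    warning); zero corrected fluorescence gives ratio 0 and is flagged.
    """
    lum = total_luminescence - background_lum
    if lum <= 0:
        logger.warning("corrected luminescence <= 0; point excluded")
        return None
    fluor = fluorescence - background_fluor
    ratio = gain_norm * fluor / lum
    if fluor <= 0:
        logger.warning("corrected fluorescence <= 0; ratio %g flagged", ratio)
    return ratio


def hyperbolic_model(ad_ratio, bretmax: float, bret50: float):
    """1:1 binding saturation curve."""
    ad_ratio = np.asarray(ad_ratio, dtype=float)
    return ad_ratio * bretmax / (bret50 + ad_ratio)


def _runs_test_pvalue(residuals: np.ndarray) -> float:
    """Two-sided Wald-Wolfowitz runs test on residual signs (normal approx.)."""
    signs = np.sign(residuals)
    signs = signs[signs != 0]
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    n = n_pos + n_neg
    if n_pos == 0 or n_neg == 0 or n < 4:
        return 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mean = 2 * n_pos * n_neg / n + 1
    var = 2 * n_pos * n_neg * (2 * n_pos * n_neg - n) / (n ** 2 * (n - 1))
    if var <= 0:
        return 1.0
    z = (runs - mean) / math.sqrt(var)
    return float(2 * norm.sf(abs(z)))


def fit_titration(points: Sequence[TitrationPoint],
                  lack_of_fit_alpha: float = 0.05) -> TitrationFit:
    """Least-squares fit of the hyperbolic saturation model.

    Standard errors are the square roots of the diagonal of the fractional
    covariance matrix multiplied by the residual variance (the conventional
    least-squares scaling).  ``converged`` is False when the optimizer fails
    or returns non-positive parameters.  A failed runs test on the residuals
    (ordered by A/D) sets ``lack_of_fit`` — the fit is still reported, but
    the saturation behaviour deviates from the 1:1 model.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 titration points")
    pts = sorted(points, key=lambda p: p.ad_ratio)
    x = np.array([p.ad_ratio for p in pts])
    y = np.array([p.cbret for p in pts])
    p0 = (max(float(y.max()), 1e-3), max(float(np.median(x)), 1e-3))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(hyperbolic_model, x, y, p0=p0, maxfev=10_000)
    except (RuntimeError, ValueError):
        return TitrationFit(bretmax=float("nan"), bret50=float("nan"),
                            se_bretmax=float("nan"), se_bret50=float("nan"),
                            residual_variance=float("nan"), converged=False,
                            n_points=len(pts))
    bretmax, bret50 = (float(v) for v in popt)
    residuals = y - hyperbolic_model(x, bretmax, bret50)
    dof = max(1, len(pts) - 2)
    residual_variance = float(np.sum(residuals ** 2) / dof)
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    converged = bool(np.isfinite(popt).all() and bretmax > 0 and bret50 > 0)
    lack_of_fit = (converged and len(pts) >= 6
                   and _runs_test_pvalue(residuals) < lack_of_fit_alpha)
    return TitrationFit(
        bretmax=bretmax, bret50=bret50,
        se_bretmax=float(se[0]), se_bret50=float(se[1]),
        residual_variance=residual_variance,
        converged=converged, lack_of_fit=lack_of_fit, n_points=len(pts),
    )


# ---------------------------------------------------------------------------
# plate-level analysis
# ---------------------------------------------------------------------------

PLATE_COLUMNS = ["pair_id", "construct_role", "donor_ng", "acceptor_ng",
                 "fluorescence", "total_lum", "short_wl_lum", "long_wl_lum",
                 "replicate"]


def analyze_plate(plate: pd.DataFrame,
                  detection_ratio: tuple[float, float] = DEFAULT_DETECTION_RATIO,
                  ratio_overrides: dict[str, tuple[float, float]] | None = None
                  ) -> pd.DataFrame:
    """Per-pair detection calls from a plate table.

    The table holds one row per well (see PLATE_COLUMNS).  For every test
    pair the two single-tag control wells at the same DNA amounts provide the
    bleedthrough correction; technical replicates are averaged on the raw
    readings before the cBRET computation.  Detection uses the wells at the
    configured donor:acceptor DNA ratio (default 2:50 ng; per-pair overrides
    as needed).
    """
    missing = set(PLATE_COLUMNS) - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    overrides = ratio_overrides or {}
    rows = []
    for pair_id, group in plate.groupby("pair_id", sort=True):
        if (group["construct_role"] == "background").all():
            continue
        ratio = overrides.get(pair_id, detection_ratio)
        at_ratio = group[(group["donor_ng"] == ratio[0])
                         & (group["acceptor_ng"] == ratio[1])]
        if at_ratio.empty:
            logger.warning("pair %s has no wells at ratio %s; skipped",
                           pair_id, ratio)
            continue

        def mean_bret(role: str) -> float | None:
            sel = at_ratio[at_ratio["construct_role"] == role]
            if sel.empty:
                return None
            return raw_bret(sel["long_wl_lum"].mean(),
                            sel["short_wl_lum"].mean())

        test = mean_bret("test")
        if test is None:
            logger.warning("pair %s has no test wells; skipped", pair_id)
            continue
        control_a = mean_bret("control_donor_only") or 0.0
        control_b = mean_bret("control_acceptor_only") or 0.0
        cbret = corrected_bret(test, control_a, control_b)
        test_wells = at_ratio[at_ratio["construct_role"] == "test"]
        fluor = float(test_wells["fluorescence"].mean())
        lum = float(test_wells["total_lum"].mean())
        rows.append({
            "pair_id": pair_id,
            "cbret": cbret,
            "fluorescence": fluor,
            "total_luminescence": lum,
            "detected": detect_interaction(cbret, fluor, lum),
        })
    return pd.DataFrame(rows)
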
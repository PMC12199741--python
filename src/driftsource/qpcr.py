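"""Pooled-qPCR eDNA screening: Cq calling, quantification, and region calls.

Screening logic mirrors a pooled surveillance design: per region one *sample
pool* (all field extracts mixed) and one *positive pool* (the same mix spiked
with extract from a site where the target alga was observed), each run in at
least triplicate alongside no-template controls (NTC) and equipment blanks
(EB).  Starting quantities come from a log-linear standard curve fitted to a
tenfold dilution series; a positive starting quantity in *any* technical
replicate of a sample pool is a detection, and a region whose positive pool
fails to amplify is invalid (the pool dilution may have masked a true
positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

ROLES = ("sample_pool", "positive_pool", "field_positive", "tissue", "standard", "NTC", "EB")


@dataclass
class AmplificationCurve:
    """Per-well fluorescence trace (RFU) over consecutive cycles from 1."""

    well: str
    role: str
    rfu: np.ndarray
    plate: str = "plate1"
    region: Optional[str] = None
    log10_copies: Optional[float] = None  # standards only

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(f"unknown well role {self.role!r}")
        self.rfu = np.asarray(self.rfu, dtype=float)
        if not np.all(np.isfinite(self.rfu)):
            raise ValidationError("fluorescence trace contains non-finite values")

    @property
    def cycles(self) -> np.ndarray:
        return np.arange(1, self.rfu.size + 1)


@dataclass
class StandardCurveFit:
    """Log-linear quantification model: Cq = intercept + slope·log10(copies)."""

    slope: float
    intercept: float
    r2: float
    n_levels: int

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency; 1.0 (100%) at slope −3.3219."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass
class PoolPlan:
    """Membership of one region's pooled reaction (< 20 samples for reliable
    amplification of low-abundance sites)."""

    region: str
    member_ids: Sequence[str]
    spiked: bool = False
    spike_source: Optional[str] = None

    def __post_init__(self):
        if not (1 <= len(self.member_ids) <= 20):
            raise ValidationError("pool must contain between 1 and 20 samples")


@dataclass
class RegionCall:
    """Screening decision for one region."""

    region: str
    status: str  # detected | presumed_negative | invalid_spike_fail | contaminated
    sample_quantities: Sequence[float]
    positive_quantities: Sequence[float]
    reliable: Optional[bool] = None


def call_cq(curve: AmplificationCurve, threshold: float) -> Optional[float]:
    """Fractional cycle of first threshold crossing (linear interpolation).

    Returns None if the trace never reaches the threshold.  A trace already at
    or above threshold at cycle 1 returns 1.0.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    r = curve.rfu
    above = r >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return 1.0
    c0 = float(curve.cycles[i - 1])
    return c0 + (threshold - r[i - 1]) / (r[i] - r[i - 1])


def estimate_threshold(curves: Sequence[AmplificationCurve], n_sd: float = 10.0,
                       baseline_cycles=(3, 15)) -> float:
    """Fallback plate threshold: baseline mean + ``n_sd``·SD over early cycles.

    The instrument normally supplies the threshold; this estimator stands in
    when a plate export lacks one.
    """
    lo, hi = baseline_cycles
    vals = np.concatenate([c.rfu[lo - 1:hi] for c in curves])
    return float(vals.mean() + n_sd * vals.std(ddof=1))


def fit_standard_curve(standards: Sequence[tuple]) -> StandardCurveFit:
    """Least-squares line of Cq on log10 copies from (log10_copies, Cq) pairs."""
    pts = [(float(x), float(c)) for x, c in standards if c is not None]
    levels = {x for x, _ in pts}
    if len(levels) < 3:
        raise ValidationError("standard curve needs >= 3 distinct dilution levels")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    res = sps.linregress(x, y)
    return StandardCurveFit(slope=float(res.slope), intercept=float(res.intercept),
                            r2=float(res.rvalue) ** 2, n_levels=len(levels))


def quantify(cq: Optional[float], fit: StandardCurveFit) -> float:
    """Starting copies from a Cq via the fitted line; an uncalled Cq is 0 copies."""
    if cq is None:
        return 0.0
    return 10.0 ** ((cq - fit.intercept) / fit.slope)


def reliability_check(replicates: Sequence[AmplificationCurve], mean_threshold: float,
                      window: int = 3) -> bool:
    """Smoothed-consensus reliability rule for a detection.

    The mean trace of the replicates is smoothed with a centred moving average
    (default 3-cycle window) and the detection is flagged reliable only if the
    smoothed consensus itself exceeds the mean threshold — concordant
    amplification, not a single-replicate spike.
    """
    if len(replicates) < 2:
        raise ValidationError("reliability check needs >= 2 replicates")
    n = min(r.rfu.size for r in replicates)
    mean_trace = np.mean([r.rfu[:n] for r in replicates], axis=0)
    kernel = np.ones(window) / window
    smooth = np.convolve(mean_trace, kernel, mode="valid")
    return bool(np.any(smooth > mean_threshold))


def call_region(region: str,
                sample_quantities: Sequence[float],
                positive_quantities: Sequence[float],
                ntc_quantities: Sequence[float],
                eb_quantities: Sequence[float],
                reliable: Optional[bool] = None) -> RegionCall:
    """Decision table for one region's pooled screen.

    Any NTC/EB amplification → contaminated; else a positive pool with no
    amplifying replicate → invalid_spike_fail (dilution may mask a true
    positive); else a sample pool with >= 1 positive replicate → detected
    (re-screen individual sites recommended); else presumed_negative.
    Pure function of its inputs — replicate order never matters.
    """
    if len(sample_quantities) < 3 or len(positive_quantities) < 3:
        raise ValidationError("each pool needs >= 3 technical replicates")
    if len(ntc_quantities) == 0 or len(eb_quantities) == 0:
        raise ValidationError("NTC and EB control results are required")
    if any(q > 0 for q in ntc_quantities) or any(q > 0 for q in eb_quantities):
        status = "contaminated"
    elif not any(q > 0 for q in positive_quantities):
        status = "invalid_spike_fail"
    elif any(q > 0 for q in sample_quantities):
        status = "detected"
    else:
        status = "presumed_negative"
    return RegionCall(region=region, status=status,
                      sample_quantities=list(sample_quantities),
                      positive_quantities=list(positive_quantities),
                      reliable=reliable)


# ----------------------------------------------------------------------
# Plate CSV I/O and the end-to-end screen


def read_plate_csv(path) -> List[AmplificationCurve]:
    """Read per-well traces from a long CSV:
    plate_id, well, role, region, cycle, rfu[, log10_copies]."""
    df = pd.read_csv(path)
    curves = []
    for (plate, well), g in df.groupby(["plate_id", "well"], sort=False):
        g = g.sort_values("cycle")
        if not np.array_equal(g["cycle"].to_numpy(), np.arange(1, len(g) + 1)):
            raise ValidationError(f"well {well}: cycles must be consecutive from 1")
        lc = g["log10_copies"].iloc[0] if "log10_copies" in g else None
        curves.append(AmplificationCurve(
            well=str(well), role=str(g["role"].iloc[0]), rfu=g["rfu"].to_numpy(),
            plate=str(plate),
            region=None if pd.isna(g["region"].iloc[0]) else str(g["region"].iloc[0]),
            log10_copies=None if lc is None or pd.isna(lc) else float(lc)))
    return curves


def screen_plate(curves: Sequence[AmplificationCurve],
                 threshold: Optional[float] = None) -> pd.DataFrame:
    """Run the full screening pipeline on one plate's curves.

    Fits the standard curve from wells with role ``standard``, quantifies every
    well, and emits one :class:`RegionCall` row per region present.
    """
    if threshold is None:
        threshold = estimate_threshold([c for c in curves if c.role in ("NTC", "EB")]
                                       or list(curves))
    fit = fit_standard_curve([(c.log10_copies, call_cq(c, threshold))
                              for c in curves if c.role == "standard"])

    def quants(role, region=None):
        sel = [c for c in curves if c.role == role and (region is None or c.region == region)]
        return sel, [quantify(call_cq(c, threshold), fit) for c in sel]

    _, ntc_q = quants("NTC")
    _, eb_q = quants("EB")
    regions = sorted({c.region for c in curves if c.role in ("sample_pool", "positive_pool")})
    rows = []
    for region in regions:
        s_curves, s_q = quants("sample_pool", region)
        _, p_q = quants("positive_pool", region)
        reliable = (reliability_check(s_curves, threshold)
                    if len(s_curves) >= 2 else None)
        call = call_region(region, s_q, p_q, ntc_q, eb_q, reliable=reliable)
        rows.append({"region": region, "status": call.status,
                     "max_sample_copies": max(s_q), "max_positive_copies": max(p_q),
                     "reliable": reliable, "threshold": threshold,
                     "slope": fit.slope, "efficiency": fit.efficiency, "r2": fit.r2})
    return pd.DataFrame(rows)
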
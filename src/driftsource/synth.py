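"""Synthetic inputs with known ground truth for every pipeline stage.

Analytic velocity fields (closed-form trajectories), island coastlines,
drifter tracks forward-simulated at known diffusivity, ENSO label series,
sigmoid qPCR amplification curves tied to a log-linear standard curve, and
sequence families with controlled per-site divergence.  All generators are
seed-deterministic: identical spec + seed → identical artifact.

Field kinds
-----------
uniform
    Constant (u0, v0) m/s everywhere; straight-line trajectories.
solid_body
    Rotation about a centre *in the lon/lat plane*: dλ/dt = −ω(φ−φc),
    dφ/dt = ω(λ−λc).  Trajectories are exact circles in degree space, so the
    radius-from-centre is a conserved quantity for integrator checks.
double_gyre
    Classic two-gyre streamfunction ψ = A sin(π f(x̂, t)) sin(π ŷ) on the
    normalised box (planar equirectangular metres), divergence-free for any ψ.
    With ``eps`` > 0 the separatrix oscillates with the given period and the
    advection is chaotic — the regime in which drifter-based diffusivity
    calibration is actually informative, since a single deterministic
    backtrack then misses the origin while a diffusing ensemble explores.
convergent_sink
    Linear radial flow of rate γ (s⁻¹) about an island centre, oriented so the
    *backtracked* (time-reversed) flow converges on the island: the designated
    known-source fixture, making source recovery decidable.  Pass
    ``converge="forward"`` for a forward-time sink instead.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import Polygon

from .calibration import DrifterTrack
from .errors import ValidationError
from .fields import M_PER_DEG, VelocityField, wrap_lon
from .qpcr import AmplificationCurve
from .barcode import SequenceRecord
from .transport import ReleaseSchedule, TransportConfig, run_simulation

import pandas as pd


def _grid(bbox, resolution, dates):
    lon0, lon1 = bbox[0]
    lat0, lat1 = bbox[1]
    extent = (lon1 - lon0) % 360.0 or (lon1 - lon0)
    lon = wrap_lon(np.arange(lon0, lon0 + extent + resolution / 2, resolution))
    lon = np.unique(lon)
    lat = np.arange(lat0, lat1 + resolution / 2, resolution)
    time = np.arange(np.datetime64(dates[0], "D"),
                     np.datetime64(dates[1], "D") + np.timedelta64(1, "D")).astype("datetime64[s]")
    return lon, lat, time


def make_field(kind: str, bbox, resolution: float, dates, *,
               u0: float = 0.0, v0: float = 0.0,
               omega: float = 0.0, center: Tuple[float, float] = (0.0, 0.0),
               amplitude: float = 0.1, eps: float = 0.0, period_days: float = 20.0,
               flow_bbox=None,
               gamma: float = 1e-6, converge: str = "backward",
               land_islands: Sequence[Tuple[Tuple[float, float], float]] = ()) -> VelocityField:
    """Sample a closed-form velocity field onto a regular grid.

    bbox = ((lon_min, lon_max), (lat_min, lat_max)); dates = (start, end)
    inclusive, daily snapshots.  ``land_islands`` marks grid nodes within the
    given (center, radius°) discs as land.
    """
    lon, lat, time = _grid(bbox, resolution, dates)
    LON, LAT = np.meshgrid(lon, lat)
    cx, cy = center
    dlon = (LON - cx + 180.0) % 360.0 - 180.0  # signed offset, seam-safe
    dlat = LAT - cy

    if kind == "uniform":
        U = np.full_like(LON, float(u0))
        V = np.full_like(LON, float(v0))
    elif kind == "solid_body":
        # degree-space rotation expressed in m/s so the integrator's metric
        # conversion recovers the exact circular ODE
        coslat = np.cos(np.radians(LAT))
        U = -omega * dlat * M_PER_DEG * coslat
        V = omega * dlon * M_PER_DEG
    elif kind == "double_gyre":
        # the analytic gyre geometry may be wider than the sampled bbox, so a
        # regional crop of the same flow can serve as a bounded model domain
        fb = flow_bbox if flow_bbox is not None else bbox
        lat0, lat1 = fb[1]
        ext = (fb[0][1] - fb[0][0]) % 360.0 or (fb[0][1] - fb[0][0])
        xh = 2.0 * ((LON - fb[0][0]) % 360.0) / ext            # [0, 2]
        yh = (LAT - lat0) / (lat1 - lat0)                       # [0, 1]
        Lx = ext * M_PER_DEG
        Ly = (lat1 - lat0) * M_PER_DEG
        # ψ = A' sin(π f(x̂,t)) sin(π ŷ) m²/s on planar equirectangular metres;
        # f = a(t)x̂² + b(t)x̂ with a = ε sin(ωt), b = 1 − 2ε sin(ωt);
        # u = −∂ψ/∂y_m, v = ∂ψ/∂x_m — divergence-free for any ψ
        A = amplitude * Ly / math.pi  # scales |u| ~ amplitude m/s
        tsec = (time - time[0]) / np.timedelta64(1, "s")
        omega_t = 2.0 * math.pi / (period_days * 86400.0)
        nt = time.size
        U = np.empty((nt,) + LON.shape)
        V = np.empty((nt,) + LON.shape)
        for k in range(nt):
            e = eps * math.sin(omega_t * tsec[k])
            fx = e * xh ** 2 + (1.0 - 2.0 * e) * xh
            dfdx = 2.0 * e * xh + (1.0 - 2.0 * e)
            U[k] = -A * (math.pi / Ly) * np.sin(math.pi * fx) * np.cos(math.pi * yh)
            V[k] = A * (math.pi * dfdx * 2.0 / Lx) * np.cos(math.pi * fx) * np.sin(math.pi * yh)
        mask = np.zeros(LON.shape, dtype=bool)
        for (icx, icy), r in land_islands:
            d = ((LON - icx + 180.0) % 360.0 - 180.0) ** 2 + (LAT - icy) ** 2
            mask |= d <= r * r
        return VelocityField(lon=lon, lat=lat, time=time, u=U, v=V, land_mask=mask)
    elif kind == "convergent_sink":
        if converge not in ("forward", "backward"):
            raise ValidationError("converge must be 'forward' or 'backward'")
        sgn = 1.0 if converge == "backward" else -1.0  # backward convergence = forward outflow
        coslat = np.cos(np.radians(LAT))
        U = sgn * gamma * dlon * M_PER_DEG * coslat
        V = sgn * gamma * dlat * M_PER_DEG
    else:
        raise ValidationError(f"unsupported field kind {kind!r}")

    mask = np.zeros(LON.shape, dtype=bool)
    for (icx, icy), r in land_islands:
        d = ((LON - icx + 180.0) % 360.0 - 180.0) ** 2 + (LAT - icy) ** 2
        mask |= d <= r * r
    u = np.broadcast_to(U, (time.size,) + U.shape).copy()
    v = np.broadcast_to(V, (time.size,) + V.shape).copy()
    return VelocityField(lon=lon, lat=lat, time=time, u=u, v=v, land_mask=mask)


def make_coastline(islands: Sequence[Tuple[Tuple[float, float], float]],
                   n_vertices: int = 64):
    """Polygonal disc (64-gon) per (center, radius°) island, antimeridian-safe.

    Polygons keep a continuous longitude around their own centre, so an island
    straddling the 0/360 seam is a single valid ring.
    """
    polys = []
    for (cx, cy), r in islands:
        if r <= 0:
            raise ValidationError("island radius must be positive")
        ang = np.linspace(0.0, 2 * math.pi, n_vertices, endpoint=False)
        polys.append(Polygon(zip(cx + r * np.cos(ang), cy + r * np.sin(ang))))
    return polys


def make_drifter(field: VelocityField, start, K_true: float, duration_days: float,
                 cadence_hours: float = 4.0, noise_sd_m: float = 0.0,
                 seed: int = 0, start_time=None, internal_step: float = 3600.0,
                 windage: Tuple[float, float] = (0.0, 0.0),
                 drifter_id: str = "drifter") -> DrifterTrack:
    """Forward-simulate one drifter and observe it at a fixed cadence.

    The track is generated with the transport module itself (K = ``K_true``)
    and observed every ``cadence_hours`` with optional Gaussian position noise;
    endpoints inclusive, so 10 days at 4 h cadence gives 61 fixes.

    ``windage`` is a constant (u, v) m/s slip the *drifter* experiences on top
    of the gridded currents — the unresolved forcing (wind slip, unmodelled
    eddies) that makes real tagged-debris tracks deviate systematically from
    any deterministic model trajectory.  It is applied only here; a model
    backtracking against ``field`` knows nothing of it.
    """
    if windage != (0.0, 0.0):
        field = VelocityField(lon=field.lon, lat=field.lat, time=field.time,
                              u=field.u + windage[0], v=field.v + windage[1],
                              land_mask=field.land_mask)
    t0 = np.datetime64(start_time if start_time is not None else field.time[0], "s")
    day = np.datetime_as_string(t0.astype("datetime64[D]"))
    cadence_s = cadence_hours * 3600.0
    sched = ReleaseSchedule(site=tuple(start), particles_per_day=1,
                            start_date=day, end_date=day)
    cfg = TransportConfig(K=K_true, direction="forward", seed=seed,
                          internal_step=internal_step, output_interval=cadence_s,
                          max_duration_days=int(round(duration_days * 86400.0 / cadence_s)))
    res = run_simulation(field, sched, settlement=None, config=cfg)
    traj = res.trajectories
    n_fix = int(round(duration_days * 24.0 / cadence_hours)) + 1
    traj = traj.iloc[:n_fix]
    lons = traj["lon"].to_numpy().copy()
    lats = traj["lat"].to_numpy().copy()
    if noise_sd_m > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(999,)))
        lats_noise = rng.normal(0, noise_sd_m, lats.size) / M_PER_DEG
        lons_noise = (rng.normal(0, noise_sd_m, lons.size)
                      / (M_PER_DEG * np.cos(np.radians(lats))))
        lons = wrap_lon(lons + lons_noise)
        lats = lats + lats_noise
    return DrifterTrack(times=traj["time"].to_numpy(), lons=lons, lats=lats,
                        origin=tuple(start), drifter_id=drifter_id, K_true=K_true)


def make_enso(start: str, end: str, probabilities=(0.25, 0.25, 0.5),
              seed: int = 0) -> pd.Series:
    """Random monthly ENSO phase series over [start, end] month periods.

    ``probabilities`` are (El Niño, La Niña, Neutral) and must sum to 1.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.size != 3 or not math.isclose(p.sum(), 1.0, abs_tol=1e-9) or np.any(p < 0):
        raise ValidationError("phase probabilities must be 3 non-negative values summing to 1")
    idx = pd.period_range(start, end, freq="M")
    rng = np.random.default_rng(seed)
    labels = rng.choice(["El Niño", "La Niña", "Neutral"], size=idx.size, p=p)
    return pd.Series(labels, index=idx, name="phase")


def make_qpcr(copies: float, slope: float = -3.3219, intercept: float = 38.0,
              threshold: float = 100.0, plateau: float = 1000.0,
              steepness: float = 0.4, noise_sd: float = 0.0,
              n_cycles: int = 45, seed: int = 0, well: str = "A1",
              role: str = "sample_pool", region: Optional[str] = None,
              log10_copies: Optional[float] = None) -> AmplificationCurve:
    """Logistic amplification curve whose threshold crossing hits the
    standard-curve line Cq = intercept + slope·log10(copies).

    ``copies`` <= 0 yields a flat near-zero trace (no amplification).  The
    analytic crossing cycle is stored as ``curve.true_cq``.
    """
    cycles = np.arange(1, n_cycles + 1, dtype=float)
    rng = np.random.default_rng(seed)
    if copies <= 0:
        rfu = np.zeros(n_cycles)
        true_cq = None
    else:
        cq = intercept + slope * math.log10(copies)
        if not (plateau > threshold > 0):
            raise ValidationError("need plateau > threshold > 0")
        c0 = cq + math.log(plateau / threshold - 1.0) / steepness
        rfu = plateau / (1.0 + np.exp(-steepness * (cycles - c0)))
        true_cq = cq
    if noise_sd > 0:
        rfu = rfu + rng.normal(0, noise_sd, n_cycles)
    curve = AmplificationCurve(well=well, role=role, rfu=rfu, region=region,
                               log10_copies=log10_copies)
    curve.true_cq = true_cq
    return curve


def make_standard_series(levels=(1, 2, 3, 4, 5, 6), slope: float = -3.3219,
                         intercept: float = 38.0, noise_sd: float = 0.0,
                         seed: int = 0, **kw):
    """Tenfold dilution series of standards at the given log10-copy levels."""
    return [make_qpcr(10.0 ** lv, slope=slope, intercept=intercept,
                      noise_sd=noise_sd, seed=seed + i, well=f"S{i+1}",
                      role="standard", log10_copies=float(lv), **kw)
            for i, lv in enumerate(levels)]


_BASES = np.array(list("ACGT"))


def make_reference_sequence(length: int = 389, seed: int = 0,
                            marker: str = "UPA", seq_id: str = "REF") -> SequenceRecord:
    rng = np.random.default_rng(seed)
    return SequenceRecord(id=seq_id, seq="".join(rng.choice(_BASES, size=length)),
                          marker=marker, taxon="reference")


def make_markers(reference: SequenceRecord, divergence: float, n: int = 10,
                 seed: int = 0, id_prefix: str = "SYN"):
    """Sequence family mutated from the reference at per-site probability d.

    Each mutated site gets a uniformly chosen *different* base, so expected
    identity to the reference is 100·(1−d)%.
    """
    if not (0.0 <= divergence < 1.0):
        raise ValidationError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ref = np.array(list(reference.seq))
    out = []
    for k in range(n):
        seq = ref.copy()
        hit = rng.random(ref.size) < divergence
        for i in np.flatnonzero(hit):
            choices = _BASES[_BASES != seq[i]]
            seq[i] = rng.choice(choices)
        out.append(SequenceRecord(id=f"{id_prefix}{k:03d}", seq="".join(seq),
                                  marker=reference.marker,
                                  taxon=f"synthetic divergence {divergence}"))
    return out
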
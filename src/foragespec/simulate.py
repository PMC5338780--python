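"""Seeded simulator of a central-place-foraging population with known truth.

The generator emulates the statistical structure the downstream estimators
assume: individuals with persistent trip headings (von Mises-distributed
bearings around an individual mean), lognormal trip distances with between-
and within-individual variation, dive depths following the two-level nested
random-effects model exactly (so variance-component recovery is a sharp
test), isotope values correlated across tissues within individuals, and
multinomial diet samples from individual Dirichlet preference vectors.

Trips are out-and-back walks simulated in colony-anchored planar km and
back-projected to lat/lon; dives are placed in the most distal third of each
trip.  All randomness flows from a single master seed through per-individual
substreams, so outputs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .isotopes import load_prey_table
from .tracks import Deployment, unproject_local_km

#: Pointe-Suzanne-like colony location (deg lat, lon)
DEFAULT_COLONY = (-49.4333, 70.4333)


@dataclass
class SimConfig:
    """Population and sampling design of the simulated colony.

    Defaults mirror a single chick-rearing deployment session on a dozen
    birds carrying both GPS (1-min fixes) and 1-Hz depth loggers, with 4-10
    trips per bird and strong individual specialisation in heading and depth.
    """

    n_individuals: int = 12
    trips_per_individual: tuple[int, int] = (4, 10)  # inclusive range
    stages: tuple[str, ...] = ("chick_rearing",)
    colony: tuple[float, float] = DEFAULT_COLONY
    # headings: individual mean ~ uniform (or strategy centres); trip bearing
    # ~ vonMises(mean_i, kappa_i); kappa_i lognormal across individuals
    kappa_log_mean: float = math.log(30.0)
    kappa_log_sd: float = 0.75
    # trip one-way distance (km), lognormal
    mean_trip_distance_km: float = 10.0
    distance_between_sd_log: float = 0.35
    distance_within_sd_log: float = 0.20
    speed_mps: float = 1.5
    fix_interval_s: float = 60.0
    track_jitter_m: float = 15.0
    # dive depths: y = mu + a_ind + b_trip + e with the variances below (m^2)
    dive_depth_mu_m: float = 25.0
    depth_sigma2_ind: float = 145.0
    depth_sigma2_trip: float = 100.0
    depth_sigma2_resid: float = 4.0
    dives_per_trip: int = 20
    descent_rate_mps: float = 1.5
    surface_noise_sd_m: float = 0.02
    depth_offset_m: float = 0.0   # sensor drift, removed by zero-offset correction
    simulate_tdr: bool = True
    # isotopes (permil): population means/SDs and between-tissue correlation
    isotope_means: dict = field(default_factory=lambda: {
        ("blood", "d13C"): -16.3, ("blood", "d15N"): 14.6,
        ("feather", "d13C"): -15.2, ("feather", "d15N"): 15.3,
    })
    isotope_sd: float = 1.2
    tissue_rho: float = 0.9
    d15n_incubation_offset: float = 0.56
    # diet: per-individual Dirichlet preference over the prey list
    diet_dirichlet_alpha: float = 0.3
    diet_items_per_sample: float = 8.0
    # planted strategies (0 = none: headings uniform per individual).  A
    # strategy is a heading sector, a distance regime and a consistency level
    # (per-strategy kappa and within-individual distance spread), so planted
    # clusters separate in every clustered feature — means, CVs, heading
    # dispersion and the consistency index — not just position; the
    # between-individual spread within a strategy is kept tight
    n_strategies: int = 0
    strategy_heading_sd_deg: float = 5.0
    strategy_distance_factors: tuple[float, ...] = (1.0, 0.5, 1.6, 0.25)
    strategy_kappas: tuple[float, ...] = (400.0, 20.0, 100.0, 45.0)
    strategy_within_sds: tuple[float, ...] = (0.08, 0.35, 0.15, 0.25)
    strategy_log_distance_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_trip_distance_km <= 0:
            raise ConfigError("trip distance must be positive")
        for name in ("depth_sigma2_ind", "depth_sigma2_trip", "depth_sigma2_resid"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0.0 <= self.tissue_rho <= 1.0:
            raise ConfigError("tissue_rho must be in [0, 1]")
        if self.seed is None:
            raise ConfigError("seed is mandatory")


@dataclass
class GroundTruth:
    """What the simulator actually drew, for testing the estimators."""

    individuals: pd.DataFrame     # per individual: mean heading, kappa, depth offset, strategy
    dives: pd.DataFrame           # per scheduled dive: individual, trip, target depth
    variance_components: dict     # true depth variance components
    trip_counts: pd.DataFrame     # individual x stage -> simulated trip count


def _individual_params(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_individuals
    rows = []
    for i in range(n):
        if cfg.n_strategies > 0:
            s = i % cfg.n_strategies
            centre = -180.0 + 360.0 * (s + 0.5) / cfg.n_strategies
            mu = centre + rng.normal(0.0, cfg.strategy_heading_sd_deg)
            kappa = cfg.strategy_kappas[s % len(cfg.strategy_kappas)]
            dist_factor = cfg.strategy_distance_factors[s % len(cfg.strategy_distance_factors)]
            between_sd = cfg.strategy_log_distance_sd
            within_sd = cfg.strategy_within_sds[s % len(cfg.strategy_within_sds)]
        else:
            s = -1
            mu = rng.uniform(-180.0, 180.0)
            kappa = float(np.exp(rng.normal(cfg.kappa_log_mean, cfg.kappa_log_sd)))
            dist_factor = 1.0
            between_sd = cfg.distance_between_sd_log
            within_sd = cfg.distance_within_sd_log
        rows.append({
            "individual_id": f"IND{i:02d}",
            "mu_heading_deg": ((mu + 180.0) % 360.0) - 180.0,
            "kappa": kappa,
            "log_distance_mu": math.log(cfg.mean_trip_distance_km * dist_factor)
                + rng.normal(0.0, between_sd),
            "log_distance_within_sd": within_sd,
            "depth_offset_ind": rng.normal(0.0, math.sqrt(cfg.depth_sigma2_ind)),
            "strategy": s,
        })
    return pd.DataFrame(rows)


def simulate_trip(rng: np.random.Generator, cfg: SimConfig, bearing_deg: float,
                  distance_km: float, start_s: float,
                  jitter_m: float | None = None):
    """One out-and-back trip; returns (fix table, start/end epoch seconds).

    The bird departs the colony at ``start_s`` (epoch seconds), travels in a
    straight line at ``speed_mps`` along ``bearing_deg`` with lateral jitter,
    turns around at ``distance_km`` and returns.  Three at-colony fixes are
    emitted before departure and after return so trip segmentation has
    bounding colony fixes.
    """
    if distance_km <= 0:
        raise ConfigError("trip distance must be positive")
    jit = cfg.track_jitter_m if jitter_m is None else jitter_m
    leg_s = distance_km * 1000.0 / cfg.speed_mps
    times = np.arange(0.0, 2 * leg_s + cfg.fix_interval_s / 2, cfg.fix_interval_s)
    along = np.where(times <= leg_s, times, 2 * leg_s - times) * cfg.speed_mps / 1000.0
    theta = math.radians(bearing_deg)
    x = along * math.sin(theta)
    y = along * math.cos(theta)
    if jit > 0:
        x = x + rng.normal(0.0, jit / 1000.0, len(x))
        y = y + rng.normal(0.0, jit / 1000.0, len(y))
    # bounding colony fixes (within the colony radius)
    pre = np.arange(-3, 0) * cfg.fix_interval_s
    post = times[-1] + np.arange(1, 4) * cfg.fix_interval_s
    t_all = np.concatenate([pre, times, post]) + start_s
    x_all = np.concatenate([np.zeros(3), x, np.zeros(3)])
    y_all = np.concatenate([np.zeros(3), y, np.zeros(3)])
    lat, lon = unproject_local_km(x_all, y_all, cfg.colony)
    fixes = pd.DataFrame({
        "time": pd.to_datetime((t_all * 1e9).round().astype(np.int64)),
        "lat": lat, "lon": lon,
    })
    return fixes, float(start_s), float(start_s + 2 * leg_s)


def _depth_profile(cfg: SimConfig, rng: np.random.Generator, n_s: int,
                   dive_depths: np.ndarray, window: tuple[int, int]):
    """1-Hz depth samples for one trip with V-shaped dives of exact target
    depth placed evenly inside ``window`` (sample indices)."""
    depth = rng.normal(0.0, cfg.surface_noise_sd_m, n_s).clip(-0.3, 0.3)
    lo, hi = window
    slots = np.linspace(lo, hi, len(dive_depths) + 1).astype(int)
    placed = []
    for d, (a, b) in zip(dive_depths, zip(slots[:-1], slots[1:])):
        n_leg = max(2, int(math.ceil(d / cfg.descent_rate_mps)))
        n_dive = 2 * n_leg + 2                     # descent, 3-sample bottom, ascent
        if a + n_dive + 2 >= b:
            continue
        down = np.linspace(0.0, d, n_leg + 1)[1:]
        prof = np.concatenate([down, [d], down[::-1][1:]])
        depth[a + 1:a + 1 + len(prof)] = prof
        placed.append(d)
    return depth + cfg.depth_offset_m, placed


def simulate_population(cfg: SimConfig):
    """Simulate the colony; returns (deployments, depth_series, isotopes,
    diets, truth).

    ``deployments`` is a list of :class:`~foragespec.tracks.Deployment` (one
    per individual × stage); ``depth_series`` a dict individual_id ->
    (times, depth) DataFrame; isotope and diet tables are long-format
    DataFrames matching the package readers' schemas.
    """
    master = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    params = _individual_params(cfg, master)
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_individuals + 1)
    prey = load_prey_table()["species"].tolist()
    prey_groups = dict(zip(load_prey_table()["species"], load_prey_table()["prey_group"]))

    deployments: list[Deployment] = []
    depth_frames: dict[str, pd.DataFrame] = {}
    iso_rows, diet_rows, truth_dives, truth_trips = [], [], [], []
    t0 = pd.Timestamp("2015-01-06T00:00:00").value / 1e9

    for i, rec in params.iterrows():
        rng = np.random.default_rng(streams[i])
        ind = rec["individual_id"]
        u13, u15 = rng.normal(size=2)          # isotope latents, shared across tissues
        pref = rng.dirichlet(np.full(len(prey), cfg.diet_dirichlet_alpha))
        params.loc[i, "u_d13C"], params.loc[i, "u_d15N"] = u13, u15
        params.loc[i, "preferred_prey"] = prey[int(np.argmax(pref))]
        clock = t0 + i * 3600.0               # stagger individuals
        all_depth_t, all_depth_d = [], []

        for stage in cfg.stages:
            lo, hi = cfg.trips_per_individual
            n_trips = int(rng.integers(lo, hi + 1))
            truth_trips.append({"individual_id": ind, "stage": stage, "n_trips": n_trips})
            fixes_parts = []
            for j in range(n_trips):
                bearing = math.degrees(rng.vonmises(math.radians(rec["mu_heading_deg"]),
                                                    rec["kappa"]))
                dist = float(np.exp(rec["log_distance_mu"]
                                    + rng.normal(0.0, rec["log_distance_within_sd"])))
                fixes, ts, te = simulate_trip(rng, cfg, bearing, dist, clock)
                fixes_parts.append(fixes)
                if cfg.simulate_tdr and stage == cfg.stages[-1]:
                    b_trip = rng.normal(0.0, math.sqrt(cfg.depth_sigma2_trip))
                    targets = (cfg.dive_depth_mu_m + rec["depth_offset_ind"] + b_trip
                               + rng.normal(0.0, math.sqrt(cfg.depth_sigma2_resid),
                                            cfg.dives_per_trip))
                    targets = np.clip(targets, 1.6, None)
                    n_s = int(te - ts) + 1
                    # distal third of the trip: middle portion around turnaround
                    win = (n_s // 3, 2 * n_s // 3)
                    depth, placed = _depth_profile(cfg, rng, n_s, targets, win)
                    all_depth_t.append(np.arange(n_s) + ts)
                    all_depth_d.append(depth)
                    for d in placed:
                        truth_dives.append({"individual_id": ind, "stage": stage,
                                            "trip": j + 1, "target_depth_m": float(d)})
                clock = te + 1800.0           # half-hour colony dwell between trips
            deployments.append(Deployment(
                individual_id=ind, stage=stage, colony=cfg.colony,
                fixes=pd.concat(fixes_parts, ignore_index=True)))
            clock += 6 * 3600.0               # rest between stages

            # isotopes: blood each stage, feather once (moult)
            for (tissue, iso), mean in cfg.isotope_means.items():
                if tissue == "feather" and stage != cfg.stages[0]:
                    continue
                u = u13 if iso == "d13C" else u15
                eps = rng.normal()
                val = mean + cfg.isotope_sd * (math.sqrt(cfg.tissue_rho) * u
                                               + math.sqrt(1 - cfg.tissue_rho) * eps)
                if iso == "d15N" and tissue == "blood" and stage == "incubation":
                    val += cfg.d15n_incubation_offset
                key = (ind, tissue, "moult" if tissue == "feather" else stage)
                iso_rows.append({"individual_id": ind, "tissue": tissue,
                                 "stage": key[2], "isotope": iso, "value": val,
                                 "cn_ratio": rng.normal(3.39 if tissue == "blood" else 3.20,
                                                        0.04)})
            # one regurgitate sample per stage
            n_items = max(1, int(rng.poisson(cfg.diet_items_per_sample)))
            counts = rng.multinomial(n_items, pref)
            for sp, c in zip(prey, counts):
                if c > 0:
                    diet_rows.append({"sample_id": f"{ind}-{stage}",
                                      "individual_id": ind, "stage": stage,
                                      "species": sp, "prey_group": prey_groups[sp],
                                      "count": int(c)})
        if all_depth_t:
            t = np.concatenate(all_depth_t)
            depth_frames[ind] = pd.DataFrame({
                "time": pd.to_datetime((t * 1e9).round().astype(np.int64)),
                "depth_m": np.concatenate(all_depth_d),
            })

    # wide isotope table: one row per individual x tissue x stage
    iso_long = pd.DataFrame(iso_rows)
    iso = (iso_long.pivot_table(index=["individual_id", "tissue", "stage"],
                                columns="isotope", values="value")
                   .reset_index())
    cn = (iso_long.groupby(["individual_id", "tissue", "stage"])["cn_ratio"]
                  .first().reset_index())
    iso = iso.merge(cn, on=["individual_id", "tissue", "stage"])
    iso.columns.name = None

    truth = GroundTruth(
        individuals=params,
        dives=pd.DataFrame(truth_dives,
                           columns=["individual_id", "stage", "trip", "target_depth_m"]),
        variance_components={"individual": cfg.depth_sigma2_ind,
                             "trip": cfg.depth_sigma2_trip,
                             "residual": cfg.depth_sigma2_resid},
        trip_counts=pd.DataFrame(truth_trips),
    )
    return deployments, depth_frames, iso, pd.DataFrame(diet_rows), truth
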
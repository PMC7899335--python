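"""Synthetic data with known ground truth for every analysis stage.

The generators emulate the statistical structure each analysis assumes:

* line scans - Gaussian puncta of known amplitude, width and position on
  a Gaussian-noise background (camera read-noise regime; Poisson shot
  noise behind a flag);
* dual-reporter images - two pools of receptor fluorescence, where the
  mCherry channel sees the total and the SEP channel sees the surface
  pool plus the unquenched remainder of the internal pool
  (``sep = total * (f_surf + (1 - f_surf)(1 - q))``);
* dual-channel FRAP - linear ODE on four pools per fluorophore
  (surface/internal x bleached/unbleached), where the bleach darkens
  mCherry in both compartments but SEP only at the surface, because
  quenched SEP in acidic endosomes is protected from the bleach;
* behavioral tables - Bernoulli trial outcomes, Poisson event counts,
  and exponential (right-censored) paralysis times per genotype.

Every generator is deterministic for a fixed seed and returns its truth
record alongside the data, enabling parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ConfigurationError
from .frap import DEFAULT_TIMEPOINTS_MIN, FrapSeries
from .puncta import LineScan

__all__ = [
    "ScanTruth",
    "ReporterTruth",
    "FrapTruth",
    "GenotypeBehavior",
    "BehaviorTruth",
    "gen_linescan",
    "gen_dual_channel",
    "solve_frap_pools",
    "frap_signals",
    "gen_frap_series",
    "sep_post_bleach_floor",
    "gen_behavior",
]

#: Default pixel size in um/pixel for generated images and line scans
#: (typical of 63-100x oil objectives on CCD cameras); always an explicit
#: parameter, never assumed downstream.
DEFAULT_PIXEL_SIZE_UM = 0.1


# ---------------------------------------------------------------------------
# truth records


@dataclass(frozen=True)
class ScanTruth:
    """Generative parameters of one synthetic line scan.

    ``puncta`` is a list of ``(center_um, amplitude, sigma_um)`` tuples;
    amplitudes are in AU above background.
    """

    length_um: float = 60.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    background_mean: float = 100.0
    background_sd: float = 5.0
    puncta: tuple[tuple[float, float, float], ...] = ()
    bead_mean: float = 250.0
    seed: int = 0
    shot_noise: bool = False

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.pixel_size_um <= 0:
            raise ConfigurationError("length_um and pixel_size_um must be positive")
        if self.background_sd < 0 or self.background_mean < 0:
            raise ConfigurationError("background parameters must be non-negative")
        for c, a, s in self.puncta:
            if a < 0 or s <= 0 or not (0 <= c <= self.length_um):
                raise ConfigurationError("puncta need amplitude >= 0, sigma > 0, center in scan")


@dataclass(frozen=True)
class ReporterTruth:
    """Generative parameters of one paired SEP/mCherry image."""

    total_per_pixel: float = 200.0
    f_surf: float = 0.5
    q: float = 1.0
    noise_sd: float = 0.0
    roi_shape: tuple[int, int] = (20, 60)
    seed: int = 0
    shot_noise: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.f_surf <= 1 and 0 <= self.q <= 1):
            raise ConfigurationError("f_surf and q must lie in [0, 1]")
        if self.total_per_pixel < 0 or self.noise_sd < 0:
            raise ConfigurationError("total_per_pixel and noise_sd must be non-negative")


@dataclass(frozen=True)
class FrapTruth:
    """Generative parameters of one dual-channel FRAP experiment.

    Rates are per minute: ``k_exo`` internal-to-surface insertion inside
    the ROI, ``k_endo`` surface-to-internal, ``k_ext`` influx of
    unbleached receptor from outside the bleached region.  ``beta`` is
    the bleach efficiency and ``noise_sd`` a multiplicative measurement
    noise on the reported totals.
    """

    f_surf: float = 0.5
    q: float = 1.0
    beta: float = 0.9
    k_exo: float = 0.1
    k_endo: float = 0.0
    k_ext: float = 0.0
    timepoints_min: tuple[float, ...] = DEFAULT_TIMEPOINTS_MIN
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k_exo, self.k_endo, self.k_ext) < 0:
            raise ConfigurationError("rates must be non-negative")
        if not (0 <= self.beta <= 1):
            raise ConfigurationError("beta must lie in [0, 1]")
        if not (0 <= self.f_surf <= 1 and 0 <= self.q <= 1):
            raise ConfigurationError("f_surf and q must lie in [0, 1]")
        t = np.asarray(self.timepoints_min, dtype=float)
        if t.size == 0 or t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ConfigurationError("timepoints must be strictly increasing and start at >= 0")


@dataclass(frozen=True)
class GenotypeBehavior:
    """Per-genotype behavioral ground truth."""

    p_resp: float = 0.9  # nose touch / optoASH response probability per trial
    lambda_thrash: float = 60.0  # thrashes per 30 s
    lambda_rev: float = 10.0  # reversals per 5 min
    paralysis_rate: float = 0.02  # 1/min exponential hazard on aldicarb
    n_worms: int = 24

    def __post_init__(self) -> None:
        if not (0 <= self.p_resp <= 1):
            raise ConfigurationError("p_resp must lie in [0, 1]")
        if min(self.lambda_thrash, self.lambda_rev, self.paralysis_rate) < 0:
            raise ConfigurationError("rates must be non-negative")
        if self.n_worms < 1:
            raise ConfigurationError("n_worms must be >= 1")


@dataclass(frozen=True)
class BehaviorTruth:
    """Behavioral ground truth for a set of genotypes."""

    genotypes: tuple[tuple[str, GenotypeBehavior], ...] = (
        ("WT", GenotypeBehavior()),
    )
    n_trials_nose: int = 10
    n_pulses_opto: int = 5
    assay_end_min: float = 120.0
    check_interval_min: float = 15.0
    worms_per_plate: int = 20
    seed: int = 0


# ---------------------------------------------------------------------------
# line scans


def gen_linescan(truth: ScanTruth) -> LineScan:
    """Generate a line scan: Gaussian puncta on a Gaussian-noise background.

    ``intensity[i] = bg_mean + sum_j a_j exp(-(x_i - c_j)^2 / (2 sigma_j^2))
    + noise``; negative noise excursions are clipped at zero to respect
    the non-negativity of camera counts.
    """
    rng = np.random.default_rng(truth.seed)
    n = int(round(truth.length_um / truth.pixel_size_um))
    x = np.arange(n) * truth.pixel_size_um
    signal = np.full(n, truth.background_mean, dtype=float)
    for c, a, s in truth.puncta:
        signal += a * np.exp(-((x - c) ** 2) / (2.0 * s * s))
    if truth.shot_noise:
        y = rng.poisson(np.clip(signal, 0, None)).astype(float)
    else:
        y = signal + rng.normal(0.0, truth.background_sd, n) if truth.background_sd > 0 else signal
    y = np.clip(y, 0.0, None)
    return LineScan(x, y, truth.pixel_size_um, truth.bead_mean)


# ---------------------------------------------------------------------------
# dual-reporter images


def gen_dual_channel(truth: ReporterTruth) -> tuple[np.ndarray, np.ndarray]:
    """Paired (sep, mcherry) images sharing one spatial layout.

    Per pixel: ``mcherry = total + noise`` and
    ``sep = total * (f_surf + (1 - f_surf)(1 - q)) + noise``.
    """
    rng = np.random.default_rng(truth.seed)
    shape = truth.roi_shape
    total = np.full(shape, truth.total_per_pixel, dtype=float)
    sep_mean = total * (truth.f_surf + (1.0 - truth.f_surf) * (1.0 - truth.q))
    if truth.shot_noise:
        mch = rng.poisson(total).astype(float)
        sep = rng.poisson(sep_mean).astype(float)
    elif truth.noise_sd > 0:
        mch = total + rng.normal(0.0, truth.noise_sd, shape)
        sep = sep_mean + rng.normal(0.0, truth.noise_sd, shape)
    else:
        mch, sep = total, sep_mean
    return np.clip(sep, 0.0, None), np.clip(mch, 0.0, None)


# ---------------------------------------------------------------------------
# FRAP


def _pool_rhs(k_exo: float, k_endo: float, k_ext: float, f_surf: float):
    """Right-hand side for [S_u, S_b, I_u, I_b] of one fluorophore.

    Unbleached influx from outside the bleached region enters the surface
    and internal unbleached pools in proportion to the pre-bleach
    composition (``k_ext * f_surf`` and ``k_ext * (1 - f_surf)``), since
    the external region retains that composition.
    """
    src_s = k_ext * f_surf
    src_i = k_ext * (1.0 - f_surf)

    def rhs(_t, y):
        s_u, s_b, i_u, i_b = y
        ds_u = k_exo * i_u - k_endo * s_u + src_s
        ds_b = k_exo * i_b - k_endo * s_b
        di_u = k_endo * s_u - k_exo * i_u + src_i
        di_b = k_endo * s_b - k_exo * i_b
        return [ds_u, ds_b, di_u, di_b]

    return rhs


def solve_frap_pools(truth: FrapTruth, times: np.ndarray) -> dict[str, np.ndarray]:
    """Pool trajectories [S_u, S_b, I_u, I_b] per fluorophore at ``times``.

    Pre-bleach state: surface fraction ``f_surf`` of a unit total, all
    unbleached.  At t = 0 the bleach multiplies unbleached mCherry in
    both compartments by ``(1 - beta)`` but unbleached SEP only at the
    surface.  Dynamics are the same linear exchange for both fluorophores
    and both bleach states; solved with an adaptive solver at rtol 1e-8.
    """
    f, beta = truth.f_surf, truth.beta
    init = {
        "mCherry": np.array([f * (1 - beta), f * beta,
                             (1 - f) * (1 - beta), (1 - f) * beta]),
        "SEP": np.array([f * (1 - beta), f * beta, (1 - f), 0.0]),
    }
    times = np.asarray(times, dtype=float)
    rhs = _pool_rhs(truth.k_exo, truth.k_endo, truth.k_ext, f)
    out = {}
    for channel, y0 in init.items():
        if times[-1] == 0:
            out[channel] = np.tile(y0, (times.size, 1))
            continue
        sol = solve_ivp(rhs, (0.0, float(times[-1])), y0, t_eval=times,
                        rtol=1e-8, atol=1e-12, method="RK45")
        if not sol.success:
            raise RuntimeError(f"FRAP ODE solve failed: {sol.message}")
        out[channel] = sol.y.T
    return out


def frap_signals(truth: FrapTruth, times: np.ndarray) -> dict[str, np.ndarray]:
    """Noiseless pre-bleach-normalized channel signals at ``times``.

    ``SEP(t) = S_u + (1 - q) I_u`` and ``mCherry(t) = S_u + I_u`` of each
    fluorophore's own unbleached pools, each divided by its pre-bleach
    value.
    """
    f, q = truth.f_surf, truth.q
    pools = solve_frap_pools(truth, times)
    pre = {"SEP": f + (1 - f) * (1 - q), "mCherry": 1.0}
    out = {}
    for channel, y in pools.items():
        s_u, i_u = y[:, 0], y[:, 2]
        raw = s_u + (1 - q) * i_u if channel == "SEP" else s_u + i_u
        if pre[channel] <= 0:
            raise ConfigurationError("pre-bleach signal is zero (f_surf=0 with q=1)")
        out[channel] = raw / pre[channel]
    return out


def sep_post_bleach_floor(f_surf: float, q: float, beta: float) -> float:
    """Closed-form normalized SEP signal immediately after the bleach.

    Only the surface SEP is bleached, so the floor is
    ``1 - beta * f / (f + (1 - f)(1 - q))``.
    """
    denom = f_surf + (1 - f_surf) * (1 - q)
    if denom <= 0:
        raise ConfigurationError("pre-bleach SEP signal is zero")
    return 1.0 - beta * f_surf / denom


def gen_frap_series(truth: FrapTruth, scale_au: float = 1000.0
                    ) -> dict[str, FrapSeries]:
    """Simulated ROI-total series for both channels.

    Totals are the normalized signals scaled to ``scale_au`` pre-bleach
    counts, with optional multiplicative Gaussian noise of relative SD
    ``noise_sd`` on each post-bleach total.
    """
    rng = np.random.default_rng(truth.seed)
    times = np.asarray(truth.timepoints_min, dtype=float)
    signals = frap_signals(truth, times)
    pre_sep = truth.f_surf + (1 - truth.f_surf) * (1 - truth.q)
    pre = {"SEP": scale_au * pre_sep, "mCherry": scale_au}
    out = {}
    for channel, norm in signals.items():
        totals = norm * pre[channel]
        if truth.noise_sd > 0:
            totals = totals * (1.0 + rng.normal(0.0, truth.noise_sd, totals.size))
        out[channel] = FrapSeries(channel=channel, times_min=times,
                                  totals=np.clip(totals, 0.0, None),
                                  pre_total=pre[channel])
    return out


# ---------------------------------------------------------------------------
# behavior


def gen_behavior(truth: BehaviorTruth) -> dict[str, pd.DataFrame]:
    """Trial, count and paralysis tables for each genotype.

    Returns a dict with keys ``nose_touch`` and ``opto`` (binary trial
    tables), ``counts`` (thrash and reversal Poisson counts) and
    ``paralysis`` (per-plate counts at 15 min checks, exponential
    paralysis times right-censored at the assay end).
    """
    rng = np.random.default_rng(truth.seed)
    nose_rows, opto_rows, count_rows, para_rows = [], [], [], []
    for genotype, g in truth.genotypes:
        for w in range(g.n_worms):
            wid = f"{genotype}_{w}"
            for t in range(truth.n_trials_nose):
                nose_rows.append((wid, genotype, t + 1,
                                  int(rng.random() < g.p_resp)))
            for t in range(truth.n_pulses_opto):
                opto_rows.append((wid, genotype, t + 1,
                                  int(rng.random() < g.p_resp)))
            count_rows.append((wid, genotype, int(rng.poisson(g.lambda_thrash)),
                               "30 s", "thrash"))
            count_rows.append((wid, genotype, int(rng.poisson(g.lambda_rev)),
                               "5 min", "reversal"))
        # aldicarb: plates of worms_per_plate, exponential paralysis times
        n_plates = max(1, int(np.ceil(g.n_worms / truth.worms_per_plate)))
        checks = np.arange(truth.check_interval_min,
                           truth.assay_end_min + 1e-9, truth.check_interval_min)
        for p in range(n_plates):
            n_on_plate = truth.worms_per_plate
            if g.paralysis_rate > 0:
                t_par = rng.exponential(1.0 / g.paralysis_rate, n_on_plate)
            else:
                t_par = np.full(n_on_plate, np.inf)
            for t in checks:
                para_rows.append((f"{genotype}_p{p}", genotype, float(t),
                                  int(np.sum(t_par <= t)), n_on_plate))
    return {
        "nose_touch": pd.DataFrame(nose_rows, columns=["worm_id", "genotype",
                                                       "trial_index", "response"]),
        "opto": pd.DataFrame(opto_rows, columns=["worm_id", "genotype",
                                                 "trial_index", "response"]),
        "counts": pd.DataFrame(count_rows, columns=["worm_id", "genotype",
                                                    "count", "period", "assay"]),
        "paralysis": pd.DataFrame(para_rows, columns=["plate_id", "genotype",
                                                      "time_min", "n_paralyzed",
                                                      "n_total"]),
    }


def truth_to_json(truth, path) -> None:
    """Write a truth record as a JSON sidecar."""
    d = asdict(truth)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2, default=lambda o: list(o) if isinstance(o, tuple) else o)
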
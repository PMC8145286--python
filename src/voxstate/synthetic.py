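"""Synthetic BOLD generator with planted task structure.

The generator emulates the statistical world the state-space method
assumes: voxel activity is a linear mixture of binary task-variable
timecourses through planted spatial weight maps, smoothed by a
hemodynamic response, corrupted by slow drift and white Gaussian noise.
Because the planted weight maps and pre-convolution neural signal are
returned alongside the observed data, every stage of the pipeline can be
validated against ground truth.

Two schemes mirror the tasks the method targets:

* ``attention`` — two binary stimulus-presence variables plus a signed
  attention variable (+1 attend category A, -1 attend category B,
  0 passive), with one contiguous block per attention condition; the 4
  presence combinations x 3 conditions give 12 state labels. An
  attention-like gain multiplies the presence signal during attended
  blocks.
* ``game`` — nine non-mutually-exclusive binary behavioral states drawn
  from persistent Markov chains with optional pairwise co-occurrence
  biases; a TR's label set is its active states (possibly empty).

State chains use the persistence parameterization
``P(on_t) = rho * on_{t-1} + (1 - rho) * marginal`` with
``rho = max(0, 1 - 1 / (dwell * (1 - marginal)))``, which gives the
requested stationary marginal exactly, a mean on-dwell of ``dwell`` TRs
when feasible, and independent per-TR draws at ``dwell = 1``.

SNR is defined as planted-signal variance divided by noise variance per
voxel, averaged over signal-carrying voxels (after HRF smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.stats import gamma as gamma_dist

from .types import ActivityMatrix, TaskDesign

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "make_task_design",
    "simulate_bold",
    "generate",
    "double_gamma_hrf",
]

ATTENTION_VARIABLES = ("human_presence", "vehicle_presence", "attention")
ATTENTION_CONDITIONS = ("attend_human", "attend_vehicle", "passive")
GAME_STATES = (
    "dead",
    "round_start",
    "safe_explore",
    "unsafe_explore",
    "kill",
    "engage_close",
    "engage_far",
    "flash",
    "run_away",
)

# Default double-gamma response: peak ~6 s, undershoot ~16 s, 1/6 ratio.
DEFAULT_HRF = {
    "peak_delay": 6.0,
    "undershoot_delay": 16.0,
    "peak_dispersion": 1.0,
    "undershoot_dispersion": 1.0,
    "ratio": 1.0 / 6.0,
    "duration": 32.0,
}


@dataclass
class SyntheticSpec:
    """Generation parameters; defaults define the package's study conditions."""

    n_trs: int = 3000
    n_voxels: int = 2000
    tr_seconds: float = 2.0
    scheme: str = "attention"
    weight_maps: np.ndarray | None = None
    weight_sparsity: float = 0.6
    network_overlap: float = 0.5
    state_dwell_trs: float = 10.0
    state_marginal: float = 0.2  # game scheme per-state marginal frequency
    state_correlation: np.ndarray | None = None
    snr: float = 50.0
    drift_amplitude: float = 1.0
    attention_gain: float = 1.0
    hrf: dict | str | None = None  # None -> double gamma; "delta" -> identity
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted quantities returned alongside the simulated BOLD."""

    neural: np.ndarray  # pre-convolution signal X_eff @ W, (TRs x voxels)
    weight_maps: np.ndarray  # (variables x voxels)
    drift: np.ndarray  # injected drift, (TRs x voxels) or zeros
    noise_sd: float
    design_effective: np.ndarray = field(default=None)  # gain-scaled X


def double_gamma_hrf(tr_seconds: float, params: dict | None = None) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR.

    Difference of two gamma densities (positive peak minus a scaled
    undershoot), normalized to unit peak.
    """
    p = dict(DEFAULT_HRF)
    if params:
        p.update(params)
    t = np.arange(0, p["duration"] + tr_seconds / 2, tr_seconds)
    peak = gamma_dist.pdf(
        t, a=p["peak_delay"] / p["peak_dispersion"], scale=p["peak_dispersion"]
    )
    under = gamma_dist.pdf(
        t,
        a=p["undershoot_delay"] / p["undershoot_dispersion"],
        scale=p["undershoot_dispersion"],
    )
    h = peak - p["ratio"] * under
    return h / np.abs(h).max()


def _persistence(dwell: float, marginal: float) -> float:
    if dwell < 1:
        raise ValueError(f"state_dwell_trs must be >= 1, got {dwell}")
    return max(0.0, 1.0 - 1.0 / (dwell * (1.0 - marginal)))


def _markov_column(
    n: int, marginal: float, dwell: float, rng: np.random.Generator
) -> np.ndarray:
    rho = _persistence(dwell, marginal)
    x = np.empty(n, dtype=float)
    x[0] = float(rng.random() < marginal)
    u = rng.random(n)
    for t in range(1, n):
        x[t] = float(u[t] < rho * x[t - 1] + (1 - rho) * marginal)
    return x


def _run_boundaries(n_trs: int, n_runs: int) -> tuple:
    edges = np.linspace(0, n_trs, n_runs + 1).astype(int)
    return tuple(int(e) for e in edges[:-1])


def make_task_design(spec: SyntheticSpec) -> TaskDesign:
    """Draw a block-structured binary task design with per-TR state labels."""
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_trs
    if spec.scheme == "attention":
        human = _markov_column(n, 0.5, spec.state_dwell_trs, rng)
        vehicle = _markov_column(n, 0.5, spec.state_dwell_trs, rng)
        bounds = _run_boundaries(n, 3)
        attention = np.zeros(n)
        cond = np.empty(n, dtype=object)
        stops = list(bounds[1:]) + [n]
        for (name, sign), a, b in zip(
            zip(ATTENTION_CONDITIONS, (1.0, -1.0, 0.0)), bounds, stops
        ):
            attention[a:b] = sign
            cond[a:b] = name
        labels = [
            f"{c}:H{int(h)}V{int(v)}" for c, h, v in zip(cond, human, vehicle)
        ]
        return TaskDesign(
            values=np.column_stack([human, vehicle, attention]),
            variable_names=ATTENTION_VARIABLES,
            labels=labels,
            run_boundaries=bounds,
        )
    if spec.scheme == "game":
        k = len(GAME_STATES)
        corr = (
            np.zeros((k, k))
            if spec.state_correlation is None
            else np.asarray(spec.state_correlation, dtype=float)
        )
        if corr.shape != (k, k) or not np.all(np.isfinite(corr)):
            raise ValueError(
                f"state_correlation must be a finite {k}x{k} matrix of "
                "log-odds co-occurrence biases"
            )
        m = spec.state_marginal
        rho = _persistence(spec.state_dwell_trs, m)
        x = np.zeros((n, k))
        x[0] = rng.random(k) < m
        for t in range(1, n):
            p = rho * x[t - 1] + (1 - rho) * m
            p = np.clip(p, 1e-9, 1 - 1e-9)
            logit = np.log(p / (1 - p)) + (x[t - 1] - m) @ corr
            p = 1.0 / (1.0 + np.exp(-logit))
            x[t] = rng.random(k) < p
        labels = [
            tuple(GAME_STATES[j] for j in np.flatnonzero(row)) for row in x
        ]
        return TaskDesign(
            values=x,
            variable_names=GAME_STATES,
            labels=labels,
            run_boundaries=_run_boundaries(n, 3),
        )
    raise ValueError(f"unknown scheme '{spec.scheme}' (attention | game)")


def _make_weight_maps(
    n_vars: int, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    """Sparse overlapping 'network' weight maps, one row per variable.

    Each variable's support is part exclusive (a disjoint slice of a
    shuffled voxel order) and part shared (an independent random sample),
    mixed by ``network_overlap``; weights on the support are standard
    normal.
    """
    v = spec.n_voxels
    if not 0 < spec.weight_sparsity <= 1:
        raise ValueError(f"weight_sparsity must be in (0, 1], got {spec.weight_sparsity}")
    per_var = int(round(spec.weight_sparsity * v))
    n_excl = per_var - int(round(per_var * spec.network_overlap))
    # exclusive supports are disjoint; cap them at an equal share of the
    # voxels and move the remainder into the shared draw
    n_excl = min(n_excl, v // n_vars)
    n_shared = per_var - n_excl
    order = rng.permutation(v)
    w = np.zeros((n_vars, v))
    for i in range(n_vars):
        support = set(order[i * n_excl : (i + 1) * n_excl])
        support.update(rng.choice(v, size=n_shared, replace=False))
        idx = np.fromiter(support, dtype=int)
        w[i, idx] = rng.standard_normal(idx.size)
    return w


def _convolve_runs(
    x: np.ndarray, kernel: np.ndarray, boundaries: tuple
) -> np.ndarray:
    """Causal convolution of each column, independently within each run."""
    n = x.shape[0]
    starts = list(boundaries)
    stops = starts[1:] + [n]
    out = np.empty_like(x)
    for a, b in zip(starts, stops):
        full = fftconvolve(x[a:b], kernel[:, None], axes=0)
        out[a:b] = full[: b - a]
    return out


def simulate_bold(
    x: TaskDesign, spec: SyntheticSpec
) -> tuple[ActivityMatrix, GroundTruth]:
    """Simulate voxel BOLD from a task design: mix, smooth, drift, noise.

    The neural signal is ``X_eff @ W`` where ``X_eff`` is the design with
    the attention gain applied (presence columns scaled by
    ``attention_gain`` during attended TRs, attention scheme only) and
    ``W`` the planted weight maps. The observed signal convolves the
    design with the HRF per run before mixing, then adds sinusoidal
    low-frequency drift scaled by ``drift_amplitude`` and white Gaussian
    noise scaled to the requested SNR.
    """
    if not (spec.snr > 0):
        raise ValueError(f"snr must be positive (np.inf allowed), got {spec.snr}")
    rng = np.random.default_rng([spec.seed, 1])
    n, k = x.values.shape

    w = (
        np.asarray(spec.weight_maps, dtype=float)
        if spec.weight_maps is not None
        else _make_weight_maps(k, spec, rng)
    )
    if w.shape != (k, spec.n_voxels):
        raise ValueError(
            f"weight_maps shape {w.shape} does not match "
            f"(variables={k}, n_voxels={spec.n_voxels})"
        )

    x_eff = x.values.astype(float).copy()
    if spec.scheme == "attention" and spec.attention_gain != 1.0:
        att = x.variable_names.index("attention")
        attended = x_eff[:, att] != 0
        presence = [i for i in range(k) if i != att]
        x_eff[np.ix_(attended, presence)] *= spec.attention_gain

    neural = x_eff @ w

    if spec.hrf == "delta":
        signal = neural.copy()
    else:
        params = spec.hrf if isinstance(spec.hrf, dict) else None
        kernel = double_gamma_hrf(spec.tr_seconds, params)
        x_conv = _convolve_runs(x_eff, kernel, x.run_boundaries)
        signal = x_conv @ w

    signal_voxels = np.abs(w).sum(axis=0) > 0
    sig_var = signal[:, signal_voxels].var(axis=0).mean()

    drift = np.zeros_like(signal)
    if spec.drift_amplitude > 0:
        t = np.arange(n) * spec.tr_seconds
        amp = spec.drift_amplitude * np.sqrt(sig_var)
        for _ in range(2):
            periods = rng.uniform(500.0, 1200.0, size=spec.n_voxels)
            phases = rng.uniform(0, 2 * np.pi, size=spec.n_voxels)
            drift += amp * np.sin(
                2 * np.pi * t[:, None] / periods[None, :] + phases[None, :]
            )

    noise_sd = 0.0 if np.isinf(spec.snr) else float(np.sqrt(sig_var / spec.snr))
    noise = (
        noise_sd * rng.standard_normal(signal.shape) if noise_sd > 0 else 0.0
    )

    bold = ActivityMatrix(
        values=signal + drift + noise,
        tr_seconds=spec.tr_seconds,
        run_boundaries=x.run_boundaries,
    )
    truth = GroundTruth(
        neural=neural,
        weight_maps=w,
        drift=drift,
        noise_sd=noise_sd,
        design_effective=x_eff,
    )
    return bold, truth


def generate(spec: SyntheticSpec) -> tuple[TaskDesign, ActivityMatrix, GroundTruth]:
    """Convenience: draw a design and simulate its BOLD in one call."""
    design = make_task_design(spec)
    bold, truth = simulate_bold(design, spec)
    return design, bold, truth
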
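"""L5 ET/PV/SST spiking circuit model.

A point-neuron network of layer-5 extratelencephalic cells (L5-ET) with their
selective inhibitory partners (PV basket-like and SST Martinotti-like cells),
placed uniformly in a cylinder, driven by Poisson background and an
orientation-tuned Poisson input, and analysed for tuning sharpening and
population oscillations.

Neurons are leaky integrate-and-fire with an optional single after-spike
adaptation current (a reduced generalised LIF).  Synapses are delta-current
events (instantaneous voltage jumps) with a fixed conduction delay.
Population heterogeneity comes from a library of 40 parameter sets sampled
from per-type lognormal perturbations around documented defaults; the
parameter values, connection probabilities, weights, delays and target rates
are package configuration with defaults chosen for a stable, biologically
plausible operating point (they are not measured quantities).

The ET outgoing-connection budget is split 8% onto other ETs, 49% onto PV
and 43% onto SST in the base model; the variant parameter f in [0, 1] is the
fraction of ET connections that target the inhibitory types (PV:SST fixed at
49:43), with the total ET connection count held fixed across variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, signal, sparse

logger = logging.getLogger("l5et")

POP_TYPES = ("L5-ET", "L5-PV", "L5-SST")
FULL_COUNTS = {"L5-ET": 6523, "L5-PV": 2866, "L5-SST": 2537}
ET_BASE_SHARES = {"L5-ET": 0.08, "L5-PV": 0.49, "L5-SST": 0.43}
ET_BASE_F = ET_BASE_SHARES["L5-PV"] + ET_BASE_SHARES["L5-SST"]  # 0.92


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class GlifParams:
    tau_m: float  # ms
    resistance: float  # MOhm
    v_rest: float  # mV
    v_th: float  # mV
    v_reset: float  # mV
    t_ref: float  # ms
    asc_amp: float = 0.0  # nA added to the adaptation current at each spike
    asc_tau: float = 100.0  # ms

    def __post_init__(self):
        if self.tau_m <= 0 or self.asc_tau <= 0:
            raise ValueError("time constants must be positive")
        if self.v_th <= self.v_reset:
            raise ValueError("threshold must exceed reset")


TYPE_DEFAULTS = {
    "L5-ET": GlifParams(tau_m=12.0, resistance=200.0, v_rest=-75.0, v_th=-50.0,
                        v_reset=-65.0, t_ref=2.0, asc_amp=-0.02, asc_tau=100.0),
    "L5-PV": GlifParams(tau_m=6.0, resistance=100.0, v_rest=-72.0, v_th=-52.0,
                        v_reset=-65.0, t_ref=1.0),
    "L5-SST": GlifParams(tau_m=15.0, resistance=250.0, v_rest=-70.0, v_th=-50.0,
                         v_reset=-62.0, t_ref=2.0, asc_amp=-0.01, asc_tau=200.0),
}


@dataclass
class ConnRule:
    prob: float
    weight: float  # mV jump
    weight_sd: float = 0.0
    delay: float = 1.5  # ms


DEFAULT_RULES = {
    ("L5-PV", "L5-ET"): ConnRule(0.40, -0.60, 0.12),
    ("L5-PV", "L5-PV"): ConnRule(0.30, -0.40, 0.10),
    ("L5-PV", "L5-SST"): ConnRule(0.10, -0.30, 0.08),
    ("L5-SST", "L5-ET"): ConnRule(0.30, -0.50, 0.10),
    ("L5-SST", "L5-PV"): ConnRule(0.25, -0.30, 0.08),
    ("L5-SST", "L5-SST"): ConnRule(0.05, -0.20, 0.05),
}
ET_WEIGHTS = {"L5-ET": ConnRule(1.0, 0.50, 0.12), "L5-PV": ConnRule(1.0, 0.90, 0.20),
              "L5-SST": ConnRule(1.0, 0.90, 0.20)}


@dataclass
class CircuitSpec:
    counts: dict = field(default_factory=lambda: dict(FULL_COUNTS))
    radius: float = 650.0  # µm
    core_radius: float = 200.0  # µm
    depth_range: tuple = (-660.0, -500.0)  # µm
    n_param_sets: int = 40
    param_jitter: float = 0.12  # lognormal sigma on tau/R; mV sd on threshold
    rules: dict = field(default_factory=lambda: dict(DEFAULT_RULES))
    et_weights: dict = field(default_factory=lambda: dict(ET_WEIGHTS))
    et_out_degree: int = 60  # outgoing connections per ET cell
    delay: float = 1.5  # ms
    target_rates: dict = field(
        default_factory=lambda: {"L5-ET": 4.0, "L5-PV": 10.0, "L5-SST": 5.0}
    )

    def scaled(self, factor: float) -> "CircuitSpec":
        """Shrink population counts; the ET out-degree stays fixed so the
        recurrent loop gain is preserved at reduced scale."""
        counts = {k: max(int(round(v * factor)), 10) for k, v in self.counts.items()}
        return replace(self, counts=counts)


@dataclass
class StimulusConfig:
    duration: float = 9000.0  # ms
    dt: float = 0.5  # ms
    bg_n_units: int = 100
    bg_rate: float = 250.0  # Hz per unit
    bg_units_per_cell: int = 4
    tuned_rate: float = 1000.0  # Hz
    tuned_weight_max: float = 0.80  # mV
    tuned_sigma: float = 60.0  # degrees
    theta_target: float = 0.0  # degrees


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


@dataclass
class Network:
    spec: CircuitSpec
    f_variant: float
    types: np.ndarray  # (n,) object
    xyz: np.ndarray  # (n, 3) µm; z = depth (negative)
    core_mask: np.ndarray
    params: pd.DataFrame  # per-neuron GLIF parameters
    param_set: np.ndarray  # per-neuron library index
    param_library: list  # GlifParams per library index
    library_type: np.ndarray  # type per library index
    W: sparse.csr_matrix  # (n, n) pre x post voltage jumps (mV)
    preferred_angle: np.ndarray  # degrees, NaN for inhibitory cells
    bg_assign: np.ndarray  # (n, bg_units_per_cell) unit indices
    bg_weight: np.ndarray  # (n,) mV per background spike
    seed: int
    et_connection_count: int = 0  # drawn ET outgoing connections (f-invariant)

    @property
    def n(self) -> int:
        return len(self.types)

    def type_mask(self, t: str) -> np.ndarray:
        return self.types == t


def _sample_library(spec: CircuitSpec, rng) -> tuple[list, np.ndarray]:
    """40 parameter sets: per-type lognormal perturbations of the defaults."""
    per_type = np.full(len(POP_TYPES), spec.n_param_sets // len(POP_TYPES))
    per_type[: spec.n_param_sets % len(POP_TYPES)] += 1
    library, lib_type = [], []
    for t, n_sets in zip(POP_TYPES, per_type):
        base = TYPE_DEFAULTS[t]
        for _ in range(n_sets):
            library.append(
                GlifParams(
                    tau_m=base.tau_m * rng.lognormal(0, spec.param_jitter),
                    resistance=base.resistance * rng.lognormal(0, spec.param_jitter),
                    v_rest=base.v_rest,
                    v_th=base.v_th + rng.normal(0, 1.5),
                    v_reset=base.v_reset,
                    t_ref=base.t_ref,
                    asc_amp=base.asc_amp,
                    asc_tau=base.asc_tau,
                )
            )
            lib_type.append(t)
    return library, np.asarray(lib_type, dtype=object)


def build_circuit(
    spec: CircuitSpec,
    f_variant: float = ET_BASE_F,
    seed: int = 0,
    stimulus: StimulusConfig | None = None,
) -> Network:
    """Instantiate the network: placement, parameters, connectivity.

    Cells are placed uniformly in the cylinder at the layer-5 depth range;
    the core mask is purely geometric (radial distance < core_radius).  ET
    outgoing connections are drawn with the f-adjusted type shares; all other
    type pairs use Bernoulli connection probabilities.  Deterministic under
    (spec, f_variant, seed).
    """
    if not 0.0 <= f_variant <= 1.0:
        raise ValueError("f_variant must lie in [0, 1]")
    if stimulus is None:
        stimulus = StimulusConfig()
    rng = np.random.default_rng(seed)

    types = np.concatenate(
        [np.repeat(t, spec.counts[t]) for t in POP_TYPES]
    ).astype(object)
    n = len(types)
    r = spec.radius * np.sqrt(rng.random(n))
    phi = rng.uniform(0, 2 * np.pi, n)
    depth = rng.uniform(spec.depth_range[0], spec.depth_range[1], n)
    xyz = np.column_stack([r * np.cos(phi), r * np.sin(phi), depth])
    core_mask = r < spec.core_radius

    library, lib_type = _sample_library(spec, rng)
    param_set = np.empty(n, dtype=np.int64)
    for t in POP_TYPES:
        pool = np.nonzero(lib_type == t)[0]
        mask = types == t
        param_set[mask] = rng.choice(pool, size=int(mask.sum()))
    params = pd.DataFrame(
        [vars(library[i]) for i in param_set],
        index=np.arange(n),
    )

    # --- connectivity -------------------------------------------------------
    pre_idx, post_idx, weights = [], [], []

    # ET outgoing: fixed budget per cell, f-adjusted type shares
    shares = {
        "L5-ET": 1.0 - f_variant,
        "L5-PV": f_variant * ET_BASE_SHARES["L5-PV"] / ET_BASE_F,
        "L5-SST": f_variant * ET_BASE_SHARES["L5-SST"] / ET_BASE_F,
    }
    type_indices = {t: np.nonzero(types == t)[0] for t in POP_TYPES}
    share_vec = np.array([shares[t] for t in POP_TYPES])
    et_connection_count = 0
    for i in type_indices["L5-ET"]:
        tgt_types = rng.choice(len(POP_TYPES), size=spec.et_out_degree, p=share_vec)
        for tt in tgt_types:
            pool = type_indices[POP_TYPES[tt]]
            j = int(pool[int(rng.integers(len(pool)))])
            while j == i and len(pool) > 1:  # redraw autapses, budget stays fixed
                j = int(pool[int(rng.integers(len(pool)))])
            if j == i:
                continue
            rule = spec.et_weights[POP_TYPES[tt]]
            w = rng.normal(rule.weight, rule.weight_sd)
            pre_idx.append(i)
            post_idx.append(j)
            weights.append(max(w, 0.0))
            et_connection_count += 1

    # inhibitory-side rules: Bernoulli per pair
    for (pre_t, post_t), rule in spec.rules.items():
        pres, posts = type_indices[pre_t], type_indices[post_t]
        block = rng.random((len(pres), len(posts))) < rule.prob
        src, dst = np.nonzero(block)
        w = rng.normal(rule.weight, rule.weight_sd, size=len(src))
        w = np.minimum(w, 0.0)  # inhibitory weights stay non-positive
        pre_idx.extend(pres[src].tolist())
        post_idx.extend(posts[dst].tolist())
        weights.extend(w.tolist())

    W = sparse.csr_matrix(
        (np.asarray(weights), (np.asarray(pre_idx), np.asarray(post_idx))),
        shape=(n, n),
    )

    preferred = np.full(n, np.nan)
    et = type_indices["L5-ET"]
    preferred[et] = rng.permutation(np.linspace(0.0, 360.0, len(et), endpoint=False))

    bg_assign = rng.integers(stimulus.bg_n_units, size=(n, stimulus.bg_units_per_cell))
    bg_weight = np.full(n, 0.2)  # placeholder until optimized

    return Network(
        spec=spec, f_variant=f_variant, types=types, xyz=xyz, core_mask=core_mask,
        params=params, param_set=param_set, param_library=library,
        library_type=lib_type, W=W, preferred_angle=preferred,
        bg_assign=bg_assign, bg_weight=bg_weight, seed=seed,
        et_connection_count=et_connection_count,
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    spike_times: list  # per neuron, np.ndarray of ms
    duration: float
    core_mask: np.ndarray
    types: np.ndarray
    seed: int

    def rates(self) -> np.ndarray:
        return np.array([len(s) for s in self.spike_times]) / (self.duration / 1000.0)


def lif_rate_closed_form(params: GlifParams, current_nA: float) -> float:
    """Steady firing rate of a LIF neuron under constant current (Hz).

    r = 1000 / (t_ref + tau * ln((RI - (v_reset - v_rest)) / (RI - (v_th - v_rest))))
    for RI > v_th - v_rest, else 0; reduces to the textbook
    1/(t_ref + tau ln(RI/(RI - theta))) when the reset equals rest.
    (No adaptation.)
    """
    drive = params.resistance * current_nA
    gap_th = params.v_th - params.v_rest
    gap_reset = params.v_reset - params.v_rest
    if drive <= gap_th:
        return 0.0
    isi = params.t_ref + params.tau_m * np.log(
        (drive - gap_reset) / (drive - gap_th)
    )
    return 1000.0 / isi


def wrap_angle(delta) -> np.ndarray:
    """Wrap angular differences to (-180, 180] degrees."""
    return -(np.mod(-(np.asarray(delta, dtype=float)) + 180.0, 360.0) - 180.0)


def run_simulation(
    network: Network,
    stimulus: StimulusConfig,
    seed: int = 0,
    recurrence: bool = True,
    constant_current: np.ndarray | None = None,
    background: bool = True,
    tuned: bool = True,
) -> SimResult:
    """Fixed-step exact-exponential-update integration of the network.

    Poisson inputs come from seeded streams; the recurrence toggle leaves the
    network untouched but silences recurrent propagation.  With
    ``constant_current`` (nA per neuron), a deterministic drive is injected
    (used by the closed-form-rate cross-check).
    """
    rng = np.random.default_rng(seed)
    n = network.n
    dt = stimulus.dt
    n_steps = int(round(stimulus.duration / dt))

    p = network.params
    tau = p["tau_m"].to_numpy()
    R = p["resistance"].to_numpy()
    v_rest = p["v_rest"].to_numpy()
    v_th = p["v_th"].to_numpy()
    v_reset = p["v_reset"].to_numpy()
    ref_steps = np.maximum(np.round(p["t_ref"].to_numpy() / dt), 1).astype(np.int64)
    asc_amp = p["asc_amp"].to_numpy()
    asc_tau = p["asc_tau"].to_numpy()

    decay = np.exp(-dt / tau)
    gain = 1.0 - decay  # fraction of steady-state reached per step
    asc_decay = np.exp(-dt / asc_tau)
    I_const = np.zeros(n) if constant_current is None else np.asarray(constant_current)

    g = np.zeros(n)
    if tuned:
        rel = wrap_angle(network.preferred_angle - stimulus.theta_target)
        with np.errstate(invalid="ignore"):
            g = stimulus.tuned_weight_max * np.exp(
                -(rel**2) / (2 * stimulus.tuned_sigma**2)
            )
        g = np.nan_to_num(g)

    delay_steps = max(int(round(network.spec.delay / dt)), 1)
    pending = np.zeros((delay_steps, n))
    W = network.W if recurrence else None

    bg_p = stimulus.bg_rate * dt / 1000.0
    tuned_p = stimulus.tuned_rate * dt / 1000.0

    V = v_rest.copy()
    A = np.zeros(n)
    ref = np.zeros(n, dtype=np.int64)
    spikes: list[list[float]] = [[] for _ in range(n)]

    for t in range(n_steps):
        V = v_rest + (V - v_rest) * decay + gain * R * (I_const + A)
        A *= asc_decay
        inp = pending[t % delay_steps]
        if background:
            bg_counts = rng.poisson(bg_p, size=stimulus.bg_n_units)
            inp = inp + bg_counts[network.bg_assign].sum(axis=1) * network.bg_weight
        if tuned:
            k = rng.poisson(tuned_p)
            if k:
                inp = inp + g * k
        active = ref == 0
        V[active] += inp[active]
        pending[t % delay_steps] = 0.0

        fired = active & (V >= v_th)
        if fired.any():
            idx = np.nonzero(fired)[0]
            t_ms = (t + 1) * dt
            for i in idx:
                spikes[i].append(t_ms)
            V[idx] = v_reset[idx]
            A[idx] += asc_amp[idx]
            ref[idx] = ref_steps[idx]
            if W is not None:
                out = np.asarray(W[idx].sum(axis=0)).ravel()
                pending[(t + delay_steps) % delay_steps] += out
        in_ref = ref > 0
        V[in_ref] = v_reset[in_ref]
        ref[in_ref] -= 1

    return SimResult(
        spike_times=[np.asarray(s) for s in spikes],
        duration=stimulus.duration,
        core_mask=network.core_mask,
        types=network.types,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Background-weight optimization
# ---------------------------------------------------------------------------


class OptimizationError(RuntimeError):
    pass


def _single_set_rate(params: GlifParams, weight: float, stimulus: StimulusConfig,
                     seed: int, duration: float) -> float:
    """Rate of one parameter set under background input only (no recurrence)."""
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / stimulus.dt))
    bg_p = stimulus.bg_rate * stimulus.dt / 1000.0
    decay = np.exp(-stimulus.dt / params.tau_m)
    gain = 1.0 - decay
    ref_steps = max(int(round(params.t_ref / stimulus.dt)), 1)
    V, A, ref, count = params.v_rest, 0.0, 0, 0
    asc_decay = np.exp(-stimulus.dt / params.asc_tau)
    for _ in range(n_steps):
        V = params.v_rest + (V - params.v_rest) * decay \
            + gain * params.resistance * A
        A *= asc_decay
        if ref == 0:
            k = rng.poisson(bg_p * stimulus.bg_units_per_cell)
            V += k * weight
            if V >= params.v_th:
                count += 1
                V = params.v_reset
                A += params.asc_amp
                ref = ref_steps
        else:
            V = params.v_reset
            ref -= 1
    return count / (duration / 1000.0)


def optimize_background_weights(
    network: Network,
    stimulus: StimulusConfig,
    tol_single: float = 0.05,
    tol_network: float = 0.10,
    max_iter: int = 60,
    seed: int = 0,
    single_duration: float = 3000.0,
    network_duration: float = 2000.0,
) -> dict:
    """Two-step background-weight calibration.

    Step 1: per parameter set, bisection on the background weight with
    recurrence disabled until the rate is within ``tol_single`` of the type's
    target.  Step 2: with recurrence enabled, multiplicative 5% updates on
    the type whose mean rate deviates most, until all types are within
    ``tol_network``.  Returns the per-cell weights and a convergence log;
    raises OptimizationError if ``max_iter`` is exceeded.
    """
    targets = network.spec.target_rates
    lib = network.param_library
    lib_type = network.library_type
    set_weight = np.zeros(len(lib))
    log: list = []
    for k, (params, t) in enumerate(zip(lib, lib_type)):
        target = targets[t]
        lo, hi = 0.0, 0.5
        while _single_set_rate(params, hi, stimulus, seed + k, single_duration) < target:
            hi *= 2.0
            if hi > 64.0:
                raise OptimizationError(f"target rate {target} Hz unreachable "
                                        f"for parameter set {k}")
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            rate = _single_set_rate(params, mid, stimulus, seed + k, single_duration)
            if abs(rate - target) <= tol_single * target:
                break
            if rate < target:
                lo = mid
            else:
                hi = mid
        else:
            mid = 0.5 * (lo + hi)
        set_weight[k] = mid
        log.append(("step1", k, t, float(mid)))

    weights = set_weight[network.param_set].copy()
    scale = {t: 1.0 for t in POP_TYPES}
    step_size = {t: 0.05 for t in POP_TYPES}
    last_dev = {t: 0.0 for t in POP_TYPES}
    sim_stim = replace(stimulus, duration=network_duration)
    transient = min(500.0, network_duration / 4)
    for it in range(max_iter):
        network.bg_weight = weights * np.array([scale[t] for t in network.types])
        # fixed noise realization across iterations: a deterministic landscape
        res = run_simulation(network, sim_stim, seed=seed + 1000,
                             recurrence=True, tuned=False)
        span = (network_duration - transient) / 1000.0
        rates = np.array(
            [np.sum(s >= transient) / span for s in res.spike_times]
        )
        dev = {}
        for t in POP_TYPES:
            mask = network.type_mask(t)
            dev[t] = (rates[mask].mean() - targets[t]) / targets[t]
        log.append(("step2", it, {t: float(d) for t, d in dev.items()}))
        worst = max(dev, key=lambda t: abs(dev[t]))
        if all(abs(d) <= tol_network for d in dev.values()):
            return {"weights": network.bg_weight.copy(), "log": log,
                    "n_iterations": it, "converged": True}
        # 5% multiplicative update; the step is damped near the target and
        # halved whenever the deviation changes sign (limit-cycle guard)
        if last_dev[worst] * dev[worst] < 0:
            step_size[worst] /= 2.0
        last_dev[worst] = dev[worst]
        step = min(step_size[worst], abs(dev[worst]) / 2.0)
        scale[worst] *= (1.0 - step) if dev[worst] > 0 else (1.0 + step)
    raise OptimizationError(f"no convergence in {max_iter} iterations; log={log[-3:]}")


# ---------------------------------------------------------------------------
# Tuning-curve fit
# ---------------------------------------------------------------------------


@dataclass
class TuningFit:
    bin_centers: np.ndarray
    bin_rates: np.ndarray
    amplitude: float | None
    center: float | None
    sigma: float | None
    baseline: float | None
    residual: float | None
    converged: bool


def _gauss(x, a, c, s, b):
    return a * np.exp(-((x - c) ** 2) / (2 * s**2)) + b


def fit_tuning_curve(
    result: SimResult,
    preferred_angles: np.ndarray,
    theta_target: float,
    bin_width: float = 10.0,
) -> TuningFit:
    """Gaussian fit of core-ET mean rate vs preferred-angle-minus-target.

    Relative angles are wrapped to (-180, 180] and binned at ``bin_width``
    degrees; a Gaussian with baseline is fitted by least squares.
    """
    mask = (result.types == "L5-ET") & result.core_mask
    rates = result.rates()[mask]
    rel = wrap_angle(np.asarray(preferred_angles)[mask] - theta_target)
    edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.digitize(rel, edges) - 1
    idx = np.clip(idx, 0, len(centers) - 1)
    sums = np.bincount(idx, weights=rates, minlength=len(centers))
    counts = np.bincount(idx, minlength=len(centers))
    with np.errstate(invalid="ignore"):
        bin_rates = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    ok = np.isfinite(bin_rates)
    x, y, w = centers[ok], bin_rates[ok], counts[ok]
    if len(x) < 5 or np.ptp(y) <= 1e-12:
        return TuningFit(centers, bin_rates, None, None, None,
                         float(np.nanmean(bin_rates)) if np.isfinite(bin_rates).any()
                         else None, None, False)
    p0 = [max(y.max() - y.min(), 1e-6), 0.0, 60.0, max(y.min(), 0.0)]
    try:
        # bins holding more cells have lower-variance means; weight accordingly
        popt, _ = optimize.curve_fit(
            _gauss, x, y, p0=p0, sigma=1.0 / np.sqrt(w),
            bounds=([0, -180, 5, 0], [np.inf, 180, 200, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return TuningFit(centers, bin_rates, None, None, None, None, None, False)
    resid = float(np.sum((y - _gauss(x, *popt)) ** 2))
    return TuningFit(centers, bin_rates, float(popt[0]), float(popt[1]),
                     float(abs(popt[2])), float(popt[3]), resid, True)


# ---------------------------------------------------------------------------
# Population power spectrum
# ---------------------------------------------------------------------------


@dataclass
class SpectrumResult:
    frequencies: np.ndarray
    power: np.ndarray
    peak_frequency: float | None
    peak_fwhm: float | None
    flat: bool


def population_power_spectrum(
    result: SimResult,
    count_window: float = 2.5,  # ms
    segment: float = 500.0,  # ms -> 2 Hz resolution
    min_freq: float = 4.0,
) -> SpectrumResult:
    """Welch spectrum of the core-ET population spike count.

    Spike counts in ``count_window`` bins, Welch with ``segment``-long
    segments and 50% overlap; the peak is the argmax above ``min_freq`` and
    its FWHM comes from half-maximum crossing interpolation.
    """
    mask = (result.types == "L5-ET") & result.core_mask
    nonempty = [s for s, m in zip(result.spike_times, mask) if m and len(s)]
    all_spikes = np.concatenate(nonempty) if nonempty else np.array([])
    n_bins = int(round(result.duration / count_window))
    counts, _ = np.histogram(all_spikes, bins=n_bins, range=(0, result.duration))
    if counts.sum() == 0:
        return SpectrumResult(np.array([]), np.array([]), None, None, True)
    fs = 1000.0 / count_window
    nperseg = int(round(segment / count_window))
    freqs, power = signal.welch(
        counts - counts.mean(), fs=fs, nperseg=nperseg, noverlap=nperseg // 2
    )
    band = freqs >= min_freq
    if not band.any() or power[band].max() <= 0:
        return SpectrumResult(freqs, power, None, None, True)
    peak_idx = np.nonzero(band)[0][np.argmax(power[band])]
    widths = signal.peak_widths(power, [peak_idx], rel_height=0.5)
    fwhm = float(widths[0][0] * (freqs[1] - freqs[0]))
    return SpectrumResult(
        frequencies=freqs, power=power,
        peak_frequency=float(freqs[peak_idx]), peak_fwhm=fwhm, flat=False,
    )


# ---------------------------------------------------------------------------
# Angle sweep
# ---------------------------------------------------------------------------


def angle_sweep(
    network: Network,
    stimulus: StimulusConfig,
    angles: np.ndarray | None = None,
    seed: int = 0,
    with_spectra: bool = False,
) -> dict:
    """Run tuned simulations across target angles, with and without recurrence.

    Returns per-angle Gaussian widths for both conditions, the per-angle
    width difference (with minus without), its mean +/- s.e.m., and
    optionally the spectral peaks.  Angles with a failed fit in either
    condition are flagged and excluded from the means.
    """
    if angles is None:
        angles = np.arange(0.0, 360.0, 15.0)
    rows = []
    for k, ang in enumerate(angles):
        stim = replace(stimulus, theta_target=float(ang))
        rec = {}
        for cond, use_rec in (("with", True), ("without", False)):
            res = run_simulation(network, stim, seed=seed + 37 * k,
                                 recurrence=use_rec)
            fit = fit_tuning_curve(res, network.preferred_angle, float(ang))
            rec[cond] = fit
            if with_spectra:
                rec[f"spectrum_{cond}"] = population_power_spectrum(res)
        row = {
            "angle": float(ang),
            "sigma_with": rec["with"].sigma,
            "sigma_without": rec["without"].sigma,
            "ok": rec["with"].converged and rec["without"].converged,
        }
        if with_spectra:
            row["peak_with"] = rec["spectrum_with"].peak_frequency
            row["peak_without"] = rec["spectrum_without"].peak_frequency
            row["fwhm_with"] = rec["spectrum_with"].peak_fwhm
        if not row["ok"]:
            logger.warning("angle %.0f: tuning fit failed; excluded", ang)
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[table["ok"]]
    delta = (ok["sigma_with"] - ok["sigma_without"]).to_numpy(dtype=float)
    return {
        "table": table,
        "delta_sigma": delta,
        "delta_sigma_mean": float(delta.mean()) if len(delta) else np.nan,
        "delta_sigma_sem": float(delta.std(ddof=1) / np.sqrt(len(delta)))
        if len(delta) > 1 else np.nan,
    }
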
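"""Flux estimation from corrected isotopologue measurements.

Minimizes the variance-weighted sum of squared residuals

    SSR = sum_fragments sum_i ((CID_sim,i - CID_meas,i) / SD_i)^2

over the free net fluxes and exchange coordinates, subject to S v = 0, fixed
measured rates (uptake, secretion, growth), and flux bounds.  Net fluxes are
parameterized on a null-space basis of the constrained stoichiometry; each
reversible reaction gets an exchange coordinate x in [0, 1) mapped to an
exchange flux x / (1 - x), keeping the optimizer box-bounded.  Nonnegativity
of dependent irreversible fluxes is enforced by penalty residuals.  The
optimizer is bounded trust-region least squares with seeded multi-start.

Confidence intervals use a Monte-Carlo resampling of the measured CIDs at
their standard deviations (perturbed distributions are clipped at zero and
renormalized), refitting each sample from the point estimate and taking
percentile intervals.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg
import scipy.optimize

from .emu import EmuNetwork, TracerSpec, emu_decompose, simulate_mdv
from .network import FluxVector, ReactionNetwork, sample_feasible_flux

SD_FLOOR = 0.001          # fraction scale; 0.1 percentage points
_PENALTY = 1e4
_EXCH_MAX = 0.95


@dataclasses.dataclass
class CIDMeasurement:
    """Corrected carbon-backbone CID of one metabolite (fractions, not %)."""

    metabolite: str
    cid: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.cid = np.asarray(self.cid, dtype=float)
        self.sd = np.maximum(np.asarray(self.sd, dtype=float), SD_FLOOR)
        if len(self.cid) != len(self.sd):
            raise ValueError(f"{self.metabolite}: CID/SD length mismatch")


@dataclasses.dataclass
class FitResult:
    flux: FluxVector
    ssr: float
    n_restarts: int
    converged: bool
    residuals: dict[str, np.ndarray]
    theta: np.ndarray               # internal optimizer coordinates


@dataclasses.dataclass
class ConfidenceIntervals:
    reaction_ids: list[str]
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_samples: int

    def interval(self, rid: str) -> tuple[float, float]:
        i = self.reaction_ids.index(rid)
        return float(self.lower[i]), float(self.upper[i])


class _FluxParameterization:
    """Net fluxes as v = v0 + N a with S v = 0 and fixed rates built in."""

    def __init__(self, net: ReactionNetwork, constraints: dict[str, float]):
        self.net = net
        S = net.stoich_matrix().to_numpy()
        n = S.shape[1]
        rows = [S]
        rhs = [np.zeros(S.shape[0])]
        for rid, value in constraints.items():
            e = np.zeros(n)
            e[net.reaction_index[rid]] = 1.0
            rows.append(e[None, :])
            rhs.append(np.array([value]))
        A = np.vstack(rows)
        b = np.concatenate(rhs)
        self.v0, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ self.v0 - b)) > 1e-8:
            raise ValueError("constraints inconsistent with S v = 0")
        self.N = scipy.linalg.null_space(A)
        self.n_free = self.N.shape[1]
        self.reversible_idx = [i for i, r in enumerate(net.reactions)
                               if r.reversible]
        self.irreversible_idx = [i for i, r in enumerate(net.reactions)
                                 if not r.reversible]

    def flux(self, theta: np.ndarray) -> FluxVector:
        alpha = theta[:self.n_free]
        x = theta[self.n_free:]
        v = self.v0 + (self.N @ alpha if self.n_free else 0.0)
        exch = np.zeros(len(self.net.reactions))
        for k, i in enumerate(self.reversible_idx):
            exch[i] = x[k] / (1.0 - x[k])
        return FluxVector([r.id for r in self.net.reactions], v, exch)

    def theta_from_flux(self, v: FluxVector) -> np.ndarray:
        alpha = (self.N.T @ (v.net - self.v0)) if self.n_free else np.empty(0)
        x = np.array([v.exchange[i] / (1.0 + v.exchange[i])
                      for i in self.reversible_idx])
        return np.concatenate([alpha, np.clip(x, 0.0, _EXCH_MAX)])

    @property
    def n_params(self) -> int:
        return self.n_free + len(self.reversible_idx)

    def bounds(self, alpha_bound: float = 50.0) -> tuple[np.ndarray, np.ndarray]:
        lo = np.concatenate([np.full(self.n_free, -alpha_bound),
                             np.zeros(len(self.reversible_idx))])
        hi = np.concatenate([np.full(self.n_free, alpha_bound),
                             np.full(len(self.reversible_idx), _EXCH_MAX)])
        return lo, hi


def _residual_fn(param: _FluxParameterization, emu_net: EmuNetwork,
                 tracers, measurements: list[CIDMeasurement],
                 natural: float, dilution: float):
    net = param.net
    targets = [m.metabolite for m in measurements]

    def fn(theta: np.ndarray) -> np.ndarray:
        v = param.flux(theta)
        penalties = np.maximum(-v.net[param.irreversible_idx], 0.0) * _PENALTY
        try:
            mdvs = simulate_mdv(net, v, tracers, targets,
                                natural=natural, emu_net=emu_net,
                                dilution=dilution)
        except ValueError:
            # infeasible labeling state (e.g. negative irreversible flux made
            # a pool unreachable): large constant residual + penalties steer
            # the optimizer back
            total = sum(len(m.cid) for m in measurements)
            return np.concatenate([np.full(total, 1e3), penalties])
        res = [(mdvs[m.metabolite][:len(m.cid)] - m.cid) / m.sd
               for m in measurements]
        return np.concatenate(res + [penalties])

    return fn


def fit_fluxes(net: ReactionNetwork, measurements: list[CIDMeasurement],
               tracers: TracerSpec | list[TracerSpec],
               constraints: dict[str, float],
               n_restarts: int = 10, rng_seed: int = 0,
               natural: float = 0.0107, dilution: float = 1e-8,
               x0: FluxVector | None = None) -> FitResult:
    """Best-SSR flux fit over seeded multi-start bounded least squares.

    ``constraints`` fixes measured rates (at minimum the substrate uptake,
    which normalizes all fluxes).  ``x0`` optionally adds a caller-supplied
    starting point to the restart list (used by the Monte-Carlo resampler).
    """
    if not measurements:
        raise ValueError("no measurements supplied")
    param = _FluxParameterization(net, constraints)
    targets = [m.metabolite for m in measurements]
    emu_net = emu_decompose(net, targets)
    fn = _residual_fn(param, emu_net, tracers, measurements, natural, dilution)
    lo, hi = param.bounds()
    rng = np.random.default_rng(rng_seed)
    starts: list[np.ndarray] = []
    if x0 is not None:
        starts.append(param.theta_from_flux(x0))
    attempts = 0
    while len(starts) < n_restarts + (x0 is not None) and attempts < 10 * n_restarts:
        attempts += 1
        try:
            # cap at a moderate multiple of the constrained rates so random
            # start vertices stay on a physiological flux scale
            cap = 5.0 * max(1.0, max((abs(x) for x in constraints.values()),
                                     default=1.0))
            v_start = sample_feasible_flux(
                net, constraints=constraints, flux_cap=cap,
                rng_seed=int(rng.integers(2 ** 31)))
        except ValueError:
            continue
        theta = param.theta_from_flux(v_start)
        theta[param.n_free:] = rng.uniform(0.05, 0.6,
                                           len(param.reversible_idx))
        starts.append(np.clip(theta, lo, hi))
    if not starts:
        raise ValueError("no feasible starting point under the constraints")
    # two-stage search: a coarser dilution smooths the near-zero-flux region
    # for the global multi-start, then one polish run at the target dilution
    coarse = max(dilution, 1e-6)
    fn_coarse = (fn if coarse == dilution else _residual_fn(
        param, emu_net, tracers, measurements, natural, coarse))
    best = None
    for theta0 in starts:
        sol = scipy.optimize.least_squares(fn_coarse, theta0, bounds=(lo, hi),
                                           method="trf", xtol=1e-12,
                                           ftol=1e-12, gtol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    if fn_coarse is not fn:
        best = scipy.optimize.least_squares(fn, best.x, bounds=(lo, hi),
                                            method="trf", xtol=1e-12,
                                            ftol=1e-12, gtol=1e-12,
                                            max_nfev=40 * param.n_params)
    v_fit = param.flux(best.x)
    mdvs = simulate_mdv(net, v_fit, tracers, targets, natural=natural,
                        emu_net=emu_net, dilution=dilution)
    residuals = {m.metabolite: (mdvs[m.metabolite][:len(m.cid)] - m.cid) / m.sd
                 for m in measurements}
    ssr = float(sum(np.sum(r ** 2) for r in residuals.values()))
    return FitResult(v_fit, ssr, len(starts), bool(best.success),
                     residuals, best.x)


def perturb_measurements(measurements: list[CIDMeasurement],
                         rng: np.random.Generator) -> list[CIDMeasurement]:
    """Gaussian perturbation at the stated SDs, clipped at 0 and renormalized."""
    out = []
    for m in measurements:
        noisy = np.clip(m.cid + rng.normal(0.0, m.sd), 0.0, None)
        total = noisy.sum()
        if total <= 0:
            noisy = m.cid.copy()
            total = noisy.sum()
        out.append(CIDMeasurement(m.metabolite, noisy / total, m.sd))
    return out


def monte_carlo_ci(net: ReactionNetwork, measurements: list[CIDMeasurement],
                   tracers: TracerSpec | list[TracerSpec],
                   constraints: dict[str, float], fit: FitResult,
                   n_samples: int = 1000, level: float = 0.95,
                   rng_seed: int = 0, natural: float = 0.0107,
                   dilution: float = 1e-8) -> ConfidenceIntervals:
    """Percentile confidence intervals from Monte-Carlo measurement resampling."""
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    if not fit.converged:
        raise ValueError("point fit did not converge")
    rng = np.random.default_rng(rng_seed)
    draws = []
    failures = 0
    for _ in range(n_samples):
        perturbed = perturb_measurements(measurements, rng)
        try:
            refit = fit_fluxes(net, perturbed, tracers, constraints,
                               n_restarts=0, rng_seed=int(rng.integers(2 ** 31)),
                               natural=natural, dilution=dilution, x0=fit.flux)
            draws.append(refit.flux.net)
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
    if failures > 0.2 * n_samples:
        raise RuntimeError(f"{failures}/{n_samples} Monte-Carlo refits failed")
    draws_arr = np.array(draws)
    alpha = (1.0 - level) / 2.0
    lower = np.percentile(draws_arr, 100 * alpha, axis=0)
    upper = np.percentile(draws_arr, 100 * (1 - alpha), axis=0)
    return ConfidenceIntervals([r.id for r in net.reactions], lower, upper,
                               level, n_samples - failures)
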
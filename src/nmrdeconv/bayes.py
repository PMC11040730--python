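"""Joint Bayesian model of a mixture spectrum and the prune-and-refit loop.

The observed spectrum, broadened and normalised to unit area, is treated as a
probability density.  Latent variables are one non-negative weight per
candidate compound (Half-Cauchy prior), one chemical shift per resonance
(Normal prior centred on the predicted shift with the method-dependent
sigma), and a global noise scale (Half-Cauchy); the likelihood is i.i.d.
Gaussian over grid points between the observed density and the normalised
model density.  The posterior is sampled with the in-package No-U-Turn
sampler using analytic gradients; J-couplings and linewidths are held fixed.

Deconvolution iterates: fit, remove candidates whose geometric-mean
concentration falls below a cutoff, refit, until the surviving set is stable.
If any surviving resonance retains a shift-posterior spread larger than twice
its prior sigma, one extra iteration runs with shift priors widened to three
times the base sigma (e.g. 0.3 ppm for DFT-quality predictions).  In interval
mode, entropy-ranked spectral intervals are fit first — each interval fit
estimates absolute spectral shares of the compounds predicted to resonate
there, pruning between intervals — followed by a final global fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import compositional
from ._kernel import loglik_and_grads
from .lineshape import (
    CompoundSpectrum,
    Spectrum,
    expand_multiplet,
    gaussian_apodize,
    normalize_density,
)
from .sampler import nuts_sample
from .segmentation import SpectralInterval, build_intervals, rank_intervals

__all__ = [
    "PriorConfig",
    "SamplerConfig",
    "FitResult",
    "NoSurvivorsError",
    "build_joint_model",
    "sample_posterior",
    "prune_candidates",
    "deconvolute",
]

logger = logging.getLogger(__name__)

#: Widening heuristic: trigger when posterior shift sd exceeds this multiple
#: of the prior sd, and rerun with priors at WIDEN_FACTOR times the base sd.
WIDEN_TRIGGER = 2.0
WIDEN_FACTOR = 3.0

#: Half width (ppm) of the per-line evaluation window in the likelihood.
LINE_WINDOW_PPM = 0.3


class NoSurvivorsError(RuntimeError):
    """Raised when every candidate falls below the concentration cutoff."""


@dataclass
class PriorConfig:
    """Hyper-parameters of the joint model.

    ``weight_scale`` is the Half-Cauchy scale of the component weights;
    ``noise_scale`` the Half-Cauchy scale of the likelihood noise sd; the
    per-compound shift sigma comes from each :class:`CompoundSpectrum` and is
    multiplied by ``shift_sigma_scale`` (used by the widening heuristic).
    ``truncate_sd``, if set, truncates each shift prior at +/- that many base
    sigmas around the prediction.
    """

    weight_scale: float = 1.0
    noise_scale: float = 0.05
    shift_sigma_scale: float = 1.0
    truncate_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.weight_scale <= 0 or self.noise_scale <= 0 or self.shift_sigma_scale <= 0:
            raise ValueError("prior scales must be positive")


@dataclass
class SamplerConfig:
    """NUTS run configuration (defaults follow the full-length procedure)."""

    warmup: int = 1000
    samples: int = 3000
    seed: int = 0
    broaden_fwhm_hz: float = 10.0
    max_depth: int = 8
    target_accept: float = 0.8
    fit_grid_points: int = 2048

    def __post_init__(self) -> None:
        if self.warmup < 1 or self.samples < 1:
            raise ValueError("warmup and samples must be >= 1")
        if self.broaden_fwhm_hz <= 0:
            raise ValueError("broaden_fwhm_hz must be > 0")


@dataclass
class FitResult:
    """Posterior summary of one HMC fit (optionally of a full deconvolution)."""

    names: list[str]
    library: list[CompoundSpectrum]
    weight_samples: np.ndarray  # (n_samples, n_compounds), raw positive weights
    shift_samples: np.ndarray  # (n_samples, n_resonances), ppm
    center: np.ndarray  # geometric-mean center of closed weight draws
    shift_posterior_mean: np.ndarray
    shift_posterior_sd: np.ndarray
    res_compound: np.ndarray  # compound index of each resonance
    res_prior_mean: np.ndarray
    res_prior_sd: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    # populated by deconvolute():
    present: Optional[np.ndarray] = None  # over the original candidate order
    library_names: Optional[list[str]] = None
    center_full: Optional[np.ndarray] = None  # zeros for pruned candidates
    history: list = field(default_factory=list)
    converged: bool = True
    intervals: Optional[list[SpectralInterval]] = None

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        """Equal-tailed credible interval of the closed weight draws."""
        closed = self.weight_samples / self.weight_samples.sum(axis=1, keepdims=True)
        tail = 100.0 * (1.0 - level) / 2.0
        return np.percentile(closed, [tail, 100.0 - tail], axis=0)


class MixtureModel:
    """Static arrays + log-posterior callable for one fit."""

    def __init__(
        self,
        library: list[CompoundSpectrum],
        observed: Spectrum,
        priors: PriorConfig,
        normalized: bool = True,
        restrict: Optional[tuple[float, float]] = None,
        broaden_fwhm_hz: float = 10.0,
    ):
        if not library:
            raise ValueError("model requires at least one candidate")
        dx = np.diff(observed.grid)
        if not np.allclose(dx, dx[0], rtol=1e-8):
            raise ValueError("grid mismatch: observed spectrum must be on a uniform grid")
        self.library = library
        self.observed = observed
        self.priors = priors
        self.normalized = normalized
        mhz = observed.spectrometer_mhz

        res_pred, res_sd, res_comp = [], [], []
        line_res, line_comp, line_off, line_amp = [], [], [], []
        gamma = []
        comp_area = np.zeros(len(library))
        for ci, comp in enumerate(library):
            total = comp.total_weight
            if total <= 0:
                raise ValueError(f"compound {comp.name!r} has zero total weight")
            comp_area[ci] = total
            for res in comp.resonances:
                if res.weight == 0.0:
                    continue
                if restrict is not None and not (restrict[0] <= res.shift <= restrict[1]):
                    continue
                ri = len(res_pred)
                res_pred.append(res.shift)
                res_sd.append(comp.shift_sigma * priors.shift_sigma_scale)
                res_comp.append(ci)
                for off, rel in expand_multiplet(res, mhz):
                    line_res.append(ri)
                    line_comp.append(ci)
                    line_off.append(off)
                    amp = res.weight * rel
                    if not normalized:
                        amp /= total  # absolute-share parametrisation
                    line_amp.append(amp)
                    gamma.append(0.5 * res.lorentz_fwhm / mhz)
        if not res_pred:
            raise ValueError("no resonances fall inside the model region")

        self.res_pred = np.asarray(res_pred)
        self.res_sd = np.asarray(res_sd)
        self.res_comp = np.asarray(res_comp, dtype=np.int64)
        self.line_res = np.asarray(line_res, dtype=np.int64)
        self.line_comp = np.asarray(line_comp, dtype=np.int64)
        self.line_off = np.asarray(line_off)
        self.line_amp = np.asarray(line_amp)
        self.gamma = np.asarray(gamma)
        self.comp_area = comp_area if normalized else np.zeros_like(comp_area)
        fwhm_g_ppm = broaden_fwhm_hz / mhz
        self.sig_g = fwhm_g_ppm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        self.x0 = float(observed.grid[0])
        self.dx = float(dx[0])
        self.y = observed.intensity
        self.K = int(min(2 * LINE_WINDOW_PPM / self.dx, observed.grid.size))
        self.n_compounds = len(library)
        self.n_resonances = self.res_pred.size
        self.dim = self.n_compounds + self.n_resonances + 1
        b = priors.truncate_sd
        self._bound = None if b is None else b * self.res_sd / priors.shift_sigma_scale

    # ---- parameter packing: theta = [u (log w), z (shifts), v (log sigma)] ----

    def initial_point(self) -> np.ndarray:
        theta = np.empty(self.dim)
        theta[: self.n_compounds] = math.log(1.0 / self.n_compounds)
        theta[self.n_compounds : -1] = 0.0 if self._bound is not None else self.res_pred
        theta[-1] = math.log(0.1)
        return theta

    def shifts_from(self, z: np.ndarray) -> np.ndarray:
        if self._bound is None:
            return z
        return self.res_pred + self._bound * np.tanh(z / self._bound)

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        nc, nr = self.n_compounds, self.n_resonances
        u = theta[:nc]
        z = theta[nc : nc + nr]
        v = theta[-1]
        if self._bound is None:
            delta = z
            jac = None
        else:
            t = np.tanh(z / self._bound)
            delta = self.res_pred + self._bound * t
            jac = 1.0 - t * t  # d delta / d z

        ll, gu, gd, gv = loglik_and_grads(
            u, delta, v,
            self.line_res, self.line_comp, self.line_off, self.line_amp,
            self.comp_area if self.normalized else np.zeros(nc),
            self.gamma, self.sig_g, self.x0, self.dx, self.y, self.K,
        )

        lp = ll
        grad = np.empty_like(theta)
        # Half-Cauchy prior on w = e^u (with log-Jacobian u); exponents are
        # clamped so extreme probe points (step-size search) stay finite
        w2 = np.exp(np.minimum(2.0 * (u - math.log(self.priors.weight_scale)), 700.0))
        lp += float(np.sum(u - np.log1p(w2)))
        grad[:nc] = gu + 1.0 - 2.0 * w2 / (1.0 + w2)
        # Normal prior on shifts (truncation handled by the z transform)
        dev = (delta - self.res_pred) / self.res_sd
        lp += float(np.sum(-0.5 * dev * dev - np.log(self.res_sd)))
        gdelta = gd - dev / self.res_sd
        if jac is None:
            grad[nc : nc + nr] = gdelta
        else:
            # change of variables delta = g(z) adds log|g'(z)| = log(1 - tanh^2)
            lp += float(np.sum(np.log(jac)))
            t = np.tanh(z / self._bound)
            grad[nc : nc + nr] = gdelta * jac - 2.0 * t / self._bound
        # Half-Cauchy prior on sigma = e^v
        s2 = math.exp(min(2.0 * (v - math.log(self.priors.noise_scale)), 700.0))
        lp += v - math.log1p(s2)
        grad[-1] = gv + 1.0 - 2.0 * s2 / (1.0 + s2)
        return lp, grad


def build_joint_model(
    library: list[CompoundSpectrum],
    observed: Spectrum,
    priors: PriorConfig | None = None,
    broaden_fwhm_hz: float = 10.0,
) -> MixtureModel:
    """Joint model over weights and shifts for a broadened, unit-area spectrum."""
    return MixtureModel(
        library, observed, priors or PriorConfig(), broaden_fwhm_hz=broaden_fwhm_hz
    )


def sample_posterior(model: MixtureModel, cfg: SamplerConfig) -> FitResult:
    """Run NUTS on the joint model and summarise the posterior."""
    rng = np.random.default_rng(cfg.seed)
    res = nuts_sample(
        model.logp_grad,
        model.initial_point(),
        n_warmup=cfg.warmup,
        n_samples=cfg.samples,
        rng=rng,
        max_depth=cfg.max_depth,
        target_accept=cfg.target_accept,
    )
    if np.isnan(res.samples).all():
        raise RuntimeError("sampler produced all-NaN draws")
    frac_div = res.divergences / max(cfg.samples, 1)
    if frac_div > 0.10:
        logger.warning("%.0f%% divergent transitions", 100 * frac_div)

    nc, nr = model.n_compounds, model.n_resonances
    weight_samples = np.exp(res.samples[:, :nc])
    shift_samples = model.shifts_from(res.samples[:, nc : nc + nr])
    ctr = compositional.center(weight_samples)
    return FitResult(
        names=[c.name for c in model.library],
        library=list(model.library),
        weight_samples=weight_samples,
        shift_samples=shift_samples,
        center=ctr,
        shift_posterior_mean=shift_samples.mean(axis=0),
        shift_posterior_sd=shift_samples.std(axis=0),
        res_compound=model.res_comp.copy(),
        res_prior_mean=model.res_pred.copy(),
        res_prior_sd=model.res_sd.copy(),
        diagnostics={
            "divergences": int(res.divergences),
            "step_size": float(res.step_size),
            "mean_accept": float(res.mean_accept),
            "mean_tree_depth": float(res.mean_tree_depth),
            "noise_sd_mean": float(np.exp(res.samples[:, -1]).mean()),
            "gradient_evals": None,
        },
    )


def prune_candidates(fit: FitResult, cutoff: float) -> list[CompoundSpectrum]:
    """Candidates whose center concentration reaches the cutoff, in input order."""
    keep = [c for c, x in zip(fit.library, fit.center) if x >= cutoff]
    if not keep:
        raise NoSurvivorsError("no candidates survive cutoff")
    return keep


def prepare_observed(
    observed: Spectrum, broaden_fwhm_hz: float, fit_grid_points: int
) -> Spectrum:
    """Broaden at native resolution, resample to the fit grid, normalise to area 1."""
    grid = observed.grid
    dx = np.diff(grid)
    if not np.allclose(dx, dx[0], rtol=1e-8):
        uni = np.linspace(grid[0], grid[-1], grid.size)
        observed = Spectrum(
            uni, np.interp(uni, grid, observed.intensity), observed.spectrometer_mhz
        )
    broadened = gaussian_apodize(observed, broaden_fwhm_hz)
    if broadened.grid.size > fit_grid_points:
        coarse = np.linspace(grid[0], grid[-1], fit_grid_points)
        broadened = Spectrum(
            coarse,
            np.interp(coarse, broadened.grid, broadened.intensity),
            observed.spectrometer_mhz,
        )
    return normalize_density(broadened)


def _geometric_mean_weights(weight_samples: np.ndarray) -> np.ndarray:
    return np.exp(np.mean(np.log(np.maximum(weight_samples, 1e-300)), axis=0))


def _fit_interval(
    survivors: list[CompoundSpectrum],
    processed: Spectrum,
    interval: SpectralInterval,
    priors: PriorConfig,
    cfg: SamplerConfig,
    seed: int,
    cutoff: float,
) -> tuple[list[CompoundSpectrum], dict]:
    """Fit one spectral interval; prune member compounds by absolute share.

    The globally normalised observed density is restricted to the interval and
    modelled as a sum of member-compound unit densities scaled by free weights,
    so each weight estimates the compound's absolute share of the whole
    spectrum and can be compared with the cutoff directly.
    """
    members = [
        c
        for c in survivors
        if any(interval.contains(r.shift) for r in c.resonances if r.weight > 0)
    ]
    if not members:
        return survivors, {"interval": (interval.lo, interval.hi), "members": []}
    mask = (processed.grid >= interval.lo) & (processed.grid <= interval.hi)
    if mask.sum() < 8:
        return survivors, {"interval": (interval.lo, interval.hi), "members": []}
    sub = Spectrum(
        processed.grid[mask], processed.intensity[mask], processed.spectrometer_mhz
    )
    model = MixtureModel(
        members,
        sub,
        priors,
        normalized=False,
        restrict=(interval.lo, interval.hi),
        broaden_fwhm_hz=cfg.broaden_fwhm_hz,
    )
    sub_cfg = SamplerConfig(
        warmup=cfg.warmup,
        samples=cfg.samples,
        seed=seed,
        broaden_fwhm_hz=cfg.broaden_fwhm_hz,
        max_depth=cfg.max_depth,
        target_accept=cfg.target_accept,
        fit_grid_points=cfg.fit_grid_points,
    )
    fit = sample_posterior(model, sub_cfg)
    shares = _geometric_mean_weights(fit.weight_samples)
    drop = {c.name for c, s in zip(members, shares) if s < cutoff}
    kept = [c for c in survivors if c.name not in drop]
    info = {
        "interval": (interval.lo, interval.hi),
        "entropy": interval.entropy,
        "members": [c.name for c in members],
        "shares": {c.name: float(s) for c, s in zip(members, shares)},
        "pruned": sorted(drop),
    }
    if not kept:
        raise NoSurvivorsError("no candidates survive cutoff")
    return kept, info


def deconvolute(
    library: list[CompoundSpectrum],
    observed: Spectrum,
    cutoff: float = 0.05,
    cfg: SamplerConfig | None = None,
    priors: PriorConfig | None = None,
    interval_mode: bool = False,
    max_iter: int = 6,
) -> FitResult:
    """Full prune-and-refit deconvolution of an observed mixture spectrum.

    Returns the final fit, with ``present``/``center_full`` expressed over the
    original candidate order (pruned candidates at zero concentration) and a
    per-iteration ``history``.
    """
    cfg = cfg or SamplerConfig()
    priors = priors or PriorConfig()
    if not library:
        raise ValueError("empty candidate library")
    names = [c.name for c in library]
    if len(set(names)) != len(names):
        raise ValueError("duplicate compound names in library")

    processed = prepare_observed(observed, cfg.broaden_fwhm_hz, cfg.fit_grid_points)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(2 * max_iter + 16) % (2**31)
    seed_iter = iter(int(s) for s in seeds)

    survivors = list(library)
    history: list[dict] = []
    intervals = None
    if interval_mode:
        intervals = rank_intervals(build_intervals(library))
        for iv in intervals:
            survivors, info = _fit_interval(
                survivors, processed, iv, priors, cfg, next(seed_iter), cutoff
            )
            if info.get("members"):
                history.append({"stage": "interval", **info})
                logger.info(
                    "interval [%.2f, %.2f] ppm: pruned %s",
                    iv.lo, iv.hi, info["pruned"] or "none",
                )

    widened = False
    converged = False
    fit: FitResult | None = None
    for iteration in range(max_iter):
        # widening applies only to the single iteration immediately after the trigger
        scale = WIDEN_FACTOR if history and history[-1].get("widen_next") else 1.0
        it_priors = PriorConfig(
            weight_scale=priors.weight_scale,
            noise_scale=priors.noise_scale,
            shift_sigma_scale=scale,
            truncate_sd=priors.truncate_sd,
        )
        model = MixtureModel(
            survivors, processed, it_priors, broaden_fwhm_hz=cfg.broaden_fwhm_hz
        )
        it_cfg = SamplerConfig(
            warmup=cfg.warmup,
            samples=cfg.samples,
            seed=next(seed_iter),
            broaden_fwhm_hz=cfg.broaden_fwhm_hz,
            max_depth=cfg.max_depth,
            target_accept=cfg.target_accept,
            fit_grid_points=cfg.fit_grid_points,
        )
        fit = sample_posterior(model, it_cfg)
        keep = prune_candidates(fit, cutoff)
        pruned = [c.name for c in survivors if c.name not in {k.name for k in keep}]
        stable = not pruned
        poor_shifts = bool(np.any(fit.shift_posterior_sd > WIDEN_TRIGGER * fit.res_prior_sd))
        widen_next = stable and poor_shifts and not widened
        history.append(
            {
                "stage": "global",
                "iteration": iteration,
                "candidates": [c.name for c in survivors],
                "center": {c.name: float(x) for c, x in zip(survivors, fit.center)},
                "pruned": pruned,
                "shift_sigma_scale": scale,
                "widen_next": widen_next,
                "divergences": fit.diagnostics["divergences"],
            }
        )
        if pruned:
            logger.info("iteration %d: pruned %s", iteration, pruned)
        if widen_next:
            widened = True
            continue
        if stable:
            converged = True
            break
        survivors = keep

    assert fit is not None
    final_names = {c.name for c in fit.library}
    present = np.array([n in final_names for n in names])
    center_full = np.zeros(len(names))
    for nm, x in zip(fit.names, fit.center):
        center_full[names.index(nm)] = x
    fit.present = present
    fit.library_names = names
    fit.center_full = center_full
    fit.history = history
    fit.converged = converged
    fit.intervals = intervals
    if not converged:
        logger.warning("deconvolution unconverged after %d iterations", max_iter)
    return fit
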
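"""Mixture-model fitting of k-mer spectra.

Estimates the model parameters (per-homolog coverage lambda, overdispersion
rho, two-copy repeat fraction d, per-form heterozygosity rates) by bounded
damped least squares on the transformed spectrum x*f(x). The distinct-k-mer
count G enters the model linearly and is profiled out in closed form at
every residual evaluation. To avoid the classic wrong-peak failure mode at
low coverage, the optimizer is restarted from one candidate per divisor of
the tallest transformed peak (lambda0 = peak/m, m = 1..2p) and the lowest
residual wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import nbinom

from .model import (
    FormRates,
    ModelParams,
    Topology,
    alpha_coefficients,
    caterpillar_topology,
    forms_for_topology,
    nucleotide_divergence,
)
from .spectra import KmerSpectrum, transform


@dataclass
class FitConfig:
    p: int
    k: int = 21
    topology: Topology | None = None
    lambda_init: float | None = None
    lambda_bounds: tuple[float, float] | None = None
    rho_bounds: tuple[float, float] = (1e-6, 50.0)
    max_nfev: int = 1000
    tol: float = 1e-8
    fit_max_factor: float = 20.0  # fit range caps at factor * p * peak estimate
    error_cutoff: int | None = None  # override the valley scan (e.g. noiseless input)

    def __post_init__(self) -> None:
        if self.topology is None:
            self.topology = caterpillar_topology(self.p)
        if self.lambda_bounds is not None and not (
            0 < self.lambda_bounds[0] < self.lambda_bounds[1]
        ):
            raise ValueError("lambda bounds must be ordered and positive")


@dataclass
class FitResult:
    params: ModelParams | None
    residual_sum: float
    error_cutoff: int
    monoploid_length: float
    polyploid_length: float
    converged: bool
    model_curve: tuple[np.ndarray, np.ndarray] | None = None
    length_is_lower_bound: bool = False
    start_residuals: list[float] = field(default_factory=list)

    def summary(self) -> dict[str, float]:
        out: dict[str, float] = {}
        if self.params is not None:
            out["ploidy"] = self.params.p
            out["lambda"] = self.params.lam
            out["rho"] = self.params.rho
            out["repetitiveness_d"] = self.params.d
            out["distinct_monoploid_kmers_G"] = self.params.G
            for pattern, rate in self.params.form_rates.by_pattern().items():
                out[f"rate_{pattern}"] = rate
            out["nucleotide_divergence"] = nucleotide_divergence(self.params.form_rates)
        out["error_cutoff"] = self.error_cutoff
        out["monoploid_length"] = self.monoploid_length
        out["polyploid_length"] = self.polyploid_length
        out["residual_sum"] = self.residual_sum
        out["converged"] = float(self.converged)
        return out


def find_error_valley(spectrum: KmerSpectrum) -> int:
    """Coverage of the first local minimum of f(x) scanning up from x = 1.

    Bins below the valley are dominated by sequencing-error k-mers and are
    excluded from fitting.
    """
    f = spectrum.frequencies
    for i in range(1, len(f) - 1):
        if f[i] <= f[i - 1] and f[i] < f[i + 1]:
            return int(spectrum.coverages[i])
    raise ValueError(
        "no error valley found: the spectrum decreases monotonically, which "
        "suggests insufficient sequencing coverage"
    )


def initialize(spectrum: KmerSpectrum, config: FitConfig) -> list[np.ndarray]:
    """Starting parameter vectors [lam, rho, d, r_1..r_{p-1}], one per
    candidate divisor of the tallest transformed-spectrum peak."""
    valley = config.error_cutoff if config.error_cutoff is not None else find_error_valley(spectrum)
    ts = transform(spectrum)
    mask = ts.coverages >= valley
    if not mask.any():
        return []
    peak_cov = float(ts.coverages[mask][np.argmax(ts.values[mask])])
    n_rates = config.p - 1
    starts = []
    if config.lambda_init is not None:
        divisors: list[float] = [peak_cov / config.lambda_init]
    else:
        divisors = list(range(1, 2 * config.p + 1))
    for m in divisors:
        lam0 = peak_cov / m
        if lam0 < 1.0:
            continue
        theta = np.concatenate(([lam0, 0.5, 0.1], np.full(n_rates, 0.01)))
        starts.append(theta)
    return starts


def _transformed_model(theta: np.ndarray, x: np.ndarray, config: FitConfig):
    """Profiled-G transformed-model prediction and the scale G itself."""
    p, k = config.p, config.k
    lam, rho, d = theta[0], theta[1], theta[2]
    raw_rates = np.asarray(theta[3:], dtype=float)
    total = raw_rates.sum()
    excess = max(0.0, total - 0.999)
    if excess > 0:
        raw_rates = raw_rates * (0.999 / total)
    forms = forms_for_topology(config.topology)
    rates = FormRates(dict(zip(forms, raw_rates)))
    params = ModelParams(
        p=p, k=k, lam=lam, rho=rho, d=d, G=1.0,
        topology=config.topology, form_rates=rates,
    )
    alphas = alpha_coefficients(params).alphas
    shape = np.zeros(len(x))
    for i in range(1, 2 * p + 1):
        if alphas[i - 1] == 0.0:
            continue
        mu = i * lam
        size = mu / rho
        shape += alphas[i - 1] * nbinom.pmf(x, size, size / (size + mu))
    tshape = x * shape
    return tshape, excess


def fit(spectrum: KmerSpectrum, config: FitConfig) -> FitResult:
    """Fit the 2p-component mixture to a spectrum, multi-start, bounded."""
    valley = config.error_cutoff if config.error_cutoff is not None else find_error_valley(spectrum)
    starts = initialize(spectrum, config)
    ts = transform(spectrum)
    peak_guess = float(
        ts.coverages[ts.coverages >= valley][
            np.argmax(ts.values[ts.coverages >= valley])
        ]
    ) if (ts.coverages >= valley).any() else 0.0
    fit_max = min(
        float(spectrum.coverages[-1]), config.fit_max_factor * config.p * max(peak_guess, 1.0)
    )
    mask = (spectrum.coverages >= valley) & (spectrum.coverages <= fit_max)
    x = spectrum.coverages[mask].astype(float)
    y = (spectrum.coverages[mask] * spectrum.frequencies[mask]).astype(float)
    if len(x) < 4 + config.p or not starts:
        return FitResult(
            params=None, residual_sum=float("inf"), error_cutoff=valley,
            monoploid_length=float("nan"), polyploid_length=float("nan"),
            converged=False,
        )

    yscale = float(np.max(y))

    def residual(theta: np.ndarray) -> np.ndarray:
        tshape, excess = _transformed_model(theta, x, config)
        denom = float(np.dot(tshape, tshape))
        G = float(np.dot(y, tshape)) / denom if denom > 0 else 0.0
        G = max(G, 0.0)
        res = y - G * tshape
        if excess > 0:
            res = res + yscale * excess  # soft push back into the simplex
        return res

    lam_lb, lam_ub = config.lambda_bounds or (1.0, fit_max)
    n_rates = config.p - 1
    lb = np.concatenate(([lam_lb, config.rho_bounds[0], 0.0], np.zeros(n_rates)))
    ub = np.concatenate(([lam_ub, config.rho_bounds[1], 1.0], np.ones(n_rates)))

    solutions = []
    start_residuals = []
    for theta0 in starts:
        theta0 = np.clip(theta0, lb, ub)
        try:
            sol = least_squares(
                residual, theta0, bounds=(lb, ub), method="trf",
                xtol=config.tol, ftol=config.tol, gtol=config.tol,
                max_nfev=config.max_nfev,
            )
        except Exception:
            continue
        rss = float(2 * sol.cost)
        start_residuals.append(rss)
        if sol.success:
            solutions.append((rss, sol))

    best = None
    best_cost = np.inf
    if solutions:
        min_rss = min(rss for rss, _ in solutions)
        # ties (e.g. a homozygous spectrum read as lam with d=0 or lam/2 with
        # d=1 fits identically): prefer the largest lambda
        near = [(rss, s) for rss, s in solutions if rss <= min_rss * (1 + 1e-6) + 1e-30]
        best_cost, best = max(near, key=lambda t: t[1].x[0])

    if best is None:
        return FitResult(
            params=None, residual_sum=float("inf"), error_cutoff=valley,
            monoploid_length=float("nan"), polyploid_length=float("nan"),
            converged=False, start_residuals=start_residuals,
        )

    theta = best.x
    tshape, _ = _transformed_model(theta, x, config)
    denom = float(np.dot(tshape, tshape))
    G = max(float(np.dot(y, tshape)) / denom if denom > 0 else 0.0, 1e-12)
    forms = forms_for_topology(config.topology)
    raw = np.asarray(theta[3:], dtype=float)
    if raw.sum() > 0.999:
        raw = raw * (0.999 / raw.sum())
    params = ModelParams(
        p=config.p, k=config.k, lam=float(theta[0]), rho=float(theta[1]),
        d=float(theta[2]), G=G, topology=config.topology,
        form_rates=FormRates(dict(zip(forms, raw))),
    )
    result = FitResult(
        params=params,
        residual_sum=best_cost,
        error_cutoff=valley,
        monoploid_length=float("nan"),
        polyploid_length=float("nan"),
        converged=True,
        model_curve=(x, G * tshape),
        length_is_lower_bound=spectrum.truncated,
        start_residuals=start_residuals,
    )
    result.monoploid_length, result.polyploid_length = genome_size(result, spectrum)
    return result


def genome_size(fit_result: FitResult, spectrum: KmerSpectrum) -> tuple[float, float]:
    """(monoploid, polyploid) genome length estimates in bases.

    The total non-error k-mer mass divided by the per-homolog coverage gives
    the polyploid length; one p-th of it is the monoploid length. Repeat
    copies beyond two contribute through their coverage mass. Results are
    lower bounds when the histogram was truncated.
    """
    if fit_result.params is None or not fit_result.converged:
        raise ValueError("genome size requires a converged fit")
    mask = spectrum.coverages >= fit_result.error_cutoff
    mass = float(np.sum(spectrum.coverages[mask] * spectrum.frequencies[mask]))
    poly = mass / fit_result.params.lam
    return poly / fit_result.params.p, poly


def render_plots(
    fit_result: FitResult, spectrum: KmerSpectrum, out_prefix: str | Path
) -> list[Path]:
    """Write the four diagnostic panels: (un)transformed x (linear, log)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    x_obs = spectrum.coverages
    f_obs = spectrum.frequencies
    ts = transform(spectrum)

    have_model = fit_result.converged and fit_result.params is not None
    if have_model:
        from .model import mixture_density

        f_model = mixture_density(fit_result.params, x_obs.astype(float))
        t_model = x_obs * f_model
        label = (
            f"fit: lam={fit_result.params.lam:.2f} d={fit_result.params.d:.3f} "
            f"div={nucleotide_divergence(fit_result.params.form_rates):.4f}"
        )

    paths = []
    panels = [
        ("untransformed_linear", x_obs, f_obs, None, False),
        ("untransformed_log", x_obs, f_obs, None, True),
        ("transformed_linear", ts.coverages, ts.values, None, False),
        ("transformed_log", ts.coverages, ts.values, None, True),
    ]
    for name, px, py, _, logy in panels:
        fig, ax = plt.subplots(figsize=(7, 5))
        if logy:
            pos = py > 0
            ax.semilogy(px[pos], py[pos], ".", ms=3, label="observed")
        else:
            ax.plot(px, py, ".", ms=3, label="observed")
        if have_model:
            my = t_model if name.startswith("transformed") else f_model
            if logy:
                pos = my > 0
                ax.semilogy(x_obs[pos], my[pos], "-", label=label)
            else:
                ax.plot(x_obs, my, "-", label=label)
        ax.axvline(fit_result.error_cutoff, ls="--", c="gray", lw=0.8)
        ax.set_xlabel("coverage")
        ax.set_ylabel("frequency x coverage" if name.startswith("transformed") else "frequency")
        ax.legend(fontsize=8)
        path = Path(f"{out_prefix}_{name}.png")
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
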
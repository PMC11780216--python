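"""MCMC convergence and predictive-accuracy diagnostics.

Split-R̂ (Gelman–Rubin) is implemented directly from its between/within
chain-variance definition; PSIS-LOO (Pareto-smoothed importance-sampling
leave-one-out cross-validation) is delegated to :mod:`arviz`, with the
pointwise log-likelihoods supplied by the package's own models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientChainsError, InsufficientDrawsError

__all__ = ["split_rhat", "compute_rhat", "psis_loo", "LooDiagnostics", "hpd_interval"]


def split_rhat(draws: np.ndarray) -> float:
    """Split-R̂ for one parameter from a (chains, iterations) array.

    Each chain is split in half, giving 2m sequences; R̂ compares the
    between-sequence and within-sequence variances and is >= 1 up to
    floating-point noise.  Chains that are all constant and equal return the
    sentinel 1.0 (a converged point mass); constant but unequal chains
    return ``inf``.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("draws must be (chains, iterations)")
    c, it = draws.shape
    if c < 2:
        raise InsufficientChainsError("split-Rhat requires >= 2 chains")
    half = it // 2
    if half < 2:
        raise InsufficientDrawsError("need at least 4 iterations per chain")
    seqs = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    if np.all(np.ptp(seqs, axis=1) == 0):  # every sequence constant
        return 1.0 if np.ptp(seqs) == 0 else float("inf")
    within = seqs.var(axis=1, ddof=1)
    m, n = seqs.shape
    W = within.mean()
    B = n * seqs.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    # var_plus can dip below W when B is at its noise floor; clamp at 1
    return max(1.0, float(np.sqrt(var_plus / W)))


def compute_rhat(draws) -> dict[str, float]:
    """Split-R̂ for every parameter.

    ``draws`` is either a mapping of parameter name -> (chains, iterations)
    array or a single (chains, iterations, parameters) array (parameters are
    then named by index).
    """
    if isinstance(draws, np.ndarray):
        if draws.ndim == 2:
            draws = {"param": draws}
        elif draws.ndim == 3:
            draws = {f"param[{j}]": draws[:, :, j] for j in range(draws.shape[2])}
        else:
            raise ValueError("expected a 2-D or 3-D draws array")
    return {name: split_rhat(np.asarray(arr)) for name, arr in draws.items()}


@dataclass(frozen=True)
class LooDiagnostics:
    """PSIS-LOO summary: elpd, its SE, and per-observation Pareto-k values."""

    elpd: float
    se: float
    pareto_k: np.ndarray
    frac_k_below_0p7: float
    frac_k_below_0p5: float

    def __post_init__(self):
        if not 0 <= self.frac_k_below_0p5 <= self.frac_k_below_0p7 <= 1:
            raise ValueError("Pareto-k fractions must be nested proportions")


def psis_loo(log_lik: np.ndarray, min_draws: int = 1000) -> LooDiagnostics:
    """PSIS-LOO from pointwise log-likelihood draws (chains, draws, n_obs)."""
    import arviz as az

    log_lik = np.asarray(log_lik, dtype=float)
    if log_lik.ndim != 3:
        raise ValueError("log_lik must be (chains, draws, n_obs)")
    if log_lik.shape[0] * log_lik.shape[1] < min_draws:
        raise InsufficientDrawsError(
            f"PSIS-LOO needs >= {min_draws} total draws, got "
            f"{log_lik.shape[0] * log_lik.shape[1]}"
        )
    idata = az.from_dict(log_likelihood={"obs": log_lik})
    S = log_lik.shape[0] * log_lik.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # relative efficiency of the importance ratios, from the ESS of the
        # pointwise log-likelihoods (no separate posterior group is stored)
        ess = az.ess(idata.log_likelihood.rename({"obs": "ll"}))["ll"].values
        reff = float(np.clip(np.nanmean(ess) / S, 1e-3, 1.0))
        res = az.loo(idata, pointwise=True, reff=reff)
    k = np.asarray(res.pareto_k, dtype=float)
    return LooDiagnostics(
        elpd=float(res.elpd_loo),
        se=float(res.se),
        pareto_k=k,
        frac_k_below_0p7=float(np.mean(k < 0.7)),
        frac_k_below_0p5=float(np.mean(k < 0.5)),
    )


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Highest-posterior-density interval of a flat sample of draws."""
    import arviz as az

    draws = np.asarray(draws, dtype=float).reshape(-1)
    lo, hi = az.hdi(draws, hdi_prob=prob)
    return float(lo), float(hi)
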
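"""Synthetic genotype and multi-environment count-phenotype generator.

Counts are conditionally independent Poisson draws with a log link:

    log mu[i,e,t] = eta_t + x_i . beta_t + gamma[e,t] + delta[i,e,t]
                    (+ c * s(x_i . beta_t)  when nonlinear)

where x_i is the line's 0/1 marker vector, beta_t a sparse causal-effect
vector (correlated across traits through a Gaussian copula on the effects),
gamma an environment main effect, delta a line x environment (G x E)
deviation and s a centered quadratic of the genetic score.  Between-trait
correlation therefore lives in the genetic signal, not in the Poisson noise.

``make_benchmark_dataset`` emulates the shape of the two CIMMYT wheat
disease-count data sets commonly used to benchmark count-trait genomic
prediction: data set 1 with 182 lines x 1635 SNPs x 3 environments x 2
traits (right-skewed counts, mode near zero), data set 2 with 438 lines x
11617 SNPs x 6 environments x 3 traits (2628 observations, mode between 0
and 5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MarkerMatrix, PhenotypeTable

LOG_MU_MAX = 20.0  # rates above e^20 indicate a mis-specified configuration


class ConfigError(ValueError):
    """Raised for invalid or numerically untenable simulation settings."""


@dataclass
class SimConfig:
    """Settings of one synthetic genotype x environment count experiment.

    ``intercepts`` are per-trait log-scale baselines eta_t; ``effect_sd`` is
    the standard deviation of each causal marker effect on the log scale;
    ``trait_cor`` is the T x T correlation of the trait-level effect vectors
    (a scalar is expanded to a compound-symmetric matrix).
    """

    n_lines: int = 100
    n_markers: int = 200
    n_envs: int = 3
    n_traits: int = 2
    maf_range: tuple = (0.05, 0.5)
    intercepts: np.ndarray | float | None = None
    n_causal: int = 10
    effect_sd: float = 0.1
    env_effect_sd: float = 0.2
    gxe_sd: float = 0.1
    trait_cor: np.ndarray | float = 0.0
    nonlinear: bool = False
    nonlinear_coef: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_lines", "n_envs", "n_traits"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_markers < 0:
            raise ConfigError("n_markers must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must be within (0, 0.5]; got {self.maf_range}")
        if self.n_causal > self.n_markers:
            raise ConfigError("n_causal cannot exceed n_markers")
        for name in ("effect_sd", "env_effect_sd", "gxe_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.intercepts is None:
            self.intercepts = np.full(self.n_traits, math.log(4.0))
        else:
            self.intercepts = np.broadcast_to(
                np.atleast_1d(np.asarray(self.intercepts, dtype=float)), (self.n_traits,)
            ).copy()
        C = self.trait_cor
        if np.isscalar(C):
            rho = float(C)
            C = np.full((self.n_traits, self.n_traits), rho)
            np.fill_diagonal(C, 1.0)
        C = np.asarray(C, dtype=float)
        if C.shape != (self.n_traits, self.n_traits):
            raise ConfigError("trait_cor must be T x T")
        if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ConfigError("trait_cor must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ConfigError("trait_cor must be positive semi-definite")
        self.trait_cor = C

    def _streams(self):
        """Independent child RNGs for markers, effects, noise."""
        ss = np.random.SeedSequence(self.seed)
        kids = ss.spawn(3)
        return {
            "markers": np.random.default_rng(kids[0]),
            "effects": np.random.default_rng(kids[1]),
            "noise": np.random.default_rng(kids[2]),
        }


def simulate_markers(cfg: SimConfig) -> MarkerMatrix:
    """Draw a binary marker matrix; entry (i, j) ~ Bernoulli(f_j) with
    f_j uniform on ``cfg.maf_range``.  Deterministic given ``cfg.seed``."""
    rng = cfg._streams()["markers"]
    freqs = rng.uniform(*cfg.maf_range, size=cfg.n_markers)
    values = (rng.random((cfg.n_lines, cfg.n_markers)) < freqs).astype(np.int8)
    width = max(4, len(str(max(cfg.n_lines, cfg.n_markers, 1))))
    lines = [f"L{i+1:0{width}d}" for i in range(cfg.n_lines)]
    markers = [f"M{j+1:0{width}d}" for j in range(cfg.n_markers)]
    return MarkerMatrix(lines, markers, values)


def simulate_phenotypes(cfg: SimConfig, m: MarkerMatrix):
    """Draw the count phenotypes for every line x environment cell.

    Returns ``(PhenotypeTable, truth)`` where ``truth`` carries the causal
    effects, environment effects, G x E deviations, and the true rates mu
    aligned with the phenotype rows — everything a recovery test needs.
    """
    if m.n_lines != cfg.n_lines or m.n_markers != cfg.n_markers:
        raise ConfigError("marker matrix dimensions do not match the configuration")
    streams = cfg._streams()
    rng_eff, rng_noise = streams["effects"], streams["noise"]
    T, n_env, n_lines = cfg.n_traits, cfg.n_envs, cfg.n_lines

    beta = np.zeros((cfg.n_markers, T))
    causal_idx = np.array([], dtype=int)
    if cfg.n_causal > 0 and cfg.n_markers > 0:
        causal_idx = rng_eff.choice(cfg.n_markers, size=cfg.n_causal, replace=False)
        causal_idx.sort()
        # Gaussian copula across traits: correlated standard normals scaled
        # to effect_sd, so each trait's marginal effect law is unchanged.
        L = np.linalg.cholesky(cfg.trait_cor + 1e-12 * np.eye(T))
        Z = rng_eff.standard_normal((cfg.n_causal, T))
        beta[causal_idx] = cfg.effect_sd * (Z @ L.T)

    gamma = rng_eff.standard_normal((n_env, T)) * cfg.env_effect_sd
    delta = rng_eff.standard_normal((n_lines, n_env, T)) * cfg.gxe_sd

    score = m.values.astype(float) @ beta  # (n_lines, T)
    log_mu = cfg.intercepts[None, None, :] + score[:, None, :] + gamma[None, :, :] + delta
    if cfg.nonlinear:
        s = score**2 - (score**2).mean(axis=0, keepdims=True)
        log_mu = log_mu + cfg.nonlinear_coef * s[:, None, :]
    if np.max(log_mu) > LOG_MU_MAX:
        raise ConfigError(
            f"max log-rate {np.max(log_mu):.2f} exceeds {LOG_MU_MAX}; "
            "reduce effect sizes or intercepts"
        )
    mu = np.exp(log_mu)
    y = rng_noise.poisson(mu)  # (n_lines, n_env, T)

    env_ids = [f"Env{e+1}" for e in range(n_env)]
    trait_names = [f"y{t+1}" for t in range(T)]
    rows = []
    for e in range(n_env):
        for i in range(n_lines):
            rows.append((m.line_ids[i], env_ids[e], *y[i, e]))
    df = pd.DataFrame(rows, columns=["line", "env", *trait_names])
    ph = PhenotypeTable(df, trait_names)

    mu_rows = np.stack([mu[i, e] for e in range(n_env) for i in range(n_lines)])
    truth = {
        "beta": beta,
        "causal_idx": causal_idx,
        "intercepts": cfg.intercepts.copy(),
        "env_effects": gamma,
        "gxe": delta,
        "score": score,
        "mu": mu_rows,  # aligned with ph rows
    }
    return ph, truth


def write_truth(truth: dict, trait_names, path) -> None:
    """Persist the generating effects to a long-form sidecar CSV."""
    rows = []
    for t, name in enumerate(trait_names):
        rows.append((name, "intercept", truth["intercepts"][t]))
        for j in truth["causal_idx"]:
            rows.append((name, f"beta:{j}", truth["beta"][j, t]))
        for e in range(truth["env_effects"].shape[0]):
            rows.append((name, f"env:{e}", truth["env_effects"][e, t]))
    pd.DataFrame(rows, columns=["trait", "term", "value"]).to_csv(path, index=False)


_BENCHMARK_SHAPES = {
    # n_lines, n_markers, n_envs, n_traits, intercept, genetic sd, env sd, gxe sd, cor
    1: dict(n_lines=182, n_markers=1635, n_envs=3, n_traits=2,
            intercept=math.log(3.0), sigma_g=0.9, env_sd=0.4, gxe_sd=0.3, rho=0.7),
    2: dict(n_lines=438, n_markers=11617, n_envs=6, n_traits=3,
            intercept=math.log(2.0), sigma_g=0.5, env_sd=0.3, gxe_sd=0.2, rho=0.5),
}


def benchmark_config(which: int, scale: float = 1.0, seed: int = 0) -> SimConfig:
    """SimConfig emulating one of the two wheat benchmark data sets."""
    if which not in _BENCHMARK_SHAPES:
        raise ConfigError("which must be 1 or 2")
    if not 0.0 < scale <= 1.0:
        raise ConfigError("scale must lie in (0, 1]")
    s = _BENCHMARK_SHAPES[which]
    n_lines = max(2, int(s["n_lines"] * scale))
    n_markers = max(1, int(s["n_markers"] * scale))
    n_causal = max(1, n_markers // 20)
    # Bernoulli markers with MAF ~ U(0.05, 0.5) have mean variance ~ 0.2;
    # scale per-marker effects so the genetic score sd is sigma_g.
    effect_sd = s["sigma_g"] / math.sqrt(0.2 * n_causal)
    return SimConfig(
        n_lines=n_lines,
        n_markers=n_markers,
        n_envs=s["n_envs"],
        n_traits=s["n_traits"],
        intercepts=s["intercept"],
        n_causal=n_causal,
        effect_sd=effect_sd,
        env_effect_sd=s["env_sd"],
        gxe_sd=s["gxe_sd"],
        trait_cor=s["rho"],
        seed=seed,
    )


def make_benchmark_dataset(which: int, scale: float = 1.0, seed: int = 0):
    """Simulate a data set shaped like one of the two wheat benchmarks.

    ``which=1``: 182 lines x 1635 markers x 3 environments x 2 traits,
    strongly right-skewed counts with mode near zero.  ``which=2``: 438
    lines x 11617 markers x 6 environments x 3 traits (2628 observations),
    counts mostly between 0 and 5.  ``scale`` shrinks lines and markers by
    flooring (environments and traits are preserved).
    """
    cfg = benchmark_config(which, scale, seed)
    markers = simulate_markers(cfg)
    ph, _ = simulate_phenotypes(cfg, markers)
    return markers, ph
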
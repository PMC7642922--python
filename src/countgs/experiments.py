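"""Reduced-scale simulation experiments probing the headline model claims.

Two qualitative claims are checked on synthetic data small enough for a
single CPU:

* joint multi-trait fitting helps a Poisson deep network when traits are
  genetically correlated and the architecture is nonlinear — the 2-hidden-
  layer multivariate network should match or beat its univariate
  counterpart on within-environment correlation (APC) for most seeds;
* when the genetic architecture is purely linear on the log scale, the
  penalized Poisson regressions should match or beat the deep networks on
  test MSE for most seeds.

Each experiment repeats over seeds with a fixed train/test split of line x
environment cells and reports the per-seed metrics, leaving the win-count
decision to the caller.  The module also hosts the numerical checks used
for acceptance: a finite-difference audit of the network gradients and a
sparse-recovery run for the cross-validated lasso.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import build_design
from .evaluation import apc, mse, _child_seed
from .glm import GPRConfig, PoissonElasticNet
from .nnet import (
    NetworkSpec,
    TrainConfig,
    forward,
    gradients,
    init_params,
    mpdn_loss,
    train,
)
from .simulate import SimConfig, simulate_markers, simulate_phenotypes


def _split(n: int, test_fraction: float, rng) -> tuple:
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    return perm[n_test:], perm[:n_test]


def _nonlinear_config(seed: int) -> SimConfig:
    """Correlated-trait nonlinear architecture: 300 lines x 500 markers x
    3 environments x 2 traits, trait correlation 0.6, quadratic coefficient
    0.5 on the genetic score."""
    return SimConfig(
        n_lines=300, n_markers=500, n_envs=3, n_traits=2,
        intercepts=np.log(3.0), n_causal=20, effect_sd=0.15,
        env_effect_sd=0.3, gxe_sd=0.1, trait_cor=0.6,
        nonlinear=True, nonlinear_coef=0.5, seed=seed,
    )


def _linear_config(seed: int) -> SimConfig:
    """Linear log-scale architecture: 200 lines x 200 markers x 3
    environments x 2 traits, no quadratic term."""
    return SimConfig(
        n_lines=200, n_markers=200, n_envs=3, n_traits=2,
        intercepts=np.log(4.0), n_causal=20, effect_sd=0.25,
        env_effect_sd=0.3, gxe_sd=0.1, trait_cor=0.6,
        nonlinear=False, seed=seed,
    )


def _net_train_config(seed: int, max_epochs: int = 600) -> TrainConfig:
    return TrainConfig(
        batch_size=64, learning_rate=0.001, max_epochs=max_epochs,
        early_stopping_patience=60, validation_fraction=0.2, seed=seed,
    )


def mpdn_vs_updn_apc(n_seeds: int = 10, seed: int = 0, n_splits: int = 3) -> pd.DataFrame:
    """Multivariate vs univariate 2-hidden-layer networks on correlated
    nonlinear data.

    Per seed, APC is averaged over ``n_splits`` random 80/20 train/test
    splits of the cells — the split-averaged form in which fold-averaged
    protocol results are reported.  Returns per-seed across-trait APC for
    both model families.
    """
    rows = []
    for s in range(n_seeds):
        cfg = _nonlinear_config(_child_seed(seed, s))
        markers = simulate_markers(cfg)
        ph, _ = simulate_phenotypes(cfg, markers)
        design, traits = build_design(ph, markers)
        X, Y = design.X, traits.Y.astype(float)
        envs = design.env_labels()
        apc_m_splits, apc_u_splits = [], []
        for k in range(n_splits):
            rng = np.random.default_rng(_child_seed(seed, s, 1, k))
            trn, tst = _split(len(Y), 0.2, rng)

            spec_m = NetworkSpec(n_hidden=2, units=64, n_outputs=2, l1_lambda=0.001)
            net_m = train(spec_m, X[trn], Y[trn], _net_train_config(_child_seed(seed, s, 2, k)))
            pred_m = net_m.predict(X[tst])

            pred_u = np.empty_like(pred_m)
            for t in range(2):
                spec_u = NetworkSpec(n_hidden=2, units=64, n_outputs=1, l1_lambda=0.001)
                net_u = train(
                    spec_u, X[trn], Y[trn, t : t + 1],
                    _net_train_config(_child_seed(seed, s, 3 + t, k)),
                )
                pred_u[:, t] = net_u.predict(X[tst])[:, 0]

            apc_m_splits.append(
                np.mean([apc(Y[tst, t], pred_m[:, t], envs[tst]) for t in range(2)])
            )
            apc_u_splits.append(
                np.mean([apc(Y[tst, t], pred_u[:, t], envs[tst]) for t in range(2)])
            )
        rows.append({
            "seed": s,
            "apc_mpdn": float(np.mean(apc_m_splits)),
            "apc_updn": float(np.mean(apc_u_splits)),
        })
    return pd.DataFrame(rows)


def gpr_vs_mpdn_mse(n_seeds: int = 10, seed: int = 0) -> pd.DataFrame:
    """CV-lasso Poisson regression vs the 2-hidden-layer multivariate
    network on linear data; returns per-seed across-trait test MSE."""
    rows = []
    for s in range(n_seeds):
        cfg = _linear_config(_child_seed(seed, 100 + s))
        markers = simulate_markers(cfg)
        ph, _ = simulate_phenotypes(cfg, markers)
        design, traits = build_design(ph, markers)
        X, Y = design.X, traits.Y.astype(float)
        rng = np.random.default_rng(_child_seed(seed, 100 + s, 1))
        trn, tst = _split(len(Y), 0.2, rng)

        pred_g = np.empty((len(tst), 2))
        for t in range(2):
            res = PoissonElasticNet(
                Y[trn, t], X[trn], GPRConfig(alpha=1.0, n_lambda=30)
            ).fit(seed=_child_seed(seed, 100 + s, 2 + t))
            pred_g[:, t] = res.predict(X[tst])

        spec_m = NetworkSpec(n_hidden=2, units=64, n_outputs=2, l1_lambda=0.001)
        net_m = train(spec_m, X[trn], Y[trn], _net_train_config(_child_seed(seed, 100 + s, 4)))
        pred_m = net_m.predict(X[tst])

        mse_g = np.mean([mse(Y[tst, t], pred_g[:, t]) for t in range(2)])
        mse_m = np.mean([mse(Y[tst, t], pred_m[:, t]) for t in range(2)])
        rows.append({"seed": s, "mse_gpr": mse_g, "mse_mpdn": mse_m})
    return pd.DataFrame(rows)


def gradient_check(n_networks: int = 100, seed: int = 0, h: float = 1e-5) -> float:
    """Central-finite-difference audit of backpropagation.

    Random topologies (depths 1-4, T in {1, 3}), random parameters and
    Poisson responses; networks whose pre-activations sit within 1e-3 of a
    ReLU kink are redrawn (the subgradient is not the derivative there).
    Returns the worst per-coordinate error, scaled by max(1, |gradient|).
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    checked = 0
    while checked < n_networks:
        depth = int(rng.integers(1, 5))
        T = int(rng.choice([1, 3]))
        d = int(rng.integers(3, 8))
        units = int(rng.integers(2, 6))
        n = int(rng.integers(2, 6))
        l1 = float(rng.choice([0.0, 0.01]))
        spec = NetworkSpec(n_hidden=depth, units=units, n_outputs=T, l1_lambda=l1)
        params = init_params(spec, d, seed=int(rng.integers(2**31)))
        for b in params.biases:
            b += rng.normal(scale=0.1, size=b.shape)
        X = rng.normal(size=(n, d))
        mu0 = forward(spec, params, X)
        Y = rng.poisson(np.clip(mu0, 0.05, 20.0)).astype(float)

        # stay away from ReLU kinks: redraw if any hidden net input ~ 0
        A = X
        near_kink = False
        for l in range(spec.n_hidden):
            Z = A @ params.weights[l] + params.biases[l]
            if np.min(np.abs(Z)) < 1e-3:
                near_kink = True
                break
            A = np.maximum(Z, 0.0)
        if near_kink:
            continue

        grads = gradients(spec, params, X, Y, l1_lambda=l1)
        arrays = [*params.weights, *params.biases]
        garrays = [*grads.weights, *grads.biases]
        for arr, garr in zip(arrays, garrays):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = arr[ix]
                arr[ix] = orig + h
                lp = mpdn_loss(Y, forward(spec, params, X), params, l1)
                arr[ix] = orig - h
                lm = mpdn_loss(Y, forward(spec, params, X), params, l1)
                arr[ix] = orig
                fd = (lp - lm) / (2 * h)
                err = abs(garr[ix] - fd) / max(1.0, abs(garr[ix]), abs(fd))
                worst = max(worst, err)
        checked += 1
    return worst


def lasso_recovery(n_seeds: int = 10, seed: int = 0, n_obs: int = 1000, d: int = 20,
                   n_causal: int = 5, effect: float = 0.3) -> pd.DataFrame:
    """Sparse-coefficient recovery by the CV-selected lasso.

    Standard-normal predictors, 5 causal effects of +-0.3 on the log rate;
    reports corr(beta_hat, beta_true) per seed.
    """
    rows = []
    for s in range(n_seeds):
        rng = np.random.default_rng(_child_seed(seed, 200 + s))
        X = rng.normal(size=(n_obs, d))
        beta = np.zeros(d)
        idx = rng.choice(d, size=n_causal, replace=False)
        beta[idx] = effect * rng.choice([-1.0, 1.0], size=n_causal)
        mu = np.exp(np.log(4.0) + X @ beta)
        y = rng.poisson(mu)
        res = PoissonElasticNet(y, X, GPRConfig(alpha=1.0, n_lambda=50)).fit(
            seed=_child_seed(seed, 200 + s, 1)
        )
        corr = float(np.corrcoef(res.beta, beta)[0, 1])
        rows.append({"seed": s, "corr": corr, "lambda": res.lambda_selected})
    return pd.DataFrame(rows)
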
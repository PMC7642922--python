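"""Evaluation protocol for count-trait genomic prediction models.

Fivefold outer cross-validation over line x environment cells: in each fold
20% of cells are the test set (TST), and the remaining 80% are split 64/16
into training (TRN) and tuning (TUN).  Deep-network hyper-parameters are
grid-searched per depth on TRN, scored by tuning-set MSE, and the winner is
refitted on TRN + TUN; penalized Poisson regressions select lambda by inner
10-fold CV on TRN + TUN.  Test-set performance is summarized per trait by
MSE, MAAPE (mean arctangent absolute percentage error, bounded in
[0, pi/2]) and APC (Pearson correlation within each environment, averaged),
each with a 500-resample bootstrap standard error; metrics are computed per
fold and averaged over folds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DesignMatrix, PhenotypeTable, TraitMatrix, build_design
from .glm import GPRConfig, PoissonElasticNet
from .nnet import NetworkSpec, TrainConfig, TrainedNetwork, train

logger = logging.getLogger(__name__)

#: the standard 13-model roster: four univariate and four multivariate
#: Poisson deep networks (by depth) plus five penalized Poisson regressions
ROSTER = (
    "UPDN_1", "UPDN_2", "UPDN_3", "UPDN_4",
    "MPDN_1", "MPDN_2", "MPDN_3", "MPDN_4",
    "GPR_0.75", "GPR_0.5", "GPR_0.25", "GPR_Lasso", "GPR_Ridge",
)

GPR_ALPHAS = {
    "GPR_0.75": 0.75,
    "GPR_0.5": 0.5,
    "GPR_0.25": 0.25,
    "GPR_Lasso": 1.0,
    "GPR_Ridge": 0.0,
}


def _child_seed(*entropy) -> int:
    """Deterministic child seed (< 2^31) from a tuple of integers."""
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# cross-validation plan


@dataclass
class CVPlan:
    """Outer CV assignment: a test fold per observation plus tuning indices."""

    n_folds: int
    fold_of: np.ndarray  # test-fold index per observation
    tune_idx: list  # per fold, indices reserved for tuning (within the outer training set)
    seed: int

    @property
    def n_obs(self) -> int:
        return len(self.fold_of)

    def test_idx(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_idx(self, fold: int) -> np.ndarray:
        """Outer-training indices excluding the tuning subset (TRN)."""
        outer = np.flatnonzero(self.fold_of != fold)
        return np.setdiff1d(outer, self.tune_idx[fold], assume_unique=True)

    def outer_train_idx(self, fold: int) -> np.ndarray:
        """TRN + TUN: everything outside the test fold."""
        return np.flatnonzero(self.fold_of != fold)


def make_cv_plan(ph, n_folds: int = 5, tune_fraction: float = 0.2, seed: int = 0) -> CVPlan:
    """Random seeded partition of cells into near-equal test folds.

    Within each fold's outer training set a seeded ``tune_fraction`` is
    reserved for tuning, so with 5 folds the split is 64/16/20 TRN/TUN/TST.
    A line can therefore be trained in some environments and tested in
    others, mimicking sparse multi-environment trials.
    """
    n = ph.n_obs if isinstance(ph, PhenotypeTable) else int(ph)
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds {n} observations")
    if not 0.0 < tune_fraction < 1.0:
        raise ValueError("tune_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        fold_of[chunk] = f
    tune_idx = []
    for f in range(n_folds):
        outer = np.flatnonzero(fold_of != f)
        n_tun = int(round(tune_fraction * len(outer)))
        tune_idx.append(np.sort(rng.choice(outer, size=n_tun, replace=False)))
    return CVPlan(n_folds=n_folds, fold_of=fold_of, tune_idx=tune_idx, seed=seed)


# ---------------------------------------------------------------------------
# metrics


def mse(y, yhat) -> float:
    """Mean squared error of prediction."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0:
        raise ValueError("empty vectors")
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    return float(np.mean((y - yhat) ** 2))


def maape(y, yhat) -> float:
    """Mean arctangent absolute percentage error, bounded in [0, pi/2].

    Terms with y = 0 contribute 0 when the prediction is also 0 and pi/2
    otherwise (the bounded limit of arctan |relative error|).
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0:
        raise ValueError("empty vectors")
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    if np.any(y < 0):
        raise ValueError("observed counts must be >= 0")
    terms = np.empty_like(y)
    zero = y == 0
    terms[zero] = np.where(yhat[zero] == 0, 0.0, np.pi / 2)
    nz = ~zero
    terms[nz] = np.arctan(np.abs((y[nz] - yhat[nz]) / y[nz]))
    return float(terms.mean())


def apc(y, yhat, env_labels) -> float:
    """Average Pearson correlation across environments.

    The correlation is computed within each environment slice; slices with
    fewer than two observations or zero variance in either vector are
    skipped, and NaN is returned when every slice is degenerate.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    env_labels = np.asarray(env_labels)
    if not y.shape == yhat.shape == env_labels.shape:
        raise ValueError("length mismatch")
    cors = []
    for env in pd.unique(env_labels):
        s = env_labels == env
        ys, ps = y[s], yhat[s]
        if len(ys) < 2 or ys.std() == 0 or ps.std() == 0:
            continue
        cors.append(float(np.corrcoef(ys, ps)[0, 1]))
    return float(np.mean(cors)) if cors else float("nan")


_METRICS = {"mse": mse, "maape": maape, "apc": apc}


def bootstrap_se(y, yhat, metric: str, n_boot: int = 500, seed: int = 0, env_labels=None) -> float:
    """Bootstrap standard error of a metric over (y, yhat) pair resamples.

    For APC the resampling is stratified within environments so every
    resample retains the per-environment structure.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    fn = _METRICS[metric]
    vals = np.empty(n_boot)
    if metric == "apc":
        if env_labels is None:
            raise ValueError("apc bootstrap requires env_labels")
        env_labels = np.asarray(env_labels)
        strata = [np.flatnonzero(env_labels == e) for e in pd.unique(env_labels)]
        for b in range(n_boot):
            idx = np.concatenate([rng.choice(s, size=len(s), replace=True) for s in strata])
            vals[b] = fn(y[idx], yhat[idx], env_labels[idx])
        vals = vals[~np.isnan(vals)]
        if vals.size < 2:
            return float("nan")
    else:
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            vals[b] = fn(y[idx], yhat[idx])
    return float(np.std(vals, ddof=1))


# ---------------------------------------------------------------------------
# summaries


def average_across_traits(per_trait_values) -> float:
    """Arithmetic mean of per-trait metric values (the table 'Average' row)."""
    v = np.asarray(per_trait_values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one trait value")
    return float(v.mean())


def percent_superiority(worst: float, best: float) -> float:
    """Percent by which the best (smaller-is-better) value beats the worst:
    (worst - best) * 100 / best."""
    if best <= 0:
        raise ValueError("best value must be > 0")
    return (worst - best) * 100.0 / best


# ---------------------------------------------------------------------------
# hyper-parameter grids


@dataclass
class GridSpec:
    """Candidate lists and fixed settings for the deep-network grid search."""

    units: tuple = (64,)
    l1_lambda: tuple = (0.001, 0.01)
    dropout: tuple = (0.0,)
    batch_size: int = 32
    learning_rate: float = 0.001
    max_epochs: int = 1000
    patience: int = 50
    validation_fraction: float = 0.2
    depths: tuple = (1, 2, 3, 4)

    def __post_init__(self):
        for name in ("units", "l1_lambda", "dropout", "depths"):
            val = getattr(self, name)
            if np.isscalar(val):
                val = (val,)
            setattr(self, name, tuple(val))
            if len(getattr(self, name)) < 1:
                raise ValueError(f"{name} needs at least one candidate")

    def combinations(self):
        """Grid order: units outer, then l1, then dropout."""
        return [
            {"units": u, "l1_lambda": l1, "dropout": dr}
            for u, l1, dr in itertools.product(self.units, self.l1_lambda, self.dropout)
        ]


#: tuning grid used for the smaller benchmark data set: 5 unit counts x 2
#: lasso penalties = 10 combinations per depth, batches of 273, no dropout
DATASET1_GRID = GridSpec(
    units=(120, 160, 200, 240, 280), l1_lambda=(0.001, 0.01), dropout=(0.0,),
    batch_size=273, learning_rate=0.001, max_epochs=1000,
)

#: tuning grid for the larger benchmark data set: 4 x 2 x 2 = 16 combinations
DATASET2_GRID = GridSpec(
    units=(400, 600, 800, 1000), l1_lambda=(0.001, 0.01), dropout=(0.0, 0.05),
    batch_size=500, learning_rate=0.001, max_epochs=1000,
)


def grid_search(model_family: str, depth: int, grid: GridSpec, trn, tun, seed: int = 0):
    """Scan the hyper-parameter grid for one network depth.

    Every combination is trained on TRN (with its internal validation split
    and early stopping) and scored by MSE on TUN — averaged over traits for
    the multivariate family.  The best combination (ties: first in grid
    order) is refitted on TRN + TUN.

    Returns ``(best_combo, refit_network, scoreboard)``.
    """
    if model_family not in ("mpdn", "updn"):
        raise ValueError("model_family must be 'mpdn' or 'updn'")
    if depth not in (1, 2, 3, 4):
        raise ValueError("depth must be in {1, 2, 3, 4}")
    X_trn, Y_trn = trn
    X_tun, Y_tun = tun
    Y_trn = np.atleast_2d(np.asarray(Y_trn, dtype=float).T).T
    Y_tun = np.atleast_2d(np.asarray(Y_tun, dtype=float).T).T
    T = Y_trn.shape[1]
    if model_family == "updn" and T != 1:
        raise ValueError("univariate family takes a single trait column")

    combos = grid.combinations()
    rows = []
    best_score, best_combo = np.inf, None
    for k, combo in enumerate(combos):
        spec = NetworkSpec(
            n_hidden=depth, units=combo["units"], n_outputs=T,
            dropout_rate=combo["dropout"], l1_lambda=combo["l1_lambda"],
        )
        cfg = TrainConfig(
            batch_size=grid.batch_size, learning_rate=grid.learning_rate,
            max_epochs=grid.max_epochs, early_stopping_patience=grid.patience,
            validation_fraction=grid.validation_fraction,
            seed=_child_seed(seed, k),
        )
        net = train(spec, X_trn, Y_trn, cfg)
        score = float(np.mean((net.predict(X_tun) - Y_tun) ** 2))
        rows.append({**combo, "tun_mse": score})
        if score < best_score:  # strict: ties keep the earlier combination
            best_score, best_combo = score, combo
    if best_combo is None or not np.isfinite(best_score):
        raise RuntimeError("every grid candidate diverged; scoreboard: " + repr(rows))

    spec = NetworkSpec(
        n_hidden=depth, units=best_combo["units"], n_outputs=T,
        dropout_rate=best_combo["dropout"], l1_lambda=best_combo["l1_lambda"],
    )
    cfg = TrainConfig(
        batch_size=grid.batch_size, learning_rate=grid.learning_rate,
        max_epochs=grid.max_epochs, early_stopping_patience=grid.patience,
        validation_fraction=grid.validation_fraction,
        seed=_child_seed(seed, len(combos)),
    )
    X_all = np.concatenate([X_trn, X_tun])
    Y_all = np.concatenate([Y_trn, Y_tun])
    refit = train(spec, X_all, Y_all, cfg)
    return best_combo, refit, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# roster runner


@dataclass
class MetricReport:
    """Per-model, per-trait prediction metrics with bootstrap SEs.

    ``table`` mirrors the standard report layout: one row per (model,
    trait) plus an 'Average' row per model with across-trait means.
    ``provenance`` records, per (model, fold), exactly which observation
    rows were fitted on and which were predicted — the no-leakage audit
    trail.
    """

    table: pd.DataFrame
    metadata: dict
    provenance: list = field(default_factory=list)

    def validate(self) -> None:
        t = self.table
        per_trait = t[t["Trait"] != "Average"]
        assert (per_trait["MSE"].dropna() >= 0).all()
        m = per_trait["MAAPE"].dropna()
        assert ((m >= 0) & (m <= np.pi / 2 + 1e-12)).all()
        a = per_trait["APC"].dropna()
        assert ((a >= -1 - 1e-12) & (a <= 1 + 1e-12)).all()
        for model, grp in per_trait.groupby("Model"):
            avg = t[(t["Model"] == model) & (t["Trait"] == "Average")]
            for col in ("MSE", "MAAPE", "APC"):
                expected = np.mean(grp[col].to_numpy())  # NaN propagates
                assert np.isclose(avg[col].iloc[0], expected, equal_nan=True)

    def check_no_leakage(self) -> None:
        """Assert no model's predictions used its own test rows in fitting."""
        if not self.provenance:
            raise AssertionError("no provenance records to audit")
        for rec in self.provenance:
            overlap = set(rec["fit_rows"]) & set(rec["test_rows"])
            if overlap:
                raise AssertionError(
                    f"leakage: model {rec['model']} fold {rec['fold']} "
                    f"fitted on test rows {sorted(overlap)[:5]}"
                )

    def averages(self) -> pd.DataFrame:
        return self.table[self.table["Trait"] == "Average"].reset_index(drop=True)

    def superiority_matrix(self, metric: str = "MSE") -> pd.DataFrame:
        """Pairwise percent superiority of column model over row model."""
        avg = self.averages().set_index("Model")[metric]
        out = pd.DataFrame(index=avg.index, columns=avg.index, dtype=float)
        for worse in avg.index:
            for better in avg.index:
                if avg[better] > 0:
                    out.loc[worse, better] = percent_superiority(avg[worse], avg[better])
        return out

    def to_csv(self, path) -> None:
        """Write the table rounded to 3 decimals (full precision stays in memory)."""
        out = self.table.copy()
        for col in out.columns[3:]:
            out[col] = out[col].round(3)
        out.to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json

        payload = {
            "metadata": {k: v for k, v in self.metadata.items()},
            "table": self.table.to_dict(orient="records"),
            "averages": self.averages().to_dict(orient="records"),
            "superiority_mse": self.superiority_matrix("MSE").to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, default=float)


def _model_depth(name: str) -> int:
    return int(name.split("_")[1])


def run_roster(
    ph: PhenotypeTable,
    markers,
    interaction: bool = False,
    roster=ROSTER,
    cv: CVPlan | None = None,
    grids: GridSpec | None = None,
    seed: int = 0,
    gpr_config: GPRConfig | None = None,
    n_boot: int = 500,
) -> MetricReport:
    """Run the full evaluation protocol for a roster of models.

    Univariate models (UPDN_*, GPR_*) are fitted once per trait; the
    multivariate networks (MPDN_*) fit all traits jointly.  Metrics are
    computed on each fold's test set and averaged over folds; bootstrap SEs
    are the mean over folds of per-fold bootstrap SEs.
    """
    roster = list(roster)
    if not roster:
        raise ValueError("empty model roster")
    bad = [m for m in roster if m not in ROSTER]
    if bad:
        raise ValueError(f"unknown model(s) {bad}; valid models: {list(ROSTER)}")

    grids = grids or GridSpec()
    design, traits = build_design(ph, markers, include_interaction=interaction)
    X, Y = design.X, traits.Y.astype(float)
    envs = design.env_labels()
    T = traits.n_traits
    trait_names = list(traits.trait_names)
    cv = cv or make_cv_plan(ph, seed=seed)

    records = []  # (model, fold, trait, metric values)
    provenance = []
    for f in range(cv.n_folds):
        trn, tun, tst = cv.train_idx(f), cv.tune_idx[f], cv.test_idx(f)
        outer = cv.outer_train_idx(f)
        for mi, model in enumerate(roster):
            logger.info("fold %d model %s: fitting", f, model)
            mseed = _child_seed(seed, f, mi)
            if model.startswith("GPR"):
                pred = np.empty((len(tst), T))
                for t in range(T):
                    cfg = GPRConfig(
                        alpha=GPR_ALPHAS[model],
                        **(
                            {
                                "n_lambda": gpr_config.n_lambda,
                                "n_inner_folds": gpr_config.n_inner_folds,
                                "max_iter": gpr_config.max_iter,
                                "tol": gpr_config.tol,
                            }
                            if gpr_config is not None
                            else {}
                        ),
                    )
                    res = PoissonElasticNet(Y[outer, t], X[outer], cfg).fit(
                        seed=_child_seed(mseed, t)
                    )
                    pred[:, t] = res.predict(X[tst])
                fit_rows = outer
            elif model.startswith(("UPDN", "MPDN")):
                depth = _model_depth(model)
                if model.startswith("MPDN"):
                    _, net, _ = grid_search(
                        "mpdn", depth, grids, (X[trn], Y[trn]), (X[tun], Y[tun]),
                        seed=mseed,
                    )
                    pred = net.predict(X[tst])
                else:
                    pred = np.empty((len(tst), T))
                    for t in range(T):
                        _, net, _ = grid_search(
                            "updn", depth, grids,
                            (X[trn], Y[trn, t : t + 1]), (X[tun], Y[tun, t : t + 1]),
                            seed=_child_seed(mseed, t),
                        )
                        pred[:, t] = net.predict(X[tst])[:, 0]
                fit_rows = outer
            provenance.append(
                {"model": model, "fold": f, "fit_rows": fit_rows.tolist(), "test_rows": tst.tolist()}
            )
            env_tst = envs[tst]
            for t in range(T):
                y_t, p_t = Y[tst, t], pred[:, t]
                bseed = _child_seed(seed, f, mi, t)
                records.append({
                    "Model": model, "fold": f, "Trait": trait_names[t],
                    "MSE": mse(y_t, p_t),
                    "SE_1": bootstrap_se(y_t, p_t, "mse", n_boot, bseed),
                    "MAAPE": maape(y_t, p_t),
                    "SE_2": bootstrap_se(y_t, p_t, "maape", n_boot, bseed + 1),
                    "APC": apc(y_t, p_t, env_tst),
                    "SE_3": bootstrap_se(y_t, p_t, "apc", n_boot, bseed + 2, env_labels=env_tst),
                })

    folds_df = pd.DataFrame(records)
    rows = []
    metric_cols = ["MSE", "SE_1", "MAAPE", "SE_2", "APC", "SE_3"]
    inter_label = "I" if interaction else "WI"
    for model in roster:
        per_trait = []
        for t in trait_names:
            sub = folds_df[(folds_df["Model"] == model) & (folds_df["Trait"] == t)]
            vals = {c: float(np.nanmean(sub[c])) for c in metric_cols}
            rows.append({"Model": model, "Interaction": inter_label, "Trait": t, **vals})
            per_trait.append(vals)
        avg = {c: average_across_traits([v[c] for v in per_trait]) for c in metric_cols}
        rows.append({"Model": model, "Interaction": inter_label, "Trait": "Average", **avg})

    report = MetricReport(
        table=pd.DataFrame(rows),
        metadata={
            "interaction": bool(interaction),
            "n_folds": cv.n_folds,
            "seed": seed,
            "n_obs": int(len(Y)),
            "traits": trait_names,
            "roster": roster,
        },
        provenance=provenance,
    )
    report.validate()
    return report
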
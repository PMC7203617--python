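"""Penalized classification with leave-one-participant-out evaluation.

The base classifier is an elastic net: logistic loss with a combined l1+l2
penalty (``loss="linear"`` switches to a least-squares elastic net whose
prediction is thresholded at 0.5).  Plain l1- or l2-penalized logistic
regression is available as ``model_kind="logistic"`` for ablations.
Hyperparameters are chosen by grid search with stratified inner
cross-validation on each training fold; imputation (training-fold column
medians) and standardization (training-fold mean/SD) are fitted strictly
inside each fold.

Significance is assessed with a Monte Carlo shuffle test: group labels are
permuted at the participant level, the full LOPO pipeline is re-run per
permutation, and the add-one p-value (1 + #{null >= observed}) / (B + 1) is
reported together with a convergence check on the running p-value.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.model_selection import StratifiedKFold

LABELS = {"NC": 0, "ASD": 1}

# Table-2 style ablation rows: every non-empty subset of the four families
ABLATION_SUBSETS = [
    ("pat",),
    ("pat", "gaze", "cm", "conf"),
    ("cm",),
    ("conf",),
    ("cm", "conf"),
    ("gaze",),
    ("gaze", "conf"),
    ("gaze", "cm"),
    ("gaze", "cm", "conf"),
    ("pat", "gaze"),
    ("pat", "gaze", "cm"),
    ("pat", "gaze", "conf"),
    ("pat", "cm"),
    ("pat", "conf"),
    ("pat", "cm", "conf"),
]


@dataclass(frozen=True)
class ModelSpec:
    model_kind: str = "elastic_net"  # elastic_net | logistic
    loss: str = "logistic"  # logistic | linear (elastic net only)
    alphas: tuple[float, ...] = (0.01, 0.1, 1.0)  # inverse-C strengths
    l1_ratios: tuple[float, ...] = (0.1, 0.5, 0.9)
    penalties: tuple[str, ...] = ("l1", "l2")  # logistic ablation only
    standardize: bool = True
    inner_folds: int = 5
    max_iter: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in ("elastic_net", "logistic"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if not self.alphas:
            raise ValueError("empty hyperparameter grid")
        if any(not 0 <= r <= 1 for r in self.l1_ratios):
            raise ValueError("l1 mixing ratios must be in [0, 1]")

    def grid(self) -> list[dict]:
        if self.model_kind == "elastic_net":
            return [
                {"alpha": a, "l1_ratio": r}
                for a, r in itertools.product(self.alphas, self.l1_ratios)
            ]
        return [
            {"alpha": a, "penalty": p}
            for a, p in itertools.product(self.alphas, self.penalties)
        ]

    def config(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "loss": self.loss,
            "alphas": list(self.alphas),
            "l1_ratios": list(self.l1_ratios),
            "penalties": list(self.penalties),
            "standardize": self.standardize,
            "inner_folds": self.inner_folds,
            "seed": self.seed,
        }


@dataclass
class EvalResult:
    participants: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    accuracy: float
    confusion: np.ndarray  # rows true (NC, ASD), cols predicted
    p_value: float | None = None
    null_accuracies: np.ndarray | None = None
    shuffle_converged: bool | None = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "participants": list(self.participants),
            "y_true": self.y_true.tolist(),
            "y_pred": self.y_pred.tolist(),
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "config": self.config,
        }
        if self.p_value is not None:
            out["p_value"] = self.p_value
            out["shuffle_converged"] = self.shuffle_converged
            nulls = np.asarray(self.null_accuracies)
            out["null_accuracy_mean"] = float(nulls.mean())
            out["null_accuracy_sd"] = float(nulls.std(ddof=1))
        return out


def _ridge_weights(Xc: np.ndarray, yc: np.ndarray, alpha: float) -> np.ndarray:
    """Ridge solution; dual (n x n) form when the data are wide."""
    n, p = Xc.shape
    if p <= n:
        return np.linalg.solve(Xc.T @ Xc + alpha * np.eye(p), Xc.T @ yc)
    return Xc.T @ np.linalg.solve(Xc @ Xc.T + alpha * np.eye(n), yc)


def _prepare(Xtr: np.ndarray, Xte: np.ndarray, standardize: bool):
    """Training-fold median imputation and standardization."""
    med = np.nanmedian(Xtr, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    Xtr = np.where(np.isnan(Xtr), med, Xtr)
    Xte = np.where(np.isnan(Xte), med, Xte)
    if standardize:
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
    return Xtr, Xte


def _fit_predict_once(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xte: np.ndarray,
    spec: ModelSpec,
    params: dict,
) -> np.ndarray:
    """Fit one configuration and predict labels; tie at 0.5 predicts NC."""
    if spec.model_kind == "elastic_net" and spec.loss == "linear":
        alpha, l1_ratio = params["alpha"], params["l1_ratio"]
        if l1_ratio == 0.0:
            # ridge closed form (intercept via centering, unpenalized)
            ymean = ytr.mean()
            Xmean = Xtr.mean(axis=0)
            Xc = Xtr - Xmean
            yc = ytr - ymean
            w = _ridge_weights(Xc, yc, alpha)
            score = (Xte - Xmean) @ w + ymean
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model = ElasticNet(
                    alpha=alpha, l1_ratio=l1_ratio, max_iter=spec.max_iter
                )
                model.fit(Xtr, ytr)
            score = model.predict(Xte)
        return (score > 0.5).astype(int)
    if spec.model_kind == "elastic_net":
        est = LogisticRegression(
            solver="saga",
            C=1.0 / params["alpha"],
            l1_ratio=params["l1_ratio"],
            max_iter=spec.max_iter,
            tol=1e-3,
        )
    else:
        est = LogisticRegression(
            solver="liblinear" if params["penalty"] == "l1" else "lbfgs",
            l1_ratio=1.0 if params["penalty"] == "l1" else 0.0,
            C=1.0 / params["alpha"],
            max_iter=spec.max_iter,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(Xtr, ytr)
    proba = est.predict_proba(Xte)[:, list(est.classes_).index(1)]
    return (proba > 0.5).astype(int)


def _select_params(
    Xtr: np.ndarray, ytr: np.ndarray, spec: ModelSpec
) -> dict:
    """Inner stratified CV over the grid, maximizing accuracy."""
    grid = spec.grid()
    if len(grid) == 1:
        return grid[0]
    n_min = int(min(np.bincount(ytr)))
    n_splits = max(2, min(spec.inner_folds, n_min))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=spec.seed)
    best, best_acc = grid[0], -1.0
    for params in grid:
        correct = 0
        for tr_idx, va_idx in cv.split(Xtr, ytr):
            a, b = _prepare(Xtr[tr_idx], Xtr[va_idx], spec.standardize)
            pred = _fit_predict_once(a, ytr[tr_idx], b, spec, params)
            correct += int((pred == ytr[va_idx]).sum())
        acc = correct / len(ytr)
        if acc > best_acc:
            best, best_acc = params, acc
    return best


def _encode(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    order = sorted(table.index)
    table = table.loc[order]
    y = table["group"].map(LABELS)
    if y.isna().any():
        raise ValueError("group column must contain only ASD / NC")
    X = table.drop(columns="group").to_numpy(dtype=float)
    return X, y.to_numpy(dtype=int), list(order)


def _lopo_predict(X: np.ndarray, y: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Held-out prediction per participant (the LOPO inner loop)."""
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("need at least 2 participants per class")
    single = spec.grid()[0] if len(spec.grid()) == 1 else None
    fast_ridge = (
        single is not None
        and spec.model_kind == "elastic_net"
        and spec.loss == "linear"
        and single["l1_ratio"] == 0.0
        and not np.isnan(X).any()
    )
    n = len(y)
    y_pred = np.empty_like(y)
    if fast_ridge:
        # tight closed-form loop: impute-free ridge per fold
        alpha = single["alpha"]
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            Xtr = X[mask]
            if spec.standardize:
                mu = Xtr.mean(axis=0)
                sd = Xtr.std(axis=0)
                sd[sd == 0] = 1.0
                Xtr = (Xtr - mu) / sd
                xte = (X[i] - mu) / sd
            else:
                xte = X[i]
            ytr = y[mask]
            ymean = ytr.mean()
            Xm = Xtr.mean(axis=0)
            Xc = Xtr - Xm
            w = _ridge_weights(Xc, ytr - ymean, alpha)
            y_pred[i] = int((xte - Xm) @ w + ymean > 0.5)
        return y_pred
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        params = single or _select_params(X[mask], y[mask], spec)
        Xtr, Xte = _prepare(X[mask], X[[i]], spec.standardize)
        y_pred[i] = _fit_predict_once(Xtr, y[mask], Xte, spec, params)[0]
    return y_pred


def fit_predict_lopo(table: pd.DataFrame, spec: ModelSpec) -> EvalResult:
    """Leave-one-participant-out evaluation of the specified model.

    ``table`` is an assembled feature table: participant index, a ``group``
    label column, numeric features (NaN allowed; imputed per fold).  Results
    are invariant to row order (rows are sorted internally).
    """
    X, y, participants = _encode(table)
    y_pred = _lopo_predict(X, y, spec)
    accuracy = float((y_pred == y).mean())
    confusion = np.zeros((2, 2), dtype=int)
    for t, p in zip(y, y_pred):
        confusion[t, p] += 1
    return EvalResult(
        participants=participants,
        y_true=y,
        y_pred=y_pred,
        accuracy=accuracy,
        confusion=confusion,
        config=spec.config(),
    )


def shuffle_test(
    table: pd.DataFrame,
    spec: ModelSpec,
    B: int = 2500,
    seed: int = 0,
) -> EvalResult:
    """Participant-level label-permutation test of LOPO accuracy.

    Re-runs the full LOPO pipeline under each of ``B`` label permutations;
    p = (1 + #{null accuracy >= observed}) / (B + 1), never exactly zero.
    The convergence flag records whether the running p-value stayed within
    +/-0.01 of its final value over the last half of the iterations.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    observed = fit_predict_lopo(table, spec)
    rng = np.random.default_rng(seed)
    nulls = np.empty(B)
    X, y, _ = _encode(table)
    for b in range(B):
        y_null = rng.permutation(y)
        nulls[b] = float((_lopo_predict(X, y_null, spec) == y_null).mean())
    exceed = nulls >= observed.accuracy - 1e-12
    p = (1 + int(exceed.sum())) / (B + 1)
    running = (1 + np.cumsum(exceed)) / (2 + np.arange(B))
    tail = running[B // 2 :]
    converged = bool(np.all(np.abs(tail - p) <= 0.01))
    observed.p_value = p
    observed.null_accuracies = nulls
    observed.shuffle_converged = converged
    return observed


def ablation_grid(
    table: pd.DataFrame,
    spec: ModelSpec,
    subsets: list[tuple[str, ...]] | None = None,
    trials: list | None = None,
    B: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy (and optionally shuffle p) per feature subset x trial choice.

    The default grid is the full 15-subset x {all, 1, 2, 3} layout.  Set
    ``B > 0`` to add shuffle p-values per cell.
    """
    from gazephen.features import select_columns

    if subsets is None:
        subsets = list(ABLATION_SUBSETS)
    if trials is None:
        trial_cols = sorted(
            {int(c.split("_")[0][1:]) for c in table.columns
             if c != "group" and not c.startswith("pat_")}
        )
        trials = ["all"] + [[t] for t in trial_cols]
    rows = []
    for subset in subsets:
        row: dict = {"features": "-".join(subset)}
        for t in trials:
            sub = select_columns(table, list(subset), t)
            tag = "all" if t == "all" else f"t{t[0] if isinstance(t, list) else t}"
            if sub.shape[1] <= 1:
                row[f"{tag}_accuracy"] = np.nan
                continue
            if B > 0:
                res = shuffle_test(sub, spec, B=B, seed=seed)
                row[f"{tag}_accuracy"] = res.accuracy
                row[f"{tag}_p"] = res.p_value
            else:
                res = fit_predict_lopo(sub, spec)
                row[f"{tag}_accuracy"] = res.accuracy
        rows.append(row)
    return pd.DataFrame(rows).set_index("features")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:12]


def report(
    out_dir,
    grid: pd.DataFrame | None = None,
    eval_result: EvalResult | None = None,
    h1: dict | None = None,
    distraction: pd.DataFrame | None = None,
    seeds: dict | None = None,
) -> dict:
    """Write grid CSV/JSON, evaluation JSON, and diagnostic plots.

    Returns the summary dict that was written to ``report.json``.  Every
    output embeds the config hash and the seeds used.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seeds": seeds or {}}
    if eval_result is not None:
        summary["config_hash"] = config_hash(eval_result.config)
        summary["eval"] = eval_result.to_dict()
        (out / "eval.json").write_text(json.dumps(summary["eval"], indent=1))
        fig, ax = plt.subplots(figsize=(3.2, 3))
        ax.imshow(eval_result.confusion, cmap="Blues")
        for (i, j), v in np.ndenumerate(eval_result.confusion):
            ax.text(j, i, str(v), ha="center", va="center")
        ax.set_xticks([0, 1], ["NC", "ASD"])
        ax.set_yticks([0, 1], ["NC", "ASD"])
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.set_title(f"LOPO accuracy {eval_result.accuracy:.2f}")
        fig.tight_layout()
        fig.savefig(out / "confusion.png", dpi=120)
        plt.close(fig)
        if eval_result.null_accuracies is not None:
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.hist(eval_result.null_accuracies, bins=20, color="0.7")
            ax.axvline(eval_result.accuracy, color="crimson",
                       label=f"observed (p={eval_result.p_value:.3f})")
            ax.set_xlabel("null LOPO accuracy")
            ax.legend()
            fig.tight_layout()
            fig.savefig(out / "shuffle_hist.png", dpi=120)
            plt.close(fig)
    if grid is not None:
        grid.to_csv(out / "grid.csv")
        summary["grid"] = json.loads(grid.to_json(orient="index"))
    if h1 is not None:
        summary["h1"] = h1
        (out / "h1_report.json").write_text(json.dumps(h1, indent=1))
    if distraction is not None and len(distraction):
        fig, ax = plt.subplots(figsize=(4.5, 3))
        d = distraction
        bins = np.logspace(-3, 0, 25)
        for grp, color in (("ASD", "crimson"), ("NC", "steelblue")):
            vals = d.loc[d["group"] == grp, "d"].clip(lower=1e-3)
            ax.hist(vals, bins=bins, alpha=0.5, color=color, label=grp)
        ax.set_xscale("log")
        ax.set_xlabel("distraction ratio d(p,s,t)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "h1_hist.png", dpi=120)
        plt.close(fig)
    (out / "report.json").write_text(json.dumps(
        {k: v for k, v in summary.items() if k != "eval"}, indent=1, default=str
    ))
    return summary
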
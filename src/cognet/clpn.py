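"""Cross-lagged panel network (CLPN) between two waves.

Each wave-2 construct is regressed on *all* wave-1 constructs (its own
baseline included, so every cross-lagged effect is adjusted for
autoregressive stability) with an L1 penalty:

    min_beta  (1/2n) || x2_j - X1 beta ||^2 + lambda ||beta||_1

All columns are standardized before fitting, so the coefficients are
standardized effects and the fit is invariant to rescaling any raw
input column.  The penalty per target is chosen by K-fold
cross-validation (10 folds by default; CV-minimum rule, with the
one-standard-error rule available).  The lasso's exact zeros are the
elimination of small coefficients — no extra threshold is applied by
default.

The resulting coefficient matrix ``B_hat`` (entry i,j = effect of
wave-1 node i on wave-2 node j) is a directed network.  Its signed
expected-influence centralities summarize each node's role: incoming
EI (IEI, how strongly a wave-2 node is predicted by the wave-1 system)
and outgoing EI (OEI, how strongly a wave-1 node predicts the wave-2
system), autoregressive paths excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

from .centrality import expected_influence
from .qc import PairedScores


@dataclass
class DirectedNetwork:
    """Directed cross-lagged coefficient network."""

    labels: list[str]
    B_hat: np.ndarray
    lambdas: dict[str, float] = field(default_factory=dict)
    cv: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.B_hat = np.asarray(self.B_hat, dtype=float)
        p = len(self.labels)
        if self.B_hat.shape != (p, p):
            raise ValueError("B_hat must be p x p")
        if not np.all(np.isfinite(self.B_hat)):
            raise ValueError("B_hat contains non-finite entries")

    @property
    def p(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.B_hat, index=self.labels, columns=self.labels
        )

    def save(self, stem: str | Path) -> None:
        stem = Path(stem)
        self.to_frame().to_csv(stem.with_suffix(".matrix.csv"))
        prediction_table(self).to_csv(
            stem.with_suffix(".predictions.tsv"), sep="\t", index=False
        )
        stem.with_suffix(".meta.json").write_text(json.dumps(
            {"labels": self.labels, "lambdas": self.lambdas,
             "cv": self.cv},
            indent=2, sort_keys=True,
        ))


def _standardize(X: np.ndarray, what: list[str]) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        names = [what[i] for i in zero]
        raise ValueError(f"zero-variance construct(s): {names}")
    return (X - mu) / sd


def _cv_lambda(
    X: np.ndarray,
    y: np.ndarray,
    alphas: np.ndarray,
    folds: int,
    seed: int,
    rule: str,
) -> float:
    """Pick the penalty by K-fold CV (fold split deterministic in the
    seed); 'min' takes the CV-error minimizer, '1se' the sparsest model
    within one standard error of it."""
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    n = len(y)
    mse = np.zeros((folds, len(alphas)))
    for f, (tr, te) in enumerate(kf.split(X)):
        _, coefs, _ = lasso_path(X[tr], y[tr], alphas=alphas)
        pred = X[te] @ coefs  # (n_te, n_alphas)
        mse[f] = ((pred - y[te][:, None]) ** 2).mean(axis=0)
    mean = mse.mean(axis=0)
    i_min = int(np.argmin(mean))
    if rule == "min":
        return float(alphas[i_min])
    if rule == "1se":
        se = mse.std(axis=0, ddof=1) / np.sqrt(folds)
        limit = mean[i_min] + se[i_min]
        # alphas are decreasing: the first (largest) one under the limit
        for i in range(len(alphas)):
            if mean[i] <= limit:
                return float(alphas[i])
        return float(alphas[i_min])
    raise ValueError("lambda_rule must be 'min' or '1se'")


def fit_clpn(
    paired: PairedScores,
    folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "min",
    n_alphas: int = 100,
    alpha_min_ratio: float = 1e-3,
    fixed_alpha: float | None = None,
    extra_threshold: float = 0.0,
) -> DirectedNetwork:
    """Fit the T1 -> T2 cross-lagged network on matched respondents.

    ``fixed_alpha`` bypasses cross-validation (``fixed_alpha=0`` or a
    tiny value recovers the ordinary least-squares coefficients as the
    penalty vanishes).  ``extra_threshold`` optionally zeroes estimated
    coefficients below a magnitude after fitting.
    """
    labels = list(paired.t1.columns)
    n = paired.n_matched
    if fixed_alpha is None and n <= folds:
        raise ValueError(f"need more than {folds} matched rows, got {n}")
    X1 = _standardize(np.asarray(paired.t1, dtype=float), labels)
    X2 = _standardize(np.asarray(paired.t2, dtype=float), labels)
    p = len(labels)
    B_hat = np.zeros((p, p))
    lambdas: dict[str, float] = {}
    child_seeds = [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(seed).spawn(p)
    ]
    for j in range(p):
        y = X2[:, j]
        if fixed_alpha is not None:
            alpha = max(float(fixed_alpha), 1e-12)
        else:
            alpha_max = np.max(np.abs(X1.T @ y)) / n
            alphas = np.exp(np.linspace(
                np.log(alpha_max),
                np.log(alpha_max * alpha_min_ratio),
                n_alphas,
            ))
            alpha = _cv_lambda(
                X1, y, alphas, folds, child_seeds[j], lambda_rule
            )
        model = Lasso(alpha=alpha, fit_intercept=False, max_iter=100000,
                      tol=1e-8)
        model.fit(X1, y)
        B_hat[:, j] = model.coef_
        lambdas[labels[j]] = alpha
    if extra_threshold > 0:
        B_hat[np.abs(B_hat) < extra_threshold] = 0.0
    return DirectedNetwork(
        labels=labels,
        B_hat=B_hat,
        lambdas=lambdas,
        cv={"folds": folds, "rule": lambda_rule, "seed": seed,
            "fixed_alpha": fixed_alpha},
    )


def clpn_centralities(net: DirectedNetwork) -> pd.DataFrame:
    """Incoming and outgoing expected influence per node
    (autoregressive paths excluded)."""
    iei = expected_influence(net.B_hat, net.labels, "in",
                             exclude_self=True)
    oei = expected_influence(net.B_hat, net.labels, "out",
                             exclude_self=True)
    out = pd.DataFrame({"IEI": iei, "OEI": oei})
    out.index.name = "node"
    return out


def prediction_table(net: DirectedNetwork) -> pd.DataFrame:
    """Directed edge list (from, to, weight), zeros omitted, sorted by
    target label then decreasing |weight|; autoregressive rows are
    flagged."""
    rows = []
    for i in range(net.p):
        for j in range(net.p):
            w = net.B_hat[i, j]
            if w != 0.0:
                rows.append({
                    "from": net.labels[i],
                    "to": net.labels[j],
                    "weight": float(w),
                    "autoregressive": i == j,
                })
    df = pd.DataFrame(
        rows, columns=["from", "to", "weight", "autoregressive"]
    )
    if len(df):
        df = df.sort_values(
            by=["to", "weight", "from"],
            key=lambda s: -s.abs() if s.name == "weight" else s,
        ).reset_index(drop=True)
    return df
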
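"""Two-wave synthetic questionnaire data with known network structure.

The generator emulates the data-generating process the downstream
analyses assume: wave-1 construct scores are multivariate normal with a
known sparse precision matrix ``K1`` (so the true contemporaneous
network — the partial-correlation structure — is known exactly), and
wave-2 scores follow a linear cross-lagged transition

    X2 = X1 @ B + E,      E ~ N(0, Sigma_e),

where ``B``'s diagonal carries autoregressive stability and a handful
of planted off-diagonal cross-lags of known sign.  Latent scores are
discretized into item-level Likert responses (linear loading plus
item noise, rounded and clipped into the scale range), and
record-validity violations (failed lie items, missing responses,
too-fast completion) can be injected at known rates, so every screening
and estimation stage has a recoverable ground truth.

Latent scores are on a standardized scale; the networks are fit on
correlations, so absolute scaling is immaterial.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ggm import precision_to_partial
from .qc import PairedScores
from .records import RawRecord
from .scales import CONSTRUCT_ITEMS, CONSTRUCTS, DEFAULT_SCALES

LABELS = list(CONSTRUCTS)

#: Planted wave-1 partial correlations (the true contemporaneous
#: network): a dense positive block among the three rumination facets,
#: a strong depression-anxiety edge, and sparse links elsewhere.
DEFAULT_PARTIALS: dict[tuple[str, str], float] = {
    ("PHQ", "GAD"): 0.35,
    ("PHQ", "SR"): 0.22,
    ("GAD", "NAT"): 0.25,
    ("NA", "NAT"): 0.25,
    ("SR", "BD"): 0.38,
    ("SR", "RP"): 0.32,
    ("BD", "RP"): 0.32,
}

#: Planted cross-lagged effects (T1 construct -> T2 construct) beside
#: the autoregressive diagonal: rumination and automatic thoughts drive
#: later distress, anxiety drives later attentional bias, and
#: reflective pondering is protective against later depression.
DEFAULT_CROSS_LAGS: dict[tuple[str, str], float] = {
    ("SR", "PHQ"): 0.15,
    ("NAT", "GAD"): 0.18,
    ("PHQ", "GAD"): 0.12,
    ("GAD", "NA"): 0.16,
    ("RP", "PHQ"): -0.12,
}

DEFAULT_AUTOREGRESSION = 0.4

#: Per-construct Likert discretization: item = round(clip(
#: loading * z + intercept + noise)).  Intercepts sit at the response
#: midpoint; loadings/noise chosen so construct totals correlate > 0.8
#: with the latent scores and have realistic spread.
DEFAULT_ITEM_MODEL: dict[str, dict[str, float]] = {
    "PHQ": {"loading": 0.7, "intercept": 1.5, "noise_sd": 0.6},
    "GAD": {"loading": 0.7, "intercept": 1.5, "noise_sd": 0.6},
    "SR": {"loading": 0.7, "intercept": 2.5, "noise_sd": 0.6},
    "BD": {"loading": 0.7, "intercept": 2.5, "noise_sd": 0.6},
    "RP": {"loading": 0.7, "intercept": 2.5, "noise_sd": 0.6},
    "NA": {"loading": 0.9, "intercept": 3.0, "noise_sd": 0.7},
    "NAT": {"loading": 0.9, "intercept": 3.0, "noise_sd": 0.7},
}


@dataclass
class GroundTruth:
    """Known generating structure for a two-wave dataset."""

    labels: list[str]
    K1: np.ndarray
    B: np.ndarray
    Sigma_e: np.ndarray
    item_model: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_ITEM_MODEL)
    )

    def __post_init__(self) -> None:
        p = len(self.labels)
        self.K1 = np.asarray(self.K1, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.Sigma_e = np.asarray(self.Sigma_e, dtype=float)
        for name, M in (("K1", self.K1), ("B", self.B),
                        ("Sigma_e", self.Sigma_e)):
            if M.shape != (p, p):
                raise ValueError(f"{name} must be {p}x{p}")
        if not np.allclose(self.K1, self.K1.T):
            raise ValueError("K1 must be symmetric")
        if np.linalg.eigvalsh(self.K1).min() <= 0:
            raise ValueError("K1 must be positive definite")
        if np.linalg.eigvalsh(self.implied_t2_cov()).min() <= 0:
            raise ValueError("implied T2 covariance is not PD")

    @property
    def p(self) -> int:
        return len(self.labels)

    def sigma1(self) -> np.ndarray:
        """Wave-1 covariance, the inverse of the precision matrix."""
        return np.linalg.inv(self.K1)

    def partial_corr1(self) -> np.ndarray:
        """True wave-1 partial-correlation (network) matrix."""
        return precision_to_partial(self.K1)

    def implied_t2_cov(self) -> np.ndarray:
        return self.B.T @ np.linalg.inv(self.K1) @ self.B + self.Sigma_e

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "labels": self.labels,
            "K1": self.K1.tolist(),
            "B": self.B.tolist(),
            "Sigma_e": self.Sigma_e.tolist(),
            "item_model": self.item_model,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            labels=list(d["labels"]),
            K1=np.array(d["K1"]),
            B=np.array(d["B"]),
            Sigma_e=np.array(d["Sigma_e"]),
            item_model=d.get("item_model", DEFAULT_ITEM_MODEL),
        )


def make_default_truth(seed: int = 0) -> GroundTruth:
    """The documented default ground truth.

    The structure is fixed (the seed argument is accepted for API
    symmetry with the sampling functions and does not alter it): unit
    precision diagonal with the planted partial correlations of
    ``DEFAULT_PARTIALS``, autoregressive transition diagonal 0.4 with
    the cross-lags of ``DEFAULT_CROSS_LAGS``, and diagonal residual
    covariance 0.5 I.
    """
    p = len(LABELS)
    ix = {lab: i for i, lab in enumerate(LABELS)}
    K1 = np.eye(p)
    for (a, b), rho in DEFAULT_PARTIALS.items():
        K1[ix[a], ix[b]] = K1[ix[b], ix[a]] = -rho
    B = np.zeros((p, p))
    np.fill_diagonal(B, DEFAULT_AUTOREGRESSION)
    for (a, b), beta in DEFAULT_CROSS_LAGS.items():
        B[ix[a], ix[b]] = beta
    return GroundTruth(
        labels=list(LABELS),
        K1=K1,
        B=B,
        Sigma_e=0.5 * np.eye(p),
    )


def sample_two_wave(
    truth: GroundTruth, n: int, seed: int = 0
) -> PairedScores:
    """Draw n respondents' latent continuous scores at both waves."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    L1 = np.linalg.cholesky(truth.sigma1())
    Le = np.linalg.cholesky(truth.Sigma_e)
    X1 = rng.standard_normal((n, truth.p)) @ L1.T
    X2 = X1 @ truth.B + rng.standard_normal((n, truth.p)) @ Le.T
    codes = [f"S{i + 1:06d}" for i in range(n)]
    t1 = pd.DataFrame(X1, index=codes, columns=truth.labels)
    t2 = pd.DataFrame(X2, index=codes, columns=truth.labels)
    t1.index.name = t2.index.name = "code"
    return PairedScores(t1=t1, t2=t2, n_t1_only=0, n_t2_only=0)


def discretize_to_items(
    latent: pd.DataFrame,
    wave: str,
    seed: int = 0,
    item_model: dict[str, dict[str, float]] | None = None,
) -> list[RawRecord]:
    """Turn one wave's latent construct scores into item-level records.

    Each item of a construct's scale is ``round(clip(loading * z +
    intercept + noise))`` into the scale's response range.  Validity
    fields are filled with clean values (correct lie items, plausible
    response times, ages 18-24, complete demographics).
    """
    if item_model is None:
        item_model = DEFAULT_ITEM_MODEL
    missing = [c for c in latent.columns if c not in CONSTRUCT_ITEMS]
    if missing:
        raise ValueError(f"unknown construct columns: {missing}")
    rng = np.random.default_rng(seed)
    n = len(latent)
    records: list[RawRecord] = []
    # Pre-draw per-record validity fields.
    ages = rng.integers(18, 25, size=n)
    grades = rng.integers(1, 5, size=n)
    rts = 480 + rng.gamma(shape=2.0, scale=150.0, size=n)
    sexes = rng.choice(["female", "male"], size=n)
    residences = rng.choice(["urban", "rural"], size=n)
    for r_idx, (code, row) in enumerate(latent.iterrows()):
        responses: dict[str, list[int | None]] = {
            s.name: [None] * s.n_items for s in DEFAULT_SCALES
        }
        for construct in latent.columns:
            scale, items = CONSTRUCT_ITEMS[construct]
            pars = item_model[construct]
            z = float(row[construct])
            raw = (
                pars["loading"] * z
                + pars["intercept"]
                + rng.normal(0.0, pars["noise_sd"], size=len(items))
            )
            vals = np.clip(
                np.rint(raw), scale.response_min, scale.response_max
            ).astype(int)
            for item_idx, v in zip(items, vals):
                responses[scale.name][item_idx - 1] = int(v)
        records.append(RawRecord(
            code=str(code),
            wave=wave,
            responses=responses,
            response_time_s=float(rts[r_idx]),
            lie_ok=True,
            age=float(ages[r_idx]),
            grade=int(grades[r_idx]),
            demographics={
                "sex": str(sexes[r_idx]),
                "residence": str(residences[r_idx]),
            },
        ))
    return records


def inject_qc_violations(
    records: list[RawRecord],
    rates: dict[str, float],
    seed: int = 0,
) -> tuple[list[RawRecord], dict[str, list[str]]]:
    """Corrupt records with screening violations at given rates.

    ``rates`` maps reason -> independent per-record probability for the
    reasons ``lie`` (flip the lie-item flag), ``missing`` (blank one
    random item), ``fast`` (set response time under 480 s),
    ``demographic`` (blank one demographic field) and ``dropout``
    (remove the record entirely).  Returns the modified copies and a
    ledger mapping respondent code -> injected reasons, for test
    assertions against the screening report.
    """
    known = {"lie", "missing", "fast", "demographic", "dropout"}
    unknown = set(rates) - known
    if unknown:
        raise ValueError(f"unknown violation kinds: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out: list[RawRecord] = []
    ledger: dict[str, list[str]] = {}
    for rec in records:
        if rng.random() < rates.get("dropout", 0.0):
            ledger.setdefault(rec.code, []).append("dropout")
            continue
        rec = copy.deepcopy(rec)
        if rng.random() < rates.get("lie", 0.0):
            rec.lie_ok = False
            ledger.setdefault(rec.code, []).append("lie")
        if rng.random() < rates.get("missing", 0.0):
            scale = rec.responses[
                list(rec.responses)[rng.integers(len(rec.responses))]
            ]
            scale[rng.integers(len(scale))] = None
            ledger.setdefault(rec.code, []).append("missing")
        if rng.random() < rates.get("fast", 0.0):
            rec.response_time_s = float(rng.uniform(60.0, 479.0))
            ledger.setdefault(rec.code, []).append("fast")
        if rng.random() < rates.get("demographic", 0.0) and rec.demographics:
            key = list(rec.demographics)[
                rng.integers(len(rec.demographics))
            ]
            rec.demographics[key] = None
            ledger.setdefault(rec.code, []).append("demographic")
        out.append(rec)
    return out, ledger


def simulate_study(
    truth: GroundTruth,
    n: int,
    seed: int = 0,
    violation_rates: dict[str, float] | None = None,
    t2_dropout: float = 0.0,
) -> tuple[list[RawRecord], list[RawRecord], dict]:
    """Convenience wrapper: latent scores -> item records for both
    waves, with optional violations and wave-2 attrition.

    Returns (t1_records, t2_records, ledger) where the ledger maps
    ``wave -> code -> reasons``.
    """
    ss = np.random.SeedSequence(seed).spawn(5)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss]
    latent = sample_two_wave(truth, n, seed=seeds[0])
    t1 = discretize_to_items(latent.t1, "T1", seed=seeds[1],
                             item_model=truth.item_model)
    t2 = discretize_to_items(latent.t2, "T2", seed=seeds[2],
                             item_model=truth.item_model)
    rates = dict(violation_rates or {})
    t2_rates = dict(rates)
    if t2_dropout:
        t2_rates["dropout"] = t2_dropout
    t1, ledger1 = inject_qc_violations(t1, rates, seed=seeds[3])
    t2, ledger2 = inject_qc_violations(t2, t2_rates, seed=seeds[4])
    return t1, t2, {"T1": ledger1, "T2": ledger2}
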
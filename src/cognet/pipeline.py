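"""End-to-end study workflow on synthetic two-wave data.

Stages: simulate -> screen (QC) -> score & match -> descriptives ->
estimate T1/T2 networks -> centrality -> bootstrap accuracy/stability
-> permutation comparison -> cross-lagged network -> summary report.

A run is fully determined by its configuration and master seed: the
master seed spawns one child seed per stage (in the fixed order of
``STAGES``) via ``numpy.random.SeedSequence.spawn``, and the summary
JSON of two runs with the same config is byte-identical.  Stage
timings go to ``run.log`` only, so they never perturb the summary.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centrality import centrality_table
from .clpn import clpn_centralities, fit_clpn
from .comparison import global_strength, nct
from .descriptives import compare_waves, prevalence
from .ggm import EstimatorConfig, estimate_network
from .qc import PairedScores, QCConfig, apply_qc, match_waves
from .records import write_records_csv
from .resampling import bootstrap_edges, case_drop_cs
from .synthetic import GroundTruth, make_default_truth, simulate_study

STAGES = (
    "simulate", "qc", "score", "descriptives", "estimate",
    "centrality", "bootstrap", "compare", "clpn",
)


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    n: int = 800
    seed: int = 0
    truth_path: str | None = None
    violation_rates: dict[str, float] = field(
        default_factory=lambda: {"lie": 0.03, "missing": 0.05,
                                 "fast": 0.03, "demographic": 0.02}
    )
    t2_dropout: float = 0.1
    qc: dict = field(default_factory=dict)
    prevalence_cutoffs: dict[str, float] = field(
        default_factory=lambda: {"PHQ": 10.0, "GAD": 10.0}
    )
    gamma: float = 0.5
    path_size: int = 100
    bootstrap_B: int = 1000
    cs_B: int = 250
    cs_centralities: tuple[str, ...] = ("strength",)
    n_perm: int = 1000
    folds: int = 10
    lambda_rule: str = "min"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cs_centralities"] = list(self.cs_centralities)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cs_centralities" in d:
            d["cs_centralities"] = tuple(d["cs_centralities"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain on disk."""

    def __init__(self, stage: str, cause: Exception) -> None:
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(STAGES))
    return {
        stage: int(c.generate_state(1)[0] % 2**31)
        for stage, c in zip(STAGES, children)
    }


def _scores_long(paired: PairedScores) -> pd.DataFrame:
    t1 = paired.t1.copy()
    t1.insert(0, "wave", "T1")
    t2 = paired.t2.copy()
    t2.insert(0, "wave", "T2")
    return pd.concat([t1, t2]).rename_axis("code").reset_index()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full workflow; returns the summary dict.

    All artifacts are written under ``outdir``; any stage failure
    raises :class:`StageError` naming the stage, leaving the artifacts
    of completed stages in place.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    log_lines: list[str] = []
    summary: dict = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "version": __version__,
    }

    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - report stage context
            log_lines.append(f"{name}: FAILED ({exc})")
            (out / "run.log").write_text("\n".join(log_lines) + "\n")
            raise StageError(name, exc) from exc
        log_lines.append(
            f"{name}: ok ({time.perf_counter() - t0:.2f}s, "
            f"seed={seeds[name]})"
        )
        return result

    # -- simulate ------------------------------------------------------
    def _simulate():
        if config.truth_path:
            truth = GroundTruth.from_json(config.truth_path)
        else:
            truth = make_default_truth()
        truth.to_json(out / "truth.json")
        t1, t2, ledger = simulate_study(
            truth, config.n, seed=seeds["simulate"],
            violation_rates=config.violation_rates,
            t2_dropout=config.t2_dropout,
        )
        write_records_csv(t1, out / "t1_records.csv")
        write_records_csv(t2, out / "t2_records.csv")
        return truth, t1, t2

    truth, t1_records, t2_records = run_stage("simulate", _simulate)

    # -- qc ------------------------------------------------------------
    def _qc():
        qc_config = QCConfig(**config.qc) if config.qc else QCConfig()
        kept1, rep1 = apply_qc(t1_records, qc_config)
        kept2, rep2 = apply_qc(t2_records, qc_config)
        (out / "qc_t1.json").write_text(
            json.dumps(rep1.to_dict(), indent=2, sort_keys=True))
        (out / "qc_t2.json").write_text(
            json.dumps(rep2.to_dict(), indent=2, sort_keys=True))
        return kept1, kept2, rep1, rep2

    kept1, kept2, rep1, rep2 = run_stage("qc", _qc)
    summary["qc"] = {
        "T1": {"n_input": rep1.n_input, "n_retained": rep1.n_retained,
               "exclusions": rep1.exclusions},
        "T2": {"n_input": rep2.n_input, "n_retained": rep2.n_retained,
               "exclusions": rep2.exclusions},
    }

    # -- score & match -------------------------------------------------
    def _score():
        paired = match_waves(kept1, kept2)
        _scores_long(paired).to_csv(out / "scores.csv", index=False)
        return paired

    paired = run_stage("score", _score)
    summary["matched"] = {
        "n_matched": paired.n_matched,
        "n_t1_only": paired.n_t1_only,
        "n_t2_only": paired.n_t2_only,
    }

    # -- descriptives --------------------------------------------------
    def _descriptives():
        tests = compare_waves(paired)
        tests.to_csv(out / "paired_tests.csv")
        prev = {
            wave: {
                c: prevalence(scores, c, cut)
                for c, cut in config.prevalence_cutoffs.items()
            }
            for wave, scores in (("T1", paired.t1), ("T2", paired.t2))
        }
        (out / "prevalence.json").write_text(
            json.dumps(prev, indent=2, sort_keys=True))
        return tests, prev

    tests, prev = run_stage("descriptives", _descriptives)
    summary["prevalence"] = prev
    summary["paired_tests"] = {
        c: {"t": round(tests.loc[c, "t"], 6),
            "p": round(tests.loc[c, "p"], 6)}
        for c in tests.index
        if not tests.loc[c, "degenerate"]
    }

    # -- estimate ------------------------------------------------------
    def _estimate():
        net1 = estimate_network(paired.t1, gamma=config.gamma,
                                path_size=config.path_size)
        net2 = estimate_network(paired.t2, gamma=config.gamma,
                                path_size=config.path_size)
        net1.save(out / "network_t1")
        net2.save(out / "network_t2")
        return net1, net2

    net1, net2 = run_stage("estimate", _estimate)
    summary["networks"] = {
        wave: {"n_edges": net.n_edges, "density": round(net.density, 6),
               "global_strength": round(global_strength(net), 6)}
        for wave, net in (("T1", net1), ("T2", net2))
    }

    # -- centrality ----------------------------------------------------
    def _centrality():
        c1 = centrality_table(net1)
        c2 = centrality_table(net2)
        c1.to_csv(out / "centrality_t1.csv")
        c2.to_csv(out / "centrality_t2.csv")
        return c1, c2

    c1, c2 = run_stage("centrality", _centrality)
    summary["strongest_node"] = {
        "T1": c1["strength"].idxmax(), "T2": c2["strength"].idxmax(),
    }

    estimator = EstimatorConfig(gamma=config.gamma,
                                path_size=config.path_size)

    # -- bootstrap -----------------------------------------------------
    if config.bootstrap_B > 0:
        def _bootstrap():
            ss = np.random.SeedSequence(seeds["bootstrap"]).spawn(
                1 + len(config.cs_centralities))
            child = [int(s.generate_state(1)[0] % 2**31) for s in ss]
            edge_res = bootstrap_edges(
                paired.t1, estimator, B=config.bootstrap_B,
                seed=child[0])
            edge_res.edge_ci.to_csv(
                out / "bootstrap_t1_edges.csv", index=False)
            cs: dict[str, float] = {}
            curves = []
            for k, cen in enumerate(config.cs_centralities):
                res = case_drop_cs(
                    paired.t1, estimator, centrality=cen,
                    B=config.cs_B, seed=child[1 + k])
                cs.update(res.cs)
                c = res.curves.copy()
                c.insert(0, "centrality", cen)
                curves.append(c)
            pd.concat(curves).to_csv(
                out / "stability_curves_t1.csv", index=False)
            (out / "stability_t1.json").write_text(
                json.dumps(cs, indent=2, sort_keys=True))
            return cs

        summary["cs"] = run_stage("bootstrap", _bootstrap)
    else:
        log_lines.append("bootstrap: skipped (bootstrap_B=0)")
        summary["cs"] = None

    # -- compare -------------------------------------------------------
    if config.n_perm > 0:
        def _compare():
            res = nct(paired.t1, paired.t2, design="paired",
                      n_perm=config.n_perm, seed=seeds["compare"],
                      config=estimator, keep_networks=False)
            res.save(out / "nct")
            return res

        nct_res = run_stage("compare", _compare)
        summary["comparison"] = nct_res.to_dict()
    else:
        log_lines.append("compare: skipped (n_perm=0)")
        summary["comparison"] = {"skipped": True, "reason": "n_perm=0"}

    # -- clpn ----------------------------------------------------------
    def _clpn():
        dirnet = fit_clpn(paired, folds=config.folds,
                          seed=seeds["clpn"],
                          lambda_rule=config.lambda_rule)
        dirnet.save(out / "clpn")
        cents = clpn_centralities(dirnet)
        cents.to_csv(out / "clpn_centrality.csv")
        return dirnet, cents

    dirnet, clpn_cents = run_stage("clpn", _clpn)
    summary["clpn"] = {
        "n_cross_lags": int(np.sum(
            (dirnet.B_hat != 0)
            & ~np.eye(dirnet.p, dtype=bool))),
        "top_iei": clpn_cents["IEI"].idxmax(),
        "top_oei": clpn_cents["OEI"].idxmax(),
    }

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    (out / "report.md").write_text(_render_report(summary))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def _render_report(summary: dict) -> str:
    lines = ["# Two-wave network analysis report", ""]
    qc = summary["qc"]
    lines += [
        "## Sample",
        f"- T1: {qc['T1']['n_retained']}/{qc['T1']['n_input']} retained "
        f"(excluded: {qc['T1']['exclusions']})",
        f"- T2: {qc['T2']['n_retained']}/{qc['T2']['n_input']} retained "
        f"(excluded: {qc['T2']['exclusions']})",
        f"- matched across waves: {summary['matched']['n_matched']}",
        "",
        "## Contemporaneous networks",
    ]
    for wave in ("T1", "T2"):
        net = summary["networks"][wave]
        lines.append(
            f"- {wave}: {net['n_edges']} edges "
            f"(density {net['density']:.2f}), global strength "
            f"{net['global_strength']:.3f}; strongest node "
            f"{summary['strongest_node'][wave]}"
        )
    if summary.get("cs"):
        lines += ["", "## Stability"]
        for cen, value in summary["cs"].items():
            lines.append(f"- CS({cen}) = {value}")
    comp = summary.get("comparison") or {}
    lines += ["", "## Network comparison"]
    if comp.get("skipped"):
        lines.append("- skipped (n_perm=0)")
    else:
        lines.append(
            f"- global strength difference {comp['gs_diff']:.3f} "
            f"(p = {comp['gs_p']:.3f}); max edge difference "
            f"{comp['omnibus_stat']:.3f} (p = {comp['omnibus_p']:.3f})"
        )
    lines += [
        "", "## Cross-lagged network",
        f"- {summary['clpn']['n_cross_lags']} nonzero cross-lagged "
        f"paths; highest incoming influence: "
        f"{summary['clpn']['top_iei']}; highest outgoing influence: "
        f"{summary['clpn']['top_oei']}",
        "",
    ]
    return "\n".join(lines)
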
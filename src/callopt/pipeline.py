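"""End-to-end study pipeline.

Reconstruct replicate vessels from the packaged treatment table, fit and
compare the three surrogates on each output, rank hormone importance by
VSR with the best surrogate, and run the GA on a full-data surrogate of
each output.  Results go to a JSON report (canonical) and a plain-text
rendering shaped like the study's comparison/sensitivity/optimum tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from . import __version__, dataset, synthetic
from .dataset import HORMONES
from .ga import GAConfig
from .model import CallogenesisModel
from .models import compare_models

log = logging.getLogger("callopt")


@dataclass
class PipelineConfig:
    """One seed fans out to the reconstruction, split, training and GA."""

    seed: int = 0
    n_reps: int = 7
    ratio: float = 0.8
    k_folds: int = 5
    vsr_scheme: str = "error_ratio"
    vsr_model: str | None = None  # None: best model by test R2
    ga: GAConfig = field(default_factory=GAConfig)
    treatments_csv: str | None = None  # None: packaged fixture
    out_dir: str = "callopt_report"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ga = GAConfig(**raw.pop("ga", {}))
        return cls(ga=ga, **raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def validation_comparison(ga_prediction: float, lab_mean: float, lab_se: float,
                          n: int = 7) -> dict:
    """One-sample check of externally supplied lab results against a GA optimum.

    The laboratory mean/SE are inputs, never computed here.  A two-sided
    t-test asks whether the lab mean differs from the GA-predicted value.
    """
    t = (lab_mean - ga_prediction) / lab_se
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return {
        "ga_prediction": ga_prediction,
        "lab_mean": lab_mean,
        "lab_se": lab_se,
        "n": n,
        "t": float(t),
        "p_value": float(p),
        "significant_at_0.05": bool(p < 0.05),
    }


def run_pipeline(config: PipelineConfig | None = None,
                 lab_results: dict | None = None) -> dict:
    """Run modelling -> sensitivity -> GA optimisation; return the report dict.

    ``lab_results`` may supply ``{"cfr": (mean, se), "cfw": (mean, se)}``
    from a wet-lab validation run to compare against the GA optima.
    """
    cfg = config or PipelineConfig()
    table = (dataset.read_table(cfg.treatments_csv) if cfg.treatments_csv
             else dataset.load_packaged_table())
    reps = synthetic.reconstruct_replicates(table, n_reps=cfg.n_reps, seed=cfg.seed)
    log.info("reconstructed %d replicate records from %d treatments",
             len(reps), len(table))

    comparison = compare_models(reps, seed=cfg.seed, ratio=cfg.ratio)
    log.info("best model by test R2: %s", comparison.best_model)

    report = {
        "provenance": {
            "package": "callopt",
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.hash(),
            "config": asdict(cfg),
        },
        "metrics": [r.as_dict() for r in comparison.reports],
        "best_model": comparison.best_model,
        "sensitivity": [],
        "ga_optima": {},
    }

    max_printed_cfr = float(table["cfr_mean"].max())
    for output in ("cfr", "cfw"):
        algo = (cfg.vsr_model or comparison.best_model[output]).lower()
        full = CallogenesisModel(reps, output=output, algorithm=algo,
                                 seed=cfg.seed).fit(holdout=False)
        vsr = full.sensitivity(scheme=cfg.vsr_scheme)
        report["sensitivity"].append(vsr.as_dict())
        ga_cfg = GAConfig(**{**asdict(cfg.ga), "seed": cfg.seed})
        ga = full.optimize(ga_cfg)
        log.info("%s optimum: %s -> %.3f", output.upper(),
                 np.round(ga.best_doses, 3).tolist(), ga.best_fitness)
        entry = ga.as_dict()
        entry["surrogate"] = full.surrogate.name
        grid_best = float(np.max(full.predict(table[HORMONES].to_numpy(dtype=float))))
        entry["best_printed_treatment_prediction"] = grid_best
        entry["beats_printed_treatments"] = bool(ga.best_fitness >= grid_best)
        if output == "cfr":
            entry["exceeds_max_printed_cfr_mean"] = bool(
                ga.best_fitness >= max_printed_cfr
            )
        if lab_results and output in lab_results:
            mean, se = lab_results[output]
            entry["validation"] = validation_comparison(ga.best_fitness, mean, se,
                                                        n=cfg.n_reps)
        report["ga_optima"][output] = entry
    return report


def render_text(report: dict) -> str:
    """Human-readable tables mirroring the comparison/VSR/optimum layout."""
    lines = ["Model comparison (R2 / RMSE / MBE)", "-" * 64]
    lines.append(f"{'Model':<6}{'Output':<8}{'Part':<7}{'R2':>8}{'RMSE':>10}{'MBE':>10}")
    for r in report["metrics"]:
        lines.append(
            f"{r['model']:<6}{r['output']:<8}{r['partition']:<7}"
            f"{r['r2']:>8.3f}{r['rmse']:>10.3f}{r['mbe']:>10.3f}"
        )
    lines += ["", "Hormone importance (VSR)", "-" * 64]
    lines.append(f"{'Output':<8}{'Item':<6}" + "".join(f"{h.upper():>8}" for h in HORMONES))
    for s in report["sensitivity"]:
        lines.append(f"{s['output']:<8}{'VSR':<6}"
                     + "".join(f"{s['vsr'][h]:>8.3f}" for h in HORMONES))
        lines.append(f"{'':<8}{'Rank':<6}"
                     + "".join(f"{s['rank'][h]:>8d}" for h in HORMONES))
    lines += ["", "GA optima", "-" * 64]
    lines.append(f"{'Output':<8}" + "".join(f"{h.upper():>8}" for h in HORMONES)
                 + f"{'Predicted':>12}")
    for output, entry in report["ga_optima"].items():
        unit = "%" if output == "cfr" else " g"
        lines.append(f"{output:<8}"
                     + "".join(f"{d:>8.2f}" for d in entry["best_doses"])
                     + f"{entry['best_fitness']:>10.2f}{unit}")
    return "\n".join(lines)


def write_report(report: dict, out_dir) -> Path:
    """Write ``report.json`` and ``report.txt``; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "report.txt").write_text(render_text(report) + "\n")
    except Exception:
        for f in ("report.json", "report.txt"):  # no partial outputs
            (out / f).unlink(missing_ok=True)
        raise
    return out
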
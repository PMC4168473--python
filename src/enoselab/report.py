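"""End-to-end pipeline: simulate -> preprocess -> extract -> classify,
assembled into a reproducible method-comparison report (one row per method
A-D with sensitivity/specificity/accuracy).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, generate_cohort
from .preprocess import (
    representative_curves,
    write_sweeps_csv,
    write_curves_csv,
)
from .features_time import extract_time_features
from .features_freq import extract_freq_features
from .classify import (
    ClassifierConfig,
    EvalResult,
    SelectionTrace,
    da_classify,
    greedy_svm_selection,
    stepwise_da,
    svm_grid_search,
)

__all__ = ["PipelineResult", "run_pipeline", "comparison_table", "write_outputs"]

METHODS = ("A", "B", "C", "D")


def _digest(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    manifest: dict
    table: pd.DataFrame
    results: dict[str, EvalResult]
    trace: SelectionTrace | None
    selected_sda: list[str]
    features: pd.DataFrame


def _curve_matrix(curves) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated per-layer curves, one row per subject, plus labels."""
    by_subject: dict[str, list] = {}
    for c in curves:
        by_subject.setdefault(c.subject_id, []).append(c)
    rows, labels = [], []
    for sid, cs in by_subject.items():
        cs = sorted(cs, key=lambda c: c.layer)
        rows.append(np.concatenate([c.values for c in cs]))
        labels.append(cs[0].group)
    return np.vstack(rows), np.asarray(labels)


def run_pipeline(
    spec: CohortSpec,
    config: ClassifierConfig | None = None,
    domains: tuple[str, ...] = ("time", "freq"),
    da_kind: str = "linear",
) -> PipelineResult:
    """Run all four methods on one synthetic cohort.

    Method A consumes the concatenated representative curves; methods B-D the
    extracted feature table (``domains`` selects time, frequency, or both).
    If ``config.C``/``config.sigma`` are unset, method D runs the grid search
    first and reuses its optimum for the greedy selection.
    """
    if config is None:
        config = ClassifierConfig()
    sweeps = generate_cohort(spec)
    curves = representative_curves(sweeps, spec.grid())

    tables = []
    if "time" in domains:
        tables.append(extract_time_features(curves))
    if "freq" in domains:
        tables.append(extract_freq_features(curves))
    if not tables:
        raise ValueError("domains must include 'time' and/or 'freq'")
    features = tables[0]
    for extra in tables[1:]:
        features = features.merge(extra, on=["subject_id", "group"], validate="1:1")

    X_curves, y = _curve_matrix(curves)
    results: dict[str, EvalResult] = {}

    results["A"] = da_classify(
        X_curves, y, kind=da_kind, cv=config.cv, seed=config.seed,
        positive=config.positive, pca_components=config.n_components,
    )
    feat_X = features[[c for c in features.columns if c not in ("subject_id", "group")]]
    results["B"] = da_classify(
        feat_X.to_numpy(float), y, kind="linear", cv=config.cv, seed=config.seed,
        positive=config.positive, pca_components=config.n_components,
        standardize=config.standardize,
    )
    selected_sda, results["C"] = stepwise_da(features, config)

    d_config = config
    if d_config.C is None or d_config.sigma is None:
        C, sigma, _ = svm_grid_search(features, config)
        d_config = replace(config, C=C, sigma=sigma)
    trace = greedy_svm_selection(features, d_config)
    results["D"] = trace.best[1]

    manifest = {
        "package_version": __version__,
        "cohort_spec": spec.to_dict(),
        "cohort_spec_digest": _digest(spec.to_dict()),
        "classifier_config": asdict(d_config),
        "classifier_config_digest": _digest(asdict(d_config)),
        "seed": spec.seed,
        "svm": {"C": d_config.C, "sigma": d_config.sigma},
        "sda_selected": selected_sda,
        "results": {m: results[m].to_dict() for m in METHODS},
        "outputs": {},
    }
    return PipelineResult(
        manifest=manifest,
        table=comparison_table(results),
        results=results,
        trace=trace,
        selected_sda=selected_sda,
        features=features,
    )


def comparison_table(results: dict[str, EvalResult]) -> pd.DataFrame:
    """Method-comparison table, metrics in percent rounded to one decimal."""
    rows = []
    for m in METHODS:
        r = results[m]
        rows.append(
            {
                "method": m,
                "sensitivity_pct": round(100.0 * r.sensitivity, 1),
                "specificity_pct": round(100.0 * r.specificity, 1),
                "accuracy_pct": round(100.0 * r.accuracy, 1),
            }
        )
    return pd.DataFrame(rows)


def write_outputs(result: PipelineResult, out_dir, spec: CohortSpec | None = None) -> dict:
    """Write comparison CSV, trace CSV, feature table and manifest JSON.

    Every written file is checksummed into the manifest; the manifest itself
    is written last.  Returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    result.table.to_csv(out / "comparison.csv", index=False)
    written["comparison.csv"] = out / "comparison.csv"
    result.features.to_csv(out / "features.csv", index=False)
    written["features.csv"] = out / "features.csv"
    if result.trace is not None:
        result.trace.to_frame().to_csv(out / "trace_D.csv", index=False)
        written["trace_D.csv"] = out / "trace_D.csv"
    if spec is not None:
        sweeps = generate_cohort(spec)
        write_sweeps_csv(sweeps, out / "sweeps.csv")
        written["sweeps.csv"] = out / "sweeps.csv"
        curves = representative_curves(sweeps, spec.grid())
        write_curves_csv(curves, out / "curves.csv")
        written["curves.csv"] = out / "curves.csv"

    result.manifest["outputs"] = {
        name: _file_digest(path) for name, path in written.items()
    }
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    return result.manifest
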
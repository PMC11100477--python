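"""File formats, run configuration, and the end-to-end pipeline driver.

Selection tables follow the Raven interchange convention: tab-delimited
with a header, times in seconds from recording start (half-open
intervals), frequencies in Hz. Extra columns pass through unchanged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .hard_clustering import ap_q_sweep
from .reliability import lights_kappa
from .resampling import bootstrap_observations
from .rules import RuleConfig, evaluate_rules
from .soft_clustering import fuzzy_cmeans, select_model, typicality_thresholds
from .supervised import svm_iterations
from .embedding import hopkins_statistic, umap_embed

logger = logging.getLogger("longcall")

#: canonical column name <-> Raven selection-table header
RAVEN_COLUMNS = {
    "begin_time": "Begin Time (s)",
    "end_time": "End Time (s)",
    "low_freq": "Low Freq (Hz)",
    "high_freq": "High Freq (Hz)",
}
REQUIRED = list(RAVEN_COLUMNS.values())


def read_selection_table(path) -> pd.DataFrame:
    """Read a Raven-style tab-delimited selection table.

    Requires the four standard time/frequency columns (renamed to
    ``begin_time``/``end_time``/``low_freq``/``high_freq``); all other
    columns are preserved as pass-through. Raises naming any missing
    required column, and reports the row number for non-numeric times.
    """
    df = pd.read_csv(path, sep="\t")
    for col in REQUIRED:
        if col not in df.columns:
            raise ValueError(f"selection table missing required column {col!r}")
    inv = {v: k for k, v in RAVEN_COLUMNS.items()}
    df = df.rename(columns=inv)
    for col in RAVEN_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r} "
                f"at row {row + 1}")
        df[col] = coerced
    return df


def write_selection_table(table: pd.DataFrame, path) -> None:
    """Write a selection table (inverse of :func:`read_selection_table`).

    Tab-delimited, newline-terminated rows, floats at 6 decimals, stable
    column order (required columns first, pass-through columns after).
    """
    df = table.copy()
    df = df.rename(columns=RAVEN_COLUMNS)
    ordered = [c for c in REQUIRED if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    df[ordered].to_csv(path, sep="\t", index=False, float_format="%.6f",
                       lineterminator="\n")


@dataclasses.dataclass
class RunConfig:
    """Configuration of an end-to-end synthetic pipeline run."""

    out_dir: str = "longcall_run"
    seed: int = 0
    n_pulses: int = 500
    graded_fraction: float = 0.1
    n_extra_features: int = 38
    observer_accuracy: float = 0.85
    svm_iterations: int = 20
    ap_q_grid: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    fcm_c_grid: tuple = (2, 3, 4, 5, 6, 7)
    fcm_mu_grid: tuple = (1.1, 1.5, 2.0)
    fcm_stability: bool = False
    boot_n_grid: tuple = (100, 200, 300)
    boot_iterations: int = 5
    run_embedding: bool = True
    n_rule_contours: int = 200

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_file(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic analysis pipeline, writing versioned outputs
    and a machine-readable manifest of every seed and setting used.

    Stages: synthesize feature table -> inter-rater reliability on
    simulated observers -> repeated-split SVM -> affinity propagation q
    sweep -> fuzzy c-means model selection with typicality -> UMAP +
    Hopkins -> observation bootstrap -> rule classifier on synthetic
    contours. Any stage failure aborts with the stage name; outputs
    written so far persist.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}
    stage = "synth"
    try:
        spec = synthetic.SyntheticSpec(
            n_pulses=config.n_pulses, graded_fraction=config.graded_fraction,
            n_extra_features=config.n_extra_features, seed=config.seed)
        table, _truth = synthetic.generate_feature_table(spec)
        feats = synthetic.feature_columns(table)
        table.to_csv(out / "feature_table.csv", index=False)
        manifest["stages"]["synth"] = {"seed": config.seed, "n": len(table),
                                       "n_features": len(feats)}
        logger.info("synth: %d pulses, %d features", len(table), len(feats))

        stage = "irr"
        obs = synthetic.simulate_observer_labels(
            table["true_class"], accuracy=config.observer_accuracy,
            seed=config.seed + 11)
        kap = lights_kappa(obs)
        pd.DataFrame(
            [{"observer_pair": f"{a}-{b}", "kappa": k}
             for (a, b), k in kap.pairwise.items()]
            + [{"observer_pair": "lights", "kappa": kap.lights_kappa}]
        ).to_csv(out / "irr.csv", index=False)
        manifest["stages"]["irr"] = {"seed": config.seed + 11,
                                     "lights_kappa": kap.lights_kappa}

        stage = "svm"
        res = svm_iterations(table[feats + ["true_class"]],
                             iterations=config.svm_iterations,
                             seed=config.seed + 21)
        res.matrix.to_csv(out / "svm_confusion.csv")
        manifest["stages"]["svm"] = {
            "seed": config.seed + 21, "iterations": config.svm_iterations,
            "mean_accuracy": res.overall_accuracy}

        stage = "apcluster"
        sweep = ap_q_sweep(_standardized(table, feats), q_grid=config.ap_q_grid)
        sweep.to_csv(out / "ap_q_sweep.csv", index=False)
        manifest["stages"]["apcluster"] = {
            "q_grid": list(config.ap_q_grid),
            "n_clusters": sweep["n_clusters"].tolist()}

        stage = "fcm"
        X = _standardized(table, feats)
        chosen, report = select_model(
            X, c_grid=config.fcm_c_grid, mu_grid=config.fcm_mu_grid,
            seed=config.seed + 31, stability=config.fcm_stability)
        sol = fuzzy_cmeans(X, chosen)
        report.to_csv(out / "fcm_validity.csv", index=False)
        typ = typicality_thresholds(sol.typicality, rule="quantile",
                                    labels=table["true_class"])
        pd.DataFrame({"pulse_id": table["pulse_id"],
                      "typicality": sol.typicality,
                      "hard_label": sol.hard_labels}).to_csv(
            out / "typicality.csv", index=False)
        manifest["stages"]["fcm"] = {
            "seed": config.seed + 31, "chosen_c": chosen.c,
            "chosen_mu": chosen.mu, "prop_typical": typ["prop_typical"]}

        stage = "embed"
        if config.run_embedding:
            coords, settings = umap_embed(X, seed=config.seed + 41)
            H = hopkins_statistic(coords, seed=config.seed + 42)
            pd.DataFrame({"pulse_id": table["pulse_id"],
                          "umap1": coords[:, 0], "umap2": coords[:, 1]}).to_csv(
                out / "umap_features.csv", index=False)
            manifest["stages"]["embed"] = {**settings,
                                           "hopkins_seed": config.seed + 42,
                                           "hopkins": H}

        stage = "boot"
        boot = bootstrap_observations(
            table, feats, label_col="true_class",
            n_grid=[g for g in config.boot_n_grid if g <= len(table)],
            iterations=config.boot_iterations, seed=config.seed + 51)
        boot.to_csv(out / "bootstrap_observations.csv", index=False)
        manifest["stages"]["boot"] = {"seed": config.seed + 51,
                                      "iterations": config.boot_iterations}

        stage = "rules"
        rng = np.random.default_rng(config.seed + 61)
        truth_labels = [str(rng.choice(synthetic.REVISED_CLASSES))
                        for _ in range(config.n_rule_contours)]
        contours = [synthetic.synthesize_f0_contour(
            lab, duration_s=1.0, seed=int(rng.integers(2**31)))
            for lab in truth_labels]
        conf = evaluate_rules(contours, truth_labels, RuleConfig())
        conf.matrix.to_csv(out / "rules_confusion.csv")
        manifest["stages"]["rules"] = {
            "seed": config.seed + 61,
            "per_class_accuracy": conf.per_class_accuracy}
    except Exception as exc:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    config.to_file(out / "config.yaml")
    return manifest


def _standardized(table: pd.DataFrame, feature_cols: list[str]) -> np.ndarray:
    X = table[feature_cols].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - mean) / sd
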
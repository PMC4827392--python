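"""End-to-end cross-validation experiment.

One experiment repeat draws a stratified training set (fixed count per
group, without replacement), fits the latent cross-covariance model and
builds the patch-atlas database on the *same* training subjects, predicts
the held-out subjects with both methods, and evaluates predictive accuracy
(regional absolute error, correlation with reference regional values,
between-group effect sizes) and discriminability (leave-one-out LDA on the
held-out subjects' latent scores).  After all repeats, component
reproducibility is assessed by matching component maps across repeats.

Every random draw is derived from ``(master seed, repeat index)`` so the
whole experiment is reproducible bit-for-bit; the configuration and derived
seeds are written alongside the results.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from .components import component_signatures, lda_loo_auc, match_components, reproducibility_counts
from .dataset_io import MultimodalDataset, center_dataset
from .patches import build_patch_db, leave_one_out_synthesis, synthesize_target
from .phantom import PhantomSpec, reference_regional_values, sample_cohort
from .plsr import fit_pls, predict, project

__all__ = ["ExperimentConfig", "run_experiment", "run_pm_loo"]


@dataclass
class ExperimentConfig:
    """Design of a cross-validation experiment.

    ``train_per_group`` may be a single count applied to every group or a
    mapping group -> count.  The scaled-down default (20/group, 10
    components, 3 repeats on the 16^3 phantom) runs in seconds; the
    study-scale design is 80/group, 30 components, 10 repeats.
    """

    train_per_group: int | Mapping[str, int] = 20
    n_components: int = 10
    n_repeats: int = 3
    seed: int = 0
    patch_side: int = 5
    search_radius: int = 0
    patch_aggregate: str = "center"
    comparisons: tuple[tuple[str, str], ...] = (("AD", "HC"), ("MCI", "HC"))
    n_top: int = 5
    match_threshold: float = 0.5
    phantom: PhantomSpec = field(default_factory=PhantomSpec)

    def counts_for(self, groups: list[str]) -> dict[str, int]:
        if isinstance(self.train_per_group, Mapping):
            missing = set(groups) - set(self.train_per_group)
            if missing:
                raise ValueError(f"train_per_group lacks groups {sorted(missing)}")
            return {g: int(self.train_per_group[g]) for g in groups}
        return {g: int(self.train_per_group) for g in groups}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"] = self.phantom.to_dict()
        d["comparisons"] = [list(c) for c in self.comparisons]
        if isinstance(self.train_per_group, Mapping):
            d["train_per_group"] = dict(self.train_per_group)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        d = dict(d)
        if "phantom" in d:
            d["phantom"] = PhantomSpec.from_dict(d["phantom"])
        if "comparisons" in d:
            d["comparisons"] = tuple(tuple(c) for c in d["comparisons"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _resolve_cohort(config, dataset, truth):
    if dataset is None:
        dataset, truth = sample_cohort(config.phantom)
    return dataset, truth


def _stratified_split(
    labels: np.ndarray, counts: Mapping[str, int], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train: list[np.ndarray] = []
    for g, c in counts.items():
        idx = np.flatnonzero(labels == g)
        if len(idx) <= c:
            raise ValueError(
                f"group {g!r} has {len(idx)} subjects; cannot train on {c} and still test"
            )
        train.append(rng.choice(idx, size=c, replace=False))
    train_idx = np.sort(np.concatenate(train))
    test_idx = np.setdiff1d(np.arange(labels.size), train_idx)
    return train_idx, test_idx


def _reference_pivot(reference: pd.DataFrame) -> pd.DataFrame:
    return reference.pivot(index="subject", columns="region", values="reference")


def run_experiment(
    config: ExperimentConfig,
    dataset: MultimodalDataset | None = None,
    truth=None,
    output_dir: str | Path | None = None,
) -> dict:
    """Run the full repeated cross-validation experiment.

    Returns a results bundle with one entry per repeat (fit, predictions,
    evaluation and discriminability tables), a per-repeat summary frame and
    the cross-repeat reproducibility analysis.  If ``output_dir`` is given,
    results are also written as CSV/YAML files (one directory per repeat).
    """
    if config.n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    dataset, truth = _resolve_cohort(config, dataset, truth)
    groups = list(pd.unique(dataset.group_labels))
    counts = config.counts_for(groups)
    if sum(counts.values()) >= dataset.n_subjects:
        raise ValueError("training design uses all subjects; nothing left to test")
    if config.n_components > sum(counts.values()) - 1:
        raise ValueError("n_components must be at most training size - 1")
    for pair in config.comparisons:
        unknown = set(pair) - set(groups)
        if unknown:
            raise ValueError(f"comparison {pair} references unknown groups {sorted(unknown)}")

    atlas = truth.atlas if truth is not None else None
    reference = _reference_pivot(reference_regional_values(truth)) if truth is not None else None

    repeats = []
    summary_rows = []
    for r in range(config.n_repeats):
        rng = np.random.default_rng([config.seed, r])
        train_idx, test_idx = _stratified_split(dataset.group_labels, counts, rng)
        train_ds = dataset.subset(train_idx)
        model = fit_pls(center_dataset(train_ds), config.n_components)
        X_test, Y_test = dataset.X[test_idx], dataset.Y[test_idx]
        test_labels = dataset.group_labels[test_idx]

        pred_plsr = predict(model, X_test)
        db = build_patch_db(
            train_ds, config.patch_side, config.search_radius, config.patch_aggregate
        )
        pred_pm = synthesize_target(X_test, db)

        rep: dict = {
            "repeat": r,
            "train_idx": train_idx,
            "test_idx": test_idx,
            "model": model,
            "signatures": component_signatures(model),
        }
        row: dict = {"repeat": r}

        if atlas is not None:
            mae_plsr = ev.regional_absolute_error(pred_plsr, Y_test, atlas, dataset.mask)
            mae_pm = ev.regional_absolute_error(pred_pm, Y_test, atlas, dataset.mask)
            t_stat, p_val = ev.paired_error_test(mae_plsr, mae_pm)
            row.update(
                mae_plsr=float(mae_plsr.mean()),
                mae_pm=float(mae_pm.mean()),
                paired_t=t_stat,
                paired_p=p_val,
            )
            rep.update(regional_mae_plsr=mae_plsr, regional_mae_pm=mae_pm)

            if reference is not None:
                ref_test = reference.loc[test_idx].to_numpy().ravel()
                for name, pred in (("plsr", pred_plsr), ("pm", pred_pm)):
                    tbl = ev.regional_table(pred, atlas, dataset.mask, "predicted")
                    pv = tbl.pivot(index="subject", columns="region", values="predicted")
                    r_val, ci = ev.correlation_with_reference(pv.to_numpy().ravel(), ref_test)
                    row[f"corr_{name}"] = r_val
                    row[f"corr_{name}_lo"], row[f"corr_{name}_hi"] = ci
                    subj_means = pv.to_numpy().mean(axis=1)
                    for a, b in config.comparisons:
                        row[f"effect_{name}_{a}_vs_{b}"] = ev.effect_size(
                            subj_means[test_labels == a], subj_means[test_labels == b]
                        )

        scores_test = project(model, X_test)
        rep["discriminability"] = {}
        for pair in config.comparisons:
            res = lda_loo_auc(scores_test, test_labels, pair, n_top=config.n_top)
            rep["discriminability"][pair] = res
            row[f"auc_{pair[0]}_vs_{pair[1]}"] = res.auc
        repeats.append(rep)
        summary_rows.append(row)

    summary = pd.DataFrame(summary_rows)

    reproducibility = {}
    if config.n_repeats >= 2:
        signatures = [rep["signatures"] for rep in repeats]
        for pair in config.comparisons:
            tops = [rep["discriminability"][pair].top_components for rep in repeats]
            counts_arr, unmatched = reproducibility_counts(
                signatures, tops, reference=0, threshold=config.match_threshold
            )
            reproducibility[pair] = {"counts": counts_arr, "unmatched": unmatched}

    results = {
        "config": config,
        "repeats": repeats,
        "summary": summary,
        "reproducibility": reproducibility,
    }
    if output_dir is not None:
        _write_results(results, Path(output_dir))
    return results


def run_pm_loo(
    config: ExperimentConfig,
    dataset: MultimodalDataset | None = None,
    truth=None,
) -> dict:
    """Patch baseline with a leave-one-out database over the whole cohort."""
    dataset, truth = _resolve_cohort(config, dataset, truth)
    pred = leave_one_out_synthesis(
        dataset, config.patch_side, config.search_radius, config.patch_aggregate
    )
    out: dict = {"predictions": pred}
    if truth is not None:
        mae = ev.regional_absolute_error(pred, dataset.Y, truth.atlas, dataset.mask)
        out["regional_mae"] = mae
        out["mae_mean"] = float(mae.mean())
    return out


def _write_results(results: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config: ExperimentConfig = results["config"]
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    results["summary"].to_csv(outdir / "summary.csv", index=False)
    for rep in results["repeats"]:
        rdir = outdir / f"repeat_{rep['repeat']:02d}"
        rdir.mkdir(exist_ok=True)
        pd.DataFrame({"train_idx": rep["train_idx"]}).to_csv(rdir / "train_idx.csv", index=False)
        pd.DataFrame({"test_idx": rep["test_idx"]}).to_csv(rdir / "test_idx.csv", index=False)
        for pair, res in rep["discriminability"].items():
            tag = f"{pair[0]}_vs_{pair[1]}"
            pd.DataFrame(
                {
                    "component": np.arange(res.lda_weights.size),
                    "lda_weight": res.lda_weights,
                }
            ).to_csv(rdir / f"lda_weights_{tag}.csv", index=False)
    rows = []
    for pair, rep_data in results["reproducibility"].items():
        for comp, c in enumerate(rep_data["counts"]):
            rows.append((f"{pair[0]}_vs_{pair[1]}", comp, int(c)))
    pd.DataFrame(rows, columns=["comparison", "component", "n_repeats_reproduced"]).to_csv(
        outdir / "reproducibility.csv", index=False
    )
    provenance = {
        "seed": config.seed,
        "repeat_seeds": [[config.seed, r] for r in range(config.n_repeats)],
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
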
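"""Full study analog: simulate subjects, preprocess, classify, map.

For each synthetic subject and modality the two runs are preprocessed, the
SVM is trained on one run and tested on the other (both directions), the
transition-exclusion sweep is repeated for each k in ``k_sweep``, and —
optionally — a permutation test localizes the significantly discriminative
voxels.  Results collect into a tidy accuracy table (one row per subject x
modality x k x direction) plus an aggregated mean +/- SE table analogous to
the usual accuracy-vs-ignored-points curves.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .paradigm import Paradigm
from .synth import SynthParams, Subject, generate_subject
from .preprocess import brain_mask, mean_image, preprocess_run, subsample
from .dataset import build_examples, ExampleSet
from .svm import cross_run_accuracy
from .permtest import permutation_null, PermResult

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "accuracy_curve",
    "plot_accuracy_curve",
    "subject_seed",
    "prepare_subject_examples",
]


def subject_seed(master_seed: int, subject_index: int) -> int:
    """Deterministic per-subject seed: a documented counter scheme keeping
    every derived seed below 2**31."""
    return (master_seed * 100_003 + subject_index) % (2**31)


@dataclass
class ExperimentConfig:
    n_subjects: int = 10
    paradigm: Paradigm = field(default_factory=lambda: Paradigm(30.0, 5, 1))
    synth: SynthParams = field(default_factory=SynthParams)
    modalities: tuple = ("bold", "asl", "avast")
    k_sweep: tuple = (0, 1, 2, 3)
    subsample_variants: bool = False
    C: float = 1.0
    fwhm_mm: float = 8.0
    mask_rule: str = "above_mean"
    n_perm: int = 0  # 0 disables permutation mapping
    perm_modalities: tuple | None = None  # None -> all
    alpha: float = 0.01
    master_seed: int = 0
    out_dir: str | None = None


@dataclass
class ExperimentResult:
    accuracy_table: pd.DataFrame
    aggregated: pd.DataFrame
    perm_results: dict  # (subject, modality) -> PermResult
    subjects: dict  # subject index -> Subject (ground truth kept for scoring)
    example_sets: dict  # (subject, modality, k) -> (ExampleSet, ExampleSet)
    manifest: dict
    errors: list


def prepare_subject_examples(
    subject: Subject,
    modality: str,
    cfg: ExperimentConfig,
    k: int = 0,
    stride: int = 1,
) -> tuple[ExampleSet, ExampleSet]:
    """Mask, preprocess and assemble both runs of one subject/modality.

    The brain mask is computed once from run 1's (unsmoothed) mean image and
    shared by both runs so their feature spaces match.
    """
    r1, r2 = subject.runs[modality]
    m = brain_mask(mean_image(r1), cfg.mask_rule)
    sets = []
    for r in (r1, r2):
        pr = preprocess_run(r, fwhm_mm=cfg.fwhm_mm)
        if stride > 1:
            pr = subsample(pr, stride=stride)
        sets.append(build_examples(pr, cfg.paradigm, m, k_ignore=k))
    return sets[0], sets[1]


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the full sweep; partial failures are recorded and skipped."""
    rows = []
    perm_results: dict = {}
    subjects: dict = {}
    example_sets: dict = {}
    errors: list = []
    perm_mods = cfg.perm_modalities if cfg.perm_modalities is not None else cfg.modalities

    variants = [("", 1)]
    if cfg.subsample_variants:
        variants.append(("s", 2))  # sBOLD / sAVAST style stride-2 subsampling

    for i in range(cfg.n_subjects):
        seed = subject_seed(cfg.master_seed, i)
        subj = generate_subject(cfg.synth, seed, cfg.paradigm)
        subjects[i] = subj
        for mod in cfg.modalities:
            for prefix, stride in variants:
                if prefix == "s" and mod == "asl":
                    continue  # only the fast contrasts get subsampled analogs
                name = prefix + mod
                for k in cfg.k_sweep:
                    try:
                        s1, s2 = prepare_subject_examples(
                            subj, mod, cfg, k=k, stride=stride
                        )
                        if stride == 1:
                            example_sets[(i, mod, k)] = (s1, s2)
                        for direction, (a, b) in (
                            ("run1->run2", (s1, s2)),
                            ("run2->run1", (s2, s1)),
                        ):
                            acc = cross_run_accuracy(a, b, C=cfg.C)
                            rows.append(
                                {
                                    "subject": i,
                                    "modality": name,
                                    "k_ignore": k,
                                    "direction": direction,
                                    "accuracy": acc,
                                }
                            )
                    except Exception as exc:  # keep the sweep alive
                        errors.append(
                            {"subject": i, "modality": name, "k": k, "error": str(exc)}
                        )
            if cfg.n_perm > 0 and mod in perm_mods:
                try:
                    s1, _ = (
                        example_sets.get((i, mod, 0))
                        or prepare_subject_examples(subj, mod, cfg, k=0)
                    )
                    perm_results[(i, mod)] = permutation_null(
                        s1,
                        C=cfg.C,
                        n_perm=cfg.n_perm,
                        seed=np.random.SeedSequence(
                            [seed, zlib.crc32(mod.encode()) % (2**31)]
                        ),
                        alpha=cfg.alpha,
                    )
                except Exception as exc:
                    errors.append(
                        {"subject": i, "modality": mod, "k": "perm", "error": str(exc)}
                    )

    table = pd.DataFrame(rows)
    agg = accuracy_curve(table) if len(table) else pd.DataFrame()
    manifest = {
        "master_seed": cfg.master_seed,
        "subject_seeds": [subject_seed(cfg.master_seed, i) for i in range(cfg.n_subjects)],
        "paradigm": cfg.paradigm.to_dict(),
        "modalities": list(cfg.modalities),
        "k_sweep": list(cfg.k_sweep),
        "C": cfg.C,
        "fwhm_mm": cfg.fwhm_mm,
        "mask_rule": cfg.mask_rule,
        "n_perm": cfg.n_perm,
        "alpha": cfg.alpha,
        "n_runs_per_modality": 2 * cfg.n_subjects,
        "avast_tr_per_subject": {i: s.avast_tr for i, s in subjects.items()},
    }
    result = ExperimentResult(
        accuracy_table=table,
        aggregated=agg,
        perm_results=perm_results,
        subjects=subjects,
        example_sets=example_sets,
        manifest=manifest,
        errors=errors,
    )
    if cfg.out_dir:
        _write_artifacts(result, cfg)
    return result


def accuracy_curve(tbl: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SE accuracy per (modality, k).

    Directions are averaged within subject first, then subjects averaged;
    SE = SD / sqrt(n_subjects) over the per-subject means.  A pooled
    (direction-level) mean is included for comparison since either
    aggregation is defensible.
    """
    if tbl.empty:
        raise ValueError("empty accuracy table")
    per_subj = (
        tbl.groupby(["modality", "k_ignore", "subject"])["accuracy"].mean().reset_index()
    )
    g = per_subj.groupby(["modality", "k_ignore"])["accuracy"]
    agg = g.agg(mean="mean", sd="std", n="count").reset_index()
    agg["se"] = agg["sd"] / np.sqrt(agg["n"])
    agg.loc[agg["n"] == 1, "se"] = np.nan  # SE undefined for one subject
    pooled = tbl.groupby(["modality", "k_ignore"])["accuracy"].mean()
    agg["pooled_mean"] = agg.set_index(["modality", "k_ignore"]).index.map(pooled)
    return agg


def plot_accuracy_curve(agg: pd.DataFrame, ax=None):
    """Accuracy vs. number of ignored transition points, one line per
    modality, error bars = SE."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for mod, sub in agg.groupby("modality"):
        sub = sub.sort_values("k_ignore")
        ax.errorbar(
            sub["k_ignore"], sub["mean"], yerr=sub["se"], marker="o", label=mod
        )
    ax.set_xlabel("ignored transition points (k)")
    ax.set_ylabel("mean cross-run accuracy")
    ax.set_ylim(0.0, 1.05)
    ax.legend()
    return ax


def _write_artifacts(result: ExperimentResult, cfg: ExperimentConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.accuracy_table.to_csv(out / "accuracy_table.tsv", sep="\t", index=False)
    if len(result.aggregated):
        result.aggregated.to_csv(out / "accuracy_aggregated.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1, default=str))
    if result.errors:
        (out / "errors.json").write_text(json.dumps(result.errors, indent=1))
    for (i, mod), pr in result.perm_results.items():
        es = result.example_sets.get((i, mod, 0))
        if es is not None:
            pr.to_frame(es[0].voxel_index).to_csv(
                out / f"perm_subject{i}_{mod}.tsv", sep="\t", index=False
            )
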
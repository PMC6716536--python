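"""Orchestration of the strategy grid: color augmentation x stain
normalization x domain-adversarial training, across seeds.

Each combination is a triple of boolean flags (CA, SN, DANN).  For every
combination and seed the runner optionally stain-normalizes all partitions
offline (normalization first, augmentation online second), builds the
matching model, trains it, and evaluates internal and external test
partitions.  Artifacts land in a fixed layout under the run directory:

    configs/        resolved plan frozen as JSON
    checkpoints/    per-cell parameters + sidecar + training log
    predictions/    per-cell per-record probabilities (CSV)
    results/        tidy per-seed metrics and the wide summary table

A failed cell is recorded and the remaining cells continue.  When
hard-negative mining is enabled the mined set is computed once, from the
baseline bootstrap, and shared by every combination.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .adversarial_training import (
    ArchitectureSpec,
    DannClassifier,
    TrainConfig,
    mine_hard_negatives,
)
from .augmentation import AugmentationConfig
from .evaluation import (
    ExperimentResult,
    PredictionSet,
    aggregate,
    results_table,
)
from .normalization import NormalizationConfig, NormalizationTemplate, fit_template, normalize
from .synthetic_cohort import PatchRecord

__all__ = ["MethodCombination", "ExperimentPlan", "run"]

log = logging.getLogger(__name__)

#: The seven non-trivial columns of the strategy grid plus the baseline.
FULL_GRID = [
    (False, False, False),
    (True, False, False),
    (False, True, False),
    (False, False, True),
    (True, True, False),
    (True, False, True),
    (True, True, True),
    (False, True, True),
]


@dataclass(frozen=True)
class MethodCombination:
    """One column of the results table."""

    color_augmentation: bool = False
    stain_normalization: bool = False
    domain_adversarial: bool = False

    @property
    def tag(self) -> str:
        parts = [
            name
            for flag, name in (
                (self.color_augmentation, "CA"),
                (self.stain_normalization, "SN"),
                (self.domain_adversarial, "DANN"),
            )
            if flag
        ]
        return "+".join(parts) if parts else "baseline"


@dataclass(frozen=True)
class ExperimentPlan:
    """Everything needed to reproduce a grid run."""

    combinations: tuple[MethodCombination, ...]
    seeds: tuple[int, ...] = (0, 1, 2, 3)
    train: TrainConfig = TrainConfig()
    arch: ArchitectureSpec = ArchitectureSpec()
    augmentation: AugmentationConfig = AugmentationConfig()
    normalization: NormalizationConfig = NormalizationConfig()
    hard_negative_mining: bool = False
    output_dir: str | None = None

    def __post_init__(self) -> None:
        tags = [c.tag for c in self.combinations]
        if len(set(tags)) != len(tags):
            raise ValueError("method combinations must be unique")


def _partition(records: list[PatchRecord], name: str) -> list[PatchRecord]:
    return [r for r in records if r.partition == name]


def _normalize_records(
    records: list[PatchRecord],
    template: NormalizationTemplate,
    config: NormalizationConfig,
) -> list[PatchRecord]:
    out = []
    for i, r in enumerate(records):
        img = normalize(np.asarray(r.image), template, config, source_id=str(i))
        out.append(PatchRecord(img, r.x, r.y, r.task_label, r.domain_label, r.partition))
    return out


def _predictions(fit, records, partition, seed, tag) -> PredictionSet:
    probs = fit.predict_proba(records)
    return PredictionSet(
        ids=np.arange(len(records)),
        probabilities=probs,
        labels=np.array([r.task_label for r in records]),
        domains=np.array([r.domain_label for r in records]),
        partition=partition,
        seed=seed,
        method=tag,
    )


def run(
    plan: ExperimentPlan,
    records: list[PatchRecord],
) -> tuple[pd.DataFrame, dict[str, ExperimentResult], dict]:
    """Execute the grid on an in-memory cohort.

    Returns the wide results table, per-method :class:`ExperimentResult`
    objects, and a dict of raw artifacts (prediction sets, fit results,
    failures).  When ``plan.output_dir`` is set the standard directory
    layout is written.
    """
    out = Path(plan.output_dir) if plan.output_dir else None
    if out is not None:
        for sub in ("configs", "checkpoints", "predictions", "results"):
            (out / sub).mkdir(parents=True, exist_ok=True)
        (out / "configs" / "plan.json").write_text(
            json.dumps(_plan_to_json(plan), indent=2)
        )

    train_recs = _partition(records, "train")
    val_recs = _partition(records, "validation")
    internal = _partition(records, "internal_test")
    external = _partition(records, "external_test")

    # Hard-negative mining: computed once, shared by every combination.
    if plan.hard_negative_mining:
        positives = [r for r in train_recs if r.task_label == 1]
        candidates = [r for r in train_recs if r.task_label == 0]
        mining_cfg = dataclasses.replace(
            plan.train, iterations=min(plan.train.iterations, 200), warmup_iters=0
        )
        mined, _ = mine_hard_negatives(
            positives, candidates, config=mining_cfg, arch=plan.arch
        )
        train_recs = positives + mined
        log.info("hard-negative mining kept %d of %d candidates",
                 len(mined), len(candidates))

    # Offline normalization (template = first training patch), reused by
    # every combination that requests it.
    needs_norm = any(c.stain_normalization for c in plan.combinations)
    normalized: dict[str, list[PatchRecord]] = {}
    template = None
    if needs_norm:
        template = fit_template(np.asarray(train_recs[0].image), plan.normalization)
        if out is not None:
            template.to_json(out / "configs" / "template.json")
        for name, recs in (
            ("train", train_recs),
            ("validation", val_recs),
            ("internal_test", internal),
            ("external_test", external),
        ):
            normalized[name] = _normalize_records(recs, template, plan.normalization)

    prediction_sets: list[PredictionSet] = []
    fits: dict[tuple[str, int], object] = {}
    failures: dict[tuple[str, int], str] = {}
    for combo in plan.combinations:
        tag = combo.tag
        if combo.stain_normalization:
            tr, va = normalized["train"], normalized["validation"]
            te_int, te_ext = normalized["internal_test"], normalized["external_test"]
        else:
            tr, va, te_int, te_ext = train_recs, val_recs, internal, external
        for seed in plan.seeds:
            cell = (tag, seed)
            try:
                cfg = dataclasses.replace(plan.train, seed=seed)
                clf = DannClassifier(
                    tr,
                    config=cfg,
                    arch=plan.arch,
                    adversarial=combo.domain_adversarial,
                    augmentation=plan.augmentation if combo.color_augmentation else None,
                    validation_records=va if cfg.eval_every > 0 else None,
                )
                fit = clf.fit()
                fits[cell] = fit
                for partition, recs in (("internal_test", te_int),
                                        ("external_test", te_ext)):
                    pset = _predictions(fit, recs, partition, seed, tag)
                    prediction_sets.append(pset)
                    if out is not None:
                        pset.to_frame().to_csv(
                            out / "predictions" / f"{tag}_seed{seed}_{partition}.csv",
                            index=False,
                        )
                if out is not None:
                    fit.save(out / "checkpoints" / f"{tag}_seed{seed}")
            except Exception as err:  # keep the rest of the grid running
                log.exception("cell %s failed", cell)
                failures[cell] = f"{type(err).__name__}: {err}"

    results: dict[str, ExperimentResult] = {}
    for combo in plan.combinations:
        runs = [p for p in prediction_sets if p.method == combo.tag]
        if runs:
            results[combo.tag] = aggregate(runs)
    table = results_table(list(results.values())) if results else pd.DataFrame()

    if out is not None:
        tidy = pd.concat(
            [r.per_seed.assign(method=tag) for tag, r in results.items()],
            ignore_index=True,
        ) if results else pd.DataFrame()
        tidy.to_csv(out / "results" / "per_seed.csv", index=False)
        table.to_csv(out / "results" / "summary.csv")
        if failures:
            (out / "results" / "failures.json").write_text(
                json.dumps({f"{t}_seed{s}": msg for (t, s), msg in failures.items()},
                           indent=2)
            )
    return table, results, {"predictions": prediction_sets, "fits": fits,
                            "failures": failures, "template": template}


def _plan_to_json(plan: ExperimentPlan) -> dict:
    return {
        "combinations": [dataclasses.asdict(c) for c in plan.combinations],
        "seeds": list(plan.seeds),
        "train": dataclasses.asdict(plan.train),
        "arch": dataclasses.asdict(plan.arch),
        "color_augmentation": {
            "space": plan.augmentation.space,
            "a_range": list(plan.augmentation.a_range),
            "b_range": list(plan.augmentation.b_range),
        },
        "normalization": dataclasses.asdict(plan.normalization),
        "hard_negative_mining": plan.hard_negative_mining,
    }
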
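"""End-to-end model construction: split -> preprocess -> GA -> CP-ANN -> AD.

The pipeline reproduces the reference workflow on any labelled descriptor
table: the dataset is split into training (TR), test (TE) and external
validation (V) partitions on a Kohonen top-map; descriptors are filtered,
autoscaled and SOM-reduced; a genetic algorithm selects the descriptor
subset with the best MCC_TR x MCC_TE wrapper fitness (the V partition is
excluded from every model-construction stage); a final CP-ANN is trained on
TR with the selected descriptors; all three partitions are scored and an
Euclidean-distance applicability domain is built with the TE maximum as the
boundary.

Every stage derives its random seed deterministically from the master seed,
every artifact is written as it is produced, and a manifest records the
configuration, seeds, partition sizes and per-stage wall times, so a run is
fully auditable and byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cpannet.data import LabeledDescriptorTable, read_labeled_csv
from cpannet.domain import assess, build_reference, records_to_frame
from cpannet.ga import GAConfig, run_ga
from cpannet.metrics import global_report
from cpannet.model import predict_batch, train_cpann
from cpannet.preprocess import (
    apply_scaling,
    autoscale,
    filter_correlated,
    filter_low_variance,
    som_reduce_descriptors,
)
from cpannet.som import SOMConfig
from cpannet.split import REFERENCE_FRACTIONS, som_split

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("cpannet")

_STAGES = ("split", "reduce", "ga", "model")


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, pre-filled with the reference defaults.

    ``scaling_scope`` chooses where the autoscaling (and the reduction
    filters) are fitted: ``"full"`` fits on the entire dataset before
    splitting, matching the reference procedure; ``"train"`` fits on the TR
    partition only and reuses the parameters elsewhere, avoiding any
    information flow from TE/V into the transform.
    """

    input_path: str | None = None
    label_column: str = "pgp_class"
    fractions: tuple[float, float, float] = REFERENCE_FRACTIONS
    # splitting SOM
    split_rows: int = 20
    split_cols: int = 20
    split_epochs: int = 100
    split_a_max: float = 0.5
    split_a_min: float = 0.01
    # preprocessing
    sd_threshold: float = 1e-4
    r_threshold: float = 0.95
    reduction_rows: int = 7
    reduction_cols: int = 7
    reduction_epochs: int = 100
    reduction_a_max: float = 0.5
    reduction_a_min: float = 0.01
    scaling_scope: str = "full"
    # descriptor selection
    ga: GAConfig = field(default_factory=GAConfig)
    # final network
    final_rows: int = 43
    final_cols: int = 43
    final_epochs: int = 600
    final_a_max: float = 0.6
    final_a_min: float = 0.001
    # applicability domain
    uncertainty_band: float = 0.1
    # bookkeeping
    seed: int = 0
    outdir: str = "cpannet_run"

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ValueError("fractions must be three positive numbers")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(self.fractions)}")
        if self.scaling_scope not in ("full", "train"):
            raise ValueError("scaling_scope must be 'full' or 'train'")

    def stage_seeds(self) -> dict[str, int]:
        """Per-stage seeds derived deterministically from the master seed."""
        state = np.random.SeedSequence(self.seed).generate_state(len(_STAGES))
        return {name: int(s % (2 ** 31)) for name, s in zip(_STAGES, state)}

    def split_som(self, seed: int) -> SOMConfig:
        return SOMConfig(rows=self.split_rows, cols=self.split_cols,
                         t_max=self.split_epochs, a_max=self.split_a_max,
                         a_min=self.split_a_min, seed=seed)

    def reduction_som(self, seed: int) -> SOMConfig:
        return SOMConfig(rows=self.reduction_rows, cols=self.reduction_cols,
                         t_max=self.reduction_epochs, a_max=self.reduction_a_max,
                         a_min=self.reduction_a_min, seed=seed)

    def final_som(self, seed: int) -> SOMConfig:
        return SOMConfig(rows=self.final_rows, cols=self.final_cols,
                         t_max=self.final_epochs, a_max=self.final_a_max,
                         a_min=self.final_a_min, seed=seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fractions"] = list(self.fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "ga" in d and isinstance(d["ga"], dict):
            d["ga"] = GAConfig(**d["ga"])
        if "fractions" in d:
            d["fractions"] = tuple(d["fractions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


def _stage(name: str, manifest: dict, fn):
    t0 = time.perf_counter()
    logger.info("stage %s: started", name)
    try:
        result = fn()
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(f"stage '{name}' failed: {exc}") from exc
    dt = time.perf_counter() - t0
    manifest.setdefault("stage_seconds", {})[name] = round(dt, 3)
    logger.info("stage %s: done in %.2fs", name, dt)
    return result


def run_pipeline(config: PipelineConfig,
                 data: LabeledDescriptorTable | None = None) -> dict:
    """Execute the full workflow and write all artifacts under ``config.outdir``.

    ``data`` overrides ``config.input_path`` when supplied. Returns a dict of
    in-memory artifacts: split, reduction report, scaling params, GA history,
    selected descriptors, model, per-partition reports/predictions, AD
    reference and records, and the manifest. Artifacts already written when a
    later stage fails are retained on disk.
    """
    if data is None:
        if config.input_path is None:
            raise ValueError("either data or config.input_path is required")
        data = read_labeled_csv(config.input_path, config.label_column)
    if data.labels.nunique() < 2:
        raise ValueError("pipeline needs at least 2 classes in the data")

    seeds = config.stage_seeds()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stage_seeds": seeds,
                      "n_compounds": int(len(data.table))}
    artifacts: dict = {"manifest": manifest}
    config.to_yaml(outdir / "config.yaml")

    classes = tuple(sorted(data.labels.unique(),
                           key=lambda c: (c != "inhibitor", c != "substrate", c)))

    # ---- low-variance filter (needed before any autoscaling) -----------
    def do_variance():
        return filter_low_variance(data.table, config.sd_threshold)
    table_v, report = _stage("variance-filter", manifest, do_variance)

    # ---- split on the full (autoscaled) descriptor matrix --------------
    def do_split():
        scaled_all, _ = autoscale(table_v)
        split_data = LabeledDescriptorTable(table=scaled_all, labels=data.labels)
        return som_split(split_data, config.split_som(seeds["split"]), config.fractions)
    split = _stage("split", manifest, do_split)
    split.to_tsv(outdir / "split.tsv")
    manifest["partition_sizes"] = {"TR": len(split.tr), "TE": len(split.te),
                                   "V": len(split.v)}
    artifacts["split"] = split

    # ---- correlation filter, autoscaling, SOM descriptor reduction -----
    fit_rows = table_v.index if config.scaling_scope == "full" else pd.Index(split.tr)

    def do_reduce():
        fit_table = table_v.loc[fit_rows]
        reduced, rep_corr = filter_correlated(fit_table, config.r_threshold)
        scaled, params = autoscale(reduced)
        final, rep_som = som_reduce_descriptors(
            scaled, som_config=config.reduction_som(seeds["reduce"]))
        return final.columns, params, rep_corr.merge(rep_som)
    retained_cols, scaling, rep_rest = _stage("preprocess", manifest, do_reduce)
    report = report.merge(rep_rest)
    report.to_tsv(outdir / "reduction.tsv")
    artifacts["reduction_report"] = report
    artifacts["scaling"] = scaling
    manifest["n_descriptors_retained"] = len(retained_cols)

    # Scaled view of every partition, restricted to the retained descriptors.
    scaled_full = apply_scaling(data.table, scaling)[list(retained_cols)]
    x_tr, y_tr = scaled_full.loc[split.tr], data.labels.loc[split.tr]
    x_te, y_te = scaled_full.loc[split.te], data.labels.loc[split.te]
    x_v, y_v = scaled_full.loc[split.v], data.labels.loc[split.v]
    # Raw views feed the final model, which applies the stored scaling itself.
    raw = {"TR": (data.table.loc[split.tr], y_tr),
           "TE": (data.table.loc[split.te], y_te),
           "V": (data.table.loc[split.v], y_v)}

    # ---- GA descriptor selection (V never enters fitness) --------------
    def do_ga():
        ga_config = dataclasses.replace(config.ga, seed=seeds["ga"])
        return run_ga(x_tr, y_tr, x_te, y_te, ga_config, classes)
    best, history = _stage("ga", manifest, do_ga)
    history.to_csv(outdir / "ga_history.tsv", sep="\t", index=False)
    selected = best.selected_names(retained_cols)
    (outdir / "selected_descriptors.txt").write_text("\n".join(selected) + "\n")
    manifest["ga"] = {"best_fitness": best.fitness, "n_selected": len(selected),
                      "fitness_compound_ids": sorted(map(str, [*split.tr, *split.te]))}
    artifacts["ga_best"] = best
    artifacts["ga_history"] = history
    artifacts["selected_descriptors"] = selected

    # ---- final CP-ANN refit on TR with the selected descriptors --------
    def do_model():
        cfg = config.final_som(seeds["model"])
        return train_cpann(x_tr[selected], y_tr, config=cfg, classes=classes,
                           scaling=scaling)
    model = _stage("final-model", manifest, do_model)
    model.to_json(outdir / "model.json")
    artifacts["model"] = model

    # ---- evaluation on TR / TE / V -------------------------------------
    reports = {}
    predictions = {}
    for name, (x, y) in raw.items():
        def do_eval(x=x, y=y):
            _, frame = predict_batch(model, x, y)
            rep = global_report(list(frame["true"]), list(frame["predicted"]), classes)
            return rep, frame
        rep, frame = _stage(f"evaluate-{name}", manifest, do_eval)
        rep.to_json(outdir / f"report_{name}.json")
        frame.to_csv(outdir / f"predictions_{name}.tsv", sep="\t")
        reports[name] = rep
        predictions[name] = frame
    artifacts["reports"] = reports
    artifacts["predictions"] = predictions
    manifest["performance"] = {name: {"ner": rep.ner, "avpr": rep.avpr}
                               for name, rep in reports.items()}

    # ---- applicability domain (reference: TE maximum) ------------------
    def do_ad():
        reference = build_reference(model, raw["TE"][0], partition="TE")
        recs = {name: assess(model, reference, x, y, config.uncertainty_band)
                for name, (x, y) in raw.items()}
        return reference, recs
    reference, ad_records = _stage("applicability-domain", manifest, do_ad)
    for name, recs in ad_records.items():
        records_to_frame(recs).to_csv(outdir / f"ad_{name}.tsv", sep="\t")
    manifest["ad_reference_ed"] = reference.reference_ed
    artifacts["ad_reference"] = reference
    artifacts["ad_records"] = ad_records

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return artifacts
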
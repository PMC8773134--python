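"""Readers, writers, run configuration and the end-to-end pipeline.

All tables are TSV: abundance views have a header row of feature ids and a
first column of sample ids; metadata has one row per sample.  Every run
emits a JSON manifest with the fully serialized configuration and a content
hash so outputs are traceable to the parameters that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess, screen, select, stacking
from .bench import CvScheme, LearnerSpec, run_bench
from .containers import AbundanceView, CohortMetadata
from .interpret import biomarker_table, interpret_model
from .synthetic import SyntheticConfig, SyntheticCohort, generate_cohort

logger = logging.getLogger("gutclock")

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_cohort",
    "align_samples",
    "RunConfig",
    "run_pipeline",
]


def read_abundance_table(path, name: str | None = None) -> AbundanceView:
    """Read a samples x features relative-abundance TSV.

    Percent-scale rows (summing to ~100) are renormalized with a notice.
    Negative values, duplicate ids and ragged rows raise with the offending
    location.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV ({exc})") from exc
    if frame.isna().any().any():
        row, col = next(
            (r, c) for r in frame.index for c in frame.columns if pd.isna(frame.at[r, c])
        )
        raise ValueError(f"{path}: missing/ragged value at sample {row!r}, feature {col!r}")
    values = frame.to_numpy()
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative abundance at sample {frame.index[i]!r}, "
            f"feature {frame.columns[j]!r}"
        )
    sums = values.sum(axis=1)
    if np.any(np.abs(sums - 100.0) < 1.0):
        logger.info("%s: rows sum to ~100; renormalizing to 1", path)
    return AbundanceView(frame, name=name or path.stem)


def write_abundance_table(view: AbundanceView, path) -> None:
    view.frame.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> CohortMetadata:
    # default NA parsing would swallow the "NA" (Northern America) subregion
    frame = pd.read_csv(
        Path(path),
        sep="\t",
        index_col=0,
        keep_default_na=False,
        na_values=["", "nan", "NaN", "missing"],
    )
    return CohortMetadata(frame)


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write a synthetic cohort in the standard pipeline input formats:
    two abundance TSVs, a metadata TSV and a JSON truth file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "species": directory / "species.tsv",
        "pathway": directory / "pathway.tsv",
        "metadata": directory / "metadata.tsv",
        "truth": directory / "truth.json",
    }
    write_abundance_table(cohort.species_view, paths["species"])
    write_abundance_table(cohort.pathway_view, paths["pathway"])
    cohort.metadata.frame.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    paths["truth"].write_text(json.dumps(cohort.truth, indent=2))
    return {k: str(v) for k, v in paths.items()}


def align_samples(views: dict, metadata: CohortMetadata):
    """Intersect views with metadata into a canonical sample order.

    Samples missing from the metadata are dropped.  A view may lack some
    metadata samples; per-view availability masks are preserved (late
    fusion only needs the intersection at the generalizer step).  Returns
    ``(views, metadata, report)`` where the report lists dropped ids and
    per-view availability.
    """
    meta_ids = pd.Index(metadata.sample_ids)
    union = pd.Index([])
    for view in views.values():
        union = union.union(view.frame.index)
    keep = meta_ids[meta_ids.isin(union)]
    if keep.empty:
        raise ValueError("no samples shared between metadata and any view")
    dropped_meta = meta_ids.difference(union).tolist()
    report = {"dropped_from_metadata": dropped_meta, "availability": {}}
    out_views = {}
    for name, view in views.items():
        avail = keep[keep.isin(view.frame.index)]
        report["availability"][name] = {
            "n_available": int(len(avail)),
            "missing": keep.difference(view.frame.index).tolist(),
        }
        out_views[name] = AbundanceView(view.frame.loc[avail].copy(), name=view.name)
    return out_views, metadata.subset_samples(keep), report


@dataclass
class RunConfig:
    """Fully serialized configuration of one pipeline run."""

    species_path: str | None = None
    pathway_path: str | None = None
    metadata_path: str | None = None
    synthetic: dict | None = None  # SyntheticConfig kwargs; overrides paths
    output_dir: str = "gutclock_run"
    seed: int = 0
    min_age: float = 18.0
    missing_threshold: float = 0.4
    redundancy_map: dict = field(default_factory=dict)
    do_screen: bool = True
    screen_threshold: float = 0.01
    min_bin_size: int = 200
    delta: float | None = None
    use_subregion_feature: bool = True
    cv_repeats: int = 10
    cv_folds: int = 5
    do_bench: bool = False
    bench_learners: list = field(
        default_factory=lambda: sorted(
            ["LR", "Lasso", "EN", "BR", "SVM", "LSVM", "DT", "RF", "GBRT", "XGB", "XGBRF", "LGB"]
        )
    )
    do_select: bool = True
    selection_method: str = "GBRT"
    keep_rule: str = "mean"
    generalizer: str = "LR"
    strategy: str = "EM2"
    stage1_k: int = 5
    do_interpret: bool = True
    n_shuffles: int = 50
    pfi_holdout_fraction: float = 0.3

    def manifest(self) -> dict:
        blob = asdict(self)
        digest = hashlib.sha256(
            json.dumps(blob, sort_keys=True, default=str).encode()
        ).hexdigest()
        return {"config": blob, "manifest_hash": digest}


def _prepare_design(view: AbundanceView, metadata, cfg: RunConfig):
    replaced = preprocess.multiplicative_replacement(view, delta=cfg.delta)
    clr = preprocess.clr_transform(replaced)
    extras = []
    if cfg.use_subregion_feature and "subregion" in metadata.frame.columns:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            extras.append(preprocess.encode_subregion(metadata))
    return preprocess.assemble_design(clr, extras)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write all stage outputs.

    Stage order: simulate/load -> metadata filter -> regroup -> subregion
    screen -> compositional preprocess -> (optional) regressor bench ->
    feature selection -> stacked training -> PFI interpretation.
    """
    cfg = config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = cfg.manifest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    stage = "input"
    try:
        if cfg.synthetic is not None:
            cohort = generate_cohort(SyntheticConfig(**cfg.synthetic))
            views = {"species": cohort.species_view, "pathway": cohort.pathway_view}
            metadata = cohort.metadata
            write_cohort(cohort, out / "synthetic_inputs")
        else:
            views = {
                "species": read_abundance_table(cfg.species_path, "species"),
                "pathway": read_abundance_table(cfg.pathway_path, "pathway"),
            }
            metadata = read_metadata(cfg.metadata_path)
        views, metadata, align_report = align_samples(views, metadata)

        stage = "metadata_filter"
        metadata = screen.filter_metadata_columns(
            metadata, cfg.missing_threshold, cfg.redundancy_map
        )
        adults = metadata.frame["age"] >= cfg.min_age
        metadata = CohortMetadata(metadata.frame[adults])

        stage = "regroup"
        if "subregion" not in metadata.frame.columns and "country" in metadata.frame.columns:
            metadata = screen.add_subregion_column(metadata)

        stage = "screen"
        scheme = CvScheme(cfg.cv_repeats, cfg.cv_folds, cfg.seed)
        if cfg.do_screen and "subregion" in metadata.frame.columns:
            result = screen.screen_subregions(
                metadata,
                min_bin_size=cfg.min_bin_size,
                threshold=cfg.screen_threshold,
                cv=scheme,
                seed=cfg.seed,
            )
            (out / "screen.json").write_text(
                json.dumps(
                    {
                        "epochs": result.epochs,
                        "retained_subregions": result.retained_subregions,
                        "final_assoc_r2": result.final_assoc_r2,
                        "dropped_small_bins": result.dropped_small_bins,
                        "n_retained": len(result.retained_sample_ids),
                    },
                    indent=2,
                )
            )
            keep = pd.Index(result.retained_sample_ids)
            metadata = metadata.subset_samples(keep)
        keep = pd.Index(metadata.sample_ids)
        views = {
            n: AbundanceView(v.frame.loc[v.frame.index.intersection(keep)], name=v.name)
            for n, v in views.items()
        }

        stage = "preprocess"
        designs = {
            n: _prepare_design(v, metadata.subset_samples(v.frame.index), cfg)
            for n, v in views.items()
        }
        y = pd.Series(metadata.ages, index=metadata.sample_ids, name="age")

        if cfg.do_bench:
            stage = "bench"
            specs = [LearnerSpec(n, seed=cfg.seed) for n in cfg.bench_learners]
            tables = []
            for name, design in designs.items():
                table = run_bench(specs, design.frame, y.loc[design.frame.index], scheme)
                table.insert(0, "view", name)
                tables.append(table)
            pd.concat(tables).to_csv(out / "bench.tsv", sep="\t", index=False)

        stage = "select"
        selected_designs = {}
        for name, design in designs.items():
            frame = design.frame
            if cfg.do_select:
                clr_cols = design.columns_from("clr:")
                kept = select.select_features(
                    cfg.selection_method,
                    frame[clr_cols],
                    y.loc[frame.index],
                    keep_rule=cfg.keep_rule,
                    seed=cfg.seed,
                )
                (out / f"selected_{name}.txt").write_text("\n".join(kept) + "\n")
                onehot = design.columns_from("onehot:")
                frame = frame[kept + onehot]
            selected_designs[name] = frame

        stage = "train"
        rng = np.random.default_rng(cfg.seed)
        if cfg.do_interpret and cfg.pfi_holdout_fraction > 0:
            n = len(y)
            held = rng.choice(n, size=max(2, int(cfg.pfi_holdout_fraction * n)), replace=False)
            held_ids = y.index[np.sort(held)]
        else:
            held_ids = pd.Index([])
        train_ids = y.index.difference(held_ids)
        model = stacking.multiview_stack(
            {n: f.loc[f.index.intersection(train_ids)] for n, f in selected_designs.items()},
            y.loc[train_ids],
            generalizer=cfg.generalizer,
            k=cfg.stage1_k,
            seed=cfg.seed,
            strategy=cfg.strategy,
        )
        stacking.save_model(model, out / "model")
        pred_views = {n: f for n, f in selected_designs.items()}
        preds = stacking.predict_ensemble(model, pred_views)
        preds.to_frame().to_csv(out / "predictions.tsv", sep="\t", index_label="sample_id")

        if cfg.do_interpret:
            stage = "interpret"
            eval_views = {
                n: f.loc[f.index.intersection(held_ids if len(held_ids) else y.index)]
                for n, f in selected_designs.items()
            }
            eval_ids = next(iter(eval_views.values())).index
            records = interpret_model(
                model,
                eval_views,
                y.loc[eval_ids],
                n_shuffles=cfg.n_shuffles,
                seed=cfg.seed,
            )
            biomarker_table(records).to_csv(out / "biomarkers.tsv", sep="\t", index=False)

        (out / "align_report.json").write_text(json.dumps(align_report, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
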
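"""End-to-end orchestration: simulate/load -> preprocess -> ERF -> qPCR ->
ROC -> MIC network, with a YAML config, seeded reproducibility and a JSON
run manifest.

Stages couple through files in the output directory so each stage is
independently re-runnable and the whole run is auditable.  Candidate species
for qPCR/ROC are the ERF-relevant features intersected with the available Ct
panel.  Outputs carry no timestamps, so two runs with the same config and
seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .erf_select import ErfConfig, erf_rank
from .mic_network import MicConfig, covariation_network, write_edge_list
from .qpcr_quant import collapse_duplicates, compare_groups, delta_delta_ct, read_ct_table, write_ct_table
from .roc_biomarker import cv_threshold_auc, univariate_auc
from .synthetic_data import SimSpec, simulate_cohort, simulate_ct, simulate_metabolome
from .tables_io import (
    CohortMetadata,
    OtuTable,
    drop_zero_variance,
    read_metadata,
    read_otu_table,
    to_relative_abundance,
    write_metadata,
    write_otu_table,
)

logger = logging.getLogger("stoolmark")

__all__ = ["PipelineConfig", "QpcrOptions", "RocOptions", "validate_config", "run_all"]

# how many non-planted decoy species join the simulated qPCR panel, mirroring
# a panel that targets more candidates than turn out to be real
_N_DECOY_SPECIES = 3
_CT_ABUNDANCE_SCALE = 1e5  # relative abundance -> template units for Ct model


@dataclass
class QpcrOptions:
    calibrator: str | None = None  # default: first control sample
    reference_species: str | None = None
    test: str = "mw"
    max_spread: float = 1.0

    def __post_init__(self) -> None:
        if self.test not in ("mw", "t"):
            raise ValueError("qpcr.test must be 'mw' or 't'")


@dataclass
class RocOptions:
    mode: str = "cv5"
    cutoff: float = 0.70
    k: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("classic", "cv5"):
            raise ValueError("roc.mode must be 'classic' or 'cv5'")
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("roc.cutoff must be in (0, 1)")


@dataclass
class PipelineConfig:
    """Everything a run needs; every stage seed derives from ``seed``."""

    out_dir: str = "stoolmark_out"
    otu_table: str | None = None
    metadata: str | None = None
    ct_table: str | None = None
    metabolome: str | None = None
    simulate: bool = False
    seed: int = 0
    erf_on: str = "relative"  # {relative, counts}
    erf: ErfConfig = field(default_factory=ErfConfig)
    sim: SimSpec = field(default_factory=SimSpec)
    qpcr: QpcrOptions = field(default_factory=QpcrOptions)
    roc: RocOptions = field(default_factory=RocOptions)
    mic: MicConfig = field(default_factory=MicConfig)

    def __post_init__(self) -> None:
        if self.erf_on not in ("relative", "counts"):
            raise ValueError("erf_on must be 'relative' or 'counts'")

    def stage_seed(self, stage: str) -> int:
        # crc32 is a stable string hash (Python's hash() is salted per process)
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return int(ss.generate_state(1)[0]) % (2**31)

    def to_yaml(self) -> str:
        # json round-trip turns tuples into plain lists for safe_dump
        plain = json.loads(json.dumps(dataclasses.asdict(self)))
        return yaml.safe_dump(plain, sort_keys=True)


_SECTIONS = {"erf": ErfConfig, "sim": SimSpec, "qpcr": QpcrOptions, "roc": RocOptions, "mic": MicConfig}


def validate_config(raw: str | dict) -> PipelineConfig:
    """Parse + validate a YAML config; unknown keys and bad ranges error out."""
    data = yaml.safe_load(raw) if isinstance(raw, str) else dict(raw)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key, val in data.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            if not isinstance(val, dict):
                raise ValueError(f"section {key!r} must be a mapping")
            sub_fields = {f.name for f in dataclasses.fields(cls)}
            bad = set(val) - sub_fields
            if bad:
                raise ValueError(f"unknown keys in section {key!r}: {sorted(bad)}")
            if cls is SimSpec and "score_scale" in val:
                val = dict(val, score_scale=tuple(val["score_scale"]))
            kwargs[key] = cls(**val)
        else:
            kwargs[key] = val
    cfg = PipelineConfig(**kwargs)
    logger.info("effective config:\n%s", cfg.to_yaml())
    return cfg


def _fail(manifest: dict, stage: str, out: Path, exc: Exception) -> None:
    manifest["failed_stage"] = stage
    manifest["error"] = str(exc)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": yaml.safe_load(cfg.to_yaml()),
        "stages": {},
    }

    # ---- stage: inputs (simulate or load) --------------------------------
    stage = "inputs"
    try:
        if cfg.simulate:
            sim = dataclasses.replace(cfg.sim, seed=cfg.stage_seed("simulate"))
            otu, meta, truth = simulate_cohort(sim)
            rel_for_ct = to_relative_abundance(otu)
            rng = np.random.default_rng(cfg.stage_seed("panel"))
            decoys = [
                f for f in rng.permutation(otu.feature_ids)
                if f not in truth.planted_feature_ids
            ][:_N_DECOY_SPECIES]
            panel = sorted(truth.planted_feature_ids) + sorted(decoys)
            ct = simulate_ct(
                rel_for_ct.data[panel] * _CT_ABUNDANCE_SCALE,
                seed=cfg.stage_seed("ct"),
            )
            metab, met_truth = simulate_metabolome(
                n_control=sim.n_control, n_case=sim.n_case, seed=cfg.stage_seed("metabolome")
            )
            write_otu_table(otu, out / "otu_counts.tsv", seed=sim.seed)
            write_metadata(meta, out / "metadata.tsv", seed=sim.seed)
            write_ct_table(ct, out / "ct.csv", seed=sim.seed)
            with open(out / "metabolome.tsv", "w") as fh:
                fh.write(f"# stoolmark v{__version__} seed={sim.seed}\n")
                metab.rename_axis("sample_id").to_csv(fh, sep="\t")
            (out / "truth.json").write_text(json.dumps({
                "planted_feature_ids": list(truth.planted_feature_ids),
                "elevated_metabolite_ids": list(met_truth.elevated_metabolite_ids),
            }, indent=2, sort_keys=True))
        else:
            if not cfg.otu_table or not cfg.metadata:
                raise ValueError("no inputs: provide otu_table+metadata or set simulate: true")
            otu = read_otu_table(cfg.otu_table)
            meta = read_metadata(cfg.metadata)
            ct = read_ct_table(cfg.ct_table) if cfg.ct_table else None
            metab = (
                pd.read_csv(cfg.metabolome, sep="\t", comment="#", index_col="sample_id")
                if cfg.metabolome else None
            )
        manifest["stages"][stage] = {
            "n_samples": otu.shape[0], "n_features": otu.shape[1],
            "n_ct_species": int(ct["species"].nunique()) if ct is not None else 0,
        }
    except Exception as exc:
        _fail(manifest, stage, out, exc)
        raise

    # ---- stage: preprocess ----------------------------------------------
    stage = "preprocess"
    try:
        filtered = drop_zero_variance(otu)
        rel = to_relative_abundance(filtered) if filtered.kind == "counts" else filtered
        write_otu_table(rel, out / "otu_relative.tsv")
        manifest["stages"][stage] = {
            "features_in": otu.shape[1],
            "features_out": filtered.shape[1],
            "zero_variance_removed": otu.shape[1] - filtered.shape[1],
        }
    except Exception as exc:
        _fail(manifest, stage, out, exc)
        raise

    # ---- stage: erf ------------------------------------------------------
    stage = "erf"
    try:
        X = rel.data if cfg.erf_on == "relative" else filtered.data
        erf_cfg = dataclasses.replace(cfg.erf, seed=cfg.stage_seed("erf"))
        y = (
            meta.symptom_score.loc[X.index]
            if erf_cfg.response_mode == "score_regression"
            else meta.group.loc[X.index]
        )
        erf_res = erf_rank(X, y, erf_cfg)
        ranked = erf_res.table.copy()
        ranked.insert(0, "taxonomy", rel.taxonomy.reindex(ranked.index).fillna(""))
        with open(out / "erf_ranking.tsv", "w") as fh:
            fh.write(f"# stoolmark v{__version__} best_shadow={erf_res.best_shadow_id} "
                     f"best_shadow_mean_vim={erf_res.best_shadow_mean_vim:.6g}\n")
            ranked.rename_axis("feature_id").to_csv(fh, sep="\t")
        manifest["stages"][stage] = {
            "n_relevant": int(ranked["relevant"].sum()),
            "threshold": erf_cfg.relevance_threshold,
            "best_shadow_mean_vim": erf_res.best_shadow_mean_vim,
            "run_seed": erf_cfg.seed,
        }
    except Exception as exc:
        _fail(manifest, stage, out, exc)
        raise

    # ---- stage: qpcr -----------------------------------------------------
    stage = "qpcr"
    fold_wide = None
    try:
        if ct is not None:
            panel_species = sorted(ct["species"].unique())
            candidates = [s for s in panel_species if s in set(erf_res.relevant_ids)]
            manifest["stages"][stage] = {"panel": panel_species, "erf_relevant_in_panel": candidates}
            calibrator = cfg.qpcr.calibrator
            if calibrator is None:
                controls = [s for s in meta.sample_ids if meta.group[s] == "control"]
                calibrator = controls[0]
            mean_ct = collapse_duplicates(ct, max_spread=cfg.qpcr.max_spread)
            # species the calibrator fails to amplify cannot be expressed
            # relative to it; drop them rather than abort the run
            cal_rows = mean_ct[mean_ct["sample_id"] == calibrator]
            dropped = sorted(cal_rows.loc[cal_rows["undetected"], "species"])
            if dropped:
                logger.warning("qpcr: calibrator %s undetected for %s; species dropped",
                               calibrator, dropped)
                mean_ct = mean_ct[~mean_ct["species"].isin(dropped)]
                manifest["stages"][stage]["species_dropped_undetected_calibrator"] = dropped
            folds = delta_delta_ct(mean_ct, calibrator, cfg.qpcr.reference_species)
            comparison = compare_groups(folds, meta, test=cfg.qpcr.test)
            folds.to_csv(out / "fold_changes.tsv", sep="\t", index=False)
            comparison.to_csv(out / "species_comparison.tsv", sep="\t", index=False)
            fold_wide = folds.pivot(index="sample_id", columns="species", values="fold_change")
            manifest["stages"][stage]["n_significant_species"] = int(comparison["significant"].sum())
            manifest["stages"][stage]["calibrator"] = calibrator
        else:
            manifest["stages"][stage] = {"skipped": "no Ct table"}
    except Exception as exc:
        _fail(manifest, stage, out, exc)
        raise

    # ---- stage: roc ------------------------------------------------------
    stage = "roc"
    try:
        roc_rows = []
        labels = meta.group
        roc_seed = cfg.stage_seed("roc")
        if fold_wide is not None:
            for sp in fold_wide.columns:
                vals = fold_wide[sp].dropna()
                if cfg.roc.mode == "cv5":
                    r = cv_threshold_auc(vals, labels.loc[vals.index], k=cfg.roc.k,
                                         seed=roc_seed, marker_id=str(sp))
                else:
                    r = univariate_auc(vals, labels.loc[vals.index], marker_id=str(sp))
                roc_rows.append(("species", r))
        if metab is not None:
            for m in metab.columns:
                r = univariate_auc(metab[m], labels.loc[metab.index], marker_id=str(m))
                roc_rows.append(("metabolite", r))
        table = pd.DataFrame(
            [
                (kind, r.marker_id, r.mode, r.auc,
                 ";".join(f"{a:.4f}" for a in r.fold_aucs), r.orientation,
                 r.auc > cfg.roc.cutoff)
                for kind, r in roc_rows
            ],
            columns=["kind", "marker", "mode", "auc", "fold_aucs", "orientation", "significant"],
        )
        table.to_csv(out / "roc_markers.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_markers": len(table),
            "n_significant": int(table["significant"].sum()) if len(table) else 0,
            "cutoff": cfg.roc.cutoff,
            "seed": roc_seed,
        }
    except Exception as exc:
        _fail(manifest, stage, out, exc)
        raise

    # ---- stage: micnet ---------------------------------------------------
    stage = "micnet"
    try:
        mic_features = list(erf_res.relevant_ids)
        if fold_wide is not None:
            mic_features = sorted(set(mic_features) | set(map(str, fold_wide.columns)))
        mic_features = [f for f in mic_features if f in rel.data.columns]
        if len(mic_features) >= 2:
            net = covariation_network(rel.data[mic_features], cfg.mic)
            write_edge_list(net, out / "mic_edges.tsv")
            manifest["stages"][stage] = {
                "n_nodes": len(net.nodes), "n_edges": len(net.edges),
                "threshold": net.threshold,
            }
        else:
            manifest["stages"][stage] = {"skipped": "fewer than 2 features"}
    except Exception as exc:
        _fail(manifest, stage, out, exc)
        raise

    manifest["completed"] = True
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
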
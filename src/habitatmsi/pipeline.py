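"""End-to-end orchestration of the habitat / MSI / risk / survival run.

Stages communicate only through files under the run directory:

    run_dir/
      config.yaml            frozen copy of the configuration
      cohort/                NIfTI volumes + masks, patients.csv, truth.json
      split.csv              patient_id, split (train/test)
      habitat/<channel>/     habitat-k metric table, habitat maps (NIfTI)
      features/              <channel>_<region>.csv MSI feature tables
      risk/                  cluster + risk labels, per-k metrics, consensus
      models/results.csv     channel x region x model evaluation grid
      manifest.json          content hashes + stage timings

Each stage writes a ``<stage>.done`` marker holding the config hash;
re-running skips stages whose marker matches, so deleting one stage's
outputs recomputes only from there on.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import habitat as hb
from . import msi as msi_mod
from . import risk as risk_mod
from . import survival as surv
from .config import RunConfig, stage_seed
from .preprocess import PreprocessParams, preprocess_region
from .synthetic import (
    CHANNELS,
    REGIONS,
    CohortConfig,
    generate_cohort,
    write_cohort,
)

log = logging.getLogger("habitatmsi")

REGION_SETS = ("GTVp", "MLN", "GTVp-MLN")


def _run_dir(config: RunConfig) -> Path:
    d = Path(config.run_dir)
    d.mkdir(parents=True, exist_ok=True)
    return d


def _marker(config: RunConfig, stage: str) -> Path:
    return _run_dir(config) / f"{stage}.done"


def _stage_complete(config: RunConfig, stage: str) -> bool:
    m = _marker(config, stage)
    return m.exists() and m.read_text().strip() == config.content_hash()

def _mark_complete(config: RunConfig, stage: str) -> None:
    _marker(config, stage).write_text(config.content_hash())


def split_cohort(
    records: pd.DataFrame,
    train_fraction: float = 0.75,
    seed: int = 0,
    stratify: bool = True,
) -> pd.Series:
    """Random train/test split (default 3:1), optionally stratified by
    event status so event fractions stay balanced in small cohorts."""
    n = len(records)
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=object)
    if stratify:
        strata = [records["event"].to_numpy() == v for v in (1, 0)]
    else:
        strata = [np.ones(n, dtype=bool)]
    for sel in strata:
        idx = np.nonzero(sel)[0]
        rng.shuffle(idx)
        n_train = int(round(train_fraction * len(idx)))
        assign[idx[:n_train]] = "train"
        assign[idx[n_train:]] = "test"
    return pd.Series(assign, index=records.index, name="split")


def cmd_simulate(config: RunConfig) -> dict:
    """Generate and write the synthetic cohort plus the train/test split."""
    run = _run_dir(config)
    if _stage_complete(config, "simulate"):
        log.info("simulate: up to date, skipping")
        return json.loads((run / "simulate_manifest.json").read_text())
    t0 = time.time()
    cc = CohortConfig(seed=stage_seed(config.master_seed, "cohort"), **config.cohort)
    cohort = generate_cohort(cc)
    manifest = write_cohort(cohort, run / "cohort")
    records = cohort.records_frame.set_index("patient_id")
    split = split_cohort(
        records,
        train_fraction=config.train_fraction,
        seed=stage_seed(config.master_seed, "split"),
        stratify=config.stratify_split,
    )
    split.rename_axis("patient_id").to_frame().to_csv(run / "split.csv")
    config.to_yaml(run / "config.yaml")
    manifest["split"] = str(run / "split.csv")
    manifest["seconds"] = round(time.time() - t0, 2)
    (run / "simulate_manifest.json").write_text(json.dumps(manifest, indent=1))
    _mark_complete(config, "simulate")
    log.info("simulate: wrote %d patients in %.1fs", cc.n_patients, manifest["seconds"])
    return manifest


def _load_records(run: Path) -> tuple[pd.DataFrame, pd.Series]:
    records = pd.read_csv(run / "cohort" / "patients.csv").set_index("patient_id")
    split = pd.read_csv(run / "split.csv").set_index("patient_id")["split"]
    return records, split.loc[records.index]


def cmd_habitat_features(config: RunConfig) -> None:
    """Preprocess every (patient, region, channel), fit the population
    habitat model per channel, write habitat maps, the per-k metric table
    and the MSI feature tables (GTVp, MLN, GTVp-MLN)."""
    import nibabel as nib

    from .synthetic import read_patient_volumes

    run = _run_dir(config)
    if _stage_complete(config, "habitat"):
        log.info("habitat: up to date, skipping")
        return
    t0 = time.time()
    records, split = _load_records(run)
    hp = config.habitat
    pp = PreprocessParams(**vars(config.preprocess))
    feat_dir = run / "features"
    feat_dir.mkdir(exist_ok=True)
    for channel in CHANNELS:
        ch_dir = run / "habitat" / channel
        ch_dir.mkdir(parents=True, exist_ok=True)
        sp_maps: dict[tuple[str, str], hb.SuperpixelMap] = {}
        offsets: dict[tuple[str, str], tuple[int, int, int]] = {}
        feats: dict[tuple[str, str], hb.SuperpixelFeatures] = {}
        for pid in records.index:
            volumes, masks = read_patient_volumes(run / "cohort", pid)
            for region in REGIONS:
                fused, mask_c = preprocess_region(
                    volumes[channel], masks[region], pp
                )
                n_sp = hb.choose_superpixel_count(
                    mask_c.n_voxels, hp.voxels_per_sp
                )
                spm = hb.slic_segment(fused, mask_c, n_sp, hp.compactness)
                sp_maps[(pid, region)] = spm
                offsets[(pid, region)] = fused.crop_offset
                feats[(pid, region)] = hb.superpixel_features(
                    fused,
                    spm,
                    provenance={
                        "patient_id": pid,
                        "region": region,
                        "channel": channel,
                    },
                )
        train_ids = set(records.index[split == "train"])
        fit_keys = [
            k
            for k in feats
            if hp.pooled or k[0] in train_ids
        ]
        pooled = hb.pool_features([feats[k] for k in fit_keys])
        seed = stage_seed(config.master_seed, f"habitat:{channel}")
        model = hb.fit_habitat_model(
            pooled,
            k=hp.k,
            seed=seed,
            perplexity=hp.perplexity,
            tsne_max_iter=hp.tsne_max_iter,
            kmeans_max_iter=hp.kmeans_max_iter,
            kmeans_replicates=hp.kmeans_replicates,
        )
        metrics, _ = hb.evaluate_habitat_k(
            model.embedding,
            hp.k_candidates,
            seed=seed,
            kmeans_max_iter=hp.kmeans_max_iter,
            kmeans_replicates=hp.kmeans_replicates,
        )
        metrics["msi_feature_dim"] = [
            msi_mod.feature_dimension(k) for k in metrics["k"]
        ]
        metrics.to_csv(ch_dir / "habitat_k_metrics.csv", index=False)
        # habitat labels: training superpixels keep their fitted labels,
        # everything else is assigned by nearest training superpixel
        rows: dict[str, dict[str, np.ndarray]] = {}
        cursor = 0
        train_label_lookup: dict[tuple[str, str], np.ndarray] = {}
        for key in fit_keys:
            n_rows = feats[key].matrix.shape[0]
            train_label_lookup[key] = model.train_labels[
                cursor : cursor + n_rows
            ]
            cursor += n_rows
        tables: dict[str, pd.DataFrame] = {r: {} for r in REGION_SETS}
        for pid in records.index:
            per_region = {}
            for region in REGIONS:
                key = (pid, region)
                sp_labels = (
                    train_label_lookup[key]
                    if key in train_label_lookup
                    else hb.assign_habitats(model, feats[key])
                )
                hmap = hb.build_habitat_map(
                    sp_maps[key],
                    sp_labels,
                    k=hp.k,
                    region=region,
                    crop_offset=offsets[key],
                )
                nib.save(
                    nib.Nifti1Image(
                        hmap.labels.astype(np.int16), np.eye(4)
                    ),
                    ch_dir / f"{pid}_habitat_{region}.nii.gz",
                )
                per_region[region] = msi_mod.features_for_map(
                    hmap, connectivity=config.msi_connectivity
                )
            combined = msi_mod.combine_regions(
                per_region["GTVp"], per_region["MLN"]
            )
            tables["GTVp"][pid] = pd.Series(
                per_region["GTVp"].values, index=per_region["GTVp"].names
            )
            tables["MLN"][pid] = pd.Series(
                per_region["MLN"].values, index=per_region["MLN"].names
            )
            tables["GTVp-MLN"][pid] = pd.Series(
                combined.values, index=combined.names
            )
        for region_set, cols in tables.items():
            df = pd.DataFrame(cols).T
            df.index.name = "patient_id"
            df.to_csv(feat_dir / f"{channel}_{region_set}.csv")
    _mark_complete(config, "habitat")
    log.info("habitat: done in %.1fs", time.time() - t0)


def cmd_stratify(config: RunConfig) -> None:
    """Consensus-cluster each (channel, region) MSI table into risk groups."""
    run = _run_dir(config)
    if _stage_complete(config, "stratify"):
        log.info("stratify: up to date, skipping")
        return
    t0 = time.time()
    records, split = _load_records(run)
    rp = config.risk
    out_dir = run / "risk"
    out_dir.mkdir(exist_ok=True)
    for channel in CHANNELS:
        for region_set in REGION_SETS:
            table = pd.read_csv(
                run / "features" / f"{channel}_{region_set}.csv"
            ).set_index("patient_id")
            use = table.index if rp.pooled else table.index[split == "train"]
            sub = table.loc[use]
            seed = stage_seed(
                config.master_seed, f"risk:{channel}:{region_set}"
            )
            result = risk_mod.consensus_cluster(
                sub,
                k_range=rp.k_range,
                n_repeats=rp.n_repeats,
                fraction=rp.fraction,
                seed=seed,
                metric=rp.metric,
                algorithm=rp.algorithm,
            )
            chosen = risk_mod.select_k(result)
            result.metrics.to_csv(
                out_dir / f"{channel}_{region_set}_metrics.csv", index=False
            )
            labels = result.labels[chosen]
            out = pd.DataFrame(
                {"cluster": labels}, index=sub.index
            )
            if chosen == 2:
                ra = risk_mod.label_risk_groups(labels, records.loc[use])
                out["risk_group"] = ra.groups.to_numpy()
            out.to_csv(out_dir / f"{channel}_{region_set}_labels.csv")
            blob = {
                "chosen_k": chosen,
                "consensus": {
                    str(k): m.round(4).tolist()
                    for k, m in result.consensus.items()
                },
            }
            (out_dir / f"{channel}_{region_set}_consensus.json").write_text(
                json.dumps(blob)
            )
    _mark_complete(config, "stratify")
    log.info("stratify: done in %.1fs", time.time() - t0)


def cmd_models(config: RunConfig) -> pd.DataFrame:
    """Fit and evaluate the channel x region x {C,R,CR} model grid."""
    run = _run_dir(config)
    out_path = run / "models" / "results.csv"
    if _stage_complete(config, "models") and out_path.exists():
        log.info("models: up to date, skipping")
        return pd.read_csv(out_path)
    t0 = time.time()
    records, split = _load_records(run)
    tables = {}
    for channel in CHANNELS:
        for region_set in REGION_SETS:
            tables[(channel, region_set)] = pd.read_csv(
                run / "features" / f"{channel}_{region_set}.csv"
            ).set_index("patient_id")
    params = surv.ModelGridParams(
        penalty=config.models.penalty,
        horizon=config.models.horizon,
        n_boot=config.models.n_boot,
        seed=stage_seed(config.master_seed, "models"),
    )
    grid = surv.run_model_grid(tables, records, split, params=params)
    out_path.parent.mkdir(exist_ok=True)
    grid.to_csv(out_path, index=False)
    _mark_complete(config, "models")
    log.info("models: done in %.1fs", time.time() - t0)
    return grid


def _hash_file(p: Path) -> str:
    return hashlib.sha256(p.read_bytes()).hexdigest()[:16]


def cmd_report(run_dir: str | Path) -> dict:
    """Collect the summary tables of a completed run."""
    run = Path(run_dir)
    missing = [
        s
        for s in ("habitat", "features", "risk", "models")
        if not (run / s).exists()
    ]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing stages: {missing}")
    habitat_tables = {
        p.parent.name: pd.read_csv(p)
        for p in sorted(run.glob("habitat/*/habitat_k_metrics.csv"))
    }
    risk_tables = {
        p.stem.replace("_metrics", ""): pd.read_csv(p)
        for p in sorted(run.glob("risk/*_metrics.csv"))
    }
    grid = pd.read_csv(run / "models" / "results.csv")
    summary_dir = run / "report"
    summary_dir.mkdir(exist_ok=True)
    hab = pd.concat(
        [t.assign(channel=c) for c, t in habitat_tables.items()],
        ignore_index=True,
    )
    hab.to_csv(summary_dir / "habitat_k_summary.csv", index=False)
    rk = pd.concat(
        [t.assign(cell=c) for c, t in risk_tables.items()], ignore_index=True
    )
    rk.to_csv(summary_dir / "risk_metrics_summary.csv", index=False)
    grid.to_csv(summary_dir / "model_grid.csv", index=False)
    return {
        "habitat_k": hab,
        "risk_metrics": rk,
        "model_grid": grid,
    }


def cmd_run_all(config: RunConfig) -> dict:
    """simulate -> habitat/features -> stratify -> models -> manifest."""
    t0 = time.time()
    cmd_simulate(config)
    cmd_habitat_features(config)
    cmd_stratify(config)
    cmd_models(config)
    run = _run_dir(config)
    files = sorted(
        p for p in run.rglob("*") if p.is_file() and p.suffix != ".done"
    )
    manifest = {
        "config_hash": config.content_hash(),
        "seconds": round(time.time() - t0, 2),
        "files": {str(p.relative_to(run)): _hash_file(p) for p in files},
    }
    (run / "manifest.json").write_text(json.dumps(manifest, indent=1))
    cmd_report(run)
    return manifest
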
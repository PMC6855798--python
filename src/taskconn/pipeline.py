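"""End-to-end pipeline orchestration with reproducible, seeded outputs.

``run_pipeline`` executes ingestion (synthetic phantom or NIfTI files) ->
preprocessing/QC -> ROI network connectivity -> mixed-model contrasts ->
global connectedness with permutation cluster-extent inference -> driver /
allegiance classification -> behavior coupling, writing per-stage CSV/NIfTI
outputs, the resolved configuration, and a manifest with checksums under the
run's output directory. Every random draw descends from the single global
seed through named per-stage substreams.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import connectedness as conn
from . import drivers as drv
from . import lme
from . import preprocess as prep
from . import roi
from . import synthetic as syn
from .experiments import atlas_from_communities
from .volume import load_motion, load_volume_series

__all__ = ["RunConfig", "run_pipeline", "validate_protocol"]

STAGES = ("simulate", "preprocess", "roi", "lme", "connectedness",
          "drivers", "behavior")


@dataclass
class RunConfig:
    """Fully serialisable pipeline configuration (all stage defaults here)."""

    out_dir: str = "results/run"
    seed: int = 0
    mode: str = "synthetic"            # 'synthetic' | 'files'
    stages: tuple = STAGES
    # synthetic phantom
    n_per_group: int = 4
    grid_shape: tuple = (12, 12, 12)
    n_timepoints: int = 80
    n_communities: int = 4
    effects: dict = field(default_factory=dict)   # EffectSpec overrides
    # file ingestion
    design_csv: str | None = None      # columns: subject, group, condition,
    atlas_csv: str | None = None       # task, order, path, motion_path
    rotation_units: str = "rad"
    drop_initial: int = 5
    # preprocessing / QC
    fd_threshold_mm: float = 0.3
    max_censored_fraction: float = 0.05
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    fwhm_mm: float = 4.0
    # inference
    hierarchy: str = "full"
    include_order: bool = False
    n_permutations: int = 200
    min_permutations: int = 100
    alpha: float = 0.05
    p_two_tailed: float = 0.05
    connectivity: int = 6
    driver_p: float = 0.001
    driver_extent: int = 20

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.mode == "files":
            for name in ("design_csv", "atlas_csv"):
                value = getattr(self, name)
                if value is None:
                    raise ValueError(f"config field {name!r} is required in "
                                     "files mode")
                if not Path(value).exists():
                    raise ValueError(f"config field {name!r}: no such file "
                                     f"{value!r}")
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}")

    def effect_spec(self) -> syn.EffectSpec:
        return syn.EffectSpec(**self.effects)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_protocol(trains: int, pulses_per_train_hz: float, train_s: float,
                      inter_train_s: float) -> dict:
    """Derived stimulation-session arithmetic.

    E.g. 40 trains of 20 Hz pulses for 2 s with 28 s gaps gives 1600 pulses
    over a 1200 s (20 min) session.
    """
    if min(trains, pulses_per_train_hz, train_s) <= 0 or inter_train_s < 0:
        raise ValueError("protocol parameters must be positive "
                         "(inter-train gap may be zero)")
    pulses = trains * pulses_per_train_hz * train_s
    duration_s = trains * (train_s + inter_train_s)
    return {"pulses_per_session": pulses, "session_duration_s": duration_s,
            "session_duration_min": duration_s / 60.0}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _stage_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(STAGES, children)}


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages in order and return the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = {"seed": config.seed, "stage_seeds": seeds, "stages": {},
                "outputs": {}, "mode": config.mode}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)

    state: dict = {}
    stages = [s for s in STAGES if s in config.stages]
    for stage in stages:
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](config, seeds, state, out)
        except Exception as exc:  # abort naming the stage
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}

    for path in sorted(out.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][path.name] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# --- stages ----------------------------------------------------------------

def _stage_simulate(config: RunConfig, seeds, state, out: Path):
    if config.mode == "files":
        design = pd.read_csv(config.design_csv)
        needed = {"subject", "group", "condition", "task", "order", "path",
                  "motion_path"}
        missing = needed - set(design.columns)
        if missing:
            raise ValueError(f"design_csv missing columns {sorted(missing)}")
        volumes = [load_volume_series(p, drop_initial=config.drop_initial)
                   for p in design["path"]]
        motions = [load_motion(p, rotation_units=config.rotation_units)
                   [config.drop_initial:]
                   for p in design["motion_path"]]
        state["atlas"] = roi.ROIAtlas.from_csv(config.atlas_csv)
        state["scans"] = design.drop(columns=["path", "motion_path"])
        state["community_map"] = None
    else:
        spec = config.effect_spec()
        design = syn.make_design(config.n_per_group, seed=seeds["simulate"])
        community_map = syn.block_community_map(config.grid_shape,
                                                config.n_communities)
        volumes, mask, scans = syn.simulate_voxel_dataset(
            design, config.grid_shape, community_map, spec,
            config.n_timepoints, seed=seeds["simulate"] + 1)
        labels = sorted(int(c) for c in np.unique(community_map) if c)
        half = len(labels) // 2
        networks = {c: ("PMN" if i < half else "ATN")
                    for i, c in enumerate(labels)}
        state["atlas"] = atlas_from_communities(
            community_map, networks, affine=volumes[0].affine)
        motions = [syn.simulate_motion(v.n_frames, seed=seeds["simulate"] + 2 + i)
                   for i, v in enumerate(volumes)]
        state["scans"] = scans
        state["community_map"] = community_map
    state["volumes"] = volumes
    state["motions"] = motions
    state["scans"].to_csv(out / "design.csv", index=False)
    state["atlas"].to_csv(out / "atlas.csv")


def _stage_preprocess(config: RunConfig, seeds, state, out: Path):
    volumes, motions = state["volumes"], state["motions"]
    mask = np.ones(volumes[0].grid_shape, dtype=bool)
    qc_rows, processed = [], []
    for i, (vol, motion) in enumerate(zip(volumes, motions)):
        fd = prep.compute_fd(motion)
        decision = prep.qc_exclude(fd, config.fd_threshold_mm,
                                   config.max_censored_fraction)
        clean = prep.regress_nuisance(vol, motion)
        tsnr_native = prep.compute_tsnr(vol, mask)
        clean = prep.bandpass(clean, config.band_low_hz, config.band_high_hz)
        clean = prep.smooth_gaussian(clean, config.fwhm_mm, mask=mask)
        processed.append(clean)
        qc_rows.append({"scan": i, "mean_fd": float(fd.mean()),
                        "censored_fraction": decision.censored_fraction,
                        "tsnr_native": tsnr_native,
                        "exclude": decision.exclude})
    qc = pd.DataFrame(qc_rows)
    qc.to_csv(out / "qc_report.csv", index=False)
    scans = state["scans"].reset_index(drop=True).copy()
    scans["tsnr"] = qc["tsnr_native"].to_numpy()  # measured, replaces any prior
    excluded_subjects = sorted(scans.loc[qc["exclude"].to_numpy(),
                                         "subject"].unique())
    keep = ~scans["subject"].isin(excluded_subjects)
    state["excluded_subjects"] = excluded_subjects
    state["volumes"] = [v for v, k in zip(processed, keep) if k]
    state["scans"] = scans.loc[keep].reset_index(drop=True)
    state["mask"] = prep.group_mask([np.ones(v.grid_shape, bool)
                                     for v in processed])


def _stage_roi(config: RunConfig, seeds, state, out: Path):
    atlas = state["atlas"]
    matrices = []
    for vol in state["volumes"]:
        series = []
        for name in atlas.names:
            row = atlas.regions.set_index("name").loc[name]
            vox = roi.sphere_voxels(atlas.center_mm(name), row["radius_mm"],
                                    vol.grid_shape, affine=vol.affine,
                                    mask=state["mask"], name=name)
            series.append(roi.extract_mean_timeseries(vol, vox))
        matrices.append(roi.connectivity_matrix(np.asarray(series), atlas.names))
    state["matrices"] = matrices
    table = roi.scan_connectivity_table(matrices, state["scans"], atlas,
                                        networks=tuple(atlas.networks))
    table.to_csv(out / "network_connectivity.csv", index=False)
    state["long_table"] = table


def _stage_lme(config: RunConfig, seeds, state, out: Path):
    rows = []
    for network, sub in state["long_table"].groupby("network"):
        res = lme.fit_lme(sub, model="threeway",
                          include_order=config.include_order,
                          hierarchy=config.hierarchy)
        terms = res.terms.copy()
        terms.insert(0, "network", network)
        terms["converged"] = res.converged
        rows.append(terms)
    pd.concat(rows).to_csv(out / "lme_results.csv", index=False)
    atlas = state["atlas"]
    pmn = atlas.members("PMN")
    if len(pmn) >= 2:
        edges = lme.edge_interaction_tests(state["matrices"], state["scans"],
                                           pmn, hierarchy=config.hierarchy)
        edges.to_csv(out / "edge_tests.csv", index=False)


def _stage_connectedness(config: RunConfig, seeds, state, out: Path):
    mask = state["mask"]
    maps = []
    for vol in state["volumes"]:
        vol_map, mask = conn.global_connectedness(vol, mask)
        maps.append(vol_map)
    state["conn_maps"] = maps
    state["mask"] = mask
    mean_map = np.nanmean(np.stack(maps), axis=0)
    vol0 = state["volumes"][0]
    import nibabel as nib
    nib.save(nib.Nifti1Image(np.nan_to_num(mean_map), vol0.affine),
             str(out / "mean_connectedness.nii.gz"))
    null = conn.permutation_cluster_cutoff(
        maps, state["scans"], mask, terms=(lme.THREEWAY_TERM,),
        n_permutations=config.n_permutations, alpha=config.alpha,
        p_two_tailed=config.p_two_tailed, connectivity=config.connectivity,
        seed=seeds["connectedness"],
        min_permutations=config.min_permutations)
    pd.DataFrame({"max_size": null.max_sizes[lme.THREEWAY_TERM]}) \
        .to_csv(out / "permutation_null.csv", index=False)
    statmap = conn.voxelwise_lme(maps, state["scans"], mask,
                                 term=lme.THREEWAY_TERM)
    clusters = conn.apply_cutoff(
        conn.threshold_and_label(statmap, config.p_two_tailed,
                                 config.connectivity),
        null.cutoff)
    clusters.table.assign(cutoff=null.cutoff) \
        .to_csv(out / "clusters.csv", index=False)
    state["clusters"] = clusters
    state["cutoff"] = null.cutoff


def _stage_drivers(config: RunConfig, seeds, state, out: Path):
    clusters = state["clusters"]
    if clusters.n_clusters == 0:
        (out / "drivers_skipped.txt").write_text(
            "no clusters survived the permutation cutoff; driver stage "
            "skipped\n")
        state["driver_clusters"] = None
        return
    largest = clusters.table.sort_values("size", ascending=False).iloc[0]
    seed_vox = clusters.voxels(int(largest["id"]))
    seed_maps = [drv.seed_driver_map(vol, seed_vox, state["mask"])
                 for vol in state["volumes"]]
    driver_clusters = drv.driver_inference(
        seed_maps, state["scans"], state["mask"],
        p_two_tailed=config.driver_p, min_extent=config.driver_extent,
        connectivity=config.connectivity)
    reference = np.zeros(state["mask"].shape, dtype=int)
    alle = drv.classify_allegiance(driver_clusters, state["atlas"], reference,
                                   affine=state["volumes"][0].affine)
    alle.to_csv(out / "driver_allegiance.csv", index=False)
    driver_clusters.table.to_csv(out / "driver_clusters.csv", index=False)
    state["driver_clusters"] = driver_clusters


def _stage_behavior(config: RunConfig, seeds, state, out: Path):
    clusters = state.get("clusters")
    scans = state["scans"]
    if clusters is not None and clusters.n_clusters:
        target = clusters.table.sort_values("size", ascending=False).iloc[0]
        vox = clusters.voxels(int(target["id"]))
    elif state.get("community_map") is not None:
        vox = np.argwhere(state["community_map"] > 0)
    else:
        vox = np.argwhere(state["mask"])
    values = scans.copy()
    values["value"] = [float(np.nanmean(m[tuple(vox.T)]))
                       for m in state["conn_maps"]]
    effects = bhv.interaction_effect_per_subject(values)
    spec = config.effect_spec()
    _, scores = syn.simulate_behavior(scans, effects, spec,
                                      seed=seeds["behavior"])
    scores.to_csv(out / "behavior_scores.csv", index=False)
    wide = scores.pivot(index="subject", columns="assessment",
                        values="context_recollection")
    change = (wide["post_stim"] - wide["post_sham"]).reindex(effects.index)
    tsnr = scans.groupby("subject")["tsnr"].mean().reindex(effects.index) \
        if "tsnr" in scans else None
    fit = bhv.robust_brain_behavior(
        effects.to_numpy(), change.to_numpy(),
        tsnr=None if tsnr is None else tsnr.to_numpy())
    contrast = bhv.behavior_contrast(scores)
    report = {
        "robust_slope": fit.slope, "robust_F": fit.f_stat,
        "robust_df": list(fit.df), "robust_p": fit.p,
        "r_squared": fit.r_squared, "n": fit.n,
        "paired_t": contrast.t, "paired_p_one_tailed": contrast.p,
        "mean_context_change": contrast.mean_difference,
    }
    with open(out / "brain_behavior.json", "w") as fh:
        json.dump(report, fh, indent=2)
    state["brain_behavior"] = report


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "roi": _stage_roi,
    "lme": _stage_lme,
    "connectedness": _stage_connectedness,
    "drivers": _stage_drivers,
    "behavior": _stage_behavior,
}
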
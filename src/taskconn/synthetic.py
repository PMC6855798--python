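"""Synthetic multi-subject study generator.

Emulates the study design downstream stages expect: two stimulation-target
groups (PMN-targeted, PFC-targeted control) x two conditions (stim, sham) x
two tasks (autobiographical retrieval, rest) per subject, with a planted
condition x task x group interaction on within-network Fisher-z connectivity,
heterogeneous tSNR, head-motion traces, and a behavioural context-recollection
change linearly coupled to each subject's connectivity interaction effect.

ROI-level series are multivariate Gaussian draws whose population correlation
between same-network regions is tanh(baseline_z + subject intercept + planted
increments), zero across networks — exactly the structure Pearson correlation
plus Fisher-z mixed-model inference assumes. Voxel-level series share a latent
signal within labelled communities so community voxels have elevated global
connectedness. No hemodynamic or physiological-noise modelling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import score_memory
from .volume import VolumeSeries

__all__ = [
    "EffectSpec",
    "make_design",
    "simulate_roi_timeseries",
    "simulate_voxel_dataset",
    "simulate_behavior",
    "simulate_motion",
    "block_community_map",
]

GROUPS = ("PMN", "PFC")
CONDITIONS = ("stim", "sham")
TASKS = ("retrieval", "rest")

#: Additive offset giving the series a realistic nonzero mean so tSNR
#: (temporal mean / SD) is well defined.
SIGNAL_MEAN = 100.0


@dataclass(frozen=True)
class EffectSpec:
    """Generating effect sizes, all on the Fisher-z connectivity scale.

    delta_3way is the planted interaction: it is added to within-network
    (or within-community) z only for scans in the (group=PMN, condition=stim,
    task=retrieval) cell. delta_task (retrieval minus rest) is available for
    direction checks and defaults to zero. subject_sd is the SD of the
    additive per-subject random intercept; noise_sd is per-scan, per-edge
    Gaussian jitter on the generating z. behavior_slope couples the
    per-subject interaction effect to the context-recollection change
    (proportion units per unit Fisher z) with Gaussian noise behavior_sd.
    """

    baseline_z: float = 0.3
    delta_3way: float = 0.25
    delta_task: float = 0.0
    subject_sd: float = 0.1
    noise_sd: float = 0.05
    behavior_slope: float = 0.5
    behavior_sd: float = 0.1
    community_mixing: float = 0.5
    tsnr_base: float = 60.0
    tsnr_log_sd: float = 0.2

    def __post_init__(self):
        for name in ("subject_sd", "noise_sd", "behavior_sd", "tsnr_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.community_mixing <= 1.0:
            raise ValueError("community_mixing must lie in [0, 1]")
        if self.tsnr_base <= 0:
            raise ValueError("tsnr_base must be positive")
        for name in ("baseline_z", "delta_3way", "delta_task"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def make_design(n_per_group: int, seed: int) -> pd.DataFrame:
    """Scan design table: 2*n_per_group subjects x 4 scans each.

    Group is constant within subject (first block PMN-targeted, second block
    PFC-targeted control); stim/sham week order is counterbalanced within
    each group (exactly half stim-first when n_per_group is even; the odd
    subject's order is randomised).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    subject = 0
    for group in GROUPS:
        half = n_per_group // 2
        orders = ["stim_first"] * half + ["sham_first"] * half
        if n_per_group % 2:
            orders.append(rng.choice(["stim_first", "sham_first"]))
        orders = list(rng.permutation(orders))
        for order in orders:
            subject += 1
            for condition in CONDITIONS:
                for task in TASKS:
                    rows.append({"subject": subject, "group": group,
                                 "condition": condition, "task": task,
                                 "order": order})
    return pd.DataFrame(rows)


def _subject_intercepts(design: pd.DataFrame, effects: EffectSpec,
                        rng: np.random.Generator) -> dict:
    subjects = design["subject"].unique()
    draws = rng.normal(0.0, effects.subject_sd, size=subjects.size)
    return dict(zip(subjects, draws))


def _cell_z(scan, effects: EffectSpec, intercept: float) -> float:
    """Generating within-network Fisher z for one scan's design cell."""
    z = effects.baseline_z + intercept
    if scan["task"] == "retrieval":
        z += effects.delta_task
    if (scan["group"] == "PMN" and scan["condition"] == "stim"
            and scan["task"] == "retrieval"):
        z += effects.delta_3way
    return z


def _scan_noise_scale(effects: EffectSpec, rng: np.random.Generator):
    scale = float(np.exp(rng.normal(0.0, effects.tsnr_log_sd)))
    return scale, effects.tsnr_base / scale


def _nearest_correlation(C: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and renormalise the diagonal to 1."""
    vals, vecs = np.linalg.eigh(C)
    if vals.min() > 1e-10:
        return C
    vals = np.clip(vals, 1e-8, None)
    C = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def simulate_roi_timeseries(design: pd.DataFrame, atlas, effects: EffectSpec,
                            n_timepoints: int, seed: int,
                            planted_networks=None):
    """Per-scan region x time series with block correlation structure.

    Returns ``(series_list, scans)`` where ``series_list[i]`` is the
    (n_regions, n_timepoints) array for row i of the returned ``scans``
    table (the design plus a per-scan tsnr column). By default the planted
    delta_3way/delta_task increments apply to every within-network edge;
    ``planted_networks`` restricts them to a subset of networks.
    """
    if n_timepoints < 20:
        raise ValueError("n_timepoints must be >= 20")
    networks = atlas.regions["network"].to_numpy()
    for network in np.unique(networks):
        if (networks == network).sum() < 2:
            raise ValueError(f"network {network!r} needs >= 2 regions")
    rng = np.random.default_rng(seed)
    intercepts = _subject_intercepts(design, effects, rng)
    same_network = (networks[:, None] == networks[None, :])
    n_regions = networks.size
    off_diag = ~np.eye(n_regions, dtype=bool)
    planted = set(np.unique(networks) if planted_networks is None
                  else planted_networks)
    in_planted = np.isin(networks, sorted(planted))
    planted_block = in_planted[:, None] & in_planted[None, :]
    series_list, tsnrs = [], []
    for _, scan in design.iterrows():
        base = effects.baseline_z + intercepts[scan["subject"]]
        z0 = _cell_z(scan, effects, intercepts[scan["subject"]])
        Z = np.zeros((n_regions, n_regions))
        Z[same_network & off_diag] = base
        Z[same_network & off_diag & planted_block] = z0
        if effects.noise_sd > 0:
            noise = rng.normal(0.0, effects.noise_sd,
                               size=(n_regions, n_regions))
            noise = (noise + noise.T) / np.sqrt(2.0)
            Z = np.where(same_network & off_diag, Z + noise, Z)
        C = np.tanh(Z)
        np.fill_diagonal(C, 1.0)
        C = _nearest_correlation(C)
        L = np.linalg.cholesky(C)
        x = L @ rng.standard_normal((n_regions, n_timepoints))
        scale, tsnr = _scan_noise_scale(effects, rng)
        series_list.append(SIGNAL_MEAN + scale * x)
        tsnrs.append(tsnr)
    scans = design.reset_index(drop=True).copy()
    scans["tsnr"] = tsnrs
    return series_list, scans


def block_community_map(grid_shape, n_communities: int,
                        block: int = 4) -> np.ndarray:
    """Pack ``n_communities`` cubic blocks of side ``block`` into a grid.

    Labels are 1..n_communities; 0 is unlabelled background. Blocks are laid
    out on a regular lattice with one-voxel gaps where space allows.
    """
    grid_shape = tuple(grid_shape)
    labels = np.zeros(grid_shape, dtype=int)
    step = block + 1
    anchors = [(i, j, k)
               for i in range(0, grid_shape[0] - block + 1, step)
               for j in range(0, grid_shape[1] - block + 1, step)
               for k in range(0, grid_shape[2] - block + 1, step)]
    if len(anchors) < n_communities:
        raise ValueError(f"grid {grid_shape} fits only {len(anchors)} "
                         f"blocks of side {block}")
    for label, (i, j, k) in enumerate(anchors[:n_communities], start=1):
        labels[i:i + block, j:j + block, k:k + block] = label
    return labels


def simulate_voxel_dataset(design: pd.DataFrame, grid_shape, community_map,
                           effects: EffectSpec, n_timepoints: int, seed: int,
                           planted_communities=None, voxel_size_mm=2.0,
                           repetition_time_s=0.555):
    """Voxel-level study: per-scan 4D series with community-shared latents.

    Voxels sharing a community label mix a common latent signal with weight
    w = sqrt(r), where r = tanh(z) is the community's generating correlation
    for that scan (baseline ``community_mixing^2`` coupling plus planted
    increments, analogous to :func:`simulate_roi_timeseries`). Background
    (label 0) voxels are independent noise. ``planted_communities`` limits
    delta_3way / delta_task to a subset of labels (default: all communities).

    Returns ``(volumes, mask, scans)``: a list of :class:`VolumeSeries`, an
    all-true analysis mask, and the design with a tsnr column.
    """
    grid_shape = tuple(grid_shape)
    community_map = np.asarray(community_map)
    if community_map.shape != grid_shape:
        raise ValueError(f"community map shape {community_map.shape} != grid "
                         f"{grid_shape}")
    labels = [int(c) for c in np.unique(community_map) if c != 0]
    planted = set(labels if planted_communities is None
                  else [int(c) for c in planted_communities])
    base_r = effects.community_mixing ** 2
    base_z = np.inf if base_r >= 1.0 else float(np.arctanh(base_r))
    rng = np.random.default_rng(seed)
    intercepts = _subject_intercepts(design, effects, rng)
    flat_labels = community_map.ravel()
    n_vox = flat_labels.size
    volumes, tsnrs = [], []
    vsize = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    for _, scan in design.iterrows():
        interc = intercepts[scan["subject"]]
        data = rng.standard_normal((n_timepoints, n_vox))
        for c in labels:
            z = base_z + interc
            if c in planted:
                z += _cell_z(scan, effects, 0.0) - effects.baseline_z
            if effects.noise_sd > 0:
                z += rng.normal(0.0, effects.noise_sd)
            r = float(np.clip(np.tanh(z), 0.0, 1.0))
            latent = rng.standard_normal(n_timepoints)
            members = flat_labels == c
            if r >= 1.0 - 1e-12:  # perfectly coupled community
                data[:, members] = latent[:, None]
            else:
                data[:, members] = (np.sqrt(r) * latent[:, None]
                                    + np.sqrt(1.0 - r) * data[:, members])
        scale, tsnr = _scan_noise_scale(effects, rng)
        data = SIGNAL_MEAN + scale * data
        volumes.append(VolumeSeries(data=data.reshape((n_timepoints,) + grid_shape),
                                    voxel_size_mm=vsize,
                                    repetition_time_s=repetition_time_s))
        tsnrs.append(tsnr)
    scans = design.reset_index(drop=True).copy()
    scans["tsnr"] = tsnrs
    mask = np.ones(grid_shape, dtype=bool)
    return volumes, mask, scans


def simulate_motion(n_frames: int, seed: int, step_mm: float = 0.02,
                    step_rad: float = 2e-4, spike_rate: float = 0.02,
                    spike_mm: float = 0.4) -> np.ndarray:
    """Random-walk 6-parameter motion trace with occasional spikes.

    Columns: x/y/z translations (mm) then roll/pitch/yaw rotations (rad).
    """
    rng = np.random.default_rng(seed)
    steps = np.column_stack([
        rng.normal(0.0, step_mm, size=(n_frames, 3)).reshape(n_frames, 3),
        rng.normal(0.0, step_rad, size=(n_frames, 3)).reshape(n_frames, 3),
    ])
    spikes = rng.random(n_frames) < spike_rate
    steps[spikes, 0] += rng.choice([-1, 1], size=spikes.sum()) * spike_mm
    motion = np.cumsum(steps, axis=0)
    motion[0] = 0.0
    return motion


ASSESSMENTS = ("pre_stim", "post_stim", "pre_sham", "post_sham")


def simulate_behavior(design: pd.DataFrame, interaction_effects,
                      effects: EffectSpec, seed: int, n_old: int = 42,
                      p_item: float = 0.85, p_high_conf: float = 0.75,
                      p_context_base: float = 0.5):
    """Trial-level memory data coupled to the connectivity interaction effect.

    Each subject completes four assessments with 84 test trials each (42 old
    + 42 new objects; context chosen among 6 options). The generating
    post-stim minus post-sham context-recollection change equals
    ``behavior_slope * interaction_effect + N(0, behavior_sd)``, truncated so
    all proportions stay in [0, 1].

    Returns ``(trials, scores)``: a dict keyed by (subject, assessment) of
    trial tables, and a tidy per-subject per-assessment score table.
    """
    subjects = design["subject"].unique()
    ie = pd.Series(interaction_effects)
    missing = set(subjects) - set(ie.index)
    if missing:
        raise ValueError(f"no interaction effect for subjects {sorted(missing)}")
    rng = np.random.default_rng(seed)
    trials_out, score_rows = {}, []
    for subject in subjects:
        change = (effects.behavior_slope * float(ie[subject])
                  + rng.normal(0.0, effects.behavior_sd))
        p_ctx = {a: p_context_base for a in ASSESSMENTS}
        p_ctx["post_stim"] = float(np.clip(p_context_base + change, 0.0, 1.0))
        for assessment in ASSESSMENTS:
            trials = _simulate_trials(rng, n_old, p_item, p_high_conf,
                                      p_ctx[assessment])
            trials_out[(subject, assessment)] = trials
            score = score_memory(trials)
            score_rows.append({"subject": subject, "assessment": assessment,
                               "item_recognition": score.item_recognition,
                               "context_recollection": score.context_recollection,
                               "n_high_conf_hits": score.n_high_conf_hits})
    return trials_out, pd.DataFrame(score_rows)


def _simulate_trials(rng, n_old, p_item, p_high_conf, p_context) -> pd.DataFrame:
    n = 2 * n_old
    is_old = np.r_[np.ones(n_old, bool), np.zeros(n_old, bool)]
    correct = rng.random(n) < p_item
    resp_old = np.where(is_old, correct, ~correct)
    confidence = np.where(rng.random(n) < p_high_conf, "high", "low")
    context_truth = np.where(is_old, rng.integers(1, 7, size=n), 0)
    context_choice = np.zeros(n, dtype=int)
    for i in range(n):
        if not is_old[i]:
            continue
        if rng.random() < p_context:
            context_choice[i] = context_truth[i]
        else:
            others = [c for c in range(1, 7) if c != context_truth[i]]
            context_choice[i] = rng.choice(others)
    trials = pd.DataFrame({
        "is_old": is_old, "resp_old": resp_old, "confidence": confidence,
        "context_truth": context_truth, "context_choice": context_choice,
    })
    return trials.sample(frac=1.0, random_state=rng.integers(2 ** 31)) \
                 .reset_index(drop=True)
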
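"""Synthetic ROI time-series panels with planted, block-varying community
structure, and synthetic trial-outcome tables.

The generator emulates the block design of an in-scanner dual n-back run:
20 alternating 1-back/2-back blocks of 30 s (15 volumes at TR = 2 s), with
ROI signals drawn per block from a zero-mean Gaussian whose correlation
structure encodes a planted partition (compound symmetry: ``rho_within`` on
same-module pairs, ``rho_between`` elsewhere). Planted partitions may change
from block to block, which gives every downstream stage — connectivity,
community detection, allegiance cartography — a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seeds

__all__ = [
    "SystemAtlas",
    "ScenarioSpec",
    "TrialSpec",
    "planted_covariance",
    "generate_panel",
    "generate_trials",
    "alternating_conditions",
    "constant_partitions",
    "stable_splitting_partitions",
    "simulate_trial_table",
]


@dataclass(frozen=True)
class SystemAtlas:
    """ROI -> large-scale-system lookup (an atlas table).

    ``labels[i]`` is the system label of the ROI in row ``i`` of a panel.
    """

    roi_ids: tuple
    labels: tuple

    def __post_init__(self):
        if len(self.roi_ids) != len(self.labels):
            raise ValueError("roi_ids and labels must align")
        if len(self.systems) < 2:
            raise ValueError("an atlas needs at least 2 systems")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def systems(self) -> tuple:
        seen = []
        for s in self.labels:
            if s not in seen:
                seen.append(s)
        return tuple(seen)

    def members(self, system) -> np.ndarray:
        """Row indices of the ROIs belonging to ``system``."""
        idx = np.flatnonzero(np.asarray(self.labels, dtype=object) == system)
        if idx.size == 0:
            raise KeyError(f"unknown system: {system!r}")
        return idx

    @classmethod
    def equal_systems(cls, n_rois: int, n_systems: int,
                      names: Sequence[str] | None = None) -> "SystemAtlas":
        """Atlas with ``n_systems`` contiguous equal-sized systems."""
        if n_rois % n_systems:
            raise ValueError("n_rois must be divisible by n_systems")
        if names is None:
            names = [f"sys{k}" for k in range(n_systems)]
        size = n_rois // n_systems
        labels = tuple(names[i // size] for i in range(n_rois))
        return cls(tuple(range(n_rois)), labels)

    @classmethod
    def from_table(cls, path) -> "SystemAtlas":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(df["roi_id"]), tuple(df["system_label"]))

    def to_table(self, path) -> None:
        pd.DataFrame({"roi_id": self.roi_ids, "system_label": self.labels}
                     ).to_csv(path, sep="\t", index=False)


def alternating_conditions(n_blocks: int = 20,
                           labels: Sequence[str] = ("1-back", "2-back")
                           ) -> list:
    """Strictly alternating condition sequence, as in the scanner task."""
    return [labels[b % len(labels)] for b in range(n_blocks)]


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one synthetic scanning run."""

    n_nodes: int
    atlas: SystemAtlas
    planted_partitions: tuple  # one node->module label array per block
    rho_within: float
    rho_between: float
    noise_sd: float = 1.0
    n_blocks: int = 20
    samples_per_block: int = 15  # 30 s blocks at TR = 2 s
    tr_seconds: float = 2.0
    condition_sequence: tuple = ()
    hrf_smear: bool = False  # convolve latent block signals with the HRF
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1 or self.n_blocks < 1 or self.samples_per_block < 1:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0 <= self.rho_between <= self.rho_within < 1):
            raise ValueError("need 0 <= rho_between <= rho_within < 1")
        if self.atlas.n_rois != self.n_nodes:
            raise ValueError("atlas size must match n_nodes")
        if not self.condition_sequence:
            object.__setattr__(self, "condition_sequence",
                               tuple(alternating_conditions(self.n_blocks)))
        if len(self.condition_sequence) != self.n_blocks:
            raise ValueError("condition_sequence length must equal n_blocks")
        if len(self.planted_partitions) != self.n_blocks:
            raise ValueError("need one planted partition per block")
        for part in self.planted_partitions:
            if len(part) != self.n_nodes:
                raise ValueError("each planted partition must cover all nodes")

    def with_seed(self, seed: int) -> "ScenarioSpec":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class TrialSpec:
    """Bernoulli trial-outcome model for one scored cell."""

    n_targets: int
    n_nontargets: int
    hit_prob: float
    fa_prob: float
    seed: int = 0

    def __post_init__(self):
        if self.n_targets < 1 or self.n_nontargets < 1:
            raise ValueError("trial counts must be >= 1")
        for p in (self.hit_prob, self.fa_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


def planted_covariance(partition, rho_within: float, rho_between: float
                       ) -> np.ndarray:
    """Compound-symmetric covariance encoding a module partition.

    Unit diagonal; ``rho_within`` for same-module pairs, ``rho_between``
    otherwise. Positive semidefinite for all 0 <= rho_between <= rho_within
    < 1, because it decomposes into rho_between * J + (rho_within -
    rho_between) * blockdiag(J_s) + (1 - rho_within) * I, a sum of PSD terms.
    """
    if not (0 <= rho_between <= rho_within < 1):
        raise ValueError("need 0 <= rho_between <= rho_within < 1 "
                         "(PSD not guaranteed otherwise)")
    part = np.asarray(partition, dtype=object)
    same = part[:, None] == part[None, :]
    cov = np.where(same, rho_within, rho_between)
    np.fill_diagonal(cov, 1.0)
    return cov.astype(float)


def generate_panel(spec: ScenarioSpec):
    """Draw one synthetic run: ROI x volume signal plus volume annotations.

    Each block's samples come from N(0, planted covariance) plus independent
    N(0, noise_sd^2) noise; per-block random streams derive from ``spec.seed``
    so runs are reproducible and blocks are independent. Returns a
    :class:`~dynmod.connectivity.TimeSeriesPanel`.

    Blocks are annotated 1..n_blocks. With ``hrf_smear`` the latent (pre-
    noise) signal is convolved with the canonical HRF so block boundaries
    bleed as they would in BOLD data.
    """
    from .connectivity import TimeSeriesPanel, canonical_hrf

    seeds = derive_seeds(spec.seed, spec.n_blocks)
    chunks = []
    for b in range(spec.n_blocks):
        cov = planted_covariance(spec.planted_partitions[b],
                                 spec.rho_within, spec.rho_between)
        rng = np.random.default_rng(int(seeds[b]))
        L = np.linalg.cholesky(cov)  # PD: smallest eigenvalue >= 1 - rho_within
        latent = L @ rng.standard_normal((spec.n_nodes, spec.samples_per_block))
        chunks.append((latent, rng))

    latent_all = np.concatenate([c[0] for c in chunks], axis=1)
    if spec.hrf_smear:
        kern = canonical_hrf(spec.tr_seconds)
        smeared = np.apply_along_axis(
            lambda row: np.convolve(row, kern.values)[: row.size], 1, latent_all)
        latent_all = smeared

    noise_rng = np.random.default_rng(int(derive_seeds(spec.seed + 1, 1)[0]))
    signal = latent_all + spec.noise_sd * noise_rng.standard_normal(
        latent_all.shape)

    n_vol = spec.n_blocks * spec.samples_per_block
    annotations = pd.DataFrame({
        "volume": np.arange(n_vol),
        "block": np.repeat(np.arange(1, spec.n_blocks + 1),
                           spec.samples_per_block),
        "condition": np.repeat(np.asarray(spec.condition_sequence,
                                          dtype=object),
                               spec.samples_per_block),
    })
    return TimeSeriesPanel(signal=signal, tr_seconds=spec.tr_seconds,
                           annotations=annotations,
                           roi_ids=list(spec.atlas.roi_ids))


def generate_trials(spec: TrialSpec) -> dict:
    """Binomial trial outcomes for one (subject, session, condition,
    modality) cell: hits over targets, false alarms over non-targets."""
    rng = np.random.default_rng(int(spec.seed))
    hits = int(rng.binomial(spec.n_targets, spec.hit_prob))
    fas = int(rng.binomial(spec.n_nontargets, spec.fa_prob))
    return {
        "hits": hits,
        "misses": spec.n_targets - hits,
        "false_alarms": fas,
        "correct_rejections": spec.n_nontargets - fas,
    }


# ---------------------------------------------------------------------------
# scenario builders


def constant_partitions(atlas: SystemAtlas, n_blocks: int) -> tuple:
    """Planted partition equal to the atlas systems in every block."""
    base = np.asarray(atlas.labels, dtype=object)
    return tuple(base.copy() for _ in range(n_blocks))


def stable_splitting_partitions(atlas: SystemAtlas, n_blocks: int,
                                stable, splitting,
                                merge_into=None) -> tuple:
    """Partitions where ``stable`` keeps one module throughout while
    ``splitting`` loses half its nodes on every other block.

    On odd blocks the defecting half joins ``merge_into``'s module (by
    default the first system that is neither ``stable`` nor ``splitting``),
    so the split is backed by genuine cross-system correlation rather than
    an isolated splinter module. Plants a recruitment contrast: the stable
    system should show higher normalized recruitment than the splitting
    one. Pass ``merge_into=False`` to give the defectors their own module
    instead.
    """
    base = np.asarray(atlas.labels, dtype=object)
    split_idx = atlas.members(splitting)
    atlas.members(stable)  # validate the label exists
    if merge_into is None:
        merge_into = next(s for s in atlas.systems
                          if s not in (stable, splitting))
    if merge_into is False:
        target = f"{splitting}::offshoot"
    else:
        atlas.members(merge_into)
        target = merge_into
    half = split_idx[: len(split_idx) // 2]
    parts = []
    for b in range(n_blocks):
        part = base.copy()
        if b % 2 == 1:
            part[half] = target
        parts.append(part)
    return tuple(parts)


def simulate_trial_table(subjects: Sequence, sessions: Sequence,
                         conditions: Sequence, modalities: Sequence,
                         rates: dict, n_targets: int = 24,
                         n_nontargets: int = 72, seed: int = 0
                         ) -> pd.DataFrame:
    """Full synthetic trial table over a subject x session x condition x
    modality grid.

    ``rates`` maps (session, condition) -> (hit_prob, fa_prob). Trial counts
    default to two scored runs of the scanner task (20 blocks x 12 trials,
    25% targets, per modality).
    """
    cells = [(s, ses, c, m) for s in subjects for ses in sessions
             for c in conditions for m in modalities]
    seeds = derive_seeds(seed, len(cells))
    rows = []
    for child, (subj, ses, cond, mod) in zip(seeds, cells):
        hp, fp = rates[(ses, cond)]
        counts = generate_trials(TrialSpec(n_targets, n_nontargets, hp, fp,
                                           seed=int(child)))
        rows.append({"subject": subj, "session": ses, "condition": cond,
                     "modality": mod, **counts})
    return pd.DataFrame(rows)


def write_panel(panel, out_dir, stem: str = "panel",
                ground_truth: tuple | None = None) -> dict:
    """Write a panel as delimited text: signal matrix, annotation sidecar,
    and (optionally) the ground-truth partitions. Returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sig_path = out / f"{stem}_signal.tsv"
    ann_path = out / f"{stem}_annotations.tsv"
    pd.DataFrame(panel.signal, index=panel.roi_ids).to_csv(
        sig_path, sep="\t", header=False)
    panel.annotations.to_csv(ann_path, sep="\t", index=False)
    paths = {"signal": sig_path, "annotations": ann_path}
    if ground_truth is not None:
        gt = pd.DataFrame(
            {f"block_{b + 1}": np.asarray(part, dtype=object)
             for b, part in enumerate(ground_truth)},
            index=pd.Index(panel.roi_ids, name="roi_id"))
        gt_path = out / f"{stem}_ground_truth.tsv"
        gt.to_csv(gt_path, sep="\t")
        paths["ground_truth"] = gt_path
    return paths
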
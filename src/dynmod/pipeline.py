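"""Study orchestration: synthetic panels -> connectivity -> communities ->
cartography -> behavioral scoring -> group contrasts, driven by a config.

A study is a group x subject x session grid. For every cell the pipeline
builds per-condition connectivity and normalized static modularity, the
multilayer ensemble, the allegiance matrix and permutation-normalized
cartography; behavioral trial tables are scored into d'. A thin
statistical layer then computes the planned contrasts (paired t within
group across sessions, two-sample t between groups on change scores,
Pearson correlations between network change and d' change) with
Bonferroni and Benjamini-Hochberg adjustment per family.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import behavior as bh
from . import synthgen
from ._seeds import derive_seeds
from .cartography import allegiance, permutation_normalize
from .connectivity import block_connectivity, canonical_hrf, \
    condition_connectivity, write_matrix
from .multilayer_community import MultilayerCommunities
from .static_community import LouvainCommunities

log = logging.getLogger("dynmod")

__all__ = ["StudyConfig", "ContrastReport", "run_study", "contrast_tables"]

#: default trial-outcome probabilities (hit, false alarm) per
#: (group, session, condition); chosen once as a realistic trajectory for a
#: six-week adaptive working-memory training study (experimental group
#: improving strongly on the harder condition, passive controls improving
#: mildly through task familiarity)
DEFAULT_RATES = {
    "experimental": {
        "Naive": {"1-back": (0.92, 0.05), "2-back": (0.75, 0.12)},
        "Early": {"1-back": (0.93, 0.05), "2-back": (0.80, 0.10)},
        "Middle": {"1-back": (0.94, 0.04), "2-back": (0.85, 0.08)},
        "Late": {"1-back": (0.94, 0.04), "2-back": (0.88, 0.07)},
    },
    "control": {
        "Naive": {"1-back": (0.92, 0.05), "2-back": (0.75, 0.12)},
        "Early": {"1-back": (0.93, 0.05), "2-back": (0.78, 0.11)},
        "Middle": {"1-back": (0.93, 0.04), "2-back": (0.81, 0.10)},
        "Late": {"1-back": (0.94, 0.04), "2-back": (0.83, 0.09)},
    },
}


@dataclass
class StudyConfig:
    """All knobs of one synthetic study run."""

    out_dir: str = "study_out"
    seed: int = 0
    groups: tuple = ("experimental", "control")
    n_subjects_per_group: int = 2
    sessions: tuple = bh.SESSIONS
    conditions: tuple = bh.CONDITIONS
    modalities: tuple = bh.MODALITIES
    # synthetic scenario
    n_nodes: int = 24
    n_systems: int = 4
    rho_within: float = 0.6
    rho_between: float = 0.05
    noise_sd: float = 1.0
    n_blocks: int = 20
    samples_per_block: int = 15
    tr_seconds: float = 2.0
    # analysis parameters
    gamma: float = 1.0
    omega_same: float = 1.0
    omega_diff: float = 0.5
    n_runs: int = 100
    n_null: int = 100
    n_optimizations: int = 100
    n_perm: int = 1000
    hrf: dict = field(default_factory=lambda: {
        "peak_s": 6.0, "undershoot_s": 16.0, "ratio": 6.0, "length_s": 32.0})
    # behavioral generator
    n_targets: int = 24
    n_nontargets: int = 72
    rates: dict = field(default_factory=lambda: DEFAULT_RATES)
    atlas_path: str | None = None

    def __post_init__(self):
        for name in ("n_subjects_per_group", "n_nodes", "n_systems",
                     "n_blocks", "samples_per_block", "n_runs", "n_null",
                     "n_optimizations", "n_perm", "n_targets",
                     "n_nontargets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        self.groups = tuple(self.groups)
        self.sessions = tuple(self.sessions)
        self.conditions = tuple(self.conditions)
        self.modalities = tuple(self.modalities)
        self.rates = {g: {s: {c: tuple(v) for c, v in sc.items()}
                          for s, sc in gs.items()}
                      for g, gs in self.rates.items()}

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self._as_plain(), fh, sort_keys=True)

    def _as_plain(self) -> dict:
        plain = asdict(self)
        for key in ("groups", "sessions", "conditions", "modalities"):
            plain[key] = list(plain[key])
        plain["rates"] = {g: {s: {c: list(v) for c, v in sc.items()}
                              for s, sc in gs.items()}
                          for g, gs in plain["rates"].items()}
        return plain

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self._as_plain(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def atlas(self) -> synthgen.SystemAtlas:
        if self.atlas_path is not None:
            path = Path(self.atlas_path)
            if not path.exists():
                raise FileNotFoundError(f"atlas file not found: {path}")
            return synthgen.SystemAtlas.from_table(path)
        return synthgen.SystemAtlas.equal_systems(self.n_nodes,
                                                  self.n_systems)


def _cell_seed(config: StudyConfig, group: str, subject: str,
               session: str) -> int:
    cells = [(g, i, s) for g in config.groups
             for i in range(config.n_subjects_per_group)
             for s in config.sessions]
    idx = cells.index((group, int(subject.split("-")[-1]), session))
    return int(derive_seeds(config.seed, len(cells))[idx])


def _analyze_cell(config: StudyConfig, atlas, group: str, subject: str,
                  session: str, cell_dir: Path) -> dict:
    seed = _cell_seed(config, group, subject, session)
    spec = synthgen.ScenarioSpec(
        n_nodes=config.n_nodes, atlas=atlas,
        planted_partitions=synthgen.constant_partitions(
            atlas, config.n_blocks),
        rho_within=config.rho_within, rho_between=config.rho_between,
        noise_sd=config.noise_sd, n_blocks=config.n_blocks,
        samples_per_block=config.samples_per_block,
        tr_seconds=config.tr_seconds, seed=seed)
    panel = synthgen.generate_panel(spec)
    hrf = canonical_hrf(config.tr_seconds, **config.hrf)

    cell_dir.mkdir(parents=True, exist_ok=True)
    measures = {}
    for cond in config.conditions:
        t0 = time.perf_counter()
        A = condition_connectivity(panel, cond, hrf=hrf)
        est = LouvainCommunities(gamma=config.gamma, n_runs=config.n_runs,
                                 n_null=config.n_null,
                                 random_state=seed).fit(A)
        log.info("%s %s %s [%s]: Q=%.4f Qnorm=%.4f (%.1fs)", group, subject,
                 session, cond, est.modularity_,
                 est.normalized_modularity_, time.perf_counter() - t0)
        write_matrix(A, cell_dir / f"connectivity_{cond}.tsv")
        measures[f"Q[{cond}]"] = est.modularity_
        measures[f"Qnorm[{cond}]"] = est.normalized_modularity_

    stack = block_connectivity(panel, hrf=hrf)
    ml = MultilayerCommunities(
        gamma=config.gamma, omega_same=config.omega_same,
        omega_diff=config.omega_diff,
        n_optimizations=config.n_optimizations, random_state=seed).fit(stack)
    P = allegiance(ml.ensemble_)
    carto = permutation_normalize(P, atlas, n_perm=config.n_perm, seed=seed)
    np.savetxt(cell_dir / "assignment_best.tsv", ml.assignment_,
               delimiter="\t", fmt="%d")
    write_matrix(P.P, cell_dir / "allegiance.tsv")
    carto.table.to_csv(cell_dir / "cartography.tsv", sep="\t", index=False)
    measures["Q_ML"] = ml.quality_
    for _, row in carto.table.iterrows():
        measures[f"{row['measure']}[{row['systems']}]"] = row["normalized"]
    return measures


def run_study(config: StudyConfig) -> dict:
    """Execute the full study; returns the output bundle paths and tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = config.atlas()
    atlas.to_table(out / "atlas.tsv")

    measure_rows = []
    for group in config.groups:
        for i in range(config.n_subjects_per_group):
            subject = f"{group}-{i}"
            for session in config.sessions:
                cell_dir = out / subject / session
                try:
                    cell = _analyze_cell(config, atlas, group, subject,
                                         session, cell_dir)
                except Exception as err:
                    raise RuntimeError(
                        f"analysis failed for subject={subject} "
                        f"session={session}: {err}") from err
                for name, value in cell.items():
                    measure_rows.append({
                        "group": group, "subject": subject,
                        "session": session, "measure": name, "value": value})
    measures = pd.DataFrame(measure_rows)

    # behavioral arm: trial tables per group, scored to d'
    dprime_frames = []
    for gi, group in enumerate(config.groups):
        subjects = [f"{group}-{i}"
                    for i in range(config.n_subjects_per_group)]
        rates = {(s, c): tuple(config.rates[group][s][c])
                 for s in config.sessions for c in config.conditions}
        trials = synthgen.simulate_trial_table(
            subjects, config.sessions, config.conditions, config.modalities,
            rates, n_targets=config.n_targets,
            n_nontargets=config.n_nontargets,
            seed=int(derive_seeds(config.seed + 7, gi + 1)[-1]))
        scored = bh.subject_dprime(trials, config.modalities)
        scored.insert(0, "group", group)
        dprime_frames.append(scored)
        trials.to_csv(out / f"trials_{group}.tsv", sep="\t", index=False)
    dprimes = pd.concat(dprime_frames, ignore_index=True)

    for cond in config.conditions:
        sel = dprimes[dprimes["condition"] == cond].rename(
            columns={"dprime": "value"})
        sel = sel.assign(measure=f"dprime[{cond}]")
        measures = pd.concat(
            [measures, sel[["group", "subject", "session", "measure",
                            "value"]]], ignore_index=True)

    report = contrast_tables(measures,
                             dprime_measure=f"dprime[{config.conditions[-1]}]",
                             before=config.sessions[0],
                             after=config.sessions[-1])

    measures.to_csv(out / "measures.tsv", sep="\t", index=False)
    dprimes.to_csv(out / "dprimes.tsv", sep="\t", index=False)
    report.paired.to_csv(out / "contrasts_paired.tsv", sep="\t", index=False)
    report.between.to_csv(out / "contrasts_between.tsv", sep="\t",
                          index=False)
    report.correlations.to_csv(out / "contrasts_correlations.tsv", sep="\t",
                               index=False)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    (out / "stamp.json").write_text(json.dumps(stamp, indent=2))
    config.to_yaml(out / "config_used.yaml")
    return {"out_dir": out, "measures": measures, "dprimes": dprimes,
            "contrasts": report, "stamp": stamp}


# ---------------------------------------------------------------------------
# contrast layer


@dataclass(frozen=True)
class ContrastReport:
    """Planned contrasts with raw and adjusted p-values per family."""

    paired: pd.DataFrame
    between: pd.DataFrame
    correlations: pd.DataFrame


def _paired_t(before: np.ndarray, after: np.ndarray) -> tuple:
    """Paired t with explicit handling of degenerate difference variance."""
    diff = np.asarray(after, float) - np.asarray(before, float)
    if diff.size < 2:
        raise ValueError("paired t-test needs >= 2 subjects")
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, 1.0, "no change"
        return np.inf, 0.0, "degenerate variance"
    t, p = stats.ttest_rel(after, before)
    return float(t), float(p), ""


def _adjust(df: pd.DataFrame) -> pd.DataFrame:
    """Append Bonferroni and Benjamini-Hochberg columns (family = table)."""
    if df.empty:
        return df
    p = df["p"].to_numpy()
    df = df.copy()
    df["p_bonferroni"] = np.minimum(p * len(p), 1.0)
    df["p_fdr_bh"] = multipletests(p, method="fdr_bh")[1]
    return df


def _change_scores(values: pd.DataFrame, measure: str, before: str,
                   after: str) -> pd.DataFrame:
    sel = values[values["measure"] == measure]
    pivot = sel.pivot_table(index=["group", "subject"], columns="session",
                            values="value").reset_index()
    if before not in pivot.columns or after not in pivot.columns:
        raise ValueError(f"sessions {before!r}/{after!r} missing for "
                         f"measure {measure!r}")
    pivot["change"] = pivot[after] - pivot[before]
    return pivot


def contrast_tables(values: pd.DataFrame, dprime_measure: str | None = None,
                    before: str = "Naive", after: str = "Late"
                    ) -> ContrastReport:
    """Planned contrasts over a long table (group, subject, session,
    measure, value).

    * paired: within each group and measure, t-test of ``after`` vs
      ``before`` across subjects;
    * between: two-sample Welch t-test of change scores, first group vs
      second;
    * correlations: Pearson r between each network measure's change and
      the change of ``dprime_measure`` across all subjects.

    Each table is a multiple-testing family and carries Bonferroni and
    Benjamini-Hochberg adjusted p-values.
    """
    needed = {"group", "subject", "session", "measure", "value"}
    if not needed.issubset(values.columns):
        raise ValueError(f"values table needs columns {sorted(needed)}")
    measures = list(dict.fromkeys(values["measure"]))
    groups = list(dict.fromkeys(values["group"]))

    paired_rows, between_rows, corr_rows = [], [], []
    changes = {m: _change_scores(values, m, before, after) for m in measures}
    for m in measures:
        pivot = changes[m]
        for g in groups:
            sub = pivot[pivot["group"] == g]
            if len(sub) < 2:
                raise ValueError(f"fewer than 2 subjects in cell "
                                 f"({g}, {m})")
            t, p, note = _paired_t(sub[before], sub[after])
            paired_rows.append({
                "measure": m, "group": g,
                "mean_before": float(sub[before].mean()),
                "mean_after": float(sub[after].mean()),
                "t": t, "df": len(sub) - 1, "p": p, "note": note})
        if len(groups) >= 2:
            a = pivot.loc[pivot["group"] == groups[0], "change"]
            b = pivot.loc[pivot["group"] == groups[1], "change"]
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                t, p, note = (0.0, 1.0, "no change") if np.allclose(
                    a.mean(), b.mean()) else (np.inf, 0.0,
                                              "degenerate variance")
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
                t, p, note = float(t), float(p), ""
            between_rows.append({
                "measure": m, "groups": f"{groups[0]} vs {groups[1]}",
                "mean_change_a": float(a.mean()),
                "mean_change_b": float(b.mean()),
                "t": t, "p": p, "note": note})
    if dprime_measure is not None:
        if dprime_measure not in changes:
            raise ValueError(f"{dprime_measure!r} absent from values")
        dchange = changes[dprime_measure].set_index(["group", "subject"])
        for m in measures:
            if m == dprime_measure or m.startswith("dprime"):
                continue
            mchange = changes[m].set_index(["group", "subject"])
            joined = mchange[["change"]].join(
                dchange[["change"]], lsuffix="_measure", rsuffix="_dprime"
            ).dropna()
            if len(joined) < 3:
                continue
            if (joined["change_measure"].std(ddof=1) == 0
                    or joined["change_dprime"].std(ddof=1) == 0):
                corr_rows.append({"measure": m, "r": np.nan, "p": 1.0,
                                  "n": len(joined),
                                  "note": "degenerate variance"})
                continue
            r, p = stats.pearsonr(joined["change_measure"],
                                  joined["change_dprime"])
            corr_rows.append({"measure": m, "r": float(r), "p": float(p),
                              "n": len(joined), "note": ""})
    return ContrastReport(paired=_adjust(pd.DataFrame(paired_rows)),
                          between=_adjust(pd.DataFrame(between_rows)),
                          correlations=_adjust(pd.DataFrame(corr_rows)))
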
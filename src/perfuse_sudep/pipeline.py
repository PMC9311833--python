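"""End-to-end orchestration: simulate -> quantify -> cluster -> summarize -> screen.

Every stage is a pure function of (inputs, config, seed); ``run_all`` chains
them and writes plain CSV/JSON intermediates plus a ``report.md`` so each
stage can be re-run and checked independently.  Outputs carry no timestamps,
making whole runs byte-reproducible for a given config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .atlas import AtlasSpec, default_atlas
from .cluster import cluster_scan, label_extremes, select_k_vfold
from .patterns import describe, match_frequencies, summarize_clusters
from .quantify import PerfusionVector, RoiActivityTable, change_vector, perfusion_index
from .sudep import DEFAULT_WEIGHTS, hypo_burden_correlation, screen_features
from .synthetic import generate_roi_cohort, get_config

__all__ = ["RunConfig", "run_all"]


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serializable configuration of one full pipeline run."""

    seed: int = 42
    cohort: str = "paperlike"  # named synthetic config, or "tables" for CSV input
    roi_csv: str | None = None  # required when cohort == "tables"
    clinical_csv: str | None = None
    noise_sd: float = 0.02
    pi_denominator: str = "rest"
    psf_fwhm_mm: float = 8.0
    k_min: int = 2
    k_max: int = 10
    folds: int = 10
    improvement_threshold: float = 0.05
    n_restarts: int = 20
    engine: str = "lloyd"
    screen_intervals: int = 10
    screen_top_k: int = 3
    screen_p_threshold: float = 0.05
    sudep7_weights: tuple = DEFAULT_WEIGHTS
    percent_style: str = "round"

    def validate(self) -> None:
        if self.pi_denominator not in ("rest", "global"):
            raise ConfigError(f"unknown PI denominator mode {self.pi_denominator!r}")
        if self.engine not in ("lloyd", "dp"):
            raise ConfigError(f"unknown cluster engine {self.engine!r}")
        if self.percent_style not in ("round", "truncate"):
            raise ConfigError(f"unknown percent style {self.percent_style!r}")
        if self.cohort == "tables":
            if not self.roi_csv or not self.clinical_csv:
                raise ConfigError("cohort 'tables' needs roi_csv and clinical_csv paths")
        elif self.cohort != "paperlike":
            raise ConfigError(f"unknown cohort {self.cohort!r}")
        if not (1 <= self.k_min < self.k_max):
            raise ConfigError("need 1 <= k_min < k_max")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if len(tuple(self.sudep7_weights)) != 7:
            raise ConfigError("sudep7_weights must have 7 entries")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "sudep7_weights" in raw:
            raw["sudep7_weights"] = tuple(raw["sudep7_weights"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sudep7_weights"] = list(self.sudep7_weights)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# --------------------------------------------------------------------------
# stage functions (importable by the analysis scripts and tests)

def load_inputs(config: RunConfig, atlas: AtlasSpec):
    """ROI tables + clinical table, simulated or read from CSV."""
    if config.cohort == "tables":
        frame = pd.read_csv(config.roi_csv)
        tables = {(t.patient_id, t.state): t for t in RoiActivityTable.from_frame(frame)}
        clinical = pd.read_csv(config.clinical_csv).set_index("patient")
        return tables, clinical
    cohort_cfg = get_config(config.cohort, seed=config.seed)
    cohort_cfg.noise_sd = config.noise_sd
    cohort = generate_roi_cohort(cohort_cfg, atlas)
    return cohort.tables, cohort.clinical


def relabel_vector(vec: PerfusionVector, onset_side: str, atlas: AtlasSpec) -> PerfusionVector:
    """Re-key a perfusion vector from L/R to ipsi/contra naming."""
    renamed = vec.values.rename(index=lambda n: atlas.ipsicontra_name(n, onset_side))
    return PerfusionVector(vec.patient_id, vec.state, renamed.sort_index())


def stage_quantify(tables, clinical, atlas: AtlasSpec, config: RunConfig):
    """Perfusion-index and change vectors per scan, in the ipsi/contra frame."""
    vectors: dict = {}
    patients = sorted({p for (p, _s) in tables})
    for patient in patients:
        side = clinical.loc[patient, "onset_side"]
        per_state = {}
        for state in ("interictal", "ictal"):
            if (patient, state) not in tables:
                continue
            pi = perfusion_index(tables[(patient, state)], denominator=config.pi_denominator)
            per_state[state] = relabel_vector(pi, side, atlas)
        if "interictal" in per_state and "ictal" in per_state:
            per_state["change"] = change_vector(per_state["interictal"], per_state["ictal"])
        for state, vec in per_state.items():
            vectors[(patient, state)] = vec
    return vectors


def stage_cluster(vectors, config: RunConfig):
    """Per-scan v-fold K selection and clustering; returns (solutions, traces)."""
    solutions: dict = {}
    traces: dict = {}
    for i, key in enumerate(sorted(vectors)):
        vec = vectors[key]
        scan_seed = (config.seed * 100003 + i * 7919) % (2**31 - 1)
        trace = select_k_vfold(
            vec.values,
            k_candidates=range(config.k_min, config.k_max + 1),
            folds=config.folds,
            improvement_threshold=config.improvement_threshold,
            seed=scan_seed,
            engine=config.engine,
            n_restarts=config.n_restarts,
        )
        sol = cluster_scan(
            vec.values, trace.chosen_k, engine=config.engine,
            n_restarts=config.n_restarts, seed=scan_seed,
        )
        solutions[key] = sol
        traces[key] = trace
    return solutions, traces


def extreme_sets_by_state(solutions, atlas: AtlasSpec) -> dict:
    """(state, role) -> {patient: set of structures} from per-scan solutions."""
    role_names = {"interictal": ("hypo", "hyper"), "ictal": ("hypo", "hyper"),
                  "change": ("decrease", "increase")}
    sets: dict = {}
    for (patient, state), sol in solutions.items():
        hypo, hyper, _ = label_extremes(sol, atlas)
        lo_role, hi_role = role_names[state]
        sets.setdefault((state, lo_role), {})[patient] = hypo
        sets.setdefault((state, hi_role), {})[patient] = hyper
    return sets


def stage_patterns(solutions, vectors, atlas: AtlasSpec, clinical, config: RunConfig):
    """Match table, cluster summary and cohort descriptives."""
    patients = sorted({p for (p, _s) in solutions})
    sets = extreme_sets_by_state(solutions, atlas)
    match = match_frequencies(sets, len(patients), percent_style=config.percent_style)
    summary = summarize_clusters(solutions, vectors, atlas, clinical)
    descriptives = {
        "sudep7_score": describe(clinical["sudep7_score"]),
        "injection_time_s": describe(clinical["injection_time_s"]),
        "seizure_duration_s": describe(clinical["seizure_duration_s"]),
    }
    return match, summary, descriptives


def stage_screen(vectors, clinical, config: RunConfig):
    """SUDEP-7-vs-change feature screening and hypo-burden correlation inputs."""
    patients = sorted({p for (p, s) in vectors if s == "change"})
    if not patients:
        raise StageError("screen", "no change vectors (need paired scans)")
    X = pd.DataFrame(
        {p: vectors[(p, "change")].values for p in patients}
    ).T.sort_index(axis=1)
    X.index.name = "patient"
    y = clinical["sudep7_score"].reindex(X.index)
    screen = screen_features(
        X, y, n_intervals=config.screen_intervals,
        top_k=config.screen_top_k, p_threshold=config.screen_p_threshold,
    )
    return X, y, screen


# --------------------------------------------------------------------------
# IO helpers (plain-text intermediates)

def vectors_to_frame(vectors) -> pd.DataFrame:
    return pd.concat([v.to_frame() for _k, v in sorted(vectors.items())], ignore_index=True)


def solutions_to_frame(solutions, vectors) -> pd.DataFrame:
    rows = []
    for (patient, state), sol in sorted(solutions.items()):
        for structure, cluster in sol.assignment.items():
            rows.append(
                {"patient": patient, "state": state, "structure": structure,
                 "cluster": int(cluster), "centroid": float(sol.centroids[cluster]),
                 "value": float(vectors[(patient, state)].values[structure]),
                 "is_hypo": cluster == sol.hypo_cluster,
                 "is_hyper": cluster == sol.hyper_cluster}
            )
    return pd.DataFrame(rows)


def _df_block(df: pd.DataFrame, max_rows: int | None = None) -> str:
    text = df.to_string(max_rows=max_rows)
    return f"```\n{text}\n```\n"


def run_all(config: RunConfig, outdir) -> Path:
    """Execute every stage and write all outputs plus report.md under ``outdir``."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"perfuse-sudep {__version__}", f"config sha256[:16] {config.digest()}",
                 f"seed {config.seed}"]
    atlas = default_atlas()

    def _stage(name, fn, *args):
        try:
            result = fn(*args)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, str(exc)) from exc
        log_lines.append(f"stage {name}: ok")
        return result

    tables, clinical = _stage("inputs", load_inputs, config, atlas)
    log_lines.append(f"  {len(tables)} scans, {len(clinical)} patients")
    vectors = _stage("quantify", stage_quantify, tables, clinical, atlas, config)
    solutions, traces = _stage("cluster", stage_cluster, vectors, config)
    match, summary, descriptives = _stage(
        "patterns", stage_patterns, solutions, vectors, atlas, clinical, config
    )
    X, y, screen = _stage("screen", stage_screen, vectors, clinical, config)
    correlation = _stage("correlate", hypo_burden_correlation, summary, y)

    # ---- outputs ----
    pd.concat([t.to_frame() for _k, t in sorted(tables.items())], ignore_index=True).to_csv(
        out / "roi_tables.csv", index=False
    )
    clinical.to_csv(out / "clinical.csv")
    vectors_to_frame(vectors).to_csv(out / "pi.csv", index=False)
    solutions_to_frame(solutions, vectors).to_csv(out / "clusters.csv", index=False)
    (out / "kselection.json").write_text(json.dumps(
        {f"{p}|{s}": t.as_dict() for (p, s), t in sorted(traces.items())}, indent=2
    ))
    match.to_csv(out / "match_table.csv", index=False)
    summary.to_csv(out / "cluster_summary.csv", index=False)
    (out / "descriptives.json").write_text(json.dumps(descriptives, indent=2))
    screen.to_csv(out / "screen.csv")
    (out / "correlation.json").write_text(json.dumps(correlation, indent=2))
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    k_dist = pd.Series({k: t.chosen_k for k, t in traces.items()}).value_counts().sort_index()
    top = screen[~screen["flag"]].head(10)
    report = [
        "# Perfusion-pattern run report",
        f"- package version: {__version__}",
        f"- seed: {config.seed}",
        f"- config digest: {config.digest()}",
        f"- scans: {len(tables)}; patients: {len(clinical)}",
        "",
        "## Cohort descriptives",
        "```", json.dumps(descriptives, indent=2), "```",
        "",
        "## Selected K distribution (count of scans per chosen K)",
        "```", k_dist.to_string(), "```",
        "",
        "## Structure match table (top rows by percent)",
        _df_block(match.sort_values("percent", ascending=False).head(30)),
        "## Cluster summary",
        _df_block(summary),
        "## Feature screening vs SUDEP-7 (top 10)",
        _df_block(top),
        "## Hypo-cluster burden vs SUDEP-7 (Spearman)",
        "```", json.dumps(correlation, indent=2), "```",
        "",
    ]
    (out / "report.md").write_text("\n".join(report))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
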
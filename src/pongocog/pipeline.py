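"""Configuration, CSV I/O and end-to-end orchestration.

The pipeline runs simulate -> filter -> fit -> switch-test -> report.  All
tabular interchange is CSV; configuration is YAML.  Externally produced
tables (e.g. a deposited dataset with different column names) are ingested
through a ``rename_map`` declared in the config — column names are never
hard-coded to one external source.

Every run is reproducible from (config, seed): stage seeds are derived from
the master seed with ``numpy``'s ``SeedSequence``, and the report bundle
records the config hash, seed and library versions.
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

from . import synthetic
from .dotprobe import center_rt, fit_subject, results_to_frame
from .filtering import filter_trials, merge_repetitions
from .inference import SamplerSettings
from .preference import fit_preference, per_subject_to_frame, preference_to_frame
from .switching import switch_test
from .synthetic import ChoiceGenParams, DotProbeGenParams

__all__ = ["PipelineConfig", "ReportBundle", "read_trials", "write_trials", "run_pipeline"]

logger = logging.getLogger(__name__)

DOTPROBE_COLUMNS = [
    "subject_id", "session_id", "trial_index", "task", "congruence",
    "probe_side", "rt_ms", "pair_id", "width_diff", "is_repetition",
]
PREFERENCE_COLUMNS = [
    "subject_id", "session_id", "trial_index", "phase", "block", "order",
    "flanged_colour", "flanged_dot_height", "choice",
]

DEFAULT_DOTPROBE_SUBJECTS = ["Kawan", "Samboja", "Sandy"]
DEFAULT_PREFERENCE_SUBJECTS = ["Baju", "Indah", "Kawan", "Samboja", "Sandy", "Wattana"]


@dataclass
class TaskDesign:
    n_pairs: int
    n_sessions: int
    trials_per_session: int


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    mode: str = "full"  # simulate | analyse | full
    out_dir: str = "pongocog_out"
    seed: int | None = None
    dotprobe_subjects: list[str] = field(default_factory=lambda: list(DEFAULT_DOTPROBE_SUBJECTS))
    preference_subjects: list[str] = field(
        default_factory=lambda: list(DEFAULT_PREFERENCE_SUBJECTS)
    )
    flange_design: TaskDesign = field(default_factory=lambda: TaskDesign(72, 6, 24))
    symmetry_design: TaskDesign = field(default_factory=lambda: TaskDesign(80, 8, 20))
    dotprobe_params: DotProbeGenParams = field(default_factory=DotProbeGenParams)
    choice_params: ChoiceGenParams = field(default_factory=ChoiceGenParams)
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    switch_prior_a: float = 10.0
    switch_prior_b: float = 10.0
    switch_n_sims: int = 10_000
    fit_height: bool = True
    input_dotprobe: str | None = None
    input_preference: str | None = None
    rename_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyse", "full"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in ("simulate", "full") and self.seed is None:
            raise ValueError(f"mode {self.mode!r} requires an explicit seed")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, typ in [
            ("flange_design", TaskDesign),
            ("symmetry_design", TaskDesign),
            ("dotprobe_params", DotProbeGenParams),
            ("choice_params", ChoiceGenParams),
            ("sampler", SamplerSettings),
        ]:
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All pipeline outputs plus the provenance needed to rerun them."""

    tables: dict[str, pd.DataFrame]
    provenance: dict
    failures: list[str] = field(default_factory=list)
    summary_text: str = ""

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=2, default=str))
        (out / "summary.txt").write_text(self.summary_text)


_VALIDATORS = {
    "dotprobe": {
        "required": DOTPROBE_COLUMNS[:8],  # width_diff / is_repetition may be filled in
        "checks": [
            ("rt_ms", lambda s: pd.to_numeric(s, errors="coerce") > 0, "non-positive or non-numeric rt_ms"),
            ("congruence", lambda s: s.isin(["congruent", "incongruent"]), "bad congruence level"),
            ("probe_side", lambda s: s.isin(["left", "right"]), "bad probe_side level"),
        ],
    },
    "preference": {
        "required": PREFERENCE_COLUMNS,
        "checks": [
            ("choice", lambda s: pd.to_numeric(s, errors="coerce").isin([0, 1]), "non-binary choice"),
            ("phase", lambda s: s.isin(["forced", "choice"]), "bad phase level"),
            (
                "flanged_dot_height",
                lambda s: pd.to_numeric(s, errors="coerce").abs() <= 0.35 + 1e-9,
                "flanged_dot_height outside [-0.35, 0.35]",
            ),
        ],
    },
}


def read_trials(
    path: str | Path, schema: str, rename_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read and validate a trial CSV against a schema.

    ``rename_map`` maps external column names to the canonical ones before
    validation.  All row-level violations are collected and reported with
    line numbers (header = line 1) before rejection.
    """
    if schema not in _VALIDATORS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(_VALIDATORS)}")
    df = pd.read_csv(path)
    if rename_map:
        df = df.rename(columns=rename_map)
    rules = _VALIDATORS[schema]
    missing = [c for c in rules["required"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing} (after renames)")
    problems: list[str] = []
    for col, ok_fn, msg in rules["checks"]:
        ok = ok_fn(df[col])
        bad_rows = df.index[~ok.fillna(False)]
        for idx in bad_rows[:20]:
            problems.append(f"line {idx + 2}: {msg} ({df.loc[idx, col]!r})")
        if len(bad_rows) > 20:
            problems.append(f"... and {len(bad_rows) - 20} more rows with {msg}")
    if problems:
        raise ValueError(f"{path}: {len(problems)} validation error(s):\n" + "\n".join(problems))
    if schema == "dotprobe" and "is_repetition" not in df.columns:
        df["is_repetition"] = False
    return df


def write_trials(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    cols = DOTPROBE_COLUMNS if schema == "dotprobe" else PREFERENCE_COLUMNS
    present = [c for c in cols if c in df.columns]
    df.loc[:, present].to_csv(path, index=False)


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def simulate_dotprobe_dataset(
    subjects: list[str],
    design: TaskDesign,
    params: DotProbeGenParams,
    seed: int,
    task: str = "flange",
) -> pd.DataFrame:
    """Full multi-subject dot-probe table for one task variant."""
    if task == "flange":
        pairs = synthetic.default_flange_pairs(design.n_pairs, seed=seed)
    else:
        pairs = synthetic.default_symmetry_pairs(design.n_pairs)
    seeds = _stage_seeds(seed, 2 * len(subjects))
    frames = []
    for i, subj in enumerate(subjects):
        plan = synthetic.schedule_dotprobe(
            pairs, design.n_sessions, design.trials_per_session, seed=seeds[2 * i], subject_id=subj
        )
        frames.append(synthetic.simulate_dotprobe(plan, params, seed=seeds[2 * i + 1]))
    return pd.concat(frames, ignore_index=True)


def filter_with_repetitions(
    trials: pd.DataFrame, params: DotProbeGenParams, seed: int
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Primary filtering, simulated repetition sessions, second filtering, merge.

    Emulates the study's bookkeeping: trials failing either RT rule are
    re-run once in subject-specific repetition sessions and filtered again.
    Returns (final table, combined reports, report table).
    """
    primary = filter_trials(trials)
    rep_plan = synthetic.make_repetition_plan(primary[1])
    if len(rep_plan):
        rep_trials = synthetic.simulate_dotprobe(rep_plan, params, seed=seed)
        repetition = filter_trials(rep_trials)
    else:
        repetition = filter_trials(rep_plan)
    final, combined = merge_repetitions(primary, repetition)
    rows = []
    for key, rep in sorted(combined.items()):
        rows.append(
            {
                "subject_id": key[0],
                "task": key[1] if len(key) > 1 else "",
                "n_collected": rep.n_collected,
                "n_excluded_slow": rep.n_excluded_slow,
                "n_excluded_fast": rep.n_excluded_fast,
                "n_retained": rep.n_retained,
                "exclusion_pct": rep.exclusion_pct,
            }
        )
    return final, combined, pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the stage sequence implied by ``config.mode``.

    Writes all CSV outputs plus a human-readable summary under
    ``config.out_dir`` and returns the in-memory bundle.  A stage failure is
    recorded in ``bundle.failures`` and subsequent dependent stages are
    skipped rather than aborting the whole run.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    failures: list[str] = []
    lines: list[str] = [f"pongocog pipeline run (mode={config.mode}, seed={config.seed})"]
    seeds = _stage_seeds(config.seed if config.seed is not None else 0, 8)

    dot_tables: dict[str, pd.DataFrame] = {}
    pref_table: pd.DataFrame | None = None

    if config.mode in ("simulate", "full"):
        t0 = time.time()
        dot_tables["flange"] = simulate_dotprobe_dataset(
            config.dotprobe_subjects, config.flange_design, config.dotprobe_params,
            seed=seeds[0], task="flange",
        )
        dot_tables["symmetry"] = simulate_dotprobe_dataset(
            config.dotprobe_subjects, config.symmetry_design, config.dotprobe_params,
            seed=seeds[1], task="symmetry",
        )
        plan = synthetic.schedule_preference(config.preference_subjects, seed=seeds[2])
        pref_table = synthetic.simulate_choices(plan, config.choice_params, seed=seeds[3])
        for task, df in dot_tables.items():
            write_trials(df, out / f"dotprobe_{task}.csv", "dotprobe")
        write_trials(pref_table, out / "preference.csv", "preference")
        logger.info("simulate stage done in %.1fs (seed %s)", time.time() - t0, config.seed)
        lines.append(
            f"simulated {sum(len(v) for v in dot_tables.values())} dot-probe trials, "
            f"{len(pref_table)} preference trials"
        )

    if config.mode == "simulate":
        prov = _provenance(config)
        bundle = ReportBundle(tables={}, provenance=prov, summary_text="\n".join(lines) + "\n")
        bundle.write(out)
        return bundle

    if config.mode == "analyse":
        if config.input_dotprobe:
            df = read_trials(config.input_dotprobe, "dotprobe", config.rename_map)
            for task, grp in df.groupby("task"):
                dot_tables[str(task)] = grp
        if config.input_preference:
            pref_table = read_trials(config.input_preference, "preference", config.rename_map)

    # --- filtering + per-subject robust fits ---
    dot_results = []
    for task, df in dot_tables.items():
        t0 = time.time()
        final, _, report = filter_with_repetitions(df, config.dotprobe_params, seed=seeds[4])
        tables[f"filter_report_{task}"] = report
        write_trials(final, out / f"dotprobe_{task}_filtered.csv", "dotprobe")
        lines.append(
            f"{task}: {report['n_collected'].sum()} collected, "
            f"{report['n_retained'].sum()} retained after repetition merge"
        )
        for subj, grp in final.groupby("subject_id"):
            try:
                res = fit_subject(center_rt(grp), config.sampler)
                dot_results.append((task, res))
                lines.append(
                    f"  {task}/{subj}: b_congruent {res.congruence.median:.2f} "
                    f"[{res.congruence.mad:.2f}], pd {res.congruence.pd:.2f}"
                    + ("" if res.converged else "  ** NOT CONVERGED **")
                )
            except Exception as exc:  # pragma: no cover - defensive
                failures.append(f"dotprobe fit {task}/{subj}: {exc}")
        logger.info("dot-probe stage (%s) done in %.1fs", task, time.time() - t0)
    if dot_results:
        frames = []
        for task, res in dot_results:
            frame = results_to_frame([res])
            frame.insert(0, "task", task)
            frames.append(frame)
        tables["dotprobe_results"] = pd.concat(frames, ignore_index=True)

    # --- pooled preference fit ---
    if pref_table is not None:
        t0 = time.time()
        try:
            pref_res = fit_preference(
                pref_table, include_height=config.fit_height, settings=config.sampler
            )
            tables["preference_results"] = preference_to_frame(pref_res)
            tables["preference_per_subject"] = per_subject_to_frame(pref_res)
            lines.append(
                f"preference: OR_intercept {pref_res.intercept_or.median:.2f}, "
                f"OR_green {pref_res.colour_or.median:.2f}"
                + (
                    f", OR_height {pref_res.height_or.median:.2f}"
                    if pref_res.height_or is not None
                    else ""
                )
                + ("" if pref_res.converged else "  ** NOT CONVERGED **")
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(f"preference fit: {exc}")
        logger.info("preference stage done in %.1fs", time.time() - t0)

        # --- switch test per session ---
        rows = []
        choice = pref_table.loc[pref_table["phase"] == "choice"]
        sw_seeds = _stage_seeds(seeds[5], choice.groupby(["subject_id", "session_id"]).ngroups)
        for i, ((subj, sess), grp) in enumerate(choice.groupby(["subject_id", "session_id"])):
            series = grp.sort_values("trial_index")["choice"].to_numpy()
            res = switch_test(
                series,
                prior_a=config.switch_prior_a,
                prior_b=config.switch_prior_b,
                n_sims=config.switch_n_sims,
                seed=sw_seeds[i],
            )
            rows.append(
                {
                    "subject_id": subj,
                    "session_id": sess,
                    "n": res.n,
                    "T_obs": res.T_obs,
                    "hdi_low": res.hdi95[0],
                    "hdi_high": res.hdi95[1],
                    "p_ge": res.p_ge,
                    "p_le": res.p_le,
                    "verdict": res.verdict,
                }
            )
        tables["switch_results"] = pd.DataFrame(rows)
        n_flagged = sum(r["verdict"] != "consistent" for r in rows)
        lines.append(f"switch test: {n_flagged}/{len(rows)} sessions outside the 95% null HDI")

    lines.append(f"total wall time {time.time() - t_start:.1f}s")
    bundle = ReportBundle(
        tables=tables,
        provenance=_provenance(config),
        failures=failures,
        summary_text="\n".join(lines) + "\n",
    )
    bundle.write(out)
    return bundle


def _provenance(config: PipelineConfig) -> dict:
    import arviz
    import scipy

    return {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "arviz": arviz.__version__,
        },
    }
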
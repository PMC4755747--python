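"""Cohort file formats, run configuration, and the staged pipeline.

Interchange is plain tab-separated text: one trial table per subject with
columns ``subject_id, phase, trial, orientation_deg, outcome, response,
valid`` plus a cohort ``manifest.tsv`` mapping subjects to group label and
counterbalanced CS+ orientation.  Responses are coded ``+``, ``-``, ``x``
(unsure) and empty (missing).  Orientations are degrees throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_model import ModelParams
from .fitting import (
    FitConfig,
    LikelihoodOptions,
    SubjectData,
    compare_kernels,
    fit_alpha_train,
    fit_group,
)
from .group_inference import (
    behavioral_gradient,
    fit_pearson7,
    kurtosis_of_fit,
    loo_parameter_scores,
    peak_shift_statistic,
    permutation_test_kurtosis,
    permutation_test_parameters,
)
from .synthetic_cohort import CohortSpec, simulate_cohort
from .task_design import Schedule, StimulusSpec, TrialRecord

__all__ = [
    "RESPONSE_CODES",
    "write_cohort",
    "read_cohort",
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
    "run_pipeline",
]

RESPONSE_CODES = {"plus": "+", "minus": "-", "unsure": "x", "missing": ""}
_CODE_TO_RESPONSE = {v: k for k, v in RESPONSE_CODES.items()}

COLUMNS = ["subject_id", "phase", "trial", "orientation_deg", "outcome", "response", "valid"]


def _subject_frame(subject: SubjectData) -> pd.DataFrame:
    rows = []
    for sched in (subject.training, subject.test):
        for t in sched.trials:
            rows.append(
                {
                    "subject_id": subject.subject_id,
                    "phase": t.phase,
                    "trial": t.index,
                    "orientation_deg": t.orientation,
                    "outcome": t.outcome,
                    "response": RESPONSE_CODES.get(t.response, ""),
                    "valid": int(t.valid),
                }
            )
    return pd.DataFrame(rows, columns=COLUMNS)


def write_cohort(
    cohort: Sequence[SubjectData], out_dir: str | Path, manifest: Optional[pd.DataFrame] = None
) -> Path:
    """Write one TSV per subject plus ``manifest.tsv``; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if manifest is None:
        manifest = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in cohort],
                "group": [s.group for s in cohort],
                "cs_plus_deg": [s.spec.cs_plus for s in cohort],
            }
        )
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    for s in cohort:
        _subject_frame(s).to_csv(out / f"{s.subject_id}.tsv", sep="\t", index=False)
    return out


class CohortFormatError(ValueError):
    """Malformed cohort files (message carries file and line number)."""


def _parse_subject(path: Path, subject_id: str, group: str, cs_plus: float) -> SubjectData:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortFormatError(f"{path.name}: missing columns {missing_cols}")

    def err(i: int, msg: str) -> CohortFormatError:
        return CohortFormatError(f"{path.name}, line {i + 2}: {msg}")  # +2 = header + 1-based

    records: dict[str, list[TrialRecord]] = {"training": [], "test": []}
    for i, row in df.iterrows():
        phase = row["phase"]
        if phase not in ("training", "test"):
            raise err(i, f"unknown phase {phase!r}")
        try:
            orientation = float(row["orientation_deg"])
        except ValueError:
            raise err(i, f"non-numeric orientation {row['orientation_deg']!r}") from None
        if not 0.0 <= orientation < 180.0:
            raise err(i, f"orientation {orientation} out of range [0, 180)")
        if row["outcome"] not in ("0", "1"):
            raise err(i, f"outcome must be 0 or 1, got {row['outcome']!r}")
        if row["response"] not in _CODE_TO_RESPONSE:
            raise err(i, f"unknown response code {row['response']!r}")
        response = _CODE_TO_RESPONSE[row["response"]]
        if row["valid"] not in ("0", "1"):
            raise err(i, f"valid must be 0 or 1, got {row['valid']!r}")
        try:
            records[phase].append(
                TrialRecord(
                    phase=phase,
                    index=len(records[phase]),
                    orientation=orientation,
                    outcome=int(row["outcome"]),
                    response=response,
                    valid=bool(int(row["valid"])),
                )
            )
        except ValueError as exc:
            raise err(i, str(exc)) from None

    train_orients = sorted({t.orientation for t in records["training"]})
    if cs_plus not in train_orients:
        raise CohortFormatError(
            f"{path.name}: manifest cs_plus {cs_plus} never occurs in training"
        )
    others = [x for x in train_orients if x != cs_plus]
    if len(others) != 1:
        raise CohortFormatError(
            f"{path.name}: expected exactly two training orientations, got {train_orients}"
        )
    test_orients = tuple(sorted({t.orientation for t in records["test"]}))
    spec = StimulusSpec(cs_plus=cs_plus, cs_minus=others[0], test_orientations=test_orients)
    return SubjectData(
        subject_id=subject_id,
        group=group,
        spec=spec,
        training=Schedule(tuple(records["training"]), spec, seed=-1),
        test=Schedule(tuple(records["test"]), spec, seed=-1),
    )


def read_cohort(in_dir: str | Path) -> tuple[list[SubjectData], pd.DataFrame]:
    """Read a cohort directory written by :func:`write_cohort`, validating
    schema, units, and response codes with line-numbered errors."""
    root = Path(in_dir)
    manifest_path = root / "manifest.tsv"
    if not manifest_path.exists():
        raise CohortFormatError(f"missing manifest: {manifest_path}")
    manifest = pd.read_csv(manifest_path, sep="\t")
    for col in ("subject_id", "group", "cs_plus_deg"):
        if col not in manifest.columns:
            raise CohortFormatError(f"manifest.tsv: missing column {col!r}")
    cohort = []
    for _, row in manifest.iterrows():
        path = root / f"{row['subject_id']}.tsv"
        if not path.exists():
            raise CohortFormatError(
                f"manifest names subject {row['subject_id']!r} but {path.name} is missing"
            )
        cohort.append(
            _parse_subject(path, str(row["subject_id"]), str(row["group"]), float(row["cs_plus_deg"]))
        )
    return cohort, manifest


# ---------------------------------------------------------------------------
# Run configuration


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on, round-trippable through YAML."""

    out_dir: str = "results"
    seed: int = 0
    kernel: str = "gaussian"
    # cohort
    n_pa: int = 25
    n_pp: int = 21
    n_reps: int = 100
    p_reward: float = 0.5
    n_reps_test: int = 14
    exact_reinforcement: bool = True
    counterbalance: bool = True
    # optimizer
    n_starts: int = 20
    maxfev: Optional[int] = None
    fatol: float = 1e-6
    # likelihood toggles
    include_training_likelihood: bool = False
    exclude_unsure: bool = False
    update_invalid_trials: bool = True
    # permutation / loo
    n_perm: int = 1000
    tail: str = "less"
    refit_alpha_train_in_permutations: bool = False
    # stages to run, in dependency order
    stages: tuple[str, ...] = (
        "simulate",
        "fit",
        "gradient",
        "peak_shift",
        "kurtosis",
    )

    def fit_config(self, seed_offset: int = 0) -> FitConfig:
        return FitConfig(
            n_starts=self.n_starts,
            seed=self.seed + seed_offset,
            maxfev=self.maxfev,
            fatol=self.fatol,
            options=LikelihoodOptions(
                include_training=self.include_training_likelihood,
                exclude_unsure=self.exclude_unsure,
                update_invalid=self.update_invalid_trials,
            ),
        )

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            group_sizes={"PA": self.n_pa, "PP": self.n_pp},
            n_reps=self.n_reps,
            p_reward=self.p_reward,
            n_reps_test=self.n_reps_test,
            exact_reinforcement=self.exact_reinforcement,
            counterbalance=self.counterbalance,
            master_seed=self.seed,
        )


_KNOWN_STAGES = (
    "simulate",
    "fit",
    "compare_kernels",
    "gradient",
    "peak_shift",
    "kurtosis",
    "permute_params",
    "loo",
)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; unknown keys or stages are rejected up front."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
        bad = set(raw["stages"]) - set(_KNOWN_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    data["stages"] = list(data["stages"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    data = dataclasses.asdict(config)
    data["stages"] = list(data["stages"])
    return hashlib.sha256(json.dumps(data, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order, writing one TSV or
    JSON artifact per stage under ``config.out_dir``.  Identical configs give
    identical outputs; every summary carries the config hash."""
    bad = set(config.stages) - set(_KNOWN_STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    summary: dict = {"config_hash": chash, "seed": config.seed, "stages": {}}
    cohort = None
    alpha_train = None
    fits = {}

    def need_cohort():
        nonlocal cohort
        if cohort is None:
            raise RuntimeError("stage requires 'simulate' (or a loaded cohort) first")
        return cohort

    for stage in config.stages:
        try:
            if stage == "simulate":
                cohort, manifest = simulate_cohort(config.cohort_spec())
                write_cohort(cohort, out / "cohort", manifest)
                summary["stages"]["simulate"] = {
                    "n_subjects": len(cohort),
                    "dir": str(out / "cohort"),
                }
            elif stage == "fit":
                c = need_cohort()
                alpha_train = fit_alpha_train(c, config.kernel, config.fit_config(1))
                for group in ("PA", "PP"):
                    members = [s for s in c if s.group == group]
                    fits[group] = fit_group(
                        members, alpha_train, config.kernel, config.fit_config(2)
                    )
                summary["stages"]["fit"] = {
                    "alpha_train": alpha_train,
                    **{g: f.as_dict() for g, f in fits.items()},
                }
            elif stage == "compare_kernels":
                comp = compare_kernels(need_cohort(), config.fit_config(3))
                comp.coefficients.to_csv(out / "kernel_coefficients.tsv", sep="\t", index=False)
                summary["stages"]["compare_kernels"] = {
                    "aic_gaussian": comp.gaussian.aic,
                    "aic_exponential": comp.exponential.aic,
                    "bic_gaussian": comp.gaussian.bic,
                    "bic_exponential": comp.exponential.bic,
                    "t_statistic": comp.t_statistic,
                    "p_value": comp.p_value,
                }
            elif stage == "gradient":
                grad = behavioral_gradient(need_cohort())
                grad.mean.to_csv(out / "gradient_mean.tsv", sep="\t")
                grad.sem.to_csv(out / "gradient_sem.tsv", sep="\t")
                grad.per_subject.to_csv(out / "gradient_subjects.tsv", sep="\t")
                summary["stages"]["gradient"] = {"orientations": list(map(float, grad.orientations))}
            elif stage == "peak_shift":
                ps = peak_shift_statistic(need_cohort())
                summary["stages"]["peak_shift"] = {"t": ps.statistic, "p": ps.p_value}
            elif stage == "kurtosis":
                c = need_cohort()
                pa = [s for s in c if s.group == "PA"]
                pp = [s for s in c if s.group == "PP"]
                res = permutation_test_kurtosis(
                    pa, pp, n_perm=config.n_perm, seed=config.seed, tail="greater"
                )
                summary["stages"]["kurtosis"] = {
                    "observed_diff": float(res.observed.iloc[0]),
                    "p": float(res.p_values.iloc[0]),
                    "n_perm": res.n_perm,
                }
            elif stage == "permute_params":
                c = need_cohort()
                if alpha_train is None:
                    raise RuntimeError("'permute_params' requires the 'fit' stage")
                pa = [s for s in c if s.group == "PA"]
                pp = [s for s in c if s.group == "PP"]
                res = permutation_test_parameters(
                    pa,
                    pp,
                    alpha_train,
                    n_perm=config.n_perm,
                    seed=config.seed,
                    kernel=config.kernel,
                    config=config.fit_config(4),
                    tail=config.tail,  # type: ignore[arg-type]
                )
                res.null.to_csv(out / "param_permutation_null.tsv", sep="\t", index=False)
                summary["stages"]["permute_params"] = {
                    "observed": res.observed.to_dict(),
                    "p_values": res.p_values.to_dict(),
                    "n_perm": res.n_perm,
                }
            elif stage == "loo":
                c = need_cohort()
                if alpha_train is None:
                    raise RuntimeError("'loo' requires the 'fit' stage")
                loo = loo_parameter_scores(
                    c, alpha_train, config.kernel, config.fit_config(5)
                )
                loo.scores.to_csv(out / "loo_scores.tsv", sep="\t")
                loo.tests.to_csv(out / "loo_tests.tsv", sep="\t", index=False)
                summary["stages"]["loo"] = {
                    "tests": loo.tests.to_dict(orient="records")
                }
            else:  # pragma: no cover - guarded above
                raise ValueError(stage)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
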
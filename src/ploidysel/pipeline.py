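"""Replicated-experiment orchestration and report emission.

Ties the simulator and the estimators together: run many seeded replicates
of a selection design, collect per-replicate realized heritabilities,
divergence trajectories, CVs and mean inbreeding coefficients, and write
the count/mean/CV/inbreeding report tables.  Also ships the published
per-line flowering-time means as a packaged fixture so the headline
divergence statistics can be recomputed without simulation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import EstimationError
from .response import (
    GenerationSummary,
    divergence_statistic,
    estimate_line_response,
    results_frame,
)
from .sim import DesignConfig, ExperimentRecord, GeneticArchitecture, run_experiment
from .variation import cv_table

# ---------------------------------------------------------------------------
# published means fixture
# ---------------------------------------------------------------------------


def published_flowering_means() -> pd.DataFrame:
    """Per-line flowering-time means (days) by generation for the three
    ploidy groups, as published."""
    with resources.files("ploidysel.data").joinpath(
        "flowering_time_means.csv"
    ).open("r", encoding="utf-8") as handle:
        return pd.read_csv(handle)


def published_divergences(generation: int = 4) -> dict[str, float]:
    """Generation-``generation`` divergence from control (days) for each
    ploidy group, recomputed from the packaged published means."""
    df = published_flowering_means()
    out: dict[str, float] = {}
    for group, grp in df[df["generation"] == generation].groupby("ploidy_group"):
        summaries = [
            GenerationSummary(
                line=row.line,
                generation=generation,
                n_grown=1,
                n_selected=0,
                mean_fertile=float(row.mean_days),
                sd_fertile=float("nan"),
                mean_selected=float("nan"),
            )
            for row in grp.itertuples()
        ]
        control = grp.loc[grp["role"] == "control", "line"].iloc[0]
        div, _ = divergence_statistic(summaries, control)
        out[group] = round(div, 10)
    return out


# ---------------------------------------------------------------------------
# replicated runs
# ---------------------------------------------------------------------------


def replicate_seeds(master_seed: int, n_reps: int) -> list[int]:
    """Deterministic per-replicate seeds derived from one master seed."""
    state = np.random.SeedSequence(int(master_seed)).generate_state(
        n_reps, dtype=np.uint32
    )
    return [int(s) & 0x7FFFFFFF for s in state]


def _config_digest(design: DesignConfig, arch: GeneticArchitecture) -> str:
    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return str(obj)

    payload = json.dumps(
        {"design": asdict(design), "architecture": asdict(arch)},
        sort_keys=True,
        default=default,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReplicateSummary:
    """Stacked outputs of ``n_replicates`` seeded experiment replicates."""

    design: DesignConfig
    master_seed: int
    n_replicates: int
    seeds: list[int]
    estimates: pd.DataFrame
    divergences: pd.DataFrame
    cvs: pd.DataFrame | None
    inbreeding: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)

    def mean_heritability(self) -> float:
        """Grand mean b_T over selected lines and replicates."""
        return float(self.estimates["b_t"].mean())


def run_replicates(
    design: DesignConfig,
    arch: GeneticArchitecture,
    n_reps: int,
    master_seed: int,
    *,
    level: float = 0.95,
    mode: str = "final",
    compute_cv: bool = True,
    compute_inbreeding: bool = False,
) -> ReplicateSummary:
    """Run ``n_reps`` independent replicates of one design and stack the
    per-line estimates.

    Deterministic given ``master_seed``; each replicate is independently
    reproducible from its own derived seed via :func:`run_experiment`.
    """
    if n_reps < 1:
        raise EstimationError("need at least one replicate")
    seeds = replicate_seeds(master_seed, n_reps)
    est_rows, div_rows, cv_frames, f_rows = [], [], [], []
    errors: list[tuple[int, str]] = []
    for rep, seed in enumerate(seeds):
        try:
            record = run_experiment(design, arch, seed)
        except Exception as exc:  # collect, keyed by replicate
            errors.append((rep, f"{type(exc).__name__}: {exc}"))
            continue
        ctrl = record.design.control_line
        ctrl_summaries = record.line_summaries(ctrl)
        final_gen = design.n_generations
        final_summaries = [
            s for s in record.summaries if s.generation == final_gen
        ]
        div, div_se = divergence_statistic(final_summaries, ctrl)
        div_rows.append(
            {
                "replicate": rep,
                "generation": final_gen,
                "divergence_days": div,
                "se": div_se,
            }
        )
        for line in design.selected_lines:
            est = estimate_line_response(
                record.line_summaries(line),
                ctrl_summaries,
                level=level,
                mode=mode,
            )
            est_rows.append(
                {
                    "replicate": rep,
                    "line": line,
                    "b_t": est.b_t,
                    "se": est.se,
                    "lcl": est.lower_cl,
                    "ucl": est.upper_cl,
                    "S_c": float(est.cumulative_s[-1]),
                    "R_c": float(est.cumulative_r[-1]),
                    "sigma2_P": est.base_phenotypic_variance,
                    "N_harmonic": est.n_harmonic,
                    "M_harmonic": est.m_harmonic,
                }
            )
        if compute_cv:
            cv = cv_table(record.phenotype_frame(), level)
            cv.insert(0, "replicate", rep)
            cv_frames.append(cv)
        if compute_inbreeding:
            for line in design.lines:
                f_rows.append(
                    {
                        "replicate": rep,
                        "line": line,
                        "generation": final_gen,
                        "mean_f": record.mean_inbreeding(line, final_gen),
                    }
                )
    if errors and not est_rows:
        raise EstimationError(f"all replicates failed; first: {errors[0]}")
    summary = ReplicateSummary(
        design=design,
        master_seed=int(master_seed),
        n_replicates=n_reps,
        seeds=seeds,
        estimates=pd.DataFrame(est_rows),
        divergences=pd.DataFrame(div_rows),
        cvs=pd.concat(cv_frames, ignore_index=True) if cv_frames else None,
        inbreeding=pd.DataFrame(f_rows) if f_rows else None,
    )
    summary.manifest = {
        "package_version": __version__,
        "config_digest": _config_digest(design, arch),
        "master_seed": int(master_seed),
        "n_replicates": n_reps,
        "replicate_seeds": seeds,
        "failed_replicates": errors,
    }
    return summary


# ---------------------------------------------------------------------------
# table emission
# ---------------------------------------------------------------------------


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def emit_tables(obj, out_dir, manifest: dict | None = None) -> list[Path]:
    """Write the report tables for a single :class:`ExperimentRecord` or a
    :class:`ReplicateSummary`; re-emission of the same object is
    byte-identical.  Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        _write_csv(df, path)
        written.append(path)

    if isinstance(obj, ExperimentRecord):
        emit(pd.DataFrame(obj.counts), "counts.csv")
        emit(
            pd.DataFrame(
                [
                    {
                        "line": s.line,
                        "generation": s.generation,
                        "n_grown": s.n_grown,
                        "n_selected": s.n_selected,
                        "mean_fertile": round(s.mean_fertile, 4),
                        "sd_fertile": round(s.sd_fertile, 4),
                        "mean_selected": round(s.mean_selected, 4)
                        if s.n_selected
                        else "",
                    }
                    for s in sorted(
                        obj.summaries, key=lambda s: (s.line, s.generation)
                    )
                ]
            ),
            "flowering_means.csv",
        )
        pheno = obj.phenotype_frame()
        emit(pheno, "phenotypes.csv")
        emit(cv_table(pheno), "cv.csv")
        ctrl = obj.design.control_line
        ctrl_summaries = obj.line_summaries(ctrl)
        estimates = {
            line: estimate_line_response(obj.line_summaries(line), ctrl_summaries)
            for line in obj.design.selected_lines
        }
        emit(results_frame(estimates), "results.csv")
        emit(
            pd.DataFrame(
                [
                    {
                        "line": line,
                        "generation": obj.design.n_generations,
                        "mean_f": round(
                            obj.mean_inbreeding(line, obj.design.n_generations), 6
                        ),
                    }
                    for line in obj.design.lines
                ]
            ),
            "inbreeding.csv",
        )
    elif isinstance(obj, ReplicateSummary):
        emit(obj.estimates.round(6), "estimates.csv")
        emit(obj.divergences.round(6), "divergences.csv")
        if obj.cvs is not None:
            emit(obj.cvs, "cv.csv")
        if obj.inbreeding is not None:
            emit(obj.inbreeding.round(6), "inbreeding.csv")
        if manifest is None:
            manifest = obj.manifest
    else:
        raise TypeError(
            "emit_tables expects an ExperimentRecord or ReplicateSummary"
        )
    if manifest is not None:
        path = Path(out) / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------

_PRESETS = {
    "diploid": DesignConfig.diploid,
    "tetraploid": DesignConfig.tetraploid,
    "neotetraploid": DesignConfig.neotetraploid,
}


def load_config(path) -> tuple[DesignConfig, GeneticArchitecture, dict]:
    """Read a YAML config with ``design``, ``architecture`` and ``run``
    sections.

    ``design.preset`` selects one of the three study designs
    (diploid/tetraploid/neotetraploid); remaining design keys override its
    fields.  The architecture section is passed to
    :func:`ploidysel.sim.default_architecture` (``heritability`` is
    required).
    """
    import yaml

    with open(path, "r", encoding="utf-8") as handle:
        raw = yaml.safe_load(handle) or {}
    design_cfg = dict(raw.get("design") or {})
    preset = design_cfg.pop("preset", "diploid")
    if preset not in _PRESETS:
        raise EstimationError(
            f"unknown design preset {preset!r}; expected one of {sorted(_PRESETS)}"
        )
    design = _PRESETS[preset](**design_cfg)
    arch_cfg = dict(raw.get("architecture") or {})
    h2 = arch_cfg.pop("heritability", None)
    if h2 is None:
        raise EstimationError("architecture.heritability is required")
    from .sim import default_architecture

    arch = default_architecture(design, float(h2), **arch_cfg)
    run_cfg = dict(raw.get("run") or {})
    return design, arch, run_cfg
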
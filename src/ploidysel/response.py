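"""Selection differentials, control-corrected responses, and realized
heritability with confidence limits.

For a selected line, the per-generation selection differential is

    S_i = mean(fertile cohort) - mean(selected parents)

signed so that selection for earlier flowering gives S_i > 0.  The response
is measured against the unselected control line reared alongside:

    D_t = mean(control, t) - mean(selected line, t),   D_0 = 0
    R_i = D_i - D_{i-1}

so that shared generation-wide environmental swings cancel.  Realized
heritability is the ratio of cumulative response to cumulative differential,

    b_T = R_c(T) / S_c(T),    S_c = sum_i S_i,  R_c = sum_i R_i,

with an optional through-origin regression of R_c on S_c across generations.
Confidence limits use a sampling-variance approximation

    Var(b_T) = 2 * sigma2_P * (1/M + 1/N) / S_c^2

(measurement error of the line means plus parental sampling; genetic drift
is not included, so the analytic SE understates the replicate-to-replicate
spread) with Student-t critical values on N - 1 degrees of freedom, where N
is the (harmonic mean) number of plants grown per generation, M the number
selected, and sigma2_P the base population's phenotypic variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import EstimationError


@dataclass(frozen=True)
class GenerationSummary:
    """Per-line, per-generation phenotype summary (fertile plants only)."""

    line: str
    generation: int
    n_grown: int
    n_selected: int
    mean_fertile: float
    sd_fertile: float
    mean_selected: float

    def __post_init__(self) -> None:
        if self.n_selected > self.n_grown:
            raise EstimationError("cannot select more plants than were grown")


class HeritabilityUndefined:
    """Sentinel for lines with zero cumulative selection differential
    (e.g. control lines), where b_T = R_c/S_c has no value."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "HeritabilityUndefined"


UNDEFINED_HERITABILITY = HeritabilityUndefined()


@dataclass
class ResponseEstimate:
    """One line's full selection-response accounting."""

    line: str
    s_per_generation: np.ndarray
    r_per_generation: np.ndarray
    cumulative_s: np.ndarray
    cumulative_r: np.ndarray
    b_t: float
    se: float
    lower_cl: float
    upper_cl: float
    level: float
    base_phenotypic_variance: float
    n_harmonic: float
    m_harmonic: float
    mode: str = "final"


def selection_differential(summary: GenerationSummary) -> float:
    """S_i for one generation, positive toward earliness."""
    if summary.n_selected < 1:
        raise EstimationError(
            f"no selected plants in line {summary.line!r} "
            f"generation {summary.generation}"
        )
    return summary.mean_fertile - summary.mean_selected


def response_series(
    selected_means: Sequence[float], control_means: Sequence[float]
) -> np.ndarray:
    """Per-generation responses R_i from two equal-length mean series that
    include generation 0 (where divergence is zero by construction)."""
    sel = np.asarray(selected_means, dtype=float)
    ctl = np.asarray(control_means, dtype=float)
    if sel.shape != ctl.shape:
        raise EstimationError("selected and control series differ in length")
    divergence = ctl - sel
    return np.diff(divergence)


def realized_heritability(
    cumulative_r: Sequence[float] | float,
    cumulative_s: Sequence[float] | float,
    mode: str = "final",
):
    """b_T from cumulative response and differential series (or final
    values).

    ``mode='final'`` takes R_c/S_c at the last generation; ``mode=
    'regression'`` fits a through-origin regression of R_c on S_c across
    generations.  Returns :data:`UNDEFINED_HERITABILITY` when the cumulative
    differential is exactly zero.
    """
    r = np.atleast_1d(np.asarray(cumulative_r, dtype=float))
    s = np.atleast_1d(np.asarray(cumulative_s, dtype=float))
    if r.shape != s.shape:
        raise EstimationError("cumulative series differ in length")
    if mode == "final":
        if s[-1] == 0.0:
            return UNDEFINED_HERITABILITY
        return float(r[-1] / s[-1])
    if mode == "regression":
        denom = float(np.sum(s * s))
        if denom == 0.0:
            return UNDEFINED_HERITABILITY
        return float(np.sum(s * r) / denom)
    raise ValueError("mode must be 'final' or 'regression'")


def heritability_confidence(
    b_t: float,
    n: float,
    m: float,
    sigma2_p: float,
    s_c: float,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Standard error and confidence limits for a realized heritability.

    ``n`` and ``m`` may be (harmonic-mean) per-generation counts.  The
    critical value is Student's t on ``n - 1`` degrees of freedom.
    """
    if not m >= 1:
        raise EstimationError("m must be at least 1")
    if not n > m:
        raise EstimationError("n must exceed m")
    if not sigma2_p > 0:
        raise EstimationError("sigma2_p must be positive")
    if not s_c > 0:
        raise EstimationError("cumulative differential must be positive")
    if not 0.0 < level < 1.0:
        raise EstimationError("level must be in (0, 1)")
    var = 2.0 * sigma2_p * (1.0 / m + 1.0 / n) / s_c**2
    se = float(np.sqrt(var))
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, df=n - 1.0))
    return se, b_t - tcrit * se, b_t + tcrit * se


def _harmonic_mean(values: Sequence[float]) -> float:
    arr = np.asarray(values, dtype=float)
    return float(len(arr) / np.sum(1.0 / arr))


def estimate_line_response(
    line_summaries: Sequence[GenerationSummary],
    control_summaries: Sequence[GenerationSummary],
    level: float = 0.95,
    sigma2_p: float | None = None,
    mode: str = "final",
) -> ResponseEstimate:
    """Full response accounting for one selected line against its control.

    Both summary lists must cover generations 0..T (generation 0 being the
    shared base cohort); generations 0..T-1 of the selected line must carry
    selected-group means.  ``sigma2_p`` defaults to the squared fertile
    phenotypic SD of the base generation.
    """
    line = sorted(line_summaries, key=lambda s: s.generation)
    ctrl = sorted(control_summaries, key=lambda s: s.generation)
    if len(line) != len(ctrl) or len(line) < 2:
        raise EstimationError(
            "need matching selected and control summaries for generations 0..T"
        )
    for a, b in zip(line, ctrl):
        if a.generation != b.generation:
            raise EstimationError("selected/control generations do not align")
    t_final = len(line) - 1
    s_i = np.array([selection_differential(s) for s in line[:-1]])
    r_i = response_series(
        [s.mean_fertile for s in line], [s.mean_fertile for s in ctrl]
    )
    s_c = np.cumsum(s_i)
    r_c = np.cumsum(r_i)
    b_t = realized_heritability(r_c, s_c, mode=mode)
    if sigma2_p is None:
        sigma2_p = line[0].sd_fertile ** 2
    n_h = _harmonic_mean([s.n_grown for s in line[:-1]])
    m_h = _harmonic_mean([s.n_selected for s in line[:-1]])
    if isinstance(b_t, HeritabilityUndefined):
        se = lcl = ucl = float("nan")
        b_val = float("nan")
    else:
        se, lcl, ucl = heritability_confidence(
            b_t, n_h, m_h, sigma2_p, float(s_c[-1]), level
        )
        b_val = b_t
    return ResponseEstimate(
        line=line[0].line,
        s_per_generation=s_i,
        r_per_generation=r_i,
        cumulative_s=s_c,
        cumulative_r=r_c,
        b_t=b_val,
        se=se,
        lower_cl=lcl,
        upper_cl=ucl,
        level=level,
        base_phenotypic_variance=float(sigma2_p),
        n_harmonic=n_h,
        m_harmonic=m_h,
        mode=mode,
    )


def divergence_statistic(
    summaries: Sequence[GenerationSummary],
    control_line: str,
) -> tuple[float, float]:
    """Control mean minus the average of selected-line means at one
    generation, with a standard error propagated from the per-line standard
    errors (``sd/sqrt(n)``; NaN when SDs are unavailable, e.g. for published
    line means)."""
    ctrl = [s for s in summaries if s.line == control_line]
    sel = [s for s in summaries if s.line != control_line]
    if len(ctrl) != 1:
        raise EstimationError(
            f"expected exactly one control summary for {control_line!r}"
        )
    if not sel:
        raise EstimationError("no selected-line summaries supplied")
    gens = {s.generation for s in summaries}
    if len(gens) != 1:
        raise EstimationError("summaries span multiple generations")
    div = ctrl[0].mean_fertile - float(np.mean([s.mean_fertile for s in sel]))
    ses = [s.sd_fertile / np.sqrt(s.n_grown) for s in sel]
    se_ctrl = ctrl[0].sd_fertile / np.sqrt(ctrl[0].n_grown)
    se = float(np.sqrt(se_ctrl**2 + np.sum(np.square(ses)) / len(sel) ** 2))
    return float(div), se


@dataclass(frozen=True)
class PooledHeritability:
    b_t: float
    se: float
    lower_cl: float
    upper_cl: float
    level: float


def average_line_heritability(
    estimates: Sequence[ResponseEstimate], level: float = 0.95
) -> PooledHeritability:
    """Equal-weight average of per-line realized heritabilities, with a
    pooled confidence interval from the combined (independent-line)
    variance."""
    if not estimates:
        raise EstimationError("no line estimates to average")
    b = float(np.mean([e.b_t for e in estimates]))
    var = float(np.sum([e.se**2 for e in estimates])) / len(estimates) ** 2
    se = float(np.sqrt(var))
    df = float(np.sum([e.n_harmonic - 1.0 for e in estimates]))
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, df=df))
    return PooledHeritability(
        b_t=b, se=se, lower_cl=b - tcrit * se, upper_cl=b + tcrit * se, level=level
    )


# ---------------------------------------------------------------------------
# phenotype-table plumbing
# ---------------------------------------------------------------------------


def summaries_from_phenotypes(df) -> list[GenerationSummary]:
    """Build per-line generation summaries from a phenotype table.

    The table needs columns ``id, dam, sire, line, generation, fertile,
    phenotype_days``.  The base cohort is the minimum generation (line
    ``BASE`` when present, shared by all lines); generations are renumbered
    from 0.  Selected-parent groups are recovered from parentage: the
    parents of line L's generation g+1 are its generation-g selected group.
    """
    import pandas as pd  # local import keeps module import light

    df = df.copy()
    df["generation"] = df["generation"].astype(int) - int(df["generation"].min())
    df["fertile"] = df["fertile"].astype(bool)
    gens = sorted(df["generation"].unique())
    base_mask = df["generation"] == 0
    base_df = df[base_mask]
    lines = sorted(set(df.loc[~base_mask, "line"]))
    if not lines:  # single-cohort table: summarize what is there
        lines = sorted(set(df["line"]))
    by_id = df.set_index("id")
    out: list[GenerationSummary] = []
    for line in lines:
        for g in gens:
            cohort = (
                base_df if g == 0 else df[(df["line"] == line) & (df["generation"] == g)]
            )
            if cohort.empty:
                continue
            nxt = df[(df["line"] == line) & (df["generation"] == g + 1)]
            parent_ids = sorted(set(nxt["dam"]) | set(nxt["sire"]))
            parent_ids = [p for p in parent_ids if p in by_id.index]
            fertile = cohort.loc[cohort["fertile"], "phenotype_days"]
            sel = by_id.loc[parent_ids, "phenotype_days"] if parent_ids else None
            out.append(
                GenerationSummary(
                    line=line,
                    generation=int(g),
                    n_grown=int(len(cohort)),
                    n_selected=0 if sel is None else int(len(sel)),
                    mean_fertile=float(fertile.mean()),
                    sd_fertile=float(fertile.std(ddof=1))
                    if len(fertile) > 1
                    else 0.0,
                    mean_selected=float("nan") if sel is None else float(sel.mean()),
                )
            )
    return out


def estimates_from_phenotypes(
    df,
    control_line: str | None = None,
    level: float = 0.95,
    mode: str = "final",
) -> dict[str, ResponseEstimate]:
    """Per-selected-line response estimates straight from a phenotype table.

    The control line defaults to the line whose name ends in ``C``.
    """
    summaries = summaries_from_phenotypes(df)
    lines = sorted({s.line for s in summaries})
    if control_line is None:
        candidates = [ln for ln in lines if ln.endswith("C")]
        if len(candidates) != 1:
            raise EstimationError(
                "could not infer the control line; pass control_line explicitly"
            )
        control_line = candidates[0]
    if control_line not in lines:
        raise EstimationError(f"control line {control_line!r} not in table")
    ctrl = [s for s in summaries if s.line == control_line]
    out: dict[str, ResponseEstimate] = {}
    for line in lines:
        if line == control_line:
            continue
        mine = [s for s in summaries if s.line == line]
        out[line] = estimate_line_response(mine, ctrl, level=level, mode=mode)
    return out


def results_frame(estimates: dict[str, "ResponseEstimate"]):
    """Tidy results table: one row per line and generation with S_i, R_i,
    cumulative sums, and the line-level heritability block repeated."""
    import pandas as pd

    rows = []
    for line, est in sorted(estimates.items()):
        for i in range(len(est.s_per_generation)):
            rows.append(
                {
                    "line": line,
                    "generation": i + 1,
                    "N": round(est.n_harmonic, 2),
                    "M": round(est.m_harmonic, 2),
                    "S_i": round(float(est.s_per_generation[i]), 4),
                    "R_i": round(float(est.r_per_generation[i]), 4),
                    "S_c": round(float(est.cumulative_s[i]), 4),
                    "R_c": round(float(est.cumulative_r[i]), 4),
                    "b_T": round(est.b_t, 4),
                    "se": round(est.se, 4),
                    "lcl": round(est.lower_cl, 4),
                    "ucl": round(est.upper_cl, 4),
                }
            )
    return pd.DataFrame(rows)
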
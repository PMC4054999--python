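"""Group-level statistics and study orchestration.

Per-wound measurements (the statistical unit, n wounds per arm) are summarised
into a group table (mean ± SD per parameter), compared by classical one-way
ANOVA with unprotected Fisher-LSD pairwise 95% confidence intervals reported
alongside the omnibus p (the joint reporting convention of the study this
models; a ``protected=True`` switch gates the pairwise intervals on omnibus
significance), and related within each group by Pearson correlation over
{closure, inflammation Vv, Sv, Lv, Rdiff, diameter}.  Equal-variance pooled
assumptions are used throughout; a Welch option exists for the two-sample
test but is off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counting import count_wound_fields
from .errors import EstimationError, InvalidParameterError
from .estimators import WoundMeasurement, estimate_wound
from .test_systems import build_test_system, plan_fields

__all__ = [
    "StatsReport",
    "StudyConfig",
    "two_sample_t",
    "one_way_anova",
    "fisher_lsd",
    "pearson_matrix",
    "summarize_groups",
    "run_study",
    "CORRELATION_VARS",
]

#: Variables entering the per-group correlation matrices, in report order:
#: wound closure, inflammatory infiltrate, surface density, length density,
#: radial diffusion distance, blood vessel diameter.
CORRELATION_VARS = ("closure", "Vv", "Sv", "Lv", "Rdiff", "diameter")

#: Parameters summarised per group and tested across groups.
SUMMARY_VARS = (
    "closure",
    "volume",
    "inflam_volume_total",
    "Sv",
    "surface_area_total",
    "Lv",
    "length_total",
    "Rdiff",
    "diameter",
)


@dataclass
class StatsReport:
    """Group summaries, ANOVA, pairwise LSD intervals and correlation matrices."""

    group_summaries: pd.DataFrame  # index parameter, columns (group, mean/sd/n)
    anova: dict  # parameter -> {F, df1, df2, p}
    pairwise: dict  # parameter -> list of {pair, difference, ci_low, ci_high}
    pearson: dict  # group -> DataFrame correlation matrix
    ttest: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "group_summaries": json.loads(self.group_summaries.to_json()),
                "anova": self.anova,
                "pairwise": self.pairwise,
                "pearson": {g: json.loads(m.to_json()) for g, m in self.pearson.items()},
                "ttest": self.ttest,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class StudyConfig:
    """Probe and aggregation settings used when counting rendered sections."""

    field_margin_um: float | None = None  # span inset from section edges; default fw/2
    field_size_um: tuple[float, float] = (48.0, 48.0)
    n_fields: int = 5
    cycloid_r_um: float = 4.0
    target_L_T_um: float = 288.0  # 18 arcs of 4r at r = 4 μm
    n_grid_points: int = 192
    aggregate: str = "ratio_of_sums"
    shrinkage: float = 1.6
    seed: int = 0


def two_sample_t(x: Sequence[float], y: Sequence[float], welch: bool = False):
    """Two-sided two-sample t-test, pooled variance by default.

    Degenerate samples (zero variance on both sides with equal means) return
    (0.0, 1.0) by convention.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise InvalidParameterError("each sample needs n >= 2")
    if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) == np.mean(y):
        return 0.0, 1.0
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups: Sequence[Sequence[float]]):
    """Classical one-way ANOVA: returns (F, df_between, df_within, p)."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InvalidParameterError("need >= 2 groups with n >= 2 each")
    k = len(groups)
    N = sum(len(g) for g in groups)
    if all(np.var(g) == 0 for g in groups) and len({float(np.mean(g)) for g in groups}) == 1:
        return 0.0, k - 1, N - k, 1.0
    F, p = stats.f_oneway(*groups)
    return float(F), k - 1, N - k, float(p)


def _pooled_mse(groups: Sequence[np.ndarray]) -> tuple[float, int]:
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_within = sum(len(g) for g in groups) - len(groups)
    return ss_within / df_within, df_within


def fisher_lsd(
    groups: Sequence[Sequence[float]], pair: tuple[int, int], alpha: float = 0.05
):
    """Fisher's LSD mean-difference confidence interval for one group pair.

    difference ± t(1−α/2, df_within) · sqrt(MSE · (1/n₁ + 1/n₂)) with the MSE
    pooled over *all* groups.  Intervals are unprotected; report them with the
    omnibus ANOVA p.
    """
    groups = [np.asarray(g, float) for g in groups]
    i, j = pair
    if not (0 <= i < len(groups) and 0 <= j < len(groups)) or i == j:
        raise InvalidParameterError(f"invalid group pair {pair}")
    mse, df = _pooled_mse(groups)
    diff = float(np.mean(groups[i]) - np.mean(groups[j]))
    half = stats.t.ppf(1 - alpha / 2.0, df) * np.sqrt(mse * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
    return diff, diff - float(half), diff + float(half)


def pearson_matrix(
    wounds: Sequence[WoundMeasurement], group: str, variables: Sequence[str] = CORRELATION_VARS
) -> pd.DataFrame:
    """Pairwise Pearson correlations over one group's wounds.

    Zero-variance variables yield NaN entries (flagged as undefined rather
    than silently zero); the diagonal is 1 wherever the variable varies.
    """
    rows = [w for w in wounds if w.group == group]
    if len(rows) < 3:
        raise InvalidParameterError(f"group {group!r} needs >= 3 wounds for correlations")
    data = np.array([[getattr(w, v) for v in variables] for w in rows], float)
    k = len(variables)
    out = np.full((k, k), np.nan)
    sd = data.std(axis=0)
    # a variable is degenerate when its spread is at rounding level
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(data).max(axis=0))
    for a in range(k):
        for b in range(a, k):
            if degenerate[a] or degenerate[b]:
                continue
            r = float(np.corrcoef(data[:, a], data[:, b])[0, 1])
            out[a, b] = out[b, a] = r
    return pd.DataFrame(out, index=list(variables), columns=list(variables))


def summarize_groups(
    wounds: Sequence[WoundMeasurement], variables: Sequence[str] = SUMMARY_VARS
) -> pd.DataFrame:
    """Per-group mean, SD (ddof=1) and n for each parameter."""
    groups = list(dict.fromkeys(w.group for w in wounds))
    recs = {}
    for g in groups:
        vals = [w for w in wounds if w.group == g]
        for v in variables:
            arr = np.array([getattr(w, v) for w in vals], float)
            recs[(g, "mean"), v] = arr.mean()
            recs[(g, "sd"), v] = arr.std(ddof=1) if len(arr) > 1 else 0.0
            recs[(g, "n"), v] = len(arr)
    df = pd.DataFrame(
        {
            (g, stat): {v: recs[(g, stat), v] for v in variables}
            for g in groups
            for stat in ("mean", "sd", "n")
        }
    )
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["group", "stat"])
    return df.loc[list(variables)]


def _measurements_from_study(study, config: StudyConfig) -> list[WoundMeasurement]:
    measurements = []
    missing = [w.wound_id for w in study.wounds if not study.rendered and w.measurement is None]
    if missing:
        raise EstimationError(f"wounds without measurements or sections: {missing}")
    if not study.rendered:
        return [w.measurement for w in study.wounds]
    fw, fh = config.field_size_um
    surface = build_test_system(
        "surface", config.target_L_T_um, (fw, fh), config.cycloid_r_um, config.n_grid_points
    )
    length = build_test_system(
        "length", config.target_L_T_um, (fw, fh), config.cycloid_r_um, config.n_grid_points
    )
    for w_idx, w in enumerate(study.wounds):
        if not w.sections:
            raise EstimationError(f"wound {w.wound_id} has no rendered sections")
        all_fields = []
        for s_idx, section in enumerate(w.sections):
            W_um, _ = section.extent
            margin = config.field_margin_um if config.field_margin_um is not None else fw / 2.0
            plan = plan_fields(
                (margin, W_um - margin),
                (fw, fh),
                config.n_fields,
                seed=(config.seed * 1_000_003 + w_idx * 1009 + s_idx) % 2**31,
            )
            all_fields.extend(count_wound_fields(section, plan, surface, length))
        measurements.append(
            estimate_wound(
                all_fields,
                wound_id=w.wound_id,
                group=w.group,
                A0=w.A0,
                A7=w.A7,
                thicknesses=w.thicknesses,
                section_thickness_mm=w.sections[0].section_thickness * 1e-3,
                shrinkage=config.shrinkage,
                aggregate=config.aggregate,
            )
        )
    return measurements


def run_study(
    study,
    config: StudyConfig | None = None,
    out_dir: str | Path | None = None,
    protected: bool = False,
    alpha: float = 0.05,
) -> tuple[StatsReport, pd.DataFrame]:
    """Counting → estimation → statistics for a whole study.

    Accepts a (rendered or parameter-level) ``SyntheticStudy``.  Returns the
    ``StatsReport`` and the per-wound measurement table; when ``out_dir`` is
    given, writes ``per_wound.csv``, ``group_table.csv``, ``stats.json``,
    ``correlations.csv`` and ``run.log`` deterministically.
    """
    if config is None:
        config = StudyConfig()
    measurements = _measurements_from_study(study, config)
    groups = list(dict.fromkeys(w.group for w in measurements))
    if len(groups) < 2 or any(sum(w.group == g for w in measurements) < 2 for g in groups):
        raise InvalidParameterError("need >= 2 groups with >= 2 wounds each")
    per_wound = pd.DataFrame([m.to_row() for m in measurements])
    summaries = summarize_groups(measurements)
    anova = {}
    pairwise = {}
    for v in SUMMARY_VARS:
        gvals = [
            np.array([getattr(w, v) for w in measurements if w.group == g], float)
            for g in groups
        ]
        F, df1, df2, p = one_way_anova(gvals)
        anova[v] = {"F": F, "df1": df1, "df2": df2, "p": p}
        pairs = []
        if not protected or p < alpha:
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    diff, lo, hi = fisher_lsd(gvals, (i, j), alpha)
                    pairs.append(
                        {
                            "pair": [groups[i], groups[j]],
                            "difference": diff,
                            "ci_low": lo,
                            "ci_high": hi,
                        }
                    )
        pairwise[v] = pairs
    pearson = {g: pearson_matrix(measurements, g) for g in groups}
    report = StatsReport(
        group_summaries=summaries, anova=anova, pairwise=pairwise, pearson=pearson
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_wound.to_csv(out / "per_wound.csv", index=False)
        summaries.to_csv(out / "group_table.csv")
        (out / "stats.json").write_text(report.to_json())
        corr = pd.concat(pearson, names=["group", "variable"])
        corr.to_csv(out / "correlations.csv")
        (out / "run.log").write_text(
            json.dumps(
                {
                    "seed": getattr(study, "seed", None),
                    "n_per_group": getattr(study, "n_per_group", None),
                    "rendered": getattr(study, "rendered", None),
                    "config": {
                        k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in vars(config).items()
                    },
                },
                indent=2,
                sort_keys=True,
            )
        )
    return report, per_wound
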
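"""Study-level statistics: per-participant aggregation, 2x2 within-subject
ANOVAs, Bonferroni-corrected paired t-tests, and a skewness/kurtosis
normality screen, plus end-to-end orchestration over synthetic studies.

In a balanced 2x2 within-subject design every effect (factor A, factor B,
A x B) is a single-degree-of-freedom contrast of the four cell values within
each participant, so each F statistic equals the square of the paired t of
that contrast with df = (1, n_participants - 1). The implementation uses the
contrast decomposition directly; it is exact for this design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import ensemble_average

__all__ = [
    "ObservationTable",
    "EffectResult",
    "AnovaResult",
    "aggregate_to_participant",
    "rm_anova_2x2",
    "paired_t_bonferroni",
    "normality_screen",
    "run_study",
    "simulate_null_tables",
]


@dataclass
class ObservationTable:
    """Balanced within-subject observations: one value per participant x
    factor-A level x factor-B level (within-participant means across strides).
    """

    data: pd.DataFrame  # columns: participant, a, b, value
    factor_a: str = "limb"
    factor_b: str = "speed_bin"

    def __post_init__(self):
        req = {"participant", "a", "b", "value"}
        if not req.issubset(self.data.columns):
            raise ValueError(f"observation table needs columns {sorted(req)}")
        counts = self.data.groupby(["participant", "a", "b"]).size()
        if (counts != 1).any():
            raise ValueError("design must be balanced: one value per cell")
        n_a = self.data["a"].nunique()
        n_b = self.data["b"].nunique()
        if n_a != 2 or n_b != 2:
            raise ValueError("rm_anova_2x2 requires exactly 2 levels per factor")

    @property
    def participants(self) -> list:
        return sorted(self.data["participant"].unique())

    def cell_matrix(self) -> tuple[np.ndarray, list, list]:
        """(n_participants, 4) array in (a1b1, a1b2, a2b1, a2b2) order."""
        a_levels = sorted(self.data["a"].unique())
        b_levels = sorted(self.data["b"].unique())
        wide = self.data.pivot_table(
            index="participant", columns=["a", "b"], values="value"
        )
        cols = [(a, b) for a in a_levels for b in b_levels]
        return wide[cols].to_numpy(), a_levels, b_levels


@dataclass
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float
    degenerate: bool = False


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]
    cell_means: pd.DataFrame
    cell_sd: pd.DataFrame
    factor_a: str = "limb"
    factor_b: str = "speed_bin"


def aggregate_to_participant(
    summaries: pd.DataFrame,
    value: str = "net",
    factor_a: str = "limb",
    factor_b: str = "speed_bin",
) -> ObservationTable:
    """Within-cell mean across strides for each participant.

    ``summaries`` holds one row per stride with at least
    (participant, factor_a, factor_b, value) columns. A participant missing
    any cell makes the design unbalanced and raises, naming the cells.
    """
    df = summaries.rename(
        columns={factor_a: "a", factor_b: "b", value: "value"}
    )[["participant", "a", "b", "value"]]
    agg = df.groupby(["participant", "a", "b"], as_index=False)["value"].mean()
    cells = [(a, b) for a in agg["a"].unique() for b in agg["b"].unique()]
    missing = []
    for pid in agg["participant"].unique():
        have = set(
            map(tuple, agg.loc[agg["participant"] == pid, ["a", "b"]].to_numpy())
        )
        missing += [(pid, c) for c in cells if c not in have]
    if missing:
        raise ValueError(f"unbalanced design; missing cells: {missing}")
    return ObservationTable(agg, factor_a, factor_b)


def _contrast_f(scores: np.ndarray) -> EffectResult:
    """F test of a within-participant contrast (== squared paired t)."""
    n = scores.size
    mean = scores.mean()
    sd = scores.std(ddof=1)
    if sd == 0.0:
        # zero residual variance: the contrast is exact in every participant
        return EffectResult(
            F=float("inf") if mean != 0 else 0.0,
            df_num=1,
            df_den=n - 1,
            p=0.0 if mean != 0 else 1.0,
            degenerate=True,
        )
    tval = mean / (sd / np.sqrt(n))
    F = tval**2
    p = float(sps.f.sf(F, 1, n - 1))
    return EffectResult(F=float(F), df_num=1, df_den=n - 1, p=p)


def rm_anova_2x2(table: ObservationTable) -> AnovaResult:
    """Two-way repeated-measures ANOVA for a balanced 2x2 design.

    Each effect is tested against its participant-by-effect interaction;
    with 2 levels per factor this reduces to the paired t of the effect
    contrast, F = t², df = (1, n-1).
    """
    cells, a_levels, b_levels = table.cell_matrix()
    n = cells.shape[0]
    if n < 3:
        raise ValueError("repeated-measures ANOVA needs >= 3 participants")
    # cells columns: (a1,b1), (a1,b2), (a2,b1), (a2,b2)
    c_a = (cells[:, 0] + cells[:, 1] - cells[:, 2] - cells[:, 3]) / 2.0
    c_b = (cells[:, 0] - cells[:, 1] + cells[:, 2] - cells[:, 3]) / 2.0
    c_ab = (cells[:, 0] - cells[:, 1] - cells[:, 2] + cells[:, 3]) / 2.0
    effects = {
        table.factor_a: _contrast_f(c_a),
        table.factor_b: _contrast_f(c_b),
        f"{table.factor_a}:{table.factor_b}": _contrast_f(c_ab),
    }
    means = table.data.pivot_table(
        index="a", columns="b", values="value", aggfunc="mean"
    )
    sds = table.data.pivot_table(
        index="a", columns="b", values="value", aggfunc=lambda x: x.std(ddof=1)
    )
    return AnovaResult(effects, means, sds, table.factor_a, table.factor_b)


def paired_t_bonferroni(
    pairs: dict[str, tuple[np.ndarray, np.ndarray]],
) -> pd.DataFrame:
    """Two-tailed paired t-tests with Bonferroni correction.

    ``pairs`` maps contrast names to (x, y) paired samples. Returns one row
    per contrast with t, p_raw and p_adjusted = min(1, p_raw x n_contrasts).
    Zero-variance differences are flagged and their p left undefined (NaN).
    """
    k = len(pairs)
    rows = []
    for name, (x, y) in pairs.items():
        d = np.asarray(x, float) - np.asarray(y, float)
        sd = d.std(ddof=1)
        if sd == 0.0:
            # identical samples: t = 0, p = 1; a nonzero mean with zero
            # variance has no finite t and its p is undefined
            zero_mean = d.mean() == 0
            rows.append(
                {"contrast": name, "t": 0.0 if zero_mean else np.inf,
                 "p_raw": 1.0 if zero_mean else np.nan,
                 "p_adjusted": 1.0 if zero_mean else np.nan,
                 "degenerate": True}
            )
            continue
        tval = d.mean() / (sd / np.sqrt(d.size))
        p = 2.0 * float(sps.t.sf(abs(tval), d.size - 1))
        rows.append(
            {"contrast": name, "t": float(tval), "p_raw": p,
             "p_adjusted": min(1.0, p * k), "degenerate": False}
        )
    return pd.DataFrame(rows)


def normality_screen(
    values: np.ndarray,
    skew_limit: float = 1.7,
    kurt_limit: float = 3.6,
    convention: str = "excess",
) -> dict:
    """Sample skewness/kurtosis screen for approximate normality.

    Computes both raw and excess (Fisher) kurtosis and applies the limits to
    the configured convention (default excess). Passing means
    |skewness| < skew_limit and |kurtosis| < kurt_limit.
    """
    v = np.asarray(values, float)
    if v.size < 3:
        raise ValueError("normality screen needs n >= 3")
    skew = float(sps.skew(v, bias=True))
    kurt_excess = float(sps.kurtosis(v, fisher=True, bias=True))
    kurt_raw = kurt_excess + 3.0
    kurt = {"excess": kurt_excess, "raw": kurt_raw}[convention]
    return {
        "skewness": skew,
        "kurtosis_excess": kurt_excess,
        "kurtosis_raw": kurt_raw,
        "convention": convention,
        "passed": bool(abs(skew) < skew_limit and abs(kurt) < kurt_limit),
    }


def simulate_null_tables(
    n_studies: int,
    n_participants: int = 8,
    n_strides_per_cell: int = 10,
    subject_sd: float = 0.05,
    stride_sd: float = 0.03,
    seed: int = 0,
) -> list[ObservationTable]:
    """Per-stride work values under the null (no factor effects): a
    participant random intercept plus stride-level noise, pushed through
    :func:`aggregate_to_participant`. Used for type-I-error calibration.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 4242])
    tables = []
    for _ in range(n_studies):
        rows = []
        for p in range(n_participants):
            base = rng.normal(0.0, subject_sd)
            for a in ("a1", "a2"):
                for b in ("b1", "b2"):
                    vals = base + rng.normal(0.0, stride_sd, n_strides_per_cell)
                    rows += [
                        {"participant": f"P{p}", "limb": a, "speed_bin": b,
                         "net": v}
                        for v in vals
                    ]
        tables.append(
            aggregate_to_participant(pd.DataFrame(rows), value="net")
        )
    return tables


def run_study(
    configs_by_participant: dict,
    noise_seed: int = 0,
    value: str = "net",
) -> dict:
    """End-to-end orchestration over synthetic participants.

    ``configs_by_participant`` maps participant ids to lists of
    ``SyntheticConfig``; each config is generated, optionally noised
    (per its ``noise_sd``), pushed through event detection, stride
    segmentation and limb work, and the per-stride summaries are aggregated
    and tested with the 2x2 limb x speed ANOVA. Deterministic given the
    configs and ``noise_seed``.
    """
    from .energetics import limb_power, whole_body_com
    from .preprocess import detect_contacts, segment_strides, time_normalize
    from .synthetic_gait import add_noise, generate

    rows = []
    peak_rows = []
    curves: dict[tuple[str, str], dict[str, list[np.ndarray]]] = {}
    for pi, (pid, configs) in enumerate(sorted(configs_by_participant.items())):
        for j, cfg in enumerate(configs):
            trial, truth = generate(cfg)
            if any(v > 0 for v in cfg.noise_sd.values()):
                trial = add_noise(
                    trial, cfg.noise_sd,
                    seed=(noise_seed + 101 * pi + 31 * j) & 0x7FFFFFFF,
                )
            com_pos, com_vel = whole_body_com(trial.segments)
            for limb in trial.limbs:
                events = detect_contacts(trial.vgrf(limb), trial.rate)
                strides = segment_strides(events, com_vel[:, 0], trial.rate, limb)
                f3 = trial.grf[limb][["fx", "fy", "fz"]].to_numpy()
                limb_segs = [
                    s for s in trial.segments if s.limb_assignment == limb
                ]
                for st in strides:
                    if st.speed_bin == "excluded":
                        continue
                    sl = slice(st.i_start, st.i_end + 1)
                    p = limb_power(
                        f3[sl], com_vel[sl], _slice_segments(limb_segs, sl),
                        trial.rate, limb,
                    )
                    from .energetics import work_components

                    ws = work_components(
                        p, trial.time[sl], trial.body_mass,
                        speed=st.speed, speed_bin=st.speed_bin,
                        interface=trial.meta["interface"], participant=pid,
                    )
                    rows.append(
                        {
                            "participant": pid,
                            "interface": trial.meta["interface"],
                            "limb": limb,
                            "speed": st.speed,
                            "speed_bin": st.speed_bin,
                            "net": ws.net,
                            "positive": ws.positive,
                            "negative": ws.negative,
                        }
                    )
                    peak_rows.append(
                        {
                            "participant": pid,
                            "interface": trial.meta["interface"],
                            "limb": limb,
                            "speed_bin": st.speed_bin,
                            "max_vgrf": float(trial.vgrf(limb)[sl].max())
                            / trial.body_mass,
                        }
                    )
                    full = np.zeros(len(trial.time))
                    full[sl] = p.values / trial.body_mass
                    curves.setdefault((limb, st.speed_bin), {}).setdefault(
                        pid, []
                    ).append(time_normalize(full, st, 101))
    summaries = pd.DataFrame(rows)
    peaks = pd.DataFrame(peak_rows)
    curve_rows = []
    for (limb, sbin), by_pid in sorted(curves.items()):
        mean, sd = ensemble_average(by_pid)
        for pct, (mu, s) in enumerate(zip(mean, sd)):
            curve_rows.append(
                {"limb": limb, "speed_bin": sbin, "pct_gait_cycle": pct,
                 "mean_power": mu, "sd_power": s}
            )
    result: dict = {
        "summaries": summaries,
        "peaks": peaks,
        "curves": pd.DataFrame(curve_rows),
    }
    try:
        table = aggregate_to_participant(summaries, value=value)
        result["anova"] = rm_anova_2x2(table)
    except ValueError as exc:  # e.g. single speed bin in a small study
        result["anova_error"] = str(exc)
    return result


def _slice_segments(segments, sl):
    from .gait_io import SegmentState

    return [
        SegmentState(
            s.name, s.mass, s.inertia, s.com_pos[sl], s.com_vel[sl],
            s.ang_vel[sl], s.limb_assignment,
        )
        for s in segments
    ]
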
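"""Playback-experiment model and statistics.

Models the screening protocol used to rank disruptive signals: a male in
the active reply period (ARP — two consecutive replies within 10 s) is
played a female courtship signal mixed with a candidate disruptor, and his
reply (yes/no) and reply delay within a 45 s observation window are
recorded.  The module provides

* the protocol and trial data model plus per-condition aggregation
  (reply counts, reply rate, delay mean +/- SD);
* the Kruskal-Wallis H test and Dunn's pairwise post-hoc comparisons,
  implemented from the rank-sum formulas with tie correction;
* a seeded Bernoulli / truncated-normal simulator standing in for live
  insects, parameterized by the published screening table;
* a disruption report ranking conditions by the drop in reply rate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache as _lru_cache

import numpy as np
import pandas as pd
from scipy import stats as ss

__all__ = [
    "ProtocolConfig",
    "TrialRecord",
    "ConditionSummary",
    "KWResult",
    "ConditionModel",
    "BehavioralModelParams",
    "CONDITIONS",
    "TABLE1",
    "check_arp",
    "reply_rate",
    "summarize_conditions",
    "kruskal_wallis",
    "dunn_pairwise",
    "simulate_experiment",
    "disruption_report",
]

#: Closed set of condition labels, screening-table order.
CONDITIONS = ("Control", "PT150", "PT225", "PT300",
              "CPS150", "CPS225", "CPS300", "WGN")

#: Published screening results used to parameterize the simulator:
#: condition -> (n_tests, n_replies, printed reply rate %, delay mean s,
#: delay SD s).  NOTE: the published PT225 row is internally inconsistent —
#: 17 replies out of 42 tests is 40.5%, yet the printed rate is 33.3%
#: (= 14/42).  The counts are stored as printed; rate recomputation flags
#: the row (see :func:`validate_printed_rates`).
TABLE1: dict[str, tuple[int, int, float, float, float]] = {
    "Control": (45, 43, 95.6, 5.3, 3.3),
    "PT150":   (39, 22, 56.4, 8.0, 5.2),
    "PT225":   (42, 17, 33.3, 9.1, 5.6),
    "PT300":   (42, 18, 42.9, 9.3, 5.9),
    "CPS150":  (42, 28, 66.7, 5.8, 3.2),
    "CPS225":  (40, 21, 52.5, 7.2, 5.0),
    "CPS300":  (40, 22, 55.0, 7.4, 6.0),
    "WGN":     (43, 36, 83.7, 5.0, 3.1),
}


@dataclass
class ProtocolConfig:
    """Timing rules of the playback protocol (seconds)."""

    arp_window: float = 10.0
    arp_required_consecutive: int = 2
    observation_window: float = 45.0
    inter_trial_wait: float = 60.0
    retest_wait: float = 60.0

    def __post_init__(self) -> None:
        if min(self.arp_window, self.observation_window,
               self.inter_trial_wait, self.retest_wait) <= 0:
            raise ValueError("all protocol durations must be positive")
        if self.arp_required_consecutive < 1:
            raise ValueError("arp_required_consecutive must be >= 1")


@dataclass
class TrialRecord:
    """One playback trial."""

    subject_id: str
    condition: str
    replied: bool
    delay: float | None = None
    observation_window: float = 45.0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not self.replied and self.delay is not None:
            raise ValueError("delay must be absent when the subject did not reply")
        if self.replied:
            if self.delay is None or not 0 < self.delay <= self.observation_window:
                raise ValueError(
                    f"reply delay must lie in (0, {self.observation_window}] s, got {self.delay}"
                )


@dataclass
class ConditionSummary:
    """Aggregated results for one condition (one screening-table row)."""

    condition: str
    n_tests: int
    n_replies: int
    reply_rate_pct: float
    delay_mean: float | None
    delay_sd: float | None

    def __post_init__(self) -> None:
        if not 0 <= self.n_replies <= self.n_tests:
            raise ValueError("need 0 <= n_replies <= n_tests")


@dataclass
class KWResult:
    """Kruskal-Wallis test result."""

    H: float
    df: int
    p: float
    tie_corrected: bool = True

    def __post_init__(self) -> None:
        if self.H < 0 or not 0 <= self.p <= 1:
            raise ValueError("invalid Kruskal-Wallis result")


@dataclass
class ConditionModel:
    """Behavioral model of one condition: reply probability + delay distribution."""

    reply_prob: float
    delay_mean: float
    delay_sd: float

    def __post_init__(self) -> None:
        if not 0 <= self.reply_prob <= 1:
            raise ValueError("reply_prob must be in [0, 1]")
        if self.delay_sd < 0:
            raise ValueError("delay_sd must be non-negative")


@dataclass
class BehavioralModelParams:
    """Per-condition behavioral model; delays are truncated normal on
    (0, observation_window]."""

    conditions: dict[str, ConditionModel]
    delay_family: str = "truncnorm"

    @classmethod
    def from_table1(cls) -> "BehavioralModelParams":
        """Parameterize from the published screening table (printed rates)."""
        return cls({c: ConditionModel(rate / 100.0, mean, sd)
                    for c, (_, _, rate, mean, sd) in TABLE1.items()})


# ---------------------------------------------------------------------------
# protocol screening and aggregation
# ---------------------------------------------------------------------------


def check_arp(reply_latencies, cfg: ProtocolConfig | None = None) -> bool:
    """Is the subject in the active reply period?

    True iff some run of ``cfg.arp_required_consecutive`` consecutive
    latencies are all present (not ``None``) and within ``cfg.arp_window``
    seconds.  An empty sequence is never in the ARP.
    """
    cfg = cfg or ProtocolConfig()
    run = 0
    for lat in reply_latencies:
        if lat is not None and lat <= cfg.arp_window:
            run += 1
            if run >= cfg.arp_required_consecutive:
                return True
        else:
            run = 0
    return False


def reply_rate(n_tests: int, n_replies: int) -> float:
    """Reply rate as a percentage, rounded to 1 decimal."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    if not 0 <= n_replies <= n_tests:
        raise ValueError("need 0 <= n_replies <= n_tests")
    return round(100.0 * n_replies / n_tests, 1)


def summarize_conditions(trials: pd.DataFrame) -> pd.DataFrame:
    """Aggregate trials into one screening-table row per condition.

    ``trials`` columns: ``condition``, ``replied`` (bool/0-1), ``delay_s``
    (NaN when no reply).  Delay mean/SD are over repliers only and absent
    (NaN) for conditions with no repliers.
    """
    unknown = set(trials["condition"]) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    rows = []
    for cond, grp in trials.groupby("condition", sort=False):
        replied = grp["replied"].astype(bool)
        delays = grp.loc[replied, "delay_s"].astype(float)
        n, k = len(grp), int(replied.sum())
        rows.append({
            "condition": cond,
            "n_tests": n,
            "n_replies": k,
            "reply_rate_pct": reply_rate(n, k),
            "delay_mean_s": round(float(delays.mean()), 1) if k else np.nan,
            "delay_sd_s": round(float(delays.std(ddof=1)), 1) if k > 1 else np.nan,
        })
    order = {c: i for i, c in enumerate(CONDITIONS)}
    rows.sort(key=lambda r: order[r["condition"]])
    return pd.DataFrame(rows)


def validate_printed_rates() -> pd.DataFrame:
    """Recompute screening-table reply rates from counts and flag mismatches.

    The PT225 row is known to be internally inconsistent (printed 33.3%
    vs 17/42 = 40.5%).
    """
    rows = []
    for cond, (n, k, printed, _, _) in TABLE1.items():
        computed = reply_rate(n, k)
        rows.append({"condition": cond, "n_tests": n, "n_replies": k,
                     "printed_rate_pct": printed, "computed_rate_pct": computed,
                     "consistent": abs(computed - printed) < 0.05})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------


def _pooled_ranks(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, float]:
    """Midranks of the pooled data, group sizes, and the tie term sum(t^3 - t)."""
    pooled = np.concatenate(groups)
    ranks = ss.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    sizes = np.array([g.size for g in groups])
    return ranks, sizes, tie_term


def kruskal_wallis(groups) -> KWResult:
    """Kruskal-Wallis H test on k independent samples, from the rank-sum formula.

    H = 12 / (N (N+1)) * sum_i n_i (Rbar_i - (N+1)/2)^2, computed on
    midranks and divided by the tie correction 1 - sum(t^3 - t)/(N^3 - N).
    The p-value is the chi-square upper tail with df = k - 1.  When every
    pooled observation is identical the statistic is 0 and p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    ranks, sizes, tie_term = _pooled_ranks(groups)
    n_total = int(sizes.sum())
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    mean_rank = (n_total + 1) / 2.0
    h = 0.0
    for i, n_i in enumerate(sizes):
        r_bar = ranks[offsets[i]:offsets[i + 1]].mean()
        h += n_i * (r_bar - mean_rank) ** 2
    h *= 12.0 / (n_total * (n_total + 1))
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    if correction <= 0:  # all observations identical
        return KWResult(H=0.0, df=len(groups) - 1, p=1.0)
    h /= correction
    df = len(groups) - 1
    return KWResult(H=float(h), df=df, p=float(ss.chi2.sf(h, df)))


def dunn_pairwise(groups, comparisons=None, adjust: str = "none") -> pd.DataFrame:
    """Dunn's pairwise comparisons on pooled midranks with tie correction.

    For groups i, j: z = (Rbar_i - Rbar_j) / sqrt(S * (1/n_i + 1/n_j)) with
    S = N (N+1) / 12 - sum(t^3 - t) / (12 (N - 1)); p is two-sided normal.
    ``adjust`` is one of ``"none"`` (default — published pairwise p-values
    state no adjustment), ``"bonferroni"`` or ``"holm"``.  When the pooled
    data are entirely tied every pair gets z = 0, p = 1.

    Returns a DataFrame with columns group1, group2, z, p.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if adjust not in ("none", "bonferroni", "holm"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if comparisons is None:
        comparisons = list(itertools.combinations(range(len(groups)), 2))
    ranks, sizes, tie_term = _pooled_ranks(groups)
    n_total = int(sizes.sum())
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    r_bar = np.array([ranks[offsets[i]:offsets[i + 1]].mean() for i in range(len(groups))])
    s2 = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    rows = []
    for i, j in comparisons:
        if not (0 <= i < len(groups) and 0 <= j < len(groups)):
            raise ValueError(f"comparison ({i}, {j}) references unknown groups")
        denom = np.sqrt(s2 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if denom == 0 else float((r_bar[i] - r_bar[j]) / denom)
        rows.append({"group1": i, "group2": j, "z": z, "p": float(2 * ss.norm.sf(abs(z)))})
    df = pd.DataFrame(rows)
    if adjust == "bonferroni":
        df["p"] = np.minimum(df["p"] * len(df), 1.0)
    elif adjust == "holm":
        order = np.argsort(df["p"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank_pos, idx in enumerate(order):
            running = max(running, (m - rank_pos) * df["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        df["p"] = adj
    return df


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------


@_lru_cache(maxsize=64)
def _truncnorm_matched(target_mean: float, target_sd: float, lo: float, hi: float):
    """Parent (loc, scale) of a truncated normal on (lo, hi] whose truncated
    mean and SD equal the targets.

    Published delay statistics describe the observed (truncated) delays, so
    the parent normal is moment-matched rather than used directly; without
    this the hard floor at 0 s would inflate the simulated means.
    """
    from scipy.optimize import fsolve

    def residual(params):
        loc, scale = params
        scale = abs(scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = ss.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - target_mean, np.sqrt(v) - target_sd]

    (loc, scale), _, ok, _ = fsolve(residual, [target_mean, target_sd], full_output=True)
    if ok != 1:  # fall back to direct parameterization
        return target_mean, target_sd
    return float(loc), float(abs(scale))


def simulate_experiment(params: BehavioralModelParams, n_per_condition: int,
                        cfg: ProtocolConfig | None = None,
                        seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate playback trials: Bernoulli replies, truncated-normal delays.

    Each trial is an independent subject (subjects are discarded after
    testing, so there is no repeated-measures correlation).  A replier's
    delay is drawn from a normal truncated to (0, observation_window].
    Deterministic under a fixed seed.  Returns a trials DataFrame with
    columns subject_id, condition, replied, delay_s.
    """
    cfg = cfg or ProtocolConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_per_condition < 0:
        raise ValueError("n_per_condition must be non-negative")
    rows = []
    for cond in CONDITIONS:
        if cond not in params.conditions:
            raise ValueError(f"params missing condition {cond!r}")
        model = params.conditions[cond]
        replied = rng.random(n_per_condition) < model.reply_prob
        delays = np.full(n_per_condition, np.nan)
        k = int(replied.sum())
        if k and model.delay_sd > 0:
            loc, scale = _truncnorm_matched(model.delay_mean, model.delay_sd,
                                            0.0, cfg.observation_window)
            a = (0.0 - loc) / scale
            b = (cfg.observation_window - loc) / scale
            delays[replied] = ss.truncnorm.rvs(a, b, loc=loc, scale=scale,
                                               size=k, random_state=rng)
        elif k:
            delays[replied] = model.delay_mean
        for t in range(n_per_condition):
            rows.append({"subject_id": f"{cond}_{t:05d}", "condition": cond,
                         "replied": bool(replied[t]),
                         "delay_s": float(delays[t]) if replied[t] else np.nan})
    return pd.DataFrame(rows, columns=["subject_id", "condition", "replied", "delay_s"])


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def disruption_report(summary: pd.DataFrame, kw: KWResult | None = None,
                      dunn: pd.DataFrame | None = None, control: str = "Control",
                      min_drop_points: float = 50.0) -> dict:
    """Rank conditions by courtship disruption relative to the control.

    For each condition the report gives the drop in reply rate in
    percentage points (control rate - condition rate) and the relative
    reduction in percent; conditions whose relative reduction exceeds
    ``min_drop_points`` percent are flagged as effective disruptors.
    """
    if control not in set(summary["condition"]):
        raise ValueError(f"control condition {control!r} missing from summary")
    control_row = summary[summary["condition"] == control].iloc[0]
    control_rate = float(control_row["reply_rate_pct"])
    conditions = {}
    for _, row in summary.iterrows():
        rate = float(row["reply_rate_pct"])
        drop = round(control_rate - rate, 1)
        rel = round(100.0 * drop / control_rate, 1) if control_rate else 0.0
        conditions[row["condition"]] = {
            "n_tests": int(row["n_tests"]),
            "n_replies": int(row["n_replies"]),
            "reply_rate_pct": rate,
            "delay_mean_s": None if pd.isna(row["delay_mean_s"]) else float(row["delay_mean_s"]),
            "delay_sd_s": None if pd.isna(row["delay_sd_s"]) else float(row["delay_sd_s"]),
            "drop_points": drop,
            "relative_reduction_pct": rel,
            "effective_disruptor": row["condition"] != control and rel > min_drop_points,
        }
    report = {"control": control, "control_rate_pct": control_rate,
              "conditions": conditions}
    if kw is not None:
        report["kruskal_wallis"] = {"H": round(kw.H, 3), "df": kw.df, "p": round(kw.p, 4)}
    if dunn is not None:
        report["dunn"] = dunn.to_dict(orient="records")
    return report


def render_table(summary: pd.DataFrame) -> str:
    """Screening-table-style text rendering of a condition summary."""
    lines = [f"{'Condition':<10} {'Tests':>5} {'Replies':>7} {'Rate':>7} {'Delay (s)':>12}"]
    for _, r in summary.iterrows():
        delay = ("-" if pd.isna(r["delay_mean_s"])
                 else f"{r['delay_mean_s']:.1f} ± {r['delay_sd_s']:.1f}"
                 if not pd.isna(r["delay_sd_s"]) else f"{r['delay_mean_s']:.1f}")
        lines.append(f"{r['condition']:<10} {r['n_tests']:>5} {r['n_replies']:>7} "
                     f"{r['reply_rate_pct']:>6.1f}% {delay:>12}")
    return "\n".join(lines)
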
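"""Complex-stoichiometry quantification and replicate statistics.

After both channels are classified, a spot pair is analyzable when its green
trace shows exactly one photobleaching event and its far-red trace is not
rejected.  Far-red class percentages are computed per technical replicate,
averaged (unweighted) into biological-replicate values, and summarized as
grand mean +/- SEM over biological replicates.  Group differences are
tested by nested one-way ANOVA — the group effect against the
biological-replicate stratum — with Tukey-adjusted pairwise comparisons on
biological-replicate means.  Incomplete dye labeling is modeled as binomial
thinning, giving a forward map from true copy-number distributions to
observed step-count distributions and its simplex-constrained inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import f as f_dist, studentized_range, sem

__all__ = [
    "ReplicateSummary",
    "ExperimentResult",
    "NestedAnovaResult",
    "LabelingEfficiencyResult",
    "ANALYZABLE_CLASSES",
    "filter_pairs",
    "class_percentages",
    "percent_multimeric",
    "nested_anova",
    "labeling_efficiency",
    "expected_observed_classes",
    "invert_true_distribution",
]

ANALYZABLE_CLASSES = ("1-step", "2-step", "3plus")


@dataclass
class ReplicateSummary:
    bio_rep: int
    tech_rep: int
    n_analyzable: int
    counts: dict[str, int]
    percentages: dict[str, float]  # empty when n_analyzable == 0


@dataclass
class NestedAnovaResult:
    f_statistic: float
    p_value: float
    df_group: int
    df_error: int
    tukey: dict[tuple, float] = field(default_factory=dict)
    group_means: dict = field(default_factory=dict)


@dataclass
class ExperimentResult:
    bio_values: pd.Series  # per-biological-replicate multimeric percentage
    grand_mean: float
    sem: float
    tech_values: pd.DataFrame | None = None


@dataclass
class LabelingEfficiencyResult:
    stained_mean: float
    stained_sem: float
    control_mean: float
    control_sem: float
    control_exceeds_stained: bool


def filter_pairs(records: pd.DataFrame) -> pd.DataFrame:
    """Keep analyzable pairs: green exactly 1-step and far-red not rejected."""
    keep = (records["green_class"] == "1-step") & (records["farred_class"] != "rejected")
    return records.loc[keep].reset_index(drop=True)


def class_percentages(records: pd.DataFrame) -> list[ReplicateSummary]:
    """Far-red class counts and percentages per technical replicate.

    ``records`` is an analyzable (already filtered) pair table with columns
    ``farred_class, bio_rep, tech_rep``.  Percentages are over the
    analyzable classes and sum to 100 per replicate; an empty replicate is
    flagged with ``n_analyzable = 0`` and no percentages.
    """
    out = []
    for (b, t), grp in records.groupby(["bio_rep", "tech_rep"], sort=True):
        counts = {c: int((grp["farred_class"] == c).sum()) for c in ANALYZABLE_CLASSES}
        n = sum(counts.values())
        percentages = {c: 100.0 * k / n for c, k in counts.items()} if n > 0 else {}
        out.append(ReplicateSummary(int(b), int(t), n, counts, percentages))
    return out


def percent_multimeric(summaries: list[ReplicateSummary]) -> ExperimentResult:
    """Percentage of analyzable complexes with >= 2 far-red steps.

    Per technical replicate: 2-step% + 3plus%.  Each biological replicate is
    the unweighted mean of its technical replicates; the experiment is
    summarized as grand mean +/- SEM over biological replicates.
    """
    rows = [
        {
            "bio_rep": s.bio_rep,
            "tech_rep": s.tech_rep,
            "multimeric_pct": s.percentages["2-step"] + s.percentages["3plus"],
        }
        for s in summaries
        if s.n_analyzable > 0
    ]
    if not rows:
        raise ValueError("no analyzable replicates")
    tech = pd.DataFrame(rows)
    bio = tech.groupby("bio_rep")["multimeric_pct"].mean()
    grand = float(bio.mean())
    se = float(sem(bio)) if len(bio) > 1 else float("nan")
    return ExperimentResult(bio_values=bio, grand_mean=grand, sem=se, tech_values=tech)


def nested_anova(data: pd.DataFrame, value: str = "value") -> NestedAnovaResult:
    """Nested one-way ANOVA with Tukey-adjusted pairwise comparisons.

    ``data`` needs columns ``group``, ``bio_rep`` and the value column; rows
    are technical-replicate measurements nested in biological replicates
    nested in groups.  The group effect is tested against the
    biological-replicate stratum: F = MS(group) / MS(bio within group).
    Tukey-Kramer comparisons act on biological-replicate means, using the
    between-bio-within-group mean square as the error term.
    """
    df = data.copy()
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g in groups:
        if df.loc[df["group"] == g, "bio_rep"].nunique() < 2:
            raise ValueError(f"group {g!r} needs >= 2 biological replicates")

    y = df[value].to_numpy(dtype=float)
    grand = y.mean()
    ss_group = 0.0
    ss_bio = 0.0
    for g in groups:
        dg = df[df["group"] == g]
        yg = dg[value].to_numpy(dtype=float)
        ss_group += len(yg) * (yg.mean() - grand) ** 2
        for _, db in dg.groupby("bio_rep"):
            yb = db[value].to_numpy(dtype=float)
            ss_bio += len(yb) * (yb.mean() - yg.mean()) ** 2
    n_bio_total = df.groupby(["group", "bio_rep"]).ngroups
    df_group = len(groups) - 1
    df_bio = n_bio_total - len(groups)
    if df_bio <= 0:
        raise ValueError("degenerate nesting: no biological-replicate degrees of freedom")
    ms_group = ss_group / df_group
    ms_bio = ss_bio / df_bio
    if ms_bio == 0:
        raise ValueError("zero between-biological-replicate variance")
    f_stat = ms_group / ms_bio
    p = float(f_dist.sf(f_stat, df_group, df_bio))

    # Tukey-Kramer on biological-replicate means
    bio_means = df.groupby(["group", "bio_rep"])[value].mean()
    means = {g: float(bio_means.loc[g].mean()) for g in groups}
    ns = {g: int(len(bio_means.loc[g])) for g in groups}
    mse = (
        sum(
            float(((bio_means.loc[g] - means[g]) ** 2).sum())
            for g in groups
        )
        / df_bio
    )
    tukey = {}
    for a, b in combinations(groups, 2):
        se2 = mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b])
        q = abs(means[a] - means[b]) / np.sqrt(se2) if se2 > 0 else np.inf
        tukey[(a, b)] = float(studentized_range.sf(q, len(groups), df_bio))
    return NestedAnovaResult(
        f_statistic=float(f_stat),
        p_value=p,
        df_group=df_group,
        df_error=df_bio,
        tukey=tukey,
        group_means=means,
    )


def labeling_efficiency(
    stained_fractions, control_fractions
) -> LabelingEfficiencyResult:
    """Dye labeling efficiency from colocalization fractions (in percent).

    ``stained_fractions`` / ``control_fractions`` are per-replicate
    percentages of bait spots colocalized with a dye spot, for dye-stained
    and unstained (negative-control) samples.  The control rate is reported
    alongside, not subtracted; a control exceeding the stained estimate is
    flagged.
    """
    stained = np.asarray(list(stained_fractions), dtype=float)
    control = np.asarray(list(control_fractions), dtype=float)
    res = LabelingEfficiencyResult(
        stained_mean=float(stained.mean()),
        stained_sem=float(sem(stained)) if len(stained) > 1 else float("nan"),
        control_mean=float(control.mean()) if len(control) else float("nan"),
        control_sem=float(sem(control)) if len(control) > 1 else float("nan"),
        control_exceeds_stained=bool(len(control) and control.mean() > stained.mean()),
    )
    return res


def _check_dist(dist: dict[int, float]) -> dict[int, float]:
    if any(k < 0 for k in dist) or any(v < 0 for v in dist.values()):
        raise ValueError("distribution keys and masses must be >= 0")
    total = sum(dist.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError("distribution must sum to 1")
    return {int(k): float(v) for k, v in dist.items()}


def expected_observed_classes(true_dist: dict[int, float], p_label: float) -> dict[int, float]:
    """Observed labeled-copy distribution after binomial thinning.

    observed(k) = sum_n true(n) * C(n, k) * p^k * (1-p)^(n-k).
    """
    if not (0.0 <= p_label <= 1.0):
        raise ValueError("p_label must lie in [0, 1]")
    true_dist = _check_dist(true_dist)
    K = max(true_dist) if true_dist else 0
    out = {k: 0.0 for k in range(K + 1)}
    for n, mass in true_dist.items():
        for k in range(n + 1):
            out[k] += mass * comb(n, k) * p_label**k * (1 - p_label) ** (n - k)
    return out


def invert_true_distribution(
    observed: dict[int, float], p_label: float, max_copies: int
) -> dict[int, float]:
    """Estimate the true copy-number distribution from the observed one.

    Non-negative least squares against the binomial-thinning forward model,
    constrained to the probability simplex.  ``p_label = 0`` is
    unidentifiable; observed mass above ``max_copies`` is infeasible.
    """
    if p_label <= 0:
        raise ValueError("p_label = 0 makes the true distribution unidentifiable")
    observed = _check_dist(observed)
    if max(observed) > max_copies:
        raise ValueError("observed mass at copy numbers above max_copies is infeasible")
    kmax = max_copies
    obs = np.zeros(kmax + 1)
    for k, v in observed.items():
        obs[k] = v
    # A[k, n] = P(observe k | true n)
    A = np.zeros((kmax + 1, kmax + 1))
    for n in range(kmax + 1):
        for k in range(n + 1):
            A[k, n] = comb(n, k) * p_label**k * (1 - p_label) ** (n - k)
    x, _ = optimize.nnls(A, obs)
    total = x.sum()
    if total <= 0:
        raise ValueError("inversion produced an empty distribution")
    x = x / total
    return {n: float(x[n]) for n in range(kmax + 1)}
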
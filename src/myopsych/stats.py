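"""Statistical comparison machinery: the homogeneity-branched decision
tree, cohort assignment, and paired learning-effect tests.

The comparison of an outcome across the three strategy groups follows a
fixed decision tree at α = 0.05:

1. Levene's test (median-centred, i.e. Brown-Forsythe) for homogeneity of
   variances.
2. Homogeneous → one-way ANOVA; if significant, both Tukey HSD and
   Bonferroni-corrected pairwise t-tests are run and the smaller adjusted
   p per pair is flagged as the headline.
3. Heterogeneous → Welch's robust ANOVA; if significant, Games-Howell
   post-hoc.

The branch taken is a pure function of the Levene p-value versus α.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "CohortPlan",
    "assign_cohort",
    "ComparisonResult",
    "compare_strategies",
    "paired_learning_tests",
]

ALPHA = 0.05

STRATEGY_ORDER = ("RAW", "FLT", "AUG")

#: retest strategy per subgroup, keyed by (first strategy, subgroup name)
SUBGROUP_RETESTS = {
    "RAW_to_AUG": ("RAW", "AUG"),
    "FLT_to_AUG": ("FLT", "AUG"),
    "AUG_to_RAW": ("AUG", "RAW"),
    "AUG_to_FLT": ("AUG", "FLT"),
}


@dataclass(frozen=True)
class CohortPlan:
    """24 subjects in 3 strategy groups of 8, with 4-subject retest subgroups."""

    groups: dict            # strategy -> tuple of subject ids (8 each)
    subgroups: dict         # subgroup name -> tuple of subject ids (4 each)
    seed: int

    def __post_init__(self) -> None:
        all_ids = [s for g in self.groups.values() for s in g]
        if len(all_ids) != len(set(all_ids)):
            raise ValueError("groups must be disjoint")
        for name, members in self.subgroups.items():
            first, _ = SUBGROUP_RETESTS[name]
            if not set(members) <= set(self.groups[first]):
                raise ValueError(f"subgroup {name} not a subset of group {first}")


def assign_cohort(seed: int, n_subjects: int = 24) -> CohortPlan:
    """Randomly assign subjects to the 3×8 group / 4×4 subgroup structure.

    Group 1 tests RAW (4 retest AUG), group 2 tests FLT (4 retest AUG),
    group 3 tests AUG (4 retest RAW, the other 4 retest FLT).
    Deterministic per seed.
    """
    if n_subjects != 24:
        raise ValueError("the cohort design requires exactly 24 subjects")
    rng = np.random.default_rng(seed)
    ids = [f"s{i + 1:02d}" for i in range(n_subjects)]
    perm = [ids[i] for i in rng.permutation(n_subjects)]
    groups = {
        "RAW": tuple(perm[0:8]),
        "FLT": tuple(perm[8:16]),
        "AUG": tuple(perm[16:24]),
    }
    pick = {s: rng.permutation(8) for s in STRATEGY_ORDER}
    subgroups = {
        "RAW_to_AUG": tuple(groups["RAW"][i] for i in pick["RAW"][:4]),
        "FLT_to_AUG": tuple(groups["FLT"][i] for i in pick["FLT"][:4]),
        "AUG_to_RAW": tuple(groups["AUG"][i] for i in pick["AUG"][:4]),
        "AUG_to_FLT": tuple(groups["AUG"][i] for i in pick["AUG"][4:]),
    }
    return CohortPlan(groups=groups, subgroups=subgroups, seed=seed)


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    p_tukey: float = float("nan")
    p_bonferroni: float = float("nan")
    p_games_howell: float = float("nan")
    p_headline: float = float("nan")
    headline_method: str = ""


@dataclass
class ComparisonResult:
    """Outcome of one decision-tree comparison across strategy groups."""

    outcome: str
    levene_p: float
    omnibus: str                 # 'anova' | 'welch'
    F: float
    df: tuple[float, float]
    p: float
    posthoc: str                 # '', 'tukey+bonferroni', 'games-howell'
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    group_means: dict = field(default_factory=dict)
    group_sems: dict = field(default_factory=dict)
    alpha: float = ALPHA
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def _games_howell(groups: Mapping[str, np.ndarray]) -> list[PairwiseComparison]:
    import pingouin as pg

    long = pd.DataFrame([
        {"group": g, "value": v} for g, vals in groups.items() for v in vals
    ])
    gh = pg.pairwise_gameshowell(data=long, dv="value", between="group")
    out = []
    for _, row in gh.iterrows():
        out.append(PairwiseComparison(
            group_a=str(row["A"]), group_b=str(row["B"]),
            p_games_howell=float(row["pval"]),
            p_headline=float(row["pval"]), headline_method="games-howell"))
    return out


def _tukey_bonferroni(groups: Mapping[str, np.ndarray]) -> list[PairwiseComparison]:
    names = list(groups)
    arrays = [np.asarray(groups[n], float) for n in names]
    tk = sst.tukey_hsd(*arrays)
    k = len(names)
    n_pairs = k * (k - 1) // 2
    out = []
    for i, j in itertools.combinations(range(k), 2):
        p_t = float(tk.pvalue[i, j])
        p_b = float(min(1.0, sst.ttest_ind(arrays[i], arrays[j]).pvalue * n_pairs))
        # both corrections are run; the smaller adjusted p per pair is
        # flagged as the headline (the higher-confidence report)
        if p_t <= p_b:
            head, method = p_t, "tukey"
        else:
            head, method = p_b, "bonferroni"
        out.append(PairwiseComparison(
            group_a=names[i], group_b=names[j], p_tukey=p_t,
            p_bonferroni=p_b, p_headline=head, headline_method=method))
    return out


def compare_strategies(groups: Mapping[str, Sequence[float]],
                       outcome: str = "outcome",
                       alpha: float = ALPHA) -> ComparisonResult:
    """Run the full decision tree on one outcome's per-group values.

    Requires at least 2 groups with at least 2 finite values each.
    Zero-variance groups are flagged and force the Welch branch (the
    classical ANOVA's homogeneity assumption is untestable there).
    Post-hoc tests run only when the omnibus p < α.
    """
    clean: dict[str, np.ndarray] = {}
    flags: list[str] = []
    for name, vals in groups.items():
        v = np.asarray(list(vals), dtype=float)
        dropped = int(np.sum(~np.isfinite(v)))
        if dropped:
            flags.append(f"{name}: dropped {dropped} non-finite value(s)")
        v = v[np.isfinite(v)]
        if len(v) < 2:
            raise ValueError(f"group {name!r} needs >= 2 finite values")
        clean[name] = v
    if len(clean) < 2:
        raise ValueError("need >= 2 groups")

    arrays = list(clean.values())
    degenerate = any(a.std(ddof=1) == 0.0 for a in arrays)
    if degenerate:
        flags.append("zero-variance group: Welch branch forced")
        levene_p = 0.0
    else:
        levene_p = float(sst.levene(*arrays, center="median").pvalue)

    means = {g: float(v.mean()) for g, v in clean.items()}
    sems = {g: float(v.std(ddof=1) / math.sqrt(len(v))) for g, v in clean.items()}

    homogeneous = (levene_p >= alpha) and not degenerate
    if homogeneous:
        F, p = sst.f_oneway(*arrays)
        k = len(arrays)
        N = sum(len(a) for a in arrays)
        df = (float(k - 1), float(N - k))
        omnibus = "anova"
    else:
        import pingouin as pg

        long = pd.DataFrame([
            {"group": g, "value": x} for g, v in clean.items() for x in v
        ])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            wa = pg.welch_anova(data=long, dv="value", between="group")
        F = float(wa["F"].iloc[0])
        p = float(wa["p_unc"].iloc[0])
        df = (float(wa["ddof1"].iloc[0]), float(wa["ddof2"].iloc[0]))
        omnibus = "welch"

    posthoc = ""
    pairwise: list[PairwiseComparison] = []
    if np.isfinite(p) and p < alpha:
        if homogeneous:
            posthoc = "tukey+bonferroni"
            pairwise = _tukey_bonferroni(clean)
        else:
            posthoc = "games-howell"
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    pairwise = _games_howell(clean)
            except Exception as exc:  # degenerate groups can break GH
                flags.append(f"games-howell failed: {exc}")

    return ComparisonResult(outcome=outcome, levene_p=levene_p,
                            omnibus=omnibus, F=float(F), df=df, p=float(p),
                            posthoc=posthoc, pairwise=pairwise,
                            group_means=means, group_sems=sems,
                            alpha=alpha, flags=flags)


def paired_learning_tests(pairs: Mapping[str, tuple[Sequence[float], Sequence[float]]]
                          ) -> pd.DataFrame:
    """Paired two-sample t-tests for retest (learning-effect) comparisons.

    ``pairs`` maps a label (e.g. ``"FLT_to_AUG/jnd"``) to the
    (first-exposure, retest) value vectors of the same subjects.  Returns
    a table with t, df = n−1, two-sided p, and the two means.  Zero
    within-pair variance with a non-zero shift is degenerate (|t| → ∞)
    and flagged.
    """
    rows = []
    for label, (first, retest) in pairs.items():
        a = np.asarray(list(first), dtype=float)
        b = np.asarray(list(retest), dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError(f"{label}: paired samples must be equal-length 1-D")
        if len(a) < 2:
            raise ValueError(f"{label}: need n >= 2 pairs")
        d = b - a
        degenerate = bool(np.isclose(d.std(ddof=1), 0.0) and not np.allclose(d, 0.0))
        if np.allclose(d, 0.0):
            t, p = 0.0, 1.0
        elif degenerate:
            t = math.inf if d.mean() > 0 else -math.inf
            p = 0.0
        else:
            res = sst.ttest_rel(b, a)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append({"comparison": label, "n": len(a), "t": t,
                     "df": len(a) - 1, "p": p,
                     "mean_first": float(a.mean()), "mean_retest": float(b.mean()),
                     "degenerate": degenerate})
    return pd.DataFrame(rows)
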
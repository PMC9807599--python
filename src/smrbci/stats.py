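"""Nonparametric statistical kernel and group-change reporting.

Implements the Wilcoxon signed-rank (WSR) test, the Wilcoxon rank-sum (WRS)
test and Spearman's rank correlation with the conventions typical of
clinical-style reporting:

* zero paired differences are dropped (Wilcoxon's original treatment);
* ties receive midranks, with the matching variance correction in the
  normal approximation;
* a continuity correction is applied by default and the *signed* Z value is
  reported alongside the two-sided p-value;
* for small samples the p-value is exact, computed from the full
  permutation distribution conditional on the observed (mid)ranks, which is
  valid with ties.

Z sign conventions: for WSR on differences ``d = post - pre``, Z is positive
when the positive differences dominate; for WRS, Z is positive when group A
tends to exceed group B.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as st

from .errors import DegenerateDataError, InvalidArgumentError

#: largest sample size for which the exact permutation distribution is used
EXACT_N = 12

_ALTERNATIVES = ("two-sided", "greater", "less")


@dataclass(frozen=True)
class StatResult:
    """Outcome of one test: statistic, normal-approximation Z, p, and n."""

    method: str
    statistic: float
    z: float | None
    p: float
    n: int
    alternative: str = "two-sided"
    exact: bool = False

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise InvalidArgumentError("p outside [0, 1]")

    def __str__(self):
        z = f"{self.z:.2f}" if self.z is not None else "n/a"
        return (f"{self.method}: stat={self.statistic:.4g}, Z={z}, "
                f"p={self.p:.3g} (n={self.n})")


def _check_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise InvalidArgumentError(f"alternative must be one of {_ALTERNATIVES}")


def _p_from_distribution(values: np.ndarray, observed: float,
                         alternative: str) -> float:
    """Exact p from an enumerated null distribution of the statistic."""
    eps = 1e-9
    p_greater = float(np.mean(values >= observed - eps))
    p_less = float(np.mean(values <= observed + eps))
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


def _p_from_z(z: float, alternative: str) -> float:
    if alternative == "greater":
        return float(st.norm.sf(z))
    if alternative == "less":
        return float(st.norm.cdf(z))
    return float(2.0 * st.norm.sf(abs(z)))


def _signed_z(stat: float, mean: float, sd: float, correction: bool) -> float:
    if sd == 0:
        return 0.0
    d = stat - mean
    if correction:
        d = np.sign(d) * max(abs(d) - 0.5, 0.0)
    return float(d / sd)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float] | None = None,
                         alternative: str = "two-sided",
                         correction: bool = True,
                         mode: str = "auto") -> StatResult:
    """Wilcoxon signed-rank test on paired values (or on differences).

    ``x`` is either the vector of differences, or the first member of the
    pair with ``y`` the second (differences ``x - y``).  Exact p by full
    enumeration of the 2^n sign assignments when the number of nonzero
    differences is at most :data:`EXACT_N` (valid with ties); otherwise the
    normal approximation with tie and continuity correction.  The reported
    statistic is ``W = min(W+, W-)``; Z is signed by the direction of W+.
    """
    _check_alternative(alternative)
    if mode not in ("auto", "exact", "approx"):
        raise InvalidArgumentError("mode must be auto, exact or approx")
    d = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if y.shape != d.shape:
            raise InvalidArgumentError("paired vectors must match in length")
        d = d - y
    if not np.all(np.isfinite(d)):
        raise InvalidArgumentError("non-finite paired differences")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = st.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    mean = n * (n + 1) / 4.0
    sd = float(np.sqrt(np.sum(ranks ** 2) / 4.0))
    z = _signed_z(w_plus, mean, sd, correction)
    exact = mode == "exact" or (mode == "auto" and n <= EXACT_N)
    if exact:
        signs = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1)
        dist = signs @ ranks
        p = _p_from_distribution(dist, w_plus, alternative)
    else:
        p = _p_from_z(z, alternative)
    return StatResult("wilcoxon-signed-rank", min(w_plus, w_minus), z, p, n,
                      alternative, exact)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float],
                      alternative: str = "two-sided", correction: bool = True,
                      mode: str = "auto") -> StatResult:
    """Wilcoxon rank-sum (Mann-Whitney) test on two independent samples.

    Statistic: ``U = R_a - n_a(n_a+1)/2`` from pooled midranks.  Exact p by
    enumeration of all group assignments when ``n_a + n_b <= EXACT_N``
    (valid with ties); otherwise normal approximation with tie and
    continuity correction.  Z is signed by the direction of ``a`` vs ``b``.
    """
    _check_alternative(alternative)
    if mode not in ("auto", "exact", "approx"):
        raise InvalidArgumentError("mode must be auto, exact or approx")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InvalidArgumentError("both groups must be nonempty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidArgumentError("non-finite group values")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = st.rankdata(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    n = na + nb
    mean = na * nb / 2.0
    # tie-corrected variance of U
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = _signed_z(u_a, mean, float(np.sqrt(max(var, 0.0))), correction)
    exact = mode == "exact" or (mode == "auto" and n <= EXACT_N)
    if exact:
        offs = na * (na + 1) / 2.0
        dist = np.array([sum(ranks[list(c)]) - offs
                         for c in itertools.combinations(range(n), na)])
        p = _p_from_distribution(dist, u_a, alternative)
    else:
        p = _p_from_z(z, alternative)
    return StatResult("wilcoxon-rank-sum", u_a, z, p, n, alternative, exact)


# ---------------------------------------------------------------------------
# Spearman rank correlation


def spearman(x: Sequence[float], y: Sequence[float],
             alternative: str = "two-sided") -> StatResult:
    """Spearman's rank correlation with midranks for ties.

    p-value: exact permutation over all n! orderings for n < 10, otherwise
    the t-distribution approximation with n - 2 degrees of freedom.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidArgumentError("x and y must match in length")
    n = len(x)
    if n < 4:
        raise InvalidArgumentError("need n >= 4 for rank correlation")
    rx = st.rankdata(x)
    ry = st.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise DegenerateDataError("zero rank variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n < 10:
        cx = (rx - rx.mean()) / rx.std()
        cy = (ry - ry.mean()) / ry.std()
        perms = np.array(list(itertools.permutations(range(n))))
        dist = cy[perms] @ cx / n
        p = _p_from_distribution(dist, rho, alternative) if alternative != "two-sided" \
            else float(np.mean(np.abs(dist) >= abs(rho) - 1e-9))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            if alternative == "greater":
                p = float(st.t.sf(t, n - 2))
            elif alternative == "less":
                p = float(st.t.cdf(t, n - 2))
            else:
                p = float(2.0 * st.t.sf(abs(t), n - 2))
        if alternative != "two-sided" and abs(rho) >= 1.0:
            p = 0.0 if (rho > 0) == (alternative == "greater") else 1.0
    return StatResult("spearman", rho, None, p, n, alternative, n < 10)


# ---------------------------------------------------------------------------
# group-change summaries


@dataclass
class GroupChangeSummary:
    """Pre/post change summary of one group and task."""

    group: str
    task: str
    n: int
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    change_mean: float
    change_sd: float
    wsr: StatResult | None       # None when all changes are exactly zero
    note: str = ""

    def format_row(self) -> str:
        base = (f"{self.group} {self.task} (n={self.n}): "
                f"pre {self.pre_mean:.2f} ± {self.pre_sd:.2f}, "
                f"post {self.post_mean:.2f} ± {self.post_sd:.2f}, "
                f"change {self.change_mean:.2f} ± {self.change_sd:.2f}")
        if self.wsr is None:
            return base + " (WSR degenerate: all changes zero)"
        return base + f" (WSR, Z = {self.wsr.z:.2f}, p = {self.wsr.p:.2g})"


@dataclass
class GroupComparison:
    """Between-group WRS on per-subject changes."""

    group_a: str
    group_b: str
    task: str
    wrs: StatResult

    def format_row(self) -> str:
        return (f"{self.group_a} vs {self.group_b} {self.task}: "
                f"WRS, Z = {self.wrs.z:.2f}, p = {self.wrs.p:.2g}")


REQUIRED_COLUMNS = ("subject", "group", "task", "pre", "post")


def summarize_group_change(table: pd.DataFrame,
                           group_pairs: Sequence[tuple[str, str]] = (),
                           ) -> tuple[list[GroupChangeSummary],
                                      list[GroupComparison]]:
    """Per-group pre/post summaries plus optional between-group comparisons.

    ``table`` needs columns subject, group, task, pre, post (one row per
    subject and task).  Change is post - pre per subject before averaging;
    spreads are sample standard deviations (n - 1).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidArgumentError(f"table missing columns: {missing}")
    if len(table) == 0:
        raise InvalidArgumentError("empty table")
    bad = table[table[["pre", "post"]].isna().any(axis=1)]
    if len(bad):
        raise InvalidArgumentError(
            "subjects missing pre or post: "
            + ", ".join(sorted(map(str, bad["subject"].unique()))))
    summaries = []
    for (group, task), rows in table.groupby(["group", "task"], sort=True):
        pre = rows["pre"].to_numpy(dtype=float)
        post = rows["post"].to_numpy(dtype=float)
        change = post - pre
        note = ""
        try:
            wsr = wilcoxon_signed_rank(post, pre)
        except DegenerateDataError:
            wsr = None
            note = "all changes zero"
        sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        summaries.append(GroupChangeSummary(
            str(group), str(task), len(rows),
            float(pre.mean()), sd(pre), float(post.mean()), sd(post),
            float(change.mean()), sd(change), wsr, note))
    comparisons = []
    for ga, gb in group_pairs:
        for task in sorted(table["task"].unique()):
            ra = table[(table["group"] == ga) & (table["task"] == task)]
            rb = table[(table["group"] == gb) & (table["task"] == task)]
            if len(ra) == 0 or len(rb) == 0:
                raise InvalidArgumentError(
                    f"group pair ({ga}, {gb}) missing rows for task {task}")
            wrs = wilcoxon_rank_sum(
                (ra["post"] - ra["pre"]).to_numpy(dtype=float),
                (rb["post"] - rb["pre"]).to_numpy(dtype=float))
            comparisons.append(GroupComparison(str(ga), str(gb), str(task), wrs))
    return summaries, comparisons


def summaries_to_frame(summaries: Sequence[GroupChangeSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "group": s.group, "task": s.task, "n": s.n,
        "pre_mean": s.pre_mean, "pre_sd": s.pre_sd,
        "post_mean": s.post_mean, "post_sd": s.post_sd,
        "change_mean": s.change_mean, "change_sd": s.change_sd,
        "wsr_z": s.wsr.z if s.wsr else np.nan,
        "wsr_p": s.wsr.p if s.wsr else np.nan,
        "note": s.note,
    } for s in summaries])


def format_report(summaries: Sequence[GroupChangeSummary],
                  comparisons: Sequence[GroupComparison] = (),
                  title: str = "Group change report") -> str:
    """Markdown report in 'mean ± sd (test, Z, p)' style."""
    lines = [f"# {title}", "", "## Within-group change (pre vs post)", ""]
    lines += [f"- {s.format_row()}" for s in summaries]
    if comparisons:
        lines += ["", "## Between-group comparison of changes", ""]
        lines += [f"- {c.format_row()}" for c in comparisons]
    n_tests = sum(1 for s in summaries if s.wsr is not None) + len(comparisons)
    lines += ["", f"_{n_tests} statistical tests performed; no "
                  "multiple-comparison correction applied._", ""]
    return "\n".join(lines)
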
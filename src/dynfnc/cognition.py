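"""Cognitive-domain composites, change scores, and paired statistics.

Domain composites are built by pooled standardization: each subtest's pre
and post scores are z-scored against the mean and sample SD of the pooled
pre+post sample (2n values, denominator 2n-1), subtests where a higher raw
score means worse performance (timed tests) are sign-flipped, and the
domain composite is the mean of its member z-scores.  Pooled centering
forces the baseline and post composite group means to be exact negatives of
each other, the symmetry visible in published cohort tables.

Pre/post comparisons use the paired t test with the d = pre - post sign
convention, so improvement on a higher-is-better score yields a negative t.
Brain-behavior relationships use Pearson correlation of change scores.  No
multiplicity correction is applied by default (a Benjamini-Hochberg switch
exists but is off), mirroring the exploratory analyses this package
reproduces.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ArgumentError, DegenerateDataError

logger = logging.getLogger(__name__)


@dataclass
class DomainSpec:
    """One cognitive domain: member subtests and their orientations."""

    name: str
    subtests: tuple[str, ...]
    higher_is_better: dict[str, bool] = field(default_factory=dict)

    def orientation(self, subtest: str) -> float:
        return 1.0 if self.higher_is_better.get(subtest, True) else -1.0


@dataclass
class PairedTestResult:
    feature: str
    t: float
    p: float
    n: int

    @property
    def df(self) -> int:
        return self.n - 1


def _validate_specs(specs: Sequence[DomainSpec]) -> None:
    seen: dict[str, str] = {}
    for spec in specs:
        for sub in spec.subtests:
            if sub in seen:
                raise ArgumentError(
                    f"subtest {sub!r} appears in both {seen[sub]!r} and {spec.name!r}"
                )
            seen[sub] = spec.name


def composite_domains(raw: pd.DataFrame, specs: Sequence[DomainSpec]) -> pd.DataFrame:
    """Build domain composite z-scores and change scores from raw subtests.

    ``raw`` is tidy with columns (subject, session, subtest, value);
    sessions are "pre" and "post".  Returns a frame with columns
    (subject, domain, pre, post, delta) where delta = post - pre.  Subjects
    missing a subtest are dropped from that domain only (logged).
    """
    _validate_specs(specs)
    for col in ("subject", "session", "subtest", "value"):
        if col not in raw.columns:
            raise ArgumentError(f"raw table lacks column {col!r}")
    wide = raw.pivot_table(
        index="subject", columns=["subtest", "session"], values="value", aggfunc="first"
    )
    out_rows = []
    for spec in specs:
        zscores = {}
        for sub in spec.subtests:
            if (sub, "pre") not in wide.columns or (sub, "post") not in wide.columns:
                raise ArgumentError(f"subtest {sub!r} missing from the raw table")
            pre = wide[(sub, "pre")]
            post = wide[(sub, "post")]
            pooled = pd.concat([pre, post]).dropna()
            sd = pooled.std(ddof=1)
            if not sd > 0:
                raise DegenerateDataError(f"subtest {sub!r} has zero pooled SD")
            mean = pooled.mean()
            sign = spec.orientation(sub)
            zscores[sub] = (sign * (pre - mean) / sd, sign * (post - mean) / sd)
        z_pre = pd.concat([z[0] for z in zscores.values()], axis=1).mean(axis=1, skipna=False)
        z_post = pd.concat([z[1] for z in zscores.values()], axis=1).mean(axis=1, skipna=False)
        dropped = int(z_pre.isna().sum() + z_post.isna().sum())
        if dropped:
            logger.info("domain %s: dropped %d incomplete subject-sessions", spec.name, dropped)
        for subject in wide.index:
            if np.isnan(z_pre[subject]) or np.isnan(z_post[subject]):
                continue
            out_rows.append(
                {
                    "subject": subject,
                    "domain": spec.name,
                    "pre": z_pre[subject],
                    "post": z_post[subject],
                    "delta": z_post[subject] - z_pre[subject],
                }
            )
    return pd.DataFrame(out_rows)


def paired_compare(pre: np.ndarray, post: np.ndarray, feature: str = "") -> PairedTestResult:
    """Paired t test on d = pre - post (two-sided, uncorrected p)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ArgumentError("pre and post must have equal length")
    n = pre.size
    if n < 3:
        raise ArgumentError("need at least 3 paired observations")
    d = pre - post
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("paired differences are all identical (zero variance)")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(feature=feature, t=float(t), p=float(p), n=n)


def correlate_changes(
    delta_feature: np.ndarray, delta_cognition: np.ndarray
) -> tuple[float, float]:
    """Pearson r between change scores with its two-sided uncorrected p."""
    x = np.asarray(delta_feature, dtype=float)
    y = np.asarray(delta_cognition, dtype=float)
    if x.shape != y.shape:
        raise ArgumentError("inputs must have equal length")
    if x.size < 3:
        raise ArgumentError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("zero variance input to correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = min(1.0, max(-1.0, r))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def group_difference_report(
    pre_features: pd.DataFrame,
    post_features: pd.DataFrame,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Paired pre/post t test per feature column; tidy result table.

    Rows of the two frames are subjects (must describe the same subject
    set); columns are feature names.  ``significant`` flags p < alpha with
    no multiplicity correction unless ``fdr`` enables Benjamini-Hochberg.
    """
    if set(pre_features.index) != set(post_features.index):
        raise AlignmentError("pre and post feature tables describe different subjects")
    if list(pre_features.columns) != list(post_features.columns):
        raise AlignmentError("pre and post feature tables have different columns")
    post_features = post_features.loc[pre_features.index]
    rows = []
    for col in pre_features.columns:
        res = paired_compare(
            pre_features[col].to_numpy(), post_features[col].to_numpy(), feature=str(col)
        )
        rows.append({"feature": res.feature, "t": res.t, "p": res.p, "n": res.n})
    table = pd.DataFrame(rows)
    if fdr:
        order = np.argsort(table["p"].to_numpy())
        m = len(table)
        adj = np.empty(m)
        prev = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            prev = min(prev, table["p"].iloc[i] * m / (rank_idx + 1))
            adj[i] = prev
        table["p_adj"] = adj
        table["significant"] = table["p_adj"] < alpha
    else:
        table["significant"] = table["p"] < alpha
    return table
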
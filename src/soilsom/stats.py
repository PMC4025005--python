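"""Cluster characterization statistics.

Three views of the clustered towns: per-cluster mean (SD) summary tables
with one-way ANOVA post-hoc compact letter displays; per-cluster Spearman
rank correlations between each covariate and the risk index RI, with
two-tailed significance flags at 0.05 / 0.01 and an explicit
"not computable" marker when a variable is constant within a cluster; and
the underlying one-way ANOVA F test.

Post-hoc pairwise comparisons default to Tukey HSD (Tukey-Kramer for
unequal group sizes); Duncan's multiple range test is available as an
option. Letters follow the insert-absorb compact-letter-display rule:
groups sharing a letter are not significantly different at the chosen
alpha.
"""

from __future__ import annotations

import itertools
import math
import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DataError

NOT_COMPUTABLE = "a"  # table marker for cells that cannot be computed
MISSING = "-"


@dataclass(frozen=True)
class CorrelationCell:
    """One Spearman cell: coefficient, two-tailed p, and significance flag."""

    rho: float
    p_value: float
    flag: str  # none | p<0.05 | p<0.01 | not_computable

    def format(self) -> str:
        if self.flag == "not_computable":
            return NOT_COMPUTABLE
        suffix = {"p<0.01": " **", "p<0.05": " *"}.get(self.flag, "")
        return f"{self.rho:.3f}{suffix}"


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-tailed exact p by full permutation of one rank vector (n <= 9)."""
    n = len(rx)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = float(rxc @ ryc[list(perm)]) / denom
        count += abs(r) >= target
        total += 1
    return count / total


def spearman(x, y) -> CorrelationCell:
    """Spearman rank correlation on midranks with a two-tailed p-value.

    Ties get average ranks. For n <= 9 the p-value is an exact permutation
    p; otherwise the usual t approximation with n - 2 degrees of freedom.
    Constant input (or n < 3) yields the not_computable marker.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationCell(rho=float("nan"), p_value=float("nan"), flag="not_computable")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        p = _exact_permutation_p(rx, ry, rho)
    else:
        r = min(max(rho, -1.0), 1.0)
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1 - r * r))
            p = 2 * sps.t.sf(abs(t), df=n - 2)
    flag = "p<0.01" if p < 0.01 else ("p<0.05" if p < 0.05 else "none")
    return CorrelationCell(rho=rho, p_value=float(p), flag=flag)


def correlation_table(town_data: pd.DataFrame, ri, cluster_labels) -> pd.DataFrame:
    """Per-cluster Spearman correlation of every covariate with RI.

    Rows are covariates, columns are clusters; each cell a
    :class:`CorrelationCell`. Clusters with fewer than 3 towns get
    not_computable cells throughout.
    """
    ri = np.asarray(ri, dtype=float)
    labels = np.asarray(cluster_labels)
    if len(ri) != len(town_data) or len(labels) != len(town_data):
        raise DataError("town_data, ri and cluster_labels must align")
    clusters = sorted(pd.unique(labels).tolist())
    nc = CorrelationCell(float("nan"), float("nan"), "not_computable")
    out = {}
    for c in clusters:
        mask = labels == c
        col = {}
        for var in town_data.columns:
            if mask.sum() < 3:
                col[var] = nc
            else:
                col[var] = spearman(town_data.loc[mask, var].to_numpy(dtype=float), ri[mask])
        out[c] = col
    return pd.DataFrame(out, index=list(town_data.columns))


def format_correlation_table(table: pd.DataFrame) -> pd.DataFrame:
    """Render a CorrelationCell table to strings with * / ** suffixes."""
    return table.map(lambda c: c.format())


def _group_arrays(values, groups, min_size: int = 2):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ids = sorted(pd.unique(groups).tolist())
    kept, arrays = [], []
    for g in ids:
        v = values[groups == g]
        if len(v) < min_size:
            warnings.warn(f"group {g!r} has fewer than {min_size} observations; dropped",
                          stacklevel=3)
            continue
        kept.append(g)
        arrays.append(v)
    return kept, arrays


def anova_oneway(values, groups) -> tuple[float, float]:
    """Classical one-way ANOVA F test (between / within mean squares).

    Groups with fewer than 2 observations are dropped with a warning.
    Returns (F, p) with degrees of freedom (k - 1, N - k).
    """
    ids, arrays = _group_arrays(values, groups)
    k = len(ids)
    if k < 2:
        raise DataError("need at least 2 groups with >= 2 observations")
    ns = np.array([len(a) for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()
    n_total = int(ns.sum())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((a - m) ** 2) for a, m in zip(arrays, means)))
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        return (float("inf") if ms_b > 0 else 0.0, 0.0 if ms_b > 0 else 1.0)
    f = ms_b / ms_w
    return float(f), float(sps.f.sf(f, df_b, df_w))


def _pairwise_significant(arrays, method: str, alpha: float) -> np.ndarray:
    """Boolean matrix of significantly different group pairs."""
    k = len(arrays)
    ns = np.array([len(a) for a in arrays])
    means = np.array([a.mean() for a in arrays])
    df_w = int(ns.sum()) - k
    ms_w = sum(np.sum((a - a.mean()) ** 2) for a in arrays) / df_w
    sig = np.zeros((k, k), dtype=bool)
    if ms_w == 0:
        for i, j in itertools.combinations(range(k), 2):
            sig[i, j] = sig[j, i] = means[i] != means[j]
        return sig
    if method == "tukey":
        qcrit = sps.studentized_range.ppf(1 - alpha, k, df_w)
        for i, j in itertools.combinations(range(k), 2):
            se = math.sqrt(ms_w / 2 * (1 / ns[i] + 1 / ns[j]))
            sig[i, j] = sig[j, i] = abs(means[i] - means[j]) / se > qcrit
        return sig
    if method == "duncan":
        return _duncan_pairs(means, ns, ms_w, df_w, alpha)
    raise ConfigError(f"unknown post-hoc method {method!r}")


def _duncan_pairs(means, ns, ms_w, df_w, alpha) -> np.ndarray:
    """Duncan's multiple range test on ordered means.

    A pair spanning p ordered means is compared against the studentized
    range at the protected level (1 - alpha)^(p - 1); a range is declared
    non-significant whenever any enclosing range is non-significant.
    """
    k = len(means)
    order = np.argsort(means)
    sig_ord = np.zeros((k, k), dtype=bool)
    # harmonic-mean sample size for unequal groups
    for span in range(k, 1, -1):
        qcrit = sps.studentized_range.ppf((1 - alpha) ** (span - 1), span, df_w)
        for start in range(0, k - span + 1):
            i, j = start, start + span - 1
            gi, gj = order[i], order[j]
            nh = 2.0 / (1.0 / ns[gi] + 1.0 / ns[gj])
            se = math.sqrt(ms_w / nh)
            q = (means[gj] - means[gi]) / se
            enclosing_ns = any(
                not sig_ord[a, b]
                for a in range(0, i + 1)
                for b in range(j, k)
                if (b - a) > (j - i)
            )
            sig_ord[i, j] = (q > qcrit) and not enclosing_ns
    sig = np.zeros((k, k), dtype=bool)
    for i, j in itertools.combinations(range(k), 2):
        gi, gj = order[i], order[j]
        sig[gi, gj] = sig[gj, gi] = sig_ord[i, j]
    return sig


def compact_letters(sig: np.ndarray, group_ids) -> dict:
    """Insert-absorb compact letter display from a pairwise significance matrix.

    Groups sharing any letter are not significantly different; every
    non-significant pair shares at least one letter.
    """
    k = sig.shape[0]
    columns: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if not sig[i, j]:
            continue
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            a, b = col - {i}, col - {j}
            for new in (a, b):
                if not any(new <= other for other in columns):
                    columns.append(new)
            columns = [c for c in columns
                       if not any(c < other for other in columns if other is not c)]
    columns = [c for c in columns if c]
    # order letters by the lowest group index they contain, for stable output
    columns.sort(key=lambda c: min(c))
    if len(columns) > len(string.ascii_lowercase):
        raise DataError("more letter groups than letters")
    letters = {g: "" for g in range(k)}
    for letter, col in zip(string.ascii_lowercase, columns):
        for g in sorted(col):
            letters[g] += letter
    return {gid: letters[i] for i, gid in enumerate(group_ids)}


def posthoc_letters(values, groups, method: str = "tukey", alpha: float = 0.05) -> dict:
    """All-pairs post-hoc comparison summarized as compact letters per group.

    ``method`` is ``"tukey"`` (HSD / Tukey-Kramer) or ``"duncan"`` (multiple
    range test). Groups with fewer than 2 observations are dropped.
    """
    if method not in ("tukey", "duncan"):
        raise ConfigError(f"unknown post-hoc method {method!r}")
    ids, arrays = _group_arrays(values, groups)
    if len(ids) < 2:
        raise DataError("need at least 2 groups with >= 2 observations")
    sig = _pairwise_significant(arrays, method, alpha)
    return compact_letters(sig, ids)


def cluster_summary(
    town_data: pd.DataFrame,
    labels,
    method: str = "tukey",
    alpha: float = 0.05,
    all_clusters=None,
) -> dict[str, pd.DataFrame]:
    """Per-cluster mean, SD and post-hoc letter for every variable.

    Returns a dict with numeric ``means`` and ``sds`` frames, a ``letters``
    frame, and a ``formatted`` frame of "mean (sd) letter" strings (rows:
    variables, columns: clusters). Clusters listed in ``all_clusters`` but
    holding no cases appear as columns of missing markers.
    """
    labels = np.asarray(labels)
    if len(labels) != len(town_data):
        raise DataError("labels must cover all towns")
    present = sorted(pd.unique(labels).tolist())
    clusters = sorted(set(present) | set(all_clusters or []))
    variables = list(town_data.columns)

    means = pd.DataFrame(index=variables, columns=clusters, dtype=float)
    sds = pd.DataFrame(index=variables, columns=clusters, dtype=float)
    letters = pd.DataFrame(MISSING, index=variables, columns=clusters, dtype=object)
    formatted = pd.DataFrame(MISSING, index=variables, columns=clusters, dtype=object)

    for var in variables:
        vals = town_data[var].to_numpy(dtype=float)
        for c in present:
            v = vals[labels == c]
            means.loc[var, c] = v.mean()
            sds.loc[var, c] = v.std(ddof=1) if len(v) > 1 else 0.0
        eligible = [c for c in present if np.sum(labels == c) >= 2]
        if len(eligible) >= 2 and np.ptp(vals) > 0:
            mask = np.isin(labels, eligible)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lett = posthoc_letters(vals[mask], labels[mask], method=method, alpha=alpha)
        else:
            lett = {c: "a" for c in present}
        for c in present:
            letters.loc[var, c] = lett.get(c, MISSING)
            formatted.loc[var, c] = (f"{means.loc[var, c]:.2f} "
                                     f"({sds.loc[var, c]:.2f}) {letters.loc[var, c]}")
    return {"means": means, "sds": sds, "letters": letters, "formatted": formatted}
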
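"""Independent, loop-level transcriptions of the stability measures.

These are deliberately naive (scalar loops, statistics-module helpers) and
structured differently from the library implementations, so that agreement
between the two routes is meaningful.
"""

from __future__ import annotations

import math
import statistics
from itertools import combinations

import pandas as pd


def _sd(xs) -> float:
    return statistics.stdev(list(xs))  # n-1 denominator


def oracle_delta_ct(df: pd.DataFrame) -> dict[str, float]:
    names = list(df.index)
    out = {}
    for i in names:
        sds = []
        for j in names:
            if j == i:
                continue
            diffs = [df.at[i, c] - df.at[j, c] for c in df.columns]
            sds.append(_sd(diffs))
        out[i] = sum(sds) / len(sds)
    return out


def oracle_bestkeeper(df: pd.DataFrame) -> dict[str, float]:
    out = {}
    for i in df.index:
        row = [df.at[i, c] for c in df.columns]
        center = sum(row) / len(row)
        out[i] = sum(abs(x - center) for x in row) / len(row)
    return out


def oracle_genorm(df: pd.DataFrame) -> tuple[dict[str, float], list[str]]:
    """Stepwise geNorm, recomputed from scratch each round.

    Exclusion ties go to the later candidate in input order; the final two
    both report the final-round M.
    """
    names = list(df.index)
    survivors = list(names)
    reported: dict[str, float] = {}
    order: list[str] = []
    while True:
        m = {}
        for j in survivors:
            vs = []
            for k in survivors:
                if k == j:
                    continue
                vs.append(_sd(df.at[j, c] - df.at[k, c] for c in df.columns))
            m[j] = sum(vs) / len(vs)
        if len(survivors) == 2:
            for j in survivors:
                reported[j] = m[j]
            order.extend(survivors)
            return reported, order
        worst_value = max(m.values())
        worst = [j for j in survivors if m[j] == worst_value][-1]
        reported[worst] = m[worst]
        order.append(worst)
        survivors.remove(worst)


def _centered(df: pd.DataFrame) -> pd.DataFrame:
    """Subtract each sample's mean across candidates."""
    z = df.copy().astype(float)
    for c in df.columns:
        col_mean = sum(df.at[i, c] for i in df.index) / len(df.index)
        for i in df.index:
            z.at[i, c] = df.at[i, c] - col_mean
    return z


def _candidate_variances(df: pd.DataFrame) -> dict[str, float]:
    """Method-of-moments variances from sample-centred residuals."""
    k = len(df.index)
    z = _centered(df)
    u = {i: statistics.variance([z.at[i, c] for c in df.columns]) for i in df.index}
    s_total = k / (k - 1) * sum(u.values())
    return {i: max(0.0, k / (k - 2) * (u[i] - s_total / k**2)) for i in df.index}


def oracle_normfinder_ungrouped(df: pd.DataFrame) -> dict[str, float]:
    return {i: math.sqrt(v) for i, v in _candidate_variances(df).items()}


def oracle_normfinder_grouped(df: pd.DataFrame, groups: pd.Series):
    """Grouped decomposition; returns (rho, per-group internals)."""
    names = list(df.index)
    group_names = list(dict.fromkeys(groups))
    sigma2: dict[str, dict[str, float]] = {g: {} for g in group_names}
    zbar: dict[str, dict[str, float]] = {g: {} for g in group_names}
    n_g: dict[str, int] = {}
    for g in group_names:
        cols = [c for c in df.columns if groups[c] == g]
        n_g[g] = len(cols)
        sub = df[cols]
        var = _candidate_variances(sub)
        z = _centered(sub)
        for i in names:
            sigma2[g][i] = var[i]
            zbar[g][i] = sum(z.at[i, c] for c in cols) / len(cols)
    d_raw = {
        g: {
            i: zbar[g][i] - sum(zbar[h][i] for h in group_names) / len(group_names)
            for i in names
        }
        for g in group_names
    }
    gamma2: dict[str, float] = {}
    for g in group_names:
        var_d = statistics.variance([d_raw[g][i] for i in names])
        mean_v = sum(sigma2[g][i] / n_g[g] for i in names) / len(names)
        gamma2[g] = max(0.0, var_d - mean_v)
    d_shrunk = {
        g: {
            i: d_raw[g][i] * (gamma2[g] / (gamma2[g] + sigma2[g][i] / n_g[g])
                              if gamma2[g] + sigma2[g][i] / n_g[g] > 0 else 0.0)
            for i in names
        }
        for g in group_names
    }
    rho = {}
    for i in names:
        terms = []
        for g in group_names:
            v = sigma2[g][i] / n_g[g]
            shrink = gamma2[g] / (gamma2[g] + v) if gamma2[g] + v > 0 else 0.0
            terms.append(abs(d_shrunk[g][i]) + math.sqrt(shrink * v))
        rho[i] = sum(terms) / len(terms)
    internals = {"sigma2": sigma2, "d_shrunk": d_shrunk, "gamma2": gamma2, "n_g": n_g}
    return rho, internals


def oracle_best_pair(df: pd.DataFrame, groups: pd.Series) -> tuple[tuple[str, str], float]:
    _, intern = oracle_normfinder_grouped(df, groups)
    group_names = list(intern["n_g"])
    best: tuple[str, str] | None = None
    best_value = math.inf
    for i, j in combinations(df.index, 2):
        terms = []
        for g in group_names:
            d = 0.5 * (intern["d_shrunk"][g][i] + intern["d_shrunk"][g][j])
            sig2 = 0.25 * (intern["sigma2"][g][i] + intern["sigma2"][g][j])
            v = sig2 / intern["n_g"][g]
            gamma2 = intern["gamma2"][g]
            shrink = gamma2 / (gamma2 + v) if gamma2 + v > 0 else 0.0
            terms.append(abs(d) + math.sqrt(shrink * v))
        value = sum(terms) / len(terms)
        if value < best_value:
            best_value = value
            best = (i, j)
    return best, best_value


def oracle_competition_ranks(values: dict[str, float]) -> dict[str, int]:
    return {
        i: 1 + sum(1 for j in values if values[j] < values[i]) for i in values
    }


def oracle_classify(peaks: list[tuple[float, float]], reference_tm: float | None,
                    height_min: float = 0.5, half: float = 0.5,
                    max_peaks: int = 2, tm_tol: float = 1.5) -> str:
    """Rule-by-rule verdict on a known (planted) peak list."""
    peaks = sorted(peaks, key=lambda p: -p[1])
    if not peaks:
        return "rejected"
    if peaks[0][1] < height_min:
        return "rejected"
    if len(peaks) > max_peaks:
        return "rejected"
    if len(peaks) >= 2 and peaks[1][1] >= half * peaks[0][1]:
        return "rejected"
    if reference_tm is not None and abs(peaks[0][0] - reference_tm) > tm_tol:
        return "rejected"
    return "approved"
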
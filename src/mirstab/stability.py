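"""Reference-gene stability algorithms and the ensemble ranking.

All algorithms operate on a complete-case Cp matrix (assays x samples),
working directly in Cp space under the usual assumption of amplification
efficiency 2, so that Cp differences are log2 expression ratios.  Lower
values always mean more stable.

Implemented measures:

* comparative delta-Ct: mean over partner candidates of the SD of pairwise
  Cp differences;
* BestKeeper: mean absolute deviation of each candidate's Cp values around
  their central value (only the MAD component enters the ensemble);
* geNorm: average pairwise-difference SD (M) with stepwise exclusion of the
  least stable candidate;
* NormFinder: model-based variance decomposition, optionally with sample
  groups (intragroup variance plus shrunken intergroup differences), and a
  best-pair search over candidate pairs;
* RefFinder: geometric mean of the four algorithms' ranks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CpMatrix


def _frame(matrix: CpMatrix | pd.DataFrame) -> pd.DataFrame:
    df = matrix.values if isinstance(matrix, CpMatrix) else matrix
    if df.isna().any().any():
        raise ValueError("stability algorithms require a complete-case matrix")
    return df.astype(float)


# ---------------------------------------------------------------------------
# delta-Ct
# ---------------------------------------------------------------------------


def delta_ct_stability(matrix: CpMatrix | pd.DataFrame) -> pd.Series:
    """Comparative delta-Ct stability: S_i = mean_{j != i} SD(Cp_i - Cp_j).

    Sample SDs use the n-1 denominator.  Requires >= 2 candidates and
    >= 2 samples.
    """
    df = _frame(matrix)
    k, n = df.shape
    if k < 2 or n < 2:
        raise ValueError("delta-Ct needs >= 2 candidates and >= 2 samples")
    x = df.to_numpy()
    out = np.empty(k)
    for i in range(k):
        sds = [np.std(x[i] - x[j], ddof=1) for j in range(k) if j != i]
        out[i] = float(np.mean(sds))
    return pd.Series(out, index=df.index, name="deltact")


# ---------------------------------------------------------------------------
# BestKeeper (MAD component)
# ---------------------------------------------------------------------------


def bestkeeper_stability(
    matrix: CpMatrix | pd.DataFrame, center: str = "arithmetic"
) -> pd.Series:
    """BestKeeper stability: MAD_i = mean_j |Cp_ij - center_i|.

    ``center`` is the arithmetic mean by default; ``"geometric"`` uses the
    geometric mean of the Cp values (the original BestKeeper's centring).
    """
    df = _frame(matrix)
    x = df.to_numpy()
    if center == "arithmetic":
        c = x.mean(axis=1)
    elif center == "geometric":
        if np.any(x <= 0):
            raise ValueError("geometric centring requires positive Cp values")
        c = np.exp(np.log(x).mean(axis=1))
    else:
        raise ValueError(f"unknown center {center!r}")
    mad = np.abs(x - c[:, None]).mean(axis=1)
    return pd.Series(mad, index=df.index, name="bestkeeper")


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------


def genorm_stability(matrix: CpMatrix | pd.DataFrame) -> tuple[pd.Series, list[str]]:
    """geNorm M values with stepwise exclusion.

    At each round, M_j is the mean over remaining partners k of
    V_jk = SD(Cp_j - Cp_k); the candidate with the highest M is excluded
    and its current M recorded as its reported value.  The final two
    candidates both receive the final-round M (and hence tie).  Exclusion
    ties are broken by excluding the later candidate in input order.

    Returns (reported M per candidate, exclusion order worst-first; the
    final two appear last in input order).
    """
    df = _frame(matrix)
    names = list(df.index)
    if len(names) < 3:
        raise ValueError("geNorm needs >= 3 candidates")
    x = {name: df.loc[name].to_numpy() for name in names}
    reported: dict[str, float] = {}
    order: list[str] = []
    current = list(names)
    while True:
        m = {}
        for j in current:
            vs = [np.std(x[j] - x[k], ddof=1) for k in current if k != j]
            m[j] = float(np.mean(vs))
        if len(current) == 2:
            for j in current:
                reported[j] = m[j]
            order.extend(current)
            break
        # exclude the worst; ties broken toward the later candidate in input order
        worst_val = max(m.values())
        worst = [j for j in current if m[j] == worst_val][-1]
        reported[worst] = m[worst]
        order.append(worst)
        current.remove(worst)
    series = pd.Series({name: reported[name] for name in names}, name="genorm")
    return series.loc[names], order


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairStability:
    """An unordered candidate pair and its grouped-NormFinder stability."""

    pair: tuple[str, str]
    value: float

    def __post_init__(self) -> None:
        if self.pair[0] == self.pair[1]:
            raise ValueError("pair members must be distinct")
        if self.value < 0:
            raise ValueError("pair stability must be >= 0")


def _shrink_factor(gamma2: np.ndarray, v: np.ndarray) -> np.ndarray:
    """gamma^2 / (gamma^2 + v), defined as 0 where both variances vanish."""
    denom = gamma2 + v
    out = np.zeros(np.broadcast_shapes(np.shape(gamma2), np.shape(v)))
    np.divide(np.broadcast_to(gamma2, out.shape), denom, out=out, where=denom > 0)
    return out


def _check_groups(df: pd.DataFrame, groups: pd.Series) -> pd.Series:
    groups = pd.Series(groups)
    groups = groups.reindex(df.columns)
    if groups.isna().any():
        missing = list(df.columns[groups.isna()])
        raise ValueError(f"samples without group label: {missing[:5]}")
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("grouped NormFinder needs >= 2 groups")
    small = counts[counts < 3]
    if not small.empty:
        raise ValueError(f"groups with fewer than 3 samples: {list(small.index)}")
    return groups


def _ungrouped_variances(x: np.ndarray) -> np.ndarray:
    """Method-of-moments candidate variances from sample-centred residuals.

    With z_ij = y_ij - mean_i(y_ij), E[var_j(z_i)] = sigma_i^2 (1 - 2/k)
    + sum_l sigma_l^2 / k^2, which inverts to
    sigma_i^2 = (k/(k-2)) (u_i - S/k^2) with S = (k/(k-1)) sum_i u_i.
    Negative estimates are floored at zero.
    """
    k = x.shape[0]
    z = x - x.mean(axis=0, keepdims=True)
    u = z.var(axis=1, ddof=1)
    s_total = k / (k - 1) * u.sum()
    sig2 = k / (k - 2) * (u - s_total / k**2)
    return np.maximum(sig2, 0.0)


@dataclass
class GroupedDecomposition:
    """Per-group variance components of the grouped NormFinder model."""

    genes: list[str]
    group_names: list[str]
    n_g: np.ndarray          # samples per group
    sigma2: np.ndarray       # (k, G) intragroup variances
    d_raw: np.ndarray        # (k, G) raw intergroup deviations
    d_shrunk: np.ndarray     # (k, G) shrunken intergroup deviations
    gamma2: np.ndarray       # (G,) intergroup variance estimates

    def stability(self) -> pd.Series:
        v = self.sigma2 / self.n_g[None, :]
        shrink = _shrink_factor(self.gamma2[None, :], v)
        se = np.sqrt(shrink * v)
        rho = (np.abs(self.d_shrunk) + se).mean(axis=1)
        return pd.Series(rho, index=self.genes, name="normfinder")

    def pair_stability(self, i: int, j: int) -> float:
        d = 0.5 * (self.d_shrunk[i] + self.d_shrunk[j])
        sig2 = 0.25 * (self.sigma2[i] + self.sigma2[j])
        v = sig2 / self.n_g
        shrink = _shrink_factor(self.gamma2, v)
        se = np.sqrt(shrink * v)
        return float((np.abs(d) + se).mean())


def grouped_decomposition(
    matrix: CpMatrix | pd.DataFrame, groups: pd.Series
) -> GroupedDecomposition:
    """Fit the grouped NormFinder variance decomposition.

    Within each group the intragroup variances follow the same
    method-of-moments decomposition as the ungrouped analysis.  Intergroup
    deviations d_ig (group mean of the sample-centred values, centred
    across groups per gene) are shrunk toward zero by the factor
    gamma^2 / (gamma^2 + sigma^2_ig / n_g), with gamma^2 estimated per
    group as Var_i(d_ig) - mean_i(sigma^2_ig / n_g), floored at zero.
    """
    df = _frame(matrix)
    k = df.shape[0]
    if k < 3:
        raise ValueError("NormFinder needs >= 3 candidates")
    groups = _check_groups(df, groups)
    group_names = list(dict.fromkeys(groups))
    G = len(group_names)
    sigma2 = np.empty((k, G))
    zbar = np.empty((k, G))
    n_g = np.empty(G, dtype=int)
    for gi, g in enumerate(group_names):
        sub = df.loc[:, groups[groups == g].index].to_numpy()
        n_g[gi] = sub.shape[1]
        z = sub - sub.mean(axis=0, keepdims=True)
        sigma2[:, gi] = _ungrouped_variances(sub)
        zbar[:, gi] = z.mean(axis=1)
    d_raw = zbar - zbar.mean(axis=1, keepdims=True)
    v = sigma2 / n_g[None, :]
    gamma2 = np.maximum(d_raw.var(axis=0, ddof=1) - v.mean(axis=0), 0.0)
    d_shrunk = d_raw * _shrink_factor(gamma2[None, :], v)
    return GroupedDecomposition(
        genes=list(df.index), group_names=group_names, n_g=n_g,
        sigma2=sigma2, d_raw=d_raw, d_shrunk=d_shrunk, gamma2=gamma2,
    )


def normfinder_stability(
    matrix: CpMatrix | pd.DataFrame, groups: pd.Series | None = None
) -> pd.Series:
    """NormFinder stability values (lower = more stable).

    Ungrouped: rho_i is the square root of the model-based candidate
    variance.  Grouped: rho_i averages, over groups, the absolute shrunken
    intergroup deviation plus its standard error.
    """
    df = _frame(matrix)
    if df.shape[0] < 3:
        raise ValueError("NormFinder needs >= 3 candidates")
    if groups is None:
        sig2 = _ungrouped_variances(df.to_numpy())
        return pd.Series(np.sqrt(sig2), index=df.index, name="normfinder")
    return grouped_decomposition(df, groups).stability()


def normfinder_best_pair(
    matrix: CpMatrix | pd.DataFrame, groups: pd.Series
) -> tuple[PairStability, pd.DataFrame]:
    """Exhaustive grouped-NormFinder search for the most stable pair.

    A pair's intergroup deviation per group is the mean of the members'
    shrunken deviations and its intragroup variance is a quarter of the sum
    of the members' variances (the variance of the average of two
    independent candidates); the pair value then combines these exactly as
    the single-candidate stability does.

    Returns the best pair and the full pair table sorted ascending.
    """
    dec = grouped_decomposition(matrix, groups)
    rows = []
    for i, j in itertools.combinations(range(len(dec.genes)), 2):
        rows.append(
            {
                "assay_1": dec.genes[i],
                "assay_2": dec.genes[j],
                "stability": dec.pair_stability(i, j),
            }
        )
    table = pd.DataFrame(rows).sort_values("stability", kind="mergesort").reset_index(drop=True)
    best = table.iloc[0]
    return PairStability(pair=(best.assay_1, best.assay_2), value=float(best.stability)), table


# ---------------------------------------------------------------------------
# Ranking and the RefFinder ensemble
# ---------------------------------------------------------------------------


def rank_candidates(values: pd.Series, ascending: bool = True) -> pd.Series:
    """Competition ranks: the smallest value gets rank 1, ties share the
    minimum rank, and the next distinct value's rank counts all strictly
    better candidates plus one."""
    if not np.all(np.isfinite(values.to_numpy(dtype=float))):
        raise ValueError("ranking requires finite values")
    return values.rank(method="min", ascending=ascending).astype(int)


ALGORITHMS = ("deltact", "bestkeeper", "normfinder", "genorm")


def reffinder_ensemble(ranks: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """RefFinder aggregate: geometric mean of the four per-algorithm ranks,
    then competition-ranked.  ``ranks`` must hold one column per algorithm."""
    missing = [a for a in ALGORITHMS if a not in ranks.columns]
    if missing:
        raise ValueError(f"missing algorithm rank column(s): {missing}")
    sub = ranks[list(ALGORITHMS)]
    if sub.isna().any().any():
        raise ValueError("missing rank entries")
    geo = np.exp(np.log(sub.astype(float)).mean(axis=1))
    geo.name = "reffinder_geomean"
    return geo, rank_candidates(geo).rename("reffinder_rank")


def stability_table(
    matrix: CpMatrix | pd.DataFrame,
    groups: pd.Series | None = None,
    bestkeeper_center: str = "arithmetic",
) -> pd.DataFrame:
    """Run all five algorithms and assemble the full stability table.

    Columns: value + competition rank for delta-Ct, BestKeeper, NormFinder
    and geNorm, then the RefFinder geometric mean and final rank.  Rows are
    sorted by the RefFinder rank.
    """
    df = _frame(matrix)
    values = pd.DataFrame(
        {
            "deltact": delta_ct_stability(df),
            "bestkeeper": bestkeeper_stability(df, center=bestkeeper_center),
            "normfinder": normfinder_stability(df, groups=groups),
            "genorm": genorm_stability(df)[0],
        }
    )
    ranks = values.apply(rank_candidates)
    geo, final = reffinder_ensemble(ranks)
    out = pd.DataFrame(index=df.index)
    for alg in ALGORITHMS:
        out[alg] = values[alg]
        out[f"{alg}_rank"] = ranks[alg]
    out["reffinder_geomean"] = geo
    out["reffinder_rank"] = final
    return out.sort_values(["reffinder_rank", "reffinder_geomean"], kind="mergesort")


#: printed column headers of the rendered stability table
TABLE_HEADERS = [
    "Target",
    "Avg. STDEV", "Rank",
    "MAD", "Rank",
    "Stability", "Rank",
    "Avg.M", "Rank",
    "Geom. mean value", "Rank",
]


def format_stability_table(table: pd.DataFrame, decimals: int = 3) -> pd.DataFrame:
    """Render a stability table with the conventional printed headers and
    values rounded to ``decimals`` (internal computation stays full
    precision)."""
    cols = {
        "Target": table.index,
        "Avg. STDEV": table["deltact"].round(decimals).to_numpy(),
        "Rank_1": table["deltact_rank"].to_numpy(),
        "MAD": table["bestkeeper"].round(decimals).to_numpy(),
        "Rank_2": table["bestkeeper_rank"].to_numpy(),
        "Stability": table["normfinder"].round(decimals).to_numpy(),
        "Rank_3": table["normfinder_rank"].to_numpy(),
        "Avg.M": table["genorm"].round(decimals).to_numpy(),
        "Rank_4": table["genorm_rank"].to_numpy(),
        "Geom. mean value": table["reffinder_geomean"].round(decimals).to_numpy(),
        "Rank_5": table["reffinder_rank"].to_numpy(),
    }
    rendered = pd.DataFrame(cols)
    rendered.columns = TABLE_HEADERS
    return rendered


# ---------------------------------------------------------------------------
# Downstream normalisation
# ---------------------------------------------------------------------------


def normalize_expression(
    matrix: CpMatrix | pd.DataFrame, reference_assays: list[str]
) -> pd.DataFrame:
    """Delta-Cp normalisation against the chosen references:
    dCp_ij = Cp_ij - mean over references of Cp_ref,j (per sample)."""
    df = matrix.values if isinstance(matrix, CpMatrix) else matrix
    if not reference_assays:
        raise ValueError("empty reference set")
    missing = [r for r in reference_assays if r not in df.index]
    if missing:
        raise ValueError(f"reference assay(s) not in matrix: {missing}")
    ref_mean = df.loc[reference_assays].mean(axis=0)
    return df.sub(ref_mean, axis=1)
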
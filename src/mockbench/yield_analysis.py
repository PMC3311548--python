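"""DNA-yield analysis: split-plot ANOVA, per-sample Tukey HSD, letter displays.

Concentrations are analyzed on the natural-log scale (the base is irrelevant
to F tests).  The split-plot layout has extraction method as the whole-plot
factor, sample (species) as the split-plot factor and experimenter as a
random block; the method F test uses the whole-plot error stratum
(block x method), everything else the residual.

Per-sample method comparisons use a self-contained one-way layout with
Tukey's studentized-range correction, summarized as a compact letter display
(methods share a letter iff not significantly different).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .community_model import round_half_up

__all__ = [
    "YieldTable",
    "LetterDisplay",
    "YieldTableError",
    "log_transform_yields",
    "splitplot_anova",
    "tukey_hsd_per_sample",
    "compact_letter_display",
    "yield_summary",
]

_COLUMNS = ["method", "sample", "replicate", "experimenter", "day", "concentration"]


class YieldTableError(ValueError):
    pass


@dataclass(frozen=True)
class YieldTable:
    """Long-format concentration records (µg/ml) with block labels."""

    data: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise YieldTableError(f"missing columns: {missing}")
        df = df[_COLUMNS].reset_index(drop=True)
        df["concentration"] = df["concentration"].astype(float)
        if not self.log_scale and (df["concentration"] < 0).any():
            bad = df.index[df["concentration"] < 0][0]
            raise YieldTableError(f"negative concentration at record {bad}")
        object.__setattr__(self, "data", df)

    @property
    def methods(self) -> list[str]:
        return sorted(self.data["method"].astype(str).unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample"].astype(str).unique())

    def mean_table(self) -> pd.DataFrame:
        """Mean concentration per method x sample (wide, samples as rows)."""
        return self.data.pivot_table(
            index="sample", columns="method", values="concentration", aggfunc="mean"
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "YieldTable":
        df = pd.read_csv(path, sep="\t", dtype={"method": str, "sample": str})
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def log_transform_yields(table: YieldTable) -> YieldTable:
    """Natural-log transform; zero or negative values are refused."""
    if table.log_scale:
        raise YieldTableError("table is already on the log scale")
    conc = table.data["concentration"]
    bad = conc <= 0
    if bad.any():
        i = int(table.data.index[bad][0])
        rec = table.data.loc[i]
        raise YieldTableError(
            f"non-positive concentration at method={rec['method']!r} "
            f"sample={rec['sample']!r} replicate={rec['replicate']!r}; "
            "substitute a detection limit before log-transforming"
        )
    df = table.data.copy()
    df["concentration"] = np.log(conc)
    return YieldTable(df, log_scale=True)


def _check_balanced(df: pd.DataFrame) -> int:
    cell_sizes = df.groupby(["method", "sample", "experimenter"]).size()
    n_methods = df["method"].nunique()
    n_samples = df["sample"].nunique()
    n_blocks = df["experimenter"].nunique()
    if len(cell_sizes) != n_methods * n_samples * n_blocks or cell_sizes.nunique() != 1:
        raise YieldTableError(
            "design is unbalanced (unequal replicates per method x sample x "
            "block); subset to a balanced design first"
        )
    return int(cell_sizes.iloc[0])


def splitplot_anova(table: YieldTable) -> pd.DataFrame:
    """Balanced split-plot ANOVA on log yields.

    Returns a frame with sources block, method, whole_plot_error, sample,
    method:sample and residual.  The input must already be log-transformed
    (apply :func:`log_transform_yields` first) — this is asserted via the
    ``log_scale`` flag.
    """
    if not table.log_scale:
        table = log_transform_yields(table)
    df = table.data
    n_rep = _check_balanced(df)
    y = df["concentration"].to_numpy()
    n_total = y.size
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    def ss_for(levels: list[str]) -> float:
        means = df.groupby(levels)["concentration"].mean()
        sizes = df.groupby(levels).size()
        return float((sizes * (means - grand) ** 2).sum())

    a = df["method"].nunique()
    s = df["sample"].nunique()
    b = df["experimenter"].nunique()

    ss_block = ss_for(["experimenter"])
    ss_method = ss_for(["method"])
    ss_cells_wp = ss_for(["method", "experimenter"])
    ss_wp_error = ss_cells_wp - ss_block - ss_method
    ss_sample = ss_for(["sample"])
    ss_ms_cells = ss_for(["method", "sample"])
    ss_interaction = ss_ms_cells - ss_method - ss_sample
    ss_resid = ss_total - ss_cells_wp - ss_sample - ss_interaction

    df_block = b - 1
    df_method = a - 1
    df_wp_error = (a - 1) * (b - 1)
    df_sample = s - 1
    df_interaction = (a - 1) * (s - 1)
    df_resid = (
        (n_total - 1) - df_block - df_method - df_wp_error - df_sample - df_interaction
    )
    if df_wp_error <= 0 or df_resid <= 0:
        raise YieldTableError("not enough degrees of freedom for the split-plot fit")
    _ = n_rep

    ms = {
        "block": ss_block / df_block,
        "method": ss_method / df_method,
        "whole_plot_error": ss_wp_error / df_wp_error,
        "sample": ss_sample / df_sample,
        "method:sample": ss_interaction / df_interaction,
        "residual": ss_resid / df_resid,
    }
    rows = []

    def add(source, dof, ss, f=None, p=None, stratum=""):
        rows.append(
            {
                "source": source,
                "df": dof,
                "sum_sq": max(ss, 0.0),
                "mean_sq": ss / dof,
                "F": f,
                "p": p,
                "error_stratum": stratum,
            }
        )

    f_method = ms["method"] / ms["whole_plot_error"]
    p_method = float(stats.f.sf(f_method, df_method, df_wp_error))
    f_sample = ms["sample"] / ms["residual"]
    p_sample = float(stats.f.sf(f_sample, df_sample, df_resid))
    f_inter = ms["method:sample"] / ms["residual"]
    p_inter = float(stats.f.sf(f_inter, df_interaction, df_resid))

    add("block", df_block, ss_block, stratum="whole_plot_error")
    add("method", df_method, ss_method, f_method, p_method, "whole_plot_error")
    add("whole_plot_error", df_wp_error, ss_wp_error)
    add("sample", df_sample, ss_sample, f_sample, p_sample, "residual")
    add("method:sample", df_interaction, ss_interaction, f_inter, p_inter, "residual")
    add("residual", df_resid, ss_resid)
    return pd.DataFrame(rows)


def tukey_hsd_per_sample(
    table: YieldTable, sample: str, alpha: float = 0.05
) -> dict:
    """All-pairs Tukey HSD among methods for one sample, on log yields.

    One-way layout: a pair differs significantly when |mean_i - mean_j|
    exceeds q(alpha, k, df) * sqrt(MS_within / n).
    """
    if not table.log_scale:
        table = log_transform_yields(table)
    df = table.data[table.data["sample"].astype(str) == str(sample)]
    if df.empty:
        raise YieldTableError(f"sample {sample!r} not found")
    groups = {m: g["concentration"].to_numpy() for m, g in df.groupby("method")}
    methods = sorted(groups)
    k = len(methods)
    if k < 2:
        raise YieldTableError("need at least two methods")
    sizes = {len(g) for g in groups.values()}
    if len(sizes) != 1:
        raise YieldTableError("unequal group sizes; Tukey HSD requires balance")
    n = sizes.pop()
    if n < 2:
        raise YieldTableError("need >= 2 replicates per method (no within variance)")
    dof = k * (n - 1)
    ms_within = float(
        sum(((g - g.mean()) ** 2).sum() for g in groups.values()) / dof
    )
    means = {m: float(groups[m].mean()) for m in methods}
    q_crit = float(stats.studentized_range.ppf(1 - alpha, k, dof))
    se = np.sqrt(ms_within / n)
    sig = pd.DataFrame(False, index=methods, columns=methods)
    pvals = pd.DataFrame(1.0, index=methods, columns=methods)
    for i, a in enumerate(methods):
        for b_ in methods[i + 1 :]:
            diff = abs(means[a] - means[b_])
            if se == 0:
                significant, p = diff > 0, (0.0 if diff > 0 else 1.0)
            else:
                q_obs = diff / se
                p = float(stats.studentized_range.sf(q_obs, k, dof))
                significant = diff > q_crit * se
            sig.loc[a, b_] = sig.loc[b_, a] = bool(significant)
            pvals.loc[a, b_] = pvals.loc[b_, a] = p
    return {
        "sample": str(sample),
        "means_log": means,
        "significant": sig,
        "p_values": pvals,
        "q_critical": q_crit,
        "ms_within": ms_within,
        "df": dof,
        "n_per_group": n,
        "alpha": alpha,
    }


@dataclass(frozen=True)
class LetterDisplay:
    """Letter codes per treatment; shared letter iff not significantly different."""

    letters: dict[str, str]
    significant: pd.DataFrame = field(repr=False)

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def compact_letter_display(
    significant: pd.DataFrame, means: dict[str, float] | pd.Series
) -> LetterDisplay:
    """Insert-and-absorb letter assignment, ordered by descending mean.

    Starts from a single letter covering everything; each significant pair
    found inside a letter set splits it into two overlapping children; sets
    that become subsets of others are absorbed.  The construction guarantees
    the iff invariant, which is re-checked before returning.
    """
    treatments = list(significant.index)
    if list(significant.columns) != treatments:
        raise ValueError("significance matrix must be square with matching labels")
    sig = significant.astype(bool)
    if not sig.values.T.tolist() == sig.values.tolist():
        raise ValueError("significance matrix must be symmetric")
    if any(sig.loc[t, t] for t in treatments):
        raise ValueError("diagonal of a significance matrix must be False")

    sets: list[set[str]] = [set(treatments)]
    for i, a in enumerate(treatments):
        for b in treatments[i + 1 :]:
            if not sig.loc[a, b]:
                continue
            next_sets: list[set[str]] = []
            for s in sets:
                if a in s and b in s:
                    next_sets.append(s - {a})
                    next_sets.append(s - {b})
                else:
                    next_sets.append(s)
            # absorb: drop any set contained in another
            sets = [
                s
                for idx, s in enumerate(next_sets)
                if s
                and not any(
                    s <= t and (s != t or idx > jdx)
                    for jdx, t in enumerate(next_sets)
                    if jdx != idx
                )
            ]

    means = dict(means)
    order = sorted(treatments, key=lambda t: (-means[t], treatments.index(t)))
    # letters named in first-use order while walking treatments by descending mean
    labeled: list[tuple[str, set[str]]] = []
    remaining = list(sets)
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

    def next_label() -> str:
        idx = len(labeled)
        label = ""
        while True:
            label = alphabet[idx % 26] + label
            idx = idx // 26 - 1
            if idx < 0:
                break
        return label

    for t in order:
        for s in sorted(
            [s for s in remaining if t in s],
            key=lambda s: -max(means[u] for u in s),
        ):
            labeled.append((next_label(), s))
            remaining.remove(s)
    for s in remaining:  # sets not touched (cannot happen, but keep total)
        labeled.append((next_label(), s))

    letters = {
        t: "".join(label for label, s in labeled if t in s) for t in treatments
    }
    display = LetterDisplay(letters=letters, significant=sig)
    for i, a in enumerate(treatments):
        for b in treatments[i + 1 :]:
            if sig.loc[a, b] == display.share_letter(a, b):
                raise ValueError(
                    "letter display violates its invariant for pair "
                    f"({a!r}, {b!r}); the significance pattern may be "
                    "unrealizable"
                )
    return display


def yield_summary(means: pd.DataFrame | YieldTable) -> dict:
    """Rankings, top-vs-best-other fold ratios and lowest-mean tallies.

    ``means`` is either a YieldTable (means computed from it) or a wide
    sample x method frame of mean concentrations.
    """
    if isinstance(means, YieldTable):
        means = means.mean_table()
    if means.isna().any().any():
        missing = [
            (s, m)
            for s in means.index
            for m in means.columns
            if pd.isna(means.loc[s, m])
        ]
        raise YieldTableError(f"missing method/sample cells: {missing[:5]}")
    per_sample: dict[str, dict] = {}
    lowest_counts: dict[str, int] = {str(m): 0 for m in means.columns}
    for sample in means.index:
        row = means.loc[sample]
        ranking = [str(m) for m in row.sort_values(ascending=False).index]
        top = ranking[0]
        others = row.drop(index=row.idxmax())
        best_other = float(others.max())
        top_mean = float(row.max())
        ratio = top_mean / best_other if best_other > 0 else float("inf")
        ties = [str(m) for m in row.index if row[m] == top_mean]
        lowest = [str(m) for m in row.index if row[m] == float(row.min())]
        for m in lowest:
            lowest_counts[m] += 1
        per_sample[str(sample)] = {
            "ranking": ranking,
            "top_method": top,
            "top_mean": top_mean,
            "best_other_mean": best_other,
            "fold_ratio": ratio if np.isfinite(ratio) else None,
            "fold_ratio_1dp": round_half_up(ratio, 1) if np.isfinite(ratio) else None,
            "top_ties": ties if len(ties) > 1 else [],
            "lowest_methods": lowest,
        }
    return {"per_sample": per_sample, "lowest_mean_counts": lowest_counts}
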
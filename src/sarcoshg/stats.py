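"""Heart-level aggregation and group comparisons (paired t-test, ANOVA).

Fiber-level fits are averaged to one summary per heart (fiber -> heart
directly by default; fiber -> image -> heart available), and groups are
compared at the heart level with a two-sided paired t-test and a classical
one-way ANOVA.  Results are reported in the mean ± SD convention with the
significance threshold at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

MORPHO_VARS = ("sl_um", "abl_um", "ttil_um")


@dataclass
class GroupComparison:
    variable: str
    test: str
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    statistic: float
    pvalue: float
    n: int
    degenerate: bool = False

    def format_mean_sd(self, which: str = "a") -> str:
        m, s = (self.mean_a, self.sd_a) if which == "a" else (self.mean_b, self.sd_b)
        return f"{m:.3f} ± {s:.3f}"


def summarize_hearts(
    fiber_table: pd.DataFrame,
    manifest: pd.DataFrame,
    aggregate: str = "fiber",
) -> pd.DataFrame:
    """One row per heart: mean and SD of SL/ABL/TTIL over QC-passing fibers.

    ``fiber_table`` is the per-fiber table from :func:`sarcoshg.fit.fits_to_frame`
    (must include ``image_id`` and ``qc_pass``); ``manifest`` maps image_id to
    heart_id/group/age/pair_id.  ``aggregate='image'`` averages fibers within
    each image first.  Hearts with zero passing fibers are flagged excluded
    (``n_fibers = 0``, NaN means).
    """
    if aggregate not in ("fiber", "image"):
        raise ValueError("aggregate must be 'fiber' or 'image'")
    meta = manifest.drop_duplicates("image_id").set_index("image_id")
    df = fiber_table.join(meta, on="image_id", how="left")
    if df["heart_id"].isna().any():
        missing = df.loc[df["heart_id"].isna(), "image_id"].unique()
        raise ValueError(f"images missing from manifest: {list(missing)[:5]}")
    passing = df[df["qc_pass"]].copy()
    rows = []
    for heart_id, hmeta in manifest.drop_duplicates("heart_id").set_index("heart_id").iterrows():
        sub = passing[passing["heart_id"] == heart_id]
        row = {
            "heart_id": heart_id,
            "group": hmeta["group"],
            "age": hmeta["age"],
            "pair_id": hmeta["pair_id"],
            "n_fibers": len(sub),
            "n_images": sub["image_id"].nunique(),
            "excluded": len(sub) == 0,
        }
        if aggregate == "image" and len(sub):
            sub = sub.groupby("image_id", as_index=False)[list(MORPHO_VARS) + ["ratio"]].mean()
        for v in MORPHO_VARS:
            row[f"{v}_mean"] = sub[v].mean() if len(sub) else np.nan
            row[f"{v}_sd"] = sub[v].std(ddof=1) if len(sub) > 1 else np.nan
        row["ratio_mean"] = sub["ratio"].mean() if len(sub) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(
    hearts: pd.DataFrame,
    variable: str,
    test: str = "paired_t",
    groups: tuple[str, str] = ("control", "iugr"),
) -> GroupComparison:
    """Two-sided comparison of one heart-level variable between two groups.

    ``paired_t`` aligns hearts on ``pair_id``: pairs broken by QC exclusion
    are dropped (the excluded heart has no usable measurement), while a
    pair_id missing from one group's roster altogether raises, listed by id.
    ``anova`` is the classical one-way parametric test.  A paired test with
    all differences equal is degenerate: all-zero differences give t = 0,
    p = 1; constant nonzero differences are flagged with p = 0.
    """
    usable = hearts[~hearts.get("excluded", False)]
    ga = usable[usable["group"] == groups[0]]
    gb = usable[usable["group"] == groups[1]]
    a, b = ga[variable].to_numpy(float), gb[variable].to_numpy(float)
    degenerate = False
    if test == "paired_t":
        roster_a = set(hearts.loc[hearts["group"] == groups[0], "pair_id"])
        roster_b = set(hearts.loc[hearts["group"] == groups[1], "pair_id"])
        bad = sorted(roster_a ^ roster_b)
        if bad:
            raise ValueError(f"unpaired hearts for pair_ids {bad}")
        merged = ga[["pair_id", variable]].merge(
            gb[["pair_id", variable]], on="pair_id", suffixes=("_a", "_b"), how="inner"
        )
        x = merged[f"{variable}_a"].to_numpy(float)
        y = merged[f"{variable}_b"].to_numpy(float)
        d = x - y
        scale = max(float(np.max(np.abs(d))), 1e-300)
        if len(d) < 2 or np.std(d, ddof=1) <= 1e-12 * scale:
            degenerate = True
            stat, p = (0.0, 1.0) if np.allclose(d, 0) else (np.inf, 0.0)
        else:
            stat, p = sps.ttest_rel(x, y)
        n = len(d)
    elif test == "anova":
        if np.var(np.concatenate([a, b])) == 0:
            degenerate, stat, p = True, 0.0, 1.0
        else:
            stat, p = sps.f_oneway(a, b)
        n = min(len(a), len(b))
    else:
        raise ValueError("test must be 'paired_t' or 'anova'")
    return GroupComparison(
        variable=variable,
        test=test,
        group_a=groups[0],
        group_b=groups[1],
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)) if len(a) > 1 else np.nan,
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)) if len(b) > 1 else np.nan,
        statistic=float(stat),
        pvalue=float(p),
        n=int(n),
        degenerate=degenerate,
    )


def compare_all(
    hearts: pd.DataFrame,
    tests: tuple[str, ...] = ("paired_t", "anova"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Comparison table over SL/ABL/TTIL (heart means) for each requested test."""
    rows = []
    for v in [f"{m}_mean" for m in MORPHO_VARS]:
        for t in tests:
            c = compare_groups(hearts, v, test=t)
            rows.append(
                {
                    "variable": c.variable,
                    "age": hearts["age"].iloc[0] if len(hearts) else "",
                    "test": c.test,
                    "control_mean": c.mean_a,
                    "control_sd": c.sd_a,
                    "iugr_mean": c.mean_b,
                    "iugr_sd": c.sd_b,
                    "statistic": c.statistic,
                    "pvalue": c.pvalue,
                    "n": c.n,
                    "significant": c.pvalue < alpha,
                }
            )
    return pd.DataFrame(rows)
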
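"""Reproducible benchmarks: parameter recovery, cohort recovery, test power.

These drive the full pipeline on simulated data whose ground truth is pinned
at the study's group configurations, and are shared by the test suite, the
analysis scripts and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import RunConfig
from .pipeline import analyze_cohort, measure_cohort
from .simulate import STUDY_GROUPS, CohortSpec, simulate_cohort
from .stats import compare_groups, summarize_hearts


def single_group_cohort_spec(
    age: str,
    group: str,
    seed: int,
    n_hearts: int = 7,
    images_per_heart: int = 3,
) -> CohortSpec:
    """One study group simulated at its configured heart-level distribution."""
    return CohortSpec(
        age=age,
        groups=(group,),
        n_hearts=n_hearts,
        images_per_heart=images_per_heart,
        seed=seed,
    )


def measure_group_cohort(
    age: str, group: str, seed: int, config: RunConfig | None = None
) -> dict:
    """Full pipeline on one simulated group; cohort means over heart means.

    Returns the recovered cohort-mean SL/ABL/TTIL (µm), the SL/ABL ratio of
    cohort means, and bookkeeping counts.
    """
    spec = single_group_cohort_spec(age, group, seed)
    cohort = simulate_cohort(spec)
    fibers = measure_cohort(cohort, config)
    hearts = summarize_hearts(fibers, cohort.manifest())
    usable = hearts[~hearts["excluded"]]
    sl = float(usable["sl_um_mean"].mean())
    abl = float(usable["abl_um_mean"].mean())
    ttil = float(usable["ttil_um_mean"].mean())
    return {
        "age": age,
        "group": group,
        "sl_um": sl,
        "abl_um": abl,
        "ttil_um": ttil,
        "ratio": sl / abl,
        "n_hearts": int(len(usable)),
        "n_fibers": int(fibers["qc_pass"].sum()),
    }


def fiber_recovery_errors(
    n_images: int = 10, seed: int = 0, config: RunConfig | None = None
) -> pd.DataFrame:
    """Per-fiber SL/ABL/TTIL errors (nm) on single-group images at the fetal
    control configuration, fibers matched to ground truth."""
    spec = CohortSpec(
        age="fetal",
        groups=("control",),
        n_hearts=1,
        images_per_heart=n_images,
        seed=seed,
    )
    cohort = simulate_cohort(spec)
    fibers = measure_cohort(cohort, config)
    matched = fibers.dropna(subset=["true_sl_um"])
    return matched[
        ["image_id", "fiber_id", "err_sl_nm", "err_abl_nm", "err_ttil_nm", "qc_pass"]
    ].reset_index(drop=True)


def power_study(
    n_replicates: int = 100,
    seed: int = 0,
    age: str = "fetal",
    variable: str = "sl_um_mean",
) -> pd.DataFrame:
    """Paired-t power over replicate cohorts at the printed group configurations.

    Each replicate simulates a paired 7+7 cohort in profile mode (one image
    worth of fibers per heart), measures it, and tests control vs IUGR on
    heart-level means.  Returns one row per replicate with the p-value and
    the sign of the effect (positive = control larger).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_replicates):
        spec = CohortSpec(
            age=age,
            n_hearts=7,
            images_per_heart=1,
            seed=int(rng.integers(2**31)),
        )
        cohort = simulate_cohort(spec, mode="profile")
        fibers = measure_cohort(cohort)
        hearts = summarize_hearts(fibers, cohort.manifest())
        c = compare_groups(hearts, variable, test="paired_t")
        rows.append(
            {
                "pvalue": c.pvalue,
                "control_minus_iugr": c.mean_a - c.mean_b,
                "significant": c.pvalue < 0.05,
            }
        )
    return pd.DataFrame(rows)
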
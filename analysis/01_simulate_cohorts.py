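#!/usr/bin/env python
"""Simulate the four study cohorts as ground-truthed SHG striation images.

One cohort per (age, group): fetal/adult x control/IUGR, 7 hearts x 3 images,
heart-level geometry drawn at the group configurations (SL 1.658/1.531 µm
fetal, 1.720/1.626 µm adult, with matching ABL, TTIL and SDs).  Images are
written as 16-bit TIFFs under scratch/cohorts/ (large, regenerable); the
per-heart ground truth and the image manifest go to results/.

Run from the repository root:  python analysis/01_simulate_cohorts.py [--seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

from sarcoshg.benchmarks import single_group_cohort_spec
from sarcoshg.io import write_image, write_manifest, write_truth
from sarcoshg.simulate import simulate_cohort

GROUPS = [("fetal", "control"), ("fetal", "iugr"), ("adult", "control"), ("adult", "iugr")]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("scratch/cohorts"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    manifest_rows, truth_frames = [], []
    for i, (age, group) in enumerate(GROUPS):
        spec = single_group_cohort_spec(age, group, seed=args.seed + 10 * i)
        cohort = simulate_cohort(spec)
        outdir = args.out / f"{age}_{group}"
        outdir.mkdir(parents=True, exist_ok=True)
        n = 0
        for heart in cohort.hearts:
            for image, truth in heart.images:
                write_image(outdir / f"{image.id}.tif", image)
                write_truth(outdir / f"{image.id}.truth.csv", truth)
                manifest_rows.append(
                    {
                        "heart_id": heart.heart_id,
                        "group": heart.group,
                        "age": heart.age,
                        "pair_id": heart.pair_id,
                        "image_path": str(Path(f"{age}_{group}") / f"{image.id}.tif"),
                    }
                )
                n += 1
        truth_frames.append(cohort.heart_truth())
        print(f"{age} {group}: {len(cohort.hearts)} hearts, {n} images -> {outdir}")

    write_manifest(args.out / "manifest.csv", pd.DataFrame(manifest_rows))
    truth = pd.concat(truth_frames, ignore_index=True)
    truth.to_csv(args.results / "cohort_truth.csv", index=False)
    print(f"wrote {len(manifest_rows)} images; heart truth -> {args.results}/cohort_truth.csv")


if __name__ == "__main__":
    main()
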
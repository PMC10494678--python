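"""Random-intercept trend models and the multivariable TMN models.

Fits, with health regions as the observational unit, a biennial-trend
random-intercept regression for each displacement and health indicator,
then the three TMN models (biennium only; + distance; + all indicators).
Writes tidy coefficient tables to results/trend_fits.csv and
results/tmn_models.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

import neonet as nn
from neonet import io as nio

ROOT = Path(__file__).resolve().parents[1]

RESPONSES = ["m_j", "pct_displaced", "tmn", "pct_low_weight", "pct_ga_lt28",
             "pct_apgar5_le7", "pct_maternal_35plus", "nicu_beds_per_1000"]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    summary = nio._read(args.out / "region_summary.csv",
                        ["region_id", "biennium_label", "tmn"])
    labels = sorted(summary["biennium_label"].unique())
    summary["biennium_index"] = summary["biennium_label"].map(
        {lab: i + 1 for i, lab in enumerate(labels)})

    frames = []
    print("biennial trends (slope [95% CI] per biennium):")
    for response in RESPONSES:
        fit = nn.fit_trend(summary, response)
        est, lo, hi = fit.fixed_effects["biennium"]
        direction = ("decreasing" if hi < 0 else
                     "increasing" if lo > 0 else "flat")
        print(f"  {response:<22} {est:+.3f} [{lo:+.3f}; {hi:+.3f}]  {direction}")
        frame = fit.to_frame()
        frame.insert(0, "response", response)
        frames.append(frame)
    nio.write_csv(pd.concat(frames, ignore_index=True).round(4),
                  args.out / "trend_fits.csv")

    frames = []
    print("TMN models:")
    for m in (1, 2, 3):
        fit = nn.fit_tmn_model(summary, model=m)
        est, lo, hi = fit.fixed_effects["biennium"]
        print(f"  model {m}: biennium effect {est:+.3f} [{lo:+.3f}; {hi:+.3f}]"
              f" (converged={fit.converged})")
        frame = fit.to_frame()
        frame.insert(0, "model", m)
        frames.append(frame)
    nio.write_csv(pd.concat(frames, ignore_index=True).round(4),
                  args.out / "tmn_models.csv")
    print(f"tables -> {args.out / 'trend_fits.csv'}, "
          f"{args.out / 'tmn_models.csv'}")


if __name__ == "__main__":
    main()
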
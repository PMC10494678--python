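"""Select neonatal admissions and build the origin-destination table.

Applies the 0-27-day age filter, splits records into same-municipality /
displaced / out-of-state, reports the out-of-state share, and aggregates
displaced in-state admissions into one flow per (origin, destination,
biennium).  Writes results/od_pairs.csv.
"""

import argparse
from pathlib import Path

import neonet as nn
from neonet import io as nio

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    registry = nio.read_registry(args.data / "registry.csv")
    hosp = nio.read_hospitalizations(args.data / "hospitalizations.csv")
    neo = nn.filter_neonatal(hosp)
    displaced, same, oos, share = nn.partition_displaced(neo, registry)
    od = nn.aggregate_od(displaced)
    nio.write_csv(od, args.out / "od_pairs.csv")

    print(f"admissions: {len(hosp):,}; neonatal (0-27 d): {len(neo):,}")
    print(f"displaced in-state: {len(displaced):,}; same municipality: "
          f"{len(same):,}; out of state: {len(oos):,} "
          f"({100 * share:.2f}% of displaced admissions)")
    flows = od.groupby("biennium_label")["flow"].sum()
    pairs = od.groupby("biennium_label").size()
    for label in flows.index:
        print(f"  {label}: {flows[label]:>7,} displaced admissions over "
              f"{pairs[label]:,} distinct OD pairs")
    print(f"OD table ({len(od):,} rows) -> {args.out / 'od_pairs.csv'}")


if __name__ == "__main__":
    main()
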
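"""Generate the synthetic state and administrative record tables.

Writes the municipality registry (22 health regions in 4 macroregions,
one seat each), hospitalization, live-birth, death and NICU-bed tables
under results/data/, plus a GeoJSON of municipality seats.
"""

import argparse
from pathlib import Path

import neonet as nn
from neonet import io as nio

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "data")
    args = ap.parse_args()

    params = nn.SynthParams(seed=args.seed)
    tables = nn.generate_dataset(params)
    for name, df in tables.items():
        nio.write_csv(df, args.out / f"{name}.csv")
    nio.registry_to_geojson(tables["registry"], args.out / "registry.geojson")

    reg = tables["registry"]
    print(f"registry: {len(reg)} municipalities, "
          f"{reg['is_region_seat'].sum()} region seats, "
          f"{reg['macroregion'].nunique()} macroregions")
    print(f"hospitalizations: {len(tables['hospitalizations']):,} "
          f"({params.year_start}-{params.year_end})")
    print(f"live births: {len(tables['births']):,}; "
          f"deaths: {len(tables['deaths']):,}; "
          f"bed rows: {len(tables['beds']):,}")
    print(f"tables written to {args.out}")


if __name__ == "__main__":
    main()
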
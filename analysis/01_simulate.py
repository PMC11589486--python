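"""Generate the six-cultivar synthetic seasonal dataset.

Writes per-cultivar season tables (date, replicate, oil %FW, mean R/G/B)
plus a handful of rendered image fixtures with ground-truth masks, and
prints the dataset dimensions and oil ranges so the downstream steps have a
documented starting point.
"""

import sys
from pathlib import Path

import numpy as np

from oleohyst import default_cultivars, generate_dataset, write_dataset

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main():
    config = default_cultivars()
    tables, _ = generate_dataset(config, seed=SEED, with_images=False)
    # a small image subset is enough to exercise the segmentation stage
    small = [p.with_(n_dates=4, replicates=1) for p in config[:2]]
    img_tables, fixtures = generate_dataset(small, seed=SEED, with_images=True)

    outdir = OUT / "simulated"
    write_dataset(tables, {}, outdir)
    write_dataset(img_tables, fixtures, outdir / "fixtures")

    print(f"seed {SEED}: simulated {len(tables)} cultivars -> {outdir}")
    for name, t in tables.items():
        print(
            f"  {name:10s} rows={len(t):3d}  oil {t.oil.min():5.2f}-{t.oil.max():5.2f} %FW"
            f"  R {t.red.mean():6.1f}  G {t.green.mean():6.1f}  B {t.blue.mean():6.1f}"
        )
    n_img = sum(len(v) for v in fixtures.values())
    print(f"  + {n_img} image fixtures (ground-truth masks) -> {outdir/'fixtures'}")


if __name__ == "__main__":
    main()
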
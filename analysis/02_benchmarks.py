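#!/usr/bin/env python
"""Solver verification: patch test, series-spring column, Kirsch plate.

Three problems with known answers establish that the trilinear-hexahedron
elasticity solver is implemented correctly before it is pointed at the
hole-spacing experiment:

* patch test: uniform stress state reproduced to machine precision;
* two-layer column (nu = 0): settlement matches the closed form;
* plate with circular hole: stress concentration approaches 3.0.

Writes results/benchmarks.json.
"""

import json
from pathlib import Path

from microfx.benchmarks import homogeneous_config, kirsch_benchmark, patch_test, two_layer_column

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    out = {
        "patch_test": patch_test(homogeneous_config()),
        "two_layer_column": two_layer_column(),
        "kirsch": {
            "fast": kirsch_benchmark(voxel_size=0.4),
            "refined": kirsch_benchmark(voxel_size=0.2),
        },
    }
    path = RESULTS / "benchmarks.json"
    path.write_text(json.dumps(out, indent=2))
    print(json.dumps(out, indent=2))
    print(f"\nwrote {path}")


if __name__ == "__main__":
    main()
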
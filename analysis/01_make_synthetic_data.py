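"""Generate the experimental-style target series used by later analyses.

Writes a Rao-style GC-count and total-volume series (rise to a peak around
day 10-15, contraction into the thirties) with antigen-decay ground truth,
plus a fixed-lifetime variant, under results/synthetic/.
"""

import json
from pathlib import Path

import numpy as np

from asyncgc.hypotheses import RAO_DECAY
from asyncgc.synthetic_data import (
    DEFAULT_TARGET_HILL,
    SyntheticTruth,
    generate_count_series,
    generate_volume_series,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20210709


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    for name, truth in {
        "decay": SyntheticTruth(hill=DEFAULT_TARGET_HILL, decay=RAO_DECAY),
        "fixed12": SyntheticTruth(hill=DEFAULT_TARGET_HILL, fixed_lifetime_days=12.0),
    }.items():
        count = generate_count_series(truth, rng)
        volume = generate_volume_series(truth, rng)
        count.to_csv(OUT / f"{name}_count.csv")
        volume.to_csv(OUT / f"{name}_volume.csv")
        sidecar = {
            "hill": truth.hill.model_dump(),
            "decay": truth.decay.model_dump() if truth.decay else None,
            "fixed_lifetime_days": truth.fixed_lifetime_days,
            "noise_sd": truth.noise_sd,
            "seed": SEED,
        }
        (OUT / f"{name}_truth.json").write_text(json.dumps(sidecar, indent=2) + "\n")
        print(f"{name}: peak count {count.values.max():.1f} at "
              f"day {count.times_days[count.values.argmax()]:.0f} -> {OUT}")


if __name__ == "__main__":
    main()
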
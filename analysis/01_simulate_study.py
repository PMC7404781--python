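#!/usr/bin/env python
"""Generate the synthetic screening study for both presets.

Writes the spectra (large) under scratch/data/ and a compact design summary
under results/.  Two presets are produced: "separable" (full adulterant
contrast) and "hard" (adulterant endmember pulled toward almond, so low
levels sit on the detection transition), each with apricot- and
peanut-adulterated validation sets over a shared pure-almond calibration.
"""

import sys
from pathlib import Path

import pandas as pd

from specocc.dataset import write_spectra_csv
from specocc.synthetic import generate_study, preset_design

SEED = 1


def main() -> int:
    data_dir = Path("scratch/data")
    results = Path("results")
    results.mkdir(exist_ok=True)
    rows = []
    for preset in ("separable", "hard"):
        for adulterant in ("apricot", "peanut"):
            design = preset_design(preset, adulterant=adulterant, seed=SEED)
            study = generate_study(design)
            for name, sset in study.items():
                path = data_dir / f"{preset}_{adulterant}_{name}.csv"
                write_spectra_csv(sset, path)
                meta = sset.meta
                rows.append({
                    "preset": preset,
                    "adulterant": adulterant,
                    "set": name,
                    "n_samples": sset.n_samples,
                    "n_wavenumbers": sset.n_points,
                    "n_pure": int((meta.class_label == "pure").sum()),
                    "levels": ",".join(
                        str(int(c)) for c in sorted(meta.concentration.unique())),
                })
                print(f"wrote {path}  ({sset.n_samples} x {sset.n_points})")
    summary = pd.DataFrame(rows)
    summary.to_csv(results / "study_design.csv", index=False)
    print("\nStudy design summary (results/study_design.csv):")
    print(summary.to_string(index=False))
    return 0


if __name__ == "__main__":
    sys.exit(main())
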
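#!/usr/bin/env python
"""Per-phase densitometry of the canonical phantom: the in-silico analogue
of identifying quartz, mature kerogen, and maghemite by mass density.

Runs the full quantification chain (segment -> 3-voxel erosion -> histogram
-> Gaussian fit -> air normalization -> density conversion -> candidate
matching) and writes a phase-identification table alongside the recovery
errors against the phantom's ground truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from pxct.experiments import recover_phase_densities


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--side", type=int, default=128)
    ap.add_argument("--out", type=Path, default=Path("results/densitometry"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    report, gt = recover_phase_densities(
        shape=(args.side,) * 3, seed=args.seed, output_dir=args.out / "pipeline"
    )
    rows = []
    for name, entry in report.phases.items():
        if entry.get("status") != "ok":
            continue
        row = {
            "phase": name,
            "electron_density_e_A3": entry["electron_density_e_A3"],
            "sigma_e_A3": entry["electron_density_sigma_e_A3"],
        }
        if "mass_density_g_cm3" in entry:
            truth = gt.true_density[name]
            row.update(
                mass_density_g_cm3=entry["mass_density_g_cm3"],
                sigma_g_cm3=entry["mass_density_sigma_g_cm3"],
                true_density_g_cm3=truth,
                recovery_error=abs(entry["mass_density_g_cm3"] / truth - 1),
                best_candidate=entry["candidate_ranking"][0]["name"],
                carbonaceous_class=entry.get("carbonaceous_class", ""),
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "phase_identification.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    iron = report.phases["maghemite"]["candidate_ranking"]
    print("\niron-oxide phase candidate ranking:",
          " > ".join(r["name"] for r in iron[:3]))


if __name__ == "__main__":
    main()
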
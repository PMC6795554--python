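#!/usr/bin/env python
"""Calibrate the three genotype parameter sets to the published whole-cell
measurements and write them to results/params/.

Each genotype is calibrated by round-trip search: simulate the activation,
inactivation and resurgent protocols on the reference cell, extract the
measured features, and root-find the parameter that reproduces each printed
target (activation/inactivation midpoints, persistent and resurgent % at
-30 mV, maximum peak transient amplitude).  The R853Q gating pore scale is
then set in closed form so that one nC of gating charge passes -118 nA at
-120 mV.

The parameter files shipped inside the package (src/navclamp/params/) were
produced by this script; pass --write-package to refresh them in place.
"""

import argparse
import json
import time
from pathlib import Path

from navclamp.calibrate import BASE_PARAMS, CalibrationTargets, calibrate_genotype
from navclamp.channel import Genotype, calibrate_gating_pore
from navclamp.targets import REPORTED


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/params"))
    ap.add_argument("--write-package", action="store_true",
                    help="also overwrite the shipped parameter files")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for g in (Genotype.WT, Genotype.R1882Q, Genotype.R853Q):
        r = REPORTED[g.value]
        targets = CalibrationTargets(
            act_v_half=r["act_v_half_mV"], inact_v_half=r["inact_v_half_mV"],
            persistent_pct=r["persistent_pct"], resurgent_pct=r["resurgent_pct"],
            max_peak_pA=r["max_peak_pA"])
        t0 = time.time()
        p, diag = calibrate_genotype(targets, BASE_PARAMS[g])
        if g is Genotype.R853Q:
            p = calibrate_gating_pore(p, r["gp_slope_nA_per_nC"])
        v = diag["verification"]
        print(f"{g.value} calibrated in {time.time() - t0:.0f} s:")
        print(f"  activation V1/2  {v['act_v_half']:8.2f} mV  (target {targets.act_v_half})")
        print(f"  inactivation V1/2 {v['inact_v_half']:7.2f} mV  (target {targets.inact_v_half})")
        print(f"  persistent %     {v['persistent_pct']:8.3f}    (target {targets.persistent_pct})")
        print(f"  resurgent %      {v['resurgent_pct']:8.3f}    (target {targets.resurgent_pct})")
        print(f"  max peak         {v['max_peak_pA']:8.0f} pA  (target {targets.max_peak_pA})")
        text = json.dumps(json.loads(p.model_dump_json()), indent=1, sort_keys=True)
        (args.out / f"{g.value.lower()}.json").write_text(text)
        if args.write_package:
            pkg = Path(__file__).resolve().parents[1] / "src/navclamp/params"
            (pkg / f"{g.value.lower()}.json").write_text(text)
    print(f"parameter files written to {args.out}")


if __name__ == "__main__":
    main()
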
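#!/usr/bin/env python
"""Design arithmetic of the capacitive coupling and bootstrapped front end.

Evaluates the analytic circuit model at the design component values:
coupling capacitance, capacitive reactance over the R-wave band,
bootstrapped and synthesized input impedance, divider gain, and the
effective clamp threshold.  Writes results/frontend_report.json.
"""

import json
from pathlib import Path

from capbio.frontend import frontend_report

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rep = frontend_report()
    print(f"coupling capacitance: {rep['coupling_capacitance_pF']:.1f} pF")
    print(f"bootstrap input impedance: {rep['bootstrap_impedance_Tohm']:.3f} "
          f"Tohm (clamped: {rep['bootstrap_impedance_clamped_Mohm']:.0f} Mohm)")
    print(f"synthesized with op-amp input: "
          f"{rep['synthesized_impedance_Tohm']:.2f} Tohm")
    for f, xc in rep["reactance_Mohm"].items():
        print(f"X_C at {f}: {xc:.0f} Mohm "
              f"(divider gain {rep['divider_gain'][f]:.6f})")
    print(f"effective clamp threshold: "
          f"{rep['effective_clamp_threshold_V']:.5f} V")
    (RESULTS / "frontend_report.json").write_text(json.dumps(rep, indent=1))
    print(f"wrote {RESULTS / 'frontend_report.json'}")


if __name__ == "__main__":
    main()
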
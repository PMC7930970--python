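#!/usr/bin/env python
"""Generate the three synthetic sessions the downstream analyses use.

Writes full signal tables to scratch/ (large) and a compact session
summary to results/sessions.json:

* ``clean``      - 2-min resting recording, noise-free capacitive channel
                   (the regime where detection should be perfect);
* ``distorted``  - same protocol with the T-dominant low-SNR profile
                   (T-wave > R-wave, HF attenuation, broadband noise);
* ``cough``      - full seven-cycle two-cough protocol with ground truth.
"""

import json
from pathlib import Path

from capbio.signal_core import write_annotations, write_signal_table
from capbio.synthetic import (CoughSimConfig, ECGSimConfig,
                              synth_cough_session, synth_ecg_session,
                              t_dominant_profile)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sessions"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    summary = {}

    for name, cfg in [("clean", ECGSimConfig(mean_hr=70.0, rr_sd=0.02,
                                             seed=SEED)),
                      ("distorted", t_dominant_profile(seed=SEED))]:
        ecg_ref, cecg, truth = synth_ecg_session(cfg, duration=120.0)
        write_signal_table(SCRATCH / f"{name}_signals.csv", [ecg_ref, cecg])
        summary[name] = {"duration_s": ecg_ref.duration,
                         "n_truth_beats": len(truth),
                         "r_amp_uV": cfg.r_amp * 1e6,
                         "t_amp_uV": cfg.t_amp * 1e6}
        print(f"{name}: {len(truth)} beats over {ecg_ref.duration:.0f} s "
              f"(R={cfg.r_amp * 1e6:.0f} uV, T={cfg.t_amp * 1e6:.0f} uV)")

    sess = synth_cough_session(ECGSimConfig(seed=SEED),
                               CoughSimConfig(seed=SEED))
    write_signal_table(SCRATCH / "cough_signals.csv", sess.channels)
    write_annotations(SCRATCH / "cough_annotations.csv", sess.annotations)
    summary["cough"] = {"duration_s": sess.emg_ref.duration,
                        "n_cycles": len(sess.truth_cycle_windows),
                        "n_bursts": len(sess.truth_burst_windows),
                        "n_truth_beats": len(sess.truth_rpeaks)}
    print(f"cough: {len(sess.truth_cycle_windows)} two-cough cycles, "
          f"{sess.emg_ref.duration:.0f} s")

    (RESULTS / "sessions.json").write_text(json.dumps(summary, indent=1))
    print(f"wrote {RESULTS / 'sessions.json'}")


if __name__ == "__main__":
    main()
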